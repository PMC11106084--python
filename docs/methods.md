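# Methods

This note documents the models behind `dartdose`, the parameters that
matter, the calibration of the free parameters, and what the synthetic
data do and do not establish.

## Decay-chain kinetics

The ²²⁴Ra chain is carried as an embedded nuclide table (NuDat3-keyed
half-lives, branching fractions and alpha energies), overridable from a
YAML file:

| nuclide | T½ | decay | alpha energy |
|---|---|---|---|
| ²²⁴Ra | 3.631 d | α → ²²⁰Rn | 5.685 MeV |
| ²²⁰Rn | 55.6 s | α → ²¹⁶Po | 6.288 MeV |
| ²¹⁶Po | 0.145 s | α → ²¹²Pb | 6.778 MeV |
| ²¹²Pb | 10.64 h | β → ²¹²Bi | — |
| ²¹²Bi | 60.55 min | α 35.94% → ²⁰⁸Tl; β 64.06% → ²¹²Po | 6.05 MeV (doublet merged) |
| ²¹²Po | 299 ns | α → ²⁰⁸Pb | 8.785 MeV |
| ²⁰⁸Tl | 3.053 min | β → ²⁰⁸Pb | — |

(The 0.145 s member of this chain is ²¹⁶Po; summaries occasionally
misprint it as "²²⁶Po", which does not occur here.)

Atom counts follow the closed-form Bateman solution for a linear chain
with branching, evaluated through divided differences of e^(−λt): for a
path λ₁…λ_k the Bateman sum equals (−1)^(k−1)·Π_{i<k}λ_i times the
divided difference over the nodes, which reduces to the textbook
partial-fraction form for distinct constants and to the confluent
(polynomial × exponential) limit when constants coincide.  Nodes within
1e-9 relative are snapped together before the table is built; this is the
documented degenerate-coefficient fallback.  The test oracle is an
independent stiff ODE integration (Radau, rtol 1e-10) of the same rate
equations; agreement is required to 4 significant digits despite decay
constants spanning 12 orders of magnitude (²¹²Po vs ²²⁴Ra).

The daughter-medium (DM) alpha inventory uses two model facts: ²¹²Bi and
²¹²Po are in secular equilibrium with ²¹²Pb when the exposure starts, and
each ²¹²Pb decay yields exactly one alpha — either the ²¹²Bi alpha
(branch 0.3594, 6.05 MeV) or, via the β branch, the ²¹²Po alpha (0.6406,
8.785 MeV).  Alphas emitted by ²²⁰Rn/²¹⁶Po during the 6 h DM preparation
decay away before the medium reaches the cells and are excluded from the
exposure inventory.  β/²⁰⁸Tl decays are carried in the chain but not
transported: the low-LET contribution to cell kill is treated as a
documented omission (it is negligible next to the alpha dose at these
exposure levels).  The ²¹²Pb activity of the medium under constant ²²⁰Rn
feed follows 1 − e^(−λ_Pb·t), i.e. 50% of the asymptote after one ²¹²Pb
half-life (10.64 h) and 79% after 24 h — the "stabilizes in roughly one
day" timeline.  The absolute ²¹²Pb concentration of the 1× DM is never
needed: it enters only through the measured pit counts (see calibration).

## Range–energy relation

Alpha CSDA ranges in liquid water are generated from a Bragg–Kleeman
power law R = a·E^b anchored exactly at the two field-standard ranges of
the DM lines, 47 μm at 6.05 MeV and 86 μm at 8.785 MeV (giving b ≈ 1.62).
The tabulation (161 points, 0–10 MeV) is interpolated with a monotone
PCHIP; the inverse map (range → energy) seeds from an inverse PCHIP and is
refined by three Newton steps on the forward interpolant so that the
residual-range semigroup property E(E(E₀,s₁),s₂) = E(E₀,s₁+s₂) holds to
better than 1e-6 MeV.  The implied LET at the two line energies is
~60–75 keV/μm, consistent with the 100–200 keV/μm scale quoted for alphas
near the end of their track.

## Monte-Carlo microdosimetry

**Geometry.**  Water-equivalent medium slab 0 < z < 2000 μm (ρ = 1 g/cm³)
above the CR-39 plane z = 0; a single nucleus modeled as a right circular
cylinder of footprint 280 μm² (radius 9.44 μm) resting on the plane.
Emitter positions are uniform in the slab *including the nucleus volume*;
directions are isotropic; energies are drawn from the two-line DM
spectrum.  Transport is straight-line CSDA — no straggling, scattering or
medium/cell composition contrast, all sub-percent effects at these
scales.  Because emitters farther than one range (86 μm) from both the
nucleus and the detector plane cannot score, the sampling window is
automatically clipped to the contributing region and all tallies are
normalized per unit decay density (1 decay/cm³ over the exposure); every
extensive tally is exactly linear in that density.

**Tallies.**  A *hit* is any track whose clipped path [0, R] intersects
the nucleus cylinder with positive chord length — this includes tracks
born inside, tracks that stop inside, and upward-moving tracks.  Energy
imparted per hit is E(entry) − E(exit), with E = 0 at the Bragg stop;
dose = energy × 1.602·10⁻¹³ J/MeV / (ρ·V).  A *detected pit* is a track
reaching z = 0 moving downward with positive residual energy whose dip
angle (inclination above the detector surface) is at least the critical
dip angle; pits per nucleus are computed as pit areal density × nucleus
area, matching how separately-acquired pit and nucleus images are merged
in the experiment, with the direct within-footprint tally kept as a
cross-check (the two agree within counting statistics).  Standard errors
come from per-decay indicator variances; ratio errors (hit-to-pit, dose
per pit) use the delta method with the accumulated covariances.

**Verification oracles.**  The MC is tested against closed forms for
isotropic finite-range tracks from uniform emitters: one-sided plane
crossings per area n_v·R̄/4; expected hits on a convex body
n_v·(V + R̄·S/4) (Cauchy's projection formula plus emitters born inside —
the V term is a 6% effect for the default nucleus and is part of the
exact expectation); charged-particle-equilibrium dose n_v·Ē/ρ for a
nucleus buried mid-slab; half that value for a thin scoring layer on the
non-emitting bottom boundary; Poisson hit statistics (variance/mean within
[0.9, 1.1]); and a 0.01 μm ray-marching oracle for the ray–cylinder
chord solver.  Chord agreement is required to 0.05 μm; fluence and dose
oracles to 2% (5% at the boundary).

**Free parameters and calibration.**  Two quantities are not fixed by
first principles: the *nucleus thickness* (monolayer nuclei are a few μm
tall, but no direct measurement accompanies the 280 μm² footprint) and
the *critical dip angle* (the etch-pit registration physics — etch-rate
ratios, removed-layer thickness — is deliberately reduced to a single
angular cut).  Both were calibrated once, on a coarse scan
(`analysis/02_microdosimetry.py --scan`), so that the simulation
reproduces the three published outputs simultaneously: registration
efficiency inside the 50–60% band, hit-to-pit ratio ≈3, and absorbed dose
at the measured 4.7 pits/nucleus inside 1.10 ± 0.23 Gy.  The frozen
defaults are **thickness 4.6 μm** and **critical dip angle 40.8°**
(ensemble efficiency 1 − sin²θ_c ≈ 0.57), giving hit-to-pit ≈ 3.2,
15.0 hits and ≈1.13 Gy at 4.7 pits/nucleus.  A 3 μm nucleus with the
same efficiency would put the hit-to-pit ratio at ≈2.75, at the edge of
the published ~3× statement, which is why the thicker default is used.
An optional arrival-energy registration window exists but is off by
default; with it off the registered-pit response has the closed form
n_v·R̄(1 − sin²θ_c)/4, used both as a test oracle and by the synthetic
generator.

## Calibration and survival fitting

Dilution calibrations are least-squares lines through the origin (zero
dose ⇒ zero excess response; sham-source background is supported but
defaults to zero).  The survival model is the one-parameter exponential:
ln SF regressed on dose through the origin, unweighted by default
(weights 1/SD² behind a flag), r² reported on the log scale, and the 95%
CI on k from the regression standard error.  D₀ = 1/k.  Pit-axis and
dose-axis fits are algebraically coherent: their slopes differ exactly by
the dose-per-pit factor.  Conversion uncertainties (pit SD, MC ratio SEs)
combine in quadrature at first order; a parametric bootstrap validates
the delta method within 5% in the tests.  Surviving fractions from colony
counts are SF = (colonies/plated)/PE with binomial standard errors;
replicate dishes are pooled before the fit.

## Synthetic experiments

The generator emulates the *statistical structure* of the real assay with
known truth: per-field pit counts Poisson with mean linear in dilution
(field area 98,826 μm²); per-nucleus focus counts Poisson — or
negative-binomial behind a dispersion flag, since the measured foci SD
(14.5 at mean 47.2) is over-dispersed — with mean = hits × foci-per-hit,
and nucleus areas Normal(280, 39) μm²; colony counts Binomial(plated,
PE·e^(−D/D₀)).  Defaults place the 1/2× limb at ≈4.7 pits and ≈47.2 foci
per nucleus (≈10 foci per detected pit, i.e. ≈3 foci per hit), with
D₀ = 0.196 Gy, PE = 0.7, dilutions 1×…1/8×, 5 fields, 50 nuclei and
3 dishes per limb, and plated cell numbers (2·10⁶ … 3·10³) chosen so each
limb scores a countable number of colonies.  The foci model is
phenomenological (foci ∝ hits), not a track-structure DSB model.

Not emulated: microscopy images, the spatial pit-density gradient around
a physical source (no governing spatial model is carried here), pit
overlap/saturation near a source, bystander effects, and beta/low-LET
transport.  Passing recovery tests therefore establishes that the
*analysis chain* is unbiased and correctly propagates uncertainty under
the assumed noise models — not that those models exhaust real-data
variability.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.Generator` seeded per run;
  identical (config, seed) reproduce tallies bit-for-bit.
- Default MC size is 10⁶ decays (seconds on one CPU); the verification
  oracles use 2–4·10⁶ where 2% tolerances demand it.  The acceptance
  script uses 2·10⁶.
- Degenerate inputs fail fast with explicit errors: negative times,
  dilutions outside (0, 1], SF ≤ 0, identical doses, zero pit slopes
  (conversion to dose is refused), zero registered pits.
- A medium shallower than the maximum alpha range triggers a mandatory
  warning (recorded in the tally) since boundary tallies are then biased.
- Grazing chords shorter than the 0.05 μm comparison tolerance are the
  only allowed disagreement between the chord solver and its marching
  oracle; they carry negligible energy.

## Known limitations

- The registration model compresses etch physics into one angular cut;
  it reproduces the ensemble efficiency band, not pit morphology or
  etch-time dynamics.
- CSDA ranges come from a two-anchor power-law parameterization rather
  than a full stopping-power evaluation; both anchors are reproduced
  exactly and intermediate energies are smooth and monotone, but values
  below ~1 MeV are extrapolated by the same law.
- Nucleus thickness is a calibrated effective parameter, not a
  measurement; dose scales weakly with it (energy and mass both grow
  with V), but the hit-to-pit ratio depends on it directly.
- Beta/²⁰⁸Tl dose is inventoried but never transported.
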