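"""Monte-Carlo alpha microdosimetry of a cell monolayer on a CR-39 detector.

Geometry: a water-equivalent medium slab occupies 0 < z < ``medium_depth``
with alpha emitters distributed uniformly throughout it (including the
nucleus volume).  A single cell nucleus — a right circular cylinder of the
measured mean area resting on the bottom plane — is the energy-scoring
target; the plane z = 0 is the CR-39 surface.  Tracks are straight CSDA
segments (no straggling or scattering); the etch-pit registration criterion
is the simplest SSNTD model: a pit registers when the dip angle of the
arriving track is at least ``critical_dip_angle`` (and, optionally, the
arrival energy falls inside an energy window).

Because every tally is linear in the emitter density, results are reported
per unit decay density (1 decay/cm³ over the exposure) alongside ratios
(hit-to-pit, dose per detected pit) that are density-free.  Absolute
per-nucleus tallies are produced when an experimental decay density is
supplied.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .decay import AlphaEmissionInventory
from .stopping import energy_after_pathlength, range_in_water

__all__ = [
    "GeometryConfig",
    "RegistrationModel",
    "TrackBatch",
    "TallyResult",
    "sample_decay_events",
    "chord_through_nucleus",
    "cr39_registers",
    "run_microdose",
    "dose_per_detected_pit",
    "mean_alpha_range_um",
    "mean_alpha_energy_mev",
    "analytic_registered_depth_um",
]

MEV_TO_J = 1.602176634e-13
UM_TO_CM = 1e-4
#: water density in g/cm³ (medium and nucleus treated as water)
RHO_G_CM3 = 1.0


@dataclass
class GeometryConfig:
    """Monolayer/CR-39 slab geometry.

    The nucleus is a right circular cylinder of ``nucleus_area_um2``
    footprint and ``nucleus_thickness_um`` height whose base sits at
    ``nucleus_base_z_um`` (0 = resting on the detector plane).  Lateral
    extent of the medium is effectively infinite (the sampling window is
    re-centered on the nucleus and sized to cover every track that can
    reach it).
    """

    medium_depth_um: float = 2000.0
    nucleus_area_um2: float = 280.0
    nucleus_thickness_um: float = 4.6
    nucleus_base_z_um: float = 0.0

    def __post_init__(self) -> None:
        if self.medium_depth_um <= 0 or self.nucleus_area_um2 <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.nucleus_thickness_um <= 0:
            raise ValueError("nucleus thickness must be positive")
        if self.nucleus_base_z_um < 0:
            raise ValueError("nucleus base must lie inside the medium")

    @property
    def nucleus_radius_um(self) -> float:
        return math.sqrt(self.nucleus_area_um2 / math.pi)

    @property
    def nucleus_volume_cm3(self) -> float:
        return self.nucleus_area_um2 * self.nucleus_thickness_um * UM_TO_CM**3


@dataclass
class RegistrationModel:
    """CR-39 etch-pit registration criterion.

    ``critical_dip_angle_deg`` is the dip angle (track inclination above
    the detector surface) below which no pit registers.  The default is
    calibrated so that the ensemble registration efficiency of
    plane-reaching alphas from a uniform-medium source lands inside the
    published 50–60% band.  ``energy_window_mev`` optionally restricts
    registration to an (E_min, E_max) arrival-energy window.
    """

    critical_dip_angle_deg: float = 40.8
    energy_window_mev: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.critical_dip_angle_deg < 90.0:
            raise ValueError("critical dip angle must lie in [0, 90)")
        if self.energy_window_mev is not None:
            lo, hi = self.energy_window_mev
            if not 0.0 <= lo < hi:
                raise ValueError("invalid energy window")


@dataclass
class TrackBatch:
    """A batch of alpha tracks (struct-of-arrays)."""

    origin: np.ndarray       # (N, 3) μm
    direction: np.ndarray    # (N, 3) unit vectors
    e0_mev: np.ndarray       # (N,)
    range_um: np.ndarray     # (N,)

    def __len__(self) -> int:
        return len(self.e0_mev)


def mean_alpha_range_um(spectrum) -> float:
    """Emission-weighted mean CSDA range R̄ of a line spectrum."""
    return float(sum(f * range_in_water(e) for e, f in spectrum))


def mean_alpha_energy_mev(spectrum) -> float:
    """Emission-weighted mean alpha energy Ē of a line spectrum."""
    return float(sum(f * e for e, f in spectrum))


def analytic_registered_depth_um(spectrum, model: RegistrationModel) -> float:
    """Closed-form registered-pit response of a uniform-medium source.

    For isotropic emitters of mean range R̄ distributed uniformly above the
    detector, the one-sided plane-crossing areal density is n_v·R̄/4 and a
    dip-angle cut at θ_c keeps the fraction 1 − sin²θ_c of crossings, so
    registered pits per unit area = n_v × R̄(1 − sin²θ_c)/4.  The return
    value is that response divided by n_v, in μm (multiply by n_v in μm⁻³
    and by an area in μm² to get expected pits).
    """
    if model.energy_window_mev is not None:
        raise NotImplementedError(
            "closed form only available without an energy window"
        )
    mu_c = math.sin(math.radians(model.critical_dip_angle_deg))
    return mean_alpha_range_um(spectrum) * (1.0 - mu_c**2) / 4.0


def _sim_bounds(
    inventory: AlphaEmissionInventory,
    geom: GeometryConfig,
    lateral_halfwidth_um: float | None,
    z_range_um: tuple[float, float] | None,
) -> tuple[float, float, float, float]:
    """Sampling window (half-width, z_lo, z_hi, max range).

    Emitters farther from the nucleus or the detector plane than the
    maximum alpha range contribute to no tally, so the default window
    covers exactly the region that can.
    """
    rmax = max(range_in_water(e) for e, _ in inventory.spectrum)
    if lateral_halfwidth_um is None:
        lateral_halfwidth_um = geom.nucleus_radius_um + rmax + 1.0
    if z_range_um is None:
        z_top = geom.nucleus_base_z_um + geom.nucleus_thickness_um + rmax
        z_hi = min(geom.medium_depth_um, max(z_top, rmax) + 2.0)
        z_range_um = (0.0, z_hi)
    z_lo, z_hi = z_range_um
    if not 0.0 <= z_lo < z_hi <= geom.medium_depth_um:
        raise ValueError("z range must lie inside the medium slab")
    return lateral_halfwidth_um, z_lo, z_hi, rmax


def sample_decay_events(
    inventory: AlphaEmissionInventory,
    geom: GeometryConfig,
    n: int,
    rng: np.random.Generator,
    lateral_halfwidth_um: float | None = None,
    z_range_um: tuple[float, float] | None = None,
) -> TrackBatch:
    """Draw ``n`` alpha tracks: uniform positions, isotropic directions,
    energies from the inventory spectrum."""
    if n <= 0:
        raise ValueError("n must be positive")
    hw, z_lo, z_hi, _ = _sim_bounds(inventory, geom, lateral_halfwidth_um, z_range_um)

    origin = np.empty((n, 3))
    origin[:, 0] = rng.uniform(-hw, hw, n)
    origin[:, 1] = rng.uniform(-hw, hw, n)
    origin[:, 2] = rng.uniform(z_lo, z_hi, n)

    cos_theta = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    direction = np.stack(
        (sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta), axis=1
    )

    energies = np.array([e for e, _ in inventory.spectrum])
    fracs = np.array([f for _, f in inventory.spectrum])
    idx = rng.choice(len(energies), size=n, p=fracs / fracs.sum())
    e0 = energies[idx]
    return TrackBatch(origin, direction, e0, np.asarray(range_in_water(e0)))


def chord_through_nucleus(
    batch: TrackBatch, geom: GeometryConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arc-length interval each track spends inside the nucleus cylinder.

    Returns ``(s_entry, s_exit, hit)`` with the interval clipped to
    [0, range]; a track whose origin lies inside the nucleus has
    ``s_entry = 0``.  ``hit`` is True where the clipped interval has
    positive length.
    """
    x0, y0, z0 = batch.origin.T
    dx, dy, dz = batch.direction.T
    r = geom.nucleus_radius_um
    zb = geom.nucleus_base_z_um
    zt = zb + geom.nucleus_thickness_um
    inf = np.inf

    # lateral (infinite cylinder) interval
    a = dx**2 + dy**2
    b = 2.0 * (x0 * dx + y0 * dy)
    c = x0**2 + y0**2 - r**2
    vertical = a < 1e-18
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = b**2 - 4.0 * a * c
        sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
        t1 = (-b - sqrt_disc) / (2.0 * a)
        t2 = (-b + sqrt_disc) / (2.0 * a)
    lat_lo = np.where(vertical, np.where(c < 0.0, -inf, inf), t1)
    lat_hi = np.where(vertical, np.where(c < 0.0, inf, -inf), t2)
    miss = (~vertical) & (disc <= 0.0)
    lat_lo = np.where(miss, inf, lat_lo)
    lat_hi = np.where(miss, -inf, lat_hi)

    # axial slab interval
    horizontal = np.abs(dz) < 1e-15
    with np.errstate(invalid="ignore", divide="ignore"):
        ta = (zb - z0) / dz
        tb = (zt - z0) / dz
    ax_lo = np.where(horizontal, np.where((z0 >= zb) & (z0 <= zt), -inf, inf),
                     np.minimum(ta, tb))
    ax_hi = np.where(horizontal, np.where((z0 >= zb) & (z0 <= zt), inf, -inf),
                     np.maximum(ta, tb))

    s_entry = np.maximum.reduce([lat_lo, ax_lo, np.zeros_like(lat_lo)])
    s_exit = np.minimum.reduce([lat_hi, ax_hi, batch.range_um])
    hit = s_exit > s_entry
    return np.where(hit, s_entry, np.nan), np.where(hit, s_exit, np.nan), hit


@dataclass
class _PlaneArrival:
    reaches: np.ndarray       # bool: reaches z=0 moving downward, residual E > 0
    registers: np.ndarray     # bool: passes the registration criterion
    dip_deg: np.ndarray
    arrival_e_mev: np.ndarray  # NaN where the plane is not reached
    impact_xy: np.ndarray      # (N, 2), NaN rows where not reached


def cr39_registers(batch: TrackBatch, model: RegistrationModel) -> _PlaneArrival:
    """Registration decision for every track in the batch.

    A track reaches the detector when it moves downward and its path length
    to z = 0 is strictly below its range (positive residual energy); it
    registers when additionally the dip angle is at least the critical dip
    angle and the arrival energy lies inside the energy window (when set).
    """
    z0 = batch.origin[:, 2]
    dz = batch.direction[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_plane = np.where(dz < 0.0, -z0 / dz, np.inf)
    reaches = (dz < 0.0) & (t_plane < batch.range_um)

    dip_deg = np.degrees(np.arcsin(np.clip(-dz, -1.0, 1.0)))
    arrival_e = np.full(len(batch), np.nan)
    if reaches.any():
        arrival_e[reaches] = energy_after_pathlength(
            batch.e0_mev[reaches], t_plane[reaches]
        )
    registers = reaches & (dip_deg >= model.critical_dip_angle_deg)
    if model.energy_window_mev is not None:
        lo, hi = model.energy_window_mev
        with np.errstate(invalid="ignore"):
            registers &= (arrival_e >= lo) & (arrival_e <= hi)
    impact = np.full((len(batch), 2), np.nan)
    if reaches.any():
        impact[reaches, 0] = (batch.origin[:, 0] + t_plane * batch.direction[:, 0])[reaches]
        impact[reaches, 1] = (batch.origin[:, 1] + t_plane * batch.direction[:, 1])[reaches]
    return _PlaneArrival(reaches, registers, dip_deg, arrival_e, impact)


@dataclass
class TallyResult:
    """Microdosimetry tallies, reported per decay and per unit decay density.

    ``*_per_nv`` quantities are normalized to a decay density of
    1 decay/cm³ integrated over the exposure; they scale linearly with the
    true density.  Absolute per-nucleus tallies are filled in when
    ``decay_density_cm3`` was supplied.
    """

    n_decays: int
    sim_volume_cm3: float
    lateral_area_cm2: float
    sim_depth_cm: float
    nucleus_area_cm2: float
    nucleus_mass_kg: float
    decay_density_cm3: float | None

    hit_rate: float = 0.0
    hit_rate_se: float = 0.0
    pit_rate: float = 0.0
    pit_rate_se: float = 0.0
    reach_rate: float = 0.0
    registration_efficiency: float = 0.0
    registration_efficiency_se: float = 0.0

    hits_per_nucleus_per_nv: float = 0.0
    hits_per_nucleus_per_nv_se: float = 0.0
    pits_per_nucleus_per_nv: float = 0.0
    pits_per_nucleus_per_nv_se: float = 0.0
    pits_in_footprint_per_nv: float = 0.0
    energy_per_nucleus_mev_per_nv: float = 0.0
    energy_per_nucleus_mev_per_nv_se: float = 0.0
    dose_gy_per_nv: float = 0.0
    dose_gy_per_nv_se: float = 0.0

    hit_to_pit_ratio: float = math.nan
    hit_to_pit_ratio_se: float = math.nan
    mean_energy_per_hit_mev: float = math.nan
    specific_energy_per_hit_gy: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )

    hits_per_nucleus: float | None = None
    hits_per_nucleus_se: float | None = None
    pits_per_nucleus: float | None = None
    pits_per_nucleus_se: float | None = None
    dose_gy: float | None = None
    dose_gy_se: float | None = None
    hits_per_exposure: np.ndarray | None = None

    _cov: dict | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def hits_histogram(self) -> np.ndarray | None:
        """Histogram (counts of exposures by hit number) when a decay
        density was supplied."""
        if self.hits_per_exposure is None or len(self.hits_per_exposure) == 0:
            return None
        return np.bincount(self.hits_per_exposure.astype(int))

    def to_dict(self) -> dict:
        out = {}
        for name in (
            "n_decays sim_volume_cm3 decay_density_cm3 hit_rate hit_rate_se "
            "pit_rate pit_rate_se reach_rate registration_efficiency "
            "registration_efficiency_se hits_per_nucleus_per_nv "
            "hits_per_nucleus_per_nv_se pits_per_nucleus_per_nv "
            "pits_per_nucleus_per_nv_se pits_in_footprint_per_nv "
            "energy_per_nucleus_mev_per_nv dose_gy_per_nv dose_gy_per_nv_se "
            "hit_to_pit_ratio hit_to_pit_ratio_se mean_energy_per_hit_mev "
            "hits_per_nucleus hits_per_nucleus_se pits_per_nucleus "
            "pits_per_nucleus_se dose_gy dose_gy_se"
        ).split():
            out[name] = getattr(self, name)
        out["warnings"] = list(self.warnings)
        hist = self.hits_histogram
        out["hits_histogram"] = None if hist is None else hist.tolist()
        return out


def run_microdose(
    inventory: AlphaEmissionInventory,
    geom: GeometryConfig,
    model: RegistrationModel,
    n_decays: int,
    seed: int | np.random.Generator,
    decay_density_cm3: float | None = None,
    batch_size: int = 2_000_000,
    lateral_halfwidth_um: float | None = None,
    z_range_um: tuple[float, float] | None = None,
) -> TallyResult:
    """Transport ``n_decays`` alpha tracks and tally hits, pits and dose.

    ``decay_density_cm3`` (decays per cm³ over the exposure window) turns
    the per-density rates into absolute per-nucleus tallies and groups the
    simulated decays into replicate exposures for the hits-per-nucleus
    histogram.
    """
    if n_decays < 1:
        raise ValueError("n_decays must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hw, z_lo, z_hi, rmax = _sim_bounds(inventory, geom, lateral_halfwidth_um, z_range_um)

    warn_list: list[str] = []
    if geom.medium_depth_um <= rmax:
        msg = (
            f"medium depth {geom.medium_depth_um} μm does not exceed the "
            f"maximum alpha range {rmax:.1f} μm; boundary tallies are biased"
        )
        _warnings.warn(msg, stacklevel=2)
        warn_list.append(msg)

    lateral_area_cm2 = (2.0 * hw * UM_TO_CM) ** 2
    sim_depth_cm = (z_hi - z_lo) * UM_TO_CM
    sim_volume_cm3 = lateral_area_cm2 * sim_depth_cm

    # accumulated per-decay sums for means and the (hit, pit, edep) covariance
    n_hit = n_pit = n_reach = n_foot = 0
    sum_e = sum_e2 = sum_hp = sum_he = sum_pe = sum_hp_joint = 0.0
    edep_hits: list[np.ndarray] = []

    exposure_size = None
    exposure_counts = None
    if decay_density_cm3 is not None and decay_density_cm3 > 0:
        exposure_size = max(int(round(decay_density_cm3 * sim_volume_cm3)), 1)
        n_exposures = n_decays // exposure_size
        exposure_counts = np.zeros(max(n_exposures, 0), dtype=np.int64)

    done = 0
    while done < n_decays:
        m = min(batch_size, n_decays - done)
        batch = sample_decay_events(
            inventory, geom, m, rng, lateral_halfwidth_um=hw,
            z_range_um=(z_lo, z_hi),
        )
        s_in, s_out, hit = chord_through_nucleus(batch, geom)
        arrival = cr39_registers(batch, model)

        edep = np.zeros(m)
        if hit.any():
            e_at_entry = energy_after_pathlength(batch.e0_mev[hit], s_in[hit])
            e_at_exit = energy_after_pathlength(batch.e0_mev[hit], s_out[hit])
            edep[hit] = e_at_entry - e_at_exit
            edep_hits.append(edep[hit])

        pit = arrival.registers
        foot = pit & (
            arrival.impact_xy[:, 0] ** 2 + arrival.impact_xy[:, 1] ** 2
            <= geom.nucleus_radius_um**2
        )

        n_hit += int(hit.sum())
        n_pit += int(pit.sum())
        n_reach += int(arrival.reaches.sum())
        n_foot += int(foot.sum())
        sum_e += float(edep.sum())
        sum_e2 += float((edep**2).sum())
        sum_hp_joint += float((hit & pit).sum())
        sum_he += float(edep[hit].sum())  # == sum_e; kept explicit
        sum_pe += float(edep[pit].sum())

        if exposure_counts is not None:
            ids = (done + np.arange(m)) // exposure_size
            valid = ids < len(exposure_counts)
            np.add.at(exposure_counts, ids[valid], hit[valid].astype(np.int64))
        done += m

    n = n_decays
    h_bar = n_hit / n
    p_bar = n_pit / n
    e_bar = sum_e / n

    var_h = h_bar * (1.0 - h_bar)
    var_p = p_bar * (1.0 - p_bar)
    var_e = max(sum_e2 / n - e_bar**2, 0.0)
    cov_hp = sum_hp_joint / n - h_bar * p_bar
    cov_pe = sum_pe / n - p_bar * e_bar

    nucleus_area_cm2 = geom.nucleus_area_um2 * UM_TO_CM**2
    mass_kg = geom.nucleus_volume_cm3 * RHO_G_CM3 * 1e-3

    res = TallyResult(
        n_decays=n,
        sim_volume_cm3=sim_volume_cm3,
        lateral_area_cm2=lateral_area_cm2,
        sim_depth_cm=sim_depth_cm,
        nucleus_area_cm2=nucleus_area_cm2,
        nucleus_mass_kg=mass_kg,
        decay_density_cm3=decay_density_cm3,
        warnings=warn_list,
    )
    res.hit_rate = h_bar
    res.hit_rate_se = math.sqrt(var_h / n)
    res.pit_rate = p_bar
    res.pit_rate_se = math.sqrt(var_p / n)
    res.reach_rate = n_reach / n
    if n_reach > 0:
        eff = n_pit / n_reach
        res.registration_efficiency = eff
        res.registration_efficiency_se = math.sqrt(eff * (1 - eff) / n_reach)

    res.hits_per_nucleus_per_nv = h_bar * sim_volume_cm3
    res.hits_per_nucleus_per_nv_se = res.hit_rate_se * sim_volume_cm3
    # registered pits per unit area per nv = p̄ × sim depth; per nucleus ×A
    res.pits_per_nucleus_per_nv = p_bar * sim_depth_cm * nucleus_area_cm2
    res.pits_per_nucleus_per_nv_se = res.pit_rate_se * sim_depth_cm * nucleus_area_cm2
    res.pits_in_footprint_per_nv = (n_foot / n) * sim_volume_cm3
    res.energy_per_nucleus_mev_per_nv = e_bar * sim_volume_cm3
    res.energy_per_nucleus_mev_per_nv_se = math.sqrt(var_e / n) * sim_volume_cm3
    res.dose_gy_per_nv = res.energy_per_nucleus_mev_per_nv * MEV_TO_J / mass_kg
    res.dose_gy_per_nv_se = res.energy_per_nucleus_mev_per_nv_se * MEV_TO_J / mass_kg

    if n_pit > 0 and n_hit > 0:
        ratio = res.hits_per_nucleus_per_nv / res.pits_per_nucleus_per_nv
        rel_var = (
            var_h / h_bar**2 + var_p / p_bar**2 - 2.0 * cov_hp / (h_bar * p_bar)
        ) / n
        res.hit_to_pit_ratio = ratio
        res.hit_to_pit_ratio_se = abs(ratio) * math.sqrt(max(rel_var, 0.0))
    if n_hit > 0:
        all_edep = np.concatenate(edep_hits)
        res.mean_energy_per_hit_mev = float(all_edep.mean())
        res.specific_energy_per_hit_gy = all_edep * MEV_TO_J / mass_kg
    res._cov = {
        "var_h": var_h, "var_p": var_p, "var_e": var_e,
        "cov_hp": cov_hp, "cov_pe": cov_pe,
        "h_bar": h_bar, "p_bar": p_bar, "e_bar": e_bar,
    }

    if decay_density_cm3 is not None:
        nv = decay_density_cm3
        res.hits_per_nucleus = nv * res.hits_per_nucleus_per_nv
        res.hits_per_nucleus_se = nv * res.hits_per_nucleus_per_nv_se
        res.pits_per_nucleus = nv * res.pits_per_nucleus_per_nv
        res.pits_per_nucleus_se = nv * res.pits_per_nucleus_per_nv_se
        res.dose_gy = nv * res.dose_gy_per_nv
        res.dose_gy_se = nv * res.dose_gy_per_nv_se
        res.hits_per_exposure = exposure_counts
    return res


def dose_per_detected_pit(
    tally: TallyResult,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Dose per detected pit (Gy) and hits per pit from a tally.

    Both are ratios of means, density-free; standard errors propagate by
    the delta method using the per-decay covariances accumulated during the
    run.
    """
    if tally.pits_per_nucleus_per_nv <= 0:
        raise ValueError("tally contains no registered pits")
    dose_per_pit = tally.dose_gy_per_nv / tally.pits_per_nucleus_per_nv
    hits_per_pit = tally.hit_to_pit_ratio

    c = tally._cov
    n = tally.n_decays
    if c is not None and c["p_bar"] > 0 and c["e_bar"] > 0:
        rel_var_dose = (
            c["var_e"] / c["e_bar"] ** 2
            + c["var_p"] / c["p_bar"] ** 2
            - 2.0 * c["cov_pe"] / (c["e_bar"] * c["p_bar"])
        ) / n
        dose_se = abs(dose_per_pit) * math.sqrt(max(rel_var_dose, 0.0))
    else:
        dose_se = math.nan
    return (dose_per_pit, dose_se), (hits_per_pit, tally.hit_to_pit_ratio_se)
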