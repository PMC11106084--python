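"""Decay-chain kinetics of the ²²⁴Ra daughter medium.

Closed-form Bateman solution for a linear chain with branching, the ²¹²Pb
buildup timeline under constant ²²⁰Rn feed, the alpha-emission inventory of
a daughter-medium (DM) exposure, and ²²⁴Ra activity decay-correction.

The Bateman coefficients are evaluated through divided differences of
``exp(-λt)``, which reduces to the textbook partial-fraction form for
distinct decay constants and to the confluent (polynomial × exponential)
form when decay constants coincide to within 1e-9 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclides import (
    ALPHA,
    NuclideSpec,
    PB212_HALF_LIFE_S,
    RA224_CHAIN,
    RA224_HALF_LIFE_S,
)

__all__ = [
    "ChainInventory",
    "AlphaEmissionInventory",
    "bateman_activities",
    "bateman_atoms",
    "pb212_buildup_fraction",
    "dm_alpha_inventory",
    "decay_correct_activity",
    "chain_inventory_series",
    "pb212_progeny_spectrum",
]

_CONFLUENT_RTOL = 1e-9


@dataclass
class ChainInventory:
    """Atom counts of every chain member at a common reference time."""

    time_s: float
    atoms: dict[str, float]
    chain: dict[str, NuclideSpec] = field(default_factory=lambda: RA224_CHAIN)

    def __post_init__(self) -> None:
        for name, n in self.atoms.items():
            if name not in self.chain:
                raise KeyError(f"unknown nuclide {name!r}")
            if n < 0:
                raise ValueError(f"negative atom count for {name}")

    @property
    def activities(self) -> dict[str, float]:
        """Activity in Bq per nuclide: λ·N."""
        return {
            name: self.chain[name].decay_constant * n
            for name, n in self.atoms.items()
        }

    @property
    def total_atoms(self) -> float:
        return sum(self.atoms.values())


@dataclass(frozen=True)
class AlphaEmissionInventory:
    """Alpha decays accumulated over an exposure window.

    ``spectrum`` lists (energy in MeV, fraction of all alphas); fractions
    sum to one.  ``per_volume`` is decays per cm³ when a volume was given.
    """

    total_alpha_decays: float
    spectrum: tuple[tuple[float, float], ...]
    per_volume: float | None = None

    def __post_init__(self) -> None:
        if not self.spectrum:
            raise ValueError("empty alpha spectrum")
        total = sum(f for _, f in self.spectrum)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum fractions sum to {total}, not 1")


def _exp_divided_difference(lams: list[float], t: float) -> float:
    """Divided difference of g(λ)=exp(-λt) over the given nodes.

    Nodes are sorted and snapped together when equal to within
    ``_CONFLUENT_RTOL`` relative, so that repeated nodes use the confluent
    limit g^(m)(λ)/m! = (-t)^m exp(-λt)/m!.
    """
    nodes = sorted(lams)
    snapped: list[float] = []
    for lam in nodes:
        if snapped and abs(lam - snapped[-1]) <= _CONFLUENT_RTOL * max(
            abs(lam), abs(snapped[-1]), 1e-300
        ):
            snapped.append(snapped[-1])
        else:
            snapped.append(lam)
    n = len(snapped)
    # dd[i] holds the divided difference over nodes i..i+k at sweep k
    dd = [math.exp(-lam * t) for lam in snapped]
    for k in range(1, n):
        for i in range(n - k):
            lo, hi = snapped[i], snapped[i + k]
            if lo == hi:  # all nodes in the span coincide (sorted + snapped)
                dd[i] = (-t) ** k * math.exp(-lo * t) / math.factorial(k)
            else:
                dd[i] = (dd[i + 1] - dd[i]) / (hi - lo)
        dd.pop()
    return dd[0]


def _accumulate_paths(
    chain: dict[str, NuclideSpec],
    path: list[str],
    branch_product: float,
    n0: float,
    t: float,
    out: dict[str, float],
) -> None:
    lams = [chain[name].decay_constant for name in path]
    k = len(path)
    rate_product = math.prod(lams[:-1])
    coeff = (
        n0
        * branch_product
        * rate_product
        * (-1.0) ** (k - 1)
        * _exp_divided_difference(lams, t)
    )
    tail = path[-1]
    out[tail] = out.get(tail, 0.0) + coeff
    if k > len(chain):  # acyclicity guard
        raise ValueError("decay chain contains a cycle")
    for mode in chain[tail].modes:
        if mode.daughter is not None and mode.branching > 0:
            _accumulate_paths(
                chain, path + [mode.daughter], branch_product * mode.branching,
                n0, t, out,
            )


def bateman_atoms(
    initial_atoms: dict[str, float],
    t: float,
    chain: dict[str, NuclideSpec] = RA224_CHAIN,
) -> dict[str, float]:
    """Atom counts after time ``t`` for a closed chain seeded by ``initial_atoms``."""
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    out = {name: 0.0 for name in chain}
    for seed, n0 in initial_atoms.items():
        if seed not in chain:
            raise KeyError(f"unknown nuclide {seed!r}")
        if n0 < 0:
            raise ValueError(f"negative atom count for {seed}")
        if n0 > 0:
            _accumulate_paths(chain, [seed], 1.0, n0, t, out)
    # clip the tiny negatives that finite-precision cancellation can leave
    return {name: max(n, 0.0) for name, n in out.items()}


def bateman_activities(initial: ChainInventory, t: float) -> ChainInventory:
    """Evolve a :class:`ChainInventory` forward by ``t`` seconds (closed form)."""
    atoms = bateman_atoms(initial.atoms, t, initial.chain)
    return ChainInventory(initial.time_s + t, atoms, initial.chain)


def chain_inventory_series(
    initial: ChainInventory, times_s
) -> pd.DataFrame:
    """Tidy time series (time_s, nuclide, atoms, activity_Bq) of the chain."""
    rows = []
    for t in np.asarray(times_s, dtype=float):
        inv = bateman_activities(initial, float(t))
        for name in inv.chain:
            rows.append(
                {
                    "time_s": inv.time_s,
                    "nuclide": name,
                    "atoms": inv.atoms.get(name, 0.0),
                    "activity_Bq": inv.activities.get(name, 0.0),
                }
            )
    return pd.DataFrame(rows)


def pb212_buildup_fraction(t_incubation_s: float) -> float:
    """²¹²Pb activity as a fraction of its asymptote under constant feed.

    With the source releasing ²²⁰Rn at a constant rate (the ²²⁴Ra half-life
    is long on this time scale), ²¹²Pb activity in the medium follows
    1 − exp(−λ_Pb t), reaching ~79% of the asymptote after 24 h — the
    "stabilizes in roughly one day" timeline.
    """
    if t_incubation_s < 0:
        raise ValueError("incubation time must be non-negative")
    lam = math.log(2.0) / PB212_HALF_LIFE_S
    return 1.0 - math.exp(-lam * t_incubation_s)


def pb212_progeny_spectrum(
    chain: dict[str, NuclideSpec] = RA224_CHAIN,
) -> tuple[tuple[float, float], ...]:
    """Alpha spectrum per ²¹²Pb decay with progeny in secular equilibrium.

    Every ²¹²Pb decay yields exactly one alpha: either the ²¹²Bi alpha
    (α branch) or, via the β branch, the ²¹²Po alpha.
    """
    lines: list[tuple[float, float]] = []
    for mode in chain["Bi-212"].modes:
        if mode.mode == ALPHA:
            lines.append((mode.alpha_energy_mev, mode.branching))
        else:  # beta branch feeds an alpha emitter (Po-212)
            daughter = chain[mode.daughter]
            for dm in daughter.modes:
                if dm.mode == ALPHA:
                    lines.append((dm.alpha_energy_mev, mode.branching * dm.branching))
    return tuple(lines)


def dm_alpha_inventory(
    a0_pb212_bq_per_ml: float,
    duration_s: float,
    volume_ml: float,
    dilution: float,
    chain: dict[str, NuclideSpec] = RA224_CHAIN,
) -> AlphaEmissionInventory:
    """Alpha-decay inventory of a daughter-medium exposure.

    The DM contains ²¹²Pb with ²¹²Bi/²¹²Po in secular equilibrium at the
    start of the exposure and no resupply, so the alpha emission rate tracks
    the decaying ²¹²Pb activity: total = dilution · A₀ · V / λ · (1 − e^{−λT}).
    """
    if not 0.0 < dilution <= 1.0:
        raise ValueError("dilution must lie in (0, 1]")
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    if duration_s <= 0:
        raise ValueError("exposure duration must be positive")
    if a0_pb212_bq_per_ml < 0:
        raise ValueError("activity concentration must be non-negative")
    lam = math.log(2.0) / PB212_HALF_LIFE_S
    total = (
        dilution * a0_pb212_bq_per_ml * volume_ml / lam
        * (1.0 - math.exp(-lam * duration_s))
    )
    return AlphaEmissionInventory(
        total_alpha_decays=total,
        spectrum=pb212_progeny_spectrum(chain),
        per_volume=total / volume_ml,  # 1 mL == 1 cm³
    )


def decay_correct_activity(a_ref_bq: float, dt_s: float) -> float:
    """Correct a ²²⁴Ra activity across a signed time offset.

    Positive ``dt_s`` moves forward in time (decay), negative backward
    (the correction of measured activities to the start of the source
    incubation).
    """
    if not (math.isfinite(a_ref_bq) and math.isfinite(dt_s)):
        raise ValueError("inputs must be finite")
    return a_ref_bq * 2.0 ** (-dt_s / RA224_HALF_LIFE_S)
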