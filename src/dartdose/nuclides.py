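"""Nuclear data for the ²²⁴Ra decay chain.

The chain driving daughter-medium dosimetry is

    ²²⁴Ra -α→ ²²⁰Rn -α→ ²¹⁶Po -α→ ²¹²Pb -β→ ²¹²Bi
        ²¹²Bi -α (35.94%)→ ²⁰⁸Tl -β→ ²⁰⁸Pb (stable)
        ²¹²Bi -β (64.06%)→ ²¹²Po -α→ ²⁰⁸Pb (stable)

Half-lives, branching fractions and alpha energies are keyed to the NuDat3
evaluated values; the ²¹²Bi alpha doublet (6.051/6.090 MeV) is carried as a
single 6.05 MeV line.  The table is an ordinary data structure and can be
overridden from an editable YAML file (see :func:`load_nuclide_table`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

ALPHA = "alpha"
BETA = "beta"

#: seconds per unit, for half-life strings like "3.631 d"
_TIME_UNITS = {
    "s": 1.0,
    "ms": 1e-3,
    "us": 1e-6,
    "ns": 1e-9,
    "min": 60.0,
    "h": 3600.0,
    "d": 86400.0,
    "y": 365.25 * 86400.0,
}

_BRANCHING_TOL = 1e-12


def parse_half_life(text: str | float) -> float:
    """Parse a half-life given either in seconds or as ``"<value> <unit>"``."""
    if isinstance(text, (int, float)):
        return float(text)
    parts = text.split()
    if len(parts) == 1:
        return float(parts[0])
    if len(parts) != 2 or parts[1] not in _TIME_UNITS:
        raise ValueError(f"cannot parse half-life {text!r}")
    return float(parts[0]) * _TIME_UNITS[parts[1]]


@dataclass(frozen=True)
class DecayMode:
    """One decay branch: mode, branching fraction, daughter, alpha energy."""

    mode: str
    branching: float
    daughter: str | None
    alpha_energy_mev: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in (ALPHA, BETA):
            raise ValueError(f"unknown decay mode {self.mode!r}")
        if not 0.0 <= self.branching <= 1.0:
            raise ValueError("branching fraction must lie in [0, 1]")
        if self.mode == ALPHA:
            if self.alpha_energy_mev is None or self.alpha_energy_mev <= 0:
                raise ValueError("alpha modes require a positive alpha energy")


@dataclass(frozen=True)
class NuclideSpec:
    """A nuclide with its half-life and decay branches.

    Stable nuclides carry ``half_life_s = inf`` and an empty mode tuple.
    """

    name: str
    half_life_s: float
    modes: tuple[DecayMode, ...] = ()

    def __post_init__(self) -> None:
        if not self.half_life_s > 0:
            raise ValueError(f"{self.name}: half-life must be positive")
        if self.modes:
            total = sum(m.branching for m in self.modes)
            if abs(total - 1.0) > _BRANCHING_TOL:
                raise ValueError(
                    f"{self.name}: branching fractions sum to {total}, not 1"
                )

    @property
    def is_stable(self) -> bool:
        return not self.modes

    @property
    def decay_constant(self) -> float:
        """ln2 / T½ in s⁻¹ (0 for stable nuclides)."""
        if math.isinf(self.half_life_s):
            return 0.0
        return math.log(2.0) / self.half_life_s


def _chain() -> dict[str, NuclideSpec]:
    d = parse_half_life
    return {
        "Ra-224": NuclideSpec(
            "Ra-224", d("3.631 d"),
            (DecayMode(ALPHA, 1.0, "Rn-220", 5.685),),
        ),
        "Rn-220": NuclideSpec(
            "Rn-220", d("55.6 s"),
            (DecayMode(ALPHA, 1.0, "Po-216", 6.288),),
        ),
        "Po-216": NuclideSpec(
            "Po-216", d("0.145 s"),
            (DecayMode(ALPHA, 1.0, "Pb-212", 6.778),),
        ),
        "Pb-212": NuclideSpec(
            "Pb-212", d("10.64 h"),
            (DecayMode(BETA, 1.0, "Bi-212"),),
        ),
        "Bi-212": NuclideSpec(
            "Bi-212", d("60.55 min"),
            (
                DecayMode(ALPHA, 0.3594, "Tl-208", 6.05),
                DecayMode(BETA, 0.6406, "Po-212"),
            ),
        ),
        "Po-212": NuclideSpec(
            "Po-212", 2.99e-7,
            (DecayMode(ALPHA, 1.0, "Pb-208", 8.785),),
        ),
        "Tl-208": NuclideSpec(
            "Tl-208", d("3.053 min"),
            (DecayMode(BETA, 1.0, "Pb-208"),),
        ),
        "Pb-208": NuclideSpec("Pb-208", math.inf),
    }


#: default nuclide table, topologically ordered parent before daughter
RA224_CHAIN: dict[str, NuclideSpec] = _chain()

RA224_HALF_LIFE_S = RA224_CHAIN["Ra-224"].half_life_s
PB212_HALF_LIFE_S = RA224_CHAIN["Pb-212"].half_life_s


def load_nuclide_table(path) -> dict[str, NuclideSpec]:
    """Read a nuclide table from an editable YAML key-value file.

    Schema per nuclide::

        Pb-212:
          half_life: 10.64 h        # or seconds as a bare number
          modes:
            - {mode: beta, branching: 1.0, daughter: Bi-212}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table: dict[str, NuclideSpec] = {}
    for name, entry in raw.items():
        hl = entry.get("half_life", "inf")
        half_life = math.inf if hl in ("inf", "stable") else parse_half_life(hl)
        modes = tuple(
            DecayMode(
                m["mode"], float(m["branching"]), m.get("daughter"),
                m.get("alpha_energy_mev"),
            )
            for m in entry.get("modes", [])
        )
        table[name] = NuclideSpec(name, half_life, modes)
    return table


def dump_nuclide_table(table: dict[str, NuclideSpec], path) -> None:
    """Write a nuclide table in the format read by :func:`load_nuclide_table`."""
    raw = {}
    for name, spec in table.items():
        entry: dict = {
            "half_life": "inf" if math.isinf(spec.half_life_s) else spec.half_life_s
        }
        if spec.modes:
            entry["modes"] = [
                {
                    "mode": m.mode,
                    "branching": m.branching,
                    "daughter": m.daughter,
                    **(
                        {"alpha_energy_mev": m.alpha_energy_mev}
                        if m.alpha_energy_mev is not None
                        else {}
                    ),
                }
                for m in spec.modes
            ]
        raw[name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
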