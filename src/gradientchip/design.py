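"""EC50-based design metrics for simulated growth-factor fields.

A chamber cell is *bioactive* for a factor when its concentration is at or
above the factor's EC50.  From a time-resolved concentration field these
metrics summarise how far and for how long a supplement usefully reaches:

* ``bioactive_fraction`` — fraction of the culture area above EC50, per
  snapshot;
* ``distribution_distance`` — furthest extent from the fed end (along the
  chamber length, at any transverse position) that is bioactive;
* ``max_distribution`` — the maximum of that distance over the culture and
  the earliest snapshot achieving it;
* ``limiting_factor`` — the factor in a medium with the shortest maximum
  distribution, i.e. the one that constrains where that medium acts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .device import ChipGeometry
from .transport import ConcentrationField, SimulationResult

__all__ = [
    "DistributionReport",
    "bioactive_fraction",
    "distribution_distance",
    "max_distribution",
    "limiting_factor",
    "distribution_report",
]


@dataclass(frozen=True)
class DistributionReport:
    """Distribution summary of one factor over one simulation.

    ``max_distance`` is in mm from the fed end, ``time_of_max`` in seconds,
    ``bioactive_fraction`` and ``ec50_extent`` are per-snapshot arrays
    (fraction of culture area above EC50 and the furthest bioactive extent
    in mm, respectively).
    """

    factor: str
    fed_end: str
    ec50: float
    max_distance: float
    time_of_max: float
    bioactive_fraction: np.ndarray
    ec50_extent: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_distance):
            raise ValueError("max_distance must be non-negative")
        bf = np.asarray(self.bioactive_fraction)
        if bf.size and (bf.min() < 0 or bf.max() > 1):
            raise ValueError("bioactive fractions must lie in [0, 1]")


def bioactive_fraction(field: ConcentrationField, ec50: float) -> np.ndarray:
    """Fraction of culture-area cells with C >= EC50, one value per snapshot."""
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    return (field.values >= ec50).mean(axis=(1, 2))


def distribution_distance(
    snapshot: np.ndarray,
    ec50: float,
    grid_spacing: float,
    geometry: ChipGeometry,
    fed_end: str = "left",
    *,
    mid_width_only: bool = False,
) -> float:
    """Furthest bioactive extent (mm) from the fed end in one snapshot.

    The extent is measured along the chamber length to the far edge of the
    furthest cell that is bioactive at *any* transverse position (or only at
    mid-width with ``mid_width_only=True``), so full coverage reads as the
    full compartment length; 0 if no cell is bioactive.
    """
    if fed_end not in ("left", "right"):
        raise ValueError("fed_end must be left|right")
    snap = np.asarray(snapshot)
    if mid_width_only:
        snap = snap[snap.shape[0] // 2: snap.shape[0] // 2 + 1]
    bioactive_cols = (snap >= ec50).any(axis=0)
    if not bioactive_cols.any():
        return 0.0
    x = (np.arange(snap.shape[1]) + 0.5) * grid_spacing
    if fed_end == "right":
        x = geometry.length - x
    return float(x[bioactive_cols].max() + 0.5 * grid_spacing)


def max_distribution(
    field: ConcentrationField,
    ec50: float,
    geometry: ChipGeometry,
    fed_end: str = "left",
    *,
    mid_width_only: bool = False,
) -> tuple[float, float]:
    """Maximum distribution distance over all snapshots and its earliest time.

    Returns ``(max_distance_mm, time_of_max_s)``; the time is reported at
    snapshot resolution and is the earliest snapshot attaining the maximum.
    """
    if len(field.times) < 2:
        raise ValueError("need at least two snapshots")
    dists = np.array([
        distribution_distance(field.values[i], ec50, field.grid.spacing,
                              geometry, fed_end, mid_width_only=mid_width_only)
        for i in range(len(field.times))
    ])
    i_max = int(np.argmax(dists))  # argmax returns the earliest tie
    return float(dists[i_max]), float(field.times[i_max])


def distribution_report(
    field: ConcentrationField,
    ec50: float,
    geometry: ChipGeometry,
    fed_end: str = "left",
) -> DistributionReport:
    """Full distribution summary for one factor's simulated field."""
    frac = bioactive_fraction(field, ec50)
    extent = np.array([
        distribution_distance(field.values[i], ec50, field.grid.spacing,
                              geometry, fed_end)
        for i in range(len(field.times))
    ])
    d, t = max_distribution(field, ec50, geometry, fed_end)
    return DistributionReport(
        factor=field.factor, fed_end=fed_end, ec50=ec50,
        max_distance=d, time_of_max=t,
        bioactive_fraction=frac, ec50_extent=extent,
    )


def limiting_factor(
    result: SimulationResult,
    ec50s: dict[str, float],
    side: str,
) -> str:
    """Name of the factor fed from ``side`` with the smallest maximum extent.

    The limiting factor of a medium is the supplement that stops being
    bioactive closest to its own end — it bounds the region where the full
    medium is effective.
    """
    candidates = [
        name for name, fed in result.fed_from.items()
        if fed == side or fed == "both"
    ]
    if not candidates:
        raise ValueError(f"no factor is fed from {side!r}")
    best_name, best_d = None, np.inf
    for name in candidates:
        fed = result.fed_from[name] if result.fed_from[name] != "both" else side
        d, _ = max_distribution(result.fields[name], ec50s[name],
                                result.geometry, fed)
        if d < best_d:
            best_name, best_d = name, d
    assert best_name is not None
    return best_name
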