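"""Finite-difference diffusion-decay solver for the chip culture compartment.

Each growth factor obeys

    dC/dt = D * (d2C/dx2 + d2C/dy2) + k * C

with k = ln(0.5)/t_half < 0, on the rectangular compartment.  Channel-segment
boundary cells are Dirichlet, clamped to the (decaying) reservoir
concentration of the factor; all other boundary is no-flux wall, implemented
with mirrored ghost cells.  The scheme is explicit forward-time
central-space (FTCS) with the step chosen automatically inside the stability
limit dt <= h^2/(4 D).

Distances here are in mm on the grid, concentrations in ng/mL, times in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .device import (
    ChipGeometry,
    FeedingSchedule,
    GrowthFactor,
    MediaComposition,
    ReservoirState,
    apply_media_event,
    reservoir_concentration,
)

MM_TO_UM = 1000.0

__all__ = ["Grid", "ConcentrationField", "SimulationResult",
           "simulate_factor", "simulate_media", "field_to_frame"]


@dataclass(frozen=True)
class Grid:
    """Cell-centered uniform grid over the culture compartment.

    x runs along the chamber length from the left end, y along the width from
    the bottom edge; cell (j, i) is centered at
    ``((i + 1/2) h, (j + 1/2) h)``.
    """

    spacing: float = 0.05  # mm
    nx: int = 158
    ny: int = 26

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid too coarse: need at least 2 cells per dimension")

    @classmethod
    def for_geometry(cls, geometry: ChipGeometry, spacing: float = 0.05) -> "Grid":
        nx = max(2, round(geometry.length / spacing))
        ny = max(2, round(geometry.width / spacing))
        return cls(spacing=spacing, nx=nx, ny=ny)

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.spacing

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.spacing


@dataclass(frozen=True)
class ConcentrationField:
    """Snapshots of one factor's concentration over the grid.

    ``values`` has shape ``(n_snapshots, ny, nx)`` in ng/mL; ``times`` are the
    snapshot times in seconds.
    """

    factor: str
    grid: Grid
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times), self.grid.ny, self.grid.nx):
            raise ValueError("values shape inconsistent with grid and times")

    def snapshot(self, index: int) -> np.ndarray:
        return self.values[index]


@dataclass(frozen=True)
class SimulationResult:
    """Per-factor concentration fields from one media-pair simulation."""

    fields: Mapping[str, ConcentrationField]
    geometry: ChipGeometry
    schedule: FeedingSchedule
    fed_from: Mapping[str, str] = field(default_factory=dict)  # factor -> end

    def __post_init__(self) -> None:
        grids = {f.grid for f in self.fields.values()}
        if len(grids) > 1:
            raise ValueError("all fields must share one grid")


def _segment_masks(
    geometry: ChipGeometry, grid: Grid
) -> dict[str, list[tuple[int, np.ndarray]]]:
    """Map reservoir -> list of (row index, x-column mask) of clamped edge cells."""
    x = grid.x_centers
    out: dict[str, list[tuple[int, np.ndarray]]] = {}
    for seg in geometry.segments:
        x0, x1 = seg.x_extent(geometry)
        cols = (x >= x0) & (x <= x1)
        row = grid.ny - 1 if seg.edge == "top" else 0
        out.setdefault(seg.reservoir, []).append((row, cols))
    return out


def _reservoir_timeline(
    schedule: FeedingSchedule,
    reservoir: str,
    factors: Mapping[str, GrowthFactor],
) -> list[tuple[float, ReservoirState]]:
    """Post-event reservoir states, time-ordered, for one reservoir."""
    state = ReservoirState(0.0, {})
    timeline: list[tuple[float, ReservoirState]] = []
    for event in schedule.events_for(reservoir):
        state = apply_media_event(state, event, factors)
        timeline.append((event.time, state))
    return timeline


def _boundary_value(
    timeline: Sequence[tuple[float, ReservoirState]],
    factor: GrowthFactor,
    t: float,
) -> float | None:
    """Reservoir concentration at time t, or None if the factor was never fed."""
    current: ReservoirState | None = None
    for t_ev, state in timeline:
        if t_ev <= t:
            current = state
        else:
            break
    if current is None or factor.name not in current.concentration_at_event:
        return None
    return reservoir_concentration(current, factor, t)


def simulate_factor(
    factor: GrowthFactor,
    geometry: ChipGeometry,
    schedule: FeedingSchedule,
    *,
    grid: Grid | None = None,
    duration: float | None = None,
    snapshot_interval: float = 1800.0,
    initial: np.ndarray | float = 0.0,
    clamp_boundaries: bool = True,
    factors: Mapping[str, GrowthFactor] | None = None,
    safety: float = 0.9,
) -> ConcentrationField:
    """Integrate the diffusion-decay equation for one factor.

    The interior starts at ``initial`` (fresh hydrogel: zero).  At every step
    each channel-segment edge cell whose reservoir media contains the factor
    is clamped to the decaying reservoir concentration; segments whose media
    never carried the factor act as walls.  Snapshots (including t = 0, taken
    before any clamping) are recorded every ``snapshot_interval`` seconds.

    ``clamp_boundaries=False`` disables all Dirichlet segments (all-wall
    chamber), which is useful for conservation and pure-decay checks.
    """
    if duration is None:
        duration = schedule.duration
    if duration <= 0:
        raise ValueError("duration must be positive")
    if grid is None:
        grid = Grid.for_geometry(geometry)
    if grid.ny < 2:
        raise ValueError("grid too coarse across the chamber width")

    h_um = grid.spacing * MM_TO_UM
    k = factor.decay_rate
    if factor.diffusivity > 0:
        dt_stable = safety * h_um * h_um / (4.0 * factor.diffusivity)
    else:
        dt_stable = snapshot_interval
    n_sub = max(1, int(np.ceil(snapshot_interval / dt_stable)))
    dt = snapshot_interval / n_sub
    alpha = factor.diffusivity * dt / (h_um * h_um)
    decay_factor = float(np.exp(k * dt))

    factors = factors if factors is not None else {factor.name: factor}
    masks = _segment_masks(geometry, grid) if clamp_boundaries else {}
    timelines = {
        rid: _reservoir_timeline(schedule, rid, factors) for rid in masks
    }

    c = np.full((grid.ny, grid.nx), float(initial) if np.isscalar(initial) else 0.0)
    if not np.isscalar(initial):
        c[:] = np.asarray(initial, dtype=float)

    def clamp(t: float) -> None:
        for rid, cells in masks.items():
            val = _boundary_value(timelines[rid], factor, t)
            if val is None:
                continue
            for row, cols in cells:
                c[row, cols] = val

    n_snap = int(np.floor(duration / snapshot_interval + 1e-9)) + 1
    times = np.arange(n_snap) * snapshot_interval
    values = np.empty((n_snap, grid.ny, grid.nx))
    values[0] = c

    pad = np.empty((grid.ny + 2, grid.nx + 2))
    t = 0.0
    for s in range(1, n_snap):
        for _ in range(n_sub):
            clamp(t)
            # mirrored ghost cells: zero normal gradient at every wall
            pad[1:-1, 1:-1] = c
            pad[0, 1:-1] = c[0]
            pad[-1, 1:-1] = c[-1]
            pad[1:-1, 0] = c[:, 0]
            pad[1:-1, -1] = c[:, -1]
            lap = (pad[1:-1, :-2] + pad[1:-1, 2:] + pad[:-2, 1:-1]
                   + pad[2:, 1:-1] - 4.0 * c)
            # explicit diffusion step, then exact first-order decay over dt
            c += alpha * lap
            c *= decay_factor
            t += dt
        clamp(t)
        values[s] = c
    np.clip(values, 0.0, None, out=values)
    return ConcentrationField(factor=factor.name, grid=grid,
                              times=times, values=values)


def simulate_media(
    media_pair: Mapping[str, MediaComposition],
    geometry: ChipGeometry,
    schedule: FeedingSchedule,
    *,
    factors: Mapping[str, GrowthFactor],
    grid: Grid | None = None,
    duration: float | None = None,
    snapshot_interval: float = 1800.0,
) -> SimulationResult:
    """Simulate every distinct factor present in a reservoir-to-media pair.

    ``media_pair`` maps reservoir id (``"left"``/``"right"``) to the media it
    carries; a factor supplied from both ends is simulated with both
    boundaries active.  Returns one field per distinct factor.
    """
    if not media_pair or all(not m.factors for m in media_pair.values()):
        raise ValueError("media pair supplies no factors")
    if grid is None:
        grid = Grid.for_geometry(geometry)

    names: list[str] = []
    fed_from: dict[str, str] = {}
    for rid, media in media_pair.items():
        for name in media.factors:
            if name not in names:
                names.append(name)
                fed_from[name] = rid
            elif fed_from.get(name) != rid:
                fed_from[name] = "both"
    missing = [n for n in names if n not in factors]
    if missing:
        raise KeyError(f"no GrowthFactor record for: {', '.join(missing)}")

    fields = {
        name: simulate_factor(
            factors[name], geometry, schedule, grid=grid, duration=duration,
            snapshot_interval=snapshot_interval, factors=factors,
        )
        for name in names
    }
    return SimulationResult(fields=fields, geometry=geometry,
                            schedule=schedule, fed_from=fed_from)


def field_to_frame(field_: ConcentrationField) -> pd.DataFrame:
    """Long-format table (time_h, x_mm, y_mm, factor, concentration)."""
    grid = field_.grid
    t, y, x = np.meshgrid(field_.times / 3600.0, grid.y_centers,
                          grid.x_centers, indexing="ij")
    return pd.DataFrame({
        "time_h": t.ravel(),
        "x_mm": x.ravel(),
        "y_mm": y.ravel(),
        "factor": field_.factor,
        "concentration_ng_ml": field_.values.ravel(),
    })
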