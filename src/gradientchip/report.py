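"""High-level analysis runs and file exports.

`run_distribution_analysis` is the design workflow: simulate each growth
factor's two-day single-loading diffusion-decay field on the default chip,
summarise it with the EC50 metrics, and identify the limiting factor of each
medium.  The export helpers write long-format CSV fields, JSON reports,
per-snapshot heatmaps and mid-width profile plots with the EC50 extent
marked.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .design import DistributionReport, distribution_report
from .device import (DAY, ChipGeometry, FeedingSchedule, GrowthFactor,
                     MediaComposition, MediaEvent, load_default_factors,
                     load_default_media)
from .transport import ConcentrationField, Grid, field_to_frame, simulate_factor

__all__ = [
    "DistributionAnalysis",
    "run_distribution_analysis",
    "save_field_csv",
    "save_report_json",
    "save_heatmaps",
    "save_profile_plot",
    "write_manifest",
    "MEDIA_FED_END",
]

# Which end of the chip feeds each default medium: the vasculogenic /
# stromal side is the left end, the adipogenic side the right end.
MEDIA_FED_END: dict[str, str] = {
    "vascular": "left",
    "stromal": "left",
    "adipogenic_initiation": "right",
    "adipogenic_maturation": "right",
}

_GROUP_MEDIA = {
    "vascular": "vascular",
    "stromal": "stromal",
    "adipogenic": "adipogenic_initiation",
}


@dataclass(frozen=True)
class DistributionAnalysis:
    """Per-factor distribution reports plus per-medium limiting factors."""

    reports: Mapping[str, DistributionReport]
    fields: Mapping[str, ConcentrationField]
    limiting: Mapping[str, str]  # medium name -> factor name
    geometry: ChipGeometry

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "factor": r.factor,
                "fed_end": r.fed_end,
                "ec50_ng_ml": r.ec50,
                "max_distance_mm": r.max_distance,
                "time_of_max_h": r.time_of_max / 3600.0,
            }
            for r in self.reports.values()
        ]
        return pd.DataFrame(rows)


def run_distribution_analysis(
    factors: Mapping[str, GrowthFactor] | None = None,
    media: Mapping[str, MediaComposition] | None = None,
    *,
    geometry: ChipGeometry | None = None,
    grid: Grid | None = None,
    duration: float = 2 * DAY,
    snapshot_interval: float = 1800.0,
) -> DistributionAnalysis:
    """Two-day single-loading distribution simulation of every factor.

    Each factor's medium is loaded once at t = 0 into its own end of the chip
    (vasculogenic/stromal media on the left, adipogenic on the right) and the
    reservoir then decays by half-life for the rest of the run — the
    configuration used to size the chip's counter-current gradients.  The
    limiting factor of each medium is the one whose bioactive reach from its
    own end is shortest.
    """
    factors = factors if factors is not None else load_default_factors()
    media = media if media is not None else load_default_media()
    geometry = geometry if geometry is not None else ChipGeometry()
    grid = grid if grid is not None else Grid.for_geometry(geometry)

    reports: dict[str, DistributionReport] = {}
    fields: dict[str, ConcentrationField] = {}
    for name, gf in factors.items():
        medium = _GROUP_MEDIA.get(gf.group)
        fed_end = MEDIA_FED_END.get(medium, "left") if medium else "left"
        comp = (media[medium] if medium in (media or {})
                else MediaComposition(name, {name: gf.supplemented_conc}))
        schedule = FeedingSchedule(
            (MediaEvent(0.0, (fed_end,), "full", comp),), duration=duration)
        field = simulate_factor(gf, geometry, schedule, grid=grid,
                                duration=duration,
                                snapshot_interval=snapshot_interval,
                                factors=factors)
        reports[name] = distribution_report(field, gf.ec50, geometry, fed_end)
        fields[name] = field

    limiting: dict[str, str] = {}
    for medium_name, comp in media.items():
        simulated = [f for f in comp.factors if f in reports]
        if simulated:
            limiting[medium_name] = min(
                simulated, key=lambda f: reports[f].max_distance)
    return DistributionAnalysis(reports=reports, fields=fields,
                                limiting=limiting, geometry=geometry)


# -- exports ----------------------------------------------------------------

def save_field_csv(field: ConcentrationField, path: str | Path) -> None:
    """Long-format (time_h, x_mm, y_mm, factor, concentration) CSV."""
    field_to_frame(field).to_csv(path, index=False)


def save_report_json(analysis: DistributionAnalysis, path: str | Path) -> None:
    payload = {
        "factors": {
            name: {
                "fed_end": r.fed_end,
                "ec50_ng_ml": r.ec50,
                "max_distance_mm": round(r.max_distance, 4),
                "time_of_max_h": r.time_of_max / 3600.0,
            }
            for name, r in analysis.reports.items()
        },
        "limiting_factors": dict(analysis.limiting),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def save_heatmaps(field: ConcentrationField, outdir: str | Path,
                  *, max_snapshots: int = 12) -> list[Path]:
    """Per-snapshot concentration heatmaps (PNG), snapshot times in hours."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = len(field.times)
    idx = np.unique(np.linspace(0, n - 1, min(max_snapshots, n)).astype(int))
    vmax = float(field.values.max()) or 1.0
    paths = []
    for i in idx:
        fig, ax = plt.subplots(figsize=(6, 1.6))
        im = ax.imshow(field.values[i], origin="lower", aspect="equal",
                       vmin=0, vmax=vmax, cmap="viridis",
                       extent=(0, field.grid.nx * field.grid.spacing,
                               0, field.grid.ny * field.grid.spacing))
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        t_h = field.times[i] / 3600.0
        ax.set_title(f"{field.factor} at {t_h:.1f} h")
        fig.colorbar(im, ax=ax, label="ng/mL")
        p = outdir / f"{field.factor}_{t_h:06.1f}h.png"
        fig.savefig(p, dpi=110, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths


def save_profile_plot(field: ConcentrationField, ec50: float,
                      geometry: ChipGeometry, fed_end: str,
                      path: str | Path) -> None:
    """Mid-width concentration profiles per hour with the EC50 extent marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .design import max_distribution

    x = field.grid.x_centers
    mid = field.grid.ny // 2
    hours = field.times / 3600.0
    hourly = np.isclose(hours % 1.0, 0.0) & (hours > 0)
    fig, ax = plt.subplots(figsize=(6, 3.2))
    cmap = plt.get_cmap("viridis")
    sel = np.flatnonzero(hourly)
    for rank, i in enumerate(sel):
        ax.plot(x, field.values[i, mid, :],
                color=cmap(rank / max(1, len(sel) - 1)), lw=0.8)
    d, _ = max_distribution(field, ec50, geometry, fed_end)
    x_line = d if fed_end == "left" else geometry.length - d
    ax.axvline(x_line, color="crimson", ls="--", lw=1.2,
               label=f"EC50 extent ({d:.2f} mm)")
    ax.axhline(ec50, color="gray", ls=":", lw=1.0, label="EC50")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("concentration (ng/mL)")
    ax.set_title(f"{field.factor}, mid-width, hourly")
    ax.legend(frameon=False, fontsize=8)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def write_manifest(config: Mapping, outdir: str | Path, seed: int | None) -> Path:
    """Record what produced a run: config hash, package version, seed."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "package_version": __version__,
        "seed": seed,
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return p
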