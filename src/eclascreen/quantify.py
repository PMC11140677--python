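"""Spot-level fluorescence to per-clone, per-assay net signals.

Net signal is foreground minus background, unclipped: negative values are
retained so that downstream t statistics keep their distributional meaning
(clipping is an explicit opt-in).  Duplicate spots of a clone are averaged;
a flag-excluded spot drops out of the average, and a clone with both
duplicates excluded is marked missing rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrityError, SpotExcludedError
from .layout_io import ArrayLayout, ArrayScan, Role, SpotRecord

__all__ = [
    "CloneSignal",
    "net_intensity",
    "scan_net_frame",
    "aggregate_clone",
    "assemble_matrix",
    "pivot_matrix",
]

#: Columns of the tidy clone x assay table produced by :func:`assemble_matrix`.
MATRIX_COLUMNS = (
    "clone", "assay_id", "antibody", "condition", "batch", "net_intensity", "n_spots_used",
)


@dataclass(frozen=True)
class CloneSignal:
    """Aggregated net intensity of one clone in one assay."""

    clone: str
    assay_id: str
    net_intensity: float  # NaN when excluded
    n_spots_used: int
    excluded: bool

    def __post_init__(self) -> None:
        if self.n_spots_used not in (0, 1, 2):
            raise IntegrityError("n_spots_used must be 0, 1 or 2 for duplicate printing")
        if self.excluded != (self.n_spots_used == 0):
            raise IntegrityError("excluded must hold exactly when no spot survived")


def net_intensity(spot: SpotRecord) -> float:
    """Foreground minus background for a single non-excluded spot."""
    if spot.flag < 0:
        raise SpotExcludedError(
            f"spot ({spot.block},{spot.row},{spot.column}) is flag-excluded ({spot.flag})"
        )
    return float(spot.foreground) - float(spot.background)


def scan_net_frame(scan: ArrayScan, clip_negative: bool = False) -> pd.DataFrame:
    """Per-spot net intensities of a scan (vectorised); keeps role and flag columns."""
    frame = scan.spots.copy()
    frame["net"] = frame["foreground"] - frame["background"]
    if clip_negative:
        frame["net"] = frame["net"].clip(lower=0.0)
    return frame


def aggregate_clone(scan: ArrayScan, layout: ArrayLayout, clone: str) -> CloneSignal:
    """Mean net intensity over a clone's non-excluded duplicate spots."""
    if clone not in layout.replicate_groups:
        raise KeyError(f"clone {clone!r} not in layout")
    wanted = set(layout.replicate_groups[clone])
    frame = scan_net_frame(scan)
    mask = [
        (b, r, c) in wanted
        for b, r, c in zip(frame["block"], frame["row"], frame["column"])
    ]
    sub = frame.loc[mask]
    ok = sub.loc[sub["flag"] >= 0, "net"]
    n = int(len(ok))
    value = float(ok.mean()) if n else float("nan")
    return CloneSignal(clone, scan.assay_id, value, n, excluded=(n == 0))


def _wt_scale_factors(scans: list[ArrayScan]) -> dict[str, float]:
    """Per-scan multiplicative factors equalising WT-spot medians across scans."""
    medians = {}
    for scan in scans:
        frame = scan_net_frame(scan)
        wt = frame.loc[(frame["role"] == Role.WT_LYSATE) & (frame["flag"] >= 0), "net"]
        if wt.empty:
            raise IntegrityError(f"scan {scan.assay_id!r} has no WT spots to normalise on")
        medians[scan.assay_id] = float(wt.median())
    target = float(np.mean(list(medians.values())))
    return {aid: target / m for aid, m in medians.items()}


def assemble_matrix(
    scans: list[ArrayScan],
    layout: ArrayLayout,
    *,
    normalize: bool = False,
    clip_negative: bool = False,
) -> pd.DataFrame:
    """Build the tidy clone x assay table of duplicate-averaged net intensities.

    Every scan must occupy exactly the layout's grid.  The result has one row
    per (clone, assay) with assay metadata carried alongside; clones whose
    duplicates are all flag-excluded in a scan get ``net_intensity = NaN``.

    ``normalize`` applies optional per-array median scaling over WT spots
    (off by default; the screening statistics are scale-invariant anyway).
    """
    if not scans:
        raise IntegrityError("no scans given")
    grid = layout.grid_signature()
    for scan in scans:
        if scan.grid_signature() != grid:
            raise IntegrityError(
                f"scan {scan.assay_id!r} grid does not match the layout grid"
            )
    factors = _wt_scale_factors(scans) if normalize else None

    clone_of = {pos: name for name, group in layout.replicate_groups.items() for pos in group}
    chunks = []
    for scan in scans:
        frame = scan_net_frame(scan, clip_negative=clip_negative)
        keys = list(zip(frame["block"], frame["row"], frame["column"]))
        frame = frame.assign(clone=[clone_of.get(k) for k in keys])
        frame = frame.dropna(subset=["clone"])
        ok = frame.loc[frame["flag"] >= 0]
        grouped = ok.groupby("clone")["net"].agg(["mean", "count"])
        grouped = grouped.reindex(layout.clones)
        values = grouped["mean"].to_numpy(dtype=float)
        if factors is not None:
            values = values * factors[scan.assay_id]
        chunks.append(
            pd.DataFrame(
                {
                    "clone": layout.clones,
                    "assay_id": scan.assay_id,
                    "antibody": scan.antibody,
                    "condition": scan.condition,
                    "batch": scan.batch,
                    "net_intensity": values,
                    "n_spots_used": grouped["count"].fillna(0).astype(int).to_numpy(),
                }
            )
        )
    return pd.concat(chunks, ignore_index=True)


def pivot_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Wide clones x assays view of a tidy matrix (assay ids as columns)."""
    return matrix.pivot(index="clone", columns="assay_id", values="net_intensity")
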