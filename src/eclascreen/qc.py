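"""Array quality control: immobilisation, overexpression and reproducibility.

Three metrics summarise a lysate-array print run:

* **fraction above buffer** — in a total-protein stain (amine-reactive NHS
  ester), the proportion of lysate spots whose net intensity strictly
  exceeds the mean net intensity of lysis-buffer spots; measures how much
  lysate actually immobilised.
* **fraction above WT** — in an anti-His stain, the proportion of lysate
  spots strictly above the mean of WT-lysate spots (which carry no His
  tag); measures how many clones detectably overexpress their tagged ORF.
* **inter-batch R²** — squared Pearson correlation of per-clone net
  intensities between two independent assays of the same stain.

References are means of pooled control spots; "above" is a strict
inequality.  R² is computed on raw net intensities by default (a log10
option is provided); it is symmetric and invariant to affine rescaling of
either batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .layout_io import ArrayScan, Role
from .quantify import scan_net_frame

__all__ = [
    "QCReport",
    "qc_total_protein",
    "qc_overexpression",
    "qc_reproducibility",
    "fraction_above_reference",
]


@dataclass(frozen=True)
class QCReport:
    fraction_above_buffer: float
    buffer_reference: float
    fraction_above_wt: float
    wt_reference: float
    r_squared_batches: float
    n_spots_evaluated: int

    def __post_init__(self) -> None:
        for name in ("fraction_above_buffer", "fraction_above_wt", "r_squared_batches"):
            value = getattr(self, name)
            if not (np.isnan(value) or 0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name}={value} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _reference_and_fraction(scan: ArrayScan, reference_role: Role) -> tuple[float, float, int]:
    frame = scan_net_frame(scan)
    frame = frame.loc[frame["flag"] >= 0]
    ref_spots = frame.loc[frame["role"] == reference_role, "net"]
    lysate = frame.loc[frame["role"] == Role.LYSATE, "net"]
    if ref_spots.empty:
        raise ConfigurationError(
            f"scan {scan.assay_id!r} has no {reference_role.value} spots"
        )
    if lysate.empty:
        raise ConfigurationError(f"scan {scan.assay_id!r} has no lysate spots")
    reference = float(ref_spots.mean())
    fraction = float((lysate > reference).mean())
    return fraction, reference, int(len(lysate))


def qc_total_protein(scan: ArrayScan) -> tuple[float, float]:
    """(fraction of lysate spots strictly above the buffer mean, buffer mean)."""
    fraction, reference, _ = _reference_and_fraction(scan, Role.BUFFER)
    return fraction, reference


def qc_overexpression(scan: ArrayScan) -> tuple[float, float]:
    """(fraction of lysate spots strictly above the WT-lysate mean, WT mean).

    Meaningful on an anti-His scan, where WT lysates carry no His-tagged
    protein and provide the no-overexpression background.
    """
    fraction, reference, _ = _reference_and_fraction(scan, Role.WT_LYSATE)
    return fraction, reference


def fraction_above_reference(scan: ArrayScan, reference_role: Role) -> tuple[float, float, int]:
    """Generalised QC fraction; also reports the number of lysate spots used."""
    return _reference_and_fraction(scan, reference_role)


def qc_reproducibility(batch_a: pd.Series, batch_b: pd.Series, *, log: bool = False) -> float:
    """Squared Pearson correlation of per-clone net intensities across batches.

    ``batch_a`` and ``batch_b`` are clone-indexed series (e.g. one assay's
    column of the tidy matrix pivoted wide).  Only clones present and
    non-missing in both are used; fewer than 3 raises
    :class:`InsufficientDataError`.
    """
    joined = pd.concat({"a": batch_a, "b": batch_b}, axis=1, join="inner").dropna()
    if log:
        joined = joined[(joined > 0).all(axis=1)]
        joined = np.log10(joined)
    if len(joined) < 3:
        raise InsufficientDataError(
            f"need >= 3 common non-missing clones, got {len(joined)}"
        )
    r = stats.pearsonr(joined["a"], joined["b"]).statistic
    return float(r * r)
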