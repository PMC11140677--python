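"""Forward-phase substrate calling for a purified kinase (±ATP contrast).

Each purified protein on the array is tested for elevated anti-pTyr signal
when the kinase reaction includes ATP: per protein, a two-tailed pooled
Student's t between the +ATP and −ATP replicate-assay means (p < alpha) and
an effect gate ``delta > k × SD_ref``, where ``delta`` is the +ATP minus
−ATP mean and ``SD_ref`` defaults to the protein's own −ATP replicate SD
(the no-kinase baseline).  The alternative reference — the SD of the
array-wide delta distribution — is available via ``sd_reference="delta_pool"``.
Hits are ranked by descending delta.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .layout_io import ArrayLayout, ArrayScan, layout_from_scan
from .quantify import assemble_matrix
from .screen import _t_arrays

__all__ = ["call_substrates", "SubstrateCaller"]

SUBSTRATE_COLUMNS = (
    "protein", "mean_plus_atp", "mean_minus_atp", "delta", "p_value",
    "pass_p", "pass_sd", "hit", "rank",
)


def call_substrates(
    matrix: pd.DataFrame,
    *,
    alpha: float = 0.05,
    k: float = 1.0,
    sd_reference: str = "minus_atp",
    welch: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Call kinase substrates from a tidy protein x assay ±ATP matrix.

    ``matrix`` must contain ``plus_ATP`` and ``minus_ATP`` condition assays
    (>= 2 replicates each).  Returns one row per protein ordered by
    descending delta; hits carry ranks 1..H in that order.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if sd_reference not in ("minus_atp", "delta_pool"):
        raise ConfigurationError(f"unknown sd_reference {sd_reference!r}")
    plus = matrix.loc[matrix["condition"] == "plus_ATP"].pivot(
        index="clone", columns="assay_id", values="net_intensity"
    )
    minus = matrix.loc[matrix["condition"] == "minus_ATP"].pivot(
        index="clone", columns="assay_id", values="net_intensity"
    )
    for label, block in (("plus_ATP", plus), ("minus_ATP", minus)):
        if block.shape[1] < 2:
            raise ConfigurationError(
                f"need >= 2 {label} replicate assays, got {block.shape[1]}"
            )
    minus = minus.reindex(plus.index)

    plus_arr = plus.to_numpy()
    minus_arr = minus.to_numpy()
    _, p, _, _ = _t_arrays(plus_arr, minus_arr, welch=welch)
    with np.errstate(invalid="ignore"):
        mean_plus = np.nanmean(plus_arr, axis=1)
        mean_minus = np.nanmean(minus_arr, axis=1)
    delta = mean_plus - mean_minus

    if sd_reference == "minus_atp":
        with np.errstate(invalid="ignore"):
            sd_ref = np.nanstd(minus_arr, axis=1, ddof=1)
    else:
        sd_ref = np.full(len(delta), float(np.nanstd(delta, ddof=1)))

    p_eval = p.copy()
    if bh:
        valid = ~np.isnan(p)
        adjusted = np.full_like(p, np.nan)
        if valid.any():
            adjusted[valid] = multipletests(p[valid], method="fdr_bh")[1]
        p_eval = adjusted

    with np.errstate(invalid="ignore"):
        pass_p = (p_eval < alpha) & ~np.isnan(p_eval)
        pass_sd = delta > k * sd_ref
    hit = pass_p & pass_sd

    records = pd.DataFrame(
        {
            "protein": plus.index,
            "mean_plus_atp": mean_plus,
            "mean_minus_atp": mean_minus,
            "delta": delta,
            "p_value": p,
            "pass_p": pass_p,
            "pass_sd": pass_sd,
            "hit": hit,
        }
    )
    records = records.sort_values(
        ["delta", "protein"], ascending=[False, True], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    rank = np.full(len(records), np.nan)
    rank[records["hit"].to_numpy()] = np.arange(1, int(records["hit"].sum()) + 1)
    records["rank"] = rank
    return records


class SubstrateCaller(BaseEstimator):
    """±ATP substrate screen over forward-phase proteome-array scans.

    Attributes after :meth:`fit`: ``records_`` (per-protein statistics
    ordered by delta), ``hits_`` (ordered hit protein list) and
    ``top_substrate_`` (the rank-1 hit, or None).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        k: float = 1.0,
        sd_reference: str = "minus_atp",
        welch: bool = False,
        bh: bool = False,
        normalize: bool = False,
    ):
        self.alpha = alpha
        self.k = k
        self.sd_reference = sd_reference
        self.welch = welch
        self.bh = bh
        self.normalize = normalize

    def fit(self, scans: Sequence[ArrayScan], layout: ArrayLayout | None = None):
        scans = list(scans)
        if layout is None:
            layout = layout_from_scan(scans[0])
        matrix = assemble_matrix(scans, layout, normalize=self.normalize)
        self.records_ = call_substrates(
            matrix,
            alpha=self.alpha,
            k=self.k,
            sd_reference=self.sd_reference,
            welch=self.welch,
            bh=self.bh,
        )
        self.matrix_ = matrix
        hits = self.records_.loc[self.records_["hit"]]
        self.hits_ = hits["protein"].tolist()
        self.top_substrate_ = self.hits_[0] if self.hits_ else None
        return self
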