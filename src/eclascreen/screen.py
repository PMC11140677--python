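"""Three-criterion kinase-candidate calling on lysate arrays.

A clone is called a candidate tyrosine kinase when, for a given
anti-phosphotyrosine antibody,

1. its per-assay mean net intensities differ between the experiment scans
   and the secondary-only blank scans at p < alpha (two-tailed pooled
   Student's t on the replicate-assay means; Welch available as an option);
2. its mean experiment signal exceeds the WT-lysate baseline by more than
   ``k`` WT standard deviations (``z_wt > k``, strict; the WT mean and SD
   are pooled over the WT spots of all experiment scans); and
3. — across antibodies — it is called by both antibodies
   (:func:`intersect_hits`).

Per-antibody hits are ranked by descending ``z_wt`` (ties by ascending p).
No multiple-testing correction is applied by default, matching the raw
p < 0.05 rule; Benjamini–Hochberg is available behind a flag.  The module
also provides the crystal-violet biofilm index OD540/OD600 with its
unpaired two-tailed t test.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientDataError
from .layout_io import ArrayLayout, ArrayScan, Role, layout_from_scan
from .quantify import assemble_matrix, scan_net_frame

__all__ = [
    "two_sample_t",
    "wt_baseline",
    "call_hits",
    "intersect_hits",
    "biofilm_index",
    "EclaScreen",
]

HIT_COLUMNS = (
    "clone", "antibody", "p_value", "z_wt", "exp_mean", "pass_p", "pass_sd", "hit", "rank",
)


# ---------------------------------------------------------------------------
# Student's t with degenerate-limit conventions
# ---------------------------------------------------------------------------

def _t_arrays(x: np.ndarray, y: np.ndarray, *, welch: bool = False):
    """Row-wise two-sample t over 2-D arrays (NaNs dropped per row).

    Returns (t, p, n_x, n_y).  Degenerate convention: when the pooled SD is
    zero, p is 1 for equal means and 0 for different means (the limit of the
    test as within-group variance vanishes).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nx = np.sum(~np.isnan(x), axis=1)
    ny = np.sum(~np.isnan(y), axis=1)
    with np.errstate(invalid="ignore"):
        mx = np.nanmean(x, axis=1)
        my = np.nanmean(y, axis=1)
        vx = np.nanvar(x, axis=1, ddof=1)
        vy = np.nanvar(y, axis=1, ddof=1)

    t = np.full(x.shape[0], np.nan)
    p = np.full(x.shape[0], np.nan)
    ok = (nx >= 2) & (ny >= 2)

    if welch:
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = vx / nx + vy / ny
            t_ok = (mx - my) / np.sqrt(se2)
            df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
            t_ok = (mx - my) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
            df = (nx + ny - 2).astype(float)

    zero_sp = ok & np.isclose(vx, 0.0) & np.isclose(vy, 0.0)
    finite = ok & ~zero_sp
    t[finite] = t_ok[finite]
    p[finite] = 2.0 * stats.t.sf(np.abs(t_ok[finite]), df[finite])
    equal = zero_sp & (mx == my)
    sep = zero_sp & (mx != my)
    t[equal] = 0.0
    p[equal] = 1.0
    t[sep] = np.sign((mx - my)[sep]) * np.inf
    p[sep] = 0.0
    return t, p, nx, ny


def two_sample_t(
    group_x: Sequence[float], group_y: Sequence[float], *, welch: bool = False
) -> tuple[float, float]:
    """Two-tailed two-sample Student's t (pooled variance) between two groups.

    Returns ``(t_statistic, p_value)``; p comes from the t distribution with
    ``n_x + n_y - 2`` degrees of freedom.  Zero-variance conventions: equal
    constant groups give p = 1, separated constant groups give p = 0.

    Raises :class:`InsufficientDataError` if either group has fewer than two
    observations.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if np.sum(~np.isnan(x)) < 2 or np.sum(~np.isnan(y)) < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    t, p, _, _ = _t_arrays(x[None, :], y[None, :], welch=welch)
    return float(t[0]), float(p[0])


# ---------------------------------------------------------------------------
# WT baseline and hit calling
# ---------------------------------------------------------------------------

def wt_baseline(
    scans: Iterable[ArrayScan],
    *,
    antibody: str | None = None,
    condition: str = "experiment",
) -> tuple[float, float]:
    """Pooled mean and sample SD of WT-lysate spot net intensities.

    Pools the non-excluded WT spots of every scan matching ``antibody`` (if
    given) and ``condition``; each contributing scan must carry at least two
    WT spots.
    """
    pooled: list[np.ndarray] = []
    for scan in scans:
        if scan.condition != condition:
            continue
        if antibody is not None and scan.antibody != antibody:
            continue
        frame = scan_net_frame(scan)
        wt = frame.loc[
            (frame["role"] == Role.WT_LYSATE) & (frame["flag"] >= 0), "net"
        ].to_numpy()
        if len(wt) < 2:
            raise InsufficientDataError(
                f"scan {scan.assay_id!r} has {len(wt)} usable WT spots (need >= 2)"
            )
        pooled.append(wt)
    if not pooled:
        raise InsufficientDataError(
            f"no scans with condition={condition!r}"
            + (f", antibody={antibody!r}" if antibody else "")
        )
    values = np.concatenate(pooled)
    return float(values.mean()), float(values.std(ddof=1))


def call_hits(
    matrix: pd.DataFrame,
    antibody: str,
    wt_mean: float,
    wt_sd: float,
    *,
    alpha: float = 0.05,
    k: float = 1.5,
    welch: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Apply the p-value and WT-SD criteria to one antibody's clone matrix.

    ``matrix`` is the tidy clone x assay table (see
    :func:`eclascreen.quantify.assemble_matrix`).  Per clone, the p-value
    contrasts the experiment-assay means against the secondary-only blanks;
    ``z_wt = (mean experiment signal - wt_mean) / wt_sd``.  A clone is a hit
    iff p < alpha and z_wt > k (strict).  The returned frame is ordered hits
    first by rank (descending z_wt, ties by ascending p), then non-hits by
    the same key; non-hits have no rank.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    sub = matrix.loc[matrix["antibody"] == antibody]
    exp = sub.loc[sub["condition"] == "experiment"].pivot(
        index="clone", columns="assay_id", values="net_intensity"
    )
    ctl = sub.loc[sub["condition"] == "control_no_primary"].pivot(
        index="clone", columns="assay_id", values="net_intensity"
    )
    for label, block in (("experiment", exp), ("control_no_primary", ctl)):
        if block.shape[1] < 2:
            raise ConfigurationError(
                f"antibody {antibody!r}: need >= 2 {label} assays, got {block.shape[1]}"
            )
    ctl = ctl.reindex(exp.index)

    _, p, nx, ny = _t_arrays(exp.to_numpy(), ctl.to_numpy(), welch=welch)
    exp_mean = np.nanmean(exp.to_numpy(), axis=1)
    if wt_sd > 0:
        z = (exp_mean - wt_mean) / wt_sd
    else:  # degenerate noise-free baseline: any elevation is infinitely many SDs
        diff = exp_mean - wt_mean
        z = np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf)

    p_eval = p.copy()
    if bh:
        valid = ~np.isnan(p)
        adjusted = np.full_like(p, np.nan)
        if valid.any():
            adjusted[valid] = multipletests(p[valid], method="fdr_bh")[1]
        p_eval = adjusted

    with np.errstate(invalid="ignore"):
        pass_p = (p_eval < alpha) & ~np.isnan(p_eval)
        pass_sd = z > k
    hit = pass_p & pass_sd

    records = pd.DataFrame(
        {
            "clone": exp.index,
            "antibody": antibody,
            "p_value": p,
            "z_wt": z,
            "exp_mean": exp_mean,
            "pass_p": pass_p,
            "pass_sd": pass_sd,
            "hit": hit,
        }
    )
    records = records.sort_values(
        ["hit", "z_wt", "p_value", "clone"],
        ascending=[False, False, True, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    rank = np.full(len(records), np.nan)
    rank[: int(records["hit"].sum())] = np.arange(1, int(records["hit"].sum()) + 1)
    records["rank"] = rank
    return records


def intersect_hits(hits_a: pd.DataFrame, hits_b: pd.DataFrame) -> list[str]:
    """Clones called by both antibodies, ordered by their better rank.

    Ties on the better rank break by the worse rank, then by clone name, so
    the order is deterministic and symmetric in the two arguments.
    """
    def _ranks(records: pd.DataFrame) -> dict[str, float]:
        hits = records.loc[records["hit"]]
        return dict(zip(hits["clone"], hits["rank"]))

    ra, rb = _ranks(hits_a), _ranks(hits_b)
    common = set(ra) & set(rb)
    return sorted(
        common,
        key=lambda c: (min(ra[c], rb[c]), max(ra[c], rb[c]), c),
    )


def biofilm_index(
    od540: Sequence[float],
    od600: Sequence[float],
    grouping: Sequence[str],
) -> tuple[dict[str, np.ndarray], float]:
    """Crystal-violet biofilm index OD540/OD600 per replicate, by group.

    Returns the per-group ratio arrays and the unpaired two-tailed Student's
    t p-value between the two groups (e.g. IPTG-induced vs uninduced).
    """
    od540 = np.asarray(od540, dtype=float)
    od600 = np.asarray(od600, dtype=float)
    labels = np.asarray(list(grouping))
    if od540.shape != od600.shape or od540.shape != labels.shape:
        raise ConfigurationError("od540, od600 and grouping must have equal length")
    if np.any(od600 <= 0):
        raise ValueError("od600 values must be > 0")
    ratios = od540 / od600
    groups = {str(g): ratios[labels == g] for g in pd.unique(labels)}
    if len(groups) != 2:
        raise ConfigurationError(f"need exactly 2 groups, got {len(groups)}")
    (ga, gb) = groups.values()
    _, p = two_sample_t(ga, gb)
    return groups, p


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class EclaScreen(BaseEstimator):
    """Three-criterion candidate-kinase screen over a set of array scans.

    Parameters
    ----------
    alpha : float
        Significance level for the experiment-vs-blank t-test.
    k : float
        WT-SD multiplier; a hit needs ``z_wt > k`` (strict).
    antibodies : tuple of str
        Anti-phosphotyrosine channels to screen and intersect.
    welch : bool
        Use Welch's t instead of pooled Student's t.
    bh : bool
        Benjamini–Hochberg-adjust p-values per antibody before thresholding.
    normalize : bool
        Per-array WT-median scaling before statistics (off by default).

    Attributes (after :meth:`fit`)
    ------------------------------
    records_ : DataFrame of per-clone statistics for all antibodies.
    per_antibody_hits_ : dict antibody -> ordered hit/record frame.
    intersection_ : ordered list of clones called by every antibody.
    wt_stats_ : dict antibody -> (wt_mean, wt_sd).
    n_clones_ : number of clones screened.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        k: float = 1.5,
        antibodies: tuple[str, ...] = ("pTyr100", "PY20"),
        welch: bool = False,
        bh: bool = False,
        normalize: bool = False,
    ):
        self.alpha = alpha
        self.k = k
        self.antibodies = antibodies
        self.welch = welch
        self.bh = bh
        self.normalize = normalize

    def fit(self, scans: Sequence[ArrayScan], layout: ArrayLayout | None = None):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k <= 0:
            raise ConfigurationError(f"k must be > 0, got {self.k}")
        scans = list(scans)
        if layout is None:
            layout = layout_from_scan(scans[0])
        matrix = assemble_matrix(scans, layout, normalize=self.normalize)

        self.wt_stats_: dict[str, tuple[float, float]] = {}
        self.per_antibody_hits_: dict[str, pd.DataFrame] = {}
        frames = []
        for antibody in self.antibodies:
            wt_mean, wt_sd = wt_baseline(scans, antibody=antibody, condition="experiment")
            records = call_hits(
                matrix, antibody, wt_mean, wt_sd,
                alpha=self.alpha, k=self.k, welch=self.welch, bh=self.bh,
            )
            self.wt_stats_[antibody] = (wt_mean, wt_sd)
            self.per_antibody_hits_[antibody] = records
            frames.append(records)

        self.records_ = pd.concat(frames, ignore_index=True)
        self.matrix_ = matrix
        self.n_clones_ = len(layout.clones)
        ordered = list(self.antibodies)
        inter = self.per_antibody_hits_[ordered[0]]
        intersection: list[str] | None = None
        for antibody in ordered[1:]:
            intersection = intersect_hits(inter, self.per_antibody_hits_[antibody])
            inter = inter.loc[inter["clone"].isin(intersection)]
        if intersection is None:  # single-antibody screen
            hits = self.per_antibody_hits_[ordered[0]]
            intersection = hits.loc[hits["hit"], "clone"].tolist()
        self.intersection_ = intersection
        return self
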