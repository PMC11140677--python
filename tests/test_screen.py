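"""The t statistic, WT baseline, three-criterion caller and biofilm index."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import eclascreen as ec
from eclascreen.errors import ConfigurationError, InsufficientDataError
from eclascreen.layout_io import Role
from eclascreen.screen import call_hits, intersect_hits
from conftest import manual_scan


# ---------------------------------------------------------------------------
# Student's t against an independent numerical-integration oracle
# ---------------------------------------------------------------------------

def _t_density(x, df):
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def _oracle_p(x, y):
    """Hand-computed pooled t plus numerically integrated two-tailed p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    tail, _ = quad(_t_density, abs(t), np.inf, args=(df,))
    return t, 2.0 * tail


def test_t_matches_integration_oracle_on_random_cases():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        nx, ny = rng.integers(2, 7, size=2)
        x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nx)
        y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), ny)
        t, p = ec.two_sample_t(x, y)
        t_ref, p_ref = _oracle_p(x, y)
        assert t == pytest.approx(t_ref, rel=1e-9)
        assert abs(p - p_ref) < 1e-6


def test_t_worked_example():
    t, p = ec.two_sample_t([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.6742346, rel=1e-6)
    assert p == pytest.approx(0.0213116, abs=1e-5)  # numerically integrated t tail, df=4


def test_t_degenerate_conventions():
    t, p = ec.two_sample_t([1, 2, 3], [1, 2, 3])
    assert (t, p) == (0.0, 1.0)
    t, p = ec.two_sample_t([0, 0, 0], [1, 1, 1])
    assert p == 0.0 and t == -np.inf
    t, p = ec.two_sample_t([5.0, 5.0], [5.0, 5.0])
    assert (t, p) == (0.0, 1.0)


def test_t_requires_two_per_group():
    with pytest.raises(InsufficientDataError):
        ec.two_sample_t([1.0], [1.0, 2.0])


def test_welch_differs_under_unequal_variance():
    x = [1.0, 1.1, 0.9, 1.05]
    y = [5.0, 9.0, 1.0, 13.0]
    _, p_student = ec.two_sample_t(x, y)
    _, p_welch = ec.two_sample_t(x, y, welch=True)
    assert p_welch != pytest.approx(p_student)


# ---------------------------------------------------------------------------
# WT baseline
# ---------------------------------------------------------------------------

def test_wt_baseline_mean_and_sd():
    scan = manual_scan(
        [
            (1, 1, 1, "WT", Role.WT_LYSATE, 190.0, 100.0),
            (1, 1, 2, "WT", Role.WT_LYSATE, 200.0, 100.0),
            (1, 1, 3, "WT", Role.WT_LYSATE, 210.0, 100.0),
        ],
        assay_id="wt", antibody="pTyr100", condition="experiment",
    )
    mean, sd = ec.wt_baseline([scan])
    assert mean == 100.0
    assert sd == pytest.approx(10.0)


def test_wt_baseline_rejects_single_spot():
    scan = manual_scan(
        [(1, 1, 1, "WT", Role.WT_LYSATE, 190.0, 100.0)],
        assay_id="wt", antibody="pTyr100", condition="experiment",
    )
    with pytest.raises(InsufficientDataError):
        ec.wt_baseline([scan])


def test_wt_baseline_noise_free_sim_has_zero_sd():
    cfg = ec.SimConfig(
        n_clones=20, n_blocks=2, block_columns=10,
        spot_cv=0.0, background_sd=0.0, batch_scale_sd=0.0, abundance_cv=0.0,
        antibodies=("pTyr100",), include_qc_channels=False, seed=1,
    )
    res = ec.simulate_ecla(cfg)
    mean, sd = ec.wt_baseline(res.scans, antibody="pTyr100")
    assert sd == 0.0
    assert mean == cfg.baseline_mean


# ---------------------------------------------------------------------------
# call_hits
# ---------------------------------------------------------------------------

def _matrix_from_values(values):
    """values: clone -> (experiment triple, blank triple)."""
    rows = []
    for clone, (exp, ctl) in values.items():
        for i, v in enumerate(exp):
            rows.append((clone, f"e{i}", "pTyr100", "experiment", f"r{i}", v, 2))
        for i, v in enumerate(ctl):
            rows.append((clone, f"c{i}", "pTyr100", "control_no_primary", f"r{i}", v, 2))
    return pd.DataFrame(
        rows,
        columns=["clone", "assay_id", "antibody", "condition", "batch",
                 "net_intensity", "n_spots_used"],
    )


def test_sd_gate_is_strictly_greater():
    matrix = _matrix_from_values({
        "edge": ((115.0, 115.0, 115.0), (0.0, 0.0, 0.0)),   # z_wt = 1.5 exactly
        "over": ((116.0, 116.0, 116.0), (0.0, 0.0, 0.0)),   # z_wt = 1.6
    })
    records = call_hits(matrix, "pTyr100", wt_mean=100.0, wt_sd=10.0).set_index("clone")
    assert records.loc["edge", "pass_p"] and not records.loc["edge", "pass_sd"]
    assert not records.loc["edge", "hit"]
    assert records.loc["over", "hit"]


def test_call_hits_scale_invariant():
    values = {
        f"c{i}": ((100.0 + i, 102.0 + i, 98.0 + i), (5.0, 6.0, 7.0)) for i in range(8)
    }
    values["kin"] = ((160.0, 158.0, 161.0), (5.0, 6.0, 7.0))
    matrix = _matrix_from_values(values)
    base = call_hits(matrix, "pTyr100", wt_mean=100.0, wt_sd=10.0)
    scaled = matrix.assign(net_intensity=matrix["net_intensity"] * 37.5)
    rescaled = call_hits(scaled, "pTyr100", wt_mean=3750.0, wt_sd=375.0)
    merged = base.merge(rescaled, on="clone", suffixes=("_a", "_b"))
    assert (merged["hit_a"] == merged["hit_b"]).all()
    assert merged["z_wt_a"].to_numpy() == pytest.approx(merged["z_wt_b"].to_numpy())


def test_adding_signal_never_unmakes_a_hit():
    values = {"kin": ((160.0, 158.0, 161.0), (5.0, 6.0, 7.0)),
              "null": ((100.0, 101.0, 99.0), (5.0, 6.0, 7.0))}
    matrix = _matrix_from_values(values)
    before = call_hits(matrix, "pTyr100", wt_mean=100.0, wt_sd=10.0).set_index("clone")
    assert before.loc["kin", "hit"]
    boosted = matrix.copy()
    sel = (boosted["clone"] == "kin") & (boosted["condition"] == "experiment")
    boosted.loc[sel, "net_intensity"] += 500.0
    after = call_hits(boosted, "pTyr100", wt_mean=100.0, wt_sd=10.0).set_index("clone")
    assert after.loc["kin", "hit"]


def test_call_hits_requires_both_conditions():
    matrix = _matrix_from_values({"a": ((1.0, 2.0, 3.0), (0.0, 0.0, 0.0))})
    experiment_only = matrix.loc[matrix["condition"] == "experiment"]
    with pytest.raises(ConfigurationError, match="control_no_primary"):
        call_hits(experiment_only, "pTyr100", wt_mean=0.0, wt_sd=1.0)


def test_planted_kinase_power_and_null_rate_across_seeds():
    """A 5-WT-SD planted clone is called in >= 95% of seeds; a designated
    unplanted clone is called in fewer than 6% (the joint criteria are at
    least as strict as the t-test alone)."""
    n_seeds = 200
    power = 0
    false_calls = 0
    for seed in range(n_seeds):
        cfg = ec.SimConfig(
            n_clones=60, n_blocks=2, block_columns=12,
            planted_kinases={"kin": {"pTyr100": 5.0}},
            antibodies=("pTyr100",), include_qc_channels=False, seed=1000 + seed,
        )
        res = ec.simulate_ecla(cfg)
        est = ec.EclaScreen(antibodies=("pTyr100",)).fit(res.scans, res.layout)
        records = est.per_antibody_hits_["pTyr100"].set_index("clone")
        power += bool(records.loc["kin", "hit"])
        false_calls += bool(records.loc["clone_00001", "hit"])
    assert power / n_seeds >= 0.95
    assert false_calls / n_seeds <= 0.06


# ---------------------------------------------------------------------------
# intersection and biofilm
# ---------------------------------------------------------------------------

def _hits_frame(clones_with_ranks):
    return pd.DataFrame(
        {
            "clone": list(clones_with_ranks),
            "hit": True,
            "rank": list(clones_with_ranks.values()),
        }
    )


def test_intersect_hits_by_better_rank():
    a = _hits_frame({"etk": 1, "wzc": 2, "nrdD": 3})
    b = _hits_frame({"wzc": 5, "nrdD": 1, "argG": 2})
    assert intersect_hits(a, b) == ["nrdD", "wzc"]  # nrdD best rank 1, wzc best rank 2


def test_intersect_hits_empty_and_commutative():
    a = _hits_frame({"etk": 1, "wzc": 2})
    empty = _hits_frame({})
    assert intersect_hits(a, empty) == []
    b = _hits_frame({"wzc": 1, "dgoD": 2})
    assert set(intersect_hits(a, b)) == set(intersect_hits(b, a)) == {"wzc"}
    assert len(intersect_hits(a, b)) <= min(2, 2)


def test_biofilm_index_ratio_and_test():
    groups, p = ec.biofilm_index(
        od540=[0.5, 0.6, 0.4, 1.2, 1.3, 1.1],
        od600=[0.25, 0.3, 0.2, 0.4, 0.5, 0.44],
        grouping=["un", "un", "un", "ind", "ind", "ind"],
    )
    assert groups["un"][0] == pytest.approx(2.0)
    assert p < 0.05


def test_biofilm_index_degenerate_groups():
    _, p = ec.biofilm_index([1, 1, 1, 1], [1, 1, 1, 1], ["a", "a", "b", "b"])
    assert p == 1.0
    _, p = ec.biofilm_index([2, 2, 1, 1], [1, 1, 1, 1], ["a", "a", "b", "b"])
    assert p == 0.0
    with pytest.raises(ValueError):
        ec.biofilm_index([1, 1], [0.0, 1.0], ["a", "b"])


# ---------------------------------------------------------------------------
# estimator surface
# ---------------------------------------------------------------------------

def test_estimator_params_roundtrip_and_fit(small_ecla):
    est = ec.EclaScreen(alpha=0.01, k=2.0)
    assert est.get_params()["alpha"] == 0.01
    est.set_params(alpha=0.05, k=1.5)
    est.fit(small_ecla.scans, small_ecla.layout)
    assert est.intersection_ == ["etk", "wzc"]
    assert set(est.per_antibody_hits_) == {"pTyr100", "PY20"}
    assert est.n_clones_ == 200
    for _, records in est.per_antibody_hits_.items():
        hits = records.loc[records["hit"]]
        assert list(hits["rank"]) == sorted(hits["rank"])
        assert (hits["z_wt"].diff().dropna() <= 0).all()  # ranked by descending z
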