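"""Generator invariants: determinism, degenerate noise, planted-effect structure."""

import numpy as np
import pandas as pd
import pytest

import eclascreen as ec
from eclascreen.errors import ConfigurationError
from eclascreen.layout_io import Role
from eclascreen.quantify import scan_net_frame


def _noise_free(**kw):
    base = dict(
        n_clones=40, n_blocks=2, block_columns=10,
        spot_cv=0.0, background_sd=0.0, batch_scale_sd=0.0, abundance_cv=0.0,
        antibodies=("pTyr100",), include_qc_channels=False, seed=5,
    )
    base.update(kw)
    return ec.SimConfig(**base)


def test_seed_determinism_byte_identical():
    cfg = ec.SimConfig(n_clones=60, n_blocks=2, block_columns=10,
                       antibodies=("pTyr100",), seed=42)
    a = ec.simulate_ecla(cfg)
    b = ec.simulate_ecla(cfg)
    assert len(a.scans) == len(b.scans)
    for sa, sb in zip(a.scans, b.scans):
        assert sa.assay_id == sb.assay_id
        pd.testing.assert_frame_equal(sa.spots, sb.spots)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_noise_free_lysate_spots_identical():
    res = ec.simulate_ecla(_noise_free())
    for scan in res.scans:
        frame = scan_net_frame(scan)
        lysate = frame.loc[frame["role"] == Role.LYSATE, "net"]
        assert lysate.nunique() == 1


def test_null_z_scores_standardised():
    """With no planted effects, lysate-spot z-scores against the pooled WT
    baseline are standard: mean ~ 0, SD ~ 1 (within 0.1 at 2000 clones)."""
    cfg = ec.SimConfig(n_clones=2000, antibodies=("pTyr100",),
                       include_qc_channels=False, seed=3)
    res = ec.simulate_ecla(cfg)
    nets, wts = [], []
    for scan in res.scans:
        if scan.condition != "experiment":
            continue
        frame = scan_net_frame(scan)
        nets.append(frame.loc[frame["role"] == Role.LYSATE, "net"].to_numpy())
        wts.append(frame.loc[frame["role"] == Role.WT_LYSATE, "net"].to_numpy())
    nets = np.concatenate(nets)
    wts = np.concatenate(wts)
    z = (nets - wts.mean()) / wts.std(ddof=1)
    assert abs(z.mean()) < 0.1
    assert abs(z.std() - 1.0) < 0.1


def test_planted_effect_separates_from_wt_across_seeds():
    """A 5-WT-SD planted clone among 1000 unplanted ones clears 3 WT SDs in
    >= 99% of 200 seeds."""
    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        cfg = ec.SimConfig(
            n_clones=1001, planted_kinases={"etk": {"pTyr100": 5.0}},
            antibodies=("pTyr100",), include_qc_channels=False, seed=seed,
        )
        res = ec.simulate_ecla(cfg)
        exp = [s for s in res.scans if s.condition == "experiment"]
        wt_mean, wt_sd = ec.wt_baseline(exp)
        clone_nets = []
        for scan in exp:
            frame = scan_net_frame(scan)
            clone_nets.append(frame.loc[frame["name"] == "etk", "net"].to_numpy())
        clone_mean = float(np.concatenate(clone_nets).mean())
        hits += clone_mean - wt_mean >= 3.0 * wt_sd
    assert hits / n_seeds >= 0.99


def test_effect_monotone_in_net_intensity():
    """Raising a planted effect never lowers that clone's net intensity
    (same seed, identical noise draws)."""
    means = []
    for effect in (0.0, 2.0, 4.0, 8.0):
        cfg = ec.SimConfig(
            n_clones=50, n_blocks=2, block_columns=10,
            planted_kinases={"etk": {"pTyr100": effect}},
            antibodies=("pTyr100",), include_qc_channels=False, seed=9,
        )
        res = ec.simulate_ecla(cfg)
        nets = []
        for scan in res.scans:
            if scan.condition != "experiment":
                continue
            frame = scan_net_frame(scan)
            nets.append(frame.loc[frame["name"] == "etk", "net"].to_numpy())
        means.append(float(np.concatenate(nets).mean()))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_planted_clone_not_in_layout_errors():
    cfg = ec.SimConfig(
        n_clones=3, clone_names=("a", "b", "c"),
        planted_kinases={"zz": 5.0}, antibodies=("pTyr100",),
    )
    with pytest.raises(ConfigurationError, match="zz"):
        ec.simulate_ecla(cfg)


def test_proteome_null_conditions_exchangeable():
    cfg = ec.SimConfig(
        n_clones=400, n_blocks=4, block_columns=16, antibodies=("pTyr100",),
        n_replicate_assays=3, include_qc_channels=False, seed=2,
    )
    res = ec.simulate_proteome_array(cfg)
    by_cond = {}
    for scan in res.scans:
        frame = scan_net_frame(scan)
        by_cond.setdefault(scan.condition, []).append(
            frame.loc[frame["role"] == Role.LYSATE, "net"].to_numpy()
        )
    plus = np.concatenate(by_cond["plus_ATP"])
    minus = np.concatenate(by_cond["minus_ATP"])
    # no planted substrates: the two conditions share the same distribution
    se = np.sqrt(plus.var() / plus.size + minus.var() / minus.size)
    assert abs(plus.mean() - minus.mean()) < 4 * se


def test_proteome_planted_substrates_plus_atp_only(small_proteome):
    truth = dict(zip(small_proteome.truth["name"], small_proteome.truth["effect"]))
    matrix = ec.assemble_matrix(small_proteome.scans, small_proteome.layout)
    means = matrix.groupby(["clone", "condition"], observed=True)["net_intensity"].mean()
    delta = means.xs("plus_ATP", level="condition") - means.xs("minus_ATP", level="condition")
    null = delta[~delta.index.isin(truth)]
    threshold = null.mean() + 3 * null.std()
    for name in truth:  # large-effect planted substrates stand clear of the null
        assert delta[name] > threshold
    assert (null <= threshold).mean() > 0.98


def test_truth_table_reports_expressors_and_effects(small_ecla):
    truth = small_ecla.truth
    kinases = truth.loc[truth["channel"].isin(("pTyr100", "PY20"))]
    assert set(kinases["name"]) == {"etk", "wzc"}
    expressors = truth.loc[truth["channel"] == "antiHis", "name"]
    assert len(expressors) == round(0.938 * 200)
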