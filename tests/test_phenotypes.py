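"""Phenotype hit calling: batch log2FC, mixed model, ddCt, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import statsmodels.api as sm

from perturbscreen import batch_log2fc, ddct_fold_change, fit_effect_model, summarize_hits
from perturbscreen.phenotypes import StratumError
from perturbscreen.simulate import gen_assay_data
from perturbscreen import make_config


def _measurements(rows):
    return pd.DataFrame(
        rows, columns=["assay", "cell_line", "sirna", "batch", "replicate", "dose", "value"]
    )


def _one_stratum(target_values, control_values, batch="b1"):
    rows = []
    for i, v in enumerate(target_values):
        rows.append(("viability", "scramble", "siT", batch, i + 1, "", v))
    for i, v in enumerate(control_values):
        rows.append(("viability", "scramble", "siCtrl", batch, i + 1, "", v))
    return _measurements(rows)


def test_batch_log2fc_simple_ratio():
    fcs = batch_log2fc(_one_stratum([200, 200], [100, 100]), "siCtrl")
    target = fcs.loc[fcs["sirna"] == "siT", "log2fc"].iloc[0]
    assert target == pytest.approx(1.0)
    control = fcs.loc[fcs["sirna"] == "siCtrl", "log2fc"].iloc[0]
    assert control == 0.0


def test_batch_log2fc_per_batch_arithmetic():
    """Per-batch means (120, 80, 100) vs controls at 100 give the textbook values."""
    frames = []
    for batch, tv in zip(("b1", "b2", "b3"), ([110, 130], [70, 90], [95, 105])):
        frames.append(_one_stratum(tv, [100, 100], batch=batch))
    fcs = batch_log2fc(pd.concat(frames, ignore_index=True), "siCtrl")
    got = fcs.loc[fcs["sirna"] == "siT"].sort_values("batch")["log2fc"].to_numpy()
    assert np.allclose(got, [np.log2(1.2), np.log2(0.8), 0.0], atol=1e-12)


def test_batch_log2fc_errors():
    with pytest.raises(StratumError, match="missing"):
        batch_log2fc(_one_stratum([100], [100]).query("sirna != 'siCtrl'"), "siCtrl")
    bad = _one_stratum([100, -5], [100, 100])
    with pytest.raises(ValueError, match="positive"):
        batch_log2fc(bad, "siCtrl")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(min_value=0.01, max_value=100.0))
def test_batch_log2fc_scale_equivariance(scale):
    """Multiplying all raw values in a stratum leaves every log2FC unchanged."""
    base = _one_stratum([120, 140, 90], [100, 110, 95])
    a = batch_log2fc(base, "siCtrl")
    scaled = base.assign(value=base["value"] * scale)
    b = batch_log2fc(scaled, "siCtrl")
    assert np.allclose(a["log2fc"], b["log2fc"], atol=1e-10)


def _iid_fc_table(seed, n_sirna=4, n_lines=2, n_batches=3, sd=0.2, center=False):
    """Per-batch log2FC with iid noise; ``center=True`` removes the realized
    batch-mean deviation so the data sit exactly in the zero-batch-variance
    limit."""
    rng = np.random.default_rng(seed)
    cells = [(f"si{s}", f"L{l}") for s in range(n_sirna) for l in range(n_lines)]
    effects = {c: rng.normal(0, 0.4) for c in cells}
    noise = rng.normal(0, sd, (n_batches, len(cells)))
    if center:
        noise -= noise.mean(axis=1, keepdims=True)
    rows = []
    for b in range(n_batches):
        for i, (sirna, line) in enumerate(cells):
            rows.append(("viability", line, sirna, f"b{b}", "", effects[(sirna, line)] + noise[b, i]))
    return pd.DataFrame(rows, columns=["assay", "cell_line", "sirna", "batch", "dose", "log2fc"])


def test_effect_model_effects_equal_batch_means_at_zero_batch_sd():
    """Balanced design: marginal means equal per-batch log2FC means."""
    cfg = make_config(seed=4, n_targets=3, batch_sd=0.0, assays=("viability",))
    fcs = batch_log2fc(gen_assay_data(cfg), cfg.control_label)
    est = fit_effect_model(fcs, cfg.control_label)
    data = fcs.loc[fcs["sirna"] != cfg.control_label]
    for _, row in est.iterrows():
        mean_fc = data.loc[
            (data["sirna"] == row["sirna"]) & (data["cell_line"] == row["cell_line"]), "log2fc"
        ].mean()
        assert row["effect"] == pytest.approx(mean_fc, abs=1e-9)


def test_effect_model_ols_reduction_in_realized_zero_variance_limit():
    """With zero realized batch variance the fit reduces exactly to OLS."""
    fcs = _iid_fc_table(seed=21, center=True)
    est = fit_effect_model(fcs, control="none")
    data = fcs
    X = pd.get_dummies(data["sirna"] + "\x1f" + data["cell_line"], dtype=float)
    fit = sm.OLS(data["log2fc"].to_numpy(), X).fit()
    for cell, coef, bse in zip(X.columns, fit.params, fit.bse):
        sirna, line = cell.split("\x1f")
        row = est.loc[(est["sirna"] == sirna) & (est["cell_line"] == line)].iloc[0]
        assert row["effect"] == pytest.approx(coef, abs=1e-9)
        p_oracle = 2 * stats.norm.sf(abs(coef / bse))
        assert row["p"] == pytest.approx(p_oracle, abs=1e-9)


def test_effect_model_null_target_not_hit():
    """A target with identically zero log2FC gets effect 0, p ~ 1, no hit."""
    fcs = _iid_fc_table(seed=5, sd=0.1)
    fcs.loc[fcs["sirna"] == "si0", "log2fc"] = 0.0
    est = fit_effect_model(fcs, control="none")
    row = est.loc[(est["sirna"] == "si0")].iloc[0]
    assert row["effect"] == pytest.approx(0.0, abs=1e-9)
    assert row["p"] > 0.9
    assert not row["hit"]


def test_detected_hits_monotone_in_effect_size():
    """Scaling all true effects up never reduces the detected hit count."""
    counts = []
    for scale in (0.0, 0.4, 0.8):
        cfg = make_config(seed=6, n_targets=4, assays=("viability", "phagocytosis"))
        cfg.assay_effects = {k: scale for k in cfg.assay_effects}
        fcs = batch_log2fc(gen_assay_data(cfg), cfg.control_label)
        est = fit_effect_model(fcs, cfg.control_label)
        counts.append(int(est["hit"].sum()))
    assert counts == sorted(counts)


def test_separate_line_fits_produce_per_line_estimates():
    fcs = _iid_fc_table(seed=9)
    est = fit_effect_model(fcs, control="none", separate_lines=True)
    assert set(zip(est["sirna"], est["cell_line"])) == {
        (f"si{s}", f"L{l}") for s in range(4) for l in range(2)
    }


def _ct_table(ddct):
    rows = []
    for rep in range(3):
        rows.append(("Tgt", "control", rep, 22.0))
        rows.append(("Ref", "control", rep, 18.0))
        rows.append(("Tgt", "knockdown", rep, 22.0 + ddct))
        rows.append(("Ref", "knockdown", rep, 18.0))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


@pytest.mark.parametrize(
    "ddct,fold,pct",
    [(0.0, 1.0, 0.0), (1.0, 0.5, 50.0), (2.322, 0.2, 80.0)],
)
def test_ddct_fold_change_examples(ddct, fold, pct):
    eff = ddct_fold_change(_ct_table(ddct), "Tgt", "Ref")
    assert eff.fold_change == pytest.approx(fold, abs=5e-4)
    assert eff.percent_knockdown == pytest.approx(pct, abs=0.05)


def test_ddct_invariant_to_reference_shift():
    """Shifting the reference gene equally in both conditions changes nothing."""
    base = _ct_table(1.5)
    shifted = base.copy()
    shifted.loc[shifted["gene"] == "Ref", "ct"] += 2.0
    a = ddct_fold_change(base, "Tgt", "Ref")
    b = ddct_fold_change(shifted, "Tgt", "Ref")
    assert a.fold_change == pytest.approx(b.fold_change, abs=1e-12)


def test_ddct_missing_gene_errors():
    with pytest.raises(ValueError, match="missing Ct"):
        ddct_fold_change(_ct_table(1.0), "Absent", "Ref")


def test_summarize_hits_counts_targets_once():
    est = pd.DataFrame(
        {
            "assay": ["viability", "phagocytosis", "viability"],
            "dose": ["", "", ""],
            "cell_line": ["scramble"] * 3,
            "sirna": ["siA", "siA", "siB"],
            "effect": [0.5, 0.4, 0.0],
            "se": [0.1] * 3,
            "p": [0.001, 0.002, 0.9],
            "p_adj": [0.002, 0.004, 0.9],
            "hit": [True, True, False],
        }
    )
    summary = summarize_hits(est)
    assert summary.n_targets == 2
    assert summary.n_targets_with_hit == 1  # siA hit in 2 assays counts once
    assert summary.per_assay["n_hit_targets"].tolist() == [1, 1]
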