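"""Synthetic-data generator: structure, determinism, noise-free limits."""

import numpy as np
import pandas as pd
import pytest

from perturbscreen import (
    SimulationConfig,
    batch_log2fc,
    gen_assay_data,
    gen_biodomain_annotation,
    gen_ct_table,
    gen_knockdown_proteomes,
    gen_reference_signature,
    ground_truth,
    make_config,
)


def test_annotation_shapes_and_domain_membership():
    cfg = SimulationConfig(seed=1, n_targets=2, n_genes=200, n_domains=2,
                           terms_per_domain=3, genes_per_term=20, overlap=0.0)
    coll, ann = gen_biodomain_annotation(cfg)
    assert len(coll) == 6
    domains = ann.domains()
    assert len(domains) == 2
    # terms of different domains draw from disjoint gene pools
    pools = {d: set() for d in domains}
    for term, labels in ann.term_to_domain.items():
        assert len(labels) == 1
        pools[labels[0]].update(coll.sets[term])
    assert not (pools[domains[0]] & pools[domains[1]])
    assert all(len(coll.sets[t]) == 20 for t in coll)


def test_annotation_overlap_fraction():
    cfg = SimulationConfig(seed=2, n_targets=2, n_genes=400, n_domains=2,
                           terms_per_domain=4, genes_per_term=10, overlap=0.5)
    _, ann = gen_biodomain_annotation(cfg)
    multi = [t for t, labels in ann.term_to_domain.items() if len(labels) == 2]
    assert len(multi) == 4  # half of the 8 terms carry two domain labels


def test_infeasible_sizes_raise():
    with pytest.raises(ValueError, match="infeasible"):
        SimulationConfig(seed=0, n_targets=1, n_genes=10, n_domains=1,
                         terms_per_domain=1, genes_per_term=50)


def test_generators_are_deterministic():
    kwargs = dict(seed=3, n_targets=3, n_genes=300, terms_per_domain=4, genes_per_term=12)
    a, b = make_config(**kwargs), make_config(**kwargs)
    assert a.assay_effects == b.assay_effects
    pd.testing.assert_frame_equal(gen_assay_data(a), gen_assay_data(b))
    coll_a, ann_a = gen_biodomain_annotation(a)
    coll_b, ann_b = gen_biodomain_annotation(b)
    assert coll_a.sets == coll_b.sets
    ref_a = gen_reference_signature(a, coll_a, ann_a, n_perm=100)
    ref_b = gen_reference_signature(b, coll_b, ann_b, n_perm=100)
    pd.testing.assert_series_equal(ref_a.protein_effect, ref_b.protein_effect)
    pd.testing.assert_series_equal(ref_a.term_nes, ref_b.term_nes)
    ma, _ = gen_knockdown_proteomes(a, ref_a, ann_a)
    mb, _ = gen_knockdown_proteomes(b, ref_b, ann_b)
    pd.testing.assert_frame_equal(ma, mb)


def test_assay_row_count_matches_design():
    """29 targets + control, 2 lines, 3 batches x 3 replicates, one assay."""
    cfg = make_config(seed=5, n_targets=29, assays=("viability",))
    table = gen_assay_data(cfg)
    assert len(table) == 3 * 3 * 2 * 30


def test_noise_free_limit_recovers_true_effects_exactly():
    cfg = make_config(seed=7, n_targets=3, batch_sd=0.0, residual_sd=0.0,
                      assays=("viability",))
    fcs = batch_log2fc(gen_assay_data(cfg), cfg.control_label)
    for _, row in fcs.loc[fcs["sirna"] != cfg.control_label].iterrows():
        expected = cfg.assay_effect(row["sirna"], row["cell_line"], row["assay"], row["dose"])
        assert row["log2fc"] == pytest.approx(expected, abs=1e-9)


def test_reference_signature_signs_follow_domain_effects():
    """Low-noise reference: immune terms enrich up, mitochondrial terms down."""
    cfg = SimulationConfig(seed=9, n_targets=2, n_genes=600, terms_per_domain=8,
                           genes_per_term=20, proteome_noise_sd=0.1,
                           domain_effect={"immune_response": 1.0,
                                          "mitochondrial_metabolism": -1.0})
    coll, ann = gen_biodomain_annotation(cfg)
    ref = gen_reference_signature(cfg, coll, ann, n_perm=200)
    for term, labels in ann.term_to_domain.items():
        nes = ref.term_nes[term]
        if labels[0] == "immune_response":
            assert nes > 0
        else:
            assert nes < 0


def test_knockdown_proteome_group_mean_construction():
    """c = 0 with self-knockdown: only the targeted protein shifts."""
    cfg = make_config(seed=10, n_targets=2, n_reversal=0, n_genes=200,
                      terms_per_domain=3, genes_per_term=10,
                      proteome_noise_sd=0.0, n_proteome_replicates=2)
    coll, ann = gen_biodomain_annotation(cfg)
    ref = gen_reference_signature(cfg, coll, ann, n_perm=100)
    matrix, meta = gen_knockdown_proteomes(cfg, ref, ann)
    target = cfg.targets[0]
    ctrl_cols = meta.loc[(meta["cell_line"] == "scramble") & (meta["sirna"] == cfg.control_label), "sample"]
    kd_cols = meta.loc[(meta["cell_line"] == "scramble") & (meta["sirna"] == target), "sample"]
    diff = matrix[list(kd_cols)].mean(axis=1) - matrix[list(ctrl_cols)].mean(axis=1)
    assert diff[target] == pytest.approx(cfg.knockdown_self_effect, abs=1e-9)
    assert np.allclose(diff.drop(target), 0.0, atol=1e-9)


def test_reversal_coefficient_scales_reference_effect():
    cfg = make_config(seed=12, n_targets=2, n_reversal=1, c_reversal=-0.6,
                      n_genes=200, terms_per_domain=3, genes_per_term=10,
                      proteome_noise_sd=0.0, n_proteome_replicates=2)
    coll, ann = gen_biodomain_annotation(cfg)
    ref = gen_reference_signature(cfg, coll, ann, n_perm=100)
    matrix, meta = gen_knockdown_proteomes(cfg, ref, ann)
    target = cfg.targets[0]
    ctrl = meta.loc[(meta["cell_line"] == "scramble") & (meta["sirna"] == cfg.control_label), "sample"]
    kd = meta.loc[(meta["cell_line"] == "scramble") & (meta["sirna"] == target), "sample"]
    diff = (matrix[list(kd)].mean(axis=1) - matrix[list(ctrl)].mean(axis=1)).drop(target)
    assert np.allclose(diff, -0.6 * ref.protein_effect.drop(target), atol=1e-9)


def test_ct_table_fold_change_arithmetic():
    from perturbscreen import ddct_fold_change

    cfg = make_config(seed=13, n_targets=2, n_genes=200, terms_per_domain=3,
                      genes_per_term=10)
    ct = gen_ct_table(cfg, knockdown_fold=0.25, ct_noise_sd=0.0)
    target = cfg.targets[0]
    sub = ct.loc[ct["target"] == target]
    eff = ddct_fold_change(sub, target, "Gapdh")
    assert eff.ddct == pytest.approx(2.0, abs=1e-12)
    assert eff.fold_change == pytest.approx(0.25, abs=1e-12)


def test_ground_truth_reflects_generating_parameters():
    cfg = make_config(seed=14, n_targets=4, n_reversal=2, c_reversal=-0.6)
    truth = ground_truth(cfg)
    rev_targets = {t for (t, _), c in cfg.concordance_coeff.items() if c < 0}
    assert {t for (t, *_ ) in truth.true_reversals} == rev_targets
    for key in truth.true_hits:
        assert abs(cfg.assay_effect(*key)) >= cfg.true_hit_min


def test_null_config_has_no_truth():
    cfg = make_config(seed=15, n_targets=3, null=True)
    truth = ground_truth(cfg)
    assert not truth.true_hits and not truth.true_reversals
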