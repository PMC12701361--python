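"""Biodomain concordance: zero-filling, Kendall/Pearson scoring, quadrants."""

import numpy as np
import pandas as pd
import pytest

from perturbscreen import (
    BiodomainAnnotation,
    GeneSetCollection,
    ReferenceSignature,
    compare_cell_lines,
    kendall_concordance,
    make_config,
    pearson_protein_concordance,
    score_term_concordance,
    term_quadrants,
    zero_fill_align,
)
from perturbscreen.simulate import (
    gen_biodomain_annotation,
    gen_knockdown_proteomes,
    gen_reference_signature,
)

from conftest import brute_force_bh, tau_b_oracle


def _reference(terms, nes, sig, proteins=None):
    return ReferenceSignature(
        protein_effect=proteins if proteins is not None else pd.Series(dtype=float),
        term_nes=pd.Series(nes, index=terms, dtype=float),
        term_sig=pd.Series(sig, index=terms, dtype=float),
    )


def _query(terms, nes, p_adj):
    return pd.DataFrame({"term": terms, "nes": nes, "p_adj": p_adj})


def _annotation(terms, domain="D"):
    return BiodomainAnnotation({t: (domain,) for t in terms})


def test_zero_fill_union_rules():
    terms = ["t1", "t2", "t3", "t4"]
    ref = _reference(terms, [2.0, -1.5, 1.0, 0.5], [0.01, 0.01, 0.5, 0.6])
    query = _query(terms, [1.8, 0.3, -2.0, 0.2], [0.02, 0.7, 0.01, 0.9])
    q, r = zero_fill_align(query, ref, "D", _annotation(terms))
    # universe: significant in either analysis -> t1, t2, t3
    assert list(q.index) == ["t1", "t2", "t3"]
    assert q.tolist() == [1.8, 0.0, -2.0]     # t2 not significant in query -> 0
    assert r.tolist() == [2.0, -1.5, 0.0]     # t3 not significant in reference -> 0


def test_zero_fill_empty_domain_skipped():
    terms = ["t1"]
    ref = _reference(terms, [1.0], [0.9])
    query = _query(terms, [0.5], [0.8])
    assert zero_fill_align(query, ref, "D", _annotation(terms)) is None


def test_kendall_identity_and_reversal():
    terms = [f"t{i}" for i in range(6)]
    v = pd.Series([2.0, 1.5, 1.0, -0.5, -1.0, -2.0], index=terms)
    same = kendall_concordance(v, v, "D", "tgt", "line")
    assert same["stat"] == pytest.approx(1.0)
    flipped = kendall_concordance(v, -v, "D", "tgt", "line")
    assert flipped["stat"] == pytest.approx(-1.0)


def test_kendall_matches_pair_count_oracle_with_zero_fills():
    """Tau-b on an 8-term vector with 3 zero-fills equals the explicit
    concordant/discordant pair-count computation."""
    q = pd.Series([1.8, 0.0, -2.0, 0.9, 0.0, -1.1, 0.0, 2.5],
                  index=[f"t{i}" for i in range(8)])
    r = pd.Series([2.0, -1.5, 0.0, 1.2, -0.4, 0.0, 0.8, 1.9], index=q.index)
    res = kendall_concordance(q, r, "D", "tgt", "line")
    assert res["stat"] == pytest.approx(tau_b_oracle(q.tolist(), r.tolist()), abs=1e-12)


def test_kendall_degenerate_sides_flagged():
    q = pd.Series([0.0] * 6, index=[f"t{i}" for i in range(6)])
    r = pd.Series([1.0, 2.0, -1.0, 0.5, -0.5, 0.3], index=q.index)
    res = kendall_concordance(q, r, "D", "tgt", "line")
    assert res["degenerate"] and res["p"] == 1.0


def test_score_term_concordance_bh_family_is_joint():
    rng = np.random.default_rng(4)
    terms = [f"t{i}" for i in range(10)]
    ann = _annotation(terms)
    ref = _reference(terms, rng.normal(0, 2, 10), np.full(10, 0.01))
    enrichments = {}
    for t in ("tgtA", "tgtB"):
        for line in ("scramble", "sensitized"):
            enrichments[(t, line)] = _query(terms, rng.normal(0, 2, 10), np.full(10, 0.01))
    out = score_term_concordance(enrichments, ref, ann)
    assert len(out) == 4
    assert np.allclose(out["p_adj"], brute_force_bh(out["p"].tolist()), atol=1e-12)


def test_pearson_scale_invariance_and_skips():
    genes = [f"g{i}" for i in range(20)]
    coll = GeneSetCollection({"t1": tuple(genes)})
    ann = BiodomainAnnotation({"t1": ("D",)})
    rng = np.random.default_rng(5)
    effect = pd.Series(rng.normal(0, 1, 20), index=genes)
    ref = _reference(["t1"], [1.0], [0.01], proteins=effect)
    de = pd.DataFrame({
        "protein": genes, "cell_line": "scramble", "sirna": "tgt",
        "log2fc": 2.0 * effect.to_numpy(), "testable": True,
    })
    out = pearson_protein_concordance(de, ref, ann, coll)
    assert out.loc[0, "stat"] == pytest.approx(1.0)
    assert out.loc[0, "call"] == "correlated"
    # constant reference -> degenerate, never called
    ref0 = _reference(["t1"], [1.0], [0.01], proteins=pd.Series(0.0, index=genes))
    out0 = pearson_protein_concordance(de, ref0, ann, coll)
    assert out0.loc[0, "call"] == "ns"
    # overlap below threshold -> skipped entirely
    out_min = pearson_protein_concordance(de, ref, ann, coll, min_proteins_corr=50)
    assert out_min.empty


def test_term_quadrant_counts():
    terms = ["t1", "t2", "t3", "t4", "t5"]
    ann = _annotation(terms)
    ref = _reference(terms, [2.0, -1.0, 1.5, -2.0, 1.0], [0.01, 0.01, 0.01, 0.01, 0.9])
    query = _query(terms, [1.0, 1.2, -0.5, 0.3, 2.0], [0.01, 0.02, 0.03, 0.5, 0.01])
    qc = term_quadrants(query, ref, "D", ann)
    assert (qc.up_up, qc.up_down, qc.down_up, qc.down_down) == (1, 1, 1, 0)
    assert qc.reference_only == 1   # t4 significant in reference only
    assert qc.query_only == 1       # t5 significant in query only
    assert qc.total == 5


def test_quadrants_disjoint_significance():
    terms = ["t1", "t2"]
    ann = _annotation(terms)
    ref = _reference(terms, [2.0, 1.0], [0.01, 0.9])
    query = _query(terms, [1.0, -1.0], [0.9, 0.01])
    qc = term_quadrants(query, ref, "D", ann)
    assert qc.up_up + qc.up_down + qc.down_up + qc.down_down == 0
    assert qc.reference_only == 1 and qc.query_only == 1


def test_zero_fill_reduction_to_plain_tau():
    """All terms significant in both analyses: result equals raw tau-b."""
    from scipy import stats as sps

    rng = np.random.default_rng(6)
    terms = [f"t{i}" for i in range(12)]
    ann = _annotation(terms)
    ref_nes = rng.normal(0, 2, 12)
    q_nes = rng.normal(0, 2, 12)
    ref = _reference(terms, ref_nes, np.full(12, 0.001))
    query = _query(terms, q_nes, np.full(12, 0.001))
    q, r = zero_fill_align(query, ref, "D", ann)
    res = kendall_concordance(q, r, "D", "tgt", "line")
    raw_tau = sps.kendalltau(q_nes[np.argsort(terms)], ref_nes[np.argsort(terms)]).statistic
    # order alignment: recompute directly on matched pairs
    raw_tau = sps.kendalltau(q.to_numpy(), r.to_numpy()).statistic
    assert res["stat"] == pytest.approx(raw_tau, abs=1e-12)
    assert res["stat"] == pytest.approx(tau_b_oracle(q.tolist(), r.tolist()), abs=1e-12)


def test_compare_cell_lines_detects_constructed_shift():
    """A sensitized line drifting along the disease signature shows positive
    immune enrichment, positive subtype-list enrichment, and positive
    concordance with the reference."""
    cfg = make_config(seed=21, n_targets=2, n_reversal=0, n_genes=800, n_domains=4,
                      terms_per_domain=20, genes_per_term=15,
                      n_proteome_replicates=4,
                      domain_effect={"immune_response": 0.5,
                                     "mitochondrial_metabolism": -0.5,
                                     "domain3": 0.0, "domain4": 0.0},
                      line_concordance=0.8)
    coll, ann = gen_biodomain_annotation(cfg)
    ref = gen_reference_signature(cfg, coll, ann, n_perm=500)
    matrix, meta = gen_knockdown_proteomes(cfg, ref, ann)
    up_genes = tuple(g for g, d in ann.gene_domain.items() if d == "immune_response")[:40]
    res = compare_cell_lines(
        matrix, meta, cfg.control_label, coll, ann, ref,
        subtype_lists=GeneSetCollection({"up_state": up_genes}),
        n_perm=500, seed=3,
    )
    immune = res["enrichment"].merge(
        pd.DataFrame({"term": list(ann.term_to_domain),
                      "domain": [v[0] for v in ann.term_to_domain.values()]}),
        on="term",
    )
    assert (immune.loc[immune["domain"] == "immune_response", "nes"] > 0).all()
    assert (immune.loc[immune["domain"] == "mitochondrial_metabolism", "nes"] < 0).all()
    assert res["subtype_enrichment"].loc[0, "nes"] > 0
    conc = res["concordance"].set_index("domain")
    for domain in ("immune_response", "mitochondrial_metabolism"):
        assert conc.at[domain, "stat"] > 0
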