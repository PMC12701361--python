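"""Biodomain-wise concordance and reversal scoring against a disease signature.

Enrichment results from each knockdown are compared, within each biological
domain (a curated group of gene-set terms such as "immune response" or
"mitochondrial metabolism"), to a reference disease signature: term-level
NES profiles by zero-filled Kendall tau-b, and protein-level log2 fold
changes by Pearson correlation against the reference per-protein treatment
effects.  A significantly negative correlation is a signature *reversal* —
the perturbation pushes the molecular state opposite to disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .gsea import GeneSetCollection, map_orthologs, preranked_gsea, set_enrichment_custom

logger = logging.getLogger(__name__)

__all__ = [
    "BiodomainAnnotation",
    "ReferenceSignature",
    "zero_fill_align",
    "kendall_concordance",
    "score_term_concordance",
    "pearson_protein_concordance",
    "term_quadrants",
    "compare_cell_lines",
]


@dataclass
class BiodomainAnnotation:
    """Term -> biodomain labels, plus a generator-side gene -> domain map.

    ``protein_domains`` derives the protein-level grouping the way the
    analysis defines it: a protein belongs to every domain that annotates a
    term containing it.
    """

    term_to_domain: dict[str, tuple[str, ...]]
    gene_domain: dict[str, str] = field(default_factory=dict)

    def domains(self) -> list[str]:
        out: list[str] = []
        for labels in self.term_to_domain.values():
            for d in labels:
                if d not in out:
                    out.append(d)
        return out

    def terms_in_domain(self, domain: str) -> list[str]:
        return [t for t, labels in self.term_to_domain.items() if domain in labels]

    def protein_domains(self, collection: GeneSetCollection) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for term, genes in collection.sets.items():
            for d in self.term_to_domain.get(term, ()):
                for g in genes:
                    labels = out.setdefault(g, [])
                    if d not in labels:
                        labels.append(d)
        return {g: tuple(v) for g, v in out.items()}


@dataclass
class ReferenceSignature:
    """Disease reference: per-protein effects and per-term enrichment.

    ``protein_effect`` holds the meta-analysis treatment effect used as the
    reference ranking statistic; ``term_nes``/``term_sig`` hold the NES and
    adjusted p of the reference enrichment run.
    """

    protein_effect: pd.Series
    term_nes: pd.Series
    term_sig: pd.Series
    enrichment: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.term_nes.index) - set(self.term_sig.index)
        if missing:
            raise ValueError(f"terms lacking significance entries: {sorted(missing)[:5]}")


def zero_fill_align(
    query: pd.DataFrame,
    reference: ReferenceSignature,
    domain: str,
    annotation: BiodomainAnnotation,
    alpha: float = 0.05,
    universe: str = "union",
):
    """Paired (query, reference) NES vectors for one domain, zero-filled.

    The term universe is the set of in-domain terms significant (adjusted
    p <= alpha) in either analysis (``universe="intersection"`` restricts to
    both); each side contributes its NES where significant and 0 otherwise.
    Returns ``(query_nes, reference_nes)`` as aligned Series, or ``None``
    when the universe is empty.
    """
    domain_terms = set(annotation.terms_in_domain(domain))
    q = query.set_index("term")
    q_sig = set(q.index[(q["p_adj"] <= alpha)]) & domain_terms
    r_sig = {
        t for t in reference.term_nes.index
        if t in domain_terms and reference.term_sig.get(t, 1.0) <= alpha
    }
    if universe == "union":
        terms = sorted(q_sig | r_sig)
    elif universe == "intersection":
        terms = sorted(q_sig & r_sig)
    else:
        raise ValueError("universe must be 'union' or 'intersection'")
    if not terms:
        logger.info("domain %s has no significant terms in either analysis; skipped", domain)
        return None
    q_vec = pd.Series(
        [float(q.at[t, "nes"]) if t in q_sig else 0.0 for t in terms], index=terms
    )
    r_vec = pd.Series(
        [float(reference.term_nes[t]) if t in r_sig else 0.0 for t in terms], index=terms
    )
    return q_vec, r_vec


def kendall_concordance(
    query_nes: pd.Series,
    reference_nes: pd.Series,
    domain: str,
    target: str,
    cell_line: str,
    min_terms: int = 5,
) -> dict | None:
    """Kendall tau-b between paired NES vectors for one domain.

    Tau-b's tie correction matters here because zero-filling mass-produces
    tied zeros.  The p value is the asymptotic normal approximation.
    Zero variance on either side yields a flagged, non-significant row.
    """
    n = len(query_nes)
    if n < min_terms:
        logger.info("domain %s: only %d paired terms (< %d); skipped", domain, n, min_terms)
        return None
    row = {"target": target, "cell_line": cell_line, "domain": domain,
           "method": "kendall_terms", "n": n}
    x = query_nes.to_numpy(dtype=float)
    y = reference_nes.loc[query_nes.index].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        row.update(stat=np.nan, p=1.0, degenerate=True)
        return row
    tau, p = stats.kendalltau(x, y, method="asymptotic")
    row.update(stat=float(tau), p=float(p), degenerate=False)
    return row


def _finalize_calls(rows: list[dict], alpha: float) -> pd.DataFrame:
    cols = ["target", "cell_line", "domain", "method", "stat", "n", "p", "p_adj", "call", "degenerate"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    sig = (out["p_adj"] <= alpha) & ~out["degenerate"]
    out["call"] = np.where(
        sig & (out["stat"] < 0), "anti_correlated", np.where(sig & (out["stat"] > 0), "correlated", "ns")
    )
    return out[cols]


def score_term_concordance(
    enrichments: dict[tuple[str, str], pd.DataFrame],
    reference: ReferenceSignature,
    annotation: BiodomainAnnotation,
    alpha: float = 0.05,
    min_terms: int = 5,
    universe: str = "union",
) -> pd.DataFrame:
    """Zero-filled Kendall concordance over all (target, cell line, domain).

    ``enrichments`` maps (target, cell_line) to that knockdown's enrichment
    table.  BH adjustment spans the whole term-level family jointly; calls
    are ``anti_correlated`` (reversal) / ``correlated`` / ``ns``.
    """
    rows = []
    for (target, line), query in sorted(enrichments.items()):
        for domain in annotation.domains():
            pair = zero_fill_align(query, reference, domain, annotation, alpha=alpha, universe=universe)
            if pair is None:
                continue
            row = kendall_concordance(pair[0], pair[1], domain, target, line, min_terms=min_terms)
            if row is not None:
                rows.append(row)
    return _finalize_calls(rows, alpha)


def pearson_protein_concordance(
    de: pd.DataFrame,
    reference: ReferenceSignature,
    annotation: BiodomainAnnotation,
    collection: GeneSetCollection,
    mapping=None,
    alpha: float = 0.05,
    min_proteins_corr: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of knockdown log2FC with reference protein effects.

    Proteins are grouped into domains via term membership; for each
    (target, cell line, domain) the correlation runs over in-domain proteins
    shared between the knockdown differential-abundance table and the
    (optionally ortholog-mapped) reference effects.  BH spans the whole
    protein-level family.
    """
    ref_effect = reference.protein_effect
    if mapping is not None:
        ref_effect, report = map_orthologs(ref_effect, mapping)
        logger.info("ortholog mapping: %d/%d reference proteins mapped", report.n_mapped, report.n_input)
    prot_domains = annotation.protein_domains(collection)
    rows = []
    for (line, target), sub in sorted(de.groupby(["cell_line", "sirna"], observed=True)):
        fc = sub.set_index("protein")["log2fc"]
        for domain in annotation.domains():
            in_domain = [p for p in fc.index if domain in prot_domains.get(p, ()) and p in ref_effect.index]
            if len(in_domain) < min_proteins_corr:
                logger.info("(%s, %s, %s): %d overlapping proteins (< %d); skipped",
                            target, line, domain, len(in_domain), min_proteins_corr)
                continue
            x = fc.loc[in_domain].to_numpy(dtype=float)
            y = ref_effect.loc[in_domain].to_numpy(dtype=float)
            row = {"target": target, "cell_line": line, "domain": domain,
                   "method": "pearson_proteins", "n": len(in_domain)}
            if np.all(x == x[0]) or np.all(y == y[0]):
                row.update(stat=np.nan, p=1.0, degenerate=True)
            else:
                r, p = stats.pearsonr(x, y)
                row.update(stat=float(r), p=float(p), degenerate=False)
            rows.append(row)
    return _finalize_calls(rows, alpha)


@dataclass
class TermQuadrantCounts:
    domain: str
    up_up: int          # up in reference, up in query
    up_down: int        # up in reference, down in query
    down_up: int        # down in reference, up in query  (a reversal pattern)
    down_down: int
    reference_only: int
    query_only: int

    @property
    def total(self) -> int:
        return (self.up_up + self.up_down + self.down_up + self.down_down
                + self.reference_only + self.query_only)


def term_quadrants(
    query: pd.DataFrame,
    reference: ReferenceSignature,
    domain: str,
    annotation: BiodomainAnnotation,
    alpha: float = 0.05,
) -> TermQuadrantCounts:
    """Classify significant in-domain terms by NES sign pair.

    Terms significant in both analyses are counted in one of four sign
    quadrants; terms significant in only one analysis are tallied as
    reference-only or query-only.
    """
    domain_terms = set(annotation.terms_in_domain(domain))
    q = query.set_index("term")
    q_sig = {t: float(q.at[t, "nes"]) for t in q.index
             if t in domain_terms and q.at[t, "p_adj"] <= alpha}
    r_sig = {t: float(reference.term_nes[t]) for t in reference.term_nes.index
             if t in domain_terms and reference.term_sig.get(t, 1.0) <= alpha}
    both = set(q_sig) & set(r_sig)
    counts = {"up_up": 0, "up_down": 0, "down_up": 0, "down_down": 0}
    for t in both:
        key = ("up" if r_sig[t] > 0 else "down") + "_" + ("up" if q_sig[t] > 0 else "down")
        counts[key] += 1
    return TermQuadrantCounts(
        domain=domain,
        reference_only=len(set(r_sig) - both),
        query_only=len(set(q_sig) - both),
        **counts,
    )


def compare_cell_lines(
    matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    control_sirna: str,
    collection: GeneSetCollection,
    annotation: BiodomainAnnotation,
    reference: ReferenceSignature,
    subtype_lists: GeneSetCollection | None = None,
    baseline_line: str = "scramble",
    query_line: str = "sensitized",
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    min_size: int = 10,
    max_size: int = 500,
    min_terms: int = 5,
) -> dict:
    """Characterize the sensitized line against the baseline line.

    Uses control-siRNA samples only: differential abundance of query vs
    baseline line, log2FC ranking, preranked enrichment on the term
    collection, optional custom-list enrichment, and zero-filled Kendall
    concordance of the resulting NES profile against the disease reference.
    """
    from .proteomics import anova_tukey  # local import to avoid cycle at module load

    meta = sample_meta.loc[sample_meta["sirna"] == control_sirna].copy()
    for line in (baseline_line, query_line):
        if not (meta["cell_line"] == line).any():
            raise ValueError(f"no control-siRNA samples for cell line {line!r}")
    # recast the two lines as groups within one pseudo cell line
    meta2 = meta.assign(cell_line="between_lines", sirna=meta["cell_line"])
    de = anova_tukey(matrix[list(meta2["sample"])], meta2, control=baseline_line)
    de = de.loc[de["sirna"] == query_line]
    ranking = de.set_index("protein")["log2fc"].astype(float)
    enrichment = preranked_gsea(
        ranking, collection, n_perm=n_perm, seed=seed, min_size=min_size, max_size=max_size
    )
    subtype = None
    if subtype_lists is not None and len(subtype_lists):
        subtype = set_enrichment_custom(ranking, subtype_lists, n_perm=n_perm, seed=seed)
    conc = score_term_concordance(
        {(query_line, "vs_" + baseline_line): enrichment},
        reference, annotation, alpha=alpha, min_terms=min_terms,
    )
    return {"de": de, "ranking": ranking, "enrichment": enrichment,
            "subtype_enrichment": subtype, "concordance": conc}
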