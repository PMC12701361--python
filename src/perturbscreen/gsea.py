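"""Preranked gene-set enrichment implemented from first principles.

The engine computes the weighted Kolmogorov–Smirnov-style running-sum
enrichment score (ES) over a ranked gene list, builds a permutation null by
drawing random gene sets of equal size from the universe (gene-label
permutation, the preranked convention), normalizes sign-stratified to an NES,
and reports permutation p values with Benjamini–Hochberg adjustment.  The
same machinery serves GO-style collections and arbitrary custom gene lists
(e.g., microglial-subtype signatures).

Ranking statistics are supplied as a :class:`pandas.Series` mapping gene
label to statistic; gene sets as a :class:`GeneSetCollection`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "MappingReport",
    "enrichment_score",
    "preranked_gsea",
    "set_enrichment_custom",
    "map_orthologs",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions.

    ``sets`` maps term -> ordered tuple of unique gene labels (order is the
    GMT line order, so write->read round-trips are identities).
    """

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {term!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {term!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def membership(self, term: str) -> frozenset:
        return frozenset(self.sets[term])

    def universe(self) -> frozenset:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return frozenset(out)


def _prepare_ranking(ranked: pd.Series) -> pd.Series:
    """Sort descending with a stable tie-break on input order."""
    if not isinstance(ranked, pd.Series):
        ranked = pd.Series(dict(ranked), dtype=float)
    if ranked.index.has_duplicates:
        raise ValueError("ranking contains duplicate gene labels")
    if ranked.isna().any():
        raise ValueError("ranking contains missing statistics")
    values = ranked.to_numpy(dtype=float)
    if len(np.unique(values)) < len(values):
        logger.warning("ranking contains tied statistics; ties broken by input order")
    order = np.argsort(-values, kind="stable")
    return ranked.iloc[order]


def _es_batch(absw: np.ndarray, positions: np.ndarray, n_universe: int):
    """Signed-extremum running-sum ES for a batch of same-size gene sets.

    ``positions`` is (B, n) of sorted ascending hit indices into the ranked
    list; ``absw`` is |stat|**weight over the full ranked list.  Returns
    (es, idx_pos, idx_neg) where the idx arrays locate the extremum hit for
    leading-edge extraction.
    """
    b, n = positions.shape
    n_miss = n_universe - n
    if n_miss <= 0:
        raise ValueError("gene set equals the ranked universe; ES undefined")
    w = absw[positions]
    sumw = w.sum(axis=1, keepdims=True)
    degenerate = sumw[:, 0] == 0.0
    if degenerate.any():
        # all in-set statistics are exactly zero: fall back to equal steps
        w = np.where(degenerate[:, None], 1.0, w)
        sumw = np.where(degenerate[:, None], float(n), sumw)
    hit_cum = np.cumsum(w, axis=1) / sumw
    miss_cum = (positions - np.arange(n)[None, :]) / n_miss
    val_at_hit = hit_cum - miss_cum          # running sum just after each hit
    val_before_hit = val_at_hit - w / sumw   # running sum just before each hit
    idx_pos = np.argmax(val_at_hit, axis=1)
    idx_neg = np.argmin(val_before_hit, axis=1)
    pos_ex = val_at_hit[np.arange(b), idx_pos]
    neg_ex = val_before_hit[np.arange(b), idx_neg]
    # positive extremum wins magnitude ties (tolerance absorbs fp noise)
    es = np.where(pos_ex >= -neg_ex - 1e-12, pos_ex, neg_ex)
    return es, idx_pos, idx_neg


def enrichment_score(ranked: pd.Series, geneset, weight: float = 1.0):
    """Running-sum enrichment score of one gene set in a ranked list.

    The running sum increments by ``|stat|**weight / sum_in_set`` at in-set
    genes and decrements by ``1/(N - n)`` elsewhere; the ES is the signed
    maximum deviation from zero.  Positive ties between the positive and
    negative extremum resolve to the positive one.

    Returns ``(es, leading_edge)`` where the leading edge lists the in-set
    genes at or before (after, for a negative ES) the extremum, in rank order.
    """
    ranked = _prepare_ranking(ranked)
    members = frozenset(geneset)
    genes = ranked.index.to_numpy()
    positions = np.flatnonzero(np.fromiter((g in members for g in genes), bool, len(genes)))
    if positions.size == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    absw = np.abs(ranked.to_numpy(dtype=float)) ** weight
    es, idx_pos, idx_neg = _es_batch(absw, positions[None, :], len(genes))
    es = float(es[0])
    if es >= 0:
        leading = genes[positions[: idx_pos[0] + 1]]
    else:
        leading = genes[positions[idx_neg[0]:]]
    return es, list(leading)


def _random_positions(rng: np.random.Generator, n_perm: int, size: int, n_universe: int) -> np.ndarray:
    """Sorted hit positions for ``n_perm`` random sets of ``size`` genes."""
    out = np.empty((n_perm, size), dtype=np.intp)
    chunk = max(1, min(n_perm, 4_000_000 // max(n_universe, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        r = rng.random((b, n_universe))
        part = np.argpartition(r, size - 1, axis=1)[:, :size]
        out[done : done + b] = np.sort(part, axis=1)
        done += b
    return out


def preranked_gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 10000,
    seed: int | None = None,
    min_size: int = 10,
    max_size: int = 500,
    weight: float = 1.0,
    adaptive: bool = False,
    max_perm: int = 1_000_000,
) -> pd.DataFrame:
    """Permutation-based preranked GSEA over a gene-set collection.

    For every term with ``min_size <= |set ∩ universe| <= max_size`` the
    observed ES is compared against a null of random equal-size gene sets
    (shared across terms of the same size).  The NES divides the ES by the
    mean magnitude of same-sign null scores; the nominal p value is
    ``(1 + #same-sign null at least as extreme) / (1 + #same-sign null)``.
    With ``adaptive=True`` the per-size null is doubled until every term of
    that size has >= 10 same-sign exceedances or ``max_perm`` is reached
    (a plain-permutation stand-in for multilevel split sampling).

    Returns a DataFrame with columns term, es, nes, p, p_adj, size,
    leading_edge, low_confidence; terms appear in collection order.
    """
    ranked = _prepare_ranking(ranked)
    genes = ranked.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_universe = len(genes)
    if n_universe < min_size:
        raise ValueError("ranked universe smaller than min_size")
    absw = np.abs(ranked.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(seed)

    tested: list[dict] = []
    for term in collection:
        pos = np.array(sorted(gene_pos[g] for g in collection.sets[term] if g in gene_pos), dtype=np.intp)
        size = pos.size
        if size == 0:
            logger.info("term %s has no overlap with the universe; skipped", term)
            continue
        if size < min_size or size > max_size:
            continue
        if size == n_universe:
            logger.info("term %s spans the whole universe; untestable, skipped", term)
            continue
        es, idx_pos, idx_neg = _es_batch(absw, pos[None, :], n_universe)
        es = float(es[0])
        if es >= 0:
            leading = list(genes[pos[: idx_pos[0] + 1]])
        else:
            leading = list(genes[pos[idx_neg[0]:]])
        tested.append({"term": term, "es": es, "size": int(size), "leading_edge": leading})

    # one permutation null per distinct set size, reused across terms
    nulls: dict[int, np.ndarray] = {}
    for size in sorted({t["size"] for t in tested}):
        positions = _random_positions(rng, n_perm, size, n_universe)
        nulls[size] = _es_batch(absw, positions, n_universe)[0]

    if adaptive:
        for size in sorted(nulls):
            while nulls[size].size < max_perm:
                null = nulls[size]
                need_more = False
                for t in (t for t in tested if t["size"] == size):
                    if t["es"] >= 0:
                        exceed = int((null[null > 0] >= t["es"]).sum())
                    else:
                        exceed = int((null[null < 0] <= t["es"]).sum())
                    if exceed < 10:
                        need_more = True
                        break
                if not need_more:
                    break
                extra = _random_positions(rng, null.size, size, n_universe)
                nulls[size] = np.concatenate([null, _es_batch(absw, extra, n_universe)[0]])

    rows = []
    for t in tested:
        null = nulls[t["size"]]
        es = t["es"]
        if es >= 0:
            same_sign = null[null > 0]
            extreme = int((same_sign >= es).sum())
        else:
            same_sign = null[null < 0]
            extreme = int((same_sign <= es).sum())
        low_confidence = same_sign.size == 0
        p = (1.0 + extreme) / (1.0 + same_sign.size)
        if low_confidence:
            nes = np.nan
            p = 1.0
        else:
            nes = es / np.mean(np.abs(same_sign))
        rows.append(
            {
                "term": t["term"],
                "es": es,
                "nes": nes,
                "p": p,
                "size": t["size"],
                "leading_edge": t["leading_edge"],
                "low_confidence": low_confidence,
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "es", "nes", "p", "size", "leading_edge", "low_confidence"]
    )
    result.insert(4, "p_adj", bh_adjust(result["p"].to_numpy()) if len(result) else [])
    return result


def set_enrichment_custom(
    ranked: pd.Series,
    lists: GeneSetCollection,
    n_perm: int = 10000,
    seed: int | None = None,
    min_size: int = 5,
    max_size: int = 5000,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Enrichment of custom gene lists (e.g., microglial-subtype signatures).

    Identical engine to :func:`preranked_gsea` with a lower size floor and
    adaptive permutation escalation enabled, since custom lists are few and
    their p values are read individually.
    """
    return preranked_gsea(
        ranked,
        lists,
        n_perm=n_perm,
        seed=seed,
        min_size=min_size,
        max_size=max_size,
        weight=weight,
        adaptive=True,
    )


@dataclass
class MappingReport:
    n_input: int
    n_mapped: int
    n_unmapped: int
    n_ambiguous_dropped: int
    unmapped: list[str] = field(default_factory=list)


def _clean_mapping(mapping) -> tuple[dict[str, str], int]:
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] < 2:
            raise ValueError("ortholog mapping needs two columns (source, target)")
        pairs = mapping.iloc[:, :2].astype(str)
    else:
        pairs = pd.DataFrame(list(mapping.items()), columns=["source", "target"]).astype(str)
    pairs = pairs.drop_duplicates()
    src, tgt = pairs.columns[0], pairs.columns[1]
    ambiguous = pairs[src].duplicated(keep=False) | pairs[tgt].duplicated(keep=False)
    n_ambiguous = int(ambiguous.sum())
    if n_ambiguous:
        logger.warning("dropping %d ambiguous (non one-to-one) mapping rows", n_ambiguous)
    kept = pairs.loc[~ambiguous]
    return dict(zip(kept[src], kept[tgt])), n_ambiguous


def map_orthologs(obj, mapping):
    """Translate gene labels through a one-to-one ortholog mapping.

    ``obj`` is a ranking Series or a :class:`GeneSetCollection`.  Rows whose
    source or target appears more than once in the mapping are dropped as
    ambiguous; genes without a mapping are dropped and reported.  Returns
    ``(translated, MappingReport)``.
    """
    lookup, n_ambiguous = _clean_mapping(mapping)
    if isinstance(obj, GeneSetCollection):
        new_sets, new_desc = {}, {}
        unmapped: list[str] = []
        n_input = 0
        for term, genes in obj.sets.items():
            n_input += len(genes)
            kept = tuple(lookup[g] for g in genes if g in lookup)
            unmapped.extend(g for g in genes if g not in lookup)
            if kept:
                new_sets[term] = kept
                if term in obj.descriptions:
                    new_desc[term] = obj.descriptions[term]
            else:
                logger.info("term %s lost all genes in ortholog mapping; dropped", term)
        report = MappingReport(n_input, n_input - len(unmapped), len(unmapped), n_ambiguous, unmapped)
        return GeneSetCollection(new_sets, new_desc), report
    series = obj if isinstance(obj, pd.Series) else pd.Series(dict(obj), dtype=float)
    keep = series.index.isin(lookup.keys())
    unmapped = list(series.index[~keep])
    translated = series.loc[keep].rename(index=lookup)
    report = MappingReport(len(series), int(keep.sum()), len(unmapped), n_ambiguous, unmapped)
    return translated, report
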