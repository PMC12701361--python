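"""Phenotype-proteome integration and target tiering.

Assay effect sizes are correlated (Spearman) with term-level NES across
knockdowns, pairing each (siRNA, cell line) point's phenotype effect with
that knockdown's enrichment for the term.  LPS-stimulated NF-kB effects are
excluded because the proteomes were collected without LPS induction.
Phenotype hits, signature-reversal calls and phenotype-coupled terms are
then combined into a per-target scorecard with a deterministic tier label.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["correlate_assay_terms", "build_scorecards", "TIERS"]

TIERS = ("top", "supported", "phenotype_only", "proteome_only", "none")


def correlate_assay_terms(
    effects: pd.DataFrame,
    enrichments: dict[tuple[str, str], pd.DataFrame],
    min_points: int = 8,
    alpha: float = 0.05,
    exclude_lps_nfkb: bool = True,
    per_line: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of assay effect sizes with term NES values.

    For each (assay, term), points are the (siRNA, cell line) pairs having
    both an effect estimate and an NES for the term; raw NES values are used
    whether or not the enrichment was significant.  Points pool both cell
    lines by default (``per_line=True`` stratifies).  BH adjustment spans
    all correlations jointly.
    """
    eff = effects.copy()
    if exclude_lps_nfkb:
        eff = eff.loc[~((eff["assay"] == "nfkb") & (eff["dose"] == "LPS"))]
    nes_rows = []
    for (target, line), table in enrichments.items():
        sub = table.loc[~table["nes"].isna(), ["term", "nes"]].copy()
        sub["sirna"] = target
        sub["cell_line"] = line
        nes_rows.append(sub)
    if not nes_rows:
        return pd.DataFrame(columns=["assay", "dose", "cell_line", "term", "rho", "n", "p", "p_adj"])
    nes = pd.concat(nes_rows, ignore_index=True)
    merged = eff.merge(nes, on=["sirna", "cell_line"], how="inner")

    strata = ["assay", "dose", "term"] + (["cell_line"] if per_line else [])
    rows = []
    for key, grp in merged.groupby(strata, sort=True, observed=True):
        if len(grp) < min_points:
            continue
        x = grp["effect"].to_numpy(dtype=float)
        y = grp["nes"].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            logger.info("constant vector for %s; pair skipped", key)
            continue
        rho, p = stats.spearmanr(x, y)
        row = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
        row.update(rho=float(rho), n=len(grp), p=float(p))
        rows.append(row)
    cols = strata + ["rho", "n", "p", "p_adj"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out[cols]


def build_scorecards(
    estimates: pd.DataFrame,
    concordance: pd.DataFrame,
    integration: pd.DataFrame,
    enrichments: dict[tuple[str, str], pd.DataFrame],
    alpha: float = 0.05,
    tier_methods: tuple[str, ...] = ("kendall_terms",),
) -> pd.DataFrame:
    """Per-target synthesis of phenotype, reversal and coupling evidence.

    * ``phenotype_hits``: (assay, dose, cell line, direction) of every hit.
    * ``reversal_domains``: (domain, method, cell line) of every
      anti-correlated concordance call.
    * ``coupled_terms``: (assay, term) pairs significant in the integration
      table where this target's own enrichment for the term is significant.
    * ``tier``: top (all three kinds of evidence), supported (hit and
      reversal), phenotype_only, proteome_only, or none.  Adding evidence
      can only promote a target.

    The tier predicate counts reversal evidence only from the methods in
    ``tier_methods`` (default: the term-level Kendall concordance, the
    primary reversal construct); protein-level Pearson reversals are listed
    on the scorecard as supporting evidence but do not drive the tier.
    """
    targets = sorted(
        set(estimates["sirna"])
        | set(concordance["target"]) if len(concordance) else set(estimates["sirna"])
    )
    sig_int = (
        integration.loc[integration["p_adj"] <= alpha]
        if len(integration)
        else integration
    )
    rows = []
    for target in targets:
        hits = estimates.loc[(estimates["sirna"] == target) & estimates["hit"]]
        hit_list = [
            (r["assay"], r["dose"], r["cell_line"], "up" if r["effect"] > 0 else "down")
            for _, r in hits.iterrows()
        ]
        if len(concordance):
            rev = concordance.loc[
                (concordance["target"] == target) & (concordance["call"] == "anti_correlated")
            ]
            rev_list = [(r["domain"], r["method"], r["cell_line"]) for _, r in rev.iterrows()]
        else:
            rev_list = []
        rev_for_tier = [r for r in rev_list if r[1] in tier_methods]
        coupled = []
        for _, r in sig_int.iterrows():
            for (t, line), table in enrichments.items():
                if t != target:
                    continue
                sub = table.loc[(table["term"] == r["term"]) & (table["p_adj"] <= alpha)]
                if len(sub):
                    coupled.append((r["assay"], r["term"]))
                    break
        coupled = sorted(set(coupled))
        if hit_list and rev_for_tier and coupled:
            tier = "top"
        elif hit_list and rev_for_tier:
            tier = "supported"
        elif hit_list:
            tier = "phenotype_only"
        elif rev_for_tier:
            tier = "proteome_only"
        else:
            tier = "none"
        rows.append(
            {
                "target": target,
                "n_phenotype_hits": len(hit_list),
                "phenotype_hits": hit_list,
                "n_reversal_domains": len(rev_list),
                "reversal_domains": rev_list,
                "n_coupled_terms": len(coupled),
                "coupled_terms": coupled,
                "tier": tier,
            }
        )
    return pd.DataFrame(rows)
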