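"""Sample QC and per-protein differential abundance for knockdown proteomes.

Samples with too few identified proteins are excluded, then each protein is
tested by one-way ANOVA across the (siRNA) groups within a cell line with
Tukey honestly-significant-difference post hoc p values for every
target-vs-control contrast (studentized-range reference, pooled
within-group variance, Tukey-Kramer standard errors for unbalanced groups).
Benjamini-Hochberg correction is applied per contrast across proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, studentized_range_sf

logger = logging.getLogger(__name__)

__all__ = ["qc_filter_samples", "anova_tukey", "count_significant", "QCResult"]

META_COLUMNS = ["sample", "cell_line", "sirna", "replicate"]


@dataclass
class QCResult:
    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    report: pd.DataFrame
    excluded: list[str] = field(default_factory=list)
    untestable_groups: list[tuple[str, str]] = field(default_factory=list)


def _check_meta(matrix: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in sample_meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    meta = sample_meta.set_index("sample", drop=False)
    if not set(matrix.columns) <= set(meta.index):
        raise ValueError("metadata does not cover all matrix samples")
    if matrix.index.has_duplicates:
        raise ValueError("protein labels must be unique")
    return meta.loc[list(matrix.columns)]


def qc_filter_samples(
    matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    min_proteins: int = 6100,
) -> QCResult:
    """Drop samples identifying fewer than ``min_proteins`` proteins.

    The returned report lists, per sample, the number of non-missing
    proteins, the median log2 intensity, and whether it was excluded.
    Groups left with fewer than two replicates are flagged untestable.
    """
    meta = _check_meta(matrix, sample_meta)
    counts = matrix.notna().sum(axis=0)
    medians = matrix.median(axis=0, skipna=True)
    excluded = list(counts.index[counts < min_proteins])
    report = pd.DataFrame(
        {
            "sample": counts.index,
            "n_proteins": counts.to_numpy(),
            "median_log2_intensity": medians.to_numpy(),
            "excluded": counts.to_numpy() < min_proteins,
        }
    ).reset_index(drop=True)
    kept = [s for s in matrix.columns if s not in set(excluded)]
    if not kept:
        raise ValueError(f"all samples fall below the {min_proteins}-protein threshold")
    filtered = matrix[kept]
    meta_kept = meta.loc[kept].reset_index(drop=True)
    untestable = []
    for (line, sirna), grp in meta_kept.groupby(["cell_line", "sirna"], observed=True):
        if len(grp) < 2:
            untestable.append((line, sirna))
            logger.warning("group (%s, %s) left with %d replicate(s); untestable", line, sirna, len(grp))
    return QCResult(filtered, meta_kept, report, excluded, untestable)


def _anova_tukey_block(values: np.ndarray, labels: np.ndarray, control: str, targets: list[str]):
    """Vectorized ANOVA + Tukey contrasts for a (proteins x samples) block.

    ``values`` must be complete (no NaN).  Returns (f_p, {target: (diff,
    tukey_p)}, s2) arrays over proteins.
    """
    groups = [control] + targets
    n_total = values.shape[1]
    k = len(groups)
    means = {}
    counts = {}
    ssw = np.zeros(values.shape[0])
    for g in groups:
        cols = labels == g
        counts[g] = int(cols.sum())
        sub = values[:, cols]
        m = sub.mean(axis=1)
        means[g] = m
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    df = n_total - k
    s2 = ssw / df if df > 0 else np.full(values.shape[0], np.nan)
    grand = values.mean(axis=1)
    ssb = sum(counts[g] * (means[g] - grand) ** 2 for g in groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / s2
    f_p = stats.f.sf(f, k - 1, df) if df > 0 else np.full_like(f, np.nan)
    contrasts = {}
    for g in targets:
        diff = means[g] - means[control]
        se = np.sqrt(s2 / 2.0 * (1.0 / counts[g] + 1.0 / counts[control]))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(diff) / se
        p = np.full(q.shape, np.nan)
        ok = np.isfinite(q)
        if ok.any() and df > 0:
            p[ok] = studentized_range_sf(q[ok], k, df)
        contrasts[g] = (diff, p)
    return f_p, contrasts, s2


def anova_tukey(matrix: pd.DataFrame, sample_meta: pd.DataFrame, control: str) -> pd.DataFrame:
    """Differential abundance of every protein for each knockdown vs control.

    One-way ANOVA spans all siRNA groups within a cell line (variance is
    pooled within that background); Tukey HSD p values cover each
    target-vs-control contrast; log2fc is the group-mean difference.
    Proteins with missing values are tested complete-case (samples missing
    that protein dropped); proteins with zero pooled variance are flagged
    untestable and excluded from BH adjustment and downstream ranking.
    """
    meta = _check_meta(matrix, sample_meta)
    results = []
    for line, meta_line in meta.groupby("cell_line", sort=True, observed=True):
        samples = list(meta_line["sample"])
        labels = meta_line["sirna"].to_numpy()
        if control not in set(labels):
            raise ValueError(f"control siRNA {control!r} absent from cell line {line!r}")
        targets = sorted(set(labels) - {control})
        sub = matrix[samples]
        values = sub.to_numpy(dtype=float)
        complete = ~np.isnan(values).any(axis=1)
        prot_idx = sub.index.to_numpy()

        rows: dict[str, list] = {g: [] for g in targets}
        if complete.any():
            f_p, contrasts, s2 = _anova_tukey_block(values[complete], labels, control, targets)
            for g in targets:
                diff, p = contrasts[g]
                p = np.where(s2 > 0, p, np.nan)
                rows[g].append(
                    pd.DataFrame(
                        {"protein": prot_idx[complete], "log2fc": diff, "p": p,
                         "testable": s2 > 0}
                    )
                )
        for i in np.flatnonzero(~complete):
            v = values[i]
            keep = ~np.isnan(v)
            lab = labels[keep]
            present = set(lab)
            if control not in present:
                continue
            usable = [g for g in targets if g in present and (lab == g).sum() >= 1]
            if not usable:
                continue
            groups_here = [control] + [g for g in sorted(present) if g != control]
            if any((lab == g).sum() < 1 for g in groups_here):
                continue
            kk = len(groups_here)
            if keep.sum() - kk <= 0:
                continue
            f_p, contrasts, s2 = _anova_tukey_block(
                v[keep][None, :], lab, control, [g for g in groups_here if g != control]
            )
            for g in usable:
                diff, p = contrasts[g]
                rows[g].append(
                    pd.DataFrame(
                        {"protein": [prot_idx[i]], "log2fc": diff, "p": np.where(s2 > 0, p, np.nan),
                         "testable": s2 > 0}
                    )
                )
        for g in targets:
            if not rows[g]:
                continue
            block = pd.concat(rows[g], ignore_index=True)
            block.insert(1, "cell_line", line)
            block.insert(2, "sirna", g)
            block["p_adj"] = bh_adjust(block["p"].to_numpy())
            results.append(block)
    if not results:
        return pd.DataFrame(columns=["protein", "cell_line", "sirna", "log2fc", "p", "p_adj", "testable"])
    out = pd.concat(results, ignore_index=True)
    return out[["protein", "cell_line", "sirna", "log2fc", "p", "p_adj", "testable"]]


def count_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Number of proteins with adjusted p <= alpha per (cell line, siRNA)."""
    if results.empty:
        return pd.DataFrame(columns=["cell_line", "sirna", "n_significant"])
    sig = results["p_adj"] <= alpha
    out = (
        results.assign(sig=sig.fillna(False))
        .groupby(["cell_line", "sirna"], sort=True, observed=True)["sig"]
        .sum()
        .astype(int)
        .rename("n_significant")
        .reset_index()
    )
    return out
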