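"""Hit calling for cellular phenotype assays after siRNA knockdown.

Raw well-level readouts (viability, mitochondrial membrane potential,
phagocytosis, NF-kB reporter) are reduced to per-batch log2 fold changes
against the control siRNA within each (assay, cell line, batch, dose)
stratum, then modeled per assay/dose with siRNA x cell-line fixed effects
and a batch random intercept (REML).  The estimated marginal mean per
(siRNA, cell line) is the effect size; a z test against zero with
Benjamini-Hochberg correction within the assay defines hits.

Also provides 2^-ddCt relative quantification of knockdown efficiency from
qPCR cycle thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "batch_log2fc",
    "fit_effect_model",
    "ddct_fold_change",
    "summarize_hits",
    "KnockdownEfficiency",
    "HitSummary",
    "StratumError",
]

STRATA = ["assay", "cell_line", "batch", "dose"]
ASSAY_COLUMNS = ["assay", "cell_line", "sirna", "batch", "replicate", "dose", "value"]


class StratumError(ValueError):
    """Raised when a design stratum is missing its control siRNA."""


def _normalize_dose(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "dose" not in df.columns:
        df["dose"] = ""
    df["dose"] = df["dose"].fillna("").astype(str)
    return df


def batch_log2fc(measurements: pd.DataFrame, control: str) -> pd.DataFrame:
    """Per-batch log2 fold change of each siRNA against the control siRNA.

    Replicates are averaged (arithmetic mean of raw values) within each
    (assay, cell_line, batch, dose) stratum and the ratio to the control
    mean is log2-transformed.  Control rows are retained with log2fc = 0.
    """
    missing = [c for c in ("assay", "cell_line", "sirna", "batch", "value") if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    measurements = _normalize_dose(measurements)
    values = measurements["value"].to_numpy(dtype=float)
    if not np.all(values > 0):
        raise ValueError("all raw readouts must be positive for log2 transformation")

    means = (
        measurements.groupby(STRATA + ["sirna"], sort=True, observed=True)["value"]
        .mean()
        .reset_index()
    )
    bad = []
    rows = []
    for key, grp in means.groupby(STRATA, sort=True, observed=True):
        ctrl = grp.loc[grp["sirna"] == control, "value"]
        if ctrl.empty:
            bad.append(key)
            continue
        ctrl_mean = float(ctrl.iloc[0])
        out = grp.copy()
        out["log2fc"] = np.log2(out["value"].to_numpy() / ctrl_mean)
        out.loc[out["sirna"] == control, "log2fc"] = 0.0
        rows.append(out.drop(columns="value"))
    if bad:
        raise StratumError(f"control siRNA {control!r} missing in strata: {bad}")
    return pd.concat(rows, ignore_index=True)


def _fit_cell_means(data: pd.DataFrame, cell_col: str) -> pd.DataFrame:
    """Cell-means model of log2fc with a batch random intercept.

    With the full-interaction, no-intercept coding every fixed coefficient
    is directly the estimated marginal mean of one cell.  REML mixed fit;
    falls back to OLS when the batch variance estimate is on the zero
    boundary, the design has a single batch, or the fit fails to converge.
    The z (normal) reference is used for both paths.
    """
    endog = data["log2fc"].to_numpy(dtype=float)
    design = pd.get_dummies(data[cell_col], dtype=float)
    n_batches = data["batch"].nunique()
    params = bse = None
    if n_batches >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(endog, design, groups=data["batch"]).fit(reml=True)
            if fit.converged and float(np.asarray(fit.cov_re).ravel()[0]) > 1e-8:
                params, bse = fit.fe_params, fit.bse_fe
            else:
                logger.warning("batch variance estimated at zero boundary; using OLS")
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("mixed model failed to converge; using OLS")
    else:
        logger.warning("single batch; using OLS")
    if params is None:
        fit = sm.OLS(endog, design).fit()
        params, bse = fit.params, fit.bse
    z = np.where(np.asarray(bse) > 0, np.asarray(params) / np.asarray(bse), 0.0)
    return pd.DataFrame(
        {"cell": design.columns, "effect": np.asarray(params), "se": np.asarray(bse),
         "p": 2.0 * stats.norm.sf(np.abs(z))}
    )


def fit_effect_model(
    fcs: pd.DataFrame,
    control: str,
    alpha: float = 0.05,
    separate_lines: bool = False,
) -> pd.DataFrame:
    """Effect sizes, p values and hit calls per (assay, dose, siRNA, cell line).

    Fits one model per assay/dose stratum on the per-batch log2 fold changes
    (control rows, identically zero, are excluded).  ``separate_lines`` fits
    each cell line on its own instead of the joint interaction model.
    Benjamini-Hochberg correction is applied within each assay/dose family;
    ``hit`` is ``p_adj <= alpha``.
    """
    fcs = _normalize_dose(fcs)
    data = fcs.loc[fcs["sirna"] != control].copy()
    if data.empty:
        raise ValueError("no non-control fold changes to model")
    sep = "\x1f"
    results = []
    for (assay, dose), grp in data.groupby(["assay", "dose"], sort=True, observed=True):
        if separate_lines:
            fits = []
            for line, sub in grp.groupby("cell_line", sort=True, observed=True):
                sub = sub.assign(cell=sub["sirna"] + sep + line)
                fits.append(_fit_cell_means(sub, "cell"))
            fit = pd.concat(fits, ignore_index=True)
        else:
            grp = grp.assign(cell=grp["sirna"] + sep + grp["cell_line"])
            fit = _fit_cell_means(grp, "cell")
        fit[["sirna", "cell_line"]] = fit["cell"].str.split(sep, expand=True)
        fit = fit.drop(columns="cell")
        fit.insert(0, "assay", assay)
        fit.insert(1, "dose", dose)
        fit["p_adj"] = bh_adjust(fit["p"].to_numpy())
        fit["hit"] = fit["p_adj"] <= alpha
        results.append(fit)
    out = pd.concat(results, ignore_index=True)
    return out[["assay", "dose", "cell_line", "sirna", "effect", "se", "p", "p_adj", "hit"]]


@dataclass
class KnockdownEfficiency:
    gene: str
    fold_change: float
    percent_knockdown: float
    ddct: float


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str = "control",
    knockdown_condition: str = "knockdown",
) -> KnockdownEfficiency:
    """Relative expression by the 2^-ddCt method.

    dCt = mean Ct(target) - mean Ct(reference) within each condition;
    ddCt = dCt(knockdown) - dCt(control); fold change = 2^-ddCt.
    Percent knockdown is 100 * (1 - fold change).
    """
    needed = {"gene", "condition", "ct"}
    if not needed.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(needed)}")
    dct = {}
    for cond in (control_condition, knockdown_condition):
        sub = ct.loc[ct["condition"] == cond]
        t = sub.loc[sub["gene"] == target, "ct"]
        r = sub.loc[sub["gene"] == reference, "ct"]
        if t.empty or r.empty:
            raise ValueError(f"missing Ct values for {target!r}/{reference!r} in condition {cond!r}")
        dct[cond] = float(t.mean() - r.mean())
    ddct = dct[knockdown_condition] - dct[control_condition]
    fold = float(2.0 ** (-ddct))
    return KnockdownEfficiency(target, fold, 100.0 * (1.0 - fold), ddct)


@dataclass
class HitSummary:
    per_target: pd.DataFrame   # target x (assay, dose, cell_line) hit indicator counts
    per_assay: pd.DataFrame    # hit counts per assay/dose
    n_targets_with_hit: int
    n_targets: int


def summarize_hits(estimates: pd.DataFrame) -> HitSummary:
    """Hit counts per target, per assay, and targets hit in >= 1 assay."""
    est = estimates.copy()
    per_target = (
        est.groupby(["sirna", "assay", "dose", "cell_line"], sort=True, observed=True)["hit"]
        .any()
        .reset_index()
    )
    per_assay = (
        est.loc[est["hit"]]
        .groupby(["assay", "dose"], sort=True, observed=True)["sirna"]
        .nunique()
        .rename("n_hit_targets")
        .reset_index()
    )
    hit_targets = set(est.loc[est["hit"], "sirna"])
    return HitSummary(
        per_target=per_target,
        per_assay=per_assay,
        n_targets_with_hit=len(hit_targets),
        n_targets=int(est["sirna"].nunique()),
    )
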