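"""Case-control validation statistics.

Covers the wet-lab quantification formulas and the statistical layer used
to validate candidate biomarkers:

* relative expression by the 2^-dCq method against a reference gene;
* methylation fractions from restriction-enzyme qPCR: with a
  methylation-DEPENDENT enzyme (MDRE) the digested aliquot loses
  methylated template, m = 1 - 2^(Cq_und - Cq_dig); with a
  methylation-SENSITIVE enzyme (MSRE) it loses unmethylated template,
  m = 2^(Cq_und - Cq_dig); both clamped to [0, 1];
* digestion quality control on methylated/unmethylated control DNA;
* distribution-aware two-group comparison (Student t vs Mann-Whitney),
  correlation (Pearson vs Spearman), forward-backward stepwise OLS, and
  ROC analysis with DeLong confidence intervals and the Youden-optimal
  cutoff.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05
#: replicate Cq runs differing by more than this many cycles are flagged
CQ_DISCORDANCE_CYCLES = 1.0


# ---------------------------------------------------------------------------
# qPCR quantification
# ---------------------------------------------------------------------------

def relative_expression(cq_target_mean: float, cq_reference_mean: float) -> float:
    """Relative expression by 2^-dCq, dCq = Cq_target - Cq_reference."""
    return float(2.0 ** -(cq_target_mean - cq_reference_mean))


def mdre_methylation(cq_undigested: float, cq_digested: float) -> float:
    """Methylation fraction from a methylation-dependent enzyme assay.

    m = 1 - 2^(Cq_undigested - Cq_digested), clamped to [0, 1] (noise can
    push the raw value outside; the clamp is logged).
    """
    raw = 1.0 - 2.0 ** (cq_undigested - cq_digested)
    if raw < 0.0 or raw > 1.0:
        logger.warning("MDRE methylation %.3f outside [0,1]; clamped", raw)
    return float(min(max(raw, 0.0), 1.0))


def msre_methylation(cq_undigested: float, cq_digested: float) -> float:
    """Methylation fraction from a methylation-sensitive enzyme assay.

    m = 2^(Cq_undigested - Cq_digested), clamped to [0, 1].
    """
    raw = 2.0 ** (cq_undigested - cq_digested)
    if raw > 1.0:
        logger.warning("MSRE methylation %.3f outside [0,1]; clamped", raw)
    return float(min(max(raw, 0.0), 1.0))


def control_qc(
    positive_control_m: float,
    negative_control_m: float,
    positive_min: float = 0.9,
    negative_max: float = 0.1,
) -> bool:
    """Digestion batch QC: pass iff the fully methylated control reads
    near 1 and the unmethylated control near 0 (thresholds configurable)."""
    return positive_control_m >= positive_min and negative_control_m <= negative_max


def average_duplicates(cq_values: np.ndarray | list[float]) -> float:
    """Mean of replicate Cq runs; discordance beyond 1 cycle is flagged."""
    arr = np.asarray(cq_values, float)
    if arr.size > 1 and arr.max() - arr.min() > CQ_DISCORDANCE_CYCLES:
        logger.warning(
            "replicate Cq discordance %.2f cycles exceeds %.1f",
            arr.max() - arr.min(), CQ_DISCORDANCE_CYCLES,
        )
    return float(arr.mean())


def quantify_cq_table(cq: pd.DataFrame, assay_type: dict[str, str]) -> pd.DataFrame:
    """Per (sample, gene) quantification from a tidy Cq table.

    ``assay_type`` maps gene -> "expression", "mdre" or "msre".
    Replicates are averaged first. Expression genes need target and
    reference conditions; methylation genes need undigested and digested.
    Returns sample_id, group, gene, quantity.
    """
    means = (
        cq.groupby(["sample_id", "group", "gene", "condition"])["cq"]
        .apply(lambda v: average_duplicates(v.to_numpy()))
        .unstack("condition")
    )
    rows = []
    for (sample, group, gene), row in means.iterrows():
        kind = assay_type[gene]
        if kind == "expression":
            if pd.isna(row.get("reference")):
                raise ValueError(f"missing reference Cq for sample {sample}, gene {gene}")
            q = relative_expression(row["target"], row["reference"])
        elif kind == "mdre":
            q = mdre_methylation(row["undigested"], row["digested"])
        elif kind == "msre":
            q = msre_methylation(row["undigested"], row["digested"])
        else:
            raise ValueError(f"unknown assay type {kind!r} for gene {gene}")
        rows.append({"sample_id": sample, "group": group, "gene": gene, "quantity": q})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison / correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float


def _is_normal(x: np.ndarray) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > NORMALITY_ALPHA


def compare_groups(values, labels) -> ComparisonResult:
    """Two-group comparison routed by distribution shape.

    Both groups Shapiro-normal -> Student t; otherwise Mann-Whitney U
    (two-sided). Identical constant data yields p = 1.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) != 2:
        raise ValueError("compare_groups needs exactly two groups")
    a, b = groups
    if np.ptp(values) == 0:
        return ComparisonResult("mann_whitney_u", float(len(a) * len(b) / 2.0), 1.0)
    if _is_normal(a) and _is_normal(b):
        stat, p = stats.ttest_ind(a, b)
        return ComparisonResult("student_t", float(stat), float(p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    if np.isnan(p):
        p = 1.0
    return ComparisonResult("mann_whitney_u", float(stat), float(p))


def compare_categorical(table) -> ComparisonResult:
    """Chi-square test of a contingency table, Fisher exact for 2x2
    tables with any expected cell below 5."""
    table = np.asarray(table, float)
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table)
            return ComparisonResult("fisher_exact", float(odds), float(p))
        logger.warning("expected cell < 5 in a non-2x2 table; chi-square retained")
    return ComparisonResult("chi_square", float(chi2), float(p))


@dataclass(frozen=True)
class AssocResult:
    variable: str
    method: str  # "pearson" or "spearman"
    r: float
    p_value: float


def correlate(x, y, variable: str = "") -> AssocResult:
    """Pearson when both variables pass normality, else Spearman."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if _is_normal(x) and _is_normal(y):
        r, p = stats.pearsonr(x, y)
        return AssocResult(variable, "pearson", float(r), float(p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.spearmanr(x, y)
    return AssocResult(variable, "spearman", float(r), float(p))


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

CONDITION_NUMBER_LIMIT = 1e8


def stepwise_regression(
    response,
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> pd.DataFrame:
    """Forward-backward stepwise OLS with standardized coefficients.

    Variables enter at p <= ``entry_p`` and leave at p >= ``removal_p``
    (classic defaults). All variables are z-scored first, so the reported
    beta is the standardized coefficient. Candidates that would push the
    design's condition number past a guard are skipped with a warning.
    Returns a DataFrame (variable, beta, p_value) for the selected model,
    empty when nothing enters.
    """
    y = np.asarray(response, float)
    y = (y - y.mean()) / y.std(ddof=0) if y.std(ddof=0) > 0 else y - y.mean()
    X = candidates.copy().astype(float)
    for col in X.columns:
        sd = X[col].std(ddof=0)
        if sd == 0:
            logger.warning("dropping constant candidate %r", col)
            X = X.drop(columns=[col])
        else:
            X[col] = (X[col] - X[col].mean()) / sd

    selected: list[str] = []

    def fit(cols: list[str]):
        design = sm.add_constant(X[cols], has_constant="add")
        return sm.OLS(y, design).fit()

    changed = True
    while changed:
        changed = False
        if selected and fit(selected).ssr < 1e-10 * max(float(np.sum(y**2)), 1e-12):
            break  # essentially exact fit: further p-values are meaningless
        # forward step
        best_p, best_var = None, None
        for var in X.columns:
            if var in selected:
                continue
            trial = selected + [var]
            design = sm.add_constant(X[trial], has_constant="add")
            if np.linalg.cond(design) > CONDITION_NUMBER_LIMIT:
                logger.warning("skipping collinear candidate %r", var)
                continue
            res = fit(trial)
            p = res.pvalues[var]
            if p <= entry_p and (best_p is None or p < best_p):
                best_p, best_var = p, var
        if best_var is not None:
            selected.append(best_var)
            changed = True
        # backward step
        while selected:
            res = fit(selected)
            pvals = res.pvalues[selected]
            worst = pvals.idxmax()
            if pvals[worst] >= removal_p:
                selected.remove(worst)
                changed = True
            else:
                break

    if not selected:
        return pd.DataFrame(columns=["variable", "beta", "p_value"])
    res = fit(selected)
    return pd.DataFrame(
        {
            "variable": selected,
            "beta": [res.params[v] for v in selected],
            "p_value": [res.pvalues[v] for v in selected],
        }
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    sensitivity: float  # fraction, at the Youden-optimal cutoff
    specificity: float
    cutoff: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance (midrank formulation)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    def midrank(x):
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x), float)
        sorted_x = x[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and sorted_x[j] == sorted_x[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return ranks

    combined = np.concatenate([pos, neg])
    tz = midrank(combined)
    tx = midrank(pos)
    ty = midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    var = s01 / m + s10 / n
    return float(auc), float(var)


def roc_youden(scores, labels) -> RocResult:
    """Empirical ROC with DeLong CI and the Youden-optimal cutoff.

    ``labels`` are 1/True for cases. The AUC equals the concordant-pair
    fraction (Mann-Whitney statistic scaled by n1*n0); the p-value is a
    DeLong z-test against AUC = 0.5. Among cutoffs tied on Youden's J
    the lowest cutoff value is reported; a score >= cutoff predicts case.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if set(labels) != {0, 1}:
        raise ValueError("labels must contain both classes")
    auc, var = _delong_variance(scores, labels)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 0.0 if auc != 0.5 else 1.0
    p = min(max(p, 5e-324), 1.0)

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for cutoff in np.unique(scores):
        se_frac = float((pos >= cutoff).mean())
        sp_frac = float((neg < cutoff).mean())
        j = se_frac + sp_frac - 1.0
        # ties on J resolve to the lowest cutoff
        if best is None or j > best[0] + 1e-12:
            best = (j, cutoff, se_frac, sp_frac)
    _, cutoff, sens, spec = best
    return RocResult(auc, float(ci_low), float(ci_high), float(p), sens, spec, float(cutoff))


def combined_predictor(expr_values, meth_values, labels) -> RocResult:
    """ROC of the in-sample logistic combination of two predictors.

    A two-covariate logistic model is fitted on the standardized
    expression and methylation values and its predicted case probability
    is scored with :func:`roc_youden` (no cross-validation).
    """
    X = np.column_stack([np.asarray(expr_values, float), np.asarray(meth_values, float)])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    y = np.asarray(labels).astype(int)
    # effectively unpenalized maximum likelihood
    model = LogisticRegression(C=1e10, solver="lbfgs", max_iter=5000)
    model.fit(Xs, y)
    prob = model.predict_proba(Xs)[:, 1]
    return roc_youden(prob, y)
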