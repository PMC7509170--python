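"""Two-group differential testing with empirical-Bayes variance moderation.

The moderated t follows the standard microarray framework: per-feature
sample variances are shrunk toward a common prior ``s0^2`` with ``d0``
pseudo-degrees of freedom fitted by method of moments on the log-variance
distribution, and each feature is tested with ``d0 + df_residual`` degrees
of freedom. A plain Welch t is available as an alternative.

Direction calls use strict thresholds on the raw p-value and the log2
fold change: a feature at exactly p = 0.05 or |log2FC| = 0.3 is *not*
called. For methylation layers the log2 fold change is the log2 ratio of
group mean beta values and the additive difference (delta beta) is
reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import OmicsMatrix

_P_FLOOR = 1e-300  # p-values live in (0, 1]


@dataclass(frozen=True)
class TestConfig:
    """Thresholds and test choice for differential calling."""

    p_thr: float = 0.05
    lfc_thr: float = 0.3
    test: str = "moderated_t"  # or "welch_t"
    multiple_testing: str = "none"  # or "BH"

    def __post_init__(self) -> None:
        if self.p_thr <= 0 or self.lfc_thr <= 0:
            raise ValueError("thresholds must be positive")
        if self.test not in ("moderated_t", "welch_t"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.multiple_testing not in ("none", "BH"):
            raise ValueError(f"unknown correction {self.multiple_testing!r}")


def collapse_probes(matrix: OmicsMatrix, gene_map: Mapping[str, str]) -> OmicsMatrix:
    """Collapse probe-level expression rows to gene level.

    Probes without a matching gene symbol (absent from ``gene_map`` or
    mapped to an empty string) are removed; genes measured by several
    probes get the sample-wise arithmetic mean of those probes.
    """
    genes = pd.Series(
        [gene_map.get(p, "") for p in matrix.values.index], index=matrix.values.index
    )
    keep = genes != ""
    if keep.sum() == 0:
        raise ValueError("no probe maps to a gene symbol; nothing to collapse")
    collapsed = matrix.values[keep].groupby(genes[keep]).mean()
    collapsed.index.name = matrix.values.index.name
    return OmicsMatrix(collapsed, matrix.group_labels, matrix.layer)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x by Newton iteration (vectorised)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on the log-variance scale.

    Returns ``d0 = inf`` (complete pooling) when the observed spread of
    log variances is no larger than expected under a common variance.
    """
    s2 = np.asarray(s2, float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = np.sum((e - emean) ** 2) / (n - 1)
    evar = evar * n / (n - 1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(evar))
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderate_variances(s2: np.ndarray, df: int, d0: float, s0sq: float) -> np.ndarray:
    """Posterior variance: convex combination of prior and observed."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, float), s0sq)
    return (d0 * s0sq + df * np.asarray(s2, float)) / (d0 + df)


def test_two_group(matrix: OmicsMatrix, config: TestConfig = TestConfig()) -> pd.DataFrame:
    """Per-feature two-group test.

    Returns a DataFrame indexed by feature with columns mean_case,
    mean_control, log2FC, delta, p_value and direction (all ``none``
    until :func:`call_direction` is applied).
    """
    case = matrix.case_values().to_numpy(float)
    ctrl = matrix.control_values().to_numpy(float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    m1 = case.mean(axis=1)
    m2 = ctrl.mean(axis=1)
    if matrix.layer == "expression" and ((case < 0).any() or (ctrl < 0).any()):
        raise ValueError("negative expression values")
    delta = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(m1 / m2)
    log2fc = np.where(delta == 0, 0.0, log2fc)

    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    if config.test == "welch_t":
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v1 / n1 + v2 / n2
            t = delta / np.sqrt(se2)
            dfree = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            p = 2.0 * stats.t.sf(np.abs(t), dfree)
    else:
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        d0, s0sq = fit_variance_prior(s2, df)
        s2_post = moderate_variances(s2, df, d0, s0sq)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        df_total = df + d0  # complete pooling (d0 = inf) gives the normal reference
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    # degenerate features: zero variance in both groups
    degen = (v1 == 0) & (v2 == 0)
    p = np.where(degen & (delta == 0), 1.0, p)
    p = np.where(degen & (delta != 0), _P_FLOOR, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), _P_FLOOR, 1.0)

    out = pd.DataFrame(
        {
            "mean_case": m1,
            "mean_control": m2,
            "log2FC": log2fc,
            "delta": delta,
            "p_value": p,
            "direction": "none",
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )
    return out


def call_direction(records: pd.DataFrame, config: TestConfig = TestConfig()) -> pd.DataFrame:
    """Set the direction column with strict p and log2FC thresholds."""
    out = records.copy()
    p = out["p_value"].to_numpy(float)
    if config.multiple_testing == "BH":
        p = multipletests(p, method="fdr_bh")[1]
        out["p_adjusted"] = p
    lfc = out["log2FC"].to_numpy(float)
    direction = np.full(len(out), "none", dtype=object)
    sig = p < config.p_thr
    direction[sig & (lfc > config.lfc_thr)] = "up"
    direction[sig & (lfc < -config.lfc_thr)] = "down"
    out["direction"] = direction
    return out


def differential_records(
    matrix: OmicsMatrix, config: TestConfig = TestConfig()
) -> pd.DataFrame:
    """Convenience wrapper: test then call directions."""
    return call_direction(test_two_group(matrix, config), config)


def significant(records: pd.DataFrame) -> pd.DataFrame:
    """Rows with a non-``none`` direction call."""
    return records[records["direction"] != "none"]


def direction_counts(records: pd.DataFrame) -> dict[str, int]:
    """Summary counts: up, down, none and total (= their sum)."""
    counts = records["direction"].value_counts().to_dict()
    out = {d: int(counts.get(d, 0)) for d in ("up", "down", "none")}
    out["total_significant"] = out["up"] + out["down"]
    out["total"] = len(records)
    return out


def welch_config(config: TestConfig = TestConfig()) -> TestConfig:
    return replace(config, test="welch_t")
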