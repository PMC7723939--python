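"""Two-group differential analysis with empirical-Bayes variance moderation.

Per feature the log2 fold-change is the difference of group means on the log2
scale (test minus reference). Residual variances are shrunk toward a common
scaled inverse-chi-square prior fitted across features by the method of
moments (the classical moderated-t procedure); p-values come from a t
distribution with prior-augmented degrees of freedom and are BH-adjusted.

A feature is called significant when adjusted p < alpha AND |log2FC| >
fc_cutoff (both strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import REFERENCE, TEST, AbundanceMatrix

__all__ = [
    "moderated_t_test",
    "call_significant",
    "significance_counts",
    "fit_variance_prior",
]

_COLUMNS = ["log2FC", "t", "p_value", "adj_p_value", "significant"]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0^2) of a scaled inverse-chi-square prior to feature variances.

    Moment matching on log variances: with z = log(s2), E[z] and Var[z] are
    known functions of digamma/trigamma; the excess variance of z beyond the
    sampling term trigamma(df/2) identifies the prior degrees of freedom d0.
    Features with zero variance are excluded from the fit. Returns
    ``(inf, exp(mean))`` when the observed spread is no larger than expected
    under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        return np.inf, 0.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(m: AbundanceMatrix) -> pd.DataFrame:
    """Moderated two-sample t test per feature; returns the fold-change table.

    Columns: log2FC, t, p_value, adj_p_value, significant (initialized False;
    see :func:`call_significant`). Features whose pooled variance is exactly
    zero get t = 0 and p = 1 rather than an error.
    """
    if m.state != "log2":
        raise ValueError(f"moderated_t_test expects log2 data, got state {m.state!r}")
    ref = m.data[m.samples_in(REFERENCE)].to_numpy(dtype=float)
    test = m.data[m.samples_in(TEST)].to_numpy(dtype=float)
    n1, n2 = ref.shape[1], test.shape[1]
    df_resid = n1 + n2 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    log2fc = test.mean(axis=1) - ref.mean(axis=1)
    ss = ((ref - ref.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (test - test.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    d0, s0_sq = fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.where(s2 > 0, s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "log2FC": log2fc,
            "t": t,
            "p_value": p,
            "adj_p_value": adj,
            "significant": False,
        },
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    return out


def call_significant(
    table: pd.DataFrame, alpha: float = 0.05, fc_cutoff: float = 0.5
) -> pd.DataFrame:
    """Set the significance flag: adj p < alpha and |log2FC| > fc_cutoff, strict."""
    out = table.copy()
    out["significant"] = (out["adj_p_value"] < alpha) & (out["log2FC"].abs() > fc_cutoff)
    return out


def significance_counts(table: pd.DataFrame) -> dict[str, int]:
    sig = table[table["significant"]]
    return {
        "significant": int(len(sig)),
        "up": int((sig["log2FC"] > 0).sum()),
        "down": int((sig["log2FC"] < 0).sum()),
    }
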