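"""Group-level inference: repeated-measures ANOVA with Greenhouse-Geisser
correction, then FDR-corrected paired t-tests against the first saline
session.

The omnibus test is a one-way within-subject ANOVA whose degrees of
freedom are deflated by the Greenhouse-Geisser sphericity estimate
epsilon, computed from the double-centered sample covariance of the
treatment columns; epsilon is bounded in [1/(k-1), 1].  When the omnibus
is significant, each drug is compared to the first saline session by a
paired t-test over the mice present in both columns, and the resulting
p-values are corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "gg_epsilon",
    "rm_anova_gg",
    "bh_fdr",
    "paired_t",
    "paired_t_fdr",
    "saline_stability_check",
    "decision_procedure",
]


@dataclass
class AnovaResult:
    F: float
    df1: float  # epsilon * (k-1)
    df2: float  # epsilon * (k-1) * (n-1)
    epsilon: float
    p: float
    n: int  # subjects (complete cases)
    k: int  # treatments


def _complete_cases(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[~np.isnan(X).any(axis=1)]


def gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of columns."""
    X = _complete_cases(X)
    k = X.shape[1]
    S = np.cov(X, rowvar=False)
    row = S.mean(axis=0)
    grand = S.mean()
    Sc = S - row[None, :] - row[:, None] + grand
    denom = (k - 1) * float((Sc * Sc).sum())
    if denom <= 0:
        return 1.0  # degenerate covariance: no sphericity violation measurable
    eps = float(np.trace(Sc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(X: np.ndarray) -> AnovaResult:
    """One-way within-subject F with Greenhouse-Geisser-corrected df.

    ``X`` is subjects x treatments; rows containing NaN are dropped
    (listwise deletion).
    """
    X = _complete_cases(X)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 treatments")
    gm = X.mean()
    col = X.mean(axis=0)
    row = X.mean(axis=1)
    ss_treat = n * float(((col - gm) ** 2).sum())
    ss_subj = k * float(((row - gm) ** 2).sum())
    ss_tot = float(((X - gm) ** 2).sum())
    ss_err = max(ss_tot - ss_treat - ss_subj, 0.0)
    mse = ss_err / ((n - 1) * (k - 1))
    tiny = 1e-12 * max(ss_tot, 1.0)
    if ss_treat <= tiny:
        F = 0.0
    elif mse <= tiny:
        F = np.inf
    else:
        F = (ss_treat / (k - 1)) / mse
    eps = gg_epsilon(X)
    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return AnovaResult(float(F), float(df1), float(df2), eps, p, n, k)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def paired_t(a, b):
    """Two-sided paired t with a defined answer for zero-variance pairs.

    Returns ``(t, p, n_pairs)``; pairs with missing values are dropped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        return np.nan, np.nan, n
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0, n
        return np.sign(d.mean()) * np.inf, 0.0, n
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), n


def paired_t_fdr(
    wide: pd.DataFrame, control: str = "saline1", alpha: float = 0.05, exclude=("saline2",)
) -> pd.DataFrame:
    """Paired t of every drug column against the control, BH across drugs.

    ``wide`` is mice x treatments; only mice with both cells present
    enter each pairwise test (overlapping-animals rule).  Columns listed
    in ``exclude`` (the second saline by default) are not part of the
    corrected family.
    """
    if control not in wide.columns:
        raise ValueError(f"control column {control!r} missing")
    drugs = [c for c in wide.columns if c != control and c not in exclude]
    rows = []
    for drug in drugs:
        t, p, n = paired_t(wide[drug].to_numpy(), wide[control].to_numpy())
        rows.append({"drug": drug, "n_pairs": n, "t": t, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    out["significant"] = out["q"] < alpha
    return out


def saline_stability_check(wide: pd.DataFrame, first: str = "saline1", second: str = "saline2"):
    """Paired t between the two saline sessions for each measure column set.

    Accepts either a mice x {saline1, saline2} frame (returns a single
    p) or arrays via :func:`paired_t`.  Used as a gate: all p > 0.05
    justifies using only the first saline session as control.
    """
    if first not in wide.columns or second not in wide.columns:
        raise ValueError("both saline columns must be present")
    t, p, n = paired_t(wide[first].to_numpy(), wide[second].to_numpy())
    return {"t": t, "p": p, "n_pairs": n}


def decision_procedure(
    wide: pd.DataFrame, control: str = "saline1", alpha: float = 0.05, exclude=("saline2",)
):
    """Omnibus rm-ANOVA gate, then FDR-corrected paired t-tests.

    Pairwise tests run only when the Greenhouse-Geisser-corrected
    omnibus is significant, mirroring the gated workflow.  Returns
    ``(AnovaResult, pairwise DataFrame or None)``.
    """
    cols = [c for c in wide.columns if c not in exclude]
    an = rm_anova_gg(wide[cols].to_numpy(dtype=float))
    if an.p < alpha:
        return an, paired_t_fdr(wide, control=control, alpha=alpha, exclude=exclude)
    return an, None
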