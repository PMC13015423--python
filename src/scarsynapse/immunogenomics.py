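"""Subgroup comparisons and MDF-neoantigen coupling statistics.

Homologous-recombination-deficient (HRD) tumors accumulate MMEJ deletion scars
whose frameshift products are a disproportionate source of predicted
neoantigens. This module provides the statistical kernels used to demonstrate
that coupling: pairwise Mann-Whitney subgroup contrasts, Pearson/Spearman
correlation, a TMB-adjusted residual association (so the MDF-neoantigen link is
not just total mutation count), and Pearson chi-square contingency tests for
cell-state composition shifts.

All tests are two-sided. Because the MDF z-score is an affine map of the raw
count, correlations and rank statistics are identical whichever MDF scale the
caller passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContrastResult:
    group1: str
    group2: str
    n1: int
    n2: int
    statistic: float  # Mann-Whitney U for group1
    pvalue: float


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U. Exact enumeration when both n <= 8 and there
    are no ties; otherwise the tie-corrected normal approximation (no
    continuity correction)."""
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def group_compare(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    adjust: str | None = None,
) -> pd.DataFrame:
    """All pairwise two-sided Mann-Whitney contrasts between group labels.

    Parameters
    ----------
    values, groups
        Per-tumor numeric values and the matching group labels.
    adjust
        ``None`` (default) reports raw p-values; ``"bh"`` adds a
        Benjamini-Hochberg adjusted column across the pairwise contrasts.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must be the same length")
    labels = list(dict.fromkeys(groups))
    rows = []
    for g1, g2 in combinations(labels, 2):
        x = values[groups == g1]
        y = values[groups == g2]
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty group in contrast {g1} vs {g2}")
        u, p = _mannwhitney(x, y)
        rows.append(
            ContrastResult(str(g1), str(g2), len(x), len(y), u, p)
        )
    out = pd.DataFrame([vars(r) for r in rows])
    if adjust == "bh":
        out["pvalue_bh"] = _benjamini_hochberg(out["pvalue"].to_numpy())
    elif adjust is not None:
        raise ValueError(f"unknown adjust {adjust!r}")
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value (t approximation).

    ``method`` is ``"pearson"`` or ``"spearman"``. Requires n >= 3 finite pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs matched vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def tmb_adjusted_residuals(neoantigen, tmb) -> np.ndarray:
    """Neoantigen burden residualized on TMB.

    Both quantities are log10(x+1)-transformed (matching how burden and TMB are
    conventionally displayed), then neoantigen is regressed on TMB by ordinary
    least squares via the normal equations and the residuals are returned. The
    residuals sum to zero and are orthogonal to the transformed TMB vector.

    Zero-variance TMB degrades to centered transformed neoantigen, with a
    warning.
    """
    neoantigen = np.asarray(neoantigen, dtype=float)
    tmb = np.asarray(tmb, dtype=float)
    if len(neoantigen) != len(tmb) or len(neoantigen) < 3:
        raise ValueError("need matched vectors with n >= 3")
    if (neoantigen < 0).any() or (tmb < 0).any():
        raise ValueError("counts and TMB must be non-negative")
    y = np.log10(neoantigen + 1.0)
    x = np.log10(tmb + 1.0)
    if np.ptp(x) == 0:
        warnings.warn(
            "TMB has zero variance; residuals are centered neoantigen burden",
            stacklevel=2,
        )
        return y - y.mean()
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def residual_mdf_association(neoantigen, tmb, mdf) -> tuple[float, float]:
    """Pearson association of TMB-adjusted neoantigen residuals with MDF."""
    residuals = tmb_adjusted_residuals(neoantigen, tmb)
    return correlate(residuals, np.asarray(mdf, dtype=float), method="pearson")


def composition_chisq(contingency) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table.

    Returns ``(statistic, df, pvalue)`` with df = (r-1)(c-1). Tables with a
    zero row or column sum are rejected because expected counts must be
    positive.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("contingency must be a non-negative 2-D table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column sum: expected counts must be > 0")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)
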