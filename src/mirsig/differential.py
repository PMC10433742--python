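"""Gene-wise moderated t-tests with empirical-Bayes variance shrinkage.

The model is the standard hierarchical one for microarray variances: residual
variances s_g² are scaled-χ² about a chip-wide prior (d0, s0²), estimated by
moment matching of log-variances (digamma/trigamma). The posterior variance
s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g) replaces s_g² in the two-sample t,
which then has d_g + d0 degrees of freedom. FDR is controlled with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class EBPrior:
    """Empirical-Bayes variance prior: d0 prior degrees of freedom (may be
    inf; 0 disables moderation), s0_sq prior variance in log2² units."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("prior degrees of freedom must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")


@dataclass
class DifferentialTable:
    """Per-gene moderated-t results plus the prior they were computed under.

    ``table`` columns: log2_fc (meanA − meanB), s2 (residual variance), df,
    s2_post (posterior variance), t (moderated), p (two-sided), q (BH).
    """

    table: pd.DataFrame
    prior: EBPrior
    contrast: tuple[str, str]

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


# ---------------------------------------------------------------------------
# prior estimation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by monotone Newton iteration (|Δ| < 1e-8)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8:
            break
    return float(x)


def estimate_eb_prior(variances, dfs) -> EBPrior:
    """Fit (d0, s0²) by moment matching of log residual variances.

    With e_g = log s_g² − digamma(d_g/2) + log(d_g/2), the excess spread of the
    e_g over what the gene-level sampling variability trigamma(d_g/2) explains
    identifies trigamma(d0/2); a non-positive excess means the variances are
    consistent with a single common value, giving d0 = ∞. Zero variances are
    offset to half the smallest positive value (counted in the log).
    """
    s2 = np.asarray(variances, dtype=float).copy()
    d = np.broadcast_to(np.asarray(dfs, dtype=float), s2.shape).copy()
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    ok = d >= 1
    s2, d = s2[ok], d[ok]
    G = len(s2)
    if G < 10:
        raise ValueError("need at least 10 genes with df >= 1")
    zeros = s2 == 0
    if zeros.any():
        positive = s2[~zeros]
        if positive.size == 0:
            raise ValueError("all variances are zero")
        s2[zeros] = positive.min() / 2.0
        log.info("estimate_eb_prior: offset %d zero variances", int(zeros.sum()))
    if np.allclose(s2, s2[0]):
        return EBPrior(d0=np.inf, s0_sq=float(s2[0]))
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    e_bar = e.mean()
    excess = np.mean((e - e_bar) ** 2 * G / (G - 1) - polygamma(1, d / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_bar))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0_sq = float(np.exp(e_bar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBPrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def moderated_t_table(
    matrix: ExpressionMatrix,
    groupA: str,
    groupB: str,
    prior: EBPrior | None = None,
) -> DifferentialTable:
    """Two-group moderated t-test for every gene (effect = meanA − meanB).

    The prior is estimated from this matrix's residual variances when not
    supplied. d0 = 0 reproduces the classical pooled-variance Student t;
    d0 = ∞ fully shrinks to s0² and uses the normal reference distribution.
    """
    a_cols = matrix.samples_in_group(groupA)
    b_cols = matrix.samples_in_group(groupB)
    nA, nB = len(a_cols), len(b_cols)
    if nA < 2 or nB < 2:
        raise ValueError("both groups need at least 2 samples")
    A = matrix.values[a_cols].to_numpy()
    B = matrix.values[b_cols].to_numpy()
    meanA, meanB = A.mean(axis=1), B.mean(axis=1)
    df = nA + nB - 2
    ssA = ((A - meanA[:, None]) ** 2).sum(axis=1)
    ssB = ((B - meanB[:, None]) ** 2).sum(axis=1)
    s2 = (ssA + ssB) / df
    if prior is None:
        prior = estimate_eb_prior(s2, df)
        log.info(
            "estimated EB prior: d0=%.3g, s0_sq=%.4g", prior.d0, prior.s0_sq
        )
    d0, s0_sq = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    fc = meanA - meanB
    denom = np.sqrt(s2_post * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, fc / np.where(denom > 0, denom, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2_fc": fc,
            "s2": s2,
            "df": float(df),
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "q": q,
        },
        index=matrix.values.index,
    )
    return DifferentialTable(table, prior, (groupA, groupB))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    NaN p-values yield NaN q-values and are excluded from the test count m.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def select_differential(
    table: DifferentialTable | pd.DataFrame,
    fdr_threshold: float = 0.05,
    fold_threshold: float = 2.0,
) -> tuple[set[str], set[str]]:
    """Genes passing q < fdr AND |fold change| > fold_threshold, split by sign.

    ``fold_threshold`` is on the anti-logged scale: 2.0 means |log2FC| > 1.
    Set it to 1.0 for an FDR-only selection.
    """
    if fdr_threshold <= 0 or fold_threshold <= 0:
        raise ValueError("thresholds must be positive")
    frame = table.table if isinstance(table, DifferentialTable) else table
    log2_cut = np.log2(fold_threshold)
    sig = frame["q"] < fdr_threshold
    up = set(frame.index[sig & (frame["log2_fc"] > log2_cut)])
    down = set(frame.index[sig & (frame["log2_fc"] < -log2_cut)])
    return up, down


def venn_overlap(
    upA: set[str], downA: set[str], upB: set[str], downB: set[str]
) -> dict[str, int]:
    """Concordant / discordant / exclusive counts between two differential calls."""
    up_up = upA & upB
    down_down = downA & downB
    discordant = (upA & downB) | (downA & upB)
    allA, allB = upA | downA, upB | downB
    return {
        "up_up": len(up_up),
        "down_down": len(down_down),
        "discordant": len(discordant),
        "A_exclusive": len(allA - allB),
        "B_exclusive": len(allB - allA),
    }
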