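"""Observed/Expected fold-enrichment of gene lists in target/term sets.

Observed is the frequency of term genes within a list, Expected the background
frequency on the whole chip; their ratio is the fold-enrichment. Fisher's
exact test on the 2×2 membership table validates each fold, and BH-FDR is
applied across the emitted table. A complement list "outside" (background
minus all lists) is added automatically so depletion outside the signature is
visible alongside enrichment inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import TargetCollection


@dataclass
class EnrichmentResult:
    list_name: str
    term_name: str
    k: int  # term genes in the list
    m: int  # list size on chip
    K: int  # term genes on chip
    N: int  # chip size
    fold: float  # (k/m)/(K/N)
    p: float
    q: float | None = None

    @property
    def observed_freq(self) -> float:
        return self.k / self.m if self.m else 0.0

    @property
    def expected_freq(self) -> float:
        return self.K / self.N


def fold_enrichment(
    list_genes,
    term_genes,
    background,
    alternative: str = "greater",
    list_name: str = "list",
    term_name: str = "term",
) -> EnrichmentResult:
    """Fold = (k/m)/(K/N) with a one-sided Fisher exact p for enrichment.

    List and term are intersected with the background before counting;
    ``alternative`` may be "greater" (enrichment, default), "less"
    (depletion) or "two-sided".
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    lst = set(list_genes) & bg
    term = set(term_genes) & bg
    if not lst:
        raise ValueError("list shares no genes with the background")
    N, m, K = len(bg), len(lst), len(term)
    k = len(lst & term)
    table = [[k, m - k], [K - k, N - m - K + k]]
    _, p = stats.fisher_exact(table, alternative=alternative)
    expected = K / N
    fold = (k / m) / expected if expected > 0 else 0.0
    return EnrichmentResult(list_name, term_name, k, m, K, N, fold, float(p))


def enrich_many(
    lists: dict[str, set[str]],
    terms: TargetCollection,
    alternative: str = "greater",
    add_outside: bool = True,
) -> pd.DataFrame:
    """Fold-enrichment of every (list, term) pair, plus the "outside" complement.

    Returns one row per pair with BH q across all rows; empty terms get
    fold 0 and q 1 rather than NaN.
    """
    bg = terms.background
    all_lists = dict(lists)
    if add_outside:
        covered = set().union(*lists.values()) if lists else set()
        outside = bg - covered
        if outside:
            all_lists["outside"] = outside
    rows = []
    for list_name, list_genes in all_lists.items():
        for term_name, term_genes in terms.sets.items():
            r = fold_enrichment(
                list_genes, term_genes, bg, alternative, list_name, term_name
            )
            rows.append(
                {
                    "list": r.list_name,
                    "term": r.term_name,
                    "k": r.k,
                    "m": r.m,
                    "K": r.K,
                    "N": r.N,
                    "observed_freq": r.observed_freq,
                    "expected_freq": r.expected_freq,
                    "fold": r.fold,
                    "p": r.p,
                }
            )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["q"] = bh_adjust(frame["p"].to_numpy())
    return frame


def coverage_fraction(term_genes, signature_genes, background) -> float:
    """Percent of the (background-restricted) term captured by the signature."""
    bg = set(background)
    term = set(term_genes) & bg
    if not term:
        raise ValueError("term shares no genes with the background")
    covered = term & set(signature_genes)
    return 100.0 * len(covered) / len(term)
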