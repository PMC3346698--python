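"""Scoring detected pathways against a reference main chain.

Precision is the fraction of detected proteins that lie on the reference
(KEGG-style) main chain, recall the fraction of main-chain proteins that
were detected, and F = 2pr/(p+r) their harmonic mean.  A plain term-by-term
hypergeometric enrichment test (with optional Bonferroni correction) scores
how unlikely a path's overlap with an annotation term set is under random
draws from the background.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from scipy.stats import hypergeom

__all__ = [
    "EvalResult",
    "precision_recall_f",
    "hypergeometric_enrichment",
    "format_percent",
    "format_f",
]


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f_measure: float
    n_detected: int
    n_reference: int
    n_hit: int


def precision_recall_f(detected: Iterable[str], reference: Iterable[str]) -> EvalResult:
    """Precision, recall and F-measure of a detected protein set.

    ``precision = |detected ∩ reference| / |detected|`` (0 when nothing was
    detected), ``recall = |detected ∩ reference| / |reference|``,
    ``F = 2pr/(p+r)`` (0 when p + r = 0).
    """
    det = set(detected)
    ref = set(reference)
    if not ref:
        raise ValueError("reference set must be non-empty")
    hit = len(det & ref)
    precision = hit / len(det) if det else 0.0
    recall = hit / len(ref)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalResult(precision, recall, f, len(det), len(ref), hit)


def hypergeometric_enrichment(
    path_genes: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    bonferroni: bool = False,
) -> dict[str, float]:
    """Upper-tail hypergeometric P-value of each term's overlap with a path.

    For a term annotating K of the N background genes, the P-value is the
    probability of seeing at least the observed overlap among n = |path|
    draws without replacement.  With ``bonferroni`` each P is multiplied by
    the number of terms and capped at 1.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    genes = set(path_genes)
    if not genes <= bg:
        raise ValueError("path genes must be a subset of the background")
    n_terms = len(term_sets)
    out: dict[str, float] = {}
    for term, members in term_sets.items():
        members = set(members)
        if not members <= bg:
            raise ValueError(f"term {term!r} has genes outside the background")
        overlap = len(genes & members)
        # P(X >= overlap), X ~ Hypergeom(N=|bg|, K=|members|, n=|genes|)
        p = float(hypergeom.sf(overlap - 1, len(bg), len(members), len(genes)))
        if bonferroni:
            p = min(1.0, p * n_terms)
        out[term] = min(1.0, max(p, 0.0))
    return out


def format_percent(x: float) -> str:
    """Percentage at one-decimal precision, rounding halves up so exact
    fractions match benchmark-table convention (9/16 -> '56.3')."""
    return str(Decimal(str(100 * x)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def format_f(x: float) -> str:
    """F-measure at two-decimal precision, e.g. 0.5945 -> '0.59'."""
    return str(Decimal(str(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))
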