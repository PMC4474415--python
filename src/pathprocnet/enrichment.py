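"""Gene-set over-representation with Fisher's exact test and the EASE score.

A query list is tested against each annotation term's gene set over a
background universe using the one-tailed (upper) Fisher exact test.  The
EASE score is the conservative jackknifed variant in which one gene is
removed from the overlap cell before testing, so single-gene overlaps can
never appear significant.  Terms pass when their overlap count reaches
``min_count`` and their EASE score is at most ``max_ease`` (defaults 2 and
0.05, the conventional screening thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .annotation_io import TermRecord

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    """Raised for unusable enrichment input."""


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 table for two gene sets within a universe.

    ``a``: in both sets; ``b``: first only; ``c``: second only;
    ``d``: in neither (within the universe).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise EnrichmentError(f"contingency cells must be non-negative integers, got {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_upper_tail(counts: ContingencyCounts) -> float:
    """One-tailed Fisher exact p-value: P(X >= a) for hypergeometric X.

    X counts the overlap of a size-(a+b) draw from a universe of size n
    containing a+c marked elements.  An all-zero table is an error.
    """
    if counts.n == 0:
        raise EnrichmentError("all-zero contingency table")
    # sf(a-1) = P(X >= a)
    return float(hypergeom.sf(counts.a - 1, counts.n, counts.a + counts.c, counts.a + counts.b))


def ease_score(counts: ContingencyCounts, variant: str = "decrement") -> float:
    """Jackknifed Fisher exact p-value (EASE score).

    ``decrement`` (default): the overlap cell a is replaced by max(a-1, 0),
    other cells unchanged.  ``shift``: the removed gene is moved to cell b
    instead, keeping the margins of the first set.
    """
    a = max(counts.a - 1, 0)
    if variant == "decrement":
        jack = replace(counts, a=a)
    elif variant == "shift":
        jack = replace(counts, a=a, b=counts.b + (counts.a - a))
    else:
        raise EnrichmentError(f"unknown EASE variant {variant!r}")
    if jack.n == 0:
        # a=1 with empty margins jackknifes to an empty table; P(X >= 0) = 1
        return 1.0
    return fisher_upper_tail(jack)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    source: str
    overlap_count: int
    p_fisher: float
    p_ease: float
    q_bh: float | None = None


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted


def enrich(
    query: Iterable[str],
    terms: Sequence[TermRecord],
    universe: Iterable[str] | None = None,
    min_count: int = 2,
    max_ease: float = 0.05,
    ease_variant: str = "decrement",
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Screen annotation terms for over-representation in a query gene list.

    The universe defaults to the union of all genes annotated by any
    supplied term.  Query genes outside the universe are intersected away
    with a warning.  Results with overlap >= ``min_count`` and EASE score
    <= ``max_ease`` are returned sorted by EASE score, ties broken by term
    id, so output does not depend on input order.  When ``bh_correct`` is
    set, Benjamini-Hochberg q-values over the EASE scores of all tested
    terms are attached (the filter still applies to the raw EASE score).
    """
    if min_count < 1:
        raise EnrichmentError("min_count must be >= 1")
    if universe is None:
        universe_set: set[str] = set()
        for term in terms:
            universe_set |= term.genes
    else:
        universe_set = set(universe)
    if not universe_set:
        raise EnrichmentError("empty universe")
    query_set = set(query)
    stray = query_set - universe_set
    if stray:
        logger.warning("%d query genes outside the universe were dropped", len(stray))
        query_set &= universe_set

    rows: list[EnrichmentResult] = []
    ease_all: list[float] = []
    for term in terms:
        term_genes = term.genes & universe_set
        a = len(query_set & term_genes)
        counts = ContingencyCounts(
            a=a,
            b=len(query_set) - a,
            c=len(term_genes) - a,
            d=len(universe_set) - len(query_set) - len(term_genes) + a,
        )
        p_f = fisher_upper_tail(counts)
        p_e = ease_score(counts, variant=ease_variant)
        ease_all.append(p_e)
        rows.append(EnrichmentResult(term.term_id, term.name, term.source, a, p_f, p_e))

    if bh_correct and rows:
        qvals = _bh_adjust(ease_all)
        rows = [replace(r, q_bh=q) for r, q in zip(rows, qvals)]

    selected = [r for r in rows if r.overlap_count >= min_count and r.p_ease <= max_ease]
    selected.sort(key=lambda r: (r.p_ease, r.term_id))
    return selected


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as handle:
        handle.write("term_id\tname\tsource\toverlap\tp_fisher\tp_ease\n")
        for r in results:
            handle.write(
                f"{r.term_id}\t{r.name}\t{r.source}\t{r.overlap_count}"
                f"\t{r.p_fisher:.6g}\t{r.p_ease:.6g}\n"
            )
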