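"""Cohen's kappa agreement between annotation terms.

Two annotation terms are compared as binary raters over a gene universe:
each either annotates a gene or does not.  With the 2x2 counts a (both),
b (first only), c (second only), d (neither),

    Pr_agree  = (a + d) / n
    Pr_random = ((a+b)(a+c) + (b+d)(c+d)) / n^2
    kappa     = (Pr_agree - Pr_random) / (1 - Pr_random)

kappa is 1 for identical sets, near 0 for chance-level overlap, and
negative for below-chance agreement.  The universe defaults to the union
of genes over all supplied terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import TermRecord
from .enrichment import ContingencyCounts


class KappaError(ValueError):
    pass


def contingency(
    gi: Iterable[str], gj: Iterable[str], universe: Iterable[str]
) -> ContingencyCounts:
    """2x2 membership table for two gene sets, restricted to the universe."""
    u = set(universe)
    if not u:
        raise KappaError("empty universe")
    si = set(gi) & u
    sj = set(gj) & u
    a = len(si & sj)
    b = len(si) - a
    c = len(sj) - a
    return ContingencyCounts(a=a, b=b, c=c, d=len(u) - a - b - c)


def kappa_score(counts: ContingencyCounts) -> float:
    """Chance-corrected agreement for one 2x2 table.

    Degenerate case Pr_random = 1 (e.g. both sets empty or both equal to
    the whole universe): returns 1.0 when the sets agree exactly
    (b = c = 0), else 0.0.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    n = counts.n
    if n == 0:
        raise KappaError("empty contingency table")
    pr_agree = (a + d) / n
    pr_random = ((a + b) * (a + c) + (b + d) * (c + d)) / (n * n)
    if pr_random >= 1.0:
        return 1.0 if (b == 0 and c == 0) else 0.0
    return (pr_agree - pr_random) / (1.0 - pr_random)


@dataclass
class KappaMatrix:
    """GOBP x pathway kappa similarity matrix with ordered id lists."""

    gobp_ids: list[str]
    pathway_ids: list[str]
    scores: np.ndarray  # shape (len(gobp_ids), len(pathway_ids))

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gobp_ids), len(self.pathway_ids)):
            raise KappaError("score matrix shape does not match id lists")
        if len(set(self.gobp_ids)) != len(self.gobp_ids):
            raise KappaError("duplicate GOBP ids")
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise KappaError("duplicate pathway ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gobp_ids, columns=self.pathway_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gobp_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "KappaMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


def kappa_matrix(
    gobp_terms: Sequence[TermRecord],
    pathway_terms: Sequence[TermRecord],
    universe: Iterable[str] | None = None,
) -> KappaMatrix:
    """Kappa scores for every (GOBP term, pathway) pair.

    Rows are GOBP terms, columns pathways.  The universe defaults to the
    union of genes over all terms in both lists.  Computation is
    vectorized over binary membership matrices; each cell equals
    ``kappa_score(contingency(...))`` exactly.
    """
    if not gobp_terms or not pathway_terms:
        raise KappaError("both term lists must be non-empty")
    gobp_ids = [t.term_id for t in gobp_terms]
    pathway_ids = [t.term_id for t in pathway_terms]
    if len(set(gobp_ids)) != len(gobp_ids) or len(set(pathway_ids)) != len(pathway_ids):
        raise KappaError("duplicate term ids within a list")

    if universe is None:
        u: set[str] = set()
        for term in list(gobp_terms) + list(pathway_terms):
            u |= term.genes
    else:
        u = set(universe)
    if not u:
        raise KappaError("empty universe")
    gene_index = {g: i for i, g in enumerate(sorted(u))}
    n = len(gene_index)

    def membership(terms: Sequence[TermRecord]) -> np.ndarray:
        mat = np.zeros((len(terms), n), dtype=np.int64)
        for row, term in enumerate(terms):
            for gene in term.genes:
                col = gene_index.get(gene)
                if col is not None:
                    mat[row, col] = 1
        return mat

    gm = membership(gobp_terms)  # (G, n)
    pm = membership(pathway_terms)  # (P, n)
    a = gm @ pm.T
    size_g = gm.sum(axis=1)[:, None]
    size_p = pm.sum(axis=1)[None, :]
    b = size_g - a
    c = size_p - a
    d = n - a - b - c
    pr_agree = (a + d) / n
    pr_random = ((a + b) * (a + c) + (b + d) * (c + d)) / (n * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (pr_agree - pr_random) / (1.0 - pr_random)
    degenerate = pr_random >= 1.0
    if degenerate.any():
        scores = np.where(degenerate & (b == 0) & (c == 0), 1.0, np.where(degenerate, 0.0, scores))
    return KappaMatrix(gobp_ids, pathway_ids, scores)
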