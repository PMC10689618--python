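"""Two-list hypergeometric term enrichment with BH FDR.

Given a target gene list drawn from a background list and a collection of
term gene sets (GMT), each term is scored by the fold enrichment
``(b/n) / (B/N)`` and the hypergeometric upper-tail probability
``P(X >= b)`` for ``X ~ Hypergeom(N, B, n)``, where ``N`` is the background
size, ``B`` the term genes within the background, ``n`` the target size and
``b`` the term genes within the target.  q-values are Benjamini-Hochberg
adjusted over the supplied term list only — they match a published table only
if the same term universe is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import hypergeom

from .errors import ValidationError


@dataclass(frozen=True)
class EnrichmentCounts:
    """(N, B, n, b) contingency counts for one term."""

    N: int
    B: int
    n: int
    b: int

    def __post_init__(self) -> None:
        if not (0 <= self.B <= self.N and 0 <= self.n <= self.N):
            raise ValidationError(f"need B <= N and n <= N, got {self}")
        if not (0 <= self.b <= min(self.n, self.B)):
            raise ValidationError(f"need 0 <= b <= min(n, B), got {self}")


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    description: str
    counts: EnrichmentCounts
    fold: float
    p: float
    q: float
    genes: tuple


def enrichment_ratio(counts: EnrichmentCounts) -> Fraction:
    """Fold enrichment (b/n)/(B/N) as an exact rational.

    Exact so that display rounding is the only rounding: e.g.
    (N=15154, B=10, n=28, b=2) gives 30308/280 = 108.24 at two decimals.
    """
    if counts.n == 0 or counts.B == 0:
        raise ValidationError("fold enrichment undefined for n=0 or B=0")
    return Fraction(counts.b * counts.N, counts.n * counts.B)


def hypergeom_tail(counts: EnrichmentCounts) -> float:
    """Upper-tail P(X >= b) for X ~ Hypergeom(N, B, n), exact 1.0 at b=0."""
    if counts.b == 0:
        return 1.0
    # survival function is P(X > b-1); scipy computes it stably
    return float(hypergeom.sf(counts.b - 1, counts.N, counts.B, counts.n))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, capped at
    1.  Invariant to input permutation (up to the corresponding reordering).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def read_gmt(path) -> dict:
    """Read a GMT file into {term: (description, gene set)}."""
    terms: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line has <3 fields: {line[:60]!r}")
            terms[fields[0]] = (fields[1], frozenset(g for g in fields[2:] if g))
    return terms


def read_gene_list(path) -> frozenset:
    """One-gene-per-line text file to a gene set (blank lines ignored)."""
    with open(path, "r", encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def enrich_terms(target, background, terms, fdr_universe: str = "overlapping"):
    """Score every term against a target/background gene-list pair.

    ``terms`` maps term id to either a gene set or a (description, gene set)
    pair.  Target genes absent from the background are dropped with a
    warning.  Records are returned sorted by ascending p then term id; only
    terms with ``b >= 1`` are reported.  ``fdr_universe`` chooses the BH
    multiplicity ``m``: ``"overlapping"`` (terms with b >= 1, default) or
    ``"all"`` (every term that intersects the background).
    """
    if fdr_universe not in ("overlapping", "all"):
        raise ValidationError(f"unknown fdr_universe: {fdr_universe!r}")
    background = frozenset(background)
    if not background:
        raise ValidationError("background gene set is empty")
    target = frozenset(target)
    stray = target - background
    if stray:
        warnings.warn(
            f"{len(stray)} target gene(s) absent from background dropped",
            stacklevel=2,
        )
        target = target - stray
    if not target:
        raise ValidationError("target list is empty after background subsetting")

    N, n = len(background), len(target)
    rows = []
    n_tested = 0
    for term_id in sorted(terms):
        entry = terms[term_id]
        desc, genes = entry if isinstance(entry, tuple) else ("", entry)
        term_bg = frozenset(genes) & background
        if not term_bg:
            continue  # term disjoint from background: not tested
        n_tested += 1
        hits = term_bg & target
        if not hits:
            continue
        counts = EnrichmentCounts(N=N, B=len(term_bg), n=n, b=len(hits))
        rows.append((term_id, desc, counts, hits))

    m = n_tested if fdr_universe == "all" else len(rows)
    pvals = [hypergeom_tail(c) for _, _, c, _ in rows]
    if fdr_universe == "all" and m > len(rows):
        # untested-but-eligible terms enter the multiplicity as p=1 placeholders
        q = bh_fdr(pvals + [1.0] * (m - len(rows)))[: len(rows)]
    else:
        q = bh_fdr(pvals)

    records = [
        _make_record(tid, desc, c, hits, p, qv)
        for (tid, desc, c, hits), p, qv in zip(rows, pvals, q)
    ]
    records.sort(key=lambda r: (r.p, r.term))
    return records


def _make_record(tid, desc, c, hits, p, qv):
    return EnrichmentRecord(
        term=tid,
        description=desc,
        counts=c,
        fold=float(enrichment_ratio(c)),
        p=p,
        q=float(qv),
        genes=tuple(sorted(hits)),
    )


def records_to_table(records):
    """Enrichment records as a DataFrame in published-table column order
    (term, description, p, q, enrichment, N, B, n, b, genes); write with
    ``.to_csv(path, sep="\\t", index=False)``."""
    import pandas as pd

    return pd.DataFrame(
        {
            "term": [r.term for r in records],
            "description": [r.description for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "enrichment": [r.fold for r in records],
            "N": [r.counts.N for r in records],
            "B": [r.counts.B for r in records],
            "n": [r.counts.n for r in records],
            "b": [r.counts.b for r in records],
            "genes": [";".join(r.genes) for r in records],
        }
    )
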