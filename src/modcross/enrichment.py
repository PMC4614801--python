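"""Gene-set over-representation with Benjamini-Hochberg control.

A generic hypergeometric enrichment of a query gene set against GMT
annotation collections, reported with BH-adjusted q-values and flagged at
FDR < 0.05.  Terms with zero overlap are reported with p = 1 rather than
skipped, so the tested term universe is identical across queries and the BH
denominator stays stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.05


def benjamini_hochberg(pvals) -> list[float]:
    """BH step-up adjusted q-values (delegates to statsmodels)."""
    if len(pvals) == 0:
        return []
    _, qvals, _, _ = multipletests(list(pvals), method="fdr_bh")
    return [float(q) for q in qvals]


@dataclass
class AnnotationCollection:
    """GMT-style term -> (description, gene set) collection."""

    terms: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def add(self, term: str, description: str, genes: Iterable[str]) -> None:
        if term in self.terms:
            raise ValueError(f"duplicate term id {term!r}")
        genes = set(genes)
        if not genes:
            raise ValueError(f"term {term!r} has an empty gene set")
        self.terms[term] = (description, genes)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    overlap: int        # k
    term_size: int      # K, after background restriction
    query_size: int     # n
    background_size: int  # N
    p: float
    q: float
    significant: bool


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Parse a GMT file: term TAB description TAB gene TAB gene ..."""
    path = Path(path)
    collection = AnnotationCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            try:
                collection.add(fields[0], fields[1], fields[2:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return collection


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in collection.terms:
            description, genes = collection.terms[term]
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


def enrich(
    query: set[str],
    annotations: AnnotationCollection,
    background: set[str],
    fdr: float = DEFAULT_FDR,
) -> list[EnrichmentResult]:
    """Per-term upper-tail hypergeometric p with BH adjustment.

    The query and every term are restricted to the background universe
    before testing.  Results come back sorted by q ascending (ties by term
    id).  BH is applied within this call only — one adjustment per queried
    gene set.
    """
    if not background:
        raise ValueError("empty background universe")
    query = query & background
    if not query:
        logger.warning("query is empty after background restriction")
        return []
    n = len(query)
    big_n = len(background)
    rows = []
    for term in sorted(annotations.terms):
        description, genes = annotations.terms[term]
        term_genes = genes & background
        k = len(query & term_genes)
        big_k = len(term_genes)
        if k == 0:
            p = 1.0
        else:
            p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((term, description, k, big_k, p))
    if not rows:
        return []
    qvals = benjamini_hochberg([r[4] for r in rows])
    results = [
        EnrichmentResult(
            term=term,
            description=description,
            overlap=k,
            term_size=big_k,
            query_size=n,
            background_size=big_n,
            p=p,
            q=float(q),
            significant=bool(q < fdr),
        )
        for (term, description, k, big_k, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.term))
    return results


def write_enrichment_table(path, results: Iterable[EnrichmentResult]) -> None:
    with open(path, "w") as fh:
        fh.write("term\tdescription\tk\tK\tn\tN\tp\tq\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.description}\t{r.overlap}\t{r.term_size}\t"
                f"{r.query_size}\t{r.background_size}\t{r.p:.6g}\t{r.q:.6g}\t"
                f"{int(r.significant)}\n"
            )
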