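"""Gene-set over-representation testing and the three-criterion candidate screen.

Enrichment of the genes hit by group-specific SVs is the standard one-tailed
hypergeometric over-representation test: with ``N`` background genes, ``K``
of them in a term, and a query of ``n`` genes of which ``k`` fall in the
term, ``p = P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

The candidate screen keeps a (SV, gene) pair when the SV is group-specific
(criterion 1, by construction of its input) and the gene either belongs to a
significantly enriched term tagged as skin/aging-relevant (criterion 2) or
appears in a curated aging-gene list (criterion 3). Term relevance is
data-driven — tags come from the gene-set file, not from hard-coded biology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .annotate import Annotation
from .sv_io import MergedSV

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "hypergeometric_enrichment",
    "screen_candidates",
]

DEFAULT_RELEVANT_TAGS = frozenset({"skin", "aging"})


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset
    source: str = "gene-set"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.term_id} is empty")

    @property
    def tags(self) -> frozenset:
        """Lowercase word tokens of the term name, used for relevance tagging."""
        return frozenset(re.findall(r"[a-z0-9]+", self.term_name.lower()))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes in the term
    n: int  # query size
    K: int  # term size (within background)
    N: int  # background size
    pvalue: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("overlap k cannot exceed min(query, term) size")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def read_gmt(path, source: str = "gene-set") -> list[GeneSet]:
    """Read gene sets in GMT format: term, description, then gene symbols."""
    sets = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line needs >= 3 fields: {line[:80]!r}")
            sets.append(
                GeneSet(fields[0], fields[1], frozenset(g for g in fields[2:] if g), source)
            )
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path) -> None:
    with Path(path).open("w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.genes)]) + "\n")


def read_gene_list(path, term_id: str = "aging_genes") -> GeneSet:
    """One-gene-per-line list (e.g. a curated aging-gene catalogue)."""
    genes = frozenset(
        line.strip() for line in Path(path).open() if line.strip() and not line.startswith("#")
    )
    return GeneSet(term_id, term_id.replace("_", " "), genes, source="aging-list")


def hypergeometric_enrichment(
    query_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """One-tailed over-representation test for every gene set.

    Gene sets are intersected with the background before testing; the query
    must be a subset of the background. Results are sorted by p-value (ties by
    term id); terms with no overlap get p = 1.
    """
    background = frozenset(background)
    query = frozenset(query_genes)
    if not background:
        raise ValueError("background gene universe is empty")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    N = len(background)
    n = len(query)
    results = []
    for gs in gene_sets:
        term = gs.genes & background
        if not term:
            continue
        K = len(term)
        k = len(term & query)
        if k == 0:
            p = 1.0
        else:
            # P(X >= k) for X ~ Hypergeom(N, K, n)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(gs.term_id, gs.term_name, k, n, K, N, min(p, 1.0)))
    results.sort(key=lambda r: (r.pvalue, r.term_id))
    return results


def screen_candidates(
    specific_svs: Sequence[tuple[MergedSV, Annotation]],
    enrichment: Sequence[EnrichmentResult],
    aging_genes: GeneSet | None,
    gene_sets: Sequence[GeneSet],
    alpha: float = 0.05,
    relevant_tags: frozenset = DEFAULT_RELEVANT_TAGS,
) -> pd.DataFrame:
    """Three-criterion candidate screen over group-specific SVs.

    Input SVs are already group-specific (criterion 1). A (SV, gene) pair is a
    candidate when the gene belongs to at least one enriched term
    (p < ``alpha``) whose name carries a relevant tag (criterion 2) **or** the
    gene is on the aging list (criterion 3). Intergenic SVs have no gene and
    are never candidates. Output mirrors the candidate-table layout:
    id, chrom, start, end, length, type, location, gene.
    """
    sets_by_id = {gs.term_id: gs for gs in gene_sets}
    relevant_genes: set[str] = set()
    for res in enrichment:
        if res.pvalue >= alpha:
            continue
        gs = sets_by_id.get(res.term_id)
        if gs is None or not (gs.tags & relevant_tags):
            continue
        relevant_genes |= gs.genes
    aging = aging_genes.genes if aging_genes is not None else frozenset()

    rows = []
    for sv, ann in specific_svs:
        for gene in ann.genes:
            if gene in relevant_genes or gene in aging:
                rows.append(
                    {
                        "id": ann.sv_id,
                        "chrom": sv.chrom,
                        "start": sv.start,
                        "end": sv.end,
                        "length": sv.length,
                        "type": sv.svtype,
                        "location": ann.location_string,
                        "gene": gene,
                    }
                )
    return pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "length", "type", "location", "gene"]
    )
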