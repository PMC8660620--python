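"""Gene-model annotation of merged SVs: location class, impact and consequences.

Each SV is classified against a hierarchical gene model (gene → transcript →
exon/CDS/UTR) into one of six location classes with a fixed precedence::

    exon_intron > exon > utr > intron > upstream_downstream > intergenic

and then assigned a simplified impact (``high`` for protein-destructive
consequences — stop lost, frameshift — ``modifier`` for the rest, ``none``
for intergenic). Exon and intron ordinals are reported strand-aware (exon 1
is the 5'-most exon), in the compact grammar used for candidate tables, e.g.
``EXON=7/16,INTRON=6/15,STRAND=-1`` or ``DISTANCE=1644,STRAND=1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .sv_io import MergedSV

__all__ = [
    "Transcript",
    "GeneModel",
    "Annotation",
    "LOCATION_CLASSES",
    "read_gff3",
    "write_gff3",
    "GeneIndex",
    "classify_location",
    "predict_impact",
    "annotate_all",
    "location_summary",
    "percent",
]

log = logging.getLogger(__name__)

DEFAULT_FLANK = 5000
SPLICE_REGION_BP = 8

LOCATION_CLASSES = (
    "exon_intron",
    "exon",
    "utr",
    "intron",
    "upstream_downstream",
    "intergenic",
)
_PRECEDENCE = {c: i for i, c in enumerate(LOCATION_CLASSES)}

_IMPACT_RANK = {"high": 0, "modifier": 1, "none": 2}


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple  # ((start, end), ...) genomic ascending, 1-based inclusive
    cds: tuple = ()
    utr5: tuple = ()
    utr3: tuple = ()

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"exon end < start in {self.transcript_id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"exons overlap or are unordered in {self.transcript_id}")
            prev_end = e

    @property
    def introns(self) -> tuple:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str  # protein_coding | pseudogene | noncoding
    chrom: str
    strand: int  # +1 / -1
    transcripts: tuple

    @property
    def start(self) -> int:
        return min(t.exons[0][0] for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.exons[-1][1] for t in self.transcripts)


@dataclass(frozen=True)
class Annotation:
    sv_id: str
    location: str
    impact: str = "none"
    consequences: frozenset = frozenset()
    genes: tuple = ()
    distance: int | None = None
    location_string: str = "-"

    def __post_init__(self) -> None:
        if self.location not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {self.location!r}")
        if self.location == "intergenic" and self.genes:
            raise ValueError("intergenic annotation must not list genes")
        if (self.distance is not None) != (self.location == "upstream_downstream"):
            raise ValueError("distance present iff location is upstream_downstream")


def affected_span(sv) -> tuple[int, int]:
    """Inclusive genomic span of the affected reference bases.

    DEL/DUP/INV of length L starting at ``start`` affect bases
    ``start+1 .. end`` (L bases). An insertion affects the single breakpoint
    base at ``start``.
    """
    if sv.svtype == "INS":
        return (sv.start, sv.start)
    return (sv.start + 1, sv.end)


def _overlap(lo: int, hi: int, s: int, e: int) -> int:
    return min(hi, e) - max(lo, s) + 1


# ---------------------------------------------------------------------------
# GFF3 reading/writing


def read_gff3(path) -> list[GeneModel]:
    """Load gene models from a GFF3 file (gene / mRNA|transcript / exon / CDS / UTRs)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = tuple(
                (f.start, f.end) for f in db.children(t, featuretype="exon", order_by="start")
            )
            cds = tuple(
                (f.start, f.end) for f in db.children(t, featuretype="CDS", order_by="start")
            )
            utr5 = tuple(
                (f.start, f.end)
                for f in db.children(t, featuretype="five_prime_UTR", order_by="start")
            )
            utr3 = tuple(
                (f.start, f.end)
                for f in db.children(t, featuretype="three_prime_UTR", order_by="start")
            )
            if exons:
                transcripts.append(
                    Transcript(t.id.split(":")[-1], exons, cds, utr5, utr3)
                )
        if not transcripts:
            continue
        genes.append(
            GeneModel(
                gene_id=g.id.split(":")[-1],
                gene_name=g.attributes.get("Name", [g.id.split(":")[-1]])[0],
                biotype=g.attributes.get("biotype", ["protein_coding"])[0],
                chrom=g.seqid,
                strand=-1 if g.strand == "-" else 1,
                transcripts=tuple(transcripts),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3; inverse of :func:`read_gff3`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = "-" if g.strand < 0 else "+"
            fh.write(
                f"{g.chrom}\tsvcohort\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t"
                f"ID=gene:{g.gene_id};Name={g.gene_name};biotype={g.biotype}\n"
            )
            for t in g.transcripts:
                feat = "mRNA" if t.cds else "transcript"
                fh.write(
                    f"{g.chrom}\tsvcohort\t{feat}\t{t.exons[0][0]}\t{t.exons[-1][1]}\t.\t"
                    f"{strand}\t.\tID=transcript:{t.transcript_id};Parent=gene:{g.gene_id}\n"
                )
                for kind, ivs in (
                    ("exon", t.exons),
                    ("CDS", t.cds),
                    ("five_prime_UTR", t.utr5),
                    ("three_prime_UTR", t.utr3),
                ):
                    for k, (s, e) in enumerate(ivs, start=1):
                        fh.write(
                            f"{g.chrom}\tsvcohort\t{kind}\t{s}\t{e}\t.\t{strand}\t.\t"
                            f"ID={kind}:{t.transcript_id}.{k};Parent=transcript:{t.transcript_id}\n"
                        )


# ---------------------------------------------------------------------------
# Location classification


class GeneIndex:
    """Interval index over gene spans for fast flank-aware lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end + 1, g)

    def query(self, chrom: str, lo: int, hi: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(lo, hi + 1)),
                      key=lambda g: (g.start, g.gene_id))

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees


def _transcript_hit(t: Transcript, strand: int, lo: int, hi: int):
    """Classify a span against one transcript.

    Returns (class, exon_ordinal, n_exons, intron_ordinal, n_introns), with
    ordinals strand-aware (None where not applicable).
    """
    n = len(t.exons)
    m = n - 1
    ex_hits = [i for i, (s, e) in enumerate(t.exons, start=1) if _overlap(lo, hi, s, e) > 0]
    in_hits = [i for i, (s, e) in enumerate(t.introns, start=1)
               if e >= s and _overlap(lo, hi, s, e) > 0]

    def ex_ord(gi: int) -> int:
        return gi if strand > 0 else n - gi + 1

    def in_ord(gi: int) -> int:
        return gi if strand > 0 else m - gi + 1

    exon_ord = min((ex_ord(g) for g in ex_hits), default=None)
    intron_ord = min((in_ord(g) for g in in_hits), default=None)

    if ex_hits and in_hits:
        return ("exon_intron", exon_ord, n, intron_ord, m)
    if ex_hits:
        utr = list(t.utr5) + list(t.utr3)
        covered = sum(max(0, _overlap(lo, hi, s, e)) for s, e in utr)
        if utr and covered >= hi - lo + 1:
            return ("utr", exon_ord, n, None, m)
        return ("exon", exon_ord, n, None, m)
    if in_hits:
        return ("intron", None, n, intron_ord, m)
    return (None, None, n, None, m)


def classify_location(
    sv: MergedSV,
    genes: Sequence[GeneModel] | GeneIndex,
    flank: int = DEFAULT_FLANK,
) -> Annotation:
    """Assign a location class, affected genes and the location string.

    Precedence when an SV touches several features or genes:
    ``exon_intron > exon > utr > intron > upstream_downstream > intergenic``.
    ``upstream_downstream`` means the SV lies within ``flank`` bp of a gene
    span without touching it; ``distance`` is the gap to the nearest gene. An
    SV on a chromosome absent from the gene model is intergenic (warned).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    lo, hi = affected_span(sv)
    sv_id = getattr(sv, "id", None) or f"{sv.chrom}:{sv.start}-{sv.end}:{sv.svtype}"

    if not index.has_chrom(sv.chrom):
        log.warning("chromosome %s absent from gene model; %s set intergenic", sv.chrom, sv_id)
        return Annotation(sv_id=sv_id, location="intergenic")

    overlapping = index.query(sv.chrom, lo, hi)
    if overlapping:
        best = None  # (precedence, gene, class, ordinals)
        for g in overlapping:
            for t in g.transcripts:
                cls, eo, n, io, m = _transcript_hit(t, g.strand, lo, hi)
                if cls is None:
                    continue
                cand = (_PRECEDENCE[cls], g, cls, eo, n, io, m)
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is not None:
            _, g, cls, eo, n, io, m = best
            parts = []
            if eo is not None:
                parts.append(f"EXON={eo}/{n}")
            if io is not None:
                parts.append(f"INTRON={io}/{m}")
            parts.append(f"STRAND={g.strand}")
            return Annotation(
                sv_id=sv_id,
                location=cls,
                genes=tuple(x.gene_id for x in overlapping),
                location_string=",".join(parts),
            )

    nearby = index.query(sv.chrom, lo - flank, hi + flank)
    if nearby:
        def gap(g: GeneModel) -> int:
            if hi < g.start:
                return g.start - hi
            if lo > g.end:
                return lo - g.end
            return 0

        nearest = min(nearby, key=lambda g: (gap(g), g.start))
        d = gap(nearest)
        return Annotation(
            sv_id=sv_id,
            location="upstream_downstream",
            genes=tuple(g.gene_id for g in nearby),
            distance=d,
            location_string=f"DISTANCE={d},STRAND={nearest.strand}",
        )
    return Annotation(sv_id=sv_id, location="intergenic")


# ---------------------------------------------------------------------------
# Impact prediction


def _stop_codon(t: Transcript, strand: int) -> tuple[int, int] | None:
    if not t.cds:
        return None
    if strand > 0:
        s, e = t.cds[-1]
        return (max(s, e - 2), e)
    s, e = t.cds[0]
    return (s, min(e, s + 2))


def _contained_in_cds(t: Transcript, lo: int, hi: int) -> bool:
    return any(s <= lo and hi <= e for s, e in t.cds)


def _near_splice_site(t: Transcript, lo: int, hi: int, window: int) -> bool:
    for s, e in t.introns:
        if e < s:
            continue
        donor = (s, min(e, s + window - 1))
        acceptor = (max(s, e - window + 1), e)
        if _overlap(lo, hi, *donor) > 0 or _overlap(lo, hi, *acceptor) > 0:
            return True
    return False


def predict_impact(
    sv: MergedSV,
    annotation: Annotation,
    genes: Sequence[GeneModel] | GeneIndex,
) -> Annotation:
    """Fill ``impact`` and ``consequences`` from ordered rules.

    Rules, first match per transcript (worst across transcripts wins):

    1. DEL/DUP overlapping a stop codon          → stop_lost, high
    2. DEL/INS/DUP contained in CDS, length %3≠0 → frameshift, high
    3. exon–intron spanning or ≤8 bp of a splice → splice_region, modifier
    4. within a UTR                              → utr_change, modifier
    5. in the upstream/downstream flank          → regulatory_region, modifier
    6. purely intronic                           → intron_variant, modifier
    7. intergenic                                → intergenic_variant, none
    """
    if annotation.location == "intergenic":
        return replace(annotation, impact="none", consequences=frozenset({"intergenic_variant"}))
    if annotation.location == "upstream_downstream":
        return replace(annotation, impact="modifier",
                       consequences=frozenset({"regulatory_region"}))

    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    lo, hi = affected_span(sv)
    gene_by_id = {g.gene_id: g for g in index.query(sv.chrom, lo, hi)}

    consequences: set[str] = set()
    impact = "modifier"
    for gid in annotation.genes:
        g = gene_by_id.get(gid)
        if g is None:
            continue
        for t in g.transcripts:
            hit = None
            stop = _stop_codon(t, g.strand)
            if sv.svtype in ("DEL", "DUP") and stop and _overlap(lo, hi, *stop) > 0:
                hit = ("stop_lost", "high")
            elif (
                sv.svtype in ("DEL", "INS", "DUP")
                and t.cds
                and _contained_in_cds(t, lo, hi)
                and sv.length % 3 != 0
            ):
                hit = ("frameshift", "high")
            else:
                cls, *_ = _transcript_hit(t, g.strand, lo, hi)
                if cls == "exon_intron" or (
                    cls == "intron" and _near_splice_site(t, lo, hi, SPLICE_REGION_BP)
                ):
                    hit = ("splice_region", "modifier")
                elif cls == "utr":
                    hit = ("utr_change", "modifier")
                elif cls == "intron":
                    hit = ("intron_variant", "modifier")
                elif cls == "exon":
                    # exonic but frame-preserving / non-coding transcript
                    hit = ("exon_variant", "modifier")
            if hit is not None:
                consequences.add(hit[0])
                if _IMPACT_RANK[hit[1]] < _IMPACT_RANK[impact]:
                    impact = hit[1]
    if not consequences:
        consequences = {"intron_variant"}
    return replace(annotation, impact=impact, consequences=frozenset(consequences))


def annotate_all(
    svs: Sequence[MergedSV],
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[Annotation]:
    """Classify and impact-annotate every SV against one shared gene index."""
    index = GeneIndex(genes)
    out = []
    for sv in svs:
        ann = classify_location(sv, index, flank=flank)
        out.append(predict_impact(sv, ann, index))
    return out


# ---------------------------------------------------------------------------
# Summaries


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage with exact round-half-up at ``ndigits`` decimals."""
    if total == 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def location_summary(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Counts and round-half-up percentages per location class.

    Returns a DataFrame indexed by location class (precedence order, classes
    with zero SVs included) with ``count`` and ``percent`` columns; counts sum
    to the number of annotations.
    """
    if not annotations:
        return pd.DataFrame(columns=["count", "percent"])
    total = len(annotations)
    counts = {c: 0 for c in LOCATION_CLASSES}
    for a in annotations:
        counts[a.location] += 1
    df = pd.DataFrame(
        {
            "count": [counts[c] for c in LOCATION_CLASSES],
            "percent": [percent(counts[c], total) for c in LOCATION_CLASSES],
        },
        index=pd.Index(LOCATION_CLASSES, name="location"),
    )
    return df
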