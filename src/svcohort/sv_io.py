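"""Data model for structural-variant (SV) records and tabular/VCF I/O.

Coordinate convention
---------------------
Positions are 1-based. For DEL/DUP/INV the record stores ``start < end`` and
``length == end - start`` (the affected bases are the half-open span
``(start, end]``). Insertions are breakpoints: ``start == end`` and ``length``
is the length of the inserted sequence, which is absent from the reference.

Three tabular dialects are defined here:

* normalized caller table  — ``chrom start end svtype length support``
* cohort table             — ``id chrom start end svtype length n_carriers carriers``
* minimal VCF 4.2 export   — symbolic ALTs with SVTYPE/END/SVLEN INFO keys and
  per-sample presence/absence genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = [
    "SV_TYPES",
    "SVCall",
    "SVTypeCounts",
    "ConsensusSV",
    "MergedSV",
    "CallTableError",
    "sv_length",
    "read_caller_calls",
    "write_cohort_table",
    "read_cohort_table",
    "export_vcf",
    "chrom_sort_key",
]

SV_TYPES = ("DEL", "DUP", "INS", "INV")

_CALLER_COLUMNS = ("chrom", "start", "end", "svtype", "length", "support")
_COHORT_COLUMNS = (
    "id",
    "chrom",
    "start",
    "end",
    "svtype",
    "length",
    "n_carriers",
    "carriers",
)


def _check_interval(chrom: str, start: int, end: int, svtype: str, length: int) -> None:
    if svtype not in SV_TYPES:
        raise ValueError(f"unknown svtype {svtype!r}; expected one of {SV_TYPES}")
    if not chrom:
        raise ValueError("chrom must be non-empty")
    if start < 0 or end < 0:
        raise ValueError("coordinates must be non-negative")
    if svtype == "INS":
        if end != start:
            raise ValueError(f"INS requires start == end (got {start}, {end})")
        if length <= 0:
            raise ValueError("INS requires length > 0")
    else:
        if end <= start:
            raise ValueError(f"{svtype} requires end > start (got {start}, {end})")
        if length != end - start:
            raise ValueError(
                f"{svtype} length {length} inconsistent with end - start = {end - start}"
            )


@dataclass(frozen=True)
class SVCall:
    """One caller's record for one individual."""

    caller_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    support: int

    def __post_init__(self) -> None:
        _check_interval(self.chrom, self.start, self.end, self.svtype, self.length)
        if self.support < 0:
            raise ValueError("support must be >= 0")


@dataclass(frozen=True)
class ConsensusSV:
    """Per-individual SV confirmed by two independent callers.

    The representative interval is one of the two matched calls (never an
    average); ``support`` is the larger of the two supports.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    support: int
    source_pair: tuple[SVCall, SVCall] = ()

    def __post_init__(self) -> None:
        _check_interval(self.chrom, self.start, self.end, self.svtype, self.length)
        if self.support < 0:
            raise ValueError("support must be >= 0")
        if self.source_pair:
            callers = {c.caller_id for c in self.source_pair}
            if len(self.source_pair) != 2 or len(callers) != 2:
                raise ValueError("source_pair must hold records from two distinct callers")


@dataclass(frozen=True)
class MergedSV:
    """Cohort-level non-redundant SV with its carrier set."""

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    carriers: frozenset
    id: str | None = None
    member_calls: tuple = ()

    def __post_init__(self) -> None:
        _check_interval(self.chrom, self.start, self.end, self.svtype, self.length)
        if not self.carriers:
            raise ValueError("MergedSV requires at least one carrier")
        if self.member_calls:
            members = frozenset(m.sample_id for m in self.member_calls)
            if members != self.carriers:
                raise ValueError("carriers must equal distinct sample_ids of member_calls")
            if any(m.chrom != self.chrom or m.svtype != self.svtype for m in self.member_calls):
                raise ValueError("member_calls must share chrom and svtype")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class SVTypeCounts:
    """Per-type SV tally; ``total`` is always the sum of the four counts."""

    DEL: int = 0
    DUP: int = 0
    INS: int = 0
    INV: int = 0

    @property
    def total(self) -> int:
        return self.DEL + self.DUP + self.INS + self.INV

    def as_dict(self) -> dict:
        return {"DEL": self.DEL, "DUP": self.DUP, "INS": self.INS, "INV": self.INV,
                "total": self.total}


def sv_length(call) -> int:
    """Length in bp: ``end - start`` for DEL/DUP/INV, stored insert length for INS."""
    if call.svtype == "INS":
        return call.length
    return call.end - call.start


def chrom_sort_key(chrom: str):
    """Natural chromosome order: numeric ascending, then X, then the rest."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    if name.upper() == "X":
        return (1, 0, "")
    return (2, 0, name)


def _record_sort_key(rec):
    return (chrom_sort_key(rec.chrom), rec.start, rec.end, rec.svtype)


class CallTableError(ValueError):
    """Raised when a caller table contains malformed rows.

    ``errors`` is a list of ``(line_number, message)`` pairs covering every
    offending row, so a single failed load reports all problems at once.
    """

    def __init__(self, path, errors):
        self.path = str(path)
        self.errors = list(errors)
        lines = "; ".join(f"line {n}: {m}" for n, m in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{self.path}: {len(self.errors)} malformed row(s): {lines}{more}")


def read_caller_calls(
    path,
    caller_id: str,
    sample_id: str,
    *,
    lenient: bool = False,
) -> list[SVCall]:
    """Read one caller's normalized TSV for one individual.

    The table must have a header line with columns
    ``chrom start end svtype length support``. Rows that violate the SV type
    invariants abort the load with a :class:`CallTableError` listing every bad
    row; with ``lenient=True`` bad rows are skipped instead (their count is
    available on the returned list via the error report attached by the
    caller if needed). Chromosome-Y records are retained here — dropping them
    is a later, explicit filtering stage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"caller table not found: {path}")
    calls: list[SVCall] = []
    errors: list[tuple[int, str]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip().lower() for h in header) != _CALLER_COLUMNS:
            raise CallTableError(path, [(1, f"bad header {header!r}; expected {list(_CALLER_COLUMNS)}")])
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                errors.append((lineno, f"expected 6 columns, got {len(fields)}"))
                continue
            try:
                call = SVCall(
                    caller_id=caller_id,
                    sample_id=sample_id,
                    chrom=fields[0].strip(),
                    start=int(fields[1]),
                    end=int(fields[2]),
                    svtype=fields[3].strip().upper(),
                    length=int(fields[4]),
                    support=int(fields[5]),
                )
            except ValueError as exc:
                errors.append((lineno, str(exc)))
                continue
            calls.append(call)
    if errors and not lenient:
        raise CallTableError(path, errors)
    return calls


def write_cohort_table(svs: Sequence[MergedSV], path) -> None:
    """Write the cohort call-set TSV with stable ``sv_%05d`` IDs.

    Records are ordered by (chrom, start) under natural chromosome order and
    IDs are assigned in that order, so the table layout is a pure function of
    the record set. Round-trips losslessly through :func:`read_cohort_table`.
    """
    if not svs:
        raise ValueError("refusing to write an empty cohort table")
    ordered = sorted(svs, key=_record_sort_key)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_COHORT_COLUMNS) + "\n")
        for i, sv in enumerate(ordered, start=1):
            sv_id = f"sv_{i:05d}"
            carriers = ",".join(sorted(sv.carriers))
            fh.write(
                f"{sv_id}\t{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.svtype}\t"
                f"{sv.length}\t{sv.n_carriers}\t{carriers}\n"
            )


def read_cohort_table(path) -> list[MergedSV]:
    """Read a cohort call-set TSV written by :func:`write_cohort_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    svs: list[MergedSV] = []
    with path.open() as fh:
        header = tuple(h.strip() for h in fh.readline().rstrip("\n").split("\t"))
        if header != _COHORT_COLUMNS:
            raise ValueError(f"{path}: bad cohort-table header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            svs.append(
                MergedSV(
                    id=f[0],
                    chrom=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    svtype=f[4],
                    length=int(f[5]),
                    carriers=frozenset(f[7].split(",")) if f[7] else frozenset(),
                )
            )
    return svs


def export_vcf(svs: Sequence[MergedSV], sample_ids: Sequence[str], path) -> None:
    """Write a minimal VCF 4.2 with symbolic ALTs and presence/absence GTs.

    POS is the SV start; INFO carries SVTYPE, END and SVLEN (insert length for
    INS, ``end - start`` otherwise). Each sample's GT is ``1`` if it carries
    the SV and ``0`` otherwise — the pipeline's genotype model is
    presence/absence, not diploid.
    """
    known = set(sample_ids)
    for sv in svs:
        unknown = sv.carriers - known
        if unknown:
            raise ValueError(f"carrier(s) {sorted(unknown)} not in sample list")
    ordered = sorted(svs, key=_record_sort_key)
    contig_max: dict[str, int] = {}
    for sv in ordered:
        contig_max[sv.chrom] = max(contig_max.get(sv.chrom, 0), sv.end + 1000)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svcohort\n")
        for chrom in sorted(contig_max, key=chrom_sort_key):
            fh.write(f"##contig=<ID={chrom},length={contig_max[chrom]}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Tandem duplication">\n')
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Carrier presence (1) or absence (0)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for i, sv in enumerate(ordered, start=1):
            sv_id = sv.id or f"sv_{i:05d}"
            info = f"SVTYPE={sv.svtype};END={sv.end};SVLEN={sv_length(sv)}"
            gts = "\t".join("1" if s in sv.carriers else "0" for s in sample_ids)
            fh.write(
                f"{sv.chrom}\t{sv.start}\t{sv_id}\tN\t<{sv.svtype}>\t.\tPASS\t{info}\tGT\t{gts}\n"
            )
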