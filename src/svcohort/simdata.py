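"""Synthetic cohort generator: gene models, planted SVs and two noisy callers.

The simulator emulates the *shape* of a resequencing SV study without reads:
a small multi-chromosome genome carrying non-overlapping gene models, a
planted cohort of true SVs — some shared across all groups, some private to
one group — and, per individual, two caller-style call sets with breakpoint
jitter, false negatives, uniformly scattered false positives and read-pair
support counts drawn per call. A ground-truth table records every planted
SV's carriers, group-specificity, location class and host gene, so recovery
by the consensus/merge/screen pipeline can be measured exactly.

Default study conditions: three groups of 7 (wrinkled), 7 (normal) and 21
(reference) individuals; 200 shared and 40 per-group private SVs with
log-uniform lengths of 50–2,000 bp and a type mix dominated by deletions
(86% DEL, 7% DUP, 6% INS, 1% INV); per-caller breakpoint jitter with 10 bp
standard deviation, 5% false-negative rate and 2 false positives per Mb.
False positives are drawn independently for the two callers, which is the
error mode the both-callers consensus rule suppresses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, Transcript, write_gff3
from .consensus import mergeable
from .enrich_screen import GeneSet, write_gmt
from .sv_io import MergedSV, SVCall, chrom_sort_key

__all__ = [
    "SimConfig",
    "PlantedSV",
    "TruthTable",
    "SimulatedStudy",
    "sample_sheet_for",
    "simulate_gene_models",
    "simulate_cohort",
    "simulate_caller_output",
    "generate_gene_sets",
    "simulate_study",
    "write_study",
    "both_caller_carriers",
    "match_truth_to_merged",
]

_GENE_CLASSES = ("exon", "exon_intron", "intron", "utr", "upstream_downstream")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Rates are probabilities in [0, 1]; lengths are bp. ``type_mix`` and
    ``location_weights`` are normalized draws for planted SV type and genomic
    placement class.
    """

    seed: int = 1
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    y_chrom_length: int = 400_000
    n_y_svs: int = 5
    n_genes: int = 90
    exons_per_gene: int = 5
    exon_length: int = 300
    intron_length: int = 800
    utr_length: int = 150
    noncoding_fraction: float = 0.05
    group_sizes: dict = field(default_factory=lambda: {"WXP": 7, "XP": 7, "EUP": 21})
    n_shared_svs: int = 200
    n_specific_svs: dict = field(default_factory=lambda: {"WXP": 40, "XP": 40, "EUP": 40})
    sv_length_range: tuple = (50, 2000)  # log-uniform draw
    type_mix: dict = field(
        default_factory=lambda: {"DEL": 0.86, "DUP": 0.07, "INS": 0.06, "INV": 0.01}
    )
    location_weights: dict = field(
        default_factory=lambda: {
            "intron": 0.45,
            "intergenic": 0.39,
            "upstream_downstream": 0.11,
            "exon": 0.03,
            "utr": 0.01,
            "exon_intron": 0.01,
        }
    )
    flank: int = 5000
    shared_carrier_freq: tuple = (0.3, 0.9)
    specific_carrier_freq: tuple = (0.4, 0.9)
    jitter_sd: float = 10.0
    fn_rate: float = 0.05
    fp_per_mb: float = 2.0
    support_mean: float = 8.0
    support_min: int = 1
    callers: tuple = ("callerA", "callerB")
    min_planted_gap: int = 200

    def __post_init__(self) -> None:
        for name in ("noncoding_fraction", "fn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fp_per_mb < 0 or self.jitter_sd < 0:
            raise ValueError("fp_per_mb and jitter_sd must be non-negative")
        for g, n in self.n_specific_svs.items():
            if n > 0 and self.group_sizes.get(g, 0) < 2:
                raise ValueError(
                    f"group {g} has private SVs but fewer than 2 members; the "
                    f">=2-individual filter would remove them by construction"
                )
        if self.exons_per_gene < 3:
            raise ValueError("need >= 3 exons per gene to place interior-exon SVs")

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chroms)]

    @property
    def genome_mb(self) -> float:
        return (self.n_chroms * self.chrom_length + self.y_chrom_length) / 1e6


@dataclass(frozen=True)
class PlantedSV:
    """One true SV with its genotype assignment and annotation truth."""

    uid: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    carriers: tuple
    specific_to: str | None
    location_class: str
    gene_id: str | None


@dataclass
class TruthTable:
    svs: list

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "uid": [s.uid for s in self.svs],
                "chrom": [s.chrom for s in self.svs],
                "start": [s.start for s in self.svs],
                "end": [s.end for s in self.svs],
                "svtype": [s.svtype for s in self.svs],
                "length": [s.length for s in self.svs],
                "specific_to": [s.specific_to or "" for s in self.svs],
                "location_class": [s.location_class for s in self.svs],
                "gene_id": [s.gene_id or "" for s in self.svs],
                "carriers": [",".join(s.carriers) for s in self.svs],
            }
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def specific(self, group: str) -> list:
        return [s for s in self.svs if s.specific_to == group]


def sample_sheet_for(config: SimConfig) -> dict:
    """Ordered sample → group map, e.g. WXP1..WXP7, XP1..XP7, EUP1..EUP21."""
    sheet = {}
    for group, n in config.group_sizes.items():
        for i in range(1, n + 1):
            sheet[f"{group}{i}"] = group
    return sheet


# ---------------------------------------------------------------------------
# Gene models


def _build_transcript(tid: str, exons: list, strand: int, coding: bool, utr_len: int):
    if not coding:
        return Transcript(tid, tuple(exons))
    total_exonic = sum(e - s + 1 for s, e in exons)
    utr5_len = utr_len
    cds_len = total_exonic - 2 * utr_len
    utr3_len = utr_len + cds_len % 3  # pad 3' UTR so CDS length % 3 == 0

    # walk exons in transcript (5'->3') orientation, splitting into utr5/cds/utr3
    ordered = exons if strand > 0 else list(reversed(exons))
    pieces = {"utr5": [], "cds": [], "utr3": []}
    budget = [("utr5", utr5_len), ("cds", total_exonic - utr5_len - utr3_len), ("utr3", utr3_len)]
    bi = 0
    for s, e in ordered:
        # consume this exon front-to-back in transcript orientation
        remaining = e - s + 1
        pos = 0  # offset within the exon in transcript orientation
        while remaining > 0 and bi < len(budget):
            kind, need = budget[bi]
            take = min(need, remaining)
            if take > 0:
                if strand > 0:
                    iv = (s + pos, s + pos + take - 1)
                else:
                    iv = (e - pos - take + 1, e - pos)
                pieces[kind].append(iv)
            pos += take
            remaining -= take
            need -= take
            budget[bi] = (kind, need)
            if need == 0:
                bi += 1
    for k in pieces:
        pieces[k].sort()
    return Transcript(
        tid,
        tuple(exons),
        cds=tuple(pieces["cds"]),
        utr5=tuple(pieces["utr5"]),
        utr3=tuple(pieces["utr3"]),
    )


def simulate_gene_models(config: SimConfig) -> list[GeneModel]:
    """Place non-overlapping genes with inter-gene spacing > 2 × flank.

    Genes have ``exons_per_gene`` fixed-size exons; protein-coding genes get
    5'/3' UTRs and a CDS whose length is always divisible by 3. Deterministic
    under the config seed.
    """
    rng = np.random.default_rng([config.seed, 11])
    span = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genes
    per_chrom = [0] * config.n_chroms
    for i in range(config.n_genes):
        per_chrom[i % config.n_chroms] += 1
    gap_lo = 2 * config.flank + 1000
    gap_hi = 2 * config.flank + 5000
    idx = 0
    for ci, chrom in enumerate(config.chrom_names):
        cursor = 20_000
        for _ in range(per_chrom[ci]):
            if cursor + span > config.chrom_length - 20_000:
                raise ValueError(
                    f"cannot pack {config.n_genes} genes of span {span} bp plus "
                    f"{gap_lo}-{gap_hi} bp spacing into {config.n_chroms} x "
                    f"{config.chrom_length} bp chromosomes"
                )
            idx += 1
            strand = 1 if rng.random() < 0.5 else -1
            coding = rng.random() >= config.noncoding_fraction
            exons = []
            pos = cursor
            for _e in range(config.exons_per_gene):
                exons.append((pos, pos + config.exon_length - 1))
                pos += config.exon_length + config.intron_length
            gid = f"G{idx:04d}"
            transcript = _build_transcript(f"{gid}.t1", exons, strand, coding, config.utr_length)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    gene_name=f"GENE{idx:04d}",
                    biotype="protein_coding" if coding else ("pseudogene" if rng.random() < 0.5 else "noncoding"),
                    chrom=chrom,
                    strand=strand,
                    transcripts=(transcript,),
                )
            )
            cursor += span + int(rng.integers(gap_lo, gap_hi + 1))
    return genes


# ---------------------------------------------------------------------------
# Planted cohort


def _draw_length(rng, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


class _Occupancy:
    """Tracks planted footprints to keep truth unambiguous under merging."""

    def __init__(self, gap: int):
        self.gap = gap
        self.by_chrom: dict[str, list] = {}

    def free(self, chrom: str, lo: int, hi: int) -> bool:
        for s, e in self.by_chrom.get(chrom, ()):
            if min(hi, e) - max(lo, s) >= -self.gap:
                return False
        return True

    def add(self, chrom: str, lo: int, hi: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((lo, hi))


def _place(
    rng,
    config: SimConfig,
    genes: Sequence[GeneModel],
    occupancy: _Occupancy,
    loc_class: str,
    chrom_free: dict,
):
    """Choose (chrom, start, end, svtype, length, gene_id) for one planted SV.

    Returns None if no valid placement was found in the retry budget.
    """
    lmin, lmax = config.sv_length_range
    coding = [g for g in genes if g.biotype == "protein_coding"]
    for _attempt in range(300):
        types = list(config.type_mix)
        probs = np.array([config.type_mix[t] for t in types], dtype=float)
        if loc_class == "exon_intron":  # a point insertion cannot span a boundary
            probs[types.index("INS")] = 0.0
        probs /= probs.sum()
        svtype = str(rng.choice(types, p=probs))

        if loc_class == "intergenic":
            windows = chrom_free["intergenic"]
            widths = np.array([w[2] - w[1] + 1 for w in windows], dtype=float)
            chrom, wlo, whi = windows[int(rng.choice(len(windows), p=widths / widths.sum()))]
            if svtype == "INS":
                pos = int(rng.integers(wlo, whi + 1))
                lo = hi = pos
                start, end, length = pos, pos, _draw_length(rng, lmin, lmax)
            else:
                cap = min(lmax, whi - wlo + 1 - 10)
                if cap < lmin:
                    continue
                length = _draw_length(rng, lmin, cap)
                aff_lo = int(rng.integers(wlo, whi - length + 2))
                lo, hi = aff_lo, aff_lo + length - 1
                start, end = lo - 1, hi
            gene_id = None
        else:
            pool = coding if loc_class in ("utr", "exon", "exon_intron") else genes
            if not pool:
                return None
            g = pool[int(rng.integers(len(pool)))]
            t = g.transcripts[0]
            if loc_class == "exon":
                # interior exons only: first/last exons hold the UTRs
                gi = int(rng.integers(1, len(t.exons) - 1))
                s, e = t.exons[gi]
                if svtype == "INS":
                    pos = int(rng.integers(s + 10, e - 10 + 1))
                    lo = hi = pos
                    start, end, length = pos, pos, _draw_length(rng, lmin, lmax)
                else:
                    cap = min(lmax, e - s + 1 - 20)
                    if cap < lmin:
                        continue
                    length = _draw_length(rng, lmin, cap)
                    aff_lo = int(rng.integers(s + 10, e - 10 - length + 2))
                    lo, hi = aff_lo, aff_lo + length - 1
                    start, end = lo - 1, hi
            elif loc_class == "utr":
                ivs = list(t.utr5) + list(t.utr3)
                if not ivs:
                    continue
                s, e = ivs[int(rng.integers(len(ivs)))]
                if svtype == "INS":
                    pos = int(rng.integers(s + 5, e - 5 + 1))
                    lo = hi = pos
                    start, end, length = pos, pos, _draw_length(rng, lmin, lmax)
                else:
                    cap = min(lmax, e - s + 1 - 10)
                    if cap < lmin:
                        continue
                    length = _draw_length(rng, lmin, cap)
                    aff_lo = int(rng.integers(s + 5, e - 5 - length + 2))
                    lo, hi = aff_lo, aff_lo + length - 1
                    start, end = lo - 1, hi
            elif loc_class == "exon_intron":
                gi = int(rng.integers(1, len(t.exons) - 1))
                boundary = t.exons[gi][1]  # exon end; intron starts at boundary+1
                a = int(rng.integers(10, min(100, config.exon_length - 10) + 1))
                b = int(rng.integers(10, min(100, config.intron_length - 10) + 1))
                lo, hi = boundary - a + 1, boundary + b
                start, end = lo - 1, hi
                length = hi - lo + 1
            elif loc_class == "intron":
                gi = int(rng.integers(len(t.introns)))
                s, e = t.introns[gi]
                if svtype == "INS":
                    pos = int(rng.integers(s + 10, e - 10 + 1))
                    lo = hi = pos
                    start, end, length = pos, pos, _draw_length(rng, lmin, lmax)
                else:
                    cap = min(lmax, e - s + 1 - 20)
                    if cap < lmin:
                        continue
                    length = _draw_length(rng, lmin, cap)
                    aff_lo = int(rng.integers(s + 10, e - 10 - length + 2))
                    lo, hi = aff_lo, aff_lo + length - 1
                    start, end = lo - 1, hi
            else:  # upstream_downstream
                side = rng.random() < 0.5
                d = int(rng.integers(200, config.flank - 600))
                if svtype == "INS":
                    pos = g.start - d if side else g.end + d
                    lo = hi = pos
                    start, end, length = pos, pos, _draw_length(rng, lmin, lmax)
                else:
                    cap = min(lmax, config.flank - d - 200)
                    if cap < lmin:
                        continue
                    length = _draw_length(rng, lmin, cap)
                    if side:
                        hi = g.start - d
                        lo = hi - length + 1
                    else:
                        lo = g.end + d
                        hi = lo + length - 1
                    start, end = lo - 1, hi
            chrom = g.chrom
            gene_id = g.gene_id
        if lo < 1:
            continue
        if occupancy.free(chrom, lo, hi):
            occupancy.add(chrom, lo, hi)
            return chrom, start, end, svtype, length, gene_id
    return None


def _intergenic_windows(config: SimConfig, genes: Sequence[GeneModel]) -> list:
    margin = config.flank + config.min_planted_gap
    windows = []
    for chrom in config.chrom_names:
        spans = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
        edges = [1000] + [e + margin for _, e in spans]
        stops = [s - margin for s, _ in spans] + [config.chrom_length - 1000]
        for lo, hi in zip(edges, stops):
            if hi - lo >= 100:
                windows.append((chrom, lo, hi))
    return windows


def _draw_carriers(rng, samples: list, freq_range: tuple, min_carriers: int) -> tuple:
    for _ in range(1000):
        p = rng.uniform(*freq_range)
        mask = rng.random(len(samples)) < p
        picked = [s for s, m in zip(samples, mask) if m]
        if len(picked) >= min_carriers:
            return tuple(picked)
    # extreme configs: fall back to a minimal random draw
    idx = rng.choice(len(samples), size=min(min_carriers, len(samples)), replace=False)
    return tuple(samples[i] for i in sorted(idx))


def simulate_cohort(config: SimConfig, genes: Sequence[GeneModel]) -> TruthTable:
    """Plant shared and group-specific SVs with known carriers and locations.

    Shared SVs have at least one carrier in every group; group-specific SVs
    have ≥ 2 carriers, all in one group. Placement is stratified over location
    classes (one of each class first, the rest by ``location_weights``), and
    planted footprints keep a safety gap so no two true SVs ever merge. A few
    extra SVs go on chromosome Y to exercise the chromosome filter.
    """
    rng = np.random.default_rng([config.seed, 22])
    sheet = sample_sheet_for(config)
    all_samples = list(sheet)
    by_group = {g: [s for s, grp in sheet.items() if grp == g] for g in config.group_sizes}

    occupancy = _Occupancy(config.min_planted_gap)
    chrom_free = {"intergenic": _intergenic_windows(config, genes)}

    classes = list(config.location_weights)
    weights = np.array([config.location_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    gene_classes_ok = bool(genes)

    def draw_class(i: int) -> str:
        if gene_classes_ok and i < len(classes):
            return classes[i]  # guarantee every class is represented
        if not gene_classes_ok:
            return "intergenic"
        return str(rng.choice(classes, p=weights))

    planted: list[PlantedSV] = []
    uid = 0

    def plant(n: int, group: str | None) -> None:
        nonlocal uid
        for i in range(n):
            # one planted SV per location class first (shared set), rest weighted
            loc = draw_class(i) if group is None else draw_class(len(classes))
            placed = _place(rng, config, genes, occupancy, loc, chrom_free)
            if placed is None:
                placed = _place(rng, config, genes, occupancy, "intergenic", chrom_free)
                loc = "intergenic"
            if placed is None:
                raise RuntimeError("no room left to place planted SVs")
            chrom, start, end, svtype, length, gene_id = placed
            if group is None:
                for _try in range(1000):
                    carriers = _draw_carriers(rng, all_samples, config.shared_carrier_freq, 2)
                    if all(any(sheet[s] == g for s in carriers) for g in config.group_sizes):
                        break
            else:
                carriers = _draw_carriers(
                    rng, by_group[group], config.specific_carrier_freq, 2
                )
            uid += 1
            planted.append(
                PlantedSV(
                    uid=f"planted_{uid:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    length=length,
                    carriers=tuple(sorted(carriers)),
                    specific_to=group,
                    location_class="intergenic" if gene_id is None else loc,
                    gene_id=gene_id,
                )
            )

    plant(config.n_shared_svs, None)
    for group, n in config.n_specific_svs.items():
        plant(n, group)

    # chromosome-Y records exercise the sex-chromosome filter downstream
    for _ in range(config.n_y_svs):
        length = _draw_length(rng, *config.sv_length_range)
        pos = int(rng.integers(10_000, config.y_chrom_length - 10_000))
        svtype = str(rng.choice(list(config.type_mix), p=weights_from(config.type_mix)))
        if svtype == "INS":
            start = end = pos
        else:
            start, end = pos, pos + length
        carriers = _draw_carriers(rng, all_samples, config.shared_carrier_freq, 2)
        uid += 1
        planted.append(
            PlantedSV(
                uid=f"planted_{uid:04d}",
                chrom="Y",
                start=start,
                end=end,
                svtype=svtype,
                length=length,
                carriers=tuple(sorted(carriers)),
                specific_to=None,
                location_class="intergenic",
                gene_id=None,
            )
        )
    return TruthTable(planted)


def weights_from(mix: dict) -> np.ndarray:
    w = np.array(list(mix.values()), dtype=float)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Caller emulation


def simulate_caller_output(
    truth: TruthTable, config: SimConfig, caller_id: str
) -> tuple[dict, pd.DataFrame]:
    """Emulate one caller: per-sample call lists plus an emission log.

    Each planted SV carried by a sample is emitted with probability
    ``1 - fn_rate``, its breakpoints perturbed by rounded zero-mean Gaussian
    jitter (length recomputed for interval types), and its support drawn from
    a Poisson with mean ``support_mean`` (floored at ``support_min``). False
    positives are scattered uniformly over the genome at ``fp_per_mb`` per
    sample with random types and lengths. The emission log records
    (uid, sample, caller, support) for every emitted true call.
    """
    if caller_id not in config.callers:
        raise ValueError(f"unknown caller {caller_id!r}; configured: {config.callers}")
    stream = 100 + list(config.callers).index(caller_id)
    rng = np.random.default_rng([config.seed, stream])
    sheet = sample_sheet_for(config)
    calls: dict[str, list[SVCall]] = {s: [] for s in sheet}
    emitted = []

    def draw_support() -> int:
        return int(max(config.support_min, rng.poisson(config.support_mean)))

    for sv in truth.svs:
        for sample in sv.carriers:
            if rng.random() < config.fn_rate:
                continue
            if config.jitter_sd > 0:
                ds, de = np.round(rng.normal(0.0, config.jitter_sd, size=2)).astype(int)
            else:
                ds = de = 0
            if sv.svtype == "INS":
                start = end = max(1, sv.start + ds)
                length = sv.length
            else:
                start = max(1, sv.start + ds)
                end = max(start + 1, sv.end + de)
                length = end - start
            support = draw_support()
            calls[sample].append(
                SVCall(caller_id, sample, sv.chrom, start, end, sv.svtype, length, support)
            )
            emitted.append(
                {"uid": sv.uid, "sample": sample, "caller": caller_id, "support": support}
            )

    chrom_lengths = {c: config.chrom_length for c in config.chrom_names}
    chrom_lengths["Y"] = config.y_chrom_length
    chroms = list(chrom_lengths)
    chrom_p = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    fp_mean = config.fp_per_mb * config.genome_mb
    types = list(config.type_mix)
    type_p = weights_from(config.type_mix)
    for sample in sheet:
        for _ in range(int(rng.poisson(fp_mean))):
            chrom = str(rng.choice(chroms, p=chrom_p))
            svtype = str(rng.choice(types, p=type_p))
            length = _draw_length(rng, *config.sv_length_range)
            pos = int(rng.integers(1000, chrom_lengths[chrom] - length - 1000))
            if svtype == "INS":
                start = end = pos
            else:
                start, end = pos, pos + length
            calls[sample].append(
                SVCall(caller_id, sample, chrom, start, end, svtype, length, draw_support())
            )

    for sample in calls:
        calls[sample].sort(key=lambda c: (chrom_sort_key(c.chrom), c.start, c.end, c.svtype))
    log_df = pd.DataFrame(emitted, columns=["uid", "sample", "caller", "support"])
    return calls, log_df


# ---------------------------------------------------------------------------
# Gene sets


def generate_gene_sets(
    truth: TruthTable,
    genes: Sequence[GeneModel],
    config: SimConfig,
    target_group: str = "WXP",
) -> tuple[list[GeneSet], GeneSet]:
    """Random control terms plus skin/aging-tagged terms and an aging list.

    Tagged terms and the aging list are seeded with genes hit by planted
    ``target_group``-specific SVs (plus random fill), so the downstream
    candidate screen has true positives to find.
    """
    rng = np.random.default_rng([config.seed, 33])
    background = sorted(g.gene_id for g in genes)
    if not background:
        raise ValueError("cannot build gene sets without genes")
    hit = sorted({s.gene_id for s in truth.specific(target_group) if s.gene_id})
    sets: list[GeneSet] = []
    for i in range(1, 21):
        size = int(rng.integers(10, 31))
        members = rng.choice(background, size=min(size, len(background)), replace=False)
        sets.append(
            GeneSet(f"TERM_{i:03d}", f"random control set {i}", frozenset(members))
        )
    tagged_names = [
        ("SKIN_001", "skin structure formation"),
        ("SKIN_002", "collagen fibril organization in skin"),
        ("AGING_001", "aging"),
        ("AGING_002", "cellular senescence and aging"),
        ("SKIN_003", "skin epidermis development"),
    ]
    for j, (tid, name) in enumerate(tagged_names):
        seed_genes = [h for k, h in enumerate(hit) if k % len(tagged_names) == j]
        fill = rng.choice(background, size=10, replace=False)
        members = frozenset(seed_genes) | frozenset(fill)
        sets.append(GeneSet(tid, name, members))
    aging_members = frozenset(hit[::2]) | frozenset(rng.choice(background, size=8, replace=False))
    aging = GeneSet("aging_genes", "aging genes", aging_members, source="aging-list")
    return sets, aging


# ---------------------------------------------------------------------------
# Whole-study convenience


@dataclass
class SimulatedStudy:
    config: SimConfig
    genes: list
    truth: TruthTable
    sample_sheet: dict
    calls: dict  # caller_id -> sample_id -> [SVCall]
    emissions: pd.DataFrame
    gene_sets: list
    aging_genes: GeneSet


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate gene models, planted truth, both callers' outputs and gene sets."""
    genes = simulate_gene_models(config)
    truth = simulate_cohort(config, genes)
    calls = {}
    logs = []
    for caller in config.callers:
        calls[caller], log_df = simulate_caller_output(truth, config, caller)
        logs.append(log_df)
    emissions = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(
        columns=["uid", "sample", "caller", "support"]
    )
    gene_sets, aging = generate_gene_sets(truth, genes, config)
    return SimulatedStudy(
        config=config,
        genes=genes,
        truth=truth,
        sample_sheet=sample_sheet_for(config),
        calls=calls,
        emissions=emissions,
        gene_sets=gene_sets,
        aging_genes=aging,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write the study as files: GFF3, sample sheet, caller TSVs, truth, gene sets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gff3(study.genes, outdir / "genes.gff3")
    study.truth.write(outdir / "truth.tsv")
    with (outdir / "sample_sheet.tsv").open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in study.sample_sheet.items():
            fh.write(f"{s}\t{g}\n")
    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    for caller, by_sample in study.calls.items():
        for sample, records in by_sample.items():
            with (calls_dir / f"{sample}.{caller}.tsv").open("w") as fh:
                fh.write("chrom\tstart\tend\tsvtype\tlength\tsupport\n")
                for c in records:
                    fh.write(
                        f"{c.chrom}\t{c.start}\t{c.end}\t{c.svtype}\t{c.length}\t{c.support}\n"
                    )
    write_gmt(study.gene_sets, outdir / "gene_sets.gmt")
    with (outdir / "aging_genes.txt").open("w") as fh:
        for g in sorted(study.aging_genes.genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Evaluation helpers


def both_caller_carriers(
    emissions: pd.DataFrame, config: SimConfig, min_support: int = 3
) -> dict:
    """Per planted SV, the samples where *both* callers emitted it with
    support ≥ ``min_support`` — i.e. the samples able to survive consensus."""
    ok = emissions[emissions["support"] >= min_support]
    out: dict = {}
    for uid, grp in ok.groupby("uid"):
        per_caller = [
            set(grp.loc[grp["caller"] == c, "sample"]) for c in config.callers
        ]
        samples = set.intersection(*per_caller) if per_caller else set()
        if samples:
            out[uid] = samples
    return out


def match_truth_to_merged(
    truth: TruthTable,
    merged: Sequence[MergedSV],
    min_overlap: int = 25,
    ins_window: int = 25,
) -> dict:
    """Map each planted SV uid to the merged record IDs it is mergeable with."""
    from collections import defaultdict

    by_bucket = defaultdict(list)
    for m in merged:
        by_bucket[(m.chrom, m.svtype)].append(m)
    hits: dict = {}
    for sv in truth.svs:
        matches = [
            m.id
            for m in by_bucket.get((sv.chrom, sv.svtype), ())
            if mergeable(sv, m, min_overlap, ins_window)
        ]
        hits[sv.uid] = matches
    return hits
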