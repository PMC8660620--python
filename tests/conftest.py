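from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from svcohort.annotate import GeneModel, Transcript
from svcohort.sv_io import ConsensusSV, MergedSV

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def candidate_rows() -> pd.DataFrame:
    """Published candidate-SV table rows (id, chrom, start, end, length, type...)."""
    return pd.read_csv(DATA_DIR / "candidate_svs.tsv", sep="\t", dtype={"chrom": str})


@pytest.fixture
def gene_factory():
    """Build a gene with equal-size exons/introns at a given genomic origin."""

    def make(
        chrom: str = "1",
        origin: int = 1000,
        n_exons: int = 2,
        strand: int = 1,
        exon_len: int = 300,
        intron_len: int = 700,
        gene_id: str = "G0001",
        cds=(),
        utr5=(),
        utr3=(),
        biotype: str = "protein_coding",
    ) -> GeneModel:
        unit = exon_len + intron_len
        exons = tuple(
            (origin + i * unit, origin + i * unit + exon_len - 1) for i in range(n_exons)
        )
        t = Transcript(f"{gene_id}.t1", exons, cds=tuple(cds), utr5=tuple(utr5), utr3=tuple(utr3))
        return GeneModel(gene_id, gene_id, biotype, chrom, strand, (t,))

    return make


@pytest.fixture
def random_consensus_calls():
    """Factory for random per-cohort consensus records on a tiny genome."""

    def make(rng: np.random.Generator, n: int) -> list[ConsensusSV]:
        records = []
        for _ in range(n):
            svtype = str(rng.choice(["DEL", "DUP", "INS", "INV"], p=[0.6, 0.15, 0.15, 0.1]))
            chrom = str(rng.choice(["1", "2"]))
            start = int(rng.integers(1, 5000))
            if svtype == "INS":
                end, length = start, int(rng.integers(50, 400))
            else:
                length = int(rng.integers(30, 400))
                end = start + length
            records.append(
                ConsensusSV(
                    sample_id=f"S{int(rng.integers(1, 9))}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    length=length,
                    support=int(rng.integers(3, 20)),
                )
            )
        return records

    return make


def merged_sv(chrom="1", start=1000, end=1500, svtype="DEL", carriers=("S1", "S2"), id=None):
    length = end - start if svtype != "INS" else 100
    return MergedSV(
        chrom=chrom, start=start, end=end, svtype=svtype, length=length,
        carriers=frozenset(carriers), id=id,
    )
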