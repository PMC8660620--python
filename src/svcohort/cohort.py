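"""Cohort-level comparative analyses on the presence/absence genotype matrix.

The merged call set induces a binary samples × SVs matrix (1 = the sample
carries the SV). On top of it this module provides the three-set Venn
partition by group, group-specific SV screening, per-chromosome counts,
principal component analysis of the SV pattern, and exact tests for carrier
frequency differences between groups (Fisher's exact test for two groups, the
exact conditional test with fixed margins for three or more).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sv_io import MergedSV, chrom_sort_key

__all__ = [
    "GenotypeMatrix",
    "GroupSpecificResult",
    "build_genotype_matrix",
    "venn_partition",
    "find_group_specific",
    "chrom_distribution",
    "pca_genotypes",
    "exact_count_test",
    "allele_frequency_test",
    "allele_frequency_table",
]

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Samples × SVs presence/absence table with one group label per sample."""

    data: pd.DataFrame  # index sample_ids, columns sv_ids, values {0,1}
    groups: pd.Series  # index sample_ids, values group labels

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise ValueError("groups must be indexed by the matrix sample_ids")
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("genotype matrix values must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def group_labels(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def carriers_by_group(self, sv_id: str) -> dict[str, int]:
        col = self.data[sv_id]
        return {g: int(col[self.groups == g].sum()) for g in self.group_labels}

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.groups == g).sum()) for g in self.group_labels}


@dataclass(frozen=True)
class GroupSpecificResult:
    sv_id: str
    carrier_counts: Mapping[str, int]
    specific_to: str | None


def build_genotype_matrix(
    svs: Sequence[MergedSV], sample_sheet: Mapping[str, str]
) -> GenotypeMatrix:
    """Binary carrier matrix from merged SVs and a sample → group map.

    Row order follows the sample sheet; column order follows the SV list.
    A carrier missing from the sample sheet is an error.
    """
    samples = list(sample_sheet)
    sample_pos = {s: i for i, s in enumerate(samples)}
    mat = np.zeros((len(samples), len(svs)), dtype=np.int8)
    sv_ids = []
    for j, sv in enumerate(svs):
        sv_ids.append(sv.id or f"sv_{j + 1:05d}")
        for s in sv.carriers:
            if s not in sample_pos:
                raise ValueError(f"carrier {s!r} of {sv_ids[-1]} not in sample sheet")
            mat[sample_pos[s], j] = 1
    data = pd.DataFrame(mat, index=pd.Index(samples, name="sample_id"), columns=sv_ids)
    groups = pd.Series([sample_sheet[s] for s in samples], index=data.index, name="group")
    return GenotypeMatrix(data, groups)


def venn_partition(matrix: GenotypeMatrix) -> dict[frozenset, int]:
    """Count SVs per combination of groups with at least one carrier.

    Every SV column falls in exactly one cell, so the counts sum to the number
    of SVs (columns with no carrier at all are keyed by the empty set).
    """
    counts: dict[frozenset, int] = {}
    group_arr = matrix.groups.to_numpy()
    vals = matrix.data.to_numpy()
    for j in range(vals.shape[1]):
        present = frozenset(group_arr[vals[:, j] > 0])
        counts[present] = counts.get(present, 0) + 1
    return counts


def find_group_specific(
    matrix: GenotypeMatrix, target_group: str
) -> list[GroupSpecificResult]:
    """SVs carried only within ``target_group`` (≥1 carrier there, 0 elsewhere)."""
    if target_group not in set(matrix.groups):
        raise ValueError(f"unknown group {target_group!r}")
    out = []
    group_arr = matrix.groups.to_numpy()
    vals = matrix.data.to_numpy()
    labels = matrix.group_labels
    for j, sv_id in enumerate(matrix.sv_ids):
        col = vals[:, j]
        counts = {g: int(col[group_arr == g].sum()) for g in labels}
        inside = counts.get(target_group, 0)
        outside = sum(v for g, v in counts.items() if g != target_group)
        if inside >= 1 and outside == 0:
            out.append(GroupSpecificResult(sv_id, counts, target_group))
    return out


def chrom_distribution(svs: Sequence[MergedSV]) -> dict[str, int]:
    """Per-chromosome SV counts in natural chromosome order (X after autosomes)."""
    counts: dict[str, int] = {}
    for sv in svs:
        counts[sv.chrom] = counts.get(sv.chrom, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: chrom_sort_key(kv[0])))


def pca_genotypes(
    matrix: GenotypeMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the presence/absence matrix via SVD of the column-centered data.

    Columns are mean-centered but not scaled. The sign of each component is
    fixed by forcing its largest-magnitude loading positive, so coordinates
    are deterministic. Returns (sample coordinates, explained-variance
    fractions). A constant matrix has no variance; it yields all-zero
    coordinates with a warning.
    """
    n_samples = len(matrix.sample_ids)
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components >= n_samples:
        raise ValueError("n_components must be < number of samples")
    X = matrix.data.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    if X.shape[1] == 0 or not np.any(Xc):
        warnings.warn("genotype matrix has no variance; returning zero coordinates")
        coords = pd.DataFrame(
            np.zeros((n_samples, n_components)), index=matrix.data.index, columns=cols
        )
        return coords, np.zeros(n_components)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(min(n_components, len(S))):
        pivot = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :n_components] * S[:n_components]
    total_var = float((S**2).sum())
    explained = (S[:n_components] ** 2) / total_var
    coords = pd.DataFrame(scores, index=matrix.data.index, columns=cols)
    return coords, explained


# ---------------------------------------------------------------------------
# Exact carrier-frequency tests


def exact_count_test(carriers: Sequence[int], totals: Sequence[int]) -> float:
    """Exact conditional test of equal carrier frequency across groups.

    ``carriers[g]`` of ``totals[g]`` samples in each group carry the variant.
    With both margins fixed, table probabilities follow the multivariate
    hypergeometric distribution; the two-sided p-value is the total
    probability of all tables no more probable than the observed one (the
    standard Fisher construction; identical to Fisher's exact test for two
    groups).
    """
    carriers = list(carriers)
    totals = list(totals)
    if len(carriers) != len(totals) or len(carriers) < 2:
        raise ValueError("need carrier and total counts for >= 2 groups")
    if any(t <= 0 for t in totals):
        raise ValueError("every group must have at least one sample")
    if any(k < 0 or k > t for k, t in zip(carriers, totals)):
        raise ValueError("carrier counts must lie in [0, group size]")
    K = sum(carriers)
    N = sum(totals)
    denom = math.comb(N, K)

    def table_prob(ks: tuple[int, ...]) -> float:
        num = 1
        for k, t in zip(ks, totals):
            num *= math.comb(t, k)
        return num / denom

    p_obs = table_prob(tuple(carriers))
    eps = 1e-12

    total_p = 0.0
    def recurse(g: int, remaining: int, acc: list[int]) -> None:
        nonlocal total_p
        if g == len(totals) - 1:
            if 0 <= remaining <= totals[g]:
                p = table_prob(tuple(acc + [remaining]))
                if p <= p_obs * (1 + eps):
                    total_p += p
            return
        lo = max(0, remaining - sum(totals[g + 1:]))
        hi = min(totals[g], remaining)
        for k in range(lo, hi + 1):
            recurse(g + 1, remaining - k, acc + [k])

    recurse(0, K, [])
    return min(total_p, 1.0)


def allele_frequency_test(
    sv_id: str, matrix: GenotypeMatrix, groups: Sequence[str] | None = None
) -> tuple[float, dict[str, float]]:
    """Exact test of carrier-frequency difference for one SV between groups.

    "Allele frequency" here is the carrier frequency under the
    presence/absence genotype model. Two groups use Fisher's exact test
    (two-sided); three or more use :func:`exact_count_test`. Returns the
    p-value and the per-group carrier frequencies.
    """
    labels = list(groups) if groups is not None else matrix.group_labels
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = matrix.carriers_by_group(sv_id)
    sizes = matrix.group_sizes()
    for g in labels:
        if sizes.get(g, 0) == 0:
            raise ValueError(f"group {g!r} has no samples")
    k = [counts[g] for g in labels]
    n = [sizes[g] for g in labels]
    if len(labels) == 2:
        table = [[k[0], n[0] - k[0]], [k[1], n[1] - k[1]]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        p = exact_count_test(k, n)
    freqs = {g: counts[g] / sizes[g] for g in labels}
    return p, freqs


def allele_frequency_table(
    matrix: GenotypeMatrix, adjust: bool = False, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-SV carrier-frequency test table, optionally BH-adjusted.

    Columns: carrier frequency per group, ``pvalue`` and, with
    ``adjust=True``, Benjamini–Hochberg ``p_adj``; ``significant`` flags
    ``pvalue < alpha`` (or ``p_adj`` when adjusted).
    """
    labels = matrix.group_labels
    rows = []
    for sv_id in matrix.sv_ids:
        p, freqs = allele_frequency_test(sv_id, matrix, labels)
        rows.append({"sv_id": sv_id, **{f"freq_{g}": freqs[g] for g in labels}, "pvalue": p})
    df = pd.DataFrame(rows).set_index("sv_id") if rows else pd.DataFrame(
        columns=[f"freq_{g}" for g in labels] + ["pvalue"]
    )
    if adjust and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_adj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    elif len(df):
        df["significant"] = df["pvalue"] < alpha
    return df
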