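"""Pairwise population differentiation for biallelic panels.

Implements Nei's DA genetic distance from allele-frequency tables,
Weir-Cockerham theta (FST) from genotype counts, and the Hudson FST
estimator from frequencies alone (for reference panels where only summary
frequencies are available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_model import FrequencyTable, GenotypeCounts


@dataclass
class DistanceMatrix:
    population_ids: list[str]
    values: np.ndarray
    metric_name: str = "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.population_ids)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.population_ids,
                            columns=self.population_ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="population")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format (for tree-software interchange)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.population_ids)}\n")
            for pid, row in zip(self.population_ids, self.values):
                name = pid[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def nei_da_matrix(table: FrequencyTable) -> DistanceMatrix:
    """Nei's DA distance between every pair of populations.

    For biallelic loci with insertion frequency x in one population and y in
    the other, DA = 1 - (1/L) sum_l (sqrt(x_l y_l) + sqrt((1-x_l)(1-y_l))).
    Bounded in [0, 1]; zero iff the frequency vectors coincide.
    """
    if table.n_populations < 2 or len(table.loci) < 1:
        raise ValueError("need >= 2 populations and >= 1 locus")
    p = table.freq  # (K, L)
    sqrt_ins = np.sqrt(p)
    sqrt_del = np.sqrt(1.0 - p)
    # mean over loci of summed geometric means of shared allele freqs
    shared = sqrt_ins @ sqrt_ins.T + sqrt_del @ sqrt_del.T  # (K, K) sums over loci
    da = 1.0 - shared / p.shape[1]
    np.fill_diagonal(da, 0.0)
    da = np.clip((da + da.T) / 2.0, 0.0, 1.0)  # symmetrize roundoff
    return DistanceMatrix(list(table.population_ids), da, "Nei_DA")


def _wc_components(
    p1: float, h1: float, n1: int, p2: float, h2: float, n2: int
) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) variance components a, b, c for one biallelic
    locus and two populations.  p = allele frequency, h = observed
    heterozygote proportion, n = diploid sample size."""
    r = 2
    n_bar = (n1 + n2) / r
    nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / nc) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def fst_weir_cockerham(
    counts_a: Sequence[GenotypeCounts],
    counts_b: Sequence[GenotypeCounts],
    return_components: bool = False,
):
    """Multi-locus Weir-Cockerham theta between two populations.

    theta = sum_l a_l / sum_l (a_l + b_l + c_l) over loci; loci monomorphic
    in both populations carry no information and are excluded with a
    warning.  Negative estimates are reported as-is.
    """
    if len(counts_a) != len(counts_b):
        raise ValueError("populations must share the same locus list")
    comps = []
    skipped = 0
    for ca, cb in zip(counts_a, counts_b):
        if ca.n < 2 or cb.n < 2:
            raise ValueError("Weir-Cockerham theta requires n >= 2 per population")
        p1 = ca.insertion_count / (2 * ca.n)
        p2 = cb.insertion_count / (2 * cb.n)
        if (p1 in (0.0, 1.0)) and p1 == p2:
            skipped += 1
            continue
        comps.append(
            _wc_components(p1, ca.n_ID / ca.n, ca.n, p2, cb.n_ID / cb.n, cb.n)
        )
    if skipped:
        warnings.warn(
            f"{skipped} locus/loci monomorphic in both populations excluded "
            "from theta", stacklevel=2,
        )
    if not comps:
        raise ValueError("no polymorphic loci; theta undefined")
    arr = np.array(comps)  # (L, 3)
    theta = float(arr[:, 0].sum() / arr.sum())
    if return_components:
        return theta, arr
    return theta


def fst_hudson(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson FST estimator with sample-size bias correction.

    n1, n2 are *allele* counts (2x diploids).  Following the ratio-of-
    averages form: numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    denominator p1(1-p2) + p2(1-p1).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 sampled alleles per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0:
        raise ValueError("FST undefined: both populations monomorphic and identical")
    return num / den


def fst_hudson_matrix(table: FrequencyTable, clamp: bool = False) -> DistanceMatrix:
    """Pairwise multi-locus Hudson FST (ratio of summed numerators to summed
    denominators across loci) from a frequency table.  ``clamp`` zeroes
    negative estimates for heatmap export."""
    k = table.n_populations
    out = np.zeros((k, k))
    n_alleles = 2 * table.sample_sizes
    for i in range(k):
        for j in range(i + 1, k):
            p1, p2 = table.freq[i], table.freq[j]
            n1, n2 = n_alleles[i], n_alleles[j]
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            ok = den > 0
            if not ok.any():
                raise ValueError("FST undefined for an identical monomorphic pair")
            val = num[ok].sum() / den[ok].sum()
            out[i, j] = out[j, i] = max(val, 0.0) if clamp else val
    return DistanceMatrix(list(table.population_ids), out, "Hudson_FST")
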