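"""Synthetic genotype generators and the bundled published-panel fixture.

The study design being emulated: one target population genotyped at 57
biallelic InDels (n = 262 diploids), compared against a set of reference
populations that diverged from shared founder frequencies.  Generators
cover exactly the structures the analyses assume — Hardy-Weinberg
populations at given frequencies, admixed individuals with given ancestry
fractions, two-locus haplotype draws with given LD, and drifted reference
panels under the Balding-Nichols model.

The bundled fixture rebuilds a full 262 x 57 genotype matrix from the
published per-locus summaries (insertion frequency and observed
heterozygosity).  Its single-locus statistics reproduce the published
report table exactly; its multi-locus arrangement (genotypes stacked in
II / ID / DD blocks per locus) is deliberately artificial, so the fixture
must never be used to study between-locus structure.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_model import (
    FrequencyTable,
    GenotypeMatrix,
    LocusMeta,
    reconstruct_counts_from_summary,
    SummaryReconstructionError,
)

TABLE1_N = 262  #: diploid sample size of the bundled panel


@dataclass
class PopulationSpec:
    population_id: str
    size: int
    drift: float = 0.0  # Balding-Nichols c in [0, 1); 0 = founder freqs
    freqs: np.ndarray | None = None  # fixed per-locus freqs override drift


@dataclass
class PanelSpec:
    loci: list[LocusMeta]
    founder_freqs: np.ndarray
    populations: list[PopulationSpec] = field(default_factory=list)
    admixture_q: np.ndarray | None = None


def sample_hwe_population(
    freqs: np.ndarray, n: int, seed: int = 0,
    sample_prefix: str = "s", locus_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """n diploids in Hardy-Weinberg proportions: dosage ~ Binomial(2, p)
    independently per locus."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, freqs[None, :], size=(n, len(freqs)))
    ids = locus_ids or [f"locus{j}" for j in range(len(freqs))]
    return GenotypeMatrix(
        [f"{sample_prefix}{i}" for i in range(n)],
        [LocusMeta(l) for l in ids],
        dosage,
    )


def sample_admixed_population(
    q: np.ndarray, f: np.ndarray, seed: int = 0, sample_prefix: str = "s",
) -> GenotypeMatrix:
    """Admixed diploids: each of the two allele copies of individual i at
    locus j picks ancestral component k with probability q_ik, then is an
    insertion with probability f_kj."""
    q = np.asarray(q, dtype=float)
    f = np.asarray(f, dtype=float)
    if q.ndim != 2 or f.ndim != 2 or q.shape[1] != f.shape[0]:
        raise ValueError("q (n x K) and f (K x L) dimensions do not match")
    if not np.allclose(q.sum(axis=1), 1.0):
        raise ValueError("q rows must sum to 1")
    n, k = q.shape
    L = f.shape[1]
    rng = np.random.default_rng(seed)
    dosage = np.zeros((n, L), dtype=np.int16)
    for copy in range(2):
        comp = np.array([rng.choice(k, size=L, p=q[i]) for i in range(n)])
        p = f[comp, np.arange(L)[None, :]]
        dosage += rng.random((n, L)) < p
    return GenotypeMatrix(
        [f"{sample_prefix}{i}" for i in range(n)],
        [LocusMeta(f"locus{j}") for j in range(L)],
        dosage,
    )


def sample_two_locus_ld(
    haplotype_freqs: np.ndarray, n: int, seed: int = 0
) -> np.ndarray:
    """3x3 joint dosage count table from n diploids built out of 2n
    haplotype draws at frequencies (AB, Ab, aB, ab)."""
    h = np.asarray(haplotype_freqs, dtype=float)
    if h.shape != (4,) or not np.isclose(h.sum(), 1.0):
        raise ValueError("need 4 haplotype frequencies summing to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=(n, 2), p=h)
    # haplotype index -> (A copies, B copies): AB=0 -> (1,1), Ab=1 -> (1,0),
    # aB=2 -> (0,1), ab=3 -> (0,0)
    a_copies = np.isin(draws, (0, 1)).sum(axis=1)
    b_copies = np.isin(draws, (0, 2)).sum(axis=1)
    table = np.zeros((3, 3), dtype=int)
    np.add.at(table, (a_copies, b_copies), 1)
    return table


def load_table1_summaries() -> pd.DataFrame:
    """The bundled per-locus summary file (locus, f_ins, ho) transcribed
    from the published report table."""
    ref = importlib.resources.files("indelkit.data").joinpath("tujia_table1.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def build_table1_fixture(shuffle_seed: int | None = None) -> GenotypeMatrix:
    """Rebuild the 262 x 57 target-population genotype matrix from the
    bundled published summaries.

    Per locus the genotype column is the deterministic block arrangement
    II..II ID..ID DD..DD sized by the reconstructed counts, so every
    single-locus statistic is exact while between-locus structure is
    artificial.  ``shuffle_seed`` applies an independent per-locus
    permutation for procedures that need the blocks broken up.
    """
    df = load_table1_summaries()
    cols = []
    for _, row in df.iterrows():
        try:
            c = reconstruct_counts_from_summary(row.f_ins, row.ho, TABLE1_N)
        except SummaryReconstructionError as exc:
            raise SummaryReconstructionError(
                f"locus {row.locus}: {exc}"
            ) from exc
        cols.append(
            np.repeat([2, 1, 0], [c.n_II, c.n_ID, c.n_DD]).astype(np.int16)
        )
    dosage = np.column_stack(cols)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        for j in range(dosage.shape[1]):
            rng.shuffle(dosage[:, j])
    return GenotypeMatrix(
        [f"TJ{i + 1:03d}" for i in range(TABLE1_N)],
        [LocusMeta(l) for l in df.locus],
        dosage,
    )


def balding_nichols_freqs(
    founder: np.ndarray, c: float, rng: np.random.Generator
) -> np.ndarray:
    """Drifted allele frequencies under the Balding-Nichols model:
    Beta(p(1-c)/c, (1-p)(1-c)/c) per locus; c -> 0 recovers the founder."""
    founder = np.asarray(founder, dtype=float)
    if not 0.0 <= c < 1.0:
        raise ValueError("drift parameter must lie in [0, 1)")
    if c == 0.0:
        return founder.copy()
    scale = (1.0 - c) / c
    p = np.clip(founder, 1e-9, 1 - 1e-9)
    return rng.beta(p * scale, (1.0 - p) * scale)


def build_reference_panel(
    spec: PanelSpec, seed: int = 0
) -> tuple[FrequencyTable, dict[str, GenotypeMatrix]]:
    """Simulate a reference panel: populations drift independently from the
    founder frequencies (Balding-Nichols, per-population c), then genotypes
    are drawn in HWE at the drifted frequencies.  Returns the realized
    sample frequency table and the per-population genotype matrices."""
    if not spec.populations:
        raise ValueError("panel spec lists no populations")
    rng = np.random.default_rng(seed)
    freq_rows = []
    matrices: dict[str, GenotypeMatrix] = {}
    locus_ids = [m.locus_id for m in spec.loci]
    for pop in spec.populations:
        pf = (np.asarray(pop.freqs, dtype=float) if pop.freqs is not None
              else balding_nichols_freqs(spec.founder_freqs, pop.drift, rng))
        gm = sample_hwe_population(
            pf, pop.size, seed=int(rng.integers(2**31)),
            sample_prefix=f"{pop.population_id}_", locus_ids=locus_ids,
        )
        matrices[pop.population_id] = gm
        obs = (gm.dosage.sum(axis=0) / (2 * pop.size)).astype(float)
        freq_rows.append(obs)
    table = FrequencyTable(
        [p.population_id for p in spec.populations],
        list(spec.loci),
        np.array(freq_rows),
        np.array([p.size for p in spec.populations]),
    )
    return table, matrices
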