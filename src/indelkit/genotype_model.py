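"""Core data containers for biallelic InDel panels.

An InDel locus has two alleles, insertion (I) and deletion (D); a diploid
genotype is stored as the insertion-allele dosage 0/1/2.  The module also
implements the inverse problem used throughout the package: recovering the
exact genotype counts of a locus from its published 4-decimal summary
statistics (insertion frequency, observed heterozygosity, sample size).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  #: dosage sentinel for an untyped genotype
MISSING_TOKEN = "NA"

_PAIR_TO_DOSAGE = {"I/I": 2, "I/D": 1, "D/I": 1, "D/D": 0}


class GenotypeParseError(ValueError):
    """A genotype table cell could not be interpreted."""


class SummaryReconstructionError(ValueError):
    """Published summary statistics are mutually inconsistent."""


def _round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables).

    Python's built-in ``round`` is banker's rounding; forensic reports round
    0.5 up, so 0.37505 -> 0.3751 at 4 digits.
    """
    scale = 10.0**ndigits
    scaled = x * scale
    return float(np.floor(np.abs(scaled) + 0.5) * np.sign(scaled) / scale)


def round4(x: float) -> float:
    """Half-away-from-zero rounding to 4 decimals, as in report tables."""
    return _round_half_away(x, 4)


@dataclass(frozen=True)
class LocusMeta:
    """Identity of one biallelic InDel marker."""

    locus_id: str
    insertion_label: str = "I"
    deletion_label: str = "D"

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-locus genotype counts: insertion homozygotes, heterozygotes,
    deletion homozygotes, over ``n`` typed diploid individuals."""

    n_II: int
    n_ID: int
    n_DD: int

    def __post_init__(self) -> None:
        if min(self.n_II, self.n_ID, self.n_DD) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_II + self.n_ID + self.n_DD

    @property
    def insertion_count(self) -> int:
        """Number of insertion-allele copies (out of 2n)."""
        return 2 * self.n_II + self.n_ID

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_II, self.n_ID, self.n_DD)


@dataclass
class GenotypeMatrix:
    """Samples x loci insertion-allele dosages; ``MISSING`` marks untyped cells."""

    sample_ids: list[str]
    loci: list[LocusMeta]
    dosage: np.ndarray  # int array, shape (n_samples, n_loci)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosage[~valid].ravel()[0]
            raise ValueError(f"invalid dosage value {bad}; expected 0/1/2 or missing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        ids = [m.locus_id for m in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [m.locus_id for m in self.loci]

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"locus {locus_id!r} not in matrix") from None


@dataclass
class FrequencyTable:
    """Populations x loci insertion-allele frequencies, with per-population
    diploid sample sizes."""

    population_ids: list[str]
    loci: list[LocusMeta]
    freq: np.ndarray  # float, shape (n_pops, n_loci)
    sample_sizes: np.ndarray  # int, shape (n_pops,)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)
        if self.freq.shape != (len(self.population_ids), len(self.loci)):
            raise ValueError("freq shape inconsistent with id lists")
        if self.sample_sizes.shape != (len(self.population_ids),):
            raise ValueError("sample_sizes shape inconsistent with populations")
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if np.any(self.sample_sizes < 1):
            raise ValueError("sample sizes must be >= 1")

    @property
    def n_populations(self) -> int:
        return len(self.population_ids)

    @property
    def locus_ids(self) -> list[str]:
        return [m.locus_id for m in self.loci]


# ---------------------------------------------------------------------------
# I/O


def _cell_to_dosage(cell: str, row: str, col: str) -> int:
    cell = cell.strip()
    if cell == MISSING_TOKEN or cell == "":
        return MISSING
    if cell in _PAIR_TO_DOSAGE:
        return _PAIR_TO_DOSAGE[cell]
    if cell in ("0", "1", "2"):
        return int(cell)
    raise GenotypeParseError(
        f"cannot parse genotype {cell!r} at sample {row!r}, locus {col!r}"
    )


def read_genotype_table(path: str | Path, dialect: str | None = None) -> GenotypeMatrix:
    """Read a delimited genotype table (header = locus ids, first column =
    sample id).  Cells may be dosages 0/1/2, allele pairs I/I | I/D | D/D,
    or the missing token ``NA``.  ``dialect`` forces ``"csv"``/``"tsv"``;
    by default the delimiter is inferred from the file extension.
    """
    path = Path(path)
    delim = {"csv": ",", "tsv": "\t"}.get(
        dialect or ("tsv" if path.suffix in (".tsv", ".txt") else "csv")
    )
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError(f"{path}: empty file") from None
        locus_ids = [c.strip() for c in header[1:]]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for rec in reader:
            if not rec or not any(c.strip() for c in rec):
                continue
            sid = rec[0].strip()
            if len(rec) != len(header):
                raise GenotypeParseError(
                    f"{path}: sample {sid!r} has {len(rec) - 1} cells, "
                    f"expected {len(locus_ids)}"
                )
            sample_ids.append(sid)
            rows.append(
                [_cell_to_dosage(c, sid, l) for c, l in zip(rec[1:], locus_ids)]
            )
    if len(set(sample_ids)) != len(sample_ids):
        dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
        raise ValueError(f"{path}: duplicate sample ids {sorted(dupes)}")
    dosage = np.array(rows, dtype=np.int16).reshape(len(sample_ids), len(locus_ids))
    return GenotypeMatrix(sample_ids, [LocusMeta(l) for l in locus_ids], dosage)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as delimited text re-readable by
    :func:`read_genotype_table` (dosage coding, ``NA`` for missing)."""
    path = Path(path)
    delim = "\t" if path.suffix in (".tsv", ".txt") else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["sample_id"] + matrix.locus_ids)
        for sid, row in zip(matrix.sample_ids, matrix.dosage):
            writer.writerow(
                [sid] + [MISSING_TOKEN if d == MISSING else str(int(d)) for d in row]
            )


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a populations x loci insertion-frequency table.  First column is
    the population id, last column ``n`` is the diploid sample size."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2 or df.columns[-1] != "n":
        raise ValueError(f"{path}: expected last column 'n' with sample sizes")
    pop_ids = df.iloc[:, 0].astype(str).tolist()
    locus_ids = list(df.columns[1:-1])
    freq = df.iloc[:, 1:-1].to_numpy(dtype=float)
    if np.any((freq < 0) | (freq > 1)):
        raise ValueError(f"{path}: allele frequency outside [0, 1]")
    sizes = df["n"].to_numpy(dtype=int)
    return FrequencyTable(pop_ids, [LocusMeta(l) for l in locus_ids], freq, sizes)


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    df = pd.DataFrame(table.freq, index=table.population_ids, columns=table.locus_ids)
    df["n"] = table.sample_sizes
    df.to_csv(path, index_label="population")


# ---------------------------------------------------------------------------
# Counting and reconstruction


def tabulate_counts(matrix: GenotypeMatrix, locus: int | str) -> GenotypeCounts:
    """Genotype counts at one locus over the non-missing samples."""
    j = matrix.locus_index(locus) if isinstance(locus, str) else locus
    col = matrix.dosage[:, j]
    col = col[col != MISSING]
    if col.size == 0:
        raise ValueError(f"locus {matrix.loci[j].locus_id!r} has no typed samples")
    return GenotypeCounts(
        int(np.sum(col == 2)), int(np.sum(col == 1)), int(np.sum(col == 0))
    )


def reconstruct_counts_from_summary(
    f_ins: float, ho: float, n: int
) -> GenotypeCounts:
    """Invert rounded published summaries to exact genotype counts.

    Given an insertion-allele frequency and observed heterozygosity printed
    to 4 decimals for a sample of ``n`` diploids, the underlying integers are

    * heterozygotes ``n_ID = round(ho * n)``,
    * insertion-allele copies ``a = round(f_ins * 2n)``.

    ``a - n_ID`` must be even (it is twice the insertion-homozygote count);
    if rounding broke parity, ``a`` is nudged by +/-1 toward the value whose
    frequency is closest to the printed one (ties resolved downward).  The
    reconstruction is exact whenever the printed 4-decimal values are
    unambiguous at this ``n``, which holds for n = 262.
    """
    if not (0.0 <= f_ins <= 1.0 and 0.0 <= ho <= 1.0):
        raise ValueError("f_ins and ho must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    n_ID = int(_round_half_away(ho * n))
    a = int(_round_half_away(f_ins * 2 * n))
    if (a - n_ID) % 2 != 0:
        lo, hi = a - 1, a + 1
        err_lo = abs(lo / (2 * n) - f_ins)
        err_hi = abs(hi / (2 * n) - f_ins)
        a = lo if err_lo <= err_hi else hi
    n_II = (a - n_ID) // 2
    n_DD = n - n_ID - n_II
    if n_II < 0 or n_DD < 0:
        raise SummaryReconstructionError(
            f"summaries (f_ins={f_ins}, ho={ho}, n={n}) imply negative counts "
            f"(n_II={n_II}, n_DD={n_DD})"
        )
    return GenotypeCounts(n_II, n_ID, n_DD)
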