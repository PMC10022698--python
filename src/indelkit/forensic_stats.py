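"""Forensic efficiency parameters for biallelic InDel loci.

Per-locus statistics are those of a standard forensic population report:
allele frequencies, observed heterozygosity Ho, Nei's sample-size-unbiased
expected heterozygosity He, polymorphism information content PIC, match
probability PM (sum of squared *observed* genotype frequencies), power of
discrimination PD = 1 - PM, and the trio probability of paternity exclusion
PE = h^2 (1 - 2 h H^2) with h = Ho, H = 1 - h.

Panel-level combined values multiply tiny per-locus quantities; CPD's
complement (the product of the PMs) underflows the resolution of 1 - x in
double precision, so the combined statistics are accumulated exactly as
rationals and rendered through :mod:`decimal`, alongside the conventional
log10/complement representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, getcontext
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_model import GenotypeCounts, GenotypeMatrix, round4, tabulate_counts


@dataclass
class LocusForensicSummary:
    """One row of a forensic report table."""

    locus_id: str
    f_ins: float
    f_del: float
    he: float
    ho: float
    pic: float
    pm: float
    pd: float
    pe: float
    p_hwe: float | None = None

    def rounded(self) -> "LocusForensicSummary":
        """Copy with report rounding (4 decimals, half away from zero)."""
        return LocusForensicSummary(
            self.locus_id,
            *(round4(v) for v in (self.f_ins, self.f_del, self.he, self.ho,
                                  self.pic, self.pm, self.pd, self.pe)),
            None if self.p_hwe is None else round4(self.p_hwe),
        )


@dataclass
class CombinedSummary:
    """Panel-level combined discrimination and exclusion power."""

    cpd: float
    cpe: float
    log10_pm_product: float
    log10_cpe_complement: float
    cpd_string: str  #: CPD rendered from the exact complement, 29 decimals
    cpe_string: str  #: CPE rendered from the exact complement, 15 decimals


def insertion_frequency(counts: GenotypeCounts) -> float:
    """Sample frequency of the insertion allele, (2 n_II + n_ID) / 2n."""
    if counts.n == 0:
        raise ValueError("no typed individuals")
    return counts.insertion_count / (2 * counts.n)


def observed_heterozygosity(counts: GenotypeCounts) -> float:
    """Proportion of heterozygous individuals, n_ID / n."""
    if counts.n == 0:
        raise ValueError("no typed individuals")
    return counts.n_ID / counts.n


def unbiased_expected_heterozygosity(counts: GenotypeCounts) -> float:
    """Nei's unbiased gene diversity, (2n / (2n - 1)) (1 - p^2 - q^2)."""
    n = counts.n
    if n < 2:
        raise ValueError("unbiased He requires n >= 2")
    p = insertion_frequency(counts)
    q = 1.0 - p
    return (2 * n) / (2 * n - 1) * (1.0 - p * p - q * q)


def pic_biallelic(p: float) -> float:
    """Botstein polymorphism information content for a biallelic locus,
    1 - (p^2 + q^2) - 2 p^2 q^2; maximal (0.375) at p = 0.5."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def match_probability(counts: GenotypeCounts) -> float:
    """PM: probability two random individuals share a genotype, computed
    from observed (not HWE-expected) genotype frequencies."""
    n = counts.n
    if n == 0:
        raise ValueError("no typed individuals")
    return sum((c / n) ** 2 for c in counts.as_tuple())


def power_of_discrimination(counts: GenotypeCounts) -> float:
    """PD = 1 - PM."""
    return 1.0 - match_probability(counts)


def power_of_exclusion(ho: float) -> float:
    """Trio probability of paternity exclusion from heterozygosity:
    PE = h^2 (1 - 2 h H^2), h = Ho, H = 1 - h."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError("heterozygosity must lie in [0, 1]")
    h = ho
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def locus_summary(locus_id: str, counts: GenotypeCounts,
                  p_hwe: float | None = None) -> LocusForensicSummary:
    """Full forensic summary for one locus."""
    p = insertion_frequency(counts)
    ho = observed_heterozygosity(counts)
    return LocusForensicSummary(
        locus_id=locus_id,
        f_ins=p,
        f_del=1.0 - p,
        he=unbiased_expected_heterozygosity(counts),
        ho=ho,
        pic=pic_biallelic(p),
        pm=match_probability(counts),
        pd=power_of_discrimination(counts),
        pe=power_of_exclusion(ho),
        p_hwe=p_hwe,
    )


def locus_summary_table(matrix: GenotypeMatrix,
                        hwe: bool = True) -> list[LocusForensicSummary]:
    """Per-locus forensic summaries for every locus of a genotype matrix,
    including the exact HWE p-value unless ``hwe=False``."""
    from .equilibrium_tests import hwe_exact_pvalue  # avoid import cycle

    out = []
    for j, meta in enumerate(matrix.loci):
        counts = tabulate_counts(matrix, j)
        p = hwe_exact_pvalue(counts) if hwe else None
        out.append(locus_summary(meta.locus_id, counts, p))
    return out


# ---------------------------------------------------------------------------
# Combined panel statistics


def _exact_pm(counts: GenotypeCounts) -> Fraction:
    n = counts.n
    return sum((Fraction(c, n) ** 2 for c in counts.as_tuple()), Fraction(0))


def _exact_pe(counts: GenotypeCounts) -> Fraction:
    h = Fraction(counts.n_ID, counts.n)
    H = 1 - h
    return h * h * (1 - 2 * h * H * H)


def combined_statistics(
    summaries: Sequence[LocusForensicSummary],
    counts: Sequence[GenotypeCounts] | None = None,
) -> CombinedSummary:
    """Combined power of discrimination and exclusion across a panel.

    CPD = 1 - prod(PM), CPE = 1 - prod(1 - PE).  The products are
    accumulated in log10 space for the float fields.  When the underlying
    genotype counts are supplied the complements are also computed exactly
    as rationals, so ``cpd_string`` carries the digits of CPD past the point
    where ``1 - x`` saturates in double precision (the PM product of a
    ~60-locus panel is ~1e-24).
    """
    if not summaries:
        raise ValueError("need at least one locus")
    pms = np.array([s.pm for s in summaries], dtype=float)
    pes = np.array([s.pe for s in summaries], dtype=float)
    if np.any(pms <= 0):
        raise ValueError("PM = 0 encountered; combined log product undefined")
    log10_pm = float(np.sum(np.log10(pms)))
    with np.errstate(divide="ignore"):
        log10_cpe_comp = float(np.sum(np.log10(1.0 - pes)))
    cpd = 1.0 - 10.0**log10_pm
    cpe = 1.0 - 10.0**log10_cpe_comp

    getcontext().prec = 60
    if counts is not None:
        pm_comp = Decimal(1)
        pe_comp = Decimal(1)
        for c in counts:
            pm_frac = _exact_pm(c)
            pe_frac = 1 - _exact_pe(c)
            pm_comp *= Decimal(pm_frac.numerator) / Decimal(pm_frac.denominator)
            pe_comp *= Decimal(pe_frac.numerator) / Decimal(pe_frac.denominator)
    else:
        pm_comp = Decimal(10) ** Decimal(repr(log10_pm))
        pe_comp = Decimal(10) ** Decimal(repr(log10_cpe_comp))
    cpd_string = str((Decimal(1) - pm_comp).quantize(Decimal("1e-29")))
    cpe_string = str((Decimal(1) - pe_comp).quantize(Decimal("1e-15")))
    return CombinedSummary(cpd, cpe, log10_pm, log10_cpe_comp,
                           cpd_string, cpe_string)


# ---------------------------------------------------------------------------
# Report export


def summaries_to_frame(summaries: Sequence[LocusForensicSummary],
                       rounded: bool = True) -> pd.DataFrame:
    rows = [asdict(s.rounded() if rounded else s) for s in summaries]
    df = pd.DataFrame(rows)
    return df.rename(columns={"locus_id": "locus"})


def write_report(
    summaries: Sequence[LocusForensicSummary],
    combined: CombinedSummary,
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write the per-locus table as CSV (report rounding) and the combined
    statistics as a JSON footer record."""
    summaries_to_frame(summaries).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "n_loci": len(summaries),
            "cpd": combined.cpd_string,
            "cpe": combined.cpe_string,
            "log10_pm_product": combined.log10_pm_product,
            "log10_cpe_complement": combined.log10_cpe_complement,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
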