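"""Hardy-Weinberg exact testing and two-locus linkage disequilibrium.

The HWE test is the exact conditional test for a biallelic locus: given the
observed allele counts, the probability of seeing h heterozygotes in n
diploids is

    P(h | n, nA) = n! / (n_II! h! n_DD!) * 2^h * nA! nB! / (2n)!

and the two-sided p-value sums P over every parity-consistent heterozygote
count whose probability does not exceed the observed one (ties included).
A Monte Carlo variant draws heterozygote counts from the same conditional
distribution and applies the (b+1)/(B+1) correction, so p > 0 always.

LD between two InDels is measured by r^2 from haplotype frequencies
estimated by EM on unphased two-locus genotype counts; only the double
heterozygote's phase is ambiguous, and EM redistributes it by the current
haplotype-frequency posterior each iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


@dataclass
class HweResult:
    locus_id: str
    p: float
    method: str  # enumeration | monte_carlo | chi2
    n_draws: int | None = None
    seed: int | None = None


@dataclass
class LdResult:
    locus_pair: tuple[str, str]
    r2: float
    d: float
    haplotype_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab)
    em_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def _het_support(n: int, n_a: int) -> np.ndarray:
    """All heterozygote counts consistent with n diploids carrying n_a
    copies of the minor allele (h has the parity of n_a)."""
    n_a = min(n_a, 2 * n - n_a)
    h_max = n_a
    h_min = max(0, n_a - (2 * n - n_a)) if n_a > n else n_a % 2
    # h ranges over n_a, n_a-2, ..., down to max(0/1, 2*n_a - 2n)
    low = max(n_a % 2, 2 * n_a - 2 * n)
    return np.arange(low, h_max + 1, 2)


def _het_log_probs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log-probabilities of the exact conditional heterozygote
    distribution (Levene/Haldane)."""
    n_a = min(n_a, 2 * n - n_a)
    n_b = 2 * n - n_a
    hs = _het_support(n, n_a)
    n_aa = (n_a - hs) // 2
    n_bb = n - hs - n_aa
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(hs + 1)
        - gammaln(n_bb + 1)
        + hs * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    return hs, logp


def hwe_exact_pvalue(counts) -> float:
    """Two-sided exact HWE p-value by full enumeration.

    Probability-ordering definition: p is the total conditional probability
    of all heterozygote counts no more likely than the observed one.
    """
    n = counts.n
    if n < 1:
        raise ValueError("need at least one typed individual")
    n_a = min(counts.insertion_count, 2 * n - counts.insertion_count)
    if n_a == 0:
        return 1.0  # monomorphic: single possible outcome
    hs, logp = _het_log_probs(n, n_a)
    obs = counts.n_ID
    p_obs = logp[hs == obs]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    # relative tolerance absorbs log-gamma roundoff in tie detection
    keep = logp <= p_obs[0] + 1e-9
    probs = np.exp(logp - logp.max())
    return float(min(1.0, probs[keep].sum() / probs.sum()))


def hwe_mc_pvalue(counts, n_draws: int = 10_000, seed: int = 0) -> float:
    """Monte Carlo estimate of the exact p-value.

    Heterozygote counts are drawn from the exact conditional distribution;
    the estimator is (b + 1) / (B + 1) where b counts draws at least as
    extreme (probability <= observed), guaranteeing p > 0.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    n = counts.n
    n_a = min(counts.insertion_count, 2 * n - counts.insertion_count)
    if n_a == 0:
        return 1.0
    hs, logp = _het_log_probs(n, n_a)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(hs), size=n_draws, p=probs)
    p_obs = logp[hs == counts.n_ID][0]
    b = int(np.sum(logp[draws] <= p_obs + 1e-9))
    return (b + 1) / (n_draws + 1)


def hwe_chi2_pvalue(counts) -> float:
    """One-df chi-square HWE test (no continuity correction); provided for
    comparison with the exact test, not used in reports."""
    from scipy.stats import chi2

    n = counts.n
    p = counts.insertion_count / (2 * n)
    q = 1.0 - p
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array(counts.as_tuple(), dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m for m simultaneous tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Two-locus LD


def em_haplotype_freqs(
    joint_counts: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int, bool]:
    """EM estimate of the four haplotype frequencies (AB, Ab, aB, ab) from a
    3x3 table of unphased two-locus genotype counts.

    ``joint_counts[i, j]`` is the number of individuals with dosage i at
    locus 1 (A allele) and dosage j at locus 2 (B allele), i, j in {0,1,2}
    counting from 0 copies.  Indexing convention: row/col 0 = aa/bb.
    Returns (freqs, iterations, converged); convergence is monitored on the
    multinomial log-likelihood, which EM never decreases.
    """
    c = np.asarray(joint_counts, dtype=float)
    if c.shape != (3, 3) or np.any(c < 0):
        raise ValueError("joint_counts must be a non-negative 3x3 table")
    n = c.sum()
    if n < 1:
        raise ValueError("empty table")

    # haplotype copies are fully determined outside the double heterozygote:
    # with at most one heterozygous locus the two haplotypes are unambiguous
    base = np.zeros(4)  # AB, Ab, aB, ab
    idx = {("A", "B"): 0, ("A", "b"): 1, ("a", "B"): 2, ("a", "b"): 3}
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            cnt = c[i, j]
            if cnt == 0:
                continue
            a_alleles = ["A"] * i + ["a"] * (2 - i)
            b_alleles = ["B"] * j + ["b"] * (2 - j)
            if i == 1:  # locus 1 het, locus 2 hom: pairing irrelevant
                base[idx[("A", b_alleles[0])]] += cnt
                base[idx[("a", b_alleles[0])]] += cnt
            elif j == 1:
                base[idx[(a_alleles[0], "B")]] += cnt
                base[idx[(a_alleles[0], "b")]] += cnt
            else:
                base[idx[(a_alleles[0], b_alleles[0])]] += 2 * cnt
    dh = c[1, 1]  # double heterozygotes: AB/ab or Ab/aB

    # initialize at linkage equilibrium from allele frequencies
    p_a = (2 * c[2, :].sum() + c[1, :].sum()) / (2 * n)
    p_b = (2 * c[:, 2].sum() + c[:, 1].sum()) / (2 * n)
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                  (1 - p_a) * (1 - p_b)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    def loglik(f: np.ndarray) -> float:
        ll = 0.0
        for i in range(3):
            for j in range(3):
                if c[i, j] == 0:
                    continue
                if i == 1 and j == 1:
                    pr = 2 * f[0] * f[3] + 2 * f[1] * f[2]
                else:
                    # genotype probability from haplotype freqs
                    def hap_p(a, b):
                        return f[idx[(a, b)]]
                    a_all = ["A"] * i + ["a"] * (2 - i)
                    b_all = ["B"] * j + ["b"] * (2 - j)
                    if i == 1:
                        pr = 2 * hap_p("A", b_all[0]) * hap_p("a", b_all[0])
                    elif j == 1:
                        pr = 2 * hap_p(a_all[0], "B") * hap_p(a_all[0], "b")
                    else:
                        pr = hap_p(a_all[0], b_all[0]) ** 2
                ll += c[i, j] * np.log(max(pr, 1e-300))
        return ll

    prev = loglik(f)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = f[0] * f[3] + f[1] * f[2]
        w = f[0] * f[3] / denom if denom > 0 else 0.5  # P(phase AB/ab)
        hap = base.copy()
        hap[0] += dh * w
        hap[3] += dh * w
        hap[1] += dh * (1 - w)
        hap[2] += dh * (1 - w)
        f = hap / (2 * n)
        cur = loglik(f)
        if abs(cur - prev) < tol:
            converged = True
            prev = cur
            break
        prev = cur
    return f, it, converged


def ld_r2(
    joint_counts: np.ndarray,
    locus_pair: tuple[str, str] = ("locus1", "locus2"),
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LdResult:
    """Squared allelic correlation r^2 between two biallelic loci.

    D = p_AB - p_A p_B from EM haplotype frequencies;
    r^2 = D^2 / (p_A (1-p_A) p_B (1-p_B)).
    """
    f, iters, conv = em_haplotype_freqs(joint_counts, tol=tol, max_iter=max_iter)
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise ValueError("r^2 undefined: a locus is monomorphic in the sample")
    d = f[0] - p_a * p_b
    r2 = d * d / denom
    return LdResult(locus_pair, float(min(r2, 1.0)), float(d), f, iters, conv)


def ld_matrix(matrix, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Pairwise r^2 over all locus pairs of a genotype matrix (symmetric,
    NaN diagonal).  Pairs are tabulated over samples typed at both loci."""
    from .genotype_model import MISSING

    L = matrix.n_loci
    out = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            gi = matrix.dosage[:, i]
            gj = matrix.dosage[:, j]
            ok = (gi != MISSING) & (gj != MISSING)
            table = np.zeros((3, 3))
            np.add.at(table, (gi[ok], gj[ok]), 1)
            res = ld_r2(table, (matrix.loci[i].locus_id, matrix.loci[j].locus_id),
                        tol=tol, max_iter=max_iter)
            out[i, j] = out[j, i] = res.r2
    return out
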