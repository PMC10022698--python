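"""Population-structure inference: neighbor-joining trees, PCA of allele
frequencies, and an admixture model fitted by EM.

The admixture model is the standard unsupervised binomial-likelihood model:
individual i draws each of its two allele copies at locus j from ancestral
component k with probability q_ik, and the copy is an insertion with
probability f_kj, giving

    log L = sum_ij [ g_ij log(sum_k q_ik f_kj)
                     + (2 - g_ij) log(1 - sum_k q_ik f_kj) ].

It is maximized by plain EM over Q (individuals x K) and F (K x loci);
the log-likelihood is non-decreasing by construction and the fitted trace
is kept so callers can assert it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotype_model import GenotypeMatrix, FrequencyTable, MISSING
from .population_distance import DistanceMatrix

_F_EPS = 1e-6  # ancestral frequency clip, keeps the likelihood finite


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    label: str | None = None  # leaf label; None for internal nodes
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored from an arbitrary internal vantage point (the
    final neighbor-joining join, which has three children)."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node.label)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Pairwise leaf-to-leaf path lengths along tree edges."""
        # accumulate distance from root to every leaf and per-leaf ancestor sets
        leaves: list[tuple[str, list[TreeNode], list[float]]] = []

        def walk(node: TreeNode, anc: list[TreeNode], dists: list[float]) -> None:
            if node.is_leaf():
                leaves.append((node.label, anc + [node], dists))
            for child, bl in node.children:
                walk(child, anc + [node], dists + [bl])

        walk(self.root, [], [])
        labels = [l for l, _, _ in leaves]
        k = len(labels)
        dm = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                path_i, di = leaves[i][1], leaves[i][2]
                path_j, dj = leaves[j][1], leaves[j][2]
                # depth of the lowest common ancestor
                lca = 0
                for a, b in zip(path_i, path_j):
                    if a is b:
                        lca += 1
                    else:
                        break
                d = sum(di[lca - 1:]) + sum(dj[lca - 1:])
                dm[i, j] = dm[j, i] = d
        return labels, dm


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "()[]:;, '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: Tree, precision: int = 10) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return _quote_label(node.label)
        inner = ",".join(
            f"{fmt(child)}:{bl:.{precision}g}" for child, bl in node.children
        )
        return f"({inner})"

    return fmt(tree.root) + ";"


def write_newick(tree: Tree, path) -> None:
    """Write the tree as a Newick string with branch lengths."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    For additive input distances the output tree reproduces them exactly.
    Ties on Q are broken by the smallest (row, column) index pair; negative
    branch lengths are retained with a warning.
    """
    n = len(dm.population_ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=pid) for pid in dm.population_ids]
    active = list(range(n))
    negative_seen = False

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (row, col) pair on ties: argmin over flattened row-major
        flat = np.argmin(q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            negative_seen = True
        new = TreeNode(children=[(nodes[active[i]], li), (nodes[active[j]], lj)])
        # distances from the new node to the remaining taxa
        gi, gj = active[i], active[j]
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k_idx in active:
            if k_idx in (gi, gj):
                continue
            d[u, k_idx] = d[k_idx, u] = 0.5 * (d[gi, k_idx] + d[gj, k_idx] - dij)
        nodes.append(new)
        active = [k for k in active if k not in (gi, gj)] + [u]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    if min(la, lb, lc) < 0:
        negative_seen = True
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    if negative_seen:
        warnings.warn("negative branch length(s) in NJ tree (retained)",
                      stacklevel=2)
    return Tree(root)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    population_ids: list[str]
    scores: np.ndarray  # (K, n_components)
    explained_fraction: np.ndarray  # (n_components,)
    loadings: np.ndarray  # (n_loci, n_components)


def pca_frequencies(table: FrequencyTable, n_components: int | None = None) -> PcaResult:
    """Principal components of a populations x loci frequency matrix.

    Columns (loci) are centered across populations but not scaled —
    frequencies already share a scale.  explained_fraction_i is the i-th
    eigenvalue over the total variance, so it sums to 1 at full rank.
    Component signs are fixed by forcing each component's largest-magnitude
    loading positive.
    """
    k, L = table.freq.shape
    if k < 2:
        raise ValueError("PCA needs >= 2 populations")
    max_rank = min(k - 1, L)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must lie in [1, {max_rank}]")
    x = table.freq - table.freq.mean(axis=0, keepdims=True)
    total_var = np.sum(x**2)
    if total_var <= 1e-300:
        raise ValueError("frequency matrix is constant; PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention
    for c in range(len(s)):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = (u * s)[:, :n_components]
    frac = (s**2 / total_var)[:n_components]
    return PcaResult(list(table.population_ids), scores, frac,
                     vt[:n_components].T)


# ---------------------------------------------------------------------------
# Admixture EM


@dataclass
class AdmixtureFit:
    q: np.ndarray  # (n_individuals, K) ancestry fractions, rows sum to 1
    f: np.ndarray  # (K, n_loci) ancestral insertion frequencies
    loglik_trace: np.ndarray
    k: int
    seed: int
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _admixture_loglik(g: np.ndarray, miss: np.ndarray, q: np.ndarray,
                      f: np.ndarray) -> float:
    p = np.clip(q @ f, 1e-12, 1 - 1e-12)
    ll = g * np.log(p) + (2 - g) * np.log(1 - p)
    return float(ll[~miss].sum())


def _admixture_em_once(
    g: np.ndarray, miss: np.ndarray, k: int, rng: np.random.Generator,
    tol: float, max_iter: int,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    n, L = g.shape
    q = rng.dirichlet(np.ones(k), size=n)
    f = np.clip(rng.uniform(0.05, 0.95, size=(k, L)), _F_EPS, 1 - _F_EPS)
    g_eff = np.where(miss, 0, g).astype(float)
    two_eff = np.where(miss, 0, 2).astype(float)  # missing loci contribute 0
    trace = [_admixture_loglik(g, miss, q, f)]
    converged = False
    for _ in range(max_iter):
        p = np.clip(q @ f, 1e-12, 1 - 1e-12)  # (n, L)
        # responsibilities: expected haplotype copies attributed to source k
        #   insertion copies:  a_ik = sum_j g_ij * q_ik f_kj / p_ij
        #   deletion copies:   b_ik = sum_j (2-g_ij) * q_ik (1-f_kj) / (1-p_ij)
        ga = g_eff / p          # (n, L)
        gb = two_eff - g_eff
        gbp = gb / (1 - p)
        a = q[:, :, None] * f[None, :, :] * ga[:, None, :]      # (n, K, L)
        b = q[:, :, None] * (1 - f)[None, :, :] * gbp[:, None, :]
        f = np.clip(a.sum(axis=0) / np.clip((a + b).sum(axis=0), 1e-12, None),
                    _F_EPS, 1 - _F_EPS)
        q_new = (a + b).sum(axis=2)
        q = q_new / q_new.sum(axis=1, keepdims=True)
        trace.append(_admixture_loglik(g, miss, q, f))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return q, f, trace, converged


def admixture_em(
    matrix: GenotypeMatrix,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
) -> AdmixtureFit:
    """Fit the K-component admixture model by EM, keeping the best of
    ``n_restarts`` random starts.

    For k = 1 the model degenerates to per-locus allele frequencies (the
    binomial MLE), which a single EM pass reaches exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.n_samples:
        raise ValueError("k cannot exceed the number of individuals")
    g = matrix.dosage.astype(float)
    miss = matrix.dosage == MISSING
    if miss.all(axis=1).any():
        raise ValueError("an individual has no typed loci")
    best: AdmixtureFit | None = None
    root = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        sub_seed = int(root.integers(2**31))
        rng = np.random.default_rng(sub_seed)
        q, f, trace, conv = _admixture_em_once(g, miss, k, rng, tol, max_iter)
        fit = AdmixtureFit(q, f, np.asarray(trace), k, seed, conv)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def align_components(fit_a: AdmixtureFit, fit_b: AdmixtureFit) -> np.ndarray:
    """Permutation resolving label switching between two fits of equal K.

    Returns ``perm`` such that column ``perm[c]`` of ``fit_b.q`` matches
    column ``c`` of ``fit_a.q``, maximizing the summed correlation between
    matched ancestry columns (optimal assignment, equivalent to exhaustive
    search over all K! permutations).
    """
    if fit_a.k != fit_b.k:
        raise ValueError("fits have different K")
    k = fit_a.k
    if k == 1:
        return np.array([0])
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            a, b = fit_a.q[:, i], fit_b.q[:, j]
            sa, sb = a.std(), b.std()
            if sa < 1e-12 or sb < 1e-12:
                cost[i, j] = -np.mean((a - b) ** 2)  # fall back on closeness
            else:
                cost[i, j] = np.corrcoef(a, b)[0, 1]
    rows, cols = linear_sum_assignment(-cost)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm
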