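"""Between-population structure: Weir-Cockerham F-statistics, Nei's Da
distance, and bootstrapped neighbor-joining trees.

The 1984 Weir-Cockerham variance-components estimators (theta = F_ST,
f = F_IS, F = F_IT) are computed per locus and combined across loci as
ratios of summed components.  Pairwise theta significance uses a
permutation test that shuffles individuals between the two samples.
Nei's Da feeds a Saitou-Nei neighbor-joining tree with per-locus bootstrap
supports, written as Newick.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import MISSING, AlleleFreqTable, GenotypeMatrix, allele_frequencies

__all__ = [
    "FStatsResult",
    "DistanceTree",
    "wc_components",
    "wc_fstats",
    "nei_da",
    "nj_tree",
    "bootstrap_tree",
]


@dataclass
class FStatsResult:
    loci: list[str]
    per_locus: pd.DataFrame        # locus, a, b, c, theta, f, F
    theta: float                   # multi-locus F_ST
    f: float                       # multi-locus F_IS
    F: float                       # multi-locus F_IT
    pops: list[str] = field(default_factory=list)
    pairwise_theta: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None


@dataclass
class DistanceTree:
    labels: list[str]
    distances: np.ndarray
    newick: str
    supports: dict[frozenset, float] | None = None


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def wc_components(dosage_by_pop: list[np.ndarray]) -> np.ndarray:
    """Per-locus Weir-Cockerham (1984) variance components for biallelic loci.

    Parameters
    ----------
    dosage_by_pop
        One ``(n_i, n_loci)`` dosage array per population (MISSING allowed).

    Returns
    -------
    ``(n_loci, 3)`` array of components (a, b, c): among populations, among
    individuals within populations, within individuals.  Components are
    summed over both alleles (for biallelic data this doubles each term and
    leaves every ratio unchanged).  Loci where fewer than two populations
    have two or more typed individuals are ``nan``.
    """
    n_loci = dosage_by_pop[0].shape[1]
    out = np.full((n_loci, 3), np.nan)

    # per-pop per-locus: sample size, allele freq, het freq
    ns, ps, hs = [], [], []
    for d in dosage_by_pop:
        typed = d != MISSING
        n = typed.sum(axis=0).astype(float)
        tot = np.where(typed, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, tot / np.maximum(2 * n, 1), np.nan)
            h = np.where(n > 0,
                         np.where(typed, d == 1, False).sum(axis=0) / np.maximum(n, 1),
                         np.nan)
        ns.append(n)
        ps.append(p)
        hs.append(h)
    ns_arr = np.stack(ns)      # (r, L)
    ps_arr = np.stack(ps)
    hs_arr = np.stack(hs)

    for l in range(n_loci):
        use = ns_arr[:, l] >= 2
        r = int(use.sum())
        if r < 2:
            continue
        n_i = ns_arr[use, l]
        p_i = ps_arr[use, l]
        h_i = hs_arr[use, l]
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        out[l] = (2 * a, 2 * b, 2 * c)   # summed over the two alleles
    return out


def _ratios(comp: np.ndarray) -> tuple[float, float, float]:
    valid = np.isfinite(comp).all(axis=1)
    a, b, c = comp[valid].sum(axis=0)
    tot = a + b + c
    theta = a / tot if tot > 0 else np.nan
    f = 1 - c / (b + c) if (b + c) > 0 else np.nan
    big_f = 1 - c / tot if tot > 0 else np.nan
    return float(theta), float(f), float(big_f)


def wc_fstats(
    gm: GenotypeMatrix,
    groups: list[str] | None = None,
    pairwise: bool = True,
    n_permutations: int = 0,
    seed: int | None = None,
) -> FStatsResult:
    """Weir-Cockerham F-statistics over the given population labels.

    Multi-locus values are ratios of summed variance components.  When
    ``n_permutations > 0``, each pairwise theta receives a one-sided
    permutation p (shuffling individuals between the pair; P(theta_perm >=
    theta_obs)).
    """
    labels = groups if groups is not None else gm.pops
    if len(labels) < 2:
        raise ValueError("need at least 2 populations")
    by_pop = []
    for g in labels:
        sub = gm.by_pop(g)
        if not (sub.dosage != MISSING).any():
            raise ValueError(f"population {g!r} has no typed genotypes")
        by_pop.append(sub.dosage)

    comp = wc_components(by_pop)
    theta, f, big_f = _ratios(comp)
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = comp.sum(axis=1)
        per_locus = pd.DataFrame(
            dict(
                locus=gm.loci,
                a=comp[:, 0], b=comp[:, 1], c=comp[:, 2],
                theta=np.where(tot != 0, comp[:, 0] / tot, np.nan),
                f=np.where((comp[:, 1] + comp[:, 2]) != 0,
                           1 - comp[:, 2] / (comp[:, 1] + comp[:, 2]), np.nan),
                F=np.where(tot != 0, 1 - comp[:, 2] / tot, np.nan),
            )
        )

    pt = pp = None
    if pairwise:
        rng = np.random.default_rng(seed)
        k = len(labels)
        pt = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
        pp = pd.DataFrame(np.full((k, k), np.nan), index=labels, columns=labels)
        for i in range(k):
            for j in range(i + 1, k):
                di, dj = by_pop[i], by_pop[j]
                th, _, _ = _ratios(wc_components([di, dj]))
                pt.iloc[i, j] = pt.iloc[j, i] = th
                if n_permutations:
                    pool = np.vstack([di, dj])
                    ni = di.shape[0]
                    count = 0
                    for _ in range(n_permutations):
                        perm = rng.permutation(pool.shape[0])
                        th_p, _, _ = _ratios(
                            wc_components([pool[perm[:ni]], pool[perm[ni:]]])
                        )
                        if th_p >= th - 1e-12:
                            count += 1
                    pp.iloc[i, j] = pp.iloc[j, i] = (count + 1) / (n_permutations + 1)
    return FStatsResult(list(gm.loci), per_locus, theta, f, big_f,
                        pops=list(labels), pairwise_theta=pt, pairwise_p=pp)


# ---------------------------------------------------------------------------
# Nei's Da
# ---------------------------------------------------------------------------

def nei_da(freq: AlleleFreqTable) -> pd.DataFrame:
    """Nei's Da genetic distance matrix from biallelic frequencies.

    Da = 1 - (1/L) * sum_loci sum_alleles sqrt(x_u * y_u), over the L loci
    defined in both populations.
    """
    k = len(freq.pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = freq.freq[i], freq.freq[j]
            ok = (freq.copies[i] > 0) & (freq.copies[j] > 0)
            if not ok.any():
                raise ValueError(
                    f"no shared defined loci between {freq.pops[i]} and {freq.pops[j]}"
                )
            shared = (np.sqrt(xi[ok] * xj[ok])
                      + np.sqrt((1 - xi[ok]) * (1 - xj[ok])))
            out[i, j] = out[j, i] = 1.0 - shared.mean()
    return pd.DataFrame(out, index=freq.pops, columns=freq.pops)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []   # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c, _ in self.children))


def _nj(dist: np.ndarray, labels: list[str]) -> _Node:
    """Saitou-Nei neighbor joining; ties broken by lowest (i, j) index;
    negative branch lengths clamped to 0 with the deficit moved to the
    sister branch."""
    nodes = [_Node(label=l) for l in labels]
    d = dist.astype(float).copy()
    active = list(range(len(labels)))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)          # argmin returns first minimum: lowest index tie-break
        ii, jj = divmod(flat, m)
        if ii > jj:
            ii, jj = jj, ii
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node
        dnew = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.vstack([d, np.zeros((1, d.shape[1]))])
        d = np.hstack([d, np.zeros((d.shape[0], 1))])
        k = d.shape[0] - 1
        for ai, a in enumerate(active):
            d[k, a] = d[a, k] = dnew[ai]
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [k]
    # join last two
    i, j = active
    dij = d[i, j]
    root = _Node(children=[(nodes[i], dij / 2), (nodes[j], dij / 2)])
    return root


def nj_tree(dist: pd.DataFrame) -> DistanceTree:
    """Neighbor-joining tree from a square symmetric distance matrix."""
    mat = np.asarray(dist, dtype=float)
    labels = list(dist.index)
    if mat.shape[0] != mat.shape[1] or mat.shape[0] < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    root = _nj(mat, labels)
    return DistanceTree(labels, mat, root.newick() + ";")


def _bipartitions(node: _Node, all_leaves: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions (as the smaller/canonical side) of a tree."""
    parts = set()

    def walk(n):
        lv = n.leaves()
        if 1 < len(lv) < len(all_leaves) - 1:
            other = all_leaves - lv
            parts.add(min(lv, other, key=lambda s: (len(s), tuple(sorted(s)))))
        for c, _ in n.children:
            walk(c)

    walk(node)
    return parts


def bootstrap_tree(
    gm: GenotypeMatrix,
    groups: list[str] | None = None,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> DistanceTree:
    """NJ tree on Nei's Da with per-edge bootstrap supports.

    Loci are resampled with replacement ``n_bootstrap`` times; support for
    each internal bipartition of the point tree is the percentage of
    replicates whose NJ tree contains it.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    labels = groups if groups is not None else gm.pops
    freq = allele_frequencies(gm)
    order = [freq.pops.index(g) for g in labels]
    sub = AlleleFreqTable([freq.pops[i] for i in order], list(freq.loci),
                          freq.freq[order], freq.copies[order])
    point = nj_tree(nei_da(sub))
    all_leaves = frozenset(labels)
    point_root = _nj(point.distances, labels)
    parts = _bipartitions(point_root, all_leaves)
    counts = {p: 0 for p in parts}
    rng = np.random.default_rng(seed)
    n_loci = len(freq.loci)
    for _ in range(n_bootstrap):
        pick = rng.integers(0, n_loci, size=n_loci)
        bt = AlleleFreqTable(sub.pops, [f"L{i}" for i in range(n_loci)],
                             sub.freq[:, pick], sub.copies[:, pick])
        broot = _nj(np.asarray(nei_da(bt), float), labels)
        bparts = _bipartitions(broot, all_leaves)
        for p in parts:
            if p in bparts:
                counts[p] += 1
    supports = {p: 100.0 * c / n_bootstrap for p, c in counts.items()}
    point.supports = supports
    return point
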