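"""Baseline-anchored ancestry inference and introgression quantification.

Supervised ancestry: each individual's admixture vector Q (one proportion
per source population, on the simplex) is the maximum-likelihood mixture
weight vector under fixed baseline allele frequencies, fitted by EM.  For
a biallelic locus l with reference-allele dosage g and baseline frequencies
p_kl, the log-likelihood is

    l(Q) = sum_l [ g * ln(sum_k Q_k p_kl) + (2 - g) * ln(sum_k Q_k (1 - p_kl)) ]

Unsupervised mode jointly estimates (Q, P) by block EM with random
restarts, the maximum-likelihood analogue of model-based clustering of
multilocus genotypes.

Downstream: threshold classification into genetic groups, purity flags,
immigrant detection against four baselines, introgression rates, the
ancestry-distance cline correlation, and the spawner-status contingency
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import MISSING, AlleleFreqTable, GenotypeMatrix

__all__ = [
    "Baseline",
    "AncestryResult",
    "GroupCall",
    "make_baseline",
    "select_baseline_by_diagnostic",
    "estimate_q_supervised",
    "fit_admixture_unsupervised",
    "classify_lake_group",
    "flag_pure",
    "detect_immigrants",
    "introgression_rate",
    "cline_correlation",
    "spawning_contingency",
]


@dataclass
class Baseline:
    """A reference source population: clamped allele frequencies + provenance.

    Frequencies are clamped to [eps, 1 - eps] with eps = 1/(2n + 2) before
    likelihood use, which keeps alleles unseen in a finite baseline sample
    from contributing -inf log-likelihood (equivalent to a weak uniform
    prior on the baseline frequency).
    """

    source_id: str
    loci: list[str]
    freq: np.ndarray
    n_individuals: int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        eps = 1.0 / (2 * self.n_individuals + 2)
        self.freq = np.clip(self.freq, eps, 1 - eps)


@dataclass
class AncestryResult:
    individuals: list[str]
    sources: list[str]
    Q: np.ndarray                # (n_ind, K) on the simplex
    log_likelihood: np.ndarray   # (n_ind,)
    n_loci_used: np.ndarray      # (n_ind,)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"Q_{s}" for s in self.sources])
        df.insert(0, "id", self.individuals)
        df["log_likelihood"] = self.log_likelihood
        df["n_loci_used"] = self.n_loci_used
        return df


@dataclass
class GroupCall:
    individual: str
    group: str
    pure_strict: bool      # max Q >= 0.99
    pure_relaxed: bool     # max Q > 0.75


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def make_baseline(gm: GenotypeMatrix, source_id: str,
                  provenance: str = "") -> Baseline:
    """Baseline from all individuals of a genotype matrix (single sample)."""
    typed = gm.dosage != MISSING
    n_copies = 2 * typed.sum(axis=0)
    tot = np.where(typed, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_copies > 0, tot / np.maximum(n_copies, 1), 0.5)
    return Baseline(source_id, list(gm.loci), freq, gm.n_ind, provenance)


def baseline_from_freq_table(tab: AlleleFreqTable, pop: str,
                             n_individuals: int | None = None,
                             provenance: str = "") -> Baseline:
    i = tab.pops.index(pop)
    n = n_individuals if n_individuals is not None else int(
        np.median(tab.copies[i][tab.copies[i] > 0]) // 2 or 1
    )
    freq = np.where(tab.copies[i] > 0, tab.freq[i], 0.5)
    return Baseline(pop, list(tab.loci), freq, n, provenance)


def select_baseline_by_diagnostic(
    gm: GenotypeMatrix, locus: str, allele: str = "ref",
) -> GenotypeMatrix:
    """Subset to individuals homozygous for the given allele at a diagnostic
    locus (dosage 2 for ``allele='ref'``, 0 for ``'alt'``).

    This mirrors baseline construction anchored on a fully diagnostic marker:
    in the founder generations only unadmixed fish are homozygous for their
    population's private allele.
    """
    if locus not in gm.loci:
        raise KeyError(f"locus {locus!r} not present")
    if allele not in ("ref", "alt"):
        raise ValueError("allele must be 'ref' or 'alt'")
    l = gm.loci.index(locus)
    want = 2 if allele == "ref" else 0
    rows = np.flatnonzero(gm.dosage[:, l] == want)
    if rows.size == 0:
        raise ValueError(f"no individuals homozygous for {allele} at {locus}")
    return gm.subset(rows)


# ---------------------------------------------------------------------------
# Supervised EM
# ---------------------------------------------------------------------------

def _stack_baseline_freqs(baselines: list[Baseline],
                          loci: list[str]) -> np.ndarray:
    P = np.empty((len(baselines), len(loci)))
    for k, b in enumerate(baselines):
        if b.loci != loci:
            try:
                order = [b.loci.index(l) for l in loci]
            except ValueError as e:
                raise ValueError(f"baseline {b.source_id} missing locus: {e}")
            P[k] = b.freq[order]
        else:
            P[k] = b.freq
    return P


def estimate_q_supervised(
    gm: GenotypeMatrix,
    baselines: list[Baseline],
    tol: float = 1e-8,
    max_iter: int = 2000,
    min_loci: int = 10,
) -> AncestryResult:
    """Maximum-likelihood ancestry proportions against fixed baselines.

    EM from a uniform start: each gene copy is fractionally attributed to
    source k by its posterior Q_k p_k / sum_j Q_j p_j (reference copies) or
    Q_k (1-p_k) / sum_j Q_j (1-p_j) (alternate copies); the Q update is the
    average attribution over the individual's 2 x L_typed gene copies.
    Iterates until the total log-likelihood improves by less than ``tol``
    or ``max_iter`` is reached.  Missing loci are skipped per individual.
    """
    K = len(baselines)
    if K < 2:
        raise ValueError("need at least two baselines")
    P = _stack_baseline_freqs(baselines, list(gm.loci))      # (K, L)
    G = gm.dosage.astype(float)                              # (n, L)
    typed = gm.dosage != MISSING
    n_used = typed.sum(axis=1)
    if (n_used == 0).any():
        bad = [gm.individuals[i] for i in np.flatnonzero(n_used == 0)]
        raise ValueError(f"individuals with no typed loci: {bad}")
    if (n_used < min_loci).any():
        raise ValueError(f"individuals typed at fewer than {min_loci} loci")

    n = gm.n_ind
    Gm = np.where(typed, G, 0.0)
    Am = np.where(typed, 2.0 - G, 0.0)       # alternate-copy counts
    Q = np.full((n, K), 1.0 / K)
    copies = (Gm + Am).sum(axis=1)           # 2 * n_used

    def loglik(Q):
        mix_ref = Q @ P                      # (n, L)
        mix_alt = Q @ (1 - P)
        with np.errstate(divide="ignore"):
            ll = (Gm * np.log(mix_ref) + Am * np.log(mix_alt))
        return np.where(typed, ll, 0.0).sum(axis=1)

    ll_old = loglik(Q)
    for _ in range(max_iter):
        mix_ref = Q @ P
        mix_alt = Q @ (1 - P)
        # expected copies attributed to each source
        # ref copies: G * Q_k p_k / mix_ref ; alt copies: (2-G) * Q_k (1-p_k)/mix_alt
        w_ref = Gm / np.where(mix_ref > 0, mix_ref, 1.0)
        w_alt = Am / np.where(mix_alt > 0, mix_alt, 1.0)
        newQ = Q * (w_ref @ P.T + w_alt @ (1 - P).T)
        newQ /= copies[:, None]
        newQ = np.clip(newQ, 0.0, 1.0)
        newQ /= newQ.sum(axis=1, keepdims=True)
        ll_new = loglik(newQ)
        Q = newQ
        if np.max(ll_new - ll_old) < tol:
            ll_old = ll_new
            break
        ll_old = ll_new
    return AncestryResult(list(gm.individuals), [b.source_id for b in baselines],
                          Q, ll_old, n_used)


# ---------------------------------------------------------------------------
# Unsupervised admixture (joint ML over Q and P)
# ---------------------------------------------------------------------------

def fit_admixture_unsupervised(
    gm: GenotypeMatrix,
    K: int,
    n_restarts: int = 5,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    baselines: list[Baseline] | None = None,
    ll_trace: list | None = None,
) -> tuple[AncestryResult, np.ndarray]:
    """Joint maximum-likelihood admixture by block EM with random restarts.

    Alternates the supervised Q update with the P update
    ``p_kl = (expected reference copies from k) / (expected copies from k)``.
    The best restart by total log-likelihood wins.  If ``baselines`` are
    given, clusters are relabeled to the baseline whose frequency vector
    they correlate with best (greedy assignment).

    Returns the per-individual ancestry result and the estimated ``(K, L)``
    frequency matrix.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_ind:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    G = gm.dosage.astype(float)
    typed = gm.dosage != MISSING
    Gm = np.where(typed, G, 0.0)
    Am = np.where(typed, 2.0 - G, 0.0)
    n, L = G.shape
    copies = (Gm + Am).sum(axis=1)

    def total_ll(Q, P):
        mr, ma = Q @ P, Q @ (1 - P)
        with np.errstate(divide="ignore"):
            ll = Gm * np.log(np.where(mr > 0, mr, 1)) \
                + Am * np.log(np.where(ma > 0, ma, 1))
        return float(np.where(typed, ll, 0).sum())

    if K == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = Gm.sum(axis=0) / np.maximum((Gm + Am).sum(axis=0), 1)
        P = p[None, :]
        Q = np.ones((n, 1))
        res = AncestryResult(list(gm.individuals), ["C1"], Q,
                             np.zeros(n), typed.sum(axis=1))
        return res, P

    best = None
    for _ in range(max(1, n_restarts)):
        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(rng.uniform(0.1, 0.9, size=(K, L)), 1e-4, 1 - 1e-4)
        ll_prev = -np.inf
        for _ in range(max_iter):
            mr, ma = Q @ P, Q @ (1 - P)
            w_ref = Gm / np.where(mr > 0, mr, 1.0)
            w_alt = Am / np.where(ma > 0, ma, 1.0)
            # E counts: ref copies from source k at locus l for ind i
            #   G * Q_ik p_kl / mr_il  -> sum over i for P update
            ref_k = (Q[:, :, None] * P[None, :, :]) * w_ref[:, None, :]
            alt_k = (Q[:, :, None] * (1 - P)[None, :, :]) * w_alt[:, None, :]
            newQ = (ref_k.sum(axis=2) + alt_k.sum(axis=2)) / copies[:, None]
            newQ = np.clip(newQ, 1e-12, 1)
            newQ /= newQ.sum(axis=1, keepdims=True)
            sum_ref = ref_k.sum(axis=0)
            sum_alt = alt_k.sum(axis=0)
            newP = sum_ref / np.maximum(sum_ref + sum_alt, 1e-300)
            newP = np.clip(newP, 1e-4, 1 - 1e-4)
            Q, P = newQ, newP
            ll = total_ll(Q, P)
            if ll_trace is not None:
                ll_trace.append(ll)
            if ll - ll_prev < tol and np.isfinite(ll_prev):
                break
            ll_prev = ll
        ll = total_ll(Q, P)
        if best is None or ll > best[0]:
            best = (ll, Q, P)
    _, Q, P = best

    sources = [f"C{k + 1}" for k in range(K)]
    if baselines is not None:
        PB = _stack_baseline_freqs(baselines, list(gm.loci))
        order, taken = [], set()
        names = [b.source_id for b in baselines]
        for k in range(K):
            cors = [
                (abs(np.corrcoef(P[k], PB[j])[0, 1]), j)
                for j in range(len(baselines)) if j not in taken
            ]
            if cors:
                _, j = max(cors)
                taken.add(j)
                order.append(names[j])
            else:
                order.append(f"C{k + 1}")
        sources = order

    mr, ma = Q @ P, Q @ (1 - P)
    with np.errstate(divide="ignore"):
        ll_i = (Gm * np.log(np.where(mr > 0, mr, 1))
                + Am * np.log(np.where(ma > 0, ma, 1)))
    res = AncestryResult(list(gm.individuals), sources, Q,
                         np.where(typed, ll_i, 0).sum(axis=1),
                         typed.sum(axis=1))
    return res, P


# ---------------------------------------------------------------------------
# Threshold classification
# ---------------------------------------------------------------------------

def classify_lake_group(q_a: float) -> str:
    """Genetic-group call from the ancestry proportion of source A.

    >= 0.75 -> "A"; <= 0.25 -> "B"; else admixed "AB" (boundaries belong to
    the pure classes).
    """
    if not 0 <= q_a <= 1:
        raise ValueError("Q must lie in [0, 1]")
    if q_a >= 0.75:
        return "A"
    if q_a <= 0.25:
        return "B"
    return "AB"


def flag_pure(Q: np.ndarray, cutoff: float = 0.99) -> bool:
    """Purity flag: max_k Q_k >= 0.99 (strict) or > 0.75 (relaxed)."""
    m = float(np.max(Q))
    if cutoff == 0.99:
        return m >= 0.99
    if cutoff == 0.75:
        return m > 0.75
    return m >= cutoff


def detect_immigrants(
    result: AncestryResult,
    local_source: str,
    creek_i_source: str | None = None,
    immigrant_cutoff: float = 0.25,
    downstream_cutoff: float = 0.75,
) -> list[GroupCall]:
    """Immigrant calls for a creek sample assigned against four baselines.

    An individual is an immigrant from above the waterfall when its
    assignment to the local creek baseline is below ``immigrant_cutoff``
    (Q_local < 0.25).  In the lower creek, a fish assigned to the upper
    creek at ``Q >= downstream_cutoff`` is a downstream immigrant.
    """
    if local_source not in result.sources:
        raise KeyError(f"local baseline {local_source!r} not among sources")
    li = result.sources.index(local_source)
    ci = (result.sources.index(creek_i_source)
          if creek_i_source is not None and creek_i_source in result.sources
          else None)
    calls = []
    for i, ind in enumerate(result.individuals):
        q = result.Q[i]
        if ci is not None and ci != li and q[ci] >= downstream_cutoff:
            group = "downstream-immigrant"
        elif q[li] < immigrant_cutoff:
            group = "immigrant"
        else:
            group = "local"
        calls.append(GroupCall(ind, group, flag_pure(q, 0.99), flag_pure(q, 0.75)))
    return calls


def introgression_rate(
    result: AncestryResult,
    calls: list[GroupCall],
    alien_sources: tuple[str, str] = ("A", "B"),
) -> dict[str, float]:
    """Introgression: mean alien ancestry (Q_A + Q_B) among non-immigrants.

    Also returns the total alien contribution with immigrants included.
    """
    idx = [result.sources.index(s) for s in alien_sources]
    alien = result.Q[:, idx].sum(axis=1)
    keep = np.array([c.group == "local" for c in calls])
    if not keep.any():
        raise ValueError("no non-immigrant individuals remain")
    return {
        "introgression": float(alien[keep].mean()),
        "total_alien_contribution": float(alien.mean()),
        "n_non_immigrant": int(keep.sum()),
        "n_total": int(len(calls)),
    }


# ---------------------------------------------------------------------------
# Cline and contingency
# ---------------------------------------------------------------------------

def cline_correlation(mean_q: np.ndarray, distances: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of per-lake mean ancestry with
    distance from the release site."""
    mean_q = np.asarray(mean_q, float)
    distances = np.asarray(distances, float)
    if mean_q.size < 3:
        raise ValueError("need at least 3 lakes")
    if np.std(mean_q) == 0 or np.std(distances) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(mean_q, distances)
    return float(r), float(p)


def spawning_contingency(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square contingency test (no continuity correction).

    ``table`` is an r x c count matrix, e.g. genetic group x spawner status.
    Returns (chi2, df, p).
    """
    table = np.asarray(table, float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
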