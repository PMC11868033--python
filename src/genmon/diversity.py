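"""Within-population diversity and Hardy-Weinberg statistics.

Implements the per-locus diversity measures used in long-term genetic
monitoring of biallelic SNP panels: expected/unbiased/observed
heterozygosity, rarefied allelic richness (hypergeometric rarefaction to a
standard number of gene copies), the Weir-Cockerham within-population
inbreeding coefficient f (F_IS) with a permutation test, the conditional
exact Hardy-Weinberg test, and locus-paired before/after change tests
(Wilcoxon matched pairs + paired t) that feed the within-population
diversity indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .geno_io import MISSING, GenotypeMatrix

__all__ = [
    "DiversityTable",
    "PairedChangeResult",
    "heterozygosity",
    "allelic_richness",
    "fis",
    "hwe_exact",
    "paired_change_test",
]


@dataclass
class DiversityTable:
    """Per population x locus diversity measures plus multi-locus means."""

    per_locus: pd.DataFrame  # columns: pop, locus, n_typed, He, uHe, Ho, An, Ar
    means: pd.DataFrame      # columns: pop, He, uHe, Ho, An, Ar


@dataclass
class PairedChangeResult:
    measure: str
    before: np.ndarray
    after: np.ndarray
    wilcoxon_p: float
    t_p: float
    direction: str           # "increase" | "decrease" | "none"
    significant: bool
    alpha: float = 0.05


# ---------------------------------------------------------------------------

def _group_rows(gm: GenotypeMatrix, group: str | None) -> dict[str, np.ndarray]:
    pops = gm.pops if group is None else [group]
    out = {}
    for p in pops:
        rows = np.array([i for i, q in enumerate(gm.pop_label) if q == p])
        if rows.size == 0:
            raise KeyError(f"unknown group {group!r}")
        out[p] = rows
    return out


def heterozygosity(gm: GenotypeMatrix, group: str | None = None,
                   rarefaction_g: int | None = None) -> DiversityTable:
    """Expected, unbiased and observed heterozygosity per group x locus.

    He = 1 - p^2 - q^2; uHe = 2n/(2n-1) * He with n the number of typed
    individuals; Ho = fraction of heterozygotes among typed individuals.
    An is the observed allele count (1 or 2); Ar the rarefied richness at
    ``rarefaction_g`` gene copies (default: smallest typed copy count over
    the compared groups per locus).
    """
    groups = _group_rows(gm, group)
    ar = allelic_richness(gm, group, g=rarefaction_g)
    rows = []
    for p, idx in groups.items():
        d = gm.dosage[idx]
        typed = d != MISSING
        n = typed.sum(axis=0)
        total = np.where(typed, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pfreq = np.where(n > 0, total / np.maximum(2 * n, 1), np.nan)
        he = 2 * pfreq * (1 - pfreq)
        with np.errstate(invalid="ignore", divide="ignore"):
            uhe = np.where(n > 1, 2 * n / np.maximum(2 * n - 1, 1) * he, np.nan)
        het = np.where(typed, d == 1, False).sum(axis=0)
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        an = np.where(n > 0, 1 + ((pfreq > 0) & (pfreq < 1)), np.nan)
        for l, locus in enumerate(gm.loci):
            rows.append(
                dict(pop=p, locus=locus, n_typed=int(n[l]), He=he[l],
                     uHe=uhe[l], Ho=ho[l], An=an[l],
                     Ar=ar.loc[(ar["pop"] == p) & (ar["locus"] == locus), "Ar"].iloc[0])
            )
    per_locus = pd.DataFrame(rows)
    means = (per_locus.groupby("pop", sort=False)[["He", "uHe", "Ho", "An", "Ar"]]
             .mean().reset_index())
    return DiversityTable(per_locus=per_locus, means=means)


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """A_R = sum_alleles [1 - C(2N - N_i, g) / C(2N, g)] by log-binomials."""
    counts = counts[counts > 0]
    total = counts.sum()
    if g > total:
        return np.nan

    def logc(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = 0.0
    for ni in counts:
        if total - ni < g:
            out += 1.0
        else:
            out += 1.0 - np.exp(logc(total - ni, g) - logc(total, g))
    return float(out)


def allelic_richness(gm: GenotypeMatrix, group: str | None = None,
                     g: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness per group x locus.

    ``g`` is the rarefaction size in gene copies; default is, per locus, the
    smallest typed copy count among the compared groups (the fstat
    convention).  Cells where ``g`` exceeds the available copies are ``nan``.
    """
    groups = _group_rows(gm, group)
    copy_counts = {}
    for p, idx in groups.items():
        d = gm.dosage[idx]
        typed = d != MISSING
        n_copies = 2 * typed.sum(axis=0)
        ref = np.where(typed, d, 0).sum(axis=0)
        copy_counts[p] = np.stack([ref, n_copies - ref])  # (2, n_loci)
    if g is None:
        min_copies = np.min(
            [c.sum(axis=0) for c in copy_counts.values()], axis=0
        )
        g_per_locus = min_copies
    else:
        g_per_locus = np.full(gm.n_loci, g, dtype=int)
    rows = []
    for p, cc in copy_counts.items():
        for l, locus in enumerate(gm.loci):
            gl = int(g_per_locus[l])
            val = _rarefied_richness(cc[:, l], gl) if gl >= 1 else np.nan
            rows.append(dict(pop=p, locus=locus, g=gl, Ar=val))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F_IS (Weir-Cockerham small f) within a single sample
# ---------------------------------------------------------------------------

def _het_pairing_pmf(n_ref: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the heterozygote count when 2n gene copies
    (n_ref + n_alt) are paired into n diploids uniformly at random.

    This is the same conditional-on-allele-counts distribution that underlies
    the exact Hardy-Weinberg test; returns (support, probabilities).
    """
    n = (n_ref + n_alt) // 2
    rare = min(n_ref, n_alt)
    hs = np.arange(rare % 2, rare + 1, 2)
    lp = np.array(
        [h * np.log(2) + gammaln(n + 1)
         - gammaln((n_ref - h) // 2 + 1) - gammaln(h + 1)
         - gammaln((n_alt - h) // 2 + 1)
         for h in hs],
        dtype=float,
    )
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    return hs, probs


def fis(gm: GenotypeMatrix, group: str | None = None,
        n_permutations: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Within-sample fixation index f (F_IS) per group.

    Per locus f = (He - Ho)/He with He = 2*p*(1-p) from the sample allele
    frequency; the multi-locus value combines loci by summing the He - Ho
    numerators and He denominators (ratio of sums, not mean of ratios).
    Negative f indicates heterozygote excess.

    Significance is a two-sided permutation test that re-pairs the observed
    gene copies into diploids at random within the sample.  Because the
    allele counts (hence He) are invariant under re-pairing, the permutation
    draws each locus's heterozygote count directly from the exact uniform
    pairing distribution, which is equivalent to shuffling gene copies.
    """
    rng = np.random.default_rng(seed)
    groups = _group_rows(gm, group)
    rows = []
    for pop, idx in groups.items():
        d = gm.dosage[idx]
        typed = d != MISSING
        n = typed.sum(axis=0).astype(float)
        ref = np.where(typed, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, ref / np.maximum(2 * n, 1), np.nan)
        he = 2 * p * (1 - p)
        het = np.where(typed, d == 1, False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        valid = np.isfinite(he) & (he > 0) & (n >= 2)
        if not valid.any():
            rows.append(dict(pop=pop, f=np.nan, p_value=np.nan,
                             per_locus_f=np.full(gm.n_loci, np.nan)))
            continue
        den = he[valid].sum()
        f_obs = (he[valid] - ho[valid]).sum() / den
        per_locus = np.where(valid, (he - ho) / np.where(he > 0, he, np.nan), np.nan)

        if n_permutations:
            loci_idx = np.flatnonzero(valid)
            ho_perm = np.zeros((n_permutations, loci_idx.size))
            for j, l in enumerate(loci_idx):
                n_ref = int(ref[l])
                n_alt = int(2 * n[l] - n_ref)
                hs, probs = _het_pairing_pmf(n_ref, n_alt)
                draws = rng.choice(hs, size=n_permutations, p=probs)
                ho_perm[:, j] = draws / n[l]
            f_perm = (he[valid][None, :] - ho_perm).sum(axis=1) / den
            count = int((np.abs(f_perm) >= abs(f_obs) - 1e-12).sum())
            p_value = (count + 1) / (n_permutations + 1)
        else:
            p_value = np.nan
        rows.append(dict(pop=pop, f=float(f_obs), p_value=float(p_value),
                         per_locus_f=per_locus))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact HWE test (biallelic, conditional on allele counts)
# ---------------------------------------------------------------------------

def hwe_exact_single(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p for one biallelic locus.

    Conditions on the observed allele counts and enumerates all heterozygote
    counts of matching parity; p is the summed probability of outcomes no
    more probable than the observed one (the standard "conditional" exact
    test of Haldane / Levene; cf. Wigginton et al. 2005).
    """
    n = n_het + n_hom_ref + n_hom_alt
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    if n == 0 or n_ref == 0 or n_alt == 0:
        return 1.0
    hs, probs = _het_pairing_pmf(n_ref, n_alt)
    obs = probs[hs == n_het][0]
    return float(min(1.0, probs[probs <= obs + 1e-12].sum()))


def hwe_exact(gm: GenotypeMatrix, group: str | None = None) -> pd.DataFrame:
    """Per-locus exact HWE p-values plus a Fisher-combined overall p per group."""
    groups = _group_rows(gm, group)
    rows = []
    for pop, idx in groups.items():
        d = gm.dosage[idx]
        pvals = np.ones(gm.n_loci)
        for l in range(gm.n_loci):
            col = d[:, l]
            t = col != MISSING
            n_het = int((col[t] == 1).sum())
            n_rr = int((col[t] == 2).sum())
            n_aa = int((col[t] == 0).sum())
            pvals[l] = hwe_exact_single(n_het, n_rr, n_aa)
        # Fisher's combination across polymorphic loci
        poly = pvals < 1.0
        if poly.any():
            stat = -2 * np.log(np.clip(pvals[poly], 1e-300, 1)).sum()
            overall = float(stats.chi2.sf(stat, 2 * poly.sum()))
        else:
            overall = 1.0
        for l, locus in enumerate(gm.loci):
            rows.append(dict(pop=pop, locus=locus, p=pvals[l], overall_p=overall))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Locus-paired temporal change tests
# ---------------------------------------------------------------------------

def paired_change_test(before: np.ndarray, after: np.ndarray,
                       measure: str = "He", alpha: float = 0.05) -> PairedChangeResult:
    """Locus-by-locus before/after change test for a diversity measure.

    Wilcoxon matched-pairs signed-rank (zero differences dropped; exact for
    n <= 25, else normal approximation with continuity correction) is the
    primary significance call; the paired t p-value is reported alongside.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after length mismatch")
    keep = np.isfinite(before) & np.isfinite(after)
    b, a = before[keep], after[keep]
    if b.size < 5:
        raise ValueError("need at least 5 paired loci")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return PairedChangeResult(measure, before, after, 1.0, 1.0, "none", False, alpha)
    method = "exact" if nz.size <= 25 else "approx"
    w = stats.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                       method=method)
    t = stats.ttest_rel(a, b)
    significant = bool(w.pvalue < alpha)
    if significant:
        direction = "increase" if diff.mean() > 0 else "decrease"
    else:
        direction = "none"
    return PairedChangeResult(measure, before, after, float(w.pvalue),
                              float(t.pvalue), direction, significant, alpha)
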