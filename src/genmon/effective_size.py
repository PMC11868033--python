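"""Effective population size estimation.

Two estimators, matching the standard monitoring toolkit for SNP panels:

* **LD method** — Burrows composite disequilibrium between all locus pairs
  from unphased genotypes, squared correlation r^2 = Delta^2 /
  (p(1-p)q(1-q)), bias-adjusted by the random-mating sample-size
  expectation and inverted to Ne with the Waples (2006) / Waples & Do
  corrections (separate constants for S >= 30 and S < 30).  A parametric
  chi-square confidence interval treats the locus-pair comparisons as
  independent.

* **Temporal method** — the standardized allele-frequency variance Fs of
  Jorde & Ryman pooled over loci and alleles, corrected for finite samples
  under sampling plan II (individuals removed before reproduction), with
  Ne = t / (2 Fs').  Confidence interval by delete-one-locus jackknife.

Point estimates of infinity are legitimate outputs (no detectable drift
signal) and are propagated as ``math.inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geno_io import MISSING, GenotypeMatrix

__all__ = [
    "NeEstimate",
    "HarmonicSummary",
    "ne_ld",
    "ne_temporal",
    "harmonic_mean_ne",
]

INF = math.inf


@dataclass
class NeEstimate:
    method: str                  # "LD" | "temporal"
    point: float                 # > 0 or inf
    ci: tuple[float, float]
    inputs: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)


@dataclass
class HarmonicSummary:
    values: list[float]
    harmonic_mean: float
    n_finite: int
    n_infinite: int


# ---------------------------------------------------------------------------
# LD method
# ---------------------------------------------------------------------------

def _expected_r2_sample(S: float) -> float:
    """Expected r^2 from sampling alone under random mating (Waples 2006)."""
    if S >= 30:
        return 1.0 / S + 3.19 / S ** 2
    return 0.0018 + 0.907 / S + 4.44 / S ** 2


def _invert_r2_to_ne(r2_prime: float, S: float) -> float:
    """Solve the drift-LD relation for Ne given adjusted r^2'."""
    if r2_prime <= 0:
        return INF
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2_prime
        if disc < 0:
            return INF
        ne = (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_prime)
    else:
        disc = 0.308 ** 2 - 2.08 * r2_prime
        if disc < 0:
            return INF
        ne = (0.308 + math.sqrt(disc)) / (2.0 * r2_prime)
    return ne if ne > 0 else INF


def ne_ld(
    gm: GenotypeMatrix,
    group: str | None = None,
    maf_screen: float = 0.02,
    alpha: float = 0.05,
) -> NeEstimate:
    """LD effective size from one population sample.

    For every pair of polymorphic loci passing the minor-allele-frequency
    screen, the Burrows composite disequilibrium is estimated from dosages
    as half the sample covariance (with the n/(n-1) correction), squared and
    standardized to r^2.  Pairs are combined weighting by the number of
    individuals typed at both loci; the bias-adjusted mean r^2' = mean r^2 -
    E[r^2 | S] is inverted to Ne using the random-mating model.
    """
    sub = gm if group is None else gm.by_pop(group)
    D = sub.dosage
    typed = D != MISSING
    S_all = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(S_all > 0,
                     np.where(typed, D, 0).sum(axis=0) / np.maximum(2 * S_all, 1),
                     np.nan)
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero((S_all >= 10) & (maf >= maf_screen) & (maf > 0))
    if keep.size < 2:
        raise ValueError("fewer than 2 usable polymorphic loci after screening")

    if typed.all():
        # fast path: complete data
        X = D[:, keep].astype(float)
        S = X.shape[0]
        C = np.cov(X, rowvar=False)            # (L', L')
        delta = C / 2.0
        pk = X.mean(axis=0) / 2.0
        denom = np.outer(pk * (1 - pk), pk * (1 - pk))
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = delta ** 2 / denom
        iu = np.triu_indices(keep.size, k=1)
        r2_pairs = r2[iu]
        weights = np.full(r2_pairs.size, float(S))
    else:
        r2_list, w_list = [], []
        for a in range(keep.size):
            for b in range(a + 1, keep.size):
                la, lb = keep[a], keep[b]
                ok = typed[:, la] & typed[:, lb]
                Sij = int(ok.sum())
                if Sij < 10:
                    continue
                x = D[ok, la].astype(float)
                y = D[ok, lb].astype(float)
                pa, pb = x.mean() / 2, y.mean() / 2
                if min(pa, 1 - pa) <= 0 or min(pb, 1 - pb) <= 0:
                    continue
                delta = np.cov(x, y)[0, 1] / 2.0
                r2_list.append(delta ** 2 / (pa * (1 - pa) * pb * (1 - pb)))
                w_list.append(Sij)
        if not r2_list:
            raise ValueError("no usable locus pairs")
        r2_pairs = np.asarray(r2_list)
        weights = np.asarray(w_list, float)

    mean_r2 = float(np.average(r2_pairs, weights=weights))
    # harmonic mean pairwise sample size
    S_eff = float(len(weights) / np.sum(1.0 / weights))
    exp_r2 = _expected_r2_sample(S_eff)
    r2_prime = mean_r2 - exp_r2
    point = _invert_r2_to_ne(r2_prime, S_eff)

    # parametric chi-square CI on mean r^2 with J independent comparisons
    J = len(r2_pairs)
    lo_r2 = J * mean_r2 / stats.chi2.ppf(1 - alpha / 2, J)
    hi_r2 = J * mean_r2 / stats.chi2.ppf(alpha / 2, J)
    ci_hi = _invert_r2_to_ne(lo_r2 - exp_r2, S_eff)
    ci_lo = _invert_r2_to_ne(hi_r2 - exp_r2, S_eff)
    if ci_lo > point:
        ci_lo = point
    if ci_hi < point:
        ci_hi = point
    return NeEstimate(
        method="LD",
        point=point,
        ci=(ci_lo, ci_hi),
        inputs=dict(n_ind=int(sub.n_ind), n_loci=int(keep.size),
                    n_pairs=J, maf_screen=maf_screen, S=S_eff),
        stats=dict(mean_r2=mean_r2, expected_r2=exp_r2, r2_prime=r2_prime),
    )


# ---------------------------------------------------------------------------
# Temporal method (Jorde & Ryman Fs, sampling plan II)
# ---------------------------------------------------------------------------

def _freqs_and_n(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    typed = gm.dosage != MISSING
    n = typed.sum(axis=0).astype(float)
    tot = np.where(typed, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, tot / np.maximum(2 * n, 1), np.nan)
    return p, n


def _fs_components(x: np.ndarray, y: np.ndarray,
                   use: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerator and denominator of pooled Fs, summed over the two
    alleles of each biallelic locus."""
    z = (x + y) / 2.0
    num = 2 * (x - y) ** 2            # (x-y)^2 + ((1-x)-(1-y))^2
    den = 2 * z * (1 - z)             # z(1-z) + (1-z)z
    num = np.where(use, num, 0.0)
    den = np.where(use, den, 0.0)
    return num, den


def ne_temporal(
    gm_t0: GenotypeMatrix,
    gm_t1: GenotypeMatrix,
    t_generations: float,
    plan: str = "II",
    alpha: float = 0.05,
) -> NeEstimate:
    """Temporal effective size from two samples ``t_generations`` apart.

    Fs = sum over loci and alleles of (x - y)^2 divided by the matching sum
    of z(1 - z) with z the mean frequency.  The plan-II finite-sample
    correction uses the harmonic-mean sample size n~ (individuals):

        Fs' = [ Fs * (1 - 1/(4 n~)) - 1/n~ ] / (1 + Fs/4)

    and Ne = t / (2 Fs').  Nonpositive Fs' yields infinity.
    """
    if plan != "II":
        raise NotImplementedError("only sampling plan II is implemented")
    if t_generations < 1:
        raise ValueError("t_generations must be >= 1")
    if gm_t0.loci != gm_t1.loci:
        raise ValueError("samples must share the same loci in the same order")
    x, n0 = _freqs_and_n(gm_t0)
    y, n1 = _freqs_and_n(gm_t1)
    z = (x + y) / 2.0
    use = np.isfinite(x) & np.isfinite(y) & (n0 > 0) & (n1 > 0) \
        & (z > 0) & (z < 1)
    if not use.any():
        raise ValueError("no shared polymorphic loci")
    num, den = _fs_components(x, y, use)

    def estimate(mask: np.ndarray) -> tuple[float, float]:
        fs = num[mask].sum() / den[mask].sum()
        nh0 = stats.hmean(n0[mask])
        nh1 = stats.hmean(n1[mask])
        n_tilde = 2.0 / (1.0 / nh0 + 1.0 / nh1)
        fs_prime = (fs * (1 - 1 / (4 * n_tilde)) - 1 / n_tilde) / (1 + fs / 4)
        ne = t_generations / (2 * fs_prime) if fs_prime > 0 else INF
        return fs, fs_prime

    fs, fs_prime = estimate(use)
    point = t_generations / (2 * fs_prime) if fs_prime > 0 else INF

    # jackknife over loci on Fs'
    loci_idx = np.flatnonzero(use)
    if loci_idx.size >= 5 and math.isfinite(point):
        pseudo = []
        for l in loci_idx:
            m = use.copy()
            m[l] = False
            if m.any():
                pseudo.append(estimate(m)[1])
        pseudo = np.asarray(pseudo)
        L = pseudo.size
        jack_var = (L - 1) / L * ((pseudo - pseudo.mean()) ** 2).sum()
        se = math.sqrt(jack_var)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo_fs = fs_prime - zcrit * se
        hi_fs = fs_prime + zcrit * se
        ci_hi = t_generations / (2 * lo_fs) if lo_fs > 0 else INF
        ci_lo = t_generations / (2 * hi_fs) if hi_fs > 0 else INF
        ci = (min(ci_lo, point), max(ci_hi, point))
    else:
        ci = (0.0, INF)

    return NeEstimate(
        method="temporal",
        point=point,
        ci=ci,
        inputs=dict(n0=int(gm_t0.n_ind), n1=int(gm_t1.n_ind),
                    n_loci=int(use.sum()), t=t_generations, plan=plan),
        stats=dict(Fs=float(fs), Fs_prime=float(fs_prime)),
    )


# ---------------------------------------------------------------------------

def harmonic_mean_ne(values: list[float]) -> HarmonicSummary:
    """Harmonic mean of Ne estimates; infinite values contribute zero to the
    reciprocal sum (the limit behavior), and are counted separately."""
    if not values:
        raise ValueError("no values")
    vals = [float(v) for v in values]
    if any(v <= 0 for v in vals):
        raise ValueError("all values must be positive")
    recip = sum(0.0 if math.isinf(v) else 1.0 / v for v in vals)
    hm = INF if recip == 0 else len(vals) / recip
    return HarmonicSummary(
        values=vals,
        harmonic_mean=hm,
        n_finite=sum(math.isfinite(v) for v in vals),
        n_infinite=sum(math.isinf(v) for v in vals),
    )
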