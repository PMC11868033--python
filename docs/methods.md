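# Methods

This note documents the statistical models implemented in `genmon`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter when reproducing
its output.

## Data model

Genotypes are diploid biallelic SNPs stored as reference-allele dosage
(0/1/2) with an explicit missing sentinel that is never confused with the
homozygote 0. All statistics are complete-case per locus: an individual
missing at a locus contributes no gene copies there but is retained at every
other locus, matching how the classic population-genetics tools treat missing
data. GENEPOP (2- and 3-digit), STRUCTURE-style two-row text (read-only) and
a plain CSV dosage table are supported; the reference allele in GENEPOP is
the lexicographically smaller allele code, which makes parsing deterministic
across dialects.

## Diversity and divergence

Per locus, expected heterozygosity is H_E = 1 − p² − q², the unbiased variant
uH_E = 2n/(2n−1) · H_E, and H_O the observed heterozygote fraction. Allelic
richness is hypergeometric rarefaction to g gene copies,
A_R = Σ_i [1 − C(2N−N_i, g)/C(2N, g)], with g defaulting per locus to the
smallest typed copy count among the compared samples (the fstat convention).

The within-sample fixation index is f = (H_E − H_O)/H_E per locus, combined
across loci as a ratio of sums. This form is exactly zero at sample counts in
Hardy–Weinberg proportions, which is the property the monitoring tables rely
on (consistent small negative f = heterozygote excess). Its significance test
exploits the fact that re-pairing the observed gene copies into diploids
leaves allele counts — hence H_E — unchanged: the permutation distribution of
f is induced entirely by the conditional distribution of heterozygote counts
under uniform random pairing, which we sample exactly instead of physically
shuffling copies. The exact Hardy–Weinberg test enumerates that same
conditional distribution (heterozygote counts of matching parity) and sums
the probabilities of outcomes no more probable than the observed one;
per-population summaries combine loci by Fisher's method.

Multi-population structure uses the Weir–Cockerham (1984) variance
components a, b, c per locus, with θ = a/(a+b+c), f = 1 − c/(b+c),
F = 1 − c/(a+b+c). Multi-locus estimates are always ratios of summed
components, never means of per-locus ratios, and negative per-locus
components are retained in the sums (so slightly negative multi-locus θ is a
legitimate output). Pairwise θ significance is a one-sided permutation test
shuffling individuals between the pair (default 9,999 permutations where
enabled). Nei's D_a = 1 − (1/L) Σ_l Σ_u √(x_u y_u) feeds a Saitou–Nei
neighbor-joining tree; Q-matrix ties break on the lowest taxon index, and a
negative NJ branch is clamped to zero with the deficit moved to its sister so
path lengths are preserved. Bootstrap supports resample loci with
replacement (default B = 1000) and count the point tree's internal
bipartitions in the replicate trees.

## Ancestry and introgression

Supervised ancestry conditions on baseline allele frequencies. Baseline
frequencies are clamped to [ε, 1−ε] with ε = 1/(2n+2) before likelihood use —
the weak-prior device that keeps alleles unseen in a finite baseline sample
from producing −∞ log-likelihoods. The per-individual mixture likelihood is
maximized over the simplex by EM from a uniform start (tolerance 1e-8 on the
log-likelihood, cap 2,000 iterations); EM is monotone, and the update is the
average posterior source attribution over the individual's gene copies.
Point estimation (rather than a Bayesian posterior) is deliberate: with ~96
ancestry-informative loci at founder divergence F_ST ≈ 0.4 the likelihood is
sharply peaked, and all monitoring analyses condition on fixed baselines.

One bias matters in practice: for an individual whose true ancestry lies on
the simplex boundary (a pure fish), the constrained MLE cannot go negative,
so small spurious mass (~1–2 % with 96 loci and four baselines) lands on the
other sources. Sample-mean introgression therefore has a noise floor of
about one percent even in a closed system; the recovery tests account for
this, and the simulator's truth records let any analysis report the true
alien pedigree fraction alongside the estimate.

Thresholds follow the monitoring convention: genetic group A at Q_A ≥ 0.75,
B at Q_A ≤ 0.25 (boundaries belong to the pure classes, resolving the
printed 0.74–0.26 band), purity at max Q ≥ 0.99 (strict) or > 0.75
(relaxed), immigrant when assignment to the local baseline is < 0.25, and —
in the lower creek — downstream immigrant when assignment to the upper creek
is ≥ 0.75 (this rule is checked first, since such fish also fail the local
threshold). Introgression is the mean of Q_A + Q_B over non-immigrants; the
"total alien contribution" variant keeps immigrants in. Q mass assigned to
the other creek's baseline is *not* counted as introgression.

## Effective size

**LD method.** For every locus pair passing the minor-allele-frequency
screen (default Pcrit = 0.02, the NeEstimator-style default; configurable),
the Burrows composite disequilibrium is estimated from unphased dosages as
half the sample covariance (the n/(n−1)-corrected covariance identity
cov(X,Y) = 2Δ), standardized to r̂² = Δ̂²/(p(1−p)q(1−q)), and averaged with
weights equal to the pairwise complete sample size. The sampling expectation
under random mating — E[r²] = 1/S + 3.19/S² for S ≥ 30, else
0.0018 + 0.907/S + 4.44/S² — is subtracted, and r²′ maps to Ne by
N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2r²′) for S ≥ 30 (constants 0.308, 2.08
below 30). Nonpositive r²′ or a negative discriminant yield ∞ — "no drift
signal detectable", a legitimate estimate. The parametric CI treats the
locus-pair comparisons as a chi-square with one df each. Wright–Fisher
recovery runs (true Ne = 50, S = 50, 96 loci) center the median estimate in
the low-to-mid 60s: the known mild upward bias of the method at S ≈ Ne, well
inside the recovery band used for acceptance.

**Temporal method.** F_s pools (x−y)² over loci and alleles against
z(1−z), z = (x+y)/2. The plan-II finite-sample correction used is

    F_s′ = [ F_s (1 − 1/(4ñ)) − 1/ñ ] / (1 + F_s/4),   N̂e = t / (2 F_s′),

with ñ the harmonic mean of the two sample sizes in individuals, so the
subtracted term equals the binomial sampling contribution 1/(2S₀) + 1/(2S₁).
Plan II (individuals removed before reproduction) has no census-size factor.
The formula was validated by recovery simulation rather than transcription:
on Wright–Fisher truth Ne = 100, t = 2, S = 60, the median estimate lands
near 110. Confidence intervals are a delete-one-locus jackknife on F_s′.
Elapsed generations between calendar samples default to years divided by a
5-year generation length. When the two estimators disagree, that is expected
behavior in subdivided systems (both underestimate inbreeding N_e locally);
the Ne indicator therefore consistently uses the larger of the temporal
estimate and the harmonic-mean LD estimate.

## Indicators

ΔH converts an observed change over t years to a 100-year retention at
constant proportional rate, retention₁₀₀ = (after/before)^(100/t). The clock
compounds in calendar years, not generations — the indicator system is
policy-facing and reports on fixed review horizons — but the conversion is a
single exponent and can be re-expressed in generations if desired.
Non-significant changes are green; significant declines map ≥ 0.95 → green,
0.75–0.95 → yellow, < 0.75 → red (retention exactly 0.95 is green);
significant increases are yellow when a recorded anthropogenic cause exists,
else green with a note. Significance is the locus-paired Wilcoxon
matched-pairs test (primary; exact for ≤ 25 nonzero differences, else normal
approximation with continuity correction), with the paired t reported
alongside; α = 0.05, two-sided, no multiple-testing correction at the gate.
Per-measure statuses (H_E, H_O, A_n, A_R) stay separate — they can genuinely
disagree — and an explicit worst-status roll-up row is labeled as such.

Ne applies the 50/500 rule to the max-rule estimate: > 500 green,
50 < Ne ≤ 500 yellow, ≤ 50 red (printed thresholds are strict, so the
boundary values fall to the more cautious class).

ΔF_ST maps each divergence value to island-model migrants,
Nm = (1/F_ST − 1)/4, and classifies the percent change in Nm: a significant
increase of 50–100 % or reduction of 25–50 % is yellow; > 100 % increase or
> 50 % reduction is red. The island-model mapping is an inference: it is the
mapping under which a decline from 0.21 to 0.16 equals a 40 % gene-flow
increase, the worked example the thresholds are calibrated against. The
significance gate for ΔF_ST is a Wilcoxon over per-locus θ differences — a
convention chosen here, flagged as such. A single-generation heterozygosity
loss of 1/(2Ne) (5 % at Ne = 10, i.e. 95 % retained) is exposed as
`expected_het_retention` for desk calculations around the Ne indicator.

## The synthetic-data generator

The simulator reproduces the statistical structure of the monitored release-and-spread
system with known truth, not the hydrology of a particular lake system.

*Founders.* Per-locus ancestral frequencies are Uniform(0.05, 0.95); each
population pair draws from a Balding–Nichols Beta with a single divergence
knob F, calibrated by bisection (common uniforms across iterations, so the
realized Weir–Cockerham θ is a stable near-monotone function of F) until the
realized multi-locus θ matches the target: 0.40 for the released pair
(defaults: ~100 and 17 spawners, 1,000 released fry each, 96 unlinked SNPs),
0.21 for the native creek pair. The lower creek additionally carries a low
frequency (2–15 %) of the released-population allele at the most diagnostic
loci, emulating natural pre-release polymorphism at otherwise diagnostic
markers; no published value exists for that fraction, so 10 % of loci is an
arbitrary but fixed choice.

*Spread.* Discrete generations; migration precedes reproduction. Between
adjacent lakes, each fish moves downstream with probability
m₀ + β·Q_A (defaults 0.04 + 0.12·Q_A) — dispersal linked phenomenologically
to ancestry from the migratory founder, not to an explicit migration gene,
because the underlying heritability is established only correlationally.
Any lake fish passes the one-way waterfall into the upper creek with
probability 0.0005 per generation (a small leak applied chain-wide, since
within-generation movement can traverse several lakes); the upper creek
sends migrants to the lower creek at 0.02. Reproduction is random mating
with two distinct parents per offspring and the census regulated to the deme
size (lakes 250; creeks 60 and 120 — chosen so local effective sizes land in
the tens-to-low-hundreds range typical of small stream salmonid
populations). Pedigree ancestry truth is the parental mean, so F1s carry
Q_A = 0.5 exactly and mean ancestry in a closed deme changes only by
migration and drift.

Under these defaults the simulation reproduces the monitored system's qualitative
fingerprints, which the acceptance suite checks across 50 seeds: a positive
downstream cline of migratory-founder ancestry (r ≈ 0.87 on average), lake
metapopulation heterozygosity above both founders (admixture), small
negative per-lake F_IS, and a few percent of alien ancestry below the
waterfall, concentrated in the upper creek.

*What it does not emulate:* overlapping generations and age structure,
selection, sex-biased dispersal, genotyping error, linkage (96 SNPs spread
over 40 chromosomes justify free recombination), and interspecific
interactions. Passing recovery tests on this generator therefore
demonstrates statistical correctness of the estimators under this
sampling design, not robustness to those real-data complications.

*Wright–Fisher oracle.* A separate plain Wright–Fisher helper (constant
size, unlinked loci, offspring-cohort sampling — which is exactly sampling
plan II) provides the independent truth for the effective-size recovery
tests, so those tests do not share code with the release-and-spread
generator's demography.

## Problem sizes used in the automated checks

Recovery suites use 200 replicates for the two Ne estimators (Ne = 50,
S = 50 LD; Ne = 100, t = 2, S = 60 temporal), 200 simulated F1s for ancestry
recovery, 100 replicates of 60-fish creek samples for introgression
recovery, and 50 seeded replicates of the default simulation for the
qualitative patterns. Null-calibration tests (permutation type-I error,
θ bias) use a few hundred simulations each. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands while keeping the full
suite in the minutes range on a single core.

## Known limitations

- The LD estimator's parametric CI assumes independent locus pairs; with 96
  loci the pairs overlap heavily, so the CI is anti-conservative and should
  be read qualitatively (the jackknife alternative is the temporal CI's
  mechanism).
- Supervised Q is a point estimate; per-individual uncertainty is not
  propagated into introgression CIs.
- In demes receiving ongoing migration the temporal method often returns ∞
  (migration balances drift); this is faithful to the estimator, and the
  max-rule indicator then classifies on the LD estimate alone.
- The unsupervised admixture fit does not choose K; K is a user input, and
  cluster labels are aligned to baselines by frequency correlation only when
  baselines are supplied.
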