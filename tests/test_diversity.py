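import numpy as np
import pytest

from genmon.diversity import (
    _rarefied_richness,
    allelic_richness,
    fis,
    heterozygosity,
    hwe_exact,
    hwe_exact_single,
    paired_change_test,
)
from genmon.geno_io import MISSING, GenotypeMatrix

from oracles import hwe_exact_oracle, rarefaction_oracle, wilcoxon_exact_oracle


def _single_pop(dosages):
    d = np.array(dosages)
    if d.ndim == 1:
        d = d[:, None]
    return GenotypeMatrix([f"i{k}" for k in range(d.shape[0])],
                          [f"L{k}" for k in range(d.shape[1])], d,
                          ["P"] * d.shape[0])


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def test_heterozygosity_hand_example():
    """{AA, AB}: p = 0.75, He = 0.375, uHe = 0.5, Ho = 0.5."""
    gm = _single_pop([2, 1])
    row = heterozygosity(gm).per_locus.iloc[0]
    assert row.He == pytest.approx(0.375)
    assert row.uHe == pytest.approx(0.5)
    assert row.Ho == pytest.approx(0.5)


@pytest.mark.parametrize(
    "dosages, he, ho",
    [([2, 2, 2], 0.0, 0.0),          # monomorphic
     ([2, 0], 0.5, 0.0),             # p = 0.5 symmetry maximum
     ([1, 1], 0.5, 1.0)],
)
def test_heterozygosity_edge_cases(dosages, he, ho):
    row = heterozygosity(_single_pop(dosages)).per_locus.iloc[0]
    assert row.He == pytest.approx(he)
    assert row.Ho == pytest.approx(ho)


def test_unbiased_factor_dominates():
    """uHe >= He for any finite sample; ratio is 2n/(2n-1)."""
    rng = np.random.default_rng(0)
    gm = _single_pop(rng.integers(0, 3, size=20))
    df = heterozygosity(gm).per_locus
    assert (df.uHe >= df.He - 1e-15).all()
    assert df.uHe.iloc[0] == pytest.approx(df.He.iloc[0] * 40 / 39)


# ---------------------------------------------------------------------------
# Allelic richness
# ---------------------------------------------------------------------------

def test_rarefaction_enumeration_example():
    """Copies (9,1) rarefied to g=2 gives 1.2, matching exhaustive
    enumeration of all C(10,2) subsamples."""
    assert _rarefied_richness(np.array([9, 1]), 2) == pytest.approx(1.2)
    assert rarefaction_oracle([9, 1], 2) == pytest.approx(1.2)


@pytest.mark.parametrize("counts, g", [([5, 3], 4), ([7, 2], 3), ([4, 4], 6)])
def test_rarefaction_matches_exhaustive_oracle(counts, g):
    assert _rarefied_richness(np.array(counts), g) == pytest.approx(
        rarefaction_oracle(counts, g), abs=1e-12
    )


def test_rarefaction_degenerate_cases():
    assert _rarefied_richness(np.array([8, 0]), 4) == pytest.approx(1.0)
    # g = 2N recovers the observed allele count
    assert _rarefied_richness(np.array([6, 2]), 8) == pytest.approx(2.0)


def test_rarefaction_monotone_in_g():
    counts = np.array([11, 3])
    vals = [_rarefied_richness(counts, g) for g in range(1, 15)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_allelic_richness_default_g_is_min_copies():
    dosage = np.array([[2], [1], [1], [MISSING], [0], [1]])
    gm = GenotypeMatrix([f"i{k}" for k in range(6)], ["L1"], dosage,
                        ["P1"] * 3 + ["P2"] * 3)
    df = allelic_richness(gm)
    assert set(df.g) == {4}   # P2 has 2 typed individuals -> 4 copies


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------

def test_fis_all_heterozygous_is_minus_one():
    gm = _single_pop([1, 1, 1, 1])
    assert fis(gm, n_permutations=0).f.iloc[0] == pytest.approx(-1.0)


def test_fis_hardy_weinberg_counts_are_zero():
    """Counts exactly at HW proportions (1 AA, 2 AB, 1 aa) give f = 0."""
    gm = _single_pop([2, 1, 1, 0])
    assert fis(gm, n_permutations=0).f.iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_fis_permutation_type_one_error():
    """Under random pairing (HWE), the permutation test rejects at close to
    its nominal 5% level."""
    rng = np.random.default_rng(42)
    n_sims, rejections = 300, 0
    for s in range(n_sims):
        p = rng.uniform(0.2, 0.8, 12)
        d = rng.binomial(2, p, size=(25, 12)).astype(np.int16)
        gm = GenotypeMatrix([f"i{k}" for k in range(25)],
                            [f"L{k}" for k in range(12)], d, ["P"] * 25)
        out = fis(gm, n_permutations=1000, seed=s)
        if out.p_value.iloc[0] < 0.05:
            rejections += 1
    rate = rejections / n_sims
    assert abs(rate - 0.05) <= 0.03


# ---------------------------------------------------------------------------
# Exact HWE
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "het, hom_ref, hom_alt",
    [(4, 1, 0), (2, 2, 1), (0, 3, 2), (5, 0, 5), (1, 1, 1)],
)
def test_hwe_exact_matches_multinomial_oracle(het, hom_ref, hom_alt):
    assert hwe_exact_single(het, hom_ref, hom_alt) == pytest.approx(
        hwe_exact_oracle(het, hom_ref, hom_alt), abs=1e-10
    )


def test_hwe_monomorphic_is_one():
    assert hwe_exact_single(0, 5, 0) == 1.0


def test_hwe_label_swap_symmetry():
    assert hwe_exact_single(3, 4, 1) == pytest.approx(
        hwe_exact_single(3, 1, 4), abs=1e-12
    )


def test_hwe_rejection_rate_is_conservative():
    """On data simulated under HWE the exact test rejects at <= 5%."""
    rng = np.random.default_rng(3)
    rejections = trials = 0
    for _ in range(400):
        p = rng.uniform(0.2, 0.8)
        g = rng.binomial(2, p, size=30)
        pv = hwe_exact_single(int((g == 1).sum()), int((g == 2).sum()),
                              int((g == 0).sum()))
        rejections += pv < 0.05
        trials += 1
    assert rejections / trials <= 0.055


def test_hwe_table_and_fisher_combination(toy_two_pop):
    df = hwe_exact(toy_two_pop)
    assert ((df.p >= 0) & (df.p <= 1)).all()
    assert df.overall_p.between(0, 1).all()


# ---------------------------------------------------------------------------
# Paired change tests
# ---------------------------------------------------------------------------

def test_paired_identical_vectors_no_change():
    v = np.linspace(0.1, 0.5, 20)
    res = paired_change_test(v, v)
    assert res.direction == "none" and not res.significant
    assert res.wilcoxon_p == 1.0


def test_paired_uniform_shift_is_significant():
    """A +0.05 shift at every one of 96 loci is overwhelming evidence."""
    rng = np.random.default_rng(1)
    before = rng.uniform(0.2, 0.4, 96)
    res = paired_change_test(before, before + 0.05)
    assert res.significant and res.direction == "increase"
    assert res.wilcoxon_p < 1e-3


def test_paired_sign_flip_antisymmetry():
    rng = np.random.default_rng(2)
    before = rng.uniform(0.2, 0.4, 30)
    after = before + rng.normal(0.02, 0.02, 30)
    fwd = paired_change_test(before, after)
    rev = paired_change_test(after, before)
    assert fwd.wilcoxon_p == pytest.approx(rev.wilcoxon_p)
    if fwd.significant:
        assert {fwd.direction, rev.direction} == {"increase", "decrease"}


def test_paired_exact_small_n_matches_enumeration():
    before = np.array([0.30, 0.25, 0.40, 0.35, 0.20, 0.45, 0.33])
    after = np.array([0.36, 0.24, 0.47, 0.38, 0.23, 0.50, 0.31])
    res = paired_change_test(before, after)
    assert res.wilcoxon_p == pytest.approx(
        wilcoxon_exact_oracle(after - before), abs=1e-12
    )


def test_paired_length_mismatch():
    with pytest.raises(ValueError):
        paired_change_test(np.ones(6), np.ones(7))
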