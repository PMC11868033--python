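import numpy as np
import pytest

from genmon.ancestry import (
    Baseline,
    classify_lake_group,
    cline_correlation,
    detect_immigrants,
    estimate_q_supervised,
    fit_admixture_unsupervised,
    flag_pure,
    introgression_rate,
    make_baseline,
    select_baseline_by_diagnostic,
    spawning_contingency,
    AncestryResult,
    GroupCall,
)
from genmon.geno_io import GenotypeMatrix, MISSING

from oracles import chi2_oracle, pearson_oracle


def _gm(dosage, pops=None, loci=None):
    dosage = np.asarray(dosage, dtype=np.int16)
    pops = pops or ["P"] * dosage.shape[0]
    loci = loci or [f"L{k}" for k in range(dosage.shape[1])]
    return GenotypeMatrix([f"i{k}" for k in range(dosage.shape[0])],
                          loci, dosage, pops)


def _diag_baselines(L=96, n=1000):
    """Fully diagnostic pair: A fixed for reference, B for alternate."""
    loci = [f"L{k}" for k in range(L)]
    return [Baseline("A", loci, np.ones(L), n),
            Baseline("B", loci, np.zeros(L), n)]


# ---------------------------------------------------------------------------
# Baseline selection
# ---------------------------------------------------------------------------

def test_diagnostic_selection_keeps_only_target_homozygotes():
    gm = _gm([[2, 1], [1, 1], [2, 0], [0, 2]])
    sel = select_baseline_by_diagnostic(gm, "L0", allele="ref")
    assert sel.individuals == ["i0", "i2"]
    sel_alt = select_baseline_by_diagnostic(gm, "L0", allele="alt")
    assert sel_alt.individuals == ["i3"]


def test_diagnostic_selection_unknown_locus():
    with pytest.raises(KeyError):
        select_baseline_by_diagnostic(_gm([[1]]), "nope")


def test_diagnostic_selection_recovers_pure_parents(founder_freqs):
    """P + F1 mixture with a fixed diagnostic locus: homozygote selection
    returns exactly the unadmixed individuals."""
    rng = np.random.default_rng(21)
    L = 10
    fA = np.ones(L)          # A fixed for ref everywhere (diagnostic locus = L0)
    fB = np.zeros(L)
    pure_a = rng.binomial(2, fA, (20, L))
    pure_b = rng.binomial(2, fB, (20, L))
    f1 = np.ones((20, L))    # one copy from each -> all het
    gm = _gm(np.vstack([pure_a, f1, pure_b]))
    sel = select_baseline_by_diagnostic(gm, "L0", allele="ref")
    assert set(sel.individuals) == {f"i{k}" for k in range(20)}


def test_baseline_frequencies_clamped():
    gm = _gm([[2, 0], [2, 0]])
    b = make_baseline(gm, "X")
    eps = 1 / (2 * 2 + 2)
    assert b.freq[0] == pytest.approx(1 - eps)
    assert b.freq[1] == pytest.approx(eps)


# ---------------------------------------------------------------------------
# Supervised EM
# ---------------------------------------------------------------------------

def test_supervised_degenerate_all_reference():
    gm = _gm([[2] * 96])
    res = estimate_q_supervised(gm, _diag_baselines())
    assert res.Q[0, 0] >= 0.999


def test_supervised_symmetric_heterozygote():
    gm = _gm([[1] * 96])
    res = estimate_q_supervised(gm, _diag_baselines())
    assert res.Q[0, 0] == pytest.approx(0.5, abs=1e-6)


def test_supervised_q_on_simplex_and_label_equivariance(founder_freqs):
    rng = np.random.default_rng(3)
    fA, fB = founder_freqs.freq[:2]
    g = rng.binomial(2, (fA + fB) / 2, (30, fA.size)).astype(np.int16)
    loci = list(founder_freqs.loci)
    gm = _gm(g, loci=loci)
    bl = [Baseline("A", loci, fA, 50), Baseline("B", loci, fB, 50)]
    res = estimate_q_supervised(gm, bl)
    np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
    swapped = estimate_q_supervised(gm, bl[::-1])
    np.testing.assert_allclose(res.Q[:, 0], swapped.Q[:, 1], atol=1e-6)


def test_supervised_f1_recovery(founder_freqs):
    """Simulated F1s (true Q_A = 0.5) at founder divergence 0.4 with 96
    loci: the estimator is nearly unbiased with RMSE < 0.08."""
    rng = np.random.default_rng(17)
    fA, fB = founder_freqs.freq[:2]
    n = 200
    g = ((rng.random((n, 96)) < fA).astype(np.int16)
         + (rng.random((n, 96)) < fB).astype(np.int16))
    loci = list(founder_freqs.loci)
    gm = _gm(g, loci=loci)
    bl = [Baseline("A", loci, fA, 50), Baseline("B", loci, fB, 50)]
    res = estimate_q_supervised(gm, bl)
    qa = res.Q[:, 0]
    assert np.sqrt(np.mean((qa - 0.5) ** 2)) < 0.08
    assert abs(qa.mean() - 0.5) < 0.02


def test_supervised_pure_individuals_confidently_assigned(founder_freqs):
    """Pure-A genotypes at divergence 0.4 over 96 loci get mean Q_A >= 0.95."""
    rng = np.random.default_rng(19)
    fA, fB = founder_freqs.freq[:2]
    g = rng.binomial(2, fA, (100, 96)).astype(np.int16)
    loci = list(founder_freqs.loci)
    bl = [Baseline("A", loci, fA, 50), Baseline("B", loci, fB, 50)]
    res = estimate_q_supervised(_gm(g, loci=loci), bl)
    assert res.Q[:, 0].mean() >= 0.95


def test_supervised_rejects_all_missing():
    dosage = np.full((1, 96), MISSING)
    with pytest.raises(ValueError):
        estimate_q_supervised(_gm(dosage), _diag_baselines())


# ---------------------------------------------------------------------------
# Unsupervised EM
# ---------------------------------------------------------------------------

def test_unsupervised_k1_closed_form():
    gm = _gm([[2, 0], [1, 1], [1, 2]])
    res, P = fit_admixture_unsupervised(gm, K=1)
    np.testing.assert_allclose(res.Q, 1.0)
    np.testing.assert_allclose(P[0], [4 / 6, 3 / 6])


def test_unsupervised_recovers_two_pure_clusters(founder_freqs):
    rng = np.random.default_rng(23)
    fA, fB = founder_freqs.freq[:2]
    gA = rng.binomial(2, fA, (40, 96)).astype(np.int16)
    gB = rng.binomial(2, fB, (40, 96)).astype(np.int16)
    gm = _gm(np.vstack([gA, gB]))
    res, _ = fit_admixture_unsupervised(gm, K=2, n_restarts=3, seed=1)
    calls = res.Q.argmax(axis=1)
    # cluster labels are arbitrary: compare against both assignments
    truth = np.array([0] * 40 + [1] * 40)
    agreement = max((calls == truth).mean(), (calls == 1 - truth).mean())
    assert agreement > 0.95


def test_unsupervised_loglik_monotone(founder_freqs):
    """EM total log-likelihood never decreases across iterations."""
    rng = np.random.default_rng(29)
    fA, fB = founder_freqs.freq[:2]
    g = np.vstack([rng.binomial(2, fA, (15, 96)),
                   rng.binomial(2, fB, (15, 96))]).astype(np.int16)
    trace: list[float] = []
    fit_admixture_unsupervised(_gm(g), K=2, n_restarts=1, seed=0,
                               ll_trace=trace)
    diffs = np.diff(trace)
    assert (diffs >= -1e-6).all()


def test_unsupervised_k_bounds():
    gm = _gm([[1, 1]])
    with pytest.raises(ValueError):
        fit_admixture_unsupervised(gm, K=5)


# ---------------------------------------------------------------------------
# Threshold classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("q, expected", [
    (0.80, "A"), (0.50, "AB"), (0.75, "A"), (0.25, "B"), (0.10, "B"),
])
def test_lake_group_thresholds(q, expected):
    assert classify_lake_group(q) == expected


def test_flag_pure_cutoffs():
    assert flag_pure(np.array([0.995, 0.005]), 0.99)
    assert flag_pure(np.array([0.995, 0.005]), 0.75)
    assert not flag_pure(np.array([0.80, 0.20]), 0.99)
    assert flag_pure(np.array([0.80, 0.20]), 0.75)
    assert not flag_pure(np.array([0.5, 0.5]), 0.75)


def _creek_result(qs):
    qs = np.asarray(qs, float)
    return AncestryResult([f"f{k}" for k in range(qs.shape[0])],
                          ["A", "B", "CreekI", "CreekII"], qs,
                          np.zeros(qs.shape[0]),
                          np.full(qs.shape[0], 96))


def test_immigrant_rules():
    res = _creek_result([
        [0.40, 0.40, 0.05, 0.15],   # Q_local(CreekII)=0.15 < 0.25 -> immigrant
        [0.05, 0.05, 0.80, 0.10],   # Q_CreekI = 0.80 -> downstream immigrant
        [0.02, 0.03, 0.05, 0.90],   # local
    ])
    calls = detect_immigrants(res, "CreekII", creek_i_source="CreekI")
    assert [c.group for c in calls] == ["immigrant", "downstream-immigrant", "local"]


def test_introgression_hand_values():
    res = _creek_result([
        [0.00, 0.00, 0.10, 0.90],
        [0.01, 0.02, 0.07, 0.90],
        [0.03, 0.03, 0.04, 0.90],
    ])
    calls = [GroupCall(i, "local", False, True) for i in res.individuals]
    out = introgression_rate(res, calls)
    assert out["introgression"] == pytest.approx((0.0 + 0.03 + 0.06) / 3)


def test_introgression_closed_population_zero():
    res = _creek_result([[0, 0, 0.2, 0.8]] * 5)
    calls = [GroupCall(i, "local", False, True) for i in res.individuals]
    assert introgression_rate(res, calls)["introgression"] == 0.0


def test_introgression_requires_non_immigrants():
    res = _creek_result([[0.9, 0.05, 0.02, 0.03]])
    calls = [GroupCall("f0", "immigrant", False, True)]
    with pytest.raises(ValueError):
        introgression_rate(res, calls)


# ---------------------------------------------------------------------------
# Cline and contingency
# ---------------------------------------------------------------------------

def test_cline_perfect_linearity():
    r, p = cline_correlation([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
    assert r == pytest.approx(1.0)


def test_cline_matches_covariance_oracle():
    rng = np.random.default_rng(31)
    q = rng.uniform(0, 1, 7)
    d = rng.uniform(0, 20, 7)
    r, _ = cline_correlation(q, d)
    assert r == pytest.approx(pearson_oracle(q, d), abs=1e-12)


def test_cline_null_is_centered():
    rng = np.random.default_rng(33)
    rs = [cline_correlation(rng.uniform(0, 1, 7), np.arange(7))[0]
          for _ in range(200)]
    assert abs(np.mean(rs)) < 0.1


def test_contingency_independent_table_zero():
    margins_r = np.array([0.2, 0.3, 0.5])
    margins_c = np.array([0.4, 0.6])
    table = 1000 * np.outer(margins_r, margins_c)
    chi2, df, p = spawning_contingency(table)
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert df == 2


def test_contingency_matches_hand_computation():
    table = np.array([[10, 10], [10, 10], [10, 40]])
    chi2, df, _ = spawning_contingency(table)
    o_chi2, o_df = chi2_oracle(table)
    assert chi2 == pytest.approx(o_chi2, abs=1e-10)
    assert df == o_df == 2


def test_contingency_empty_column_rejected():
    with pytest.raises(ValueError):
        spawning_contingency(np.array([[0, 5], [0, 3]]))
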