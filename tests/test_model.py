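"""Generator construction, transition matrices, marginals and summaries."""

import dataclasses
import itertools

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from mechcodon.genetic_code import ALL_CODONS, universal_code
from mechcodon.model import (
    CodonModelParams,
    CodonRateMatrix,
    ConstraintSet,
    ModelError,
    NucleotideParams,
    RateVariationLaw,
    amino_acid_marginal,
    apply_linear_constraints,
    codon_freq_from_aa,
    codon_mutation_matrix,
    codon_rate_matrix,
    gamma_transition_matrix,
    log_odds,
    logodds_spectrum,
    mutational_codon_composition,
    rate_summaries,
    transition_matrix,
)
from mechcodon.simulate import FixtureSpec, random_params

UNI = universal_code()


def _fmut64(nuc):
    q = nuc.q
    return np.array(
        [q["ACGT".index(c[0])] * q["ACGT".index(c[1])] * q["ACGT".index(c[2])]
         for c in ALL_CODONS]
    )


# ---------------------------------------------------------------------------
# mutation matrix
# ---------------------------------------------------------------------------

def test_mutation_matrix_sigma_zero_forbids_multi_changes(drawn_params):
    M = codon_mutation_matrix(drawn_params.nuc, 0.0)
    for i, x in enumerate(ALL_CODONS):
        for j, y in enumerate(ALL_CODONS):
            k = sum(a != b for a, b in zip(x, y))
            if k >= 2:
                assert M[i, j] == 0.0


def test_mutation_matrix_uniform_symmetry():
    nuc = NucleotideParams.uniform()
    M = codon_mutation_matrix(nuc, 1.0)
    off = {}
    for i, x in enumerate(ALL_CODONS):
        for j, y in enumerate(ALL_CODONS):
            if i == j:
                continue
            k = sum(a != b for a, b in zip(x, y))
            off.setdefault(k, set()).add(round(M[i, j], 15))
    # with all exchangeabilities and compositions equal, every k-change
    # entry takes a single common value
    for k, vals in off.items():
        assert len(vals) == 1, (k, vals)


def test_mutation_matrix_detailed_balance_brute_force(drawn_params):
    M = codon_mutation_matrix(drawn_params.nuc, drawn_params.sigma)
    fmut = _fmut64(drawn_params.nuc)
    resid = 0.0
    for i in range(64):
        for j in range(64):
            if i != j:
                resid = max(resid, abs(M[i, j] * fmut[i] - M[j, i] * fmut[j]))
    assert resid < 1e-12


def test_mutation_matrix_against_loop_oracle(drawn_params):
    """Independent element-by-element reimplementation of the mutation rates."""
    nuc, sigma = drawn_params.nuc, drawn_params.sigma
    f = nuc.f_matrix()
    q = nuc.q
    M = codon_mutation_matrix(nuc, sigma)
    for i, x in enumerate(ALL_CODONS):
        for j, y in enumerate(ALL_CODONS):
            if i == j:
                continue
            expected = 1.0
            k = 0
            for a, b in zip(x, y):
                if a != b:
                    k += 1
                    expected *= f["ACGT".index(a), "ACGT".index(b)] * q["ACGT".index(b)]
            expected *= sigma ** (k - 1)
            assert M[i, j] == pytest.approx(expected, rel=1e-14)


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------

def test_rate_matrix_invariants(drawn_params, drawn_codon_freq):
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    R, pi = rate.R, rate.pi
    assert R.shape == (61, 61)
    offdiag = R[~np.eye(61, dtype=bool)]
    assert np.all(offdiag >= 0)
    assert np.max(np.abs(R.sum(axis=1))) < 1e-12
    flux = pi[:, None] * R
    assert np.max(np.abs(flux - flux.T)) <= 1e-10 * np.max(np.abs(R))
    assert -float(pi @ np.diag(R)) == pytest.approx(1.0, abs=1e-10)


def test_rate_matrix_neutral_reduces_to_mutation(drawn_params):
    """With w = 0 and pi at the mutational equilibrium, R is the trimmed,
    renormalized mutation matrix."""
    params = dataclasses.replace(
        drawn_params, constraints=ConstraintSet.neutral(UNI), w0=0.0, beta=1.0
    )
    pi = mutational_codon_composition(params.nuc, UNI)
    rate = codon_rate_matrix(params, pi)
    M = codon_mutation_matrix(params.nuc, params.sigma)
    idx = [ALL_CODONS.index(c) for c in UNI.sense_codons]
    Ms = M[np.ix_(idx, idx)].copy()
    np.fill_diagonal(Ms, 0.0)
    np.fill_diagonal(Ms, -Ms.sum(axis=1))
    total = -float(pi @ np.diag(Ms))
    np.testing.assert_allclose(rate.R, Ms / total, rtol=1e-10, atol=1e-14)


def test_rate_matrix_excludes_stop_codons(drawn_params, drawn_codon_freq):
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    assert rate.states == UNI.sense_codons
    assert all(s not in rate.states for s in ("TAA", "TAG", "TGA"))


def test_rate_matrix_rejects_bad_compositions(drawn_params):
    with pytest.raises(ModelError):
        codon_rate_matrix(drawn_params, np.full(61, 1.0 / 61) * 1.5)
    bad = np.full(61, 1.0 / 61)
    bad[0] = 0.0
    bad[1] += 1.0 / 61
    with pytest.raises(ModelError):
        codon_rate_matrix(drawn_params, bad)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_generator_invariants_random_params(seed):
    """Detailed balance and unit total rate across random valid draws."""
    params = random_params(FixtureSpec(seed=seed))
    pi = mutational_codon_composition(params.nuc, UNI)
    rate = codon_rate_matrix(params, pi)
    flux = rate.pi[:, None] * rate.R
    assert np.max(np.abs(flux - flux.T)) <= 1e-10 * np.max(np.abs(rate.R))
    assert -float(rate.pi @ np.diag(rate.R)) == pytest.approx(1.0, abs=1e-10)


def test_sigma_monotonically_raises_multi_change_mass(drawn_params):
    """Pre-normalization rate mass on multi-change pairs grows with sigma."""
    fmut = _fmut64(drawn_params.nuc)
    masses = []
    for sigma in (0.2, 0.5, 1.0, 1.5):
        M = codon_mutation_matrix(drawn_params.nuc, sigma)
        mask = np.zeros((64, 64), dtype=bool)
        for i, x in enumerate(ALL_CODONS):
            for j, y in enumerate(ALL_CODONS):
                if sum(a != b for a, b in zip(x, y)) >= 2:
                    mask[i, j] = True
        masses.append(float((fmut[:, None] * M)[mask].sum()))
    assert all(a < b for a, b in zip(masses, masses[1:]))


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

def test_transition_matrix_identity_at_zero(drawn_params, drawn_codon_freq):
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    np.testing.assert_allclose(transition_matrix(rate, 0.0), np.eye(61), atol=1e-12)


def test_transition_matrix_ergodic_limit(drawn_params, drawn_codon_freq):
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    P = transition_matrix(rate, 1e3)
    np.testing.assert_allclose(P, np.tile(rate.pi, (61, 1)), atol=1e-8)


def test_transition_matrix_agrees_with_expm(drawn_params, drawn_codon_freq):
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    for t in (0.01, 0.3, 2.0):
        P = transition_matrix(rate, t)
        np.testing.assert_allclose(
            P, scipy.linalg.expm(rate.R * t), atol=1e-10
        )


def test_gamma_transition_quadrature_oracle(toy_reversible_4state):
    """Closed form matches a 10^4-node numerical integration of the
    time-averaged transition matrix on a 4-state toy generator.

    Composite 8-point Gauss-Legendre over 1250 panels after the substitution
    t = u^2 (which removes the fractional-power kink of the gamma density at
    zero); the truncated tail carries less than 1e-16 probability mass.
    """
    from scipy.stats import gamma as gamma_dist

    R, pi = toy_reversible_4state
    rate = CodonRateMatrix(R=R, pi=pi, C=1.0, code=UNI)
    alpha, b = 1.7, 0.4
    P_closed = gamma_transition_matrix(rate, RateVariationLaw(alpha=alpha, b=b))
    T = gamma_dist.isf(1e-16, a=alpha, scale=b)
    xg, wg = np.polynomial.legendre.leggauss(8)
    edges = np.linspace(0.0, np.sqrt(T), 1251)
    mid, half = 0.5 * (edges[1:] + edges[:-1]), 0.5 * np.diff(edges)
    u = (mid[:, None] + half[:, None] * xg[None, :]).ravel()
    wu = (half[:, None] * wg[None, :]).ravel()
    t = u**2
    weight = wu * gamma_dist.pdf(t, a=alpha, scale=b) * 2.0 * u
    lam, V = np.linalg.eig(R)
    Vi = np.linalg.inv(V)
    eigint = weight @ np.exp(np.outer(t, lam))
    P_quad = np.real((V * eigint[None, :]) @ Vi)
    assert len(t) == 10_000
    assert np.max(np.abs(P_closed - P_quad)) < 1e-8


def test_gamma_transition_degenerate_law_limit(drawn_params, drawn_codon_freq):
    """b -> 0 with alpha*b = t_bar fixed degenerates to exp(R t_bar)."""
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    t_bar, b = 0.05, 1e-6
    Pg = gamma_transition_matrix(rate, RateVariationLaw(alpha=t_bar / b, b=b))
    np.testing.assert_allclose(Pg, transition_matrix(rate, t_bar), atol=1e-6)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(
    alpha=st.floats(min_value=0.1, max_value=10.0),
    b=st.floats(min_value=1e-3, max_value=5.0),
)
def test_gamma_transition_is_stochastic(drawn_params, drawn_codon_freq, alpha, b):
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    P = gamma_transition_matrix(rate, RateVariationLaw(alpha=alpha, b=b))
    assert np.all(P >= 0)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# marginalization and log-odds
# ---------------------------------------------------------------------------

def test_amino_acid_marginal_matches_loop_oracle(drawn_params, drawn_codon_freq):
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    P = transition_matrix(rate, 0.1)
    A, pi_aa = amino_acid_marginal(P, rate.pi, UNI)
    np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)
    # reversibility inherited from the codon level
    fa = pi_aa[:, None] * A
    assert np.max(np.abs(fa - fa.T)) < 1e-10
    # literal double sum
    aas = UNI.amino_acids
    for ia, a in enumerate(aas):
        ga = [i for i, c in enumerate(UNI.sense_codons) if UNI.translate(c) == a]
        for ib, bb in enumerate(aas):
            gb = [i for i, c in enumerate(UNI.sense_codons) if UNI.translate(c) == bb]
            expected = sum(
                rate.pi[m] / pi_aa[ia] * P[m, n] for m in ga for n in gb
            )
            assert A[ia, ib] == pytest.approx(expected, rel=1e-12, abs=1e-15)


def test_log_odds_zero_for_stationary_rows():
    pi = np.array([0.1, 0.2, 0.3, 0.4])
    P = np.tile(pi, (4, 1))
    np.testing.assert_allclose(log_odds(P, pi), 0.0, atol=1e-14)


def test_log_odds_symmetry_and_dayhoff_scale(drawn_params, drawn_codon_freq):
    rate = codon_rate_matrix(drawn_params, drawn_codon_freq)
    A, pi_aa = amino_acid_marginal(transition_matrix(rate, 0.1), rate.pi, UNI)
    L = log_odds(A, pi_aa)
    assert np.max(np.abs(L - L.T)) < 1e-9
    D = log_odds(A, pi_aa, "dayhoff")
    np.testing.assert_allclose(D, 10.0 * L / np.log(10.0), rtol=1e-12)
    # codon-level log-exchangeability diagnostic: ln(P/(pi_a pi_b)) equals
    # log-odds minus ln pi_a, checked by the direct formula
    P = transition_matrix(rate, 0.1)
    lex = np.log(P[0, 1] / (rate.pi[0] * rate.pi[1]))
    lo = np.log(P[0, 1] / rate.pi[1])
    assert lex == pytest.approx(lo - np.log(rate.pi[0]), rel=1e-12)


def test_log_odds_rejects_zero_composition():
    with pytest.raises(ModelError):
        log_odds(np.eye(3), np.array([0.5, 0.5, 0.0]))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_rate_summaries_base_split(drawn_params, drawn_codon_freq):
    s = rate_summaries(codon_rate_matrix(drawn_params, drawn_codon_freq))
    assert s["ts_rate"] + s["tv_rate"] == pytest.approx(s["base_rate"], rel=1e-12)
    assert s["nonsyn_rate"] + s["syn_rate"] == pytest.approx(s["codon_rate"], rel=1e-12)
    assert s["codon_rate"] == pytest.approx(1.0, abs=1e-10)
    assert s["base_per_codon"] >= 1.0


def test_rate_summaries_sigma_zero_single_base_events(drawn_params, drawn_codon_freq):
    params = dataclasses.replace(drawn_params, sigma=0.0)
    s = rate_summaries(codon_rate_matrix(params, drawn_codon_freq))
    assert s["base_per_codon"] == pytest.approx(1.0, abs=1e-12)


def test_neutral_nonsyn_over_syn_matches_exhaustive_oracle(drawn_params):
    """With all w = 0 the dN/dS ratio equals the mutation-weighted count ratio."""
    params = dataclasses.replace(
        drawn_params, constraints=ConstraintSet.neutral(UNI), w0=0.0
    )
    pi = mutational_codon_composition(params.nuc, UNI)
    s = rate_summaries(codon_rate_matrix(params, pi))
    M = codon_mutation_matrix(params.nuc, params.sigma)
    idx = [ALL_CODONS.index(c) for c in UNI.sense_codons]
    nonsyn = syn = 0.0
    for i, ci in enumerate(UNI.sense_codons):
        for j, cj in enumerate(UNI.sense_codons):
            if i == j:
                continue
            fluxij = pi[i] * M[idx[i], idx[j]]
            if UNI.translate(ci) == UNI.translate(cj):
                syn += fluxij
            else:
                nonsyn += fluxij
    assert s["nonsyn_over_syn"] == pytest.approx(nonsyn / syn, rel=1e-10)


# ---------------------------------------------------------------------------
# codon usage and linear constraints
# ---------------------------------------------------------------------------

def test_codon_freq_from_aa_equal_usage(drawn_params):
    aa_freq = np.full(20, 0.05)
    out = codon_freq_from_aa(aa_freq, (0.5, 0.5, 0.5), drawn_params.nuc, UNI)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)
    for ia, a in enumerate(UNI.amino_acids):
        fam = [i for i, c in enumerate(UNI.sense_codons) if UNI.translate(c) == a]
        np.testing.assert_allclose(out[fam], aa_freq[ia] / len(fam), rtol=1e-12)


def test_codon_freq_from_aa_marginalizes_back(drawn_params):
    rng = np.random.default_rng(0)
    aa_freq = rng.dirichlet(np.full(20, 5.0))
    out = codon_freq_from_aa(aa_freq, (0.2, 0.9, 0.4), drawn_params.nuc, UNI)
    for ia, a in enumerate(UNI.amino_acids):
        fam = [i for i, c in enumerate(UNI.sense_codons) if UNI.translate(c) == a]
        assert out[fam].sum() == pytest.approx(aa_freq[ia], rel=1e-12)


def test_codon_freq_from_aa_lambda_one_weights_by_q(drawn_params):
    """lambda = 1 weights each family by the mutational composition."""
    aa_freq = np.full(20, 0.05)
    q = drawn_params.nuc.q
    out = codon_freq_from_aa(aa_freq, (1.0, 1.0, 1.0), drawn_params.nuc, UNI)
    for a in UNI.amino_acids:
        fam = UNI.codons_for(a)
        w = np.array(
            [np.prod([q["ACGT".index(x)] for x in c]) for c in fam]
        )
        w = w / w.sum() * 0.05
        got = np.array([out[UNI.sense_codons.index(c)] for c in fam])
        np.testing.assert_allclose(got, w, rtol=1e-12)


def test_apply_linear_constraints():
    base = ConstraintSet.constant(-2.0)
    out = apply_linear_constraints(base, beta=0.0, w0=-0.5)
    assert set(out.w.values()) == {-0.5}
    same = apply_linear_constraints(base, beta=1.0, w0=0.0)
    assert same.w == base.w
    assert out.value("A", "A") == 0.0  # synonymous neutrality untouched
    with pytest.raises(ModelError):
        apply_linear_constraints(base, beta=-1.0, w0=0.0)


# ---------------------------------------------------------------------------
# log-odds eigenspectrum over time
# ---------------------------------------------------------------------------

def test_logodds_spectrum_properties(drawn_params, drawn_codon_freq):
    t_grid = [0.01, 0.02, 0.05, 0.1, 0.2]
    out = logodds_spectrum(drawn_params, drawn_codon_freq, t_grid)
    assert out["eigenvalues"].shape == (5, 20)
    assert np.all(np.isreal(out["eigenvalues"]))
    # sorted descending
    assert np.all(np.diff(out["eigenvalues"], axis=1) <= 1e-12)
    ref = out["ref_index"]
    np.testing.assert_allclose(
        np.diag(out["overlaps"][ref]), 1.0, atol=1e-9
    )
    # continuity: adjacent times give close leading eigenvalues
    lead = out["eigenvalues"][:, 0]
    assert np.max(np.abs(np.diff(lead))) < np.ptp(lead) + 1.0


def test_logodds_spectrum_rejects_bad_grid(drawn_params, drawn_codon_freq):
    with pytest.raises(ModelError):
        logodds_spectrum(drawn_params, drawn_codon_freq, [0.2, 0.1])
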