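"""Mechanistic reversible codon substitution model.

Mutation acts independently at the three codon positions with a shared
reversible nucleotide exchange process; simultaneous k-nucleotide changes
carry an extra factor ``sigma**(k-1)``.  Selection acts at the amino-acid
level through per-pair log fixation factors (selective constraints) ``w``,
with synonymous changes structurally neutral.  The resulting codon generator
``R`` is reversible with respect to a prescribed codon composition ``pi``
and is normalized to unit total rate, so model time is measured in expected
codon substitutions per codon.

The generator factorizes, for sense codons ``mu != nu``,

    R[mu,nu] = C * M[mu,nu] * g[mu,nu] * exp(w[a(mu), a(nu)])

where ``M`` is the mutation-rate matrix, ``g`` the frequency-dependent part
of the fixation probability (see :func:`fixation_frequency_term`), and
``C`` the normalization constant enforcing ``-sum(pi * diag(R)) = 1``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .genetic_code import (
    ALL_CODONS,
    AMINO_ACIDS,
    NUCLEOTIDES,
    GeneticCode,
    universal_code,
)

__all__ = [
    "NucleotideParams",
    "ConstraintSet",
    "CodonModelParams",
    "CodonRateMatrix",
    "RateVariationLaw",
    "codon_mutation_matrix",
    "codon_rate_matrix",
    "transition_matrix",
    "gamma_transition_matrix",
    "amino_acid_marginal",
    "log_odds",
    "rate_summaries",
    "codon_freq_from_aa",
    "apply_linear_constraints",
    "logodds_spectrum",
    "mutational_codon_composition",
    "neutral_params",
]

NEGATIVE_CLIP = 1e-12
#: Finite floor for the "least exchangeable" constraint class
#: (rate factor exp(-20) ~ 2e-9); never -inf, so likelihoods stay finite.
CONSTRAINT_FLOOR = -20.0

_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
_PAIR_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_TRANSITIONS = ("AG", "CT")
_TRANSVERSIONS = ("AC", "AT", "CG", "GT")

# codon -> per-position nucleotide indices, canonical order
_CODON_NUC = np.array(
    [[_NUC_INDEX[c] for c in codon] for codon in ALL_CODONS], dtype=int
)


class ModelError(ValueError):
    """Invalid model parameter or composition."""


class NumericalError(RuntimeError):
    """Numerical failure (eigendecomposition, excessive negative entries)."""


def _pair_key(a: str, b: str) -> str:
    return a + b if a <= b else b + a


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleotideParams:
    """Reversible nucleotide mutation parameters, shared across codon positions.

    Parameters
    ----------
    exchangeabilities
        Map over the six unordered nucleotide pairs ``AC, AG, AT, CG, CT, GT``
        of positive reals.  Only ratios are identifiable; :meth:`normalized`
        rescales so the mean transversion-type exchangeability is one.
    compositions
        Mutational equilibrium composition ``q`` over ``A, C, G, T``
        (positive, summing to one).
    """

    exchangeabilities: dict[str, float]
    compositions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if set(self.exchangeabilities) != set(_PAIR_ORDER):
            raise ModelError(
                f"exchangeabilities must cover pairs {_PAIR_ORDER}"
            )
        if any(v <= 0 for v in self.exchangeabilities.values()):
            raise ModelError("exchangeabilities must be positive")
        q = np.asarray(self.compositions, dtype=float)
        if q.shape != (4,) or np.any(q <= 0):
            raise ModelError("compositions must be 4 positive reals")
        if abs(q.sum() - 1.0) > 1e-9:
            raise ModelError("compositions must sum to 1 within 1e-9")

    @property
    def q(self) -> np.ndarray:
        return np.asarray(self.compositions, dtype=float)

    def f_matrix(self) -> np.ndarray:
        """Symmetric 4x4 exchangeability matrix (zero diagonal)."""
        f = np.zeros((4, 4))
        for pair, v in self.exchangeabilities.items():
            i, j = _NUC_INDEX[pair[0]], _NUC_INDEX[pair[1]]
            f[i, j] = f[j, i] = v
        return f

    def transversion_mean(self) -> float:
        return float(
            np.mean([self.exchangeabilities[p] for p in _TRANSVERSIONS])
        )

    def normalized(self) -> "NucleotideParams":
        """Rescale so the mean transversion exchangeability equals one."""
        s = self.transversion_mean()
        return replace(
            self,
            exchangeabilities={
                k: v / s for k, v in self.exchangeabilities.items()
            },
        )

    def ratios(self) -> dict[str, float]:
        """Exchangeabilities relative to the mean transversion exchangeability."""
        return self.normalized().exchangeabilities

    @staticmethod
    def uniform() -> "NucleotideParams":
        return NucleotideParams(
            exchangeabilities={p: 1.0 for p in _PAIR_ORDER},
            compositions=(0.25, 0.25, 0.25, 0.25),
        )


@dataclass(frozen=True)
class ConstraintSet:
    """Selective constraints: log-scale fixation factors per amino-acid pair.

    ``w[ab] = 0`` means a neutral replacement; negative values penalize it.
    Synonymous neutrality (``w[aa] = 0``) is structural and never stored.
    Pairs at :attr:`floor_value` form the "least exchangeable" class.
    """

    w: dict[str, float]
    floor_value: float = CONSTRAINT_FLOOR

    def value(self, aa_a: str, aa_b: str) -> float:
        if aa_a == aa_b:
            return 0.0
        return self.w[_pair_key(aa_a, aa_b)]

    def complete_for(self, code: GeneticCode) -> bool:
        return all(
            _pair_key(a, b) in self.w
            for a, b in itertools.combinations(code.amino_acids, 2)
        )

    def require_complete(self, code: GeneticCode) -> None:
        missing = [
            _pair_key(a, b)
            for a, b in itertools.combinations(code.amino_acids, 2)
            if _pair_key(a, b) not in self.w
        ]
        if missing:
            raise ModelError(
                f"constraint set missing pairs: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )

    def floor_pairs(self) -> list[str]:
        """Pairs pinned at the least-exchangeable floor value."""
        return sorted(k for k, v in self.w.items() if v <= self.floor_value)

    @staticmethod
    def neutral(code: GeneticCode | None = None) -> "ConstraintSet":
        code = code or universal_code()
        return ConstraintSet(
            w={
                _pair_key(a, b): 0.0
                for a, b in itertools.combinations(code.amino_acids, 2)
            }
        )

    @staticmethod
    def constant(value: float, code: GeneticCode | None = None) -> "ConstraintSet":
        code = code or universal_code()
        return ConstraintSet(
            w={
                _pair_key(a, b): float(value)
                for a, b in itertools.combinations(code.amino_acids, 2)
            }
        )


@dataclass(frozen=True)
class CodonModelParams:
    """All free quantities of the codon substitution generator.

    Parameters
    ----------
    w0
        Nonsynonymous offset added to every constraint (controls the
        nonsynonymous/synonymous rate ratio; conventionally 0 for
        amino-acid-level data).
    beta
        Nonnegative strength multiplier applied to a reference constraint
        estimate in the linear constraint map.
    sigma
        Ratio of a double-change exchangeability to a single-change one (and
        triple to double); 0 forbids simultaneous multi-nucleotide events.
    nuc
        Nucleotide mutation parameters.
    usage_lambda
        Per-position codon-usage parameters in ``[0, 1]``; 0.5 at every
        position means equal usage within each synonymous family.
    rate_var_b
        Scale-type parameter of the gamma law on time/rate; 0 disables
        rate averaging.
    constraints
        The selective-constraint set actually entering the generator.
    """

    w0: float = 0.0
    beta: float = 1.0
    sigma: float = 1.0
    nuc: NucleotideParams = field(default_factory=NucleotideParams.uniform)
    usage_lambda: tuple[float, float, float] = (0.5, 0.5, 0.5)
    rate_var_b: float = 0.0
    constraints: ConstraintSet = None  # type: ignore[assignment]
    code: GeneticCode = field(default_factory=universal_code)
    fixation_form: str = "acceptance"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ModelError("beta must be nonnegative")
        if self.sigma < 0:
            raise ModelError("sigma must be nonnegative")
        if self.rate_var_b < 0:
            raise ModelError("rate_var_b must be nonnegative")
        if any(not (0.0 <= v <= 1.0) for v in self.usage_lambda):
            raise ModelError("usage_lambda components must lie in [0, 1]")
        if self.constraints is None:
            object.__setattr__(
                self, "constraints", ConstraintSet.neutral(self.code)
            )

    def effective_constraints(self) -> ConstraintSet:
        """Constraints after the linear map ``w = beta * w_hat + w0``."""
        return apply_linear_constraints(self.constraints, self.beta, self.w0)


def neutral_params(code: GeneticCode | None = None) -> CodonModelParams:
    """Parameters with no selection and uniform mutation: a handy baseline."""
    code = code or universal_code()
    return CodonModelParams(code=code, constraints=ConstraintSet.neutral(code))


@dataclass(frozen=True)
class RateVariationLaw:
    """Gamma law on evolutionary time/rate with shape ``alpha``, scale ``b``.

    Mean ``alpha * b`` and variance ``alpha * b**2``.
    """

    alpha: float
    b: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.b <= 0:
            raise ModelError("gamma law requires alpha > 0 and b > 0")

    @property
    def mean(self) -> float:
        return self.alpha * self.b


# ---------------------------------------------------------------------------
# generator construction
# ---------------------------------------------------------------------------

def fixation_frequency_term(
    pi: np.ndarray, fmut: np.ndarray, form: str = "acceptance"
) -> np.ndarray:
    """Frequency-dependent part of the fixation probability.

    Both forms preserve detailed balance of the generator with respect to
    ``pi`` (the conditions admit a one-parameter family of symmetric-kernel
    decompositions):

    ``"acceptance"`` (default)
        ``g[mu, nu] = pi_nu / fmut_nu`` — the acceptance-rate form, the rate
        into a codon proportional to the ratio of its actual to its
        mutational frequency.  Under this form the mutational compositions
        remain identifiable from amino-acid-level data even at equal codon
        usage, matching how composition estimates behave in fits.
    ``"sqrt"``
        ``g[mu, nu] = sqrt((pi_nu / fmut_nu) / (pi_mu / fmut_mu))`` — the
        symmetric square-root member of the family; under it the
        exchangeabilities and compositions enter only through the products
        ``f(x,y) sqrt(q_x q_y)`` and are not separately identifiable.
    """
    ratio = pi / fmut
    if form == "acceptance":
        return np.broadcast_to(ratio[None, :], (len(pi), len(pi)))
    if form == "sqrt":
        return np.sqrt(ratio[None, :] / ratio[:, None])
    raise ModelError(f"unknown fixation form {form!r}")


def codon_mutation_matrix(
    nuc: NucleotideParams, sigma: float, code: GeneticCode | None = None
) -> np.ndarray:
    """Mutation-rate matrix over all 64 codons.

    For codons differing at the position set ``D`` with ``k = |D| >= 1``,

        M[mu, nu] = sigma**(k-1) * prod_{l in D} f(mu_l, nu_l) * q(nu_l),

    and the diagonal makes rows sum to zero.  ``M`` satisfies detailed
    balance with respect to the product composition
    ``f_mut[nu] = prod_l q(nu_l)``.  The *code* argument is accepted for
    interface symmetry; the mutation process is code-independent.
    """
    if sigma < 0:
        raise ModelError("sigma must be nonnegative")
    f = nuc.f_matrix()
    q = nuc.q
    n1, n2, n3 = _CODON_NUC[:, 0], _CODON_NUC[:, 1], _CODON_NUC[:, 2]
    # per-position factor: f(mu_l, nu_l) * q(nu_l) if changed else 1
    def pos_factor(ni: np.ndarray) -> np.ndarray:
        changed = ni[:, None] != ni[None, :]
        fac = f[ni[:, None], ni[None, :]] * q[ni[None, :]]
        return np.where(changed, fac, 1.0), changed

    fac1, ch1 = pos_factor(n1)
    fac2, ch2 = pos_factor(n2)
    fac3, ch3 = pos_factor(n3)
    k = ch1.astype(int) + ch2 + ch3
    M = fac1 * fac2 * fac3
    with np.errstate(invalid="ignore"):
        sig = np.where(k >= 1, float(sigma) ** np.maximum(k - 1, 0), 0.0)
    M = M * sig
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, -M.sum(axis=1))
    return M


def mutational_codon_composition(
    nuc: NucleotideParams, code: GeneticCode | None = None, sense_only: bool = True
) -> np.ndarray:
    """Product composition ``f_mut[nu] = prod_l q(nu_l)``.

    With ``sense_only`` the composition is restricted to the sense codons of
    *code* and renormalized.
    """
    q = nuc.q
    fmut = q[_CODON_NUC[:, 0]] * q[_CODON_NUC[:, 1]] * q[_CODON_NUC[:, 2]]
    if not sense_only:
        return fmut
    code = code or universal_code()
    idx = [ALL_CODONS.index(c) for c in code.sense_codons]
    out = fmut[idx]
    return out / out.sum()


@dataclass(frozen=True)
class CodonRateMatrix:
    """Normalized reversible codon generator with its stationary composition.

    ``R`` is square over the sense codons of ``code`` (canonical order),
    off-diagonals nonnegative, rows summing to zero, reversible w.r.t.
    ``pi`` and scaled by ``C`` so the total rate ``-sum(pi * diag(R))`` is 1.
    """

    R: np.ndarray
    pi: np.ndarray
    C: float
    code: GeneticCode

    @property
    def states(self) -> tuple[str, ...]:
        return self.code.sense_codons

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigenvalues and the symmetrizing transform of the generator.

        Returns ``(lam, V, d)`` where ``d = sqrt(pi)``,
        ``diag(d) R diag(1/d) = V diag(lam) V^T`` with orthonormal ``V``.
        """
        d = np.sqrt(self.pi)
        S = self.R * (d[:, None] / d[None, :])
        S = 0.5 * (S + S.T)
        try:
            lam, V = np.linalg.eigh(S)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalError(
                f"eigendecomposition failed (cond ~ {np.linalg.cond(S):.3g})"
            ) from exc
        return lam, V, d


def codon_rate_matrix(
    params: CodonModelParams, codon_freq: np.ndarray
) -> CodonRateMatrix:
    """Build the normalized reversible generator for *params*.

    *codon_freq* is the stationary composition over the sense codons of
    ``params.code`` (canonical order), strictly positive and summing to one.
    Stop codons are excluded from the state space outright, which zeroes all
    rates into termination codons.
    """
    code = params.code
    pi = np.asarray(codon_freq, dtype=float)
    n = len(code.sense_codons)
    if pi.shape != (n,):
        raise ModelError(
            f"codon_freq must have length {n} for code {code.name!r}"
        )
    if np.any(pi <= 0):
        raise ModelError("codon_freq must be strictly positive on sense codons")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ModelError("codon_freq must sum to 1")

    M64 = codon_mutation_matrix(params.nuc, params.sigma, code)
    idx = np.array([ALL_CODONS.index(c) for c in code.sense_codons])
    M = M64[np.ix_(idx, idx)]

    q = params.nuc.q
    fmut = (
        q[_CODON_NUC[idx, 0]] * q[_CODON_NUC[idx, 1]] * q[_CODON_NUC[idx, 2]]
    )
    g = fixation_frequency_term(pi, fmut, form=params.fixation_form)

    w = params.effective_constraints()
    w.require_complete(code)
    aa = [code.translate(c) for c in code.sense_codons]
    W = np.array([[w.value(a, b) for b in aa] for a in aa])

    R = M * g * np.exp(W)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    total = -float(np.dot(pi, np.diag(R)))
    if total <= 0:
        raise ModelError("degenerate generator: zero total rate")
    C = 1.0 / total
    return CodonRateMatrix(R=R * C, pi=pi, C=C, code=code)


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

def _reconstruct(rate: CodonRateMatrix, eigmap: np.ndarray) -> np.ndarray:
    lam, V, d = rate.eigensystem()
    P = (V * eigmap(lam)[None, :]) @ V.T
    P = P / d[:, None] * d[None, :]
    return _clip_stochastic(P)


def _clip_stochastic(P: np.ndarray) -> np.ndarray:
    neg = P.min()
    if neg < -NEGATIVE_CLIP:
        raise NumericalError(
            f"reconstructed transition matrix has entry {neg:.3g} "
            f"below -{NEGATIVE_CLIP:g}"
        )
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def transition_matrix(rate: CodonRateMatrix, t: float) -> np.ndarray:
    """Transition probability matrix ``P(t) = exp(R t)``.

    Computed through the symmetrized eigendecomposition; tiny negative
    entries (roundoff) are clipped to zero and rows renormalized.
    """
    if t < 0:
        raise ModelError("time must be nonnegative")
    return _reconstruct(rate, lambda lam: np.exp(lam * t))


def gamma_transition_matrix(
    rate: CodonRateMatrix, law: RateVariationLaw
) -> np.ndarray:
    """Gamma-averaged transition matrix ``int exp(R t) g(t; b, alpha) dt``.

    Closed form on the eigenbasis: eigenvalue ``lam <= 0`` maps to
    ``(1 - b*lam)**(-alpha)``.
    """
    b, alpha = law.b, law.alpha
    return _reconstruct(rate, lambda lam: (1.0 - b * lam) ** (-alpha))


def expected_transition_matrix(
    rate: CodonRateMatrix, t_bar: float, b: float
) -> np.ndarray:
    """Mean transition matrix at mean time ``t_bar``; gamma-averaged if b > 0."""
    if b > 0:
        return gamma_transition_matrix(
            rate, RateVariationLaw(alpha=t_bar / b, b=b)
        )
    return transition_matrix(rate, t_bar)


# ---------------------------------------------------------------------------
# marginals, log-odds, summaries
# ---------------------------------------------------------------------------

def amino_acid_marginal(
    P_codon: np.ndarray, codon_freq: np.ndarray, code: GeneticCode
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a codon transition matrix to the amino-acid level.

    ``P[a,b] = sum_{mu in a} sum_{nu in b} (pi_mu / pi_a) P[mu,nu]`` with
    ``pi_a = sum_{mu in a} pi_mu``.  Returns the 20x20 (or 20xN for reduced
    codes) stochastic matrix and the amino-acid composition, both in
    alphabetical amino-acid order.
    """
    pi = np.asarray(codon_freq, dtype=float)
    aas = code.amino_acids
    groups = [
        [i for i, c in enumerate(code.sense_codons) if code.translate(c) == a]
        for a in aas
    ]
    pi_aa = np.array([pi[g].sum() for g in groups])
    if np.any(pi_aa <= 0):
        bad = [a for a, p in zip(aas, pi_aa) if p <= 0]
        raise ModelError(f"amino acids with zero total frequency: {bad}")
    A = np.zeros((len(aas), len(aas)))
    for ia, ga in enumerate(groups):
        wa = pi[ga] / pi_aa[ia]
        for ib, gb in enumerate(groups):
            A[ia, ib] = wa @ P_codon[np.ix_(ga, gb)].sum(axis=1)
    return A, pi_aa


def log_odds(
    P: np.ndarray, freq: np.ndarray, scaling: str = "natural"
) -> np.ndarray:
    """Log-odds matrix ``log(P[a,b] / pi_b)``.

    ``scaling="natural"`` returns natural logs; ``"dayhoff"`` returns
    ``10 * log10`` of the odds, the constant of the original PAM log-odds
    tables.  Under detailed balance the result is symmetric.
    """
    freq = np.asarray(freq, dtype=float)
    if np.any(freq <= 0):
        raise ModelError("composition must be strictly positive")
    odds = P / freq[None, :]
    with np.errstate(divide="ignore"):
        ln = np.log(odds)
    if scaling == "natural":
        return ln
    if scaling == "dayhoff":
        return 10.0 * ln / np.log(10.0)
    raise ModelError(f"unknown scaling {scaling!r}")


def _pair_change_counts(code: GeneticCode) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per sense-codon pair: (#changed positions, #transition-type, #transversion-type)."""
    codons = code.sense_codons
    n = len(codons)
    k = np.zeros((n, n), dtype=int)
    ts = np.zeros((n, n), dtype=int)
    tv = np.zeros((n, n), dtype=int)
    for i, x in enumerate(codons):
        for j, y in enumerate(codons):
            if i == j:
                continue
            for a, b in zip(x, y):
                if a == b:
                    continue
                k[i, j] += 1
                if _pair_key(a, b) in _TRANSITIONS:
                    ts[i, j] += 1
                else:
                    tv[i, j] += 1
    return k, ts, tv


def rate_summaries(rate: CodonRateMatrix, code: GeneticCode | None = None) -> dict:
    """Per-codon rate ratios: base/codon, transition/transversion, dN/dS.

    ``base_per_codon`` is the total nucleotide substitution rate per codon
    divided by the codon substitution rate (the mean number of nucleotide
    changes per codon event; 1 exactly when ``sigma = 0``).  The transition
    and transversion rates count changed positions by type and sum to the
    base rate.  ``nonsyn_over_syn`` is the per-codon (not per-site)
    nonsynonymous/synonymous rate ratio.
    """
    code = code or rate.code
    k, ts, tv = _pair_change_counts(code)
    flux = rate.pi[:, None] * rate.R
    np.fill_diagonal(flux, 0.0)
    codon_rate = float(flux.sum())
    base_rate = float((flux * k).sum())
    ts_rate = float((flux * ts).sum())
    tv_rate = float((flux * tv).sum())
    aa = np.array([code.translate(c) for c in code.sense_codons])
    nonsyn_mask = aa[:, None] != aa[None, :]
    nonsyn = float(flux[nonsyn_mask].sum())
    syn = codon_rate - nonsyn
    return {
        "codon_rate": codon_rate,
        "base_rate": base_rate,
        "ts_rate": ts_rate,
        "tv_rate": tv_rate,
        "base_per_codon": base_rate / codon_rate,
        "ts_over_tv": ts_rate / tv_rate if tv_rate > 0 else np.inf,
        "nonsyn_rate": nonsyn,
        "syn_rate": syn,
        "nonsyn_over_syn": nonsyn / syn if syn > 0 else np.inf,
    }


def codon_freq_from_aa(
    aa_freq: np.ndarray,
    usage_lambda: tuple[float, float, float],
    nuc: NucleotideParams,
    code: GeneticCode,
) -> np.ndarray:
    """Codon composition from an amino-acid composition and usage parameters.

    Within each synonymous family, codon ``nu`` gets weight
    ``prod_l q(nu_l)**(2*lambda_l - 1)`` normalized over the family and then
    scaled by the family's amino-acid frequency.  ``lambda = (.5, .5, .5)``
    gives equal usage within every family; ``lambda = (1, 1, 1)`` weights
    codons by the mutational composition.
    """
    aa_freq = np.asarray(aa_freq, dtype=float)
    aas = code.amino_acids
    if aa_freq.shape != (len(aas),):
        raise ModelError(
            f"aa_freq must have length {len(aas)} for code {code.name!r}"
        )
    if abs(aa_freq.sum() - 1.0) > 1e-8:
        raise ModelError("aa_freq must sum to 1")
    lam = np.asarray(usage_lambda, dtype=float)
    q = nuc.q
    out = np.zeros(len(code.sense_codons))
    for ia, a in enumerate(aas):
        idxs = [
            i for i, c in enumerate(code.sense_codons) if code.translate(c) == a
        ]
        w = np.ones(len(idxs))
        for pos in range(3):
            ql = q[_CODON_NUC[[ALL_CODONS.index(code.sense_codons[i]) for i in idxs], pos]]
            w = w * ql ** (2.0 * lam[pos] - 1.0)
        out[idxs] = aa_freq[ia] * w / w.sum()
    return out


def apply_linear_constraints(
    w_hat: ConstraintSet, beta: float, w0: float
) -> ConstraintSet:
    """Linear constraint map ``w_ab = beta * w_hat_ab + w0`` (diagonal stays 0)."""
    if beta < 0:
        raise ModelError("beta must be nonnegative")
    return ConstraintSet(
        w={k: beta * v + w0 for k, v in w_hat.w.items()},
        floor_value=beta * w_hat.floor_value + w0,
    )


def logodds_spectrum(
    params: CodonModelParams,
    codon_freq: np.ndarray,
    t_grid: list[float],
    ref_index: int = -1,
) -> dict:
    """Eigenspectrum of the amino-acid log-odds matrix along a time grid.

    For each time the codon transition matrix is built, marginalized to
    amino acids, converted to natural log-odds, symmetrized, and
    diagonalized.  Eigenvalues are sorted in descending order; eigenvector
    overlaps are reported against the spectrum at ``t_grid[ref_index]``.
    """
    t_grid = list(t_grid)
    if any(t <= 0 for t in t_grid) or sorted(t_grid) != t_grid:
        raise ModelError("t_grid must be positive and increasing")
    rate = codon_rate_matrix(params, codon_freq)
    eigvals, eigvecs = [], []
    for t in t_grid:
        P = transition_matrix(rate, t)
        A, pi_aa = amino_acid_marginal(P, rate.pi, params.code)
        L = log_odds(A, pi_aa)
        L = 0.5 * (L + L.T)
        lam, V = np.linalg.eigh(L)
        order = np.argsort(lam)[::-1]
        eigvals.append(lam[order])
        eigvecs.append(V[:, order])
    ref = eigvecs[ref_index]
    overlaps = [np.abs(ref.T @ V) for V in eigvecs]
    return {
        "t_grid": np.asarray(t_grid),
        "eigenvalues": np.vstack(eigvals),
        "eigenvectors": eigvecs,
        "overlaps": overlaps,
        "ref_index": ref_index % len(t_grid),
    }
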