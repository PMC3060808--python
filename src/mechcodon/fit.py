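"""Maximum-likelihood fitting of the codon model to empirical 1-PAM matrices.

An empirical input is a row-stochastic 1-PAM substitution matrix (amino-acid
20x20 or codon 61x61) with its composition, assumed stationary, and an
effective number of site comparisons ``N``.  The multinomial log-likelihood

    l = N * sum_ab pi_a P_obs[a,b] * ln P_model[a,b]

is maximized over a configurable subset of model parameters with the
Nelder-Mead simplex.  The gamma time-scale is never optimized directly:
inside every objective evaluation the mean time ``t_bar`` (and hence the
shape ``alpha = t_bar / b``) is re-solved so the model's expected
substitution fraction matches the observed one (moment matching at the
1-PAM definition, ``sum_a pi_a (1 - P_aa) = 0.01`` for true 1-PAM inputs).

Model goodness is reported as the plug-in Kullback-Leibler divergence of the
observed from the model transition distribution, and as AIC / delta-AIC,
``delta_aic = 2 N kl_hat + 2 k`` with the saturated model (the empirical
matrix itself) as baseline, so delta-AIC is nonnegative by construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, minimize

from .genetic_code import AMINO_ACIDS, GeneticCode, universal_code
from .model import (
    CodonModelParams,
    CodonRateMatrix,
    ConstraintSet,
    ModelError,
    NucleotideParams,
    NumericalError,
    RateVariationLaw,
    amino_acid_marginal,
    codon_freq_from_aa,
    codon_rate_matrix,
    log_odds,
    rate_summaries,
)

__all__ = [
    "EmpiricalSubstitutionMatrix",
    "FitConfig",
    "FitResult",
    "SolvedTimeScale",
    "one_pam_from_exchangeabilities",
    "expected_substitution_fraction",
    "solve_gamma_shape",
    "log_likelihood",
    "kl_and_aic",
    "fit",
    "fit_plus",
    "group_multistep_pairs",
    "expand_preset",
    "total_parameter_count",
    "general_reversible_freedoms",
    "PRESET_ID_SETS",
]

NEG_INF = float("-inf")

#: Scalar parameter ids, following the convention that 0 is the
#: nonsynonymous offset, 1 the constraint-strength multiplier, 2 the
#: multi-change ratio, 3-7 five free exchangeability ratios (the sixth is a
#: gauge), 8-10 the three mutational composition freedoms, 11-13 the three
#: codon-usage parameters, and 14 the gamma scale parameter.
ID_W0, ID_BETA, ID_SIGMA = 0, 1, 2
ID_EXCH = (3, 4, 5, 6, 7)          # log f_AC, f_AG, f_AT, f_CG, f_CT (f_GT = 1 gauge)
ID_COMP = (8, 9, 10)               # q via (AT-content, A/(A+T), G/(G+C))
ID_LAMBDA = (11, 12, 13)
ID_B = 14
_EXCH_PAIRS = ("AC", "AG", "AT", "CG", "CT")  # GT is the gauge pair


class FitError(RuntimeError):
    """Fitting or time-scale solving failure."""


# ---------------------------------------------------------------------------
# empirical inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalSubstitutionMatrix:
    """An observed 1-PAM transition matrix with composition and comparison count.

    ``pi_obs`` is assumed to be the stationary composition of ``P_obs``
    (recorded, not enforced).  ``N`` may be ``None`` when the effective
    number of site comparisons is unknown; the likelihood and delta-AIC are
    then unavailable but the K-L objective is not.
    """

    level: str
    states: tuple[str, ...]
    P_obs: np.ndarray
    pi_obs: np.ndarray
    N: float | None = None
    name: str = "empirical"

    def __post_init__(self) -> None:
        if self.level not in ("amino_acid", "codon"):
            raise ModelError(f"level must be amino_acid or codon, got {self.level!r}")
        P = np.asarray(self.P_obs, dtype=float)
        pi = np.asarray(self.pi_obs, dtype=float)
        n = len(self.states)
        if P.shape != (n, n):
            raise ModelError(f"P_obs must be {n}x{n}, got {P.shape}")
        if np.any(~np.isfinite(P)) or np.any(P < 0):
            raise ModelError("P_obs must be finite and nonnegative")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-6:
            raise ModelError("rows of P_obs must sum to 1 within 1e-6")
        if abs(pi.sum() - 1.0) > 1e-6 or np.any(pi < 0):
            raise ModelError("pi_obs must be a composition")
        if self.N is not None and self.N <= 0:
            raise ModelError("N must be positive when given")
        object.__setattr__(self, "P_obs", P)
        object.__setattr__(self, "pi_obs", pi)
        frac = expected_substitution_fraction(P, pi)
        if not (0.005 <= frac <= 0.02):
            warnings.warn(
                f"{self.name}: substitution fraction {frac:.4g} outside "
                "[0.005, 0.02]; input may not be a 1-PAM matrix",
                stacklevel=2,
            )

    @property
    def substitution_fraction(self) -> float:
        return expected_substitution_fraction(self.P_obs, self.pi_obs)

    def zero_cell_count(self) -> int:
        """Observed cells with zero frequency (they contribute 0 to l and kl)."""
        off = self.P_obs.copy()
        return int(np.sum(off == 0.0))


def expected_substitution_fraction(P: np.ndarray, freq: np.ndarray) -> float:
    """Expected fraction of sites substituted: ``sum_a pi_a (1 - P_aa)``."""
    P = np.asarray(P, dtype=float)
    freq = np.asarray(freq, dtype=float)
    return float(np.dot(freq, 1.0 - np.diag(P)))


def one_pam_from_exchangeabilities(
    S: np.ndarray,
    freq: np.ndarray,
    N: float | None = None,
    level: str = "amino_acid",
    states: tuple[str, ...] | None = None,
    name: str = "one_pam",
    target: float = 0.01,
) -> EmpiricalSubstitutionMatrix:
    """1-PAM transition matrix from a symmetric exchangeability matrix.

    ``Q[a,b] = S[a,b] * freq[b]`` off-diagonal, diagonal minus row sums; the
    time ``t*`` is solved so the expected substitution fraction equals
    *target* (0.01 for 1 PAM), and ``exp(Q t*)`` is returned.
    """
    S = np.asarray(S, dtype=float)
    freq = np.asarray(freq, dtype=float)
    n = len(freq)
    if S.shape != (n, n):
        raise ModelError("S and freq have incompatible shapes")
    if np.max(np.abs(S - S.T)) > 1e-8 * max(1.0, np.max(np.abs(S))):
        raise ModelError("exchangeability matrix must be symmetric")
    if np.any(freq <= 0):
        raise ModelError("freq must be strictly positive")
    Q = S * freq[None, :]
    np.fill_diagonal(Q, 0.0)
    if np.any(Q < 0):
        raise ModelError("off-diagonal exchangeabilities must be nonnegative")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    d = np.sqrt(freq)
    sym = Q * (d[:, None] / d[None, :])
    lam, V = np.linalg.eigh(0.5 * (sym + sym.T))
    if np.sum(lam > -1e-12 * max(1.0, np.max(np.abs(lam)))) > 1:
        raise ModelError("exchangeability matrix is reducible")
    s = _diag_weights(V, d, [[i] for i in range(n)])

    def frac(t: float) -> float:
        return 1.0 - float(s @ np.exp(lam * t))

    max_frac = 1.0 - float(freq @ freq)
    if not (0.0 < target < max_frac):
        raise FitError(f"target fraction {target} unattainable (max {max_frac:.4g})")
    hi = 1.0
    while frac(hi) < target:
        hi *= 4.0
    t_star = brentq(lambda t: frac(t) - target, 0.0, hi, xtol=1e-16, rtol=8.9e-16)
    P = (V * np.exp(lam * t_star)[None, :]) @ V.T
    P = P / d[:, None] * d[None, :]
    P = np.clip(P, 0.0, None)
    P = P / P.sum(axis=1, keepdims=True)
    if states is None:
        states = tuple(AMINO_ACIDS) if n == 20 else tuple(str(i) for i in range(n))
    return EmpiricalSubstitutionMatrix(
        level=level, states=tuple(states), P_obs=P, pi_obs=freq, N=N, name=name
    )


# ---------------------------------------------------------------------------
# time-scale solving (moment matching)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolvedTimeScale:
    """Moment-matched time scale: mean time and, when ``b > 0``, the gamma law."""

    t_bar: float
    b: float

    @property
    def alpha(self) -> float | None:
        return self.t_bar / self.b if self.b > 0 else None

    @property
    def law(self) -> RateVariationLaw | None:
        if self.b > 0:
            return RateVariationLaw(alpha=self.t_bar / self.b, b=self.b)
        return None


def _diag_weights(V: np.ndarray, d: np.ndarray, groups: list[list[int]]) -> np.ndarray:
    """Spectral weights s_j with sum_j s_j m_j(t) = sum_groups pi-block mass.

    For groups of states (synonymous families, or singletons at codon
    level), ``1 - sum_j s_j m_j(t)`` is the expected substitution fraction
    at that level, where ``m_j`` is the per-eigenvalue time map.
    """
    s = np.zeros(V.shape[1])
    for g in groups:
        w = d[g] @ V[g, :]
        s += w * w
    return s


def _model_machinery(
    params: CodonModelParams, empirical: EmpiricalSubstitutionMatrix
) -> tuple[CodonRateMatrix, np.ndarray, np.ndarray, np.ndarray, list[list[int]]]:
    """Generator, eigensystem, and aggregation groups for *empirical*'s level."""
    code = params.code
    if empirical.level == "codon":
        if tuple(empirical.states) != code.sense_codons:
            raise ModelError(
                "codon-level empirical states must match the code's sense codons"
            )
        codon_freq = empirical.pi_obs
        groups = [[i] for i in range(len(code.sense_codons))]
    else:
        if tuple(empirical.states) != tuple(code.amino_acids):
            raise ModelError(
                "amino-acid-level empirical states must match the code's amino acids"
            )
        codon_freq = codon_freq_from_aa(
            empirical.pi_obs, params.usage_lambda, params.nuc, code
        )
        groups = [
            [
                i
                for i, c in enumerate(code.sense_codons)
                if code.translate(c) == a
            ]
            for a in code.amino_acids
        ]
    rate = codon_rate_matrix(params, codon_freq)
    lam, V, d = rate.eigensystem()
    return rate, lam, V, d, groups


def solve_gamma_shape(
    params: CodonModelParams,
    empirical: EmpiricalSubstitutionMatrix,
    tol: float = 1e-12,
) -> SolvedTimeScale:
    """Solve the mean time so the model matches the observed substitution fraction.

    With ``b = params.rate_var_b > 0`` the gamma-averaged matrix is used and
    the solved quantity fixes the shape ``alpha = t_bar / b``; with ``b = 0``
    it is a pure point time.  Matching is done at the empirical matrix's
    level (amino-acid matrices are compared after marginalization).
    """
    _, lam, V, d, groups = _model_machinery(params, empirical)
    target = empirical.substitution_fraction
    return _solve_t_bar(lam, V, d, groups, target, params.rate_var_b, tol)


def _solve_t_bar(
    lam: np.ndarray,
    V: np.ndarray,
    d: np.ndarray,
    groups: list[list[int]],
    target: float,
    b: float,
    tol: float = 1e-12,
) -> SolvedTimeScale:
    s = _diag_weights(V, d, groups)
    max_frac = 1.0 - float(np.sum([np.sum(d[g] ** 2) ** 2 for g in groups]))

    if b > 0:
        base = np.log1p(-b * np.minimum(lam, 0.0)) / b  # (1-b*lam)^(-t/b)

        def frac(t: float) -> float:
            return 1.0 - float(s @ np.exp(-t * base))
    else:

        def frac(t: float) -> float:
            return 1.0 - float(s @ np.exp(lam * t))

    if not (0.0 < target < max_frac):
        raise FitError(
            f"target substitution fraction {target:.4g} outside attainable "
            f"range (0, {max_frac:.4g})"
        )
    hi = 1.0
    while frac(hi) < target and hi < 1e12:
        hi *= 4.0
    t_bar = brentq(lambda t: frac(t) - target, 0.0, hi, xtol=tol * 1e-2, rtol=8.9e-16)
    return SolvedTimeScale(t_bar=float(t_bar), b=float(b))


# ---------------------------------------------------------------------------
# likelihood, K-L, AIC
# ---------------------------------------------------------------------------

def log_likelihood(
    empirical: EmpiricalSubstitutionMatrix, P_model: np.ndarray
) -> float:
    """Multinomial log-likelihood of the observed 1-PAM frequencies.

    Cells with zero observed frequency contribute nothing; a zero model
    probability at an observed cell yields ``-inf``.
    """
    if empirical.N is None:
        raise FitError(
            f"{empirical.name}: N is unknown, log-likelihood unavailable "
            "(use the K-L estimate instead)"
        )
    counts = empirical.pi_obs[:, None] * empirical.P_obs
    mask = counts > 0
    if np.any(P_model[mask] <= 0):
        return NEG_INF
    return float(empirical.N * np.sum(counts[mask] * np.log(P_model[mask])))


def kl_divergence(
    empirical: EmpiricalSubstitutionMatrix, P_model: np.ndarray
) -> float:
    """Plug-in K-L estimate sum pi_a P_obs ln(P_obs / P_model); >= 0."""
    counts = empirical.pi_obs[:, None] * empirical.P_obs
    mask = counts > 0
    if np.any(P_model[mask] <= 0):
        return float("inf")
    return float(
        np.sum(counts[mask] * (np.log(empirical.P_obs[mask]) - np.log(P_model[mask])))
    )


def kl_and_aic(
    empirical: EmpiricalSubstitutionMatrix,
    P_model: np.ndarray,
    n_params: int,
) -> dict:
    """K-L estimate, AIC and delta-AIC (vs the saturated model) of *P_model*."""
    kl = kl_divergence(empirical, P_model)
    out = {"kl_hat": kl, "aic": None, "delta_aic": None}
    if empirical.N is not None:
        l = log_likelihood(empirical, P_model)
        out["aic"] = -2.0 * l + 2.0 * n_params
        out["delta_aic"] = 2.0 * empirical.N * kl + 2.0 * n_params
    return out


# ---------------------------------------------------------------------------
# parameter masks and presets
# ---------------------------------------------------------------------------

#: Printed free-parameter id sets for the linear-constraint model families,
#: keyed by the model-name suffix (the number of scalar ML parameters).
PRESET_ID_SETS: dict[str, tuple[int, ...]] = {
    "0": (),
    "1": (14,),
    "2": (1, 3),
    "2G": (1, 14),
    "3": (1, 3, 14),
    "4": (1, 2, 3, 14),
    "7": (1, 2, 3, 8, 9, 10, 14),
    "8": (1, 2, 3, 4, 5, 6, 7, 14),
    "10": (1, 3, 4, 5, 6, 7, 8, 9, 10, 14),
    "10M": (1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    "10MU": (1, 2, 3, 8, 9, 10, 11, 12, 13, 14),
    "11": (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 14),
    "12": (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 14),
    "13": (1, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14),
    "14": (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14),
}

#: The constraint-free family has no strength/offset freedom (beta is pinned
#: at zero), so its printed masks differ from the other linear families.
NO_CONSTRAINTS_ID_SETS: dict[str, tuple[int, ...]] = {
    "0": (),
    "1": (3,),
    "10": (2, 3, 4, 5, 6, 7, 8, 9, 10, 14),
    "13": (2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14),
}

#: Constraint-block tokens usable in a free mask.
W_SINGLE = "w_single"          # one w per single-step pair
W_MULTI_GROUPS = "w_multi_groups"  # one w per multi-step group
W_ALL = "w_all"                # one w per amino-acid pair (190 universal)
W_MULTI_PAIRS = "w_multi_pairs"    # one w per multi-step pair (the "+" refit)


@dataclass
class FitConfig:
    """What to optimize and how.

    ``free`` is a tuple of scalar parameter ids (0-14) and constraint-block
    tokens.  ``preset`` names expand to the standard masks: ``ML-87`` (all
    single-step constraints, stepwise only), ``ML-91``/``ML-94`` (plus six
    grouped multi-step classes), ``ML-200`` (codon level, all pairs), and
    ``<source>-<n>`` linear-constraint families where *n* indexes
    :data:`PRESET_ID_SETS` and *source* supplies the reference constraints.
    """

    preset: str | None = None
    free: tuple = ()
    fixed_values: dict = field(default_factory=dict)
    constraint_source: ConstraintSet | None = None
    multi_groups: dict[str, int] | None = None
    n_groups: int = 6
    init: CodonModelParams | None = None
    code: GeneticCode = field(default_factory=universal_code)
    maxiter: int = 100_000
    fatol: float = 1e-8
    xatol: float = 1e-6
    restarts: int = 3
    seed: int = 0

    def expanded(self) -> "FitConfig":
        if self.preset is None:
            return self
        return expand_preset(self.preset, self)


def expand_preset(name: str, base: FitConfig | None = None) -> FitConfig:
    """Expand a preset name into a concrete :class:`FitConfig` mask."""
    cfg = base or FitConfig()
    fixed = dict(cfg.fixed_values)
    if name == "ML-87":
        free = (W_SINGLE,) + ID_EXCH + ID_COMP + ID_LAMBDA + (ID_B,)
        fixed.setdefault("sigma", 0.0)
        fixed.setdefault("w0", 0.0)
    elif name == "ML-91":
        free = (W_SINGLE, W_MULTI_GROUPS, ID_SIGMA) + ID_EXCH + ID_COMP + (ID_B,)
        fixed.setdefault("usage_lambda", (0.5, 0.5, 0.5))
        fixed.setdefault("w0", 0.0)
    elif name == "ML-94":
        free = (
            (W_SINGLE, W_MULTI_GROUPS, ID_SIGMA)
            + ID_EXCH
            + ID_COMP
            + ID_LAMBDA
            + (ID_B,)
        )
        fixed.setdefault("w0", 0.0)
    elif name == "ML-200":
        free = (W_ALL, ID_SIGMA) + ID_EXCH + ID_COMP + (ID_B,)
        fixed.setdefault("w0", 0.0)
    else:
        # linear-constraint family: "<source>-<suffix>"
        try:
            prefix, suffix = name.rsplit("-", 1)
            table = (
                NO_CONSTRAINTS_ID_SETS
                if prefix == "No-Constraints"
                else PRESET_ID_SETS
            )
            ids = table[suffix]
        except (ValueError, KeyError):
            raise FitError(f"unknown preset {name!r}") from None
        free = tuple(ids)
        if cfg.constraint_source is None and prefix != "No-Constraints":
            raise FitError(
                f"preset {name!r} needs a constraint_source reference set"
            )
        if prefix == "No-Constraints":
            fixed.setdefault("beta", 0.0)
        if ID_W0 not in ids:
            fixed.setdefault("w0", 0.0)
        if ID_BETA not in ids and prefix != "No-Constraints":
            fixed.setdefault("beta", 1.0)
    return replace(cfg, preset=None, free=free, fixed_values=fixed)


def _mask_size(cfg: FitConfig, code: GeneticCode) -> int:
    classes = code.pair_step_classes()
    n = 0
    for tok in cfg.free:
        if tok == W_SINGLE:
            n += sum(1 for k in classes.values() if k == 1)
        elif tok == W_MULTI_GROUPS:
            n += cfg.n_groups
        elif tok == W_ALL:
            n += len(classes)
        elif tok == W_MULTI_PAIRS:
            n += sum(1 for k in classes.values() if k >= 2)
        else:
            n += 1
    return n


def total_parameter_count(n_scalar: int, level: str, code: GeneticCode) -> int:
    """Total fitted freedoms: mask size plus compositions plus the shape parameter."""
    n_states = (
        len(code.sense_codons) if level == "codon" else len(code.amino_acids)
    )
    return n_scalar + (n_states - 1) + 1


def general_reversible_freedoms(n_states: int) -> int:
    """Freedoms of a general reversible model: exchangeabilities + frequencies."""
    return n_states * (n_states - 1) // 2 + (n_states - 1)


# ---------------------------------------------------------------------------
# parameter vector encoding
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return float(np.log(p / (1.0 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _q_to_theta(q: np.ndarray) -> tuple[float, float, float]:
    a, c, g, t = q
    at, gc = a + t, g + c
    return (at, a / at, g / gc)


def _theta_to_q(theta: tuple[float, float, float]) -> tuple[float, ...]:
    at, ra, rg = theta
    a, t = at * ra, at * (1.0 - ra)
    g, c = (1.0 - at) * rg, (1.0 - at) * (1.0 - rg)
    return (a, c, g, t)


def _sorted_pairs(code: GeneticCode, which: str, classes=None) -> list[str]:
    classes = classes or code.pair_step_classes()
    keys = sorted("".join(sorted(p)) for p in classes)
    if which == "single":
        return [k for k in keys if classes[frozenset(k)] == 1]
    if which == "multi":
        return [k for k in keys if classes[frozenset(k)] >= 2]
    return keys


class _ParamCodec:
    """Bijective map between a FitConfig mask and a flat optimizer vector."""

    def __init__(self, cfg: FitConfig, base: CodonModelParams):
        self.cfg = cfg
        self.base = base
        self.code = base.code
        self.classes = self.code.pair_step_classes()
        self.scalar_ids = [t for t in cfg.free if isinstance(t, int)]
        self.blocks = [t for t in cfg.free if not isinstance(t, int)]
        self.single_keys = _sorted_pairs(self.code, "single", self.classes)
        self.multi_keys = _sorted_pairs(self.code, "multi", self.classes)
        self.all_keys = _sorted_pairs(self.code, "all", self.classes)
        if W_MULTI_GROUPS in self.blocks and cfg.multi_groups is None:
            raise FitError(
                "mask frees grouped multi-step constraints but no grouping "
                "map was provided (run group_multistep_pairs first)"
            )

    # -- initial vector --------------------------------------------------

    def encode(self, params: CodonModelParams) -> np.ndarray:
        x: list[float] = []
        ex = params.nuc.exchangeabilities
        gauge = ex["GT"]
        theta = _q_to_theta(params.nuc.q)
        for i in self.scalar_ids:
            if i == ID_W0:
                x.append(params.w0)
            elif i == ID_BETA:
                x.append(np.log(max(params.beta, 1e-8)))
            elif i == ID_SIGMA:
                x.append(np.log(max(params.sigma, 1e-8)))
            elif i in ID_EXCH:
                pair = _EXCH_PAIRS[ID_EXCH.index(i)]
                x.append(np.log(ex[pair] / gauge))
            elif i in ID_COMP:
                x.append(_logit(theta[ID_COMP.index(i)]))
            elif i in ID_LAMBDA:
                x.append(_logit(params.usage_lambda[ID_LAMBDA.index(i)]))
            elif i == ID_B:
                x.append(np.log(max(params.rate_var_b, 1e-8)))
            else:
                raise FitError(f"unknown parameter id {i}")
        w = params.constraints.w
        for tok in self.blocks:
            if tok == W_SINGLE:
                x.extend(w.get(k, -1.0) for k in self.single_keys)
            elif tok == W_MULTI_GROUPS:
                groups = self.cfg.multi_groups
                means = []
                for g in range(self.cfg.n_groups):
                    vals = [w[k] for k in self.multi_keys if groups.get(k) == g]
                    means.append(float(np.mean(vals)) if vals else -3.0)
                x.extend(means)
            elif tok == W_MULTI_PAIRS:
                x.extend(w.get(k, -3.0) for k in self.multi_keys)
            elif tok == W_ALL:
                x.extend(w.get(k, -1.0) for k in self.all_keys)
        return np.asarray(x, dtype=float)

    # -- decode ----------------------------------------------------------

    def decode(self, x: np.ndarray) -> CodonModelParams:
        p = self.base
        fixed = self.cfg.fixed_values
        w0 = fixed.get("w0", p.w0)
        beta = fixed.get("beta", p.beta)
        sigma = fixed.get("sigma", p.sigma)
        b = fixed.get("rate_var_b", p.rate_var_b)
        lam = list(fixed.get("usage_lambda", p.usage_lambda))
        ex = dict(p.nuc.exchangeabilities)
        gauge = ex["GT"]  # f_GT stays put; freed pairs move relative to it
        theta = list(_q_to_theta(p.nuc.q))
        j = 0
        for i in self.scalar_ids:
            v = float(x[j]); j += 1
            if i == ID_W0:
                w0 = v
            elif i == ID_BETA:
                beta = float(np.exp(v))
            elif i == ID_SIGMA:
                sigma = float(np.exp(v))
            elif i in ID_EXCH:
                ex[_EXCH_PAIRS[ID_EXCH.index(i)]] = float(np.exp(v)) * gauge
            elif i in ID_COMP:
                theta[ID_COMP.index(i)] = _expit(v)
            elif i in ID_LAMBDA:
                lam[ID_LAMBDA.index(i)] = _expit(v)
            elif i == ID_B:
                b = float(np.exp(v))
        w = dict(p.constraints.w)
        for tok in self.blocks:
            if tok == W_SINGLE:
                for k in self.single_keys:
                    w[k] = float(x[j]); j += 1
            elif tok == W_MULTI_GROUPS:
                gv = [float(x[j + g]) for g in range(self.cfg.n_groups)]
                j += self.cfg.n_groups
                groups = self.cfg.multi_groups
                for k in self.multi_keys:
                    w[k] = gv[groups[k]]
            elif tok == W_MULTI_PAIRS:
                for k in self.multi_keys:
                    w[k] = float(x[j]); j += 1
            elif tok == W_ALL:
                for k in self.all_keys:
                    w[k] = float(x[j]); j += 1
        nuc = NucleotideParams(
            exchangeabilities=ex, compositions=_theta_to_q(tuple(theta))
        )
        return replace(
            p,
            w0=w0,
            beta=beta,
            sigma=sigma,
            nuc=nuc,
            usage_lambda=tuple(lam),
            rate_var_b=b,
            constraints=ConstraintSet(w=w, floor_value=p.constraints.floor_value),
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params_hat: CodonModelParams
    kl_hat: float
    loglik: float | None
    n_params: int
    aic: float | None
    delta_aic: float | None
    t_bar: float
    alpha_hat: float | None
    summaries: dict
    converged: bool
    n_evaluations: int
    trace: list = field(default_factory=list)
    config: FitConfig | None = None
    empirical_name: str = ""
    multi_step_ml: bool = True  # False for "+"-refit multi-step values
    P_model: np.ndarray | None = None

    @property
    def time_scale(self) -> SolvedTimeScale:
        return SolvedTimeScale(t_bar=self.t_bar, b=self.params_hat.rate_var_b)


def _evaluate(
    params: CodonModelParams, empirical: EmpiricalSubstitutionMatrix
) -> tuple[float, np.ndarray, SolvedTimeScale, CodonRateMatrix]:
    """K-L of the moment-matched model matrix against the empirical one."""
    rate, lam, V, d, groups = _model_machinery(params, empirical)
    scale = _solve_t_bar(
        lam, V, d, groups, empirical.substitution_fraction, params.rate_var_b
    )
    if scale.b > 0:
        base = np.log1p(-params.rate_var_b * np.minimum(lam, 0.0)) / scale.b
        eig = np.exp(-scale.t_bar * base)
    else:
        eig = np.exp(lam * scale.t_bar)
    P = (V * eig[None, :]) @ V.T
    P = P / d[:, None] * d[None, :]
    P = np.clip(P, 0.0, None)
    P = P / P.sum(axis=1, keepdims=True)
    if empirical.level == "amino_acid":
        P, _ = amino_acid_marginal(P, rate.pi, params.code)
    kl = kl_divergence(empirical, P)
    return kl, P, scale, rate


def evaluate_params(
    params: CodonModelParams,
    empirical: EmpiricalSubstitutionMatrix,
    n_params: int = 0,
) -> FitResult:
    """Pure evaluation of fixed parameters against an empirical matrix."""
    kl, P, scale, rate = _evaluate(params, empirical)
    ll = log_likelihood(empirical, P) if empirical.N is not None else None
    stats = kl_and_aic(empirical, P, n_params)
    return FitResult(
        params_hat=params,
        kl_hat=kl,
        loglik=ll,
        n_params=n_params,
        aic=stats["aic"],
        delta_aic=stats["delta_aic"],
        t_bar=scale.t_bar,
        alpha_hat=scale.alpha,
        summaries=rate_summaries(rate),
        converged=True,
        n_evaluations=1,
        empirical_name=empirical.name,
        P_model=P,
    )


def fit(
    empirical: EmpiricalSubstitutionMatrix, config: FitConfig
) -> FitResult:
    """Maximize the likelihood of *empirical* over the configured free mask.

    The objective is the (N-independent) K-L divergence; the gamma law is
    profiled out inside every evaluation by moment matching.  Nelder-Mead
    with seeded random restarts; determinism follows from the seed.
    """
    cfg = config.expanded()
    code = cfg.code
    if empirical.level == "codon" and any(t in ID_LAMBDA for t in cfg.free):
        raise FitError(
            "codon-usage parameters are only meaningful for amino-acid-level "
            "fits; codon-level compositions are pinned to the observed ones"
        )

    base = cfg.init or CodonModelParams(
        code=code, constraints=ConstraintSet.neutral(code)
    )
    if cfg.constraint_source is not None:
        base = replace(base, constraints=cfg.constraint_source)
    fixed = cfg.fixed_values
    base = replace(
        base,
        w0=fixed.get("w0", base.w0),
        beta=fixed.get("beta", base.beta),
        sigma=fixed.get("sigma", base.sigma),
        rate_var_b=fixed.get("rate_var_b", base.rate_var_b),
        usage_lambda=tuple(fixed.get("usage_lambda", base.usage_lambda)),
    )
    if "constraints" in fixed:
        base = replace(base, constraints=fixed["constraints"])

    codec = _ParamCodec(cfg, base)
    n_params = _mask_size(cfg, code)
    trace: list[tuple[int, float]] = []
    n_eval = 0

    if n_params == 0:
        result = evaluate_params(base, empirical, n_params=0)
        result.config = cfg
        return result

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            params = codec.decode(x)
            kl, _, _, _ = _evaluate(params, empirical)
        except (ModelError, NumericalError, FitError, FloatingPointError):
            return 1e6
        if not np.isfinite(kl):
            return 1e6
        trace.append((n_eval, kl))
        return kl

    x0 = codec.encode(base)
    rng = np.random.default_rng(cfg.seed)
    best = None
    start = x0
    for attempt in range(max(1, cfg.restarts)):
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={
                "maxiter": cfg.maxiter,
                "maxfev": cfg.maxiter,
                "fatol": cfg.fatol,
                "xatol": cfg.xatol,
                "adaptive": len(start) > 6,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        start = best.x + rng.normal(scale=0.05, size=len(x0))

    params_hat = codec.decode(best.x)
    result = evaluate_params(params_hat, empirical, n_params=n_params)
    result.converged = bool(best.success)
    result.n_evaluations = n_eval
    result.trace = trace
    result.config = cfg
    return result


def fit_plus(
    empirical: EmpiricalSubstitutionMatrix, base: FitResult
) -> FitResult:
    """The "+" refit: free per-pair multi-step constraints, fix all else.

    Single-step constraints and every scalar parameter stay at the *base*
    estimates; only multi-step pair values move.  The refitted multi-step
    values maximize the likelihood conditionally on the base fit and are
    therefore not joint ML estimates; ``multi_step_ml`` is flagged False.
    """
    cfg0 = base.config or FitConfig(code=base.params_hat.code)
    cfg = replace(
        cfg0,
        preset=None,
        free=(W_MULTI_PAIRS,),
        init=base.params_hat,
        fixed_values={},
        constraint_source=None,
    )
    result = fit(empirical, cfg)
    result.multi_step_ml = False
    result.n_params = base.n_params
    return result


def group_multistep_pairs(
    empirical: EmpiricalSubstitutionMatrix,
    base: FitResult,
    n_groups: int = 6,
) -> dict[str, int]:
    """Classify multi-step amino-acid pairs by log-odds discrepancy.

    The discrepancy of a pair is the observed amino-acid log-odds minus the
    log-odds of the *base* model (typically a stepwise-only fit, where the
    discrepancies expose the missing multi-change events).  Pairs are split
    into *n_groups* equal-width bins of discrepancy; group 0 (lowest
    discrepancy, i.e. most over-estimated) is the "least exchangeable" class.
    """
    if n_groups < 2:
        raise ModelError("n_groups must be at least 2")
    code = base.params_hat.code
    if empirical.level == "codon":
        P_obs, pi_obs = amino_acid_marginal(
            empirical.P_obs, empirical.pi_obs, code
        )
        P_mod, _ = amino_acid_marginal(base.P_model, empirical.pi_obs, code)
    else:
        P_obs, pi_obs = empirical.P_obs, empirical.pi_obs
        P_mod = base.P_model
    with np.errstate(divide="ignore"):
        lo_obs = log_odds(P_obs, pi_obs)
        lo_mod = log_odds(P_mod, pi_obs)
    aas = code.amino_acids
    classes = code.pair_step_classes()
    keys = _sorted_pairs(code, "multi", classes)
    disc = {}
    for k in keys:
        ia, ib = aas.index(k[0]), aas.index(k[1])
        d = 0.5 * (lo_obs[ia, ib] + lo_obs[ib, ia]) - 0.5 * (
            lo_mod[ia, ib] + lo_mod[ib, ia]
        )
        disc[k] = d
    finite = [v for v in disc.values() if np.isfinite(v)]
    lo, hi = min(finite), max(finite)
    width = (hi - lo) / n_groups or 1.0
    out = {}
    for k, d in disc.items():
        if not np.isfinite(d):
            out[k] = 0
        else:
            out[k] = int(min((d - lo) // width, n_groups - 1))
    return out
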