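"""Model-true synthetic 1-PAM matrices with known ground truth.

The generator builds a codon substitution generator from drawn or supplied
parameters, solves the time scale (gamma-averaged when the rate-variation
scale is positive) so the expected substitution fraction hits the 1-PAM
target, marginalizes to amino acids when requested, and optionally degrades
the exact model matrix with per-row multinomial counting noise at a finite
number of site comparisons ``N``.  Compositions stay at truth even under
noise, mirroring how empirical matrices pin compositions to observed ones.

Every draw is fully determined by the fixture seed (a named, portable PRNG:
numpy's PCG64 via ``default_rng``), so fixtures are reproducible without
shipping data files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fit import (
    EmpiricalSubstitutionMatrix,
    _solve_t_bar,
)
from .genetic_code import GeneticCode, universal_code
from .model import (
    CodonModelParams,
    ConstraintSet,
    NucleotideParams,
    amino_acid_marginal,
    codon_freq_from_aa,
    codon_rate_matrix,
)

__all__ = ["FixtureSpec", "random_params", "synthetic_empirical", "recovery_truth_params"]


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for one synthetic empirical matrix.

    ``params=None`` draws parameters from realistic ranges; ``N=None``
    yields the exact (noise-free) model matrix.
    """

    seed: int
    level: str = "amino_acid"
    params: CodonModelParams | None = None
    N: float | None = None
    target_pam: float = 0.01
    code: GeneticCode = field(default_factory=universal_code)

    def __post_init__(self) -> None:
        if self.level not in ("amino_acid", "codon"):
            raise ValueError("level must be amino_acid or codon")
        if self.N is not None and self.N <= 0:
            raise ValueError("N must be positive or None")
        if not (0.0 < self.target_pam < 1.0):
            raise ValueError("target_pam must lie in (0, 1)")


def random_params(spec: FixtureSpec) -> CodonModelParams:
    """Seeded draw of a full, valid parameter set.

    Exchangeability ratios are lognormal around one, the mutational
    composition is a moderate Dirichlet draw, and constraints are drawn with
    distinct single-step and multi-step blocks (multi-step pairs more
    constrained on average), the separation typical of fitted constraint
    sets.
    """
    rng = np.random.default_rng(spec.seed)
    code = spec.code
    ex = {
        p: float(np.exp(rng.normal(0.0, 0.35)))
        for p in ("AC", "AG", "AT", "CG", "CT", "GT")
    }
    # mild transition bias on average
    ex["AG"] *= 1.5
    ex["CT"] *= 1.5
    q = rng.dirichlet(np.full(4, 20.0))
    q = tuple(float(v) for v in q / q.sum())
    classes = code.pair_step_classes()
    w = {}
    for k, step in classes.items():
        key = "".join(sorted(k))
        mu = -1.0 if step == 1 else -2.5
        w[key] = float(rng.normal(mu, 0.6))
    return CodonModelParams(
        w0=0.0,
        beta=1.0,
        sigma=float(rng.uniform(0.3, 1.2)),
        nuc=NucleotideParams(exchangeabilities=ex, compositions=q),
        usage_lambda=(0.5, 0.5, 0.5),
        rate_var_b=float(rng.uniform(0.0, 0.8)),
        constraints=ConstraintSet(w=w),
        code=code,
    )


def recovery_truth_params(code: GeneticCode | None = None, seed: int = 2024) -> CodonModelParams:
    """The reference ground truth used for parameter-recovery studies.

    A moderate multi-change ratio (0.7), a 1.6-fold transition bias,
    AT-skewed mutational composition (0.3, 0.2, 0.2, 0.3) and appreciable
    rate variation (scale 0.5), with seeded per-pair constraints.
    """
    code = code or universal_code()
    rng = np.random.default_rng(seed)
    classes = code.pair_step_classes()
    w = {}
    for k, step in classes.items():
        mu = -1.0 if step == 1 else -2.5
        w["".join(sorted(k))] = float(rng.normal(mu, 0.5))
    return CodonModelParams(
        sigma=0.7,
        nuc=NucleotideParams(
            exchangeabilities={
                "AC": 1.0, "AG": 1.6, "AT": 1.0, "CG": 1.0, "CT": 1.6, "GT": 1.0,
            },
            compositions=(0.3, 0.2, 0.2, 0.3),
        ),
        rate_var_b=0.5,
        constraints=ConstraintSet(w=w),
        code=code,
    )


def synthetic_empirical(
    spec: FixtureSpec,
) -> tuple[EmpiricalSubstitutionMatrix, dict]:
    """Generate a synthetic 1-PAM matrix and its ground-truth record.

    Returns the empirical matrix (noise-free when ``spec.N`` is ``None``;
    multinomially resampled per row otherwise) together with a record
    carrying the true parameters, time scale, and exact matrix.
    """
    params = spec.params if spec.params is not None else random_params(spec)
    if params.code is not spec.code and params.code.name != spec.code.name:
        params = replace(params, code=spec.code)
    code = params.code

    codon_freq = codon_freq_from_aa(
        _stationary_aa_freq(params), params.usage_lambda, params.nuc, code
    )
    # build the generator once and reuse its eigensystem for time solving
    rate = codon_rate_matrix(params, codon_freq)
    lam, V, d = rate.eigensystem()
    groups = (
        [[i] for i in range(len(code.sense_codons))]
        if spec.level == "codon"
        else [
            [
                i
                for i, c in enumerate(code.sense_codons)
                if code.translate(c) == a
            ]
            for a in code.amino_acids
        ]
    )
    scale = _solve_t_bar(
        lam, V, d, groups, spec.target_pam, params.rate_var_b
    )
    if scale.b > 0:
        basis = np.log1p(-scale.b * np.minimum(lam, 0.0)) / scale.b
        eig = np.exp(-scale.t_bar * basis)
    else:
        eig = np.exp(lam * scale.t_bar)
    P = (V * eig[None, :]) @ V.T
    P = P / d[:, None] * d[None, :]
    P = np.clip(P, 0.0, None)
    P = P / P.sum(axis=1, keepdims=True)

    if spec.level == "amino_acid":
        P_level, pi_level = amino_acid_marginal(P, rate.pi, code)
        states = code.amino_acids
    else:
        P_level, pi_level = P, rate.pi
        states = code.sense_codons

    P_exact = P_level.copy()
    if spec.N is not None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1D]))
        P_noisy = np.zeros_like(P_level)
        for i, row in enumerate(P_level):
            n_i = max(1, int(round(spec.N * pi_level[i])))
            counts = rng.multinomial(n_i, row / row.sum())
            P_noisy[i] = counts / counts.sum()
        P_level = P_noisy

    emp = EmpiricalSubstitutionMatrix(
        level=spec.level,
        states=tuple(states),
        P_obs=P_level,
        pi_obs=pi_level,
        N=spec.N,
        name=f"synthetic-{spec.level}-seed{spec.seed}",
    )
    truth = {
        "params": params,
        "time_scale": scale,
        "P_exact": P_exact,
        "codon_freq": codon_freq,
        "seed": spec.seed,
        "target_pam": spec.target_pam,
    }
    return emp, truth


def _stationary_aa_freq(params: CodonModelParams) -> np.ndarray:
    """Amino-acid composition implied by the mutational equilibrium and selection.

    The generator's stationary composition is an input of the model; for
    synthetic data we choose the composition implied by the mutational
    product measure reweighted by mean fixation factors, a realistic,
    strictly positive choice that depends smoothly on the parameters.
    """
    code = params.code
    q = params.nuc.q
    w = params.effective_constraints()
    aas = code.amino_acids
    base = np.zeros(len(aas))
    for ia, a in enumerate(aas):
        fam = code.codons_for(a)
        mass = 0.0
        for c in fam:
            mass += math.prod(q["ACGT".index(x)] for x in c)
        # reweight by mean retention against replacement
        mean_w = np.mean([np.exp(w.value(a, b)) for b in aas if b != a])
        base[ia] = mass * (1.0 + 0.5 * (1.0 - mean_w))
    return base / base.sum()
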