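# Methods

## Model

The package implements a time-reversible Markov model of codon substitution
in which mutation and selection are factorized.  Mutation acts independently
and identically at the three codon positions: a reversible nucleotide
process with exchangeabilities `f(x,y)` over the six unordered nucleotide
pairs and equilibrium composition `q` over `A, C, G, T`.  A simultaneous
change of `k` positions is damped by `σ^(k−1)`, so `σ` measures how much
rarer a double change is than a single one (and a triple than a double);
`σ = 0` is the classical stepwise model in which amino-acid pairs whose
codons differ at two or three positions can only be reached through
intermediate states.  The 64×64 mutation generator satisfies detailed
balance with respect to the product measure `f^mut_ν = Π_l q(ν_l)`.

Selection acts on the encoded amino acids.  The fixation probability splits
into a frequency-dependent factor and a frequency-independent factor
`exp(w_ab)`; `w_ab ≤ 0` is the selective constraint against replacing amino
acid `a` with `b`, `w = 0` exactly for synonymous changes (structural, not
stored).  Reversibility of the full generator with respect to a prescribed
codon composition `π` constrains the frequency-dependent factor to a
one-parameter family of symmetric-kernel decompositions; two members are
implemented behind `fixation_frequency_term`:

* `acceptance` (default): `g[μ,ν] = π_ν / f^mut_ν` — the rate of acceptance
  into codon `ν` is proportional to how over- or under-represented `ν` is
  relative to the mutational equilibrium;
* `sqrt`: the symmetric square-root form
  `g[μ,ν] = sqrt((π_ν/f^mut_ν)·(f^mut_μ/π_μ))`.

The acceptance form is the default for an identifiability reason worth
recording: under the square-root form the generator depends on `f` and `q`
only through the products `f(x,y)·sqrt(q_x q_y)` (and, at equal codon
usage, the codon composition is `q`-free), so the mutational composition is
exactly unidentifiable from substitution data — fits reach the global
optimum at arbitrary points of a three-dimensional ridge.  Under the
acceptance form, unchanged codon positions carry `q`-dependence and all
eight mutation freedoms (five exchangeability ratios, three composition
freedoms) are recoverable from amino-acid-level data; the parameter-recovery
test demonstrates recovery to ~1e-7 relative error.

Stop codons are removed from the state space before normalization (their
frequencies are zero, hence all rates into them vanish) rather than kept as
absorbing states.  The generator is scaled to unit total rate,
`−Σ_μ π_μ R_μμ = 1`, so one unit of model time is one expected codon
substitution per codon; only relative exchangeabilities are meaningful.

Transition matrices are computed by symmetrizing `R` with `diag(√π)` and
diagonalizing (real spectrum guaranteed by reversibility).  Gamma rate/time
variation with scale `b` and shape `α` has the closed form
`λ ↦ (1 − bλ)^{−α}` on each eigenvalue, always well defined because
`λ ≤ 0`; `b → 0` at fixed mean `αb` degenerates to the point-time matrix.
Reconstructed stochastic matrices may carry roundoff negatives; entries
above `−1e−12` are clipped to zero and rows renormalized, anything worse
raises a numerical error.

## Parameters

| parameter | meaning | domain | default |
|---|---|---|---|
| `f(x,y)` | nucleotide exchangeabilities (6) | > 0, scale-free | 1 |
| `q` | mutational composition (A,C,G,T) | simplex interior | 0.25 each |
| `σ` | multi-change exchangeability ratio | ≥ 0 | 1 |
| `w_ab` | selective constraint per amino-acid pair | real, 0 = neutral | 0 |
| `w0` | nonsynonymous offset | real | 0 |
| `β` | constraint-strength multiplier | ≥ 0 | 1 |
| `λ1..λ3` | per-position codon-usage parameters | [0, 1] | 0.5 |
| `b` | gamma scale for rate variation | ≥ 0 (0 = none) | 0 |

Reported exchangeabilities are normalized so the mean of the four
transversion-type values (`AC, AT, CG, GT`) is one, leaving five free
ratios; during optimization the gauge is instead `f_GT` of the starting
point (a pure reparameterization — the likelihood absorbs the overall scale
into the unit-rate constant).  Compositions are optimized through the
bijection `(AT-content, A/(A+T), G/(G+C))` with logit transforms; `β`, `σ`,
`b` and exchangeabilities are log-transformed; `λ` is logit-transformed.
The "least exchangeable" constraint class is represented by a finite floor,
`w = −20` (rate factor ≈ 2·10⁻⁹), never `−∞`, keeping likelihoods finite.

Codon compositions for amino-acid-level data are parameterized from the
amino-acid composition: within each synonymous family codon `ν` gets weight
`Π_l q(ν_l)^(2λ_l − 1)`, renormalized per family.  `λ = 0.5` everywhere
means equal codon usage; `λ = 1` weights codons by the mutational measure.

## Fitting

The objective is the plug-in Kullback–Leibler divergence of the observed
1-PAM transition distribution from the model's (equivalent to maximizing the
multinomial log-likelihood, but defined even when the effective comparison
count `N` is unknown — then AIC and ΔAIC are reported as unavailable).  The
gamma law is profiled out rather than optimized: inside every evaluation the
mean time is re-solved by monotone bracketing/Brent so the model's expected
substitution fraction matches the observed one, at the empirical matrix's
own level (amino-acid matrices are compared after marginalization).  This
matches the 1-PAM convention `Σ_a π_a (1 − P_aa) = 0.01` and removes one
optimization dimension.

Optimization is Nelder–Mead (adaptive simplex for > 6 dimensions) with
seeded random restarts (default 3) from perturbations of the running best;
identical seed and configuration give identical results.  Observed zero
cells contribute nothing to the likelihood or the divergence; their count is
available from the empirical container.  Equilibrium compositions are pinned
to the observed ones (codon level) or derived from the observed amino-acid
composition via the usage map (amino-acid level).

Preset masks reproduce the standard model families.  Under the universal
code: the stepwise-only fit frees all 75 single-step constraints plus five
exchangeability ratios, three composition freedoms, three usage parameters
and the gamma scale (87 scalars; 107 freedoms counting the 19 amino-acid
frequencies and the shape parameter); the multi-change fits add `σ` and six
grouped multi-step constraint classes (91 at equal usage, 94 with usage
free); the codon-level fit frees all 190 pair constraints (200 scalars, 261
freedoms).  A general reversible 20-state model has 209 freedoms, the
ceiling that makes a 190-constraint amino-acid-level fit non-identifiable —
hence the grouping of multi-step pairs.  The grouping assigns each
multi-step pair to one of six classes by the discrepancy between observed
and model log-odds under a stepwise-only base fit, using equal-width bins
(the class boundaries are a package choice; only the count and the
criterion are fixed by the model family), with the lowest class designated
least exchangeable.  The `+`-refit then frees every multi-step pair's
constraint individually while holding all other parameters at the base
estimates; those refitted values are conditional estimates, not joint ML
estimates, and results carry a flag saying so.

Linear-constraint families evaluate `w = β·ŵ + w0` against a reference set
`ŵ`: bundled physico-chemical distances (negated and scaled to unit mean
magnitude so `β` is comparable across sources) or constraint sets loaded
from the flat TSV dialect.  The printed mask id sets for these families are
encoded as data (`PRESET_ID_SETS`), with the constraint-free family's
masks kept separately since its strength parameter is pinned at zero.

## Synthetic data

The fixture generator emulates the package's own inputs: a 1-PAM transition
matrix with composition and optional comparison count.  Parameters are
drawn from ranges a practitioner would call typical — lognormal
exchangeability ratios around one with a mild transition bias, a moderate
Dirichlet composition, `σ ∈ [0.3, 1.2]`, `b ∈ [0, 0.8]`, and per-pair
constraints with distinct single-step (mean −1) and multi-step (mean −2.5)
blocks.  The amino-acid composition is derived from the mutational measure
reweighted by mean fixation factors; the time scale is solved so the
emitted matrix sits exactly at the target substitution fraction (0.01 by
default) at its own level.  Finite `N` adds per-row multinomial counting
noise conditional on the true composition, mirroring how empirical matrices
pin compositions to observed values; `N = None` emits the exact model
matrix.  All randomness flows from a single seed through numpy's PCG64.

What passing tests on these fixtures do show: the estimation machinery is
consistent (exact recovery from noise-free data, shrinking error with
growing `N`) and the algebraic pipeline (generator → averaging →
marginalization → log-odds) is self-consistent against independent oracles.
What they do not show: that real empirical matrices satisfy the model's
assumptions — position-independent mutation, a single gamma law, one
constraint per unordered pair — so goodness-of-fit conclusions for real
data still require the AIC machinery on those data.

Because the time scale is matched at the emitted level, a codon-level
fixture (1% codon substitutions) runs slightly longer than an
amino-acid-level one (synonymous events do not count there); aligning the
targets makes the codon fixture marginalize to the amino-acid one exactly.

## Numerical choices

* Moment-matching tolerance 1e-12 on the substitution fraction (Brent with
  near-machine relative tolerance); attainability is checked against the
  ergodic ceiling `1 − Σ π²`.
* Negative-entry clip for reconstructed stochastic matrices: 1e-12.
* Nelder–Mead: `fatol` 1e-8 (1e-12 in recovery studies), up to 1e5
  evaluations, 3 seeded restarts.
* Degenerate inputs raise typed errors: non-simplex compositions,
  amino acids with zero frequency at marginalization, unattainable target
  fractions, reducible exchangeability matrices in the 1-PAM constructor.
* The quadrature oracle for the gamma average uses a composite 8-point
  Gauss–Legendre rule (10⁴ nodes) after the substitution `t = u²`, which
  removes the fractional-power kink of the gamma density at zero; the
  truncated tail carries < 1e-16 mass.

## Data provenance

The bundled amino-acid property table (composition, polarity, molecular
volume) is Grantham's published 1974 table; both bundled distance scales
are computed from it at run time — the Grantham distance with the published
weights (`α = 1.833, β = 0.1018, γ = 0.000399, ρ = 50.723`, mean distance
100) and the Miyata-style polarity–volume distance normalized by the
property standard deviations over the twenty amino acids.  Spot checks pin
the Grantham values to the published integers within ±1 (the published
table is rounded).  Published constraint-estimate datasets are not bundled;
the loader accepts them in the flat `pair<TAB>value` TSV dialect, flags
floor-valued entries as the least-exchangeable class, and the comparison
tests run when the files are supplied under `data/external/data_s1/`.

## Limitations

* Mutation parameters are position-independent by assumption; the type
  layout permits per-position parameters but no code path estimates them.
* Exchangeabilities of multi-nucleotide changes are products of
  single-change exchangeabilities (times `σ^(k−1)`), so no specific codon
  pair can be singled out as exceptionally exchangeable or unexchangeable
  at the triple-change level.
* Only reversible generators are supported, and stationarity of the
  observed composition is assumed, not tested.
* Tree likelihoods over sequence alignments are out of scope; the package
  exports generators, transition and log-odds matrices for engines that
  consume them.
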