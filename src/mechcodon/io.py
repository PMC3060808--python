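"""Readers and writers for the matrix formats the tool exchanges.

Supported formats:

``plain_matrix``
    A header line of state labels, one whitespace-separated row per state
    prefixed by its label, and an optional final ``pi`` line carrying the
    composition.  When the composition line is absent the stationary left
    eigenvector of the matrix is used.
``paml_aa_dat`` / ``paml_codon_dat``
    PAML-style lower-triangle exchangeabilities (19 rows for amino acids, or
    ``n-1`` rows over a declared codon order) followed by a frequency line.
    Exchangeability inputs are converted to 1-PAM transition matrices on
    read.
``json_bundle``
    Matrix, composition and metadata in one JSON object; also used to
    serialize fit results.

External state orders are remapped to the package's canonical orders
(alphabetical amino acids; lexicographic codons) on read; files written by
the package always carry explicit labels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .fit import (
    EmpiricalSubstitutionMatrix,
    FitResult,
    one_pam_from_exchangeabilities,
)
from .genetic_code import AMINO_ACIDS, GeneticCode, universal_code
from .model import (
    CodonModelParams,
    ConstraintSet,
    ModelError,
    NucleotideParams,
)

__all__ = [
    "MatrixFileSpec",
    "FormatError",
    "read_empirical",
    "read_plain_matrix",
    "write_plain_matrix",
    "write_paml_dat",
    "write_json_bundle",
    "write_outputs",
    "fit_result_to_dict",
    "fit_result_from_dict",
    "params_to_dict",
    "params_from_dict",
]

FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Malformed matrix file."""


@dataclass(frozen=True)
class MatrixFileSpec:
    """How to interpret a matrix file: format, level, and external state order."""

    format: str = "plain_matrix"
    level: str = "amino_acid"
    codon_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.format not in (
            "plain_matrix",
            "paml_aa_dat",
            "paml_codon_dat",
            "json_bundle",
        ):
            raise FormatError(f"unknown format {self.format!r}")
        if self.level not in ("amino_acid", "codon"):
            raise FormatError(f"unknown level {self.level!r}")
        if self.format == "paml_aa_dat" and self.level != "amino_acid":
            raise FormatError("paml_aa_dat is an amino-acid-level format")
        if self.format == "paml_codon_dat" and self.level != "codon":
            raise FormatError("paml_codon_dat is a codon-level format")


def _stationary(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# plain matrix
# ---------------------------------------------------------------------------

def write_plain_matrix(
    path: str | Path,
    M: np.ndarray,
    labels: tuple[str, ...],
    pi: np.ndarray | None = None,
) -> None:
    path = Path(path)
    lines = [" ".join(labels)]
    for lab, row in zip(labels, np.asarray(M, dtype=float)):
        lines.append(lab + " " + " ".join(FLOAT_FMT % v for v in row))
    if pi is not None:
        lines.append("pi " + " ".join(FLOAT_FMT % v for v in np.asarray(pi)))
    path.write_text("\n".join(lines) + "\n")


def read_plain_matrix(
    path: str | Path,
) -> tuple[np.ndarray, tuple[str, ...], np.ndarray | None]:
    """Read a labelled plain matrix; returns (matrix, labels, composition or None)."""
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    labels = tuple(lines[0].split())
    n = len(labels)
    rows = {}
    pi = None
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if parts[0] == "pi":
            if len(parts) != n + 1:
                raise FormatError(f"{path}:{lineno}: pi line needs {n} values")
            pi = np.array([_parse_float(path, lineno, v) for v in parts[1:]])
            continue
        if parts[0] not in labels:
            raise FormatError(f"{path}:{lineno}: unknown state label {parts[0]!r}")
        if len(parts) != n + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {n} values for state {parts[0]}"
            )
        rows[parts[0]] = [_parse_float(path, lineno, v) for v in parts[1:]]
    missing = [lab for lab in labels if lab not in rows]
    if missing:
        raise FormatError(f"{path}: missing rows for states {missing[:5]}")
    M = np.array([rows[lab] for lab in labels])
    if np.any(~np.isfinite(M)):
        raise FormatError(f"{path}: non-finite entries")
    return M, labels, pi


def _parse_float(path: Path, lineno: int, raw: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: unparseable value {raw!r}") from None


# ---------------------------------------------------------------------------
# PAML-style .dat (lower triangle + frequencies)
# ---------------------------------------------------------------------------

def _read_paml_numbers(path: Path) -> list[float]:
    vals = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        for tok in line.split():
            vals.append(_parse_float(path, lineno, tok))
    return vals


def _read_paml_dat(
    path: str | Path, states: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    n = len(states)
    need = n * (n - 1) // 2 + n
    vals = _read_paml_numbers(path)
    if len(vals) != need:
        raise FormatError(
            f"{path}: expected {need} numbers "
            f"({n*(n-1)//2} lower-triangle + {n} frequencies), got {len(vals)}"
        )
    S = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            S[i, j] = S[j, i] = vals[k]
            k += 1
    freq = np.array(vals[k:])
    if abs(freq.sum() - 1.0) > 1e-4:
        raise FormatError(f"{path}: frequency line sums to {freq.sum():.6g}, not 1")
    freq = freq / freq.sum()
    return S, freq


def write_paml_dat(
    path: str | Path,
    S: np.ndarray,
    freq: np.ndarray,
    states: tuple[str, ...] | None = None,
) -> None:
    """Write symmetric exchangeabilities + frequencies in PAML lower-triangle form."""
    path = Path(path)
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    lines = []
    for i in range(1, n):
        lines.append(" ".join(FLOAT_FMT % S[i, j] for j in range(i)))
    lines.append("")
    lines.append(" ".join(FLOAT_FMT % v for v in np.asarray(freq)))
    if states:
        lines.append("")
        lines.append("# states: " + " ".join(states))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# empirical readers
# ---------------------------------------------------------------------------

def read_empirical(
    path: str | Path,
    spec: MatrixFileSpec,
    N: float | None = None,
    name: str | None = None,
    code: GeneticCode | None = None,
) -> EmpiricalSubstitutionMatrix:
    """Read an empirical matrix file into the internal canonical order.

    PAML exchangeability inputs are converted to 1-PAM transition matrices;
    direct probability inputs are validated row-stochastic.
    """
    path = Path(path)
    code = code or universal_code()
    name = name or path.stem
    if spec.level == "amino_acid":
        canonical = tuple(AMINO_ACIDS)
    else:
        canonical = code.sense_codons

    if spec.format in ("paml_aa_dat", "paml_codon_dat"):
        order = (
            tuple(AMINO_ACIDS)
            if spec.format == "paml_aa_dat"
            else (spec.codon_order or canonical)
        )
        S, freq = _read_paml_dat(path, order)
        perm = _permutation(order, canonical, path)
        S = S[np.ix_(perm, perm)]
        freq = freq[perm]
        return one_pam_from_exchangeabilities(
            S, freq, N=N, level=spec.level, states=canonical, name=name
        )

    if spec.format == "plain_matrix":
        M, labels, pi = read_plain_matrix(path)
        if len(labels) != len(canonical):
            raise FormatError(
                f"{path}: {len(labels)} states, expected {len(canonical)} "
                f"for level {spec.level!r}"
            )
        perm = _permutation(labels, canonical, path)
        M = M[np.ix_(perm, perm)]
        pi = pi[perm] if pi is not None else _stationary(M)
        return EmpiricalSubstitutionMatrix(
            level=spec.level,
            states=canonical,
            P_obs=M,
            pi_obs=pi,
            N=N,
            name=name,
        )

    if spec.format == "json_bundle":
        bundle = json.loads(path.read_text())
        M = np.asarray(bundle["matrix"], dtype=float)
        labels = tuple(bundle["states"])
        pi = np.asarray(bundle["composition"], dtype=float)
        perm = _permutation(labels, canonical, path)
        return EmpiricalSubstitutionMatrix(
            level=spec.level,
            states=canonical,
            P_obs=M[np.ix_(perm, perm)],
            pi_obs=pi[perm],
            N=N if N is not None else bundle.get("N"),
            name=name,
        )

    raise FormatError(f"unsupported format {spec.format!r}")


def _permutation(
    src: tuple[str, ...], dst: tuple[str, ...], path: Path
) -> np.ndarray:
    if set(src) != set(dst):
        unknown = sorted(set(src) - set(dst))[:5]
        raise FormatError(f"{path}: unknown state labels {unknown}")
    index = {lab: i for i, lab in enumerate(src)}
    return np.array([index[lab] for lab in dst])


# ---------------------------------------------------------------------------
# serialization of parameters and fit results
# ---------------------------------------------------------------------------

def params_to_dict(p: CodonModelParams) -> dict:
    return {
        "w0": p.w0,
        "beta": p.beta,
        "sigma": p.sigma,
        "exchangeabilities": dict(sorted(p.nuc.exchangeabilities.items())),
        "compositions": list(p.nuc.compositions),
        "usage_lambda": list(p.usage_lambda),
        "rate_var_b": p.rate_var_b,
        "constraints": {k: p.constraints.w[k] for k in sorted(p.constraints.w)},
        "constraint_floor": p.constraints.floor_value,
        "code": p.code.name,
    }


def params_from_dict(d: dict, code: GeneticCode | None = None) -> CodonModelParams:
    from .genetic_code import get_code

    code = code or get_code(d.get("code", "universal"))
    constraints = (
        ConstraintSet(
            w=dict(d["constraints"]),
            floor_value=d.get("constraint_floor", -20.0),
        )
        if "constraints" in d
        else ConstraintSet.neutral(code)
    )
    nuc = NucleotideParams(
        exchangeabilities=dict(
            d.get("exchangeabilities", {p: 1.0 for p in ("AC", "AG", "AT", "CG", "CT", "GT")})
        ),
        compositions=tuple(d.get("compositions", (0.25,) * 4)),
    )
    return CodonModelParams(
        w0=float(d.get("w0", 0.0)),
        beta=float(d.get("beta", 1.0)),
        sigma=float(d.get("sigma", 1.0)),
        nuc=nuc,
        usage_lambda=tuple(d.get("usage_lambda", (0.5, 0.5, 0.5))),
        rate_var_b=float(d.get("rate_var_b", 0.0)),
        constraints=constraints,
        code=code,
    )


def fit_result_to_dict(r: FitResult) -> dict:
    return {
        "params": params_to_dict(r.params_hat),
        "kl_hat": r.kl_hat,
        "loglik": r.loglik,
        "n_params": r.n_params,
        "aic": r.aic,
        "delta_aic": r.delta_aic,
        "t_bar": r.t_bar,
        "alpha_hat": r.alpha_hat,
        "summaries": r.summaries,
        "converged": r.converged,
        "n_evaluations": r.n_evaluations,
        "empirical_name": r.empirical_name,
        "multi_step_ml": r.multi_step_ml,
    }


def fit_result_from_dict(d: dict) -> FitResult:
    return FitResult(
        params_hat=params_from_dict(d["params"]),
        kl_hat=d["kl_hat"],
        loglik=d["loglik"],
        n_params=d["n_params"],
        aic=d["aic"],
        delta_aic=d["delta_aic"],
        t_bar=d["t_bar"],
        alpha_hat=d["alpha_hat"],
        summaries=d["summaries"],
        converged=d["converged"],
        n_evaluations=d["n_evaluations"],
        empirical_name=d["empirical_name"],
        multi_step_ml=d["multi_step_ml"],
    )


def write_json_bundle(
    path: str | Path,
    M: np.ndarray,
    labels: tuple[str, ...],
    pi: np.ndarray,
    metadata: dict | None = None,
) -> None:
    bundle = {
        "states": list(labels),
        "matrix": [[float(FLOAT_FMT % v) for v in row] for row in np.asarray(M)],
        "composition": [float(FLOAT_FMT % v) for v in np.asarray(pi)],
    }
    if metadata:
        bundle["metadata"] = metadata
    Path(path).write_text(json.dumps(bundle, sort_keys=True, indent=1) + "\n")


# ---------------------------------------------------------------------------
# output manifests
# ---------------------------------------------------------------------------

def write_outputs(
    objects: dict, path: str | Path, formats: tuple[str, ...] = ("json",)
) -> dict:
    """Write named matrices / results to *path*; return a checksum manifest.

    *objects* maps a base name either to a ``(matrix, labels, pi)`` triple
    or to a :class:`FitResult`.  Contents are deterministic for fixed inputs
    (sorted keys, fixed float format).
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"files": []}
    for base in sorted(objects):
        obj = objects[base]
        written = []
        if isinstance(obj, FitResult):
            f = outdir / f"{base}.fit.json"
            f.write_text(
                json.dumps(fit_result_to_dict(obj), sort_keys=True, indent=1)
                + "\n"
            )
            written.append(f)
        else:
            M, labels, pi = obj
            if "plain" in formats or "txt" in formats:
                f = outdir / f"{base}.txt"
                write_plain_matrix(f, M, labels, pi)
                written.append(f)
            if "json" in formats:
                f = outdir / f"{base}.json"
                write_json_bundle(f, M, labels, pi)
                written.append(f)
        for f in written:
            digest = hashlib.sha256(f.read_bytes()).hexdigest()
            manifest["files"].append({"name": f.name, "sha256": digest})
    mf = outdir / "manifest.json"
    mf.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
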