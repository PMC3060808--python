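"""Reference selective-constraint sources and constraint-set comparison.

Two physico-chemical distance scales are bundled, both derived from the
Grantham (1974) amino-acid property table (composition ``c``, polarity
``p``, molecular volume ``v``) that ships with the package:

* the Grantham distance,
  ``D = rho * sqrt(alpha (dc)^2 + beta (dp)^2 + gamma (dv)^2)`` with the
  published weights ``alpha=1.833, beta=0.1018, gamma=0.000399`` and
  ``rho=50.723`` (mean distance 100);
* the Miyata et al. (1979) distance,
  ``d = sqrt((dp/sd_p)^2 + (dv/sd_v)^2)`` with the property standard
  deviations taken over the 20 amino acids.

Distances are negated (and scaled) on import into a
:class:`~mechcodon.model.ConstraintSet`, so larger physico-chemical distance
means a more negative log fixation factor.  Constraint estimate files (the
flat TSV dialect also written by the fitting layer) can be loaded, and
Pearson correlations between constraint sets computed over single-step,
multi-step or all amino-acid pairs, optionally excluding the least
exchangeable (floor-valued) class.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .genetic_code import AMINO_ACIDS, GeneticCode, universal_code
from .model import ConstraintSet, ModelError

__all__ = [
    "DistanceTable",
    "grantham_properties",
    "grantham_distances",
    "miyata_distances",
    "constraints_from_distance",
    "load_constraint_estimates",
    "save_constraint_estimates",
    "constraint_correlation",
]


class ConstraintFormatError(ValueError):
    """Malformed constraint or distance file."""


def _pair_key(a: str, b: str) -> str:
    return a + b if a <= b else b + a


@dataclass(frozen=True)
class DistanceTable:
    """A symmetric nonnegative amino-acid pair distance table."""

    name: str
    d: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        expected = {
            _pair_key(a, b) for a, b in itertools.combinations(AMINO_ACIDS, 2)
        }
        if set(self.d) != expected:
            missing = sorted(expected - set(self.d))
            extra = sorted(set(self.d) - expected)
            raise ConstraintFormatError(
                f"distance table {self.name!r} must cover all 190 pairs "
                f"(missing={missing[:5]}, extra={extra[:5]})"
            )
        if any(v < 0 for v in self.d.values()):
            raise ConstraintFormatError("distances must be nonnegative")

    def value(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.d[_pair_key(a, b)]

    def mean(self) -> float:
        return float(np.mean(list(self.d.values())))


def grantham_properties() -> dict[str, tuple[float, float, float]]:
    """Published (composition, polarity, volume) per amino acid."""
    out = {}
    ref = resources.files("mechcodon").joinpath("data/grantham_properties.tsv")
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, c, p, v = line.split("\t")
        out[aa] = (float(c), float(p), float(v))
    if set(out) != set(AMINO_ACIDS):
        raise ConstraintFormatError("property table must cover the 20 amino acids")
    return out


_GRANTHAM_ALPHA, _GRANTHAM_BETA, _GRANTHAM_GAMMA = 1.833, 0.1018, 0.000399
_GRANTHAM_RHO = 50.723


def grantham_distances() -> DistanceTable:
    """The Grantham (1974) chemical distance over all 190 amino-acid pairs."""
    props = grantham_properties()
    d = {}
    for a, b in itertools.combinations(AMINO_ACIDS, 2):
        (ca, pa, va), (cb, pb, vb) = props[a], props[b]
        d[_pair_key(a, b)] = _GRANTHAM_RHO * float(
            np.sqrt(
                _GRANTHAM_ALPHA * (ca - cb) ** 2
                + _GRANTHAM_BETA * (pa - pb) ** 2
                + _GRANTHAM_GAMMA * (va - vb) ** 2
            )
        )
    return DistanceTable(
        name="grantham",
        d=d,
        provenance="Grantham 1974 composition/polarity/volume distance",
    )


def miyata_distances() -> DistanceTable:
    """The Miyata et al. (1979) polarity-volume distance over all pairs."""
    props = grantham_properties()
    p = np.array([props[a][1] for a in AMINO_ACIDS])
    v = np.array([props[a][2] for a in AMINO_ACIDS])
    sp, sv = float(p.std(ddof=0)), float(v.std(ddof=0))
    d = {}
    for a, b in itertools.combinations(AMINO_ACIDS, 2):
        dp = (props[a][1] - props[b][1]) / sp
        dv = (props[a][2] - props[b][2]) / sv
        d[_pair_key(a, b)] = float(np.hypot(dp, dv))
    return DistanceTable(
        name="miyata",
        d=d,
        provenance="Miyata, Miyazawa & Yasunaga 1979 polarity-volume distance",
    )


def constraints_from_distance(
    table: DistanceTable, scale: float | None = None
) -> ConstraintSet:
    """Reference constraints ``w_hat = -d / scale`` from a distance table.

    Larger distance means a more negative log fixation factor.  The default
    scale is the mean distance over the 190 pairs, so the mean magnitude of
    the resulting constraints is one; strength and offset are applied later
    through the linear constraint map.
    """
    if scale is None:
        scale = table.mean()
    if scale <= 0:
        raise ModelError("scale must be positive")
    return ConstraintSet(w={k: -v / scale for k, v in table.d.items()})


# ---------------------------------------------------------------------------
# constraint-estimate files (flat TSV dialect: pair<TAB>value)
# ---------------------------------------------------------------------------

def save_constraint_estimates(cs: ConstraintSet, path: str | Path) -> None:
    """Write a constraint set as the flat ``pair<TAB>value`` TSV dialect."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pair", "value"])
        for k in sorted(cs.w):
            writer.writerow([k, f"{cs.w[k]:.10g}"])


def load_constraint_estimates(
    path: str | Path,
    floor_value: float | None = None,
    code: GeneticCode | None = None,
) -> ConstraintSet:
    """Load a constraint set from the flat TSV dialect.

    The file must contain every amino-acid pair of the code exactly once.
    Entries at the floor value (explicit *floor_value*, or the file minimum
    when at least two pairs share it) are flagged as the least exchangeable
    class and countable through :meth:`ConstraintSet.floor_pairs`.
    """
    code = code or universal_code()
    path = Path(path)
    w: dict[str, float] = {}
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if lineno == 1 and line.lower().startswith("pair"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConstraintFormatError(
                f"{path}:{lineno}: expected 'pair<TAB>value', got {line!r}"
            )
        pair, raw = parts
        pair = "".join(sorted(pair.strip()))
        if len(pair) != 2 or any(c not in AMINO_ACIDS for c in pair):
            raise ConstraintFormatError(
                f"{path}:{lineno}: invalid pair label {parts[0]!r}"
            )
        if pair in w:
            raise ConstraintFormatError(f"{path}:{lineno}: duplicate pair {pair}")
        try:
            w[pair] = float(raw)
        except ValueError:
            raise ConstraintFormatError(
                f"{path}:{lineno}: unparseable value {raw!r}"
            ) from None
    expected = {
        _pair_key(a, b)
        for a, b in itertools.combinations(code.amino_acids, 2)
    }
    missing = sorted(expected - set(w))
    if missing:
        raise ConstraintFormatError(
            f"{path}: missing pair(s): {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    if floor_value is None:
        vmin = min(w.values())
        n_at_min = sum(1 for v in w.values() if v == vmin)
        floor_value = vmin if n_at_min >= 2 else float("-inf")
    return ConstraintSet(w=w, floor_value=floor_value)


# ---------------------------------------------------------------------------
# correlation analysis
# ---------------------------------------------------------------------------

def constraint_correlation(
    A: ConstraintSet,
    B: ConstraintSet,
    subset: str = "all",
    code: GeneticCode | None = None,
    exclude_floor: bool = False,
) -> float:
    """Pearson correlation of two constraint sets over a pair subset.

    *subset* selects ``single_step``, ``multi_step`` or ``all`` amino-acid
    pairs of *code*; *exclude_floor* drops pairs sitting at the floor value
    in either set.  Correlation is invariant under affine rescaling of
    either set, so the strength/offset parameters of the linear constraint
    map do not affect it.
    """
    code = code or universal_code()
    classes = code.pair_step_classes()
    if subset == "single_step":
        keys = [k for k in classes if classes[k] == 1]
    elif subset == "multi_step":
        keys = [k for k in classes if classes[k] >= 2]
    elif subset == "all":
        keys = list(classes)
    else:
        raise ModelError(f"unknown subset {subset!r}")
    pairs = sorted("".join(sorted(k)) for k in keys)
    if exclude_floor:
        pairs = [
            k
            for k in pairs
            if A.w[k] > A.floor_value and B.w[k] > B.floor_value
        ]
    if len(pairs) < 3:
        raise ModelError(
            f"fewer than 3 pairs left in subset {subset!r} after exclusions"
        )
    xa = np.array([A.w[k] for k in pairs])
    xb = np.array([B.w[k] for k in pairs])
    return float(np.corrcoef(xa, xb)[0, 1])
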