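"""Genetic-code tables and codon-pair combinatorics.

A :class:`GeneticCode` maps each of the 64 trinucleotides over ``{A,C,G,T}``
to one of the 20 amino acids or to the stop sentinel ``"*"``.  Everything the
substitution model needs from the code is derived here: the ordered list of
sense codons, synonymy, the minimum number of nucleotide changes separating
two amino acids, and the partition of amino-acid pairs into single-,
double- and triple-step classes.

Canonical orders used throughout the package:

* codons: lexicographic over ``A < C < G < T``, i.e. index
  ``16*i1 + 4*i2 + i3``;
* amino acids: alphabetical by one-letter code (``A, C, D, ..., Y``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "NUCLEOTIDES",
    "STOP",
    "AMINO_ACIDS",
    "ALL_CODONS",
    "GeneticCode",
    "universal_code",
    "vertebrate_mitochondrial_code",
    "get_code",
    "load_code_table",
    "translate",
    "min_nucleotide_changes",
    "single_step_pairs",
    "pair_step_classes",
    "all_amino_acid_pairs",
]

NUCLEOTIDES = "ACGT"
STOP = "*"
#: The 20 amino acids, alphabetical by one-letter code.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
#: All 64 codons in canonical (lexicographic A<C<G<T) order.
ALL_CODONS = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)

_UNIVERSAL_TABLE = (
    "AAA:K AAC:N AAG:K AAT:N ACA:T ACC:T ACG:T ACT:T AGA:R AGC:S AGG:R AGT:S "
    "ATA:I ATC:I ATG:M ATT:I CAA:Q CAC:H CAG:Q CAT:H CCA:P CCC:P CCG:P CCT:P "
    "CGA:R CGC:R CGG:R CGT:R CTA:L CTC:L CTG:L CTT:L GAA:E GAC:D GAG:E GAT:D "
    "GCA:A GCC:A GCG:A GCT:A GGA:G GGC:G GGG:G GGT:G GTA:V GTC:V GTG:V GTT:V "
    "TAA:* TAC:Y TAG:* TAT:Y TCA:S TCC:S TCG:S TCT:S TGA:* TGC:C TGG:W TGT:C "
    "TTA:L TTC:F TTG:L TTT:F"
)

# Vertebrate mitochondrial code: TGA->Trp, ATA->Met, AGA/AGG->stop.
_VERT_MITO_TABLE = (
    "AAA:K AAC:N AAG:K AAT:N ACA:T ACC:T ACG:T ACT:T AGA:* AGC:S AGG:* AGT:S "
    "ATA:M ATC:I ATG:M ATT:I CAA:Q CAC:H CAG:Q CAT:H CCA:P CCC:P CCG:P CCT:P "
    "CGA:R CGC:R CGG:R CGT:R CTA:L CTC:L CTG:L CTT:L GAA:E GAC:D GAG:E GAT:D "
    "GCA:A GCC:A GCG:A GCT:A GGA:G GGC:G GGG:G GGT:G GTA:V GTC:V GTG:V GTT:V "
    "TAA:* TAC:Y TAG:* TAT:Y TCA:S TCC:S TCG:S TCT:S TGA:W TGC:C TGG:W TGT:C "
    "TTA:L TTC:F TTG:L TTT:F"
)


def _parse_table(text: str) -> dict[str, str]:
    out = {}
    for item in text.split():
        codon, aa = item.split(":")
        out[codon] = aa
    return out


class CodeError(ValueError):
    """Invalid codon, amino acid, or genetic-code table."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon -> amino-acid (or stop) map plus derived views.

    Attributes
    ----------
    name
        Identifier, e.g. ``"universal"``.
    codon_to_aa
        Map from each of the 64 codons to a one-letter amino-acid code or
        ``"*"`` for stop.
    """

    name: str
    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    amino_acids: tuple[str, ...] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            missing = set(ALL_CODONS) - set(self.codon_to_aa)
            extra = set(self.codon_to_aa) - set(ALL_CODONS)
            raise CodeError(
                f"code table must map exactly the 64 codons "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        bad = sorted(
            aa for aa in self.codon_to_aa.values()
            if aa != STOP and aa not in AMINO_ACIDS
        )
        if bad:
            raise CodeError(f"unknown amino-acid symbols in table: {bad}")
        sense = tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)
        stops = tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == STOP)
        aas = tuple(sorted({self.codon_to_aa[c] for c in sense}))
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(self, "amino_acids", aas)

    # -- basic queries ---------------------------------------------------

    def translate(self, codon: str) -> str:
        """Return the amino acid encoded by *codon*, or ``"*"`` for stop."""
        if not isinstance(codon, str) or len(codon) != 3 or any(
            c not in NUCLEOTIDES for c in codon
        ):
            raise CodeError(
                f"codon must be three characters over ACGT, got {codon!r}"
            )
        return self.codon_to_aa[codon]

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """Synonymous codon family of amino acid *aa* (canonical order)."""
        if aa not in self.amino_acids:
            raise CodeError(f"amino acid {aa!r} not encoded by {self.name}")
        return tuple(c for c in self.sense_codons if self.codon_to_aa[c] == aa)

    # -- combinatorics ---------------------------------------------------

    def min_nucleotide_changes(self, aa_a: str, aa_b: str) -> int:
        """Minimum Hamming distance between any codon of *aa_a* and any of *aa_b*.

        Zero if and only if the two amino acids are identical.
        """
        ca, cb = self.codons_for(aa_a), self.codons_for(aa_b)
        return min(_hamming(x, y) for x in ca for y in cb)

    def single_step_pairs(self) -> frozenset[frozenset[str]]:
        """Unordered amino-acid pairs separated by a single nucleotide change."""
        return frozenset(
            p for p, k in self.pair_step_classes().items() if k == 1
        )

    def pair_step_classes(self) -> dict[frozenset[str], int]:
        """Partition of all unordered amino-acid pairs into step classes 1-3."""
        out: dict[frozenset[str], int] = {}
        for aa_a, aa_b in itertools.combinations(self.amino_acids, 2):
            out[frozenset((aa_a, aa_b))] = self.min_nucleotide_changes(aa_a, aa_b)
        return out

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        return self.translate(codon_a) == self.translate(codon_b)


def _hamming(x: str, y: str) -> int:
    return sum(a != b for a, b in zip(x, y))


_UNIVERSAL = GeneticCode("universal", _parse_table(_UNIVERSAL_TABLE))
_VERT_MITO = GeneticCode(
    "vertebrate_mitochondrial", _parse_table(_VERT_MITO_TABLE)
)


def universal_code() -> GeneticCode:
    """The universal (standard) nuclear genetic code: 61 sense codons, 3 stops."""
    return _UNIVERSAL


def vertebrate_mitochondrial_code() -> GeneticCode:
    """The vertebrate mitochondrial code: 60 sense codons, 4 stops."""
    return _VERT_MITO


def get_code(name: str) -> GeneticCode:
    """Look up a built-in genetic code by name."""
    try:
        return {
            "universal": _UNIVERSAL,
            "standard": _UNIVERSAL,
            "vertebrate_mitochondrial": _VERT_MITO,
            "vertebrate_mito": _VERT_MITO,
        }[name]
    except KeyError:
        raise CodeError(f"unknown genetic code {name!r}") from None


def load_code_table(path: str | Path, name: str | None = None) -> GeneticCode:
    """Load a genetic code from a two-column text table (codon, amino acid or ``*``).

    Blank lines and lines starting with ``#`` are ignored.
    """
    path = Path(path)
    table: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise CodeError(f"{path}:{lineno}: expected 'codon aa', got {line!r}")
        codon, aa = parts[0].upper(), parts[1]
        if codon in table:
            raise CodeError(f"{path}:{lineno}: duplicate codon {codon}")
        table[codon] = aa
    return GeneticCode(name or path.stem, table)


# -- module-level functional wrappers -------------------------------------

def translate(codon: str, code: GeneticCode) -> str:
    """Translate *codon* under *code*; returns ``"*"`` for stop codons."""
    return code.translate(codon)


def min_nucleotide_changes(aa_a: str, aa_b: str, code: GeneticCode) -> int:
    """Minimum nucleotide changes needed to interchange two amino acids."""
    return code.min_nucleotide_changes(aa_a, aa_b)


def single_step_pairs(code: GeneticCode) -> frozenset[frozenset[str]]:
    """All unordered amino-acid pairs reachable by one nucleotide change."""
    return code.single_step_pairs()


def pair_step_classes(code: GeneticCode) -> dict[frozenset[str], int]:
    """Map every unordered amino-acid pair to its step class (1, 2 or 3)."""
    return code.pair_step_classes()


def all_amino_acid_pairs(code: GeneticCode) -> list[tuple[str, str]]:
    """All unordered amino-acid pairs of *code* as sorted tuples, sorted."""
    return list(itertools.combinations(code.amino_acids, 2))
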