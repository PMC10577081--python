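"""Amino-acid variant identities and codon-level helpers.

A variant effect map scores every single amino-acid substitution of a target
protein.  Internally each substitution is a :class:`VariantKey` — a 1-based
residue position, the reference residue, and the alternate residue, where
``'*'`` marks a stop gain (nonsense) and ``alt == ref`` marks a synonymous
(codon-level) change.  Nucleotide coordinates are 0-based and half-open
everywhere; residue positions are 1-based in keys and human-readable output.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import seq3

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
#: alt-residue alphabet used for integer encodings (20 amino acids + stop)
ALT_ALPHABET = AMINO_ACIDS + STOP
NUCLEOTIDES = "ACGT"

MISSENSE = "missense"
NONSENSE = "nonsense"
SYNONYMOUS = "synonymous"

_standard_table = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard_table.forward_table)
for _stop_codon in _standard_table.stop_codons:
    CODON_TO_AA[_stop_codon] = STOP

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TO_AA):
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in sorted(CODON_TO_AA) if CODON_TO_AA[c] != STOP
)


class VariantKey(NamedTuple):
    """One amino-acid-level change: (position, reference, alternate)."""

    pos: int
    ref: str
    alt: str

    @property
    def variant_class(self) -> str:
        if self.alt == STOP:
            return NONSENSE
        if self.alt == self.ref:
            return SYNONYMOUS
        return MISSENSE

    def hgvs_pro(self) -> str:
        """HGVS-like protein notation (``p.Arg26Pro``, ``p.Trp198Ter``,
        ``p.Ala5=`` for synonymous changes)."""
        ref3 = seq3(self.ref)
        if self.variant_class == SYNONYMOUS:
            return f"p.{ref3}{self.pos}="
        alt3 = "Ter" if self.alt == STOP else seq3(self.alt)
        return f"p.{ref3}{self.pos}{alt3}"


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a DNA codon: {codon!r}")
    return CODON_TO_AA[codon]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@lru_cache(maxsize=None)
def canonical_codon_change(ref_codon: str, alt_aa: str) -> str | None:
    """Pick the single codon used to realise an amino-acid change.

    The library simulator and read-level machinery collapse codon detail to
    one canonical codon per amino-acid substitution: the codon encoding
    ``alt_aa`` with the fewest nucleotide differences from ``ref_codon``
    (ties broken alphabetically).  Returns ``None`` when no distinct codon
    exists — a synonymous change at a single-codon residue (Met, Trp).
    """
    best: str | None = None
    best_key: tuple[int, str] | None = None
    for codon in AA_TO_CODONS[alt_aa]:
        if codon == ref_codon:
            continue
        key = (hamming(ref_codon, codon), codon)
        if best_key is None or key < best_key:
            best, best_key = codon, key
    return best


def codon_changes(ref_codon: str, alt_codon: str) -> tuple[tuple[int, str, str], ...]:
    """Nucleotide edits ``(offset_in_codon, ref_base, alt_base)`` between codons."""
    return tuple(
        (i, r, a) for i, (r, a) in enumerate(zip(ref_codon, alt_codon)) if r != a
    )


def encode_key(key: VariantKey) -> int:
    """Dense integer code for a variant key (used by the clone-pool arrays)."""
    return (key.pos - 1) * len(ALT_ALPHABET) + ALT_ALPHABET.index(key.alt)


def decode_key(code: int, protein: str) -> VariantKey:
    n_alt = len(ALT_ALPHABET)
    pos = code // n_alt + 1
    alt = ALT_ALPHABET[code % n_alt]
    return VariantKey(pos, protein[pos - 1], alt)


def all_keys_for_position(pos: int, ref: str) -> list[VariantKey]:
    """Every substitution at one position: 19 missense, 1 nonsense, 1 synonymous."""
    return [VariantKey(pos, ref, alt) for alt in ALT_ALPHABET]
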