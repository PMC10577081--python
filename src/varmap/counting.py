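"""Duplex variant calling and depth-normalised count tables.

Short amplicon tiles are sequenced on both strands; a substitution is only
trusted where the forward and reverse read of a pair agree on the same
non-reference base.  The posterior that such a concordant call is real is
computed from the two Phred qualities against a uniform prior over bases,
and calls with posterior at or below the threshold (default 90%) are
dropped.  Surviving nucleotide calls are translated — jointly per codon —
to amino-acid variants and aggregated into per-condition count tables whose
frequencies are normalised by the sequencing depth of the covering tile.

Alignment is out of scope: read pairs arrive with known tile offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import CoordinateError, MalformedInputError
from .variants import VariantKey, translate_codon

DEFAULT_POSTERIOR_THRESHOLD = 0.9
PHRED_OFFSET = 33


@dataclass(frozen=True)
class ReadPair:
    """An aligned duplex observation covering exactly one tile.

    ``offset`` is the 0-based coding-strand coordinate of the first covered
    base; call and quality strings are given in coding-strand orientation
    for both reads.
    """

    tile_id: int
    offset: int
    calls_fwd: str
    calls_rev: str
    quals_fwd: str
    quals_rev: str

    def __post_init__(self) -> None:
        lens = {
            len(self.calls_fwd),
            len(self.calls_rev),
            len(self.quals_fwd),
            len(self.quals_rev),
        }
        if len(lens) != 1:
            raise MalformedInputError(
                "call and quality strings of a read pair must have equal length"
            )


class VariantCall(NamedTuple):
    """A trusted nucleotide-level substitution within one read pair."""

    pos: int  # 0-based coding coordinate
    ref: str
    alt: str
    posterior: float


def phred_to_error(q: float) -> float:
    return 10.0 ** (-q / 10.0)


def error_to_phred(eps: float, max_q: int = 41) -> int:
    """Integer Phred score for an error probability (capped at ``max_q``)."""
    if eps <= 0:
        return max_q
    return int(min(max_q, round(-10.0 * np.log10(eps))))


def duplex_posterior(q_fwd: float, q_rev: float) -> float:
    """Posterior probability that a concordant non-reference call is real.

    Both reads of a pair report the same alternate base ``b``.  With
    per-read error probabilities ``e1, e2`` (from the Phred scores), a
    symmetric error model spreading each error uniformly over the three
    other bases, independent reads, and a uniform prior over the four
    possible true bases:

        P(b | obs) = (1-e1)(1-e2) / [ (1-e1)(1-e2) + e1*e2/3 ]

    since each of the three non-``b`` true bases (reference included)
    explains the double observation with probability (e1/3)(e2/3).
    """
    e1 = phred_to_error(q_fwd)
    e2 = phred_to_error(q_rev)
    agree = (1.0 - e1) * (1.0 - e2)
    return agree / (agree + e1 * e2 / 3.0)


def call_pair(
    pair: ReadPair,
    reference: str,
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    phred_offset: int = PHRED_OFFSET,
) -> list[VariantCall]:
    """Call concordant substitutions in one duplex read pair.

    A position yields a candidate only where both reads agree on the same
    non-reference base; discordant mismatches are ignored.  Candidates with
    duplex posterior <= ``posterior_threshold`` are suppressed.
    """
    if not 0.0 < posterior_threshold < 1.0:
        raise MalformedInputError("posterior_threshold must lie in (0, 1)")
    n = len(pair.calls_fwd)
    ref_segment = reference[pair.offset : pair.offset + n]
    if len(ref_segment) != n:
        raise CoordinateError("read pair extends past the reference")
    if pair.calls_fwd == ref_segment and pair.calls_rev == ref_segment:
        return []
    fwd = np.frombuffer(pair.calls_fwd.encode(), dtype=np.uint8)
    rev = np.frombuffer(pair.calls_rev.encode(), dtype=np.uint8)
    ref = np.frombuffer(ref_segment.encode(), dtype=np.uint8)
    candidates = np.flatnonzero((fwd == rev) & (fwd != ref))
    calls: list[VariantCall] = []
    for i in candidates:
        alt = pair.calls_fwd[i]
        if alt not in "ACGT":
            continue
        post = duplex_posterior(
            ord(pair.quals_fwd[i]) - phred_offset,
            ord(pair.quals_rev[i]) - phred_offset,
        )
        if post > posterior_threshold:
            calls.append(
                VariantCall(pair.offset + int(i), ref_segment[i], alt, post)
            )
    return calls


def translate_calls(
    calls: Iterable[VariantCall], reference: str
) -> list[VariantKey]:
    """Translate nucleotide calls to amino-acid variant keys.

    Multiple substitutions falling in one codon within the same pair are
    applied jointly before translation (standard genetic code).  Stop gains
    come back with ``alt='*'``; synonymous changes with ``alt == ref``.
    """
    if len(reference) % 3 != 0:
        raise CoordinateError("coding sequence length must be divisible by 3")
    by_codon: dict[int, list[VariantCall]] = {}
    for call in calls:
        if not 0 <= call.pos < len(reference):
            raise CoordinateError(f"call position {call.pos} outside reference")
        by_codon.setdefault(call.pos // 3, []).append(call)
    keys: list[VariantKey] = []
    for codon_idx, codon_calls in sorted(by_codon.items()):
        ref_codon = reference[codon_idx * 3 : codon_idx * 3 + 3]
        mutated = list(ref_codon)
        for call in codon_calls:
            mutated[call.pos - codon_idx * 3] = call.alt
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon("".join(mutated))
        keys.append(VariantKey(codon_idx + 1, ref_aa, alt_aa))
    return keys


@dataclass
class CountTable:
    """Per-variant read counts and depth-normalised frequencies.

    ``depth`` maps tile ids to read-pair counts; a variant's frequency is
    its count divided by the depth of its covering tile (the tile containing
    the first base of its codon).
    """

    condition: str
    replicate: int
    counts: dict[VariantKey, int]
    depth: dict[int, int]
    tile_bounds: dict[int, tuple[int, int]]  # tile_id -> (start, end) nt, half-open
    _freq: dict[VariantKey, float] | None = field(default=None, repr=False)

    def tile_of(self, key: VariantKey) -> int:
        nt = (key.pos - 1) * 3
        for tile_id, (start, end) in self.tile_bounds.items():
            if start <= nt < end:
                return tile_id
        raise CoordinateError(f"no tile covers residue {key.pos}")

    def depth_of(self, key: VariantKey) -> int:
        return self.depth.get(self.tile_of(key), 0)

    @property
    def frequency(self) -> dict[VariantKey, float]:
        if self._freq is None:
            freq = {}
            for key, count in self.counts.items():
                d = self.depth_of(key)
                freq[key] = count / d if d > 0 else float("nan")
            self._freq = freq
        return self._freq

    def frequency_of(self, key: VariantKey) -> float:
        d = self.depth_of(key)
        return self.counts.get(key, 0) / d if d > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant": key.hgvs_pro(),
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "condition": self.condition,
                "replicate": self.replicate,
                "count": count,
                "depth": self.depth_of(key),
                "frequency": self.frequency[key],
            }
            for key, count in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "variant",
                "pos",
                "ref",
                "alt",
                "condition",
                "replicate",
                "count",
                "depth",
                "frequency",
            ],
        )


def tabulate(
    pairs: Iterable[ReadPair],
    reference: str,
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    condition: str = "nonselective",
    replicate: int = 1,
) -> CountTable:
    """Aggregate a stream of read pairs into a :class:`CountTable`.

    Per-tile depths count every pair (wild-type pairs included); variant
    counts aggregate the translated calls of each pair.  Deterministic in
    the input order.  An empty stream yields an empty table with a warning.
    """
    counts: dict[VariantKey, int] = {}
    depth: dict[int, int] = {}
    tile_bounds: dict[int, tuple[int, int]] = {}
    seen = False
    for pair in pairs:
        seen = True
        depth[pair.tile_id] = depth.get(pair.tile_id, 0) + 1
        tile_bounds.setdefault(
            pair.tile_id, (pair.offset, pair.offset + len(pair.calls_fwd))
        )
        calls = call_pair(pair, reference, posterior_threshold)
        if calls:
            for key in translate_calls(calls, reference):
                counts[key] = counts.get(key, 0) + 1
    if not seen:
        warnings.warn("empty read-pair stream: returning empty count table")
    return CountTable(condition, replicate, counts, depth, tile_bounds)
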