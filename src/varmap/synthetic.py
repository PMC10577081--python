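"""In-silico stand-in for a saturation-mutagenesis selection experiment.

This module generates a ground-truth fitness map for a protein, simulates a
codon-randomised clone library (Poisson number of amino-acid changes per
clone, two mutagenesis regions), applies exponential growth selection in
which a clone's fitness is the minimum true score among its variants, and
sequences the pool as tiled duplex read pairs.  Every stochastic operation
takes an explicit seed; there is no global random state.

Two sequencing paths are provided.  :func:`simulate_read_pairs` emits
individual :class:`~varmap.counting.ReadPair` observations suitable for the
duplex caller and is used at modest depth.  :func:`simulate_tile_counts`
samples the count table that the caller would produce directly from the
closed-form per-pair detection and double-error probabilities of the same
error model, applying the identical duplex-posterior rule; it is
distributionally equivalent at the count level and fast enough for
million-pair depths.  Tests assert the two paths agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .counting import (
    CountTable,
    ReadPair,
    duplex_posterior,
    error_to_phred,
)
from .errors import InputError, ParameterError
from .variants import (
    ALT_ALPHABET,
    AMINO_ACIDS,
    MISSENSE,
    NONSENSE,
    STOP,
    SENSE_CODONS,
    SYNONYMOUS,
    VariantKey,
    canonical_codon_change,
    codon_changes,
    decode_key,
    encode_key,
    translate_codon,
)

#: nonsense changes within this many residues of the C terminus are treated
#: as tolerated (true score 1) — truncations there rarely matter.
C_TERMINAL_TOLERANT = 14


@dataclass(frozen=True)
class BimodalParams:
    """Two-component Gaussian mixture for missense true scores.

    Missense variants in complementation maps cluster around null-like (0)
    and wild-type-like (1) behaviour; the defaults put roughly a third of
    missense changes in the damaging mode.
    """

    weight_low: float = 0.35
    weight_high: float = 0.65
    mean_low: float = 0.03
    sd_low: float = 0.08
    mean_high: float = 0.97
    sd_high: float = 0.08

    def validate(self) -> None:
        if abs(self.weight_low + self.weight_high - 1.0) > 1e-9:
            raise ParameterError("mixture weights must sum to 1")
        if self.sd_low < 0 or self.sd_high < 0:
            raise ParameterError("mixture standard deviations must be nonnegative")


@dataclass(frozen=True)
class GroundTruthMap:
    """True functional scores and classes for every substitution.

    Synonymous variants score exactly 1; nonsense variants score exactly 0
    except within the last ``C_TERMINAL_TOLERANT`` residues; a configurable
    fraction of missense variants are hyper-complementing (score > 1).
    """

    protein_length: int
    cds: str
    true_score: dict[VariantKey, float]
    variant_class: dict[VariantKey, str]
    hyper_fraction: float

    @property
    def protein(self) -> str:
        return "".join(
            translate_codon(self.cds[i : i + 3]) for i in range(0, len(self.cds), 3)
        )


@dataclass(frozen=True)
class LibraryModel:
    """Clone-library composition: Poisson variants per clone, regional pools."""

    mean_variants_per_clone: float = 1.7
    n_clones: int = 1_000_000
    region_bounds: tuple[tuple[int, int], ...] | None = None  # 1-based, half-open
    wt_clone_fraction: float = 0.0

    def regions_for(self, protein_length: int) -> tuple[tuple[int, int], ...]:
        """Resolved mutagenesis regions; default is two equal halves."""
        if self.region_bounds is None:
            half = protein_length // 2 + 1
            return ((1, half), (half, protein_length + 1))
        bounds = tuple(self.region_bounds)
        expected = 1
        for start, end in bounds:
            if start != expected or end <= start:
                raise ParameterError("region bounds must partition [1, protein_length]")
            expected = end
        if expected != protein_length + 1:
            raise ParameterError("region bounds must partition [1, protein_length]")
        return bounds

    def __post_init__(self) -> None:
        if self.mean_variants_per_clone <= 0:
            raise ParameterError("mean_variants_per_clone must be positive")
        if self.n_clones < 1:
            raise ParameterError("n_clones must be positive")
        if not 0.0 <= self.wt_clone_fraction <= 1.0:
            raise ParameterError("wt_clone_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SequencingModel:
    """Tiled duplex sequencing: tile geometry, depth, and error rate."""

    depth_per_tile: int = 2_000_000
    tile_length: int = 150
    per_base_error: float = 0.001
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error < 0.75:
            raise ParameterError("per_base_error must lie in [0, 0.75)")
        if self.depth_per_tile < 1 or self.tile_length < 3:
            raise ParameterError("depth_per_tile and tile_length must be positive")
        if self.tile_length % 3 != 0:
            raise ParameterError(
                "tile_length must be a multiple of 3 so tiles respect codon bounds"
            )

    def tiles(self, cds_length: int) -> list[tuple[int, int]]:
        """Gap-free tiling of the coding sequence (0-based, half-open nt)."""
        if cds_length % self.tile_length != 0:
            raise ParameterError(
                f"coding length {cds_length} is not divisible into "
                f"{self.tile_length} bp tiles"
            )
        return [
            (s, s + self.tile_length) for s in range(0, cds_length, self.tile_length)
        ]

    @property
    def quality(self) -> int:
        return error_to_phred(self.per_base_error)


@dataclass(frozen=True)
class SelectionModel:
    """Exponential-growth selection, linear in true score.

    Growth rate is affine in score with ``stop_syn_growth_gap`` the log-fold
    rate difference between a score-0 and a score-1 clone, so after
    ``generations`` of growth the frequency ratio of a score-1 to a score-0
    clone is multiplied by ``exp(gap * generations)``.  Per-clone
    multiplicative log-normal noise with s.d. ``noise_sd`` models biological
    replicate variation.
    """

    generations: float = 6.0
    stop_syn_growth_gap: float = 0.5
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ParameterError("generations must be positive")
        if self.stop_syn_growth_gap <= 0:
            raise ParameterError("stop_syn_growth_gap must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")


@dataclass
class ClonePool:
    """A set of clones with relative abundances (CSR-style variant arrays)."""

    codes: np.ndarray  # flat encoded VariantKeys for all clones
    indptr: np.ndarray  # clone i owns codes[indptr[i]:indptr[i+1]]
    abundance: np.ndarray  # sums to 1
    truth: GroundTruthMap
    region: tuple[int, int] | None = None

    @property
    def n_clones(self) -> int:
        return len(self.abundance)

    def clone_variants(self, i: int) -> list[VariantKey]:
        protein = self.truth.protein
        return [
            decode_key(int(c), protein)
            for c in self.codes[self.indptr[i] : self.indptr[i + 1]]
        ]

    def variants_per_clone(self) -> np.ndarray:
        return np.diff(self.indptr)

    def min_scores(self) -> np.ndarray:
        """Per-clone fitness: minimum true score over carried variants (1 for WT)."""
        protein = self.truth.protein
        score_lookup = np.ones(len(protein) * len(ALT_ALPHABET))
        for key, s in self.truth.true_score.items():
            score_lookup[encode_key(key)] = s
        out = np.ones(self.n_clones)
        sizes = self.variants_per_clone()
        nonempty = np.flatnonzero(sizes > 0)
        if len(nonempty):
            flat = score_lookup[self.codes]
            out[nonempty] = np.minimum.reduceat(flat, self.indptr[nonempty])
        return out

    def marginal_frequencies(self) -> dict[VariantKey, float]:
        """Abundance-weighted fraction of the pool carrying each variant.

        Summed over variants this equals the mean number of variants per
        clone draw.
        """
        n_codes = self.truth.protein_length * len(ALT_ALPHABET)
        acc = np.zeros(n_codes)
        weights = np.repeat(self.abundance, self.variants_per_clone())
        np.add.at(acc, self.codes, weights)
        protein = self.truth.protein
        return {
            decode_key(int(c), protein): acc[c] for c in np.flatnonzero(acc > 0)
        }


def _random_cds(protein_length: int, rng: np.random.Generator) -> str:
    codons = rng.choice(len(SENSE_CODONS), size=protein_length)
    return "".join(SENSE_CODONS[i] for i in codons)


def generate_ground_truth(
    protein_length: int,
    hyper_fraction: float = 0.025,
    bimodal_params: BimodalParams | None = None,
    seed: int = 0,
) -> GroundTruthMap:
    """Draw a ground-truth map: reference CDS plus a score for every change.

    Missense scores come from a two-component mixture (null-like and
    wild-type-like modes); a ``hyper_fraction`` of missense variants are
    re-drawn uniformly on (1.05, 1.5) to emulate hyper-complementation.
    Deterministic given the seed.
    """
    if protein_length < 30:
        raise ParameterError("protein_length must be at least 30")
    if not 0.0 <= hyper_fraction <= 0.2:
        raise ParameterError("hyper_fraction must lie in [0, 0.2]")
    params = bimodal_params or BimodalParams()
    params.validate()
    rng = np.random.default_rng(seed)
    cds = _random_cds(protein_length, rng)
    protein = "".join(
        translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3)
    )
    true_score: dict[VariantKey, float] = {}
    classes: dict[VariantKey, str] = {}
    for pos in range(1, protein_length + 1):
        ref = protein[pos - 1]
        syn = VariantKey(pos, ref, ref)
        true_score[syn] = 1.0
        classes[syn] = SYNONYMOUS
        stop_key = VariantKey(pos, ref, STOP)
        true_score[stop_key] = (
            1.0 if pos > protein_length - C_TERMINAL_TOLERANT else 0.0
        )
        classes[stop_key] = NONSENSE
        for alt in AMINO_ACIDS:
            if alt == ref:
                continue
            key = VariantKey(pos, ref, alt)
            if rng.random() < hyper_fraction:
                score = rng.uniform(1.05, 1.5)
            else:
                # ordinary missense scores are confined to [0, 1]; only
                # hyper-complementing variants may exceed wild type.
                # Out-of-range draws are reflected at the boundaries so the
                # distribution stays continuous (no artificial atoms).
                if rng.random() < params.weight_low:
                    score = rng.normal(params.mean_low, params.sd_low)
                else:
                    score = rng.normal(params.mean_high, params.sd_high)
                if score < 0.0:
                    score = -score
                if score > 1.0:
                    score = 2.0 - score
                score = min(max(score, 0.0), 1.0)
            true_score[key] = float(score)
            classes[key] = MISSENSE
    return GroundTruthMap(
        protein_length=protein_length,
        cds=cds,
        true_score=true_score,
        variant_class=classes,
        hyper_fraction=hyper_fraction,
    )


def realizable_alts(truth: GroundTruthMap, pos: int) -> list[str]:
    """Alternate residues reachable by some codon change at this position.

    All missense and nonsense changes are reachable; a synonymous change
    needs a second codon for the reference residue.
    """
    ref_codon = truth.cds[(pos - 1) * 3 : pos * 3]
    ref = translate_codon(ref_codon)
    alts = []
    for alt in ALT_ALPHABET:
        if alt == ref and canonical_codon_change(ref_codon, ref) is None:
            continue
        alts.append(alt)
    return alts


def simulate_clone_pool(
    truth: GroundTruthMap,
    lib: LibraryModel,
    seed: int = 0,
    region: tuple[int, int] | None = None,
) -> ClonePool:
    """Simulate one mutagenised clone pool.

    Each clone carries a Poisson(``mean_variants_per_clone``) number of
    amino-acid changes at distinct positions within its mutagenised region
    (zero-variant clones are wild type), drawn uniformly over the
    realizable substitutions at each position.  ``region`` restricts the
    whole pool to one mutagenesis region (1-based, half-open residues);
    otherwise clones are spread over the library's regions.
    """
    rng = np.random.default_rng(seed)
    regions = (region,) if region is not None else lib.regions_for(truth.protein_length)
    for start, end in regions:
        if start < 1 or end > truth.protein_length + 1 or end <= start:
            raise ParameterError(f"region ({start}, {end}) outside protein")
    n = lib.n_clones
    k = rng.poisson(lib.mean_variants_per_clone, size=n)
    if lib.wt_clone_fraction > 0:
        k[rng.random(n) < lib.wt_clone_fraction] = 0
    clone_region = rng.integers(0, len(regions), size=n)

    # positions drawn with replacement, then clones with intra-clone
    # duplicates redrawn without replacement (duplicates are rare)
    starts = np.array([r[0] for r in regions])
    sizes = np.array([r[1] - r[0] for r in regions])
    pos_flat = (
        starts[clone_region].repeat(k)
        + (rng.random(int(k.sum())) * sizes[clone_region].repeat(k)).astype(np.int64)
    )
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(k, out=indptr[1:])
    for i in np.flatnonzero(k > 1):
        seg = pos_flat[indptr[i] : indptr[i + 1]]
        if len(np.unique(seg)) != len(seg):
            lo, width = regions[clone_region[i]][0], sizes[clone_region[i]]
            if k[i] > width:
                raise ParameterError("more variants per clone than region positions")
            pos_flat[indptr[i] : indptr[i + 1]] = lo + rng.choice(
                width, size=k[i], replace=False
            )

    alts_by_pos = {
        pos: realizable_alts(truth, pos)
        for pos in range(1, truth.protein_length + 1)
    }
    protein = truth.protein
    n_alt = len(ALT_ALPHABET)
    codes = np.empty(len(pos_flat), dtype=np.int64)
    alt_pick = rng.random(len(pos_flat))
    for j, pos in enumerate(pos_flat):
        alts = alts_by_pos[int(pos)]
        alt = alts[int(alt_pick[j] * len(alts))]
        codes[j] = (pos - 1) * n_alt + ALT_ALPHABET.index(alt)

    abundance = np.full(n, 1.0 / n)
    return ClonePool(
        codes=codes,
        indptr=indptr,
        abundance=abundance,
        truth=truth,
        region=region,
    )


def wild_type_pool(truth: GroundTruthMap, n_clones: int = 1) -> ClonePool:
    """A control pool carrying no variants (mirrors the WT ORF control)."""
    return ClonePool(
        codes=np.empty(0, dtype=np.int64),
        indptr=np.zeros(n_clones + 1, dtype=np.int64),
        abundance=np.full(n_clones, 1.0 / n_clones),
        truth=truth,
    )


def simulate_selection(
    pool: ClonePool,
    truth: GroundTruthMap,
    sel: SelectionModel,
    seed: int = 0,
) -> ClonePool:
    """Apply growth selection to a pool and renormalise abundances.

    Each clone's abundance is multiplied by
    ``exp(generations * gap * min_score) * lognormal(0, noise_sd)`` and the
    pool is renormalised, so expected post-selection frequency is monotone
    nondecreasing in clone fitness.
    """
    if pool.n_clones == 0:
        raise InputError("cannot select on an empty clone pool")
    rng = np.random.default_rng(seed)
    log_growth = sel.generations * sel.stop_syn_growth_gap * pool.min_scores()
    if sel.noise_sd > 0:
        log_growth = log_growth + rng.normal(0.0, sel.noise_sd, size=pool.n_clones)
    log_growth -= log_growth.max()  # overflow guard; cancels in renormalisation
    weights = pool.abundance * np.exp(log_growth)
    total = weights.sum()
    if total <= 0:
        raise InputError("selection annihilated the pool")
    return replace(pool, abundance=weights / total)


def _clone_tile_sequence(
    pool: ClonePool, clone_idx: int, start: int, end: int
) -> str:
    """Tile-restricted mutant sequence of one clone (canonical codon changes)."""
    cds = pool.truth.cds
    seg = list(cds[start:end])
    for key in pool.clone_variants(clone_idx):
        codon_start = (key.pos - 1) * 3
        if codon_start < start or codon_start >= end:
            continue
        ref_codon = cds[codon_start : codon_start + 3]
        alt_codon = canonical_codon_change(ref_codon, key.alt)
        if alt_codon is None:
            continue
        for off, _, alt_base in codon_changes(ref_codon, alt_codon):
            seg[codon_start - start + off] = alt_base
    return "".join(seg)


def simulate_read_pairs(
    pool: ClonePool,
    seqm: SequencingModel,
    seed: int = 0,
    depth_per_tile: int | None = None,
) -> Iterator[ReadPair]:
    """Yield duplex read pairs tile by tile.

    Each pair covers exactly one tile on both strands; per-base sequencing
    errors are injected independently in the two reads; constant Phred
    qualities reflect the configured error rate.  Tiles carrying no variant
    still emit (wild-type) pairs.
    """
    rng = np.random.default_rng(seed)
    depth = seqm.depth_per_tile if depth_per_tile is None else depth_per_tile
    cds = pool.truth.cds
    eps = seqm.per_base_error
    qual_char = chr(seqm.quality + seqm.phred_offset)
    tile_len = seqm.tile_length
    quals = qual_char * tile_len
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for tile_id, (start, end) in enumerate(seqm.tiles(len(cds))):
        pair_counts = rng.multinomial(depth, pool.abundance)
        cache: dict[int, str] = {}
        for clone_idx in np.flatnonzero(pair_counts):
            if clone_idx not in cache:
                cache[int(clone_idx)] = _clone_tile_sequence(
                    pool, int(clone_idx), start, end
                )
            template = cache[int(clone_idx)]
            for _ in range(pair_counts[clone_idx]):
                reads = []
                for _strand in range(2):
                    if eps > 0:
                        n_err = rng.binomial(tile_len, eps)
                    else:
                        n_err = 0
                    if n_err == 0:
                        reads.append(template)
                        continue
                    arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
                    err_pos = rng.choice(tile_len, size=n_err, replace=False)
                    for p in err_pos:
                        choices = bases[bases != arr[p]]
                        arr[p] = choices[rng.integers(3)]
                    reads.append(arr.tobytes().decode())
                yield ReadPair(
                    tile_id=tile_id,
                    offset=start,
                    calls_fwd=reads[0],
                    calls_rev=reads[1],
                    quals_fwd=quals,
                    quals_rev=quals,
                )


def simulate_tile_counts(
    pool: ClonePool,
    seqm: SequencingModel,
    seed: int = 0,
    condition: str = "nonselective",
    replicate: int = 1,
    posterior_threshold: float = 0.9,
    depth_per_tile: int | None = None,
) -> CountTable:
    """Sample the count table the duplex caller would produce, directly.

    For each tile, a variant carried at marginal frequency ``f`` whose
    canonical codon change spans ``k`` nucleotides is recovered from a pair
    with probability ``f * (1-eps)^(2k)`` (both reads must agree at every
    changed base), and every (position, alternate-base) cell accrues
    concordant double errors with probability ``(eps/3)^2`` per pair —
    translated through the reference codon to its amino-acid key.  The same
    duplex posterior rule as the read-level caller gates all calls.  Counts
    are binomial draws at sequencing depth; cross-talk between partially
    recovered multi-nucleotide changes is neglected (it is
    epsilon-suppressed relative to the double-error background).
    """
    rng = np.random.default_rng(seed)
    depth = seqm.depth_per_tile if depth_per_tile is None else depth_per_tile
    cds = pool.truth.cds
    eps = seqm.per_base_error
    q = seqm.quality
    passes = duplex_posterior(q, q) > posterior_threshold
    detect_1nt = (1.0 - eps) ** 2
    marginals = pool.marginal_frequencies()
    counts: dict[VariantKey, int] = {}
    depth_map: dict[int, int] = {}
    tile_bounds: dict[int, tuple[int, int]] = {}
    tiles = seqm.tiles(len(cds))
    for tile_id, (start, end) in enumerate(tiles):
        depth_map[tile_id] = depth
        tile_bounds[tile_id] = (start, end)
        if passes:
            for key, f in marginals.items():
                codon_start = (key.pos - 1) * 3
                if not start <= codon_start < end:
                    continue
                ref_codon = cds[codon_start : codon_start + 3]
                alt_codon = canonical_codon_change(ref_codon, key.alt)
                if alt_codon is None:
                    continue
                n_changes = len(codon_changes(ref_codon, alt_codon))
                c = rng.binomial(depth, f * detect_1nt**n_changes)
                if c:
                    counts[key] = counts.get(key, 0) + int(c)
            if eps > 0:
                p_bg = (eps / 3.0) ** 2
                bg = rng.binomial(depth, p_bg, size=(end - start, 3))
                for i, j in zip(*np.nonzero(bg)):
                    nt_pos = start + int(i)
                    ref_base = cds[nt_pos]
                    alt_base = [b for b in "ACGT" if b != ref_base][int(j)]
                    codon_idx = nt_pos // 3
                    ref_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
                    mutated = list(ref_codon)
                    mutated[nt_pos - codon_idx * 3] = alt_base
                    key = VariantKey(
                        codon_idx + 1,
                        translate_codon(ref_codon),
                        translate_codon("".join(mutated)),
                    )
                    counts[key] = counts.get(key, 0) + int(bg[i, j])
    return CountTable(condition, replicate, counts, depth_map, tile_bounds)
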