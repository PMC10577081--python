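"""End-to-end orchestration: simulate, count, score, combine, recover.

These helpers wire the synthetic experiment through the scoring stack the
way the real assay is processed: per mutagenesis region, two sequencing
replicates of the non-selective and selective pools plus a wild-type
control per condition; per-replicate enrichment ratios anchored on the
region's nonsense/synonymous medians; replicate-regularised errors; quality
filters; and finally rescaling plus inverse-variance combination of two
isoform maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import scoring
from .counting import CountTable
from .errors import ParameterError
from .synthetic import (
    ClonePool,
    GroundTruthMap,
    generate_ground_truth,
    LibraryModel,
    SelectionModel,
    SequencingModel,
    simulate_clone_pool,
    simulate_selection,
    simulate_tile_counts,
    wild_type_pool,
)
from .variants import VariantKey


@dataclass(frozen=True)
class ScoringConfig:
    """Every scoring threshold in one place (values mirror the method)."""

    min_count: int = scoring.DEFAULT_MIN_COUNT
    wt_percentile: float = scoring.DEFAULT_WT_PERCENTILE
    max_sigma: float = scoring.DEFAULT_MAX_SIGMA
    min_f_ns: float = scoring.DEFAULT_MIN_F_NS
    c_term_exclusion: int = scoring.C_TERM_EXCLUSION
    error_prior_replicates: float = 2.0
    error_trend_window: int = 51
    posterior_threshold: float = 0.9


@dataclass
class RegionExperiment:
    """Count tables for one mutagenesis region of one isoform."""

    region_index: int
    bounds: tuple[int, int]
    nonselect: list[CountTable]
    select: list[CountTable]
    wt_nonselect: CountTable
    wt_select: CountTable


def simulate_isoform_experiment(
    truth: GroundTruthMap,
    lib: LibraryModel,
    sel: SelectionModel,
    seqm: SequencingModel,
    seed: int,
    n_replicates: int = 2,
    depth_per_tile: int | None = None,
) -> list[RegionExperiment]:
    """Simulate the full experiment for one isoform.

    One clone pool per mutagenesis region; selection replicates are
    independent growth draws of the same pool; sequencing replicates use
    independent seeds.  The wild-type control is a variant-free pool run
    through the same sequencing model for both conditions.
    """
    if n_replicates < 1:
        raise ParameterError("need at least one replicate")
    rng = np.random.default_rng(seed)
    regions = lib.regions_for(truth.protein_length)
    wt = wild_type_pool(truth)
    experiments = []
    for region_index, bounds in enumerate(regions):
        pool = simulate_clone_pool(
            truth, lib, seed=int(rng.integers(2**31)), region=bounds
        )
        nonselect, select = [], []
        for rep in range(1, n_replicates + 1):
            nonselect.append(
                simulate_tile_counts(
                    pool,
                    seqm,
                    seed=int(rng.integers(2**31)),
                    condition="nonselective",
                    replicate=rep,
                    depth_per_tile=depth_per_tile,
                )
            )
            selected = simulate_selection(
                pool, truth, sel, seed=int(rng.integers(2**31))
            )
            select.append(
                simulate_tile_counts(
                    selected,
                    seqm,
                    seed=int(rng.integers(2**31)),
                    condition="selective",
                    replicate=rep,
                    depth_per_tile=depth_per_tile,
                )
            )
        wt_nonselect = simulate_tile_counts(
            wt,
            seqm,
            seed=int(rng.integers(2**31)),
            condition="wt_nonselective",
            depth_per_tile=depth_per_tile,
        )
        wt_select = simulate_tile_counts(
            wt,
            seqm,
            seed=int(rng.integers(2**31)),
            condition="wt_selective",
            depth_per_tile=depth_per_tile,
        )
        experiments.append(
            RegionExperiment(
                region_index=region_index,
                bounds=bounds,
                nonselect=nonselect,
                select=select,
                wt_nonselect=wt_nonselect,
                wt_select=wt_select,
            )
        )
    return experiments


def score_isoform(
    experiments: list[RegionExperiment],
    classes: Mapping[VariantKey, str],
    protein_length: int,
    config: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Score one isoform map from its regional count tables.

    Per region and replicate: count filters, background subtraction,
    enrichment, anchoring on the region's own nonsense/synonymous medians.
    Replicate scores are averaged; sigma comes from the regularised
    replicate deviation; quality filters are recorded per variant.
    Variants outside a region's mutagenised bounds (sequencing-error calls)
    are dropped before scoring.
    """
    frames = []
    for exp in experiments:
        lo, hi = exp.bounds
        fs_by_rep: dict[int, pd.Series] = {}
        f_ns_by_rep: dict[int, pd.Series] = {}
        for rep_idx, (sel_t, ns_t) in enumerate(zip(exp.select, exp.nonselect), 1):
            kept, _ = scoring.filter_counts(
                sel_t,
                ns_t,
                exp.wt_select,
                exp.wt_nonselect,
                min_count=config.min_count,
                wt_percentile=config.wt_percentile,
            )
            kept = {k for k in kept if lo <= k.pos < hi}
            if not kept:
                continue
            records = scoring.adjust_and_enrich(
                sel_t, ns_t, exp.wt_select, exp.wt_nonselect, keys=kept
            )
            scales = scoring.compute_scales(
                records,
                classes,
                protein_length,
                c_term_exclusion=config.c_term_exclusion,
                region_of=lambda pos, idx=exp.region_index: idx,
            )
            fs = scoring.score_records(
                records, scales, region_of=lambda pos, idx=exp.region_index: idx
            )
            fs_by_rep[rep_idx] = fs
            f_ns_by_rep[rep_idx] = records["f_ns"]
        if not fs_by_rep:
            continue
        fs_frame = pd.DataFrame(fs_by_rep)
        f_ns = pd.DataFrame(f_ns_by_rep).mean(axis=1)
        err = scoring.estimate_error(
            fs_frame,
            f_ns,
            m=config.error_prior_replicates,
            window=config.error_trend_window,
        )
        region_scores = pd.DataFrame(
            {
                "fs": fs_frame.mean(axis=1),
                "sigma": err["sigma"],
                "n_rep": err["n_rep"],
                "f_ns": f_ns,
                "region": exp.region_index,
            }
        )
        frames.append(scoring.quality_filter(
            region_scores, max_sigma=config.max_sigma, min_f_ns=config.min_f_ns
        ))
    if not frames:
        raise ParameterError("no region produced scores")
    return pd.concat(frames).sort_index()


def combine_isoforms(
    map_erythroid: pd.DataFrame,
    map_ubiquitous: pd.DataFrame,
    min_shared: int = 50,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Rescale the first map onto the second, then combine.

    Only variants passing quality filters in a map contribute its score.
    Returns the combined frame plus the fitted affine transform.
    """
    a = map_erythroid.loc[map_erythroid["passed_filters"], ["fs", "sigma"]]
    b = map_ubiquitous.loc[map_ubiquitous["passed_filters"], ["fs", "sigma"]]
    rescaled_fs, transform = scoring.rescale_isoform(
        a["fs"], b["fs"], min_shared=min_shared
    )
    a = a.assign(fs=rescaled_fs, sigma=a["sigma"] * abs(transform[0]))
    return scoring.combine_maps(a, b), transform


@dataclass
class RecoveryResult:
    """Truth-vs-recovered comparison of a simulated experiment."""

    truth: GroundTruthMap
    combined: pd.DataFrame
    isoform_maps: tuple[pd.DataFrame, pd.DataFrame]
    spearman: float
    rmse: float
    nonsense_median: float
    synonymous_median: float
    filtered_fraction: float
    inter_isoform_pearson: float


def _truth_series(truth: GroundTruthMap) -> pd.Series:
    idx = pd.MultiIndex.from_tuples(truth.true_score, names=["pos", "ref", "alt"])
    return pd.Series(list(truth.true_score.values()), index=idx)


def run_recovery(
    protein_length: int = 120,
    n_clones: int = 1_000_000,
    depth_per_tile: int = 500_000,
    seed: int = 0,
    hyper_fraction: float = 0.025,
    n_replicates: int = 2,
    tile_length: int | None = None,
    per_base_error: float = 0.001,
    selection: SelectionModel | None = None,
    config: ScoringConfig = ScoringConfig(),
) -> RecoveryResult:
    """Simulate two isoform experiments from one truth and score them.

    The desk-scale defaults (120 residues, 1e6 clones per regional pool,
    5e5 pairs per tile) keep a full run under a minute while leaving every
    variant well covered.
    """
    truth = generate_ground_truth(
        protein_length, hyper_fraction=hyper_fraction, seed=seed
    )
    lib = LibraryModel(n_clones=n_clones)
    sel = selection or SelectionModel()
    if tile_length is None:
        cds_len = 3 * protein_length
        tile_length = next(
            t for t in range(150, 2, -3) if cds_len % t == 0
        )
    seqm = SequencingModel(
        depth_per_tile=depth_per_tile,
        tile_length=tile_length,
        per_base_error=per_base_error,
    )
    maps = []
    for isoform_seed in (seed * 2 + 1, seed * 2 + 2):
        experiments = simulate_isoform_experiment(
            truth, lib, sel, seqm, seed=isoform_seed, n_replicates=n_replicates
        )
        maps.append(
            score_isoform(experiments, truth.variant_class, protein_length, config)
        )
    combined, _ = combine_isoforms(maps[0], maps[1])
    truth_scores = _truth_series(truth)
    merged = combined.join(truth_scores.rename("true_score"), how="inner")
    well = merged[merged["fs_combined"].notna()]
    rho = float(
        spearmanr(well["fs_combined"], well["true_score"]).statistic
    )
    rmse = float(
        np.sqrt(np.mean((well["fs_combined"] - well["true_score"]) ** 2))
    )
    classes = pd.Series(
        {k: v for k, v in truth.variant_class.items()},
    )
    classes.index = pd.MultiIndex.from_tuples(classes.index, names=["pos", "ref", "alt"])
    well_classes = classes.reindex(well.index)
    stop_scores = well.loc[well_classes == "nonsense", "fs_combined"]
    syn_scores = well.loc[well_classes == "synonymous", "fs_combined"]
    # anchoring check excludes C-terminal tolerated truncations
    stop_core = stop_scores[
        stop_scores.index.get_level_values("pos")
        <= protein_length - config.c_term_exclusion
    ]
    shared = maps[0]["fs"].dropna().index.intersection(maps[1]["fs"].dropna().index)
    pearson = float(
        np.corrcoef(maps[0]["fs"].loc[shared], maps[1]["fs"].loc[shared])[0, 1]
    )
    n_scored = len(maps[0]) + len(maps[1])
    n_failed = int((~maps[0]["passed_filters"]).sum() + (~maps[1]["passed_filters"]).sum())
    return RecoveryResult(
        truth=truth,
        combined=combined,
        isoform_maps=(maps[0], maps[1]),
        spearman=rho,
        rmse=rmse,
        nonsense_median=float(stop_core.median()),
        synonymous_median=float(syn_scores.median()),
        filtered_fraction=n_failed / n_scored if n_scored else float("nan"),
        inter_isoform_pearson=pearson,
    )
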