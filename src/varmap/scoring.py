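"""Enrichment-ratio functional scoring of variant count tables.

The scoring model follows the standard multiplexed-selection recipe:

1.  Count filters — variants seen fewer than ``min_count`` times in either
    the selective or the non-selective library, or whose frequency falls
    below a percentile of the frequencies observed in the matched wild-type
    control library, are removed.
2.  Background subtraction — wild-type-control frequencies are subtracted
    from variant frequencies in both conditions; the enrichment ratio is
    ``phi = f_select_adj / f_nonselect_adj``.
3.  Scaling — per mutagenesis region, ``phi_stop`` and ``phi_syn`` are the
    medians of nonsense and synonymous enrichment ratios (nonsense changes
    in the C-terminal 14 residues are excluded from ``phi_stop``), and the
    functional impact score is
    ``fs = ln(phi / phi_stop) / ln(phi_syn / phi_stop)``,
    anchoring nonsense medians at 0 and synonymous medians at 1.  Scores
    above 1 (hyper-complementation) and below 0 are permitted.
4.  Error regularisation — the empirical replicate deviation is shrunk
    toward a running-quantile trend of deviations against the log
    non-selective frequency; a quality filter removes scores with sigma
    above 0.3 or non-selective frequency below 0.005%.
5.  Map combination — isoform maps are put on a common scale by an affine
    least-squares fit on shared variants, then averaged with
    inverse-variance weights; a delta score records the difference between
    isoform maps.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .counting import CountTable
from .errors import CalibrationError, ParameterError
from .variants import AMINO_ACIDS, NONSENSE, SYNONYMOUS, VariantKey

DEFAULT_MIN_COUNT = 10
DEFAULT_WT_PERCENTILE = 90.0
DEFAULT_MAX_SIGMA = 0.3
DEFAULT_MIN_F_NS = 5e-5  # 0.005%
C_TERM_EXCLUSION = 14
PREFERENCE_FLOOR = 1e-6


def _index_from_keys(keys: Iterable[VariantKey]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(list(keys), names=["pos", "ref", "alt"])


def _wt_percentile_threshold(wt_table: CountTable, percentile: float) -> float:
    if not wt_table.depth:
        raise CalibrationError(
            "wild-type control table has no depth: percentile filter undefined"
        )
    observed = [f for f in wt_table.frequency.values() if not math.isnan(f)]
    if not observed:
        return 0.0
    return float(np.percentile(observed, percentile))


def filter_counts(
    select: CountTable,
    nonselect: CountTable,
    wt_select: CountTable,
    wt_nonselect: CountTable,
    min_count: int = DEFAULT_MIN_COUNT,
    wt_percentile: float = DEFAULT_WT_PERCENTILE,
) -> tuple[set[VariantKey], pd.DataFrame]:
    """Apply the count and wild-type-percentile filters.

    A variant is removed when its raw count falls below ``min_count`` in the
    selective or the non-selective table, or when its frequency in either
    condition falls strictly below the ``wt_percentile``-th percentile of
    the frequencies observed in the matched wild-type control.  Returns the
    surviving keys and a log of removals with reasons.
    """
    thr_s = _wt_percentile_threshold(wt_select, wt_percentile)
    thr_ns = _wt_percentile_threshold(wt_nonselect, wt_percentile)
    keys = sorted(set(select.counts) | set(nonselect.counts))
    kept: set[VariantKey] = set()
    log_rows = []
    for key in keys:
        reasons = []
        if select.counts.get(key, 0) < min_count:
            reasons.append("low_count_selective")
        if nonselect.counts.get(key, 0) < min_count:
            reasons.append("low_count_nonselective")
        if select.frequency_of(key) < thr_s:
            reasons.append("below_wt_percentile_selective")
        if nonselect.frequency_of(key) < thr_ns:
            reasons.append("below_wt_percentile_nonselective")
        if reasons:
            log_rows.append({"variant": key.hgvs_pro(), "reasons": ";".join(reasons)})
        else:
            kept.add(key)
    log = pd.DataFrame(log_rows, columns=["variant", "reasons"])
    return kept, log


def adjust_and_enrich(
    select: CountTable,
    nonselect: CountTable,
    wt_select: CountTable,
    wt_nonselect: CountTable,
    keys: Iterable[VariantKey] | None = None,
) -> pd.DataFrame:
    """Background-subtract frequencies and compute enrichment ratios.

    Adjusted frequency is ``f - f_wt`` per condition.  A non-positive
    adjusted selective frequency is floored at a pseudo-frequency of half a
    read over the covering tile's selective depth, keeping ``phi`` defined
    but strongly null-like; a non-positive adjusted non-selective frequency
    marks the record unusable (no ``phi``).
    """
    if keys is None:
        keys = sorted(set(select.counts) | set(nonselect.counts))
    else:
        keys = sorted(keys)
    rows = []
    for key in keys:
        f_s = select.frequency_of(key)
        f_ns = nonselect.frequency_of(key)
        f_wt_s = wt_select.frequency_of(key) if key in wt_select.counts else 0.0
        f_wt_ns = wt_nonselect.frequency_of(key) if key in wt_nonselect.counts else 0.0
        f_s_adj = f_s - f_wt_s
        floored = False
        if not f_s_adj > 0:
            depth_s = select.depth_of(key)
            f_s_adj = 0.5 / depth_s if depth_s > 0 else float("nan")
            floored = True
        f_ns_adj = f_ns - f_wt_ns
        usable = bool(f_ns_adj > 0 and f_s_adj > 0)
        rows.append(
            {
                "f_ns": f_ns,
                "f_s": f_s,
                "f_wt_ns": f_wt_ns,
                "f_wt_s": f_wt_s,
                "f_ns_adj": f_ns_adj,
                "f_s_adj": f_s_adj,
                "phi": f_s_adj / f_ns_adj if usable else float("nan"),
                "usable": usable,
                "floored_selective": floored,
            }
        )
    return pd.DataFrame(rows, index=_index_from_keys(keys))


def compute_scales(
    records: pd.DataFrame,
    classes: Mapping[VariantKey, str],
    protein_length: int,
    c_term_exclusion: int = C_TERM_EXCLUSION,
    region_of: Callable[[int], object] | None = None,
    min_records: int = 3,
) -> dict[object, tuple[float, float]]:
    """Median nonsense and synonymous enrichment ratios per region.

    Nonsense records within ``c_term_exclusion`` residues of the C terminus
    are excluded from the nonsense median.  Raises
    :class:`~varmap.errors.CalibrationError` when a region lacks usable
    records or when selection failed to separate the classes
    (``phi_syn <= phi_stop``).
    """
    if region_of is None:
        region_of = lambda pos: 0  # noqa: E731 - single-region default
    usable = records[records["usable"]]
    scales: dict[object, tuple[float, float]] = {}
    by_region: dict[object, dict[str, list[float]]] = {}
    for (pos, ref, alt), row in usable.iterrows():
        cls = classes.get(VariantKey(pos, ref, alt))
        if cls not in (NONSENSE, SYNONYMOUS):
            continue
        if cls == NONSENSE and pos > protein_length - c_term_exclusion:
            continue
        region = region_of(pos)
        by_region.setdefault(region, {NONSENSE: [], SYNONYMOUS: []})[cls].append(
            row["phi"]
        )
    if not by_region:
        raise CalibrationError("no usable nonsense/synonymous records")
    for region, groups in sorted(by_region.items(), key=lambda kv: str(kv[0])):
        if len(groups[NONSENSE]) < min_records or len(groups[SYNONYMOUS]) < min_records:
            raise CalibrationError(
                f"region {region}: need at least {min_records} usable nonsense "
                "and synonymous records"
            )
        phi_stop = float(np.median(groups[NONSENSE]))
        phi_syn = float(np.median(groups[SYNONYMOUS]))
        if phi_syn <= phi_stop:
            raise CalibrationError(
                f"region {region}: phi_syn ({phi_syn:.4g}) <= phi_stop "
                f"({phi_stop:.4g}); selection did not separate classes"
            )
        scales[region] = (phi_stop, phi_syn)
    return scales


def functional_score(phi: float, scales: tuple[float, float]) -> float:
    """``ln(phi/phi_stop) / ln(phi_syn/phi_stop)``; 0 at stop, 1 at synonymous."""
    phi_stop, phi_syn = scales
    if not (phi_syn > phi_stop > 0):
        raise CalibrationError("require phi_syn > phi_stop > 0")
    if not phi > 0:
        return float("nan")
    return math.log(phi / phi_stop) / math.log(phi_syn / phi_stop)


def score_records(
    records: pd.DataFrame,
    scales: Mapping[object, tuple[float, float]],
    region_of: Callable[[int], object] | None = None,
) -> pd.Series:
    """Vectorised :func:`functional_score` over an enrichment frame."""
    if region_of is None:
        region_of = lambda pos: 0  # noqa: E731
    fs = pd.Series(np.nan, index=records.index, name="fs")
    pos_level = records.index.get_level_values("pos")
    for region, (phi_stop, phi_syn) in scales.items():
        mask = np.array([region_of(p) == region for p in pos_level])
        mask &= records["usable"].to_numpy() & (records["phi"].to_numpy() > 0)
        denom = math.log(phi_syn / phi_stop)
        fs[mask] = np.log(records.loc[mask, "phi"] / phi_stop) / denom
    return fs


def _c4(n: int) -> float:
    """Unbiasing constant for the sample s.d. of ``n`` normal replicates."""
    if n < 2:
        return 1.0
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


def _chi_median_factor(n: int) -> float:
    """Median of the sample-s.d. distribution relative to the true s.d."""
    if n < 2:
        return 1.0
    from scipy.stats import chi

    return float(chi(df=n - 1).median() / math.sqrt(n - 1))


def estimate_error(
    fs_reps: pd.DataFrame,
    f_ns: pd.Series,
    m: float = 2.0,
    window: int = 51,
    min_periods: int = 5,
    bias_correct: bool = True,
) -> pd.DataFrame:
    """Regularised standard error of the replicate-mean score.

    The empirical replicate standard deviation is shrunk toward a
    frequency-conditional expected deviation ``t`` (a centred running
    median of replicate deviations over variants ordered by ``log f_ns``)
    with ``m`` prior pseudo-replicates:

        sd_shrunk = (m * t + n_rep * sd_emp) / (m + n_rep)
        sigma     = sd_shrunk / sqrt(n_rep)

    With few replicates the raw sample s.d. and its running median both
    underestimate the true deviation (the chi-distribution bias is ~20-33%
    at two replicates), so by default both terms are rescaled by the exact
    normal-theory factors before blending; ``bias_correct=False`` disables
    this.  With ``m = 0`` (and correction off) sigma is exactly the
    empirical standard error.  Variants with a single replicate take
    ``sigma = t`` and are flagged.
    """
    if m < 0:
        raise ParameterError("prior pseudo-replicate count m must be nonnegative")
    n_rep = fs_reps.notna().sum(axis=1)
    sd_emp = fs_reps.std(axis=1, ddof=1)
    order = np.log(f_ns.reindex(fs_reps.index)).sort_values(kind="stable").index
    sd_ordered = sd_emp.reindex(order)
    trend = (
        sd_ordered.rolling(window, center=True, min_periods=min_periods)
        .median()
        .ffill()
        .bfill()
        .reindex(fs_reps.index)
    )
    trend = trend.fillna(sd_emp.median())
    if bias_correct:
        n_typical = int(n_rep[n_rep >= 2].mode().iloc[0]) if (n_rep >= 2).any() else 2
        trend = trend / _chi_median_factor(n_typical)
        c4 = n_rep.map(_c4)
        sd_cal = sd_emp / c4
    else:
        sd_cal = sd_emp
    single = n_rep < 2
    sd_shrunk = (m * trend + n_rep * sd_cal.fillna(0.0)) / (m + n_rep).where(
        m + n_rep > 0, np.nan
    )
    sigma = sd_shrunk / np.sqrt(n_rep.clip(lower=1))
    sigma[single] = trend[single]
    return pd.DataFrame(
        {
            "sigma": sigma,
            "n_rep": n_rep,
            "sd_emp": sd_emp,
            "trend": trend,
            "single_replicate": single,
        }
    )


def quality_filter(
    scores: pd.DataFrame,
    max_sigma: float = DEFAULT_MAX_SIGMA,
    min_f_ns: float = DEFAULT_MIN_F_NS,
) -> pd.DataFrame:
    """Flag well-measured scores; nothing is deleted, only marked.

    Boundary convention is strict: ``sigma`` exactly at ``max_sigma`` and
    ``f_ns`` exactly at ``min_f_ns`` both pass.
    """
    out = scores.copy()
    fail_sigma = out["sigma"] > max_sigma
    fail_freq = out["f_ns"] < min_f_ns
    reasons = np.where(
        fail_sigma & fail_freq,
        "sigma_above_max;f_ns_below_min",
        np.where(fail_sigma, "sigma_above_max", np.where(fail_freq, "f_ns_below_min", "")),
    )
    out["passed_filters"] = ~(fail_sigma | fail_freq) & out["fs"].notna()
    out.loc[out["fs"].isna(), "passed_filters"] = False
    out["filter_reason"] = reasons
    out.loc[out["fs"].isna(), "filter_reason"] = "no_score"
    return out


def rescale_isoform(
    map_a: pd.Series,
    map_b: pd.Series,
    min_shared: int = 50,
) -> tuple[pd.Series, tuple[float, float]]:
    """Affine least-squares rescaling of ``map_a`` onto ``map_b``'s scale.

    Fits ``b ~ slope * a + intercept`` on shared well-measured variants
    (minimising the mean squared distance between the maps) and applies the
    transform to every ``map_a`` score.  Monotone, so rank correlations are
    untouched.
    """
    shared = map_a.dropna().index.intersection(map_b.dropna().index)
    if len(shared) < min_shared:
        raise ParameterError(
            f"need at least {min_shared} shared variants to rescale "
            f"(have {len(shared)})"
        )
    a = map_a.loc[shared].to_numpy(dtype=float)
    b = map_b.loc[shared].to_numpy(dtype=float)
    if np.ptp(a) == 0:
        raise CalibrationError("degenerate shared set: zero variance in map_a")
    slope, intercept = np.polyfit(a, b, 1)
    return map_a * slope + intercept, (float(slope), float(intercept))


def combine_scores(
    fs_1: float | None,
    sigma_1: float | None,
    fs_2: float | None,
    sigma_2: float | None,
) -> tuple[float, float]:
    """Inverse-variance weighted combination of two scores.

    ``fs = (fs1/s1^2 + fs2/s2^2) / (1/s1^2 + 1/s2^2)`` with combined
    variance ``1 / (1/s1^2 + 1/s2^2)``; with one input present it passes
    through unchanged.
    """
    have_1 = fs_1 is not None and not math.isnan(fs_1)
    have_2 = fs_2 is not None and not math.isnan(fs_2)
    if not have_1 and not have_2:
        raise ParameterError("at least one score must be present")
    if have_1 and (sigma_1 is None or not sigma_1 > 0):
        raise ParameterError("sigma_1 must be positive")
    if have_2 and (sigma_2 is None or not sigma_2 > 0):
        raise ParameterError("sigma_2 must be positive")
    if not have_2:
        return float(fs_1), float(sigma_1)
    if not have_1:
        return float(fs_2), float(sigma_2)
    w1, w2 = 1.0 / sigma_1**2, 1.0 / sigma_2**2
    fs = (fs_1 * w1 + fs_2 * w2) / (w1 + w2)
    return float(fs), float(math.sqrt(1.0 / (w1 + w2)))


def combine_maps(map_1: pd.DataFrame, map_2: pd.DataFrame) -> pd.DataFrame:
    """Combine two isoform maps variant-by-variant.

    Inputs are frames with ``fs`` and ``sigma`` columns (map 1 is the
    erythroid-style map, map 2 the ubiquitous-style map for the sign of the
    delta score).  Where both maps score a variant the result is the
    inverse-variance weighted mean and ``delta = fs_1 - fs_2``; where one
    map scores it, that score passes through and ``delta`` is absent.
    """
    index = map_1.index.union(map_2.index)
    fs1 = map_1["fs"].reindex(index)
    s1 = map_1["sigma"].reindex(index)
    fs2 = map_2["fs"].reindex(index)
    s2 = map_2["sigma"].reindex(index)
    have1 = fs1.notna() & s1.notna() & (s1 > 0)
    have2 = fs2.notna() & s2.notna() & (s2 > 0)
    if ((fs1.notna() & s1.notna() & ~(s1 > 0)) | (fs2.notna() & s2.notna() & ~(s2 > 0))).any():
        raise ParameterError("nonpositive sigma in input map")
    w1 = np.where(have1, 1.0 / s1**2, 0.0)
    w2 = np.where(have2, 1.0 / s2**2, 0.0)
    wsum = w1 + w2
    with np.errstate(invalid="ignore", divide="ignore"):
        fs_combined = (np.nan_to_num(fs1) * w1 + np.nan_to_num(fs2) * w2) / wsum
        sigma_combined = np.sqrt(1.0 / wsum)
    fs_combined = np.where(wsum > 0, fs_combined, np.nan)
    sigma_combined = np.where(wsum > 0, sigma_combined, np.nan)
    delta = np.where(have1 & have2, fs1 - fs2, np.nan)
    sources = np.select(
        [have1 & have2, have1, have2],
        ["both", "map_1", "map_2"],
        default="none",
    )
    return pd.DataFrame(
        {
            "fs_combined": fs_combined,
            "sigma_combined": sigma_combined,
            "delta": delta,
            "sources": sources,
        },
        index=index,
    )


def normalize_to_wt(scores: pd.DataFrame, wt_scores: pd.Series) -> pd.DataFrame:
    """Divide each position's scores by that position's wild-type score."""
    return scores.div(wt_scores.reindex(scores.index), axis=0)


def preference_transforms(
    scores: pd.DataFrame,
    floor: float = PREFERENCE_FLOOR,
) -> dict[str, pd.DataFrame]:
    """Amino-acid preference matrices under three hyper-complementation models.

    ``scores`` is a positions-by-amino-acids frame of WT-normalised scores
    (the wild-type residue scores 1 at each position).  Scores at or below
    zero are clipped to a small positive floor so preferences stay defined.

    * ``advantageous`` — preferences proportional to the scores unchanged;
    * ``neutral`` — scores above 1 are capped at 1 (better-than-WT treated
      as WT-equivalent);
    * ``damaging`` — scores above 1 are inverted to ``1/s`` (better-than-WT
      in the assay treated as deleterious).

    Every row of every returned matrix sums to 1.
    """
    missing = [c for c in scores.columns if c not in AMINO_ACIDS]
    if missing:
        raise ParameterError(f"unexpected amino-acid columns: {missing}")
    if scores.isna().any().any():
        raise ParameterError("preference transforms require a complete score matrix")
    s = scores.clip(lower=floor)
    variants = {
        "advantageous": s,
        "neutral": s.where(s <= 1.0, 1.0),
        "damaging": s.where(s <= 1.0, 1.0 / s),
    }
    return {
        model: mat.div(mat.sum(axis=1), axis=0) for model, mat in variants.items()
    }
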