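"""Map-performance metrics and auxiliary positional analyses.

Score orientation is explicit throughout: in a functional-impact map lower
scores mean more damage, so the positive (pathogenic) class is called at
*low* scores.  All curve functions take ``lower_is_positive`` and default
to that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InputError, ParameterError

#: residue windows the assay is suspected to under-call (benignity must not
#: be inferred there); used to flag reference variants for exclusion.
EXCLUDED_RANGES: tuple[tuple[int, int], ...] = ((160, 215),)
EXCLUDED_POSITIONS: frozenset[int] = frozenset({255, 355})


def in_excluded_region(pos: int) -> bool:
    """True for positions in the assay's unreliable-for-benignity windows."""
    return any(lo <= pos <= hi for lo, hi in EXCLUDED_RANGES) or (
        pos in EXCLUDED_POSITIONS
    )


@dataclass(frozen=True)
class PerfSummary:
    auroc: float
    aubprc: float
    r90bp: float
    n_pos: int
    n_neg: int
    threshold_at_r90bp: float


def _validate_classes(labels: np.ndarray) -> None:
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise InputError("both classes must be nonempty")


def _oriented(scores: np.ndarray, lower_is_positive: bool) -> np.ndarray:
    return -scores if lower_is_positive else scores


def roc_and_auroc(
    scores: Sequence[float],
    labels: Sequence[int],
    lower_is_positive: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Empirical ROC curve and trapezoid AUROC (ties handled by rank)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, _oriented(scores, lower_is_positive))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(np.trapezoid(tpr, fpr))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(
    scores_1: Sequence[float],
    scores_2: Sequence[float],
    labels: Sequence[int],
    lower_is_positive: bool = True,
) -> tuple[float, float, float, float]:
    """Paired comparison of two AUROCs with the DeLong variance estimator.

    Returns ``(auroc_1, auroc_2, z, p)`` for the two-sided test of equal
    AUROC on the same labelled set.
    """
    labels = np.asarray(labels, dtype=int)
    _validate_classes(labels)
    order = np.argsort(-labels, kind="stable")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    preds = np.vstack(
        [
            _oriented(np.asarray(s, dtype=float), lower_is_positive)[order]
            for s in (scores_1, scores_2)
        ]
    )
    k = preds.shape[0]
    tx = np.empty((k, n_pos))
    ty = np.empty((k, n_neg))
    tz = np.empty((k, n_pos + n_neg))
    for r in range(k):
        tx[r] = _midrank(preds[r, :n_pos])
        ty[r] = _midrank(preds[r, n_pos:])
        tz[r] = _midrank(preds[r])
    aucs = tz[:, :n_pos].sum(axis=1) / (n_pos * n_neg) - (n_pos + 1.0) / (
        2.0 * n_neg
    )
    v01 = (tz[:, :n_pos] - tx) / n_neg
    v10 = 1.0 - (tz[:, n_pos:] - ty) / n_pos
    sx = np.cov(v01)
    sy = np.cov(v10)
    cov = sx / n_pos + sy / n_neg
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), float(z), p


def balanced_pr(
    scores: Sequence[float],
    labels: Sequence[int],
    lower_is_positive: bool = True,
    precision_target: float = 0.90,
) -> tuple[pd.DataFrame, float, float, float]:
    """Balanced precision-recall curve, AUBPRC, and recall at 90% precision.

    Balanced precision at a threshold is ``TPR / (TPR + FPR)`` — the
    precision that would be observed under equal class priors.  The curve
    is evaluated at the empirical operating points (step-wise; no
    interpolation between points) and the area is the trapezoid over
    recall.  ``r90bp`` is the maximum recall over thresholds whose balanced
    precision reaches ``precision_target``; if no threshold reaches it,
    zero is returned with a warning.

    Returns ``(curve, aubprc, r90bp, threshold_at_r90bp)``; thresholds in
    the curve are on the original score scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_classes(labels)
    s = _oriented(scores, lower_is_positive)
    order = np.argsort(-s, kind="stable")
    y = labels[order]
    s_sorted = s[order]
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # operating points: last index of each distinct threshold
    distinct = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])
    tpr = tp[distinct] / n_pos
    fpr = fp[distinct] / n_neg
    with np.errstate(invalid="ignore"):
        bprec = np.where(tpr + fpr > 0, tpr / (tpr + fpr), 1.0)
    thresholds = s_sorted[distinct] * (-1 if lower_is_positive else 1)
    curve = pd.DataFrame(
        {"threshold": thresholds, "recall": tpr, "balanced_precision": bprec}
    )
    # prepend the zero-recall endpoint for integration
    recall_grid = np.r_[0.0, tpr]
    bprec_grid = np.r_[bprec[0], bprec]
    aubprc = float(np.trapezoid(bprec_grid, recall_grid))
    reaches = bprec >= precision_target
    if reaches.any():
        r90bp = float(tpr[reaches].max())
        threshold_at = float(thresholds[reaches][np.argmax(tpr[reaches])])
    else:
        warnings.warn("no threshold reaches the balanced-precision target")
        r90bp, threshold_at = 0.0, float("nan")
    return curve, aubprc, r90bp, threshold_at


def paired_bootstrap_aubprc(
    scores_1: Sequence[float],
    scores_2: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    seed: int = 0,
    lower_is_positive: bool = True,
) -> tuple[float, float, float]:
    """Simple paired bootstrap for an AUBPRC difference.

    Resamples the labelled set with replacement, recomputes both maps'
    AUBPRC on each resample, and returns ``(aubprc_1, aubprc_2, p)`` where
    ``p`` is the two-sided sign-flip probability of the difference.  A
    pragmatic utility, not a derived sampling theory for the statistic.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = np.asarray(labels, dtype=int)
    _validate_classes(y)
    _, base1, _, _ = balanced_pr(s1, y, lower_is_positive)
    _, base2, _, _ = balanced_pr(s2, y, lower_is_positive)
    rng = np.random.default_rng(seed)
    diffs = []
    n = len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while len(diffs) < n_boot:
            idx = rng.integers(0, n, size=n)
            if y[idx].sum() in (0, n):
                continue
            _, a1, _, _ = balanced_pr(s1[idx], y[idx], lower_is_positive)
            _, a2, _, _ = balanced_pr(s2[idx], y[idx], lower_is_positive)
            diffs.append(a1 - a2)
    diffs = np.asarray(diffs)
    # two-sided: how often the bootstrap difference crosses zero
    p = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return float(base1), float(base2), float(min(p, 1.0))


def performance_summary(
    scores: Sequence[float],
    labels: Sequence[int],
    lower_is_positive: bool = True,
) -> PerfSummary:
    labels_arr = np.asarray(labels, dtype=int)
    _, auroc = roc_and_auroc(scores, labels, lower_is_positive)
    _, aubprc, r90bp, thr = balanced_pr(scores, labels, lower_is_positive)
    return PerfSummary(
        auroc=auroc,
        aubprc=aubprc,
        r90bp=r90bp,
        n_pos=int(labels_arr.sum()),
        n_neg=int(len(labels_arr) - labels_arr.sum()),
        threshold_at_r90bp=thr,
    )


def compare_distributions(
    set_a: Sequence[float],
    set_b: Sequence[float],
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney comparison of two score sets.

    Returns ``(delta_median, U, p)`` where ``delta_median`` is
    ``median(b) - median(a)`` — positive when the second (benign-style) set
    sits above the first (pathogenic-style) set.
    """
    a = np.asarray(list(set_a), dtype=float)
    b = np.asarray(list(set_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputError("both sets must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(np.median(b) - np.median(a)), float(res.statistic), float(res.pvalue)


def moving_window_profile(
    per_position_values: Mapping[int, float],
    window: int = 5,
) -> pd.DataFrame:
    """Centred running mean over residue positions, truncated at termini.

    Positions missing from the input are simply skipped from each window's
    mean.  ``window`` must be odd.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be odd and positive")
    if not per_position_values:
        return pd.DataFrame(columns=["position", "windowed_value", "window"])
    positions = sorted(per_position_values)
    half = window // 2
    rows = []
    for pos in positions:
        vals = [
            per_position_values[p]
            for p in range(pos - half, pos + half + 1)
            if p in per_position_values
        ]
        rows.append(
            {"position": pos, "windowed_value": float(np.mean(vals)), "window": window}
        )
    return pd.DataFrame(rows)


def classify_positions(
    asa: Mapping[int, float],
    delta_asa: Mapping[int, float] | None = None,
    buried_below: float = 20.0,
    exposed_above: float = 40.0,
    interface_delta: float = 1.0,
) -> pd.DataFrame:
    """Solvent-accessibility classes plus an independent interface flag.

    Relative accessible surface area below 20% is buried, above 40% is
    exposed, in between is intermediate.  A residue is interfacial when its
    accessible-surface-area change on complex formation strictly exceeds
    1 A^2; where no change value is supplied the flag is absent (NA), not
    false.
    """
    rows = []
    for pos in sorted(asa):
        value = asa[pos]
        if value < 0:
            raise ParameterError("accessible surface area must be nonnegative")
        if value < buried_below:
            cls = "buried"
        elif value > exposed_above:
            cls = "exposed"
        else:
            cls = "intermediate"
        if delta_asa is not None and pos in delta_asa:
            interface: object = bool(delta_asa[pos] > interface_delta)
        else:
            interface = pd.NA
        rows.append(
            {"position": pos, "asa_percent": value, "asa_class": cls,
             "interface": interface}
        )
    return pd.DataFrame(rows)


def normalize_predictor(scores: Sequence[float]) -> np.ndarray:
    """Unity-based normalisation flipping a predictor onto the map scale.

    ``s' = 1 - (s - min) / (max - min)`` maps the maximum input to 0
    (null-like) and the minimum to 1 (neutral), for predictors where larger
    raw scores mean more damage.
    """
    x = np.asarray(list(scores), dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise InputError("constant input: normalisation undefined")
    return 1.0 - (x - lo) / (hi - lo)


def allele_depletion_or(
    table: Sequence[Sequence[int]],
) -> tuple[float, float]:
    """Odds ratio and Fisher exact p for a 2x2 allele-depletion table.

    Rows: map-damaging / map-neutral; columns: observed / not observed in
    population cohorts.  ``OR = (a*d)/(b*c)`` with a Haldane correction of
    0.5 added to every cell when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.all(t == t.astype(int)):
        raise InputError("expected a 2x2 table of nonnegative integers")
    if t.sum() == 0:
        raise InputError("all-zero table: odds ratio undefined")
    (a, b), (c, d) = t
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return float(odds_ratio), float(p)
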