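"""Clinical calibration: reference sets, LLR of pathogenicity, ACMG thresholds.

Scores are converted to evidence for clinical interpretation in three steps.
Positive (pathogenic / likely pathogenic) and negative (benign / likely
benign / proxy-benign) reference variant sets are assembled from annotation
tables.  Gaussian kernel density estimates of the score distributions in the
two sets give a log10 likelihood ratio of pathogenicity,
``llr(s) = log10( pi+(s) / pi-(s) )``.  Finally, a Bayesian point-system
solver in the style of Tavtigian et al. maps LLR values to ACMG/AMP evidence
strength categories: posterior odds are modelled as
``prior_odds * X**w`` where ``X`` is the odds of pathogenicity carried by
one "pathogenic very strong" item and ``w`` sums evidence contributions in
very-strong units (very strong 1, strong 1/2, moderate 1/4, supporting 1/8;
benign items contribute negatively).  ``X`` is the smallest value for which
every ACMG/AMP evidence-combining rule yields a posterior inside its bound
(>99% pathogenic, >90% likely pathogenic, <10% likely benign, <1% benign),
and evidence-level LLR cuts descend from ``log10 X`` by factors of two,
mirrored for benign evidence.

All logarithms are base 10: at the conventional global prior of 0.1 the
solver lands on combining odds of about 350, i.e. a very-strong cut of 2.54.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import CalibrationError, InputError, ParameterError
from .variants import VariantKey

PROXY_BENIGN_MAX_MAF = 0.0005
POSITIVE_LABELS = frozenset({"pathogenic", "likely_pathogenic"})
NEGATIVE_LABELS = frozenset({"benign", "likely_benign"})

#: Evidence-strength exponents in very-strong units.
EVIDENCE_WEIGHTS = {
    "PVSt": 1.0,
    "PSt": 0.5,
    "PM": 0.25,
    "PSu": 0.125,
    "BSu": -0.125,
    "BSt": -0.5,
}

#: ACMG/AMP evidence-combining rules as (constraint family, item counts).
#: Each pathogenic rule is encoded at its minimum-strength instantiation.
#: The two-Strong combination is held to the likely-pathogenic bound: in the
#: published point-system calibration it is the one combination that cannot
#: reach 99% posterior at prior 0.1, and the internally consistent reading
#: constrains it at >90% instead.
ACMG_COMBINING_RULES: tuple[tuple[str, dict[str, int]], ...] = (
    ("P", {"PVSt": 1, "PSt": 1}),
    ("P", {"PVSt": 1, "PM": 2}),
    ("P", {"PVSt": 1, "PM": 1, "PSu": 1}),
    ("P", {"PVSt": 1, "PSu": 2}),
    ("LP", {"PSt": 2}),
    ("P", {"PSt": 1, "PM": 3}),
    ("P", {"PSt": 1, "PM": 2, "PSu": 2}),
    ("P", {"PSt": 1, "PM": 1, "PSu": 4}),
    ("LP", {"PVSt": 1, "PM": 1}),
    ("LP", {"PSt": 1, "PM": 1}),
    ("LP", {"PSt": 1, "PSu": 2}),
    ("LP", {"PM": 3}),
    ("LP", {"PM": 2, "PSu": 2}),
    ("LP", {"PM": 1, "PSu": 4}),
    ("B", {"BSt": 2}),
    ("LB", {"BSt": 1, "BSu": 1}),
    ("LB", {"BSu": 2}),
)

#: Posterior-probability bounds per constraint family.
POSTERIOR_CONSTRAINTS = {
    "P": (">", 0.99),
    "LP": (">", 0.90),
    "LB": ("<", 0.10),
    "B": ("<", 0.01),
}

PATHOGENIC_LEVELS = ("PVSt", "PSt", "PM", "PSu")
BENIGN_LEVELS = ("BSu", "BSt")


@dataclass(frozen=True)
class ReferenceVariant:
    """One annotated variant used to build reference sets."""

    variant: VariantKey
    clinical_label: str  # pathogenic/likely_pathogenic/benign/likely_benign/
    #                      VUS/conflicting/none
    maf: float = 0.0
    n_homozygotes: int = 0
    source: str = ""

    def is_proxy_benign(self) -> bool:
        """Rare, homozygous-observed, annotation-free population variant."""
        return (
            self.clinical_label == "none"
            and self.maf < PROXY_BENIGN_MAX_MAF
            and self.n_homozygotes >= 1
        )


def build_reference_sets(
    annotated: Iterable[ReferenceVariant],
) -> tuple[list[ReferenceVariant], list[ReferenceVariant], pd.DataFrame]:
    """Split annotated variants into positive and negative reference sets.

    Positive: pathogenic or likely pathogenic.  Negative: benign or likely
    benign (conflicting interpretations excluded) plus proxy-benign
    variants.  Returns the two sets and a membership log.
    """
    positive: list[ReferenceVariant] = []
    negative: list[ReferenceVariant] = []
    rows = []
    for rv in annotated:
        in_pos = rv.clinical_label in POSITIVE_LABELS
        in_neg = rv.clinical_label in NEGATIVE_LABELS or rv.is_proxy_benign()
        if in_pos and in_neg:
            raise InputError(
                f"{rv.variant.hgvs_pro()} qualifies for both reference sets"
            )
        if in_pos:
            positive.append(rv)
            membership = "positive"
        elif in_neg:
            negative.append(rv)
            membership = (
                "negative_proxy_benign" if rv.is_proxy_benign() else "negative"
            )
        else:
            membership = f"excluded ({rv.clinical_label})"
        rows.append(
            {"variant": rv.variant.hgvs_pro(), "label": rv.clinical_label,
             "membership": membership}
        )
    return positive, negative, pd.DataFrame(rows)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb for a Gaussian kernel."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def _kde(x: np.ndarray, h: float) -> Callable[[np.ndarray], np.ndarray]:
    def density(s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return norm.pdf((s[:, None] - x[None, :]) / h).mean(axis=1) / h

    return density


@dataclass
class LlrCalibration:
    """KDE score densities and the induced log10 likelihood ratio."""

    density_pos: Callable[[np.ndarray], np.ndarray]
    density_neg: Callable[[np.ndarray], np.ndarray]
    bandwidths: tuple[float, float]
    support: tuple[float, float]
    floor_pos: float
    floor_neg: float

    def llr(self, s: float | np.ndarray) -> np.ndarray:
        """log10(pi+(s) / pi-(s)) with density floors applied."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        p = np.maximum(self.density_pos(s), self.floor_pos)
        q = np.maximum(self.density_neg(s), self.floor_neg)
        return np.log10(p / q)

    def in_support(self, s: float) -> bool:
        return self.support[0] <= s <= self.support[1]


def estimate_densities(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    bandwidths: tuple[float, float] | None = None,
    min_bandwidth: float = 1e-3,
    floor_fraction: float = 1e-6,
) -> LlrCalibration:
    """Gaussian-kernel densities for the two reference score sets.

    Bandwidths default to Silverman's rule per set (pass ``bandwidths`` for
    fixed values).  Each density is floored at ``floor_fraction`` of its own
    maximum over the observed support before ratio-taking, keeping the LLR
    finite in the tails.  A zero-variance set falls back to
    ``min_bandwidth`` with a warning.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if len(pos) < 5 or len(neg) < 5:
        raise InputError("need at least 5 scores in each reference set")
    if bandwidths is None:
        hs = []
        for x in (pos, neg):
            h = silverman_bandwidth(x)
            if not h > 0:
                warnings.warn(
                    "zero-variance reference set: falling back to minimum bandwidth"
                )
                h = min_bandwidth
            hs.append(h)
        h_pos, h_neg = hs
    else:
        h_pos, h_neg = bandwidths
        if not (h_pos > 0 and h_neg > 0):
            raise ParameterError("bandwidths must be positive")
    density_pos = _kde(pos, h_pos)
    density_neg = _kde(neg, h_neg)
    lo = min(pos.min(), neg.min())
    hi = max(pos.max(), neg.max())
    pad = 3 * max(h_pos, h_neg)
    grid = np.linspace(lo - pad, hi + pad, 512)
    floor_pos = floor_fraction * density_pos(grid).max()
    floor_neg = floor_fraction * density_neg(grid).max()
    return LlrCalibration(
        density_pos=density_pos,
        density_neg=density_neg,
        bandwidths=(float(h_pos), float(h_neg)),
        support=(float(lo), float(hi)),
        floor_pos=float(floor_pos),
        floor_neg=float(floor_neg),
    )


@dataclass(frozen=True)
class EvidenceThresholds:
    """The six LLR cut points mapping scores to evidence strengths."""

    prior: float
    odds_pvst: float
    llr_cuts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.llr_cuts
        ladder = [c["PVSt"], c["PSt"], c["PM"], c["PSu"], 0.0, c["BSu"], c["BSt"]]
        if not all(a > b for a, b in zip(ladder, ladder[1:])):
            raise CalibrationError("LLR cuts must strictly decrease PVSt..BSt")


def _rule_weight(items: dict[str, int]) -> float:
    return sum(EVIDENCE_WEIGHTS[level] * count for level, count in items.items())


def _violations(
    x: float,
    prior_odds: float,
    rules: Sequence[tuple[str, dict[str, int]]],
) -> list[str]:
    bad = []
    for family, items in rules:
        w = _rule_weight(items)
        odds = prior_odds * x**w
        posterior = odds / (1.0 + odds)
        direction, bound = POSTERIOR_CONSTRAINTS[family]
        ok = posterior > bound if direction == ">" else posterior < bound
        if not ok:
            bad.append(f"{family}:{items} posterior={posterior:.4f}")
    return bad


def solve_acmg_thresholds(
    prior: float = 0.1,
    rules: Sequence[tuple[str, dict[str, int]]] = ACMG_COMBINING_RULES,
    log10_x_range: tuple[float, float] = (0.0, 6.0),
    grid_points: int = 601,
    tol: float = 1e-10,
) -> EvidenceThresholds:
    """Find the most conservative combining odds satisfying every rule.

    ``X`` is scanned on a log grid over ``log10_x_range`` and the smallest
    feasible value is refined by bisection ("most conservative" = the
    weakest evidence claim consistent with the rules; all constraints are
    lower bounds on ``X``, so the feasible set is an interval upward).
    LLR cuts follow the factor-of-two ladder from ``log10 X``.
    """
    if not 0.0 < prior < 1.0:
        raise ParameterError("prior must lie in (0, 1)")
    prior_odds = prior / (1.0 - prior)
    grid = np.logspace(*log10_x_range, grid_points)
    feasible_idx = None
    for i, x in enumerate(grid):
        if not _violations(float(x), prior_odds, rules):
            feasible_idx = i
            break
    if feasible_idx is None:
        binding = _violations(float(grid[-1]), prior_odds, rules)
        raise CalibrationError(
            "no feasible combining odds in scanned range; binding constraints: "
            + "; ".join(binding)
        )
    if feasible_idx == 0:
        x_star = float(grid[0])
    else:
        lo, hi = float(grid[feasible_idx - 1]), float(grid[feasible_idx])
        while (hi - lo) / hi > tol:
            mid = (lo * hi) ** 0.5
            if _violations(mid, prior_odds, rules):
                lo = mid
            else:
                hi = mid
        x_star = hi
    log_x = float(np.log10(x_star))
    cuts = {
        "PVSt": log_x,
        "PSt": log_x / 2.0,
        "PM": log_x / 4.0,
        "PSu": log_x / 8.0,
        "BSu": -log_x / 8.0,
        "BSt": -log_x / 2.0,
    }
    return EvidenceThresholds(prior=prior, odds_pvst=x_star, llr_cuts=cuts)


def assign_evidence(
    score: float,
    calib: LlrCalibration,
    thresholds: EvidenceThresholds,
) -> tuple[str, float, bool]:
    """Evidence category for one score.

    Returns ``(category, llr, extrapolated)``.  The category is the
    strongest pathogenic level whose cut the LLR strictly exceeds, or the
    strongest benign level whose cut strictly exceeds the LLR; an LLR
    exactly at a cut takes the weaker category.  ``extrapolated`` flags
    scores outside the calibration's observed score range.
    """
    llr = float(calib.llr(score)[0])
    extrapolated = not calib.in_support(score)
    cuts = thresholds.llr_cuts
    category = "indeterminate"
    for level in PATHOGENIC_LEVELS:  # strongest first
        if llr > cuts[level]:
            category = f"pathogenic_{_level_name(level)}"
            break
    else:
        for level in reversed(BENIGN_LEVELS):  # strongest first: BSt then BSu
            if llr < cuts[level]:
                category = f"benign_{_level_name(level)}"
                break
    return category, llr, extrapolated


def _level_name(level: str) -> str:
    return {
        "PVSt": "very_strong",
        "PSt": "strong",
        "PM": "moderate",
        "PSu": "supporting",
        "BSu": "supporting",
        "BSt": "strong",
    }[level]
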