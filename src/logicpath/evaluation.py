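"""Direction-aware scoring of predictions and inter-rater agreement.

Every scored case lands in exactly one confusion category.  A predicted
change in the direction opposite to the observed one is a false positive of
the special "wrong direction" kind (FP-WD), counted inside the FP total.
Undefined ratios (zero denominators) are reported as ``None``, never as 0.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .logic_network import OutcomeClass, TestCase, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Category", "ConfusionSummary", "RatingMatrix", "AgreementResult",
    "categorize", "score_cases", "score_labels", "aggregate",
    "percent_agreement", "cohens_kappa", "fleiss_kappa",
    "kappa_from_agreement", "rate_agreement", "stratify",
    "expected_random_accuracy", "mann_whitney", "round_half_up",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "fdr", "f1")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding where .5 goes away from zero (display
    convention for integer-percent tables)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


class Category(str, enum.Enum):
    TP = "TP"
    TN = "TN"
    FP = "FP"
    FP_WD = "FP-WD"
    FN = "FN"


def categorize(predicted: OutcomeClass, observed: OutcomeClass) -> Category:
    if predicted.is_change and observed.is_change:
        return Category.TP if predicted is observed else Category.FP_WD
    if predicted.is_change:
        return Category.FP
    if observed.is_change:
        return Category.FN
    return Category.TN


@dataclass
class ConfusionSummary:
    tp: int = 0
    tn: int = 0
    fp_total: int = 0
    fp_wd: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp_total, self.fp_wd, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.fp_wd > self.fp_total:
            raise ValidationError("fp_wd cannot exceed fp_total")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp_total + self.fn

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp_total)

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp_total)

    @property
    def fdr(self) -> float | None:
        p = self.precision
        return None if p is None else 1.0 - p

    @property
    def fpr(self) -> float | None:
        return self._ratio(self.fp_total, self.fp_total + self.tn)

    @property
    def f1(self) -> float | None:
        p, s = self.precision, self.sensitivity
        if p is None and s is None:
            return None
        p = p or 0.0
        s = s or 0.0
        if p + s == 0:
            return 0.0
        return 2 * p * s / (p + s)

    def metric(self, name: str) -> float | None:
        return getattr(self, name)

    def percent(self, name: str) -> float | None:
        """Metric as a round-half-up integer percentage, or None."""
        v = self.metric(name)
        return None if v is None else round_half_up(100.0 * v)

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            tp=self.tp + other.tp, tn=self.tn + other.tn,
            fp_total=self.fp_total + other.fp_total,
            fp_wd=self.fp_wd + other.fp_wd, fn=self.fn + other.fn)


def score_labels(
        pairs: Iterable[tuple[OutcomeClass, OutcomeClass]]) -> ConfusionSummary:
    """Confusion summary from (predicted, observed) label pairs."""
    s = ConfusionSummary()
    for predicted, observed in pairs:
        cat = categorize(predicted, observed)
        if cat is Category.TP:
            s.tp += 1
        elif cat is Category.TN:
            s.tn += 1
        elif cat is Category.FN:
            s.fn += 1
        else:
            s.fp_total += 1
            if cat is Category.FP_WD:
                s.fp_wd += 1
    return s


def score_cases(cases: Sequence[TestCase]) -> ConfusionSummary:
    for case in cases:
        if case.predicted_class is None or case.observed_class is None:
            raise ValidationError(
                f"case {case.case_id()} has an unset predicted or observed "
                "class")
    return score_labels(
        (c.predicted_class, c.observed_class) for c in cases)


def aggregate(summaries: Sequence[ConfusionSummary],
              mode: str = "pooled"):
    """Combine per-pathway summaries.

    ``pooled`` sums the counts and returns one ConfusionSummary; ``averaged``
    computes each pathway's metrics first and returns
    ``{metric: (mean, sample_sd)}``, skipping undefined values the way a
    table with NA cells would.
    """
    if not summaries:
        raise ValidationError("nothing to aggregate")
    if mode == "pooled":
        out = ConfusionSummary()
        for s in summaries:
            out = out + s
        return out
    if mode != "averaged":
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    result: dict[str, tuple[float | None, float | None]] = {}
    for name in METRIC_NAMES:
        vals = [s.metric(name) for s in summaries]
        vals = [v for v in vals if v is not None]
        if not vals:
            result[name] = (None, None)
        elif len(vals) == 1:
            result[name] = (vals[0], None)
        else:
            arr = np.asarray(vals, dtype=float)
            result[name] = (float(arr.mean()), float(arr.std(ddof=1)))
    return result


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

@dataclass
class RatingMatrix:
    """Cases x raters grid of outcome labels (fixed rater panel)."""

    labels: list[list[OutcomeClass]]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("rating matrix has no cases")
        widths = {len(row) for row in self.labels}
        if len(widths) != 1:
            raise ValidationError("unequal number of raters per case")
        if widths.pop() < 2:
            raise ValidationError("need at least 2 raters")
        for row in self.labels:
            for cell in row:
                if not isinstance(cell, OutcomeClass):
                    raise ValidationError(f"bad label {cell!r}")

    @property
    def n_cases(self) -> int:
        return len(self.labels)

    @property
    def n_raters(self) -> int:
        return len(self.labels[0])

    def rater(self, j: int) -> list[OutcomeClass]:
        return [row[j] for row in self.labels]


@dataclass
class AgreementResult:
    pairwise_percent: dict[tuple[int, int], float]
    average_percent: float
    pairwise_kappa: dict[tuple[int, int], float | None]
    average_kappa: float | None
    observed_agreement: float
    expected_agreement: float
    fleiss_kappa: float


def percent_agreement(
        m: RatingMatrix) -> tuple[dict[tuple[int, int], float], float]:
    """Pairwise fraction of identically labeled cases, and the unweighted
    mean over rater pairs."""
    pairs: dict[tuple[int, int], float] = {}
    for i in range(m.n_raters):
        for j in range(i + 1, m.n_raters):
            same = sum(1 for row in m.labels if row[i] is row[j])
            pairs[(i, j)] = same / m.n_cases
    avg = sum(pairs.values()) / len(pairs)
    return pairs, avg


def cohens_kappa(rater_a: Sequence[OutcomeClass],
                 rater_b: Sequence[OutcomeClass]) -> float | None:
    if len(rater_a) != len(rater_b) or not rater_a:
        raise ValidationError("raters must label the same non-empty cases")
    n = len(rater_a)
    p_o = sum(1 for a, b in zip(rater_a, rater_b) if a is b) / n
    cats = list(OutcomeClass)
    p_e = sum(
        (sum(1 for a in rater_a if a is c) / n)
        * (sum(1 for b in rater_b if b is c) / n)
        for c in cats)
    if 1.0 - p_e == 0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_agreement(observed: float, expected: float) -> float:
    """Chance-corrected agreement from precomputed observed and expected
    agreement fractions."""
    if expected >= 1.0:
        raise ValidationError("expected agreement must be < 1")
    return (observed - expected) / (1.0 - expected)


def fleiss_kappa(m: RatingMatrix) -> AgreementResult:
    """Standard multi-rater chance-corrected agreement over the three
    outcome categories, plus pairwise statistics."""
    n, k = m.n_cases, m.n_raters
    cats = list(OutcomeClass)
    counts = np.zeros((n, len(cats)))
    for i, row in enumerate(m.labels):
        for label in row:
            counts[i, cats.index(label)] += 1
    p_i = (np.sum(counts * (counts - 1), axis=1)) / (k * (k - 1))
    p_bar = float(np.mean(p_i))
    p_j = counts.sum(axis=0) / (n * k)
    p_e = float(np.sum(p_j ** 2))
    kappa = kappa_from_agreement(p_bar, p_e)
    pairs_pct, avg_pct = percent_agreement(m)
    pairs_ck = {
        (i, j): cohens_kappa(m.rater(i), m.rater(j))
        for (i, j) in pairs_pct}
    defined = [v for v in pairs_ck.values() if v is not None]
    avg_ck = sum(defined) / len(defined) if defined else None
    return AgreementResult(
        pairwise_percent=pairs_pct, average_percent=avg_pct,
        pairwise_kappa=pairs_ck, average_kappa=avg_ck,
        observed_agreement=p_bar, expected_agreement=p_e,
        fleiss_kappa=kappa)


def rate_agreement(m: RatingMatrix) -> AgreementResult:
    """Alias for :func:`fleiss_kappa` returning the full agreement bundle."""
    return fleiss_kappa(m)


# ---------------------------------------------------------------------------
# Stratification and baselines
# ---------------------------------------------------------------------------

def stratify(cases: Sequence[TestCase], by: str,
             path_lengths: Mapping[str, int | None] | None = None,
             ) -> dict[str, ConfusionSummary]:
    """Per-stratum confusion summaries.

    ``by`` is one of ``effect_type`` (observed class), ``pathway`` or
    ``path_length`` (requires *path_lengths* keyed by case id).  Strata with
    zero cases are simply absent.
    """
    groups: dict[str, list[TestCase]] = {}
    for case in cases:
        if by == "effect_type":
            key = (case.observed_class.value
                   if case.observed_class is not None else "unset")
        elif by == "pathway":
            key = case.pathway or "unassigned"
        elif by == "path_length":
            if path_lengths is None:
                raise ValidationError(
                    "path_length stratification needs a lengths mapping")
            length = path_lengths.get(case.case_id())
            key = "none" if length is None else str(length)
        else:
            raise ValidationError(f"unknown stratifier {by!r}")
        groups.setdefault(key, []).append(case)
    out = {key: score_cases(group) for key, group in sorted(groups.items())}
    for key, summary in out.items():
        logger.info("stratum %s: %d cases (tp=%d tn=%d fp=%d fn=%d)",
                    key, summary.total, summary.tp, summary.tn,
                    summary.fp_total, summary.fn)
    return out


def expected_random_accuracy(observed: Sequence[OutcomeClass],
                             n_sim: int = 1000,
                             seed: int | None = None) -> float:
    """Accuracy of a predictor assigning one of the three classes uniformly
    at random against fixed observed labels, estimated by simulation.
    Returns a fraction in [0, 1] (analytically 1/3 for any labels)."""
    if not observed:
        raise ValidationError("no observed labels")
    rng = np.random.default_rng(seed)
    cats = list(OutcomeClass)
    obs_idx = np.array([cats.index(c) for c in observed])
    draws = rng.integers(0, len(cats), size=(n_sim, len(observed)))
    return float(np.mean(draws == obs_idx[None, :]))


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 alternative: str = "two-sided"):
    """Thin wrapper around :func:`scipy.stats.mannwhitneyu` for comparing
    per-pathway metric vectors between two predictors."""
    from scipy.stats import mannwhitneyu
    return mannwhitneyu(list(x), list(y), alternative=alternative)
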