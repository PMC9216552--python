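"""Discretization of continuous activities and F1-optimal cutoff sweeps.

A continuous key-output activity (1.0 = unchanged) is called ``up`` when it
rises by at least the fractional cutoff ``c`` and ``down`` when it falls by
the symmetric amount.  The default boundary convention is reciprocal
("multiplicative") symmetry — down at ``1/(1+c)`` — matching a model that
is symmetric in log space; plain additive symmetry (down at ``1-c``) is
available as an option.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

from .logic_network import OutcomeClass, ValidationError
from .evaluation import ConfusionSummary, score_labels

__all__ = ["Convention", "CutoffConfig", "CutoffMetrics", "SweepResult",
           "discretize", "sweep_cutoffs", "default_grid", "literal_grid"]


class Convention(str, enum.Enum):
    MULTIPLICATIVE_SYMMETRIC = "multiplicative_symmetric"
    ADDITIVE_SYMMETRIC = "additive_symmetric"


@dataclass(frozen=True)
class CutoffConfig:
    cutoff: float
    convention: Convention = Convention.MULTIPLICATIVE_SYMMETRIC

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError(
                f"cutoff must be in (0, 1), got {self.cutoff}")
        object.__setattr__(self, "convention", Convention(self.convention))


def discretize(value: float, cfg: CutoffConfig) -> OutcomeClass:
    """Map a positive activity to up / down / no_change at the cutoff."""
    if value <= 0:
        raise ValidationError(f"activity must be positive, got {value}")
    c = cfg.cutoff
    if value >= 1.0 + c:
        return OutcomeClass.UP
    if cfg.convention is Convention.MULTIPLICATIVE_SYMMETRIC:
        down_at = 1.0 / (1.0 + c)
    else:
        down_at = 1.0 - c
    if value <= down_at:
        return OutcomeClass.DOWN
    return OutcomeClass.NO_CHANGE


def default_grid() -> list[float]:
    """5%-spaced grid from 1% to 99% with the 15% point included."""
    pts = {0.01, 0.99, 0.15}
    pts.update(round(x / 100.0, 2) for x in range(5, 100, 5))
    return sorted(pts)


def literal_grid() -> list[float]:
    """1% to 99% in 5% increments read literally: 1, 6, 11, ..., 96."""
    return [round(x / 100.0, 2) for x in range(1, 100, 5)]


@dataclass
class CutoffMetrics:
    cutoff: float
    summary: ConfusionSummary

    @property
    def f1(self) -> float:
        return self.summary.f1 if self.summary.f1 is not None else 0.0

    @property
    def tpr(self) -> float | None:
        return self.summary.sensitivity

    @property
    def fpr(self) -> float | None:
        return self.summary.fpr


@dataclass
class SweepResult:
    rows: list[CutoffMetrics]
    best_cutoff: float

    def roc_points(self) -> list[tuple[float, float]]:
        """(FPR, TPR) per cutoff, skipping cutoffs where either is
        undefined."""
        pts = []
        for row in self.rows:
            if row.fpr is not None and row.tpr is not None:
                pts.append((row.fpr, row.tpr))
        return pts


def sweep_cutoffs(values: Mapping[str, float],
                  reference: Mapping[str, OutcomeClass],
                  grid: Sequence[float] | None = None,
                  convention: Convention = Convention.MULTIPLICATIVE_SYMMETRIC,
                  ) -> SweepResult:
    """Evaluate every cutoff on the grid against reference classes.

    ``values`` maps case ids to continuous activities, ``reference`` maps the
    same ids to three-class labels treated as ground truth.  A predicted
    change only counts as a true positive when its direction matches the
    reference; a change in the wrong direction is a false positive.  Returns
    per-cutoff metrics and the F1-maximizing cutoff (ties break toward the
    smallest cutoff).
    """
    if not reference:
        raise ValidationError("empty reference set")
    missing = sorted(set(reference) - set(values))
    if missing:
        raise ValidationError(
            "continuous predictions missing for cases: " + ", ".join(missing))
    case_ids = sorted(reference)
    if grid is None:
        grid = default_grid()
    rows = []
    for c in grid:
        cfg = CutoffConfig(cutoff=c, convention=convention)
        pairs = [(discretize(values[cid], cfg), reference[cid])
                 for cid in case_ids]
        rows.append(CutoffMetrics(cutoff=c, summary=score_labels(pairs)))
    best = max(rows, key=lambda r: (r.f1, -r.cutoff))
    return SweepResult(rows=rows, best_cutoff=best.cutoff)
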