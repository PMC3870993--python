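"""Risk categories and standardisation weights.

A risk category scheme partitions the predicted-risk axis [0, 1] into
ordered half-open intervals [b_{k-1}, b_k), the top interval closed above.
Schemes are always built from the *pooled* predicted risks (all centres
together), so every centre is measured against the same partition.

Four construction strategies are supported:

* ``equal_width`` — fixed-width intervals 1/K wide. Often unusable in
  practice: extreme intervals may be empty in some centres.
* ``equal_patients`` — roughly equal patient counts per category.
* ``equal_observed_events`` — roughly equal observed events per category
  (the preferred strategy: it keeps events, hence patients, in every
  category even at low overall event rates).
* ``equal_predicted_events`` — roughly equal sums of predicted risk.

Patients sharing one predicted-risk value can never be split across a
boundary, so exactly equal counts are a guiding principle rather than a
guarantee: the realised number of categories ``effective_K`` may fall below
the requested ``K`` when ties force large blocks.

Weights for combining category-specific event rates are the corresponding
four options; the natural choice is the proportion of all pooled patients
per category, which makes the standardised rate of the pooled population
equal its observed rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data_model import Cohort
from .errors import ParameterError, ValidationError

__all__ = [
    "CATEGORY_METHODS",
    "WEIGHT_SOURCES",
    "RiskCategoryScheme",
    "CategoryWeights",
    "EmptyCategoryAudit",
    "build_risk_categories",
    "assign_category",
    "category_weights",
    "empty_category_audit",
]

CATEGORY_METHODS = (
    "equal_width",
    "equal_patients",
    "equal_observed_events",
    "equal_predicted_events",
)
WEIGHT_SOURCES = (
    "equal",
    "patient_proportion",
    "observed_event_proportion",
    "predicted_event_proportion",
)

CategoryMethod = Literal[
    "equal_width", "equal_patients", "equal_observed_events", "equal_predicted_events"
]
WeightSource = Literal[
    "equal", "patient_proportion", "observed_event_proportion", "predicted_event_proportion"
]


@dataclass(frozen=True)
class RiskCategoryScheme:
    """An ordered partition of the risk axis.

    ``cuts`` are the interior boundaries (strictly increasing risk values);
    category k (1-based) is [b_{k-1}, b_k) with b_0 = 0, b_K = 1 and the top
    interval closed above. A risk exactly on a cut belongs to the upper
    category.
    """

    method: CategoryMethod
    K: int
    cuts: np.ndarray

    def __post_init__(self):
        cuts = np.asarray(self.cuts, dtype=float)
        if cuts.ndim != 1 or (len(cuts) > 1 and not np.all(np.diff(cuts) > 0)):
            raise ValidationError("category cuts must be strictly increasing")
        object.__setattr__(self, "cuts", cuts)

    @property
    def effective_K(self) -> int:
        return len(self.cuts) + 1

    @property
    def boundaries(self) -> np.ndarray:
        """Full boundary vector [0, cuts..., 1]."""
        return np.concatenate(([0.0], self.cuts, [1.0]))

    def assign_indices(self, risks) -> np.ndarray:
        """0-based category index for each risk (vectorised)."""
        return np.searchsorted(self.cuts, np.asarray(risks, dtype=float), side="right")

    def to_dict(self) -> dict:
        return {"method": self.method, "K": self.K, "cuts": self.cuts.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RiskCategoryScheme":
        return cls(method=d["method"], K=int(d["K"]), cuts=np.asarray(d["cuts"], dtype=float))


@dataclass(frozen=True)
class CategoryWeights:
    """Normalised weights, one per category (Σ w_k = 1)."""

    weights: np.ndarray
    source: WeightSource

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValidationError("weights must be nonnegative")
        s = w.sum()
        if s <= 0:
            raise ValidationError("weights sum to zero")
        object.__setattr__(self, "weights", w / s)

    def __len__(self) -> int:
        return len(self.weights)


def _tied_blocks(risks: np.ndarray, events: np.ndarray):
    """Unique risk values ascending, with patient/event/predicted totals."""
    order = np.argsort(risks, kind="stable")
    r, e = risks[order], events[order]
    vals, start = np.unique(r, return_index=True)
    n = np.diff(np.append(start, len(r)))
    d = np.add.reduceat(e.astype(float), start)
    pred = vals * n
    return vals, n.astype(float), d, pred


def build_risk_categories(
    risks,
    events,
    method: CategoryMethod = "equal_observed_events",
    K: int = 10,
) -> RiskCategoryScheme:
    """Build a risk category scheme from the pooled predicted risks.

    For the data-driven strategies the cut rule is greedy over blocks of
    tied risk values, scanned in ascending order with a per-category target
    of ``remaining quantity / remaining categories`` (patients, observed
    events, or predicted events), re-computed after every cut. A category
    closes when extending it past the next block would land further from
    the target than stopping here (so a single heavy block of tied risks
    closes its category early rather than swallowing everything after it),
    and closes unconditionally once the remaining distinct risk values are
    only just enough to populate the remaining categories. Ties are never
    split, so ``effective_K`` may still fall below ``K``; with all risks
    identical the scheme degenerates to a single category with a warning.
    """
    risks = np.asarray(risks, dtype=float)
    events = np.asarray(events)
    if K < 1:
        raise ParameterError(f"K must be ≥ 1, got {K}")
    if method not in CATEGORY_METHODS:
        raise ParameterError(f"unknown category method {method!r}")
    if risks.shape != events.shape:
        raise ValidationError("risks and events must be aligned, same length")
    if (risks < 0).any() or (risks > 1).any():
        raise ValidationError("risks must lie in [0, 1]")

    if method == "equal_width":
        return RiskCategoryScheme(method=method, K=K, cuts=np.arange(1, K) / K)

    vals, n_blk, d_blk, p_blk = _tied_blocks(risks, events)
    quantity = {"equal_patients": n_blk, "equal_observed_events": d_blk,
                "equal_predicted_events": p_blk}[method]
    integral = method != "equal_predicted_events"
    total = float(quantity.sum())
    if method == "equal_observed_events" and total < K:
        warnings.warn(
            f"only {int(total)} observed events for K={K} categories; "
            "expect effective_K < K",
            stacklevel=2,
        )

    cuts: list[float] = []
    remaining, rem_cats, cum = total, K, 0.0
    m = len(vals)
    for i, q in enumerate(quantity):
        cum += float(q)
        if rem_cats <= 1 or i == m - 1:
            continue
        target = math.ceil(remaining / rem_cats) if integral else remaining / rem_cats
        # close when the next block would overshoot the target by more than
        # the current undershoot, or when the remaining distinct risk values
        # are only just enough for the remaining categories
        nearest = target > 0 and cum >= target - float(quantity[i + 1]) / 2.0
        forced = (m - 1 - i) <= rem_cats - 1
        if nearest or forced:
            cuts.append(float(vals[i + 1]))
            remaining -= cum
            cum = 0.0
            rem_cats -= 1

    if len(vals) == 1 and K > 1:
        warnings.warn("all risks identical; scheme degenerates to one category",
                      stacklevel=2)
    return RiskCategoryScheme(method=method, K=K, cuts=np.asarray(cuts))


def assign_category(scheme: RiskCategoryScheme, risk: float) -> int:
    """1-based category index for a single risk in [0, 1].

    A risk exactly on a boundary falls in the upper category (half-open
    convention); risk = 1.0 falls in the top category.
    """
    if not 0.0 <= risk <= 1.0:
        raise ValidationError(f"risk {risk} outside [0, 1]")
    return int(scheme.assign_indices(np.array([risk]))[0]) + 1


def category_weights(
    scheme: RiskCategoryScheme,
    pooled_risks,
    pooled_events,
    source: WeightSource = "patient_proportion",
    *,
    allow_empty: bool = False,
) -> CategoryWeights:
    """Standardisation weights from the pooled data the scheme was built on.

    A category containing zero pooled patients is an error (it would leave
    the weight meaningless); with ``allow_empty=True`` empty categories get
    weight zero and the rest are renormalised — intended only for
    ``equal_width`` schemes, where empty extreme intervals are common.
    """
    if source not in WEIGHT_SOURCES:
        raise ParameterError(f"unknown weight source {source!r}")
    risks = np.asarray(pooled_risks, dtype=float)
    events = np.asarray(pooled_events, dtype=float)
    K = scheme.effective_K
    idx = scheme.assign_indices(risks)
    n_k = np.bincount(idx, minlength=K).astype(float)
    empty = n_k == 0
    if empty.any() and not allow_empty:
        raise ValidationError(
            f"categories {list(np.flatnonzero(empty) + 1)} contain no pooled "
            "patients; pass allow_empty=True to drop them and renormalise"
        )
    if source == "equal":
        w = (~empty).astype(float)
    elif source == "patient_proportion":
        w = n_k
    elif source == "observed_event_proportion":
        w = np.bincount(idx, weights=events, minlength=K)
    else:  # predicted_event_proportion
        w = np.bincount(idx, weights=risks, minlength=K)
    if w.sum() <= 0:
        raise ValidationError(f"weight source {source!r} yields all-zero weights")
    return CategoryWeights(weights=w, source=source)


@dataclass(frozen=True)
class EmptyCategoryAudit:
    """Which categories are empty in which centres (1-based indices)."""

    empty_by_centre: dict[str, list[int]]
    all_populated: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "all_populated", not any(self.empty_by_centre.values())
        )


def empty_category_audit(
    cohort: Cohort, scheme: RiskCategoryScheme, risks_by_record
) -> EmptyCategoryAudit:
    """Per-centre report of risk categories with no patients.

    DRS is computable for every centre only when no centre has an empty
    positively-weighted category; this diagnostic flags the offenders before
    any rate is attempted.
    """
    risks = np.asarray(risks_by_record, dtype=float)
    if len(risks) != cohort.n:
        raise ValidationError("risks_by_record must align with the cohort records")
    idx = scheme.assign_indices(risks)
    K = scheme.effective_K
    report: dict[str, list[int]] = {}
    for cid in cohort.centre_ids():
        counts = np.bincount(idx[cohort.centre_mask(cid)], minlength=K)
        report[cid] = list(np.flatnonzero(counts == 0) + 1)
    return EmptyCategoryAudit(empty_by_centre=report)
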