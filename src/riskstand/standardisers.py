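"""Standardised measures: DRS rate, CMF, SMR, and conventional direct
casemix standardisation.

All between-centre measures are computed from one pooled risk model and one
risk-category scheme, so the methods are compared like-for-like:

* SMR_j = O_j / E_j — observed events over the sum of pooled-model
  predicted probabilities for centre j (indirect standardisation).
* DRS_j = Σ_k w_k · p_jk — a weighted sum of centre j's event rates within
  pooled risk categories, with one shared weight vector w (direct risk
  standardisation).
* CMF_j = DRS_j / r̄ — the DRS rate divided by the pooled overall rate; the
  directly standardised analogue of the SMR.
* DSR_j = Σ_c w_c · (d_jc / n_jc) over casemix *cells* — conventional
  direct standardisation, which fails quietly when a centre has empty
  cells: the effective weight sum Σ w_c over populated cells drops below 1
  and the raw rate is biased towards the populated cells. Renormalising the
  weights per centre restores Σ w = 1 but gives each centre its own weights,
  reintroducing the non-comparability that afflicts SMRs.

A centre missing a positively-weighted risk category has no defined DRS
rate; this is reported as undefined (with the offending category named),
never patched per centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .categorisation import (
    CategoryWeights,
    RiskCategoryScheme,
    build_risk_categories,
    category_weights,
)
from .data_model import (
    CasemixCell,
    Cohort,
    StandardisationResult,
    tabulate_casemix,
)
from .errors import NotComputableError, ParameterError, ValidationError
from .risk_model import RiskModel, expected_events

__all__ = [
    "CentreRateTable",
    "centre_rate_table",
    "drs_rate",
    "cmf",
    "smr",
    "direct_casemix_rate",
    "standardise_all",
    "category_sensitivity",
    "SensitivityResult",
]


@dataclass(frozen=True)
class CentreRateTable:
    """Patients, events and event rates of one centre by risk category."""

    centre_id: str
    n: np.ndarray  # patients per category, length effective_K
    d: np.ndarray  # events per category

    def __post_init__(self):
        n = np.asarray(self.n, dtype=np.int64)
        d = np.asarray(self.d, dtype=np.int64)
        if n.shape != d.shape or ((d < 0) | (d > n)).any():
            raise ValidationError("need 0 ≤ d_jk ≤ n_jk per category")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "d", d)

    @property
    def rates(self) -> np.ndarray:
        """p_jk = d_jk / n_jk, NaN-marked where the category is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.d / np.maximum(self.n, 1), np.nan)

    def rate(self, k: int) -> float | None:
        """Rate of 1-based category k; None when the category is empty."""
        return None if self.n[k - 1] == 0 else float(self.d[k - 1] / self.n[k - 1])


def centre_rate_table(
    cohort: Cohort,
    scheme: RiskCategoryScheme,
    risks_by_record,
    centre_id=None,
) -> CentreRateTable:
    """Tabulate one centre (or, with ``centre_id=None``, the pooled cohort)
    into per-category patient and event counts."""
    risks = np.asarray(risks_by_record, dtype=float)
    if len(risks) != cohort.n:
        raise ValidationError("risks_by_record must align with the cohort records")
    idx = scheme.assign_indices(risks)
    ev = cohort.events
    if centre_id is not None:
        mask = cohort.centre_mask(centre_id)
        idx, ev = idx[mask], ev[mask]
    K = scheme.effective_K
    return CentreRateTable(
        centre_id="<pooled>" if centre_id is None else centre_id,
        n=np.bincount(idx, minlength=K),
        d=np.bincount(idx, weights=ev.astype(float), minlength=K).astype(np.int64),
    )


def drs_rate(table: CentreRateTable, weights: CategoryWeights) -> float:
    """Directly risk standardised rate Σ_k w_k · p_jk.

    Raises :class:`NotComputableError` if any positively-weighted category
    holds no patients in this centre — the defined failure mode of every
    direct method, reported rather than patched per centre.
    """
    w = weights.weights
    if len(w) != len(table.n):
        raise ValidationError(
            f"weights ({len(w)}) and rate table ({len(table.n)}) disagree on K"
        )
    missing = np.flatnonzero((w > 0) & (table.n == 0))
    if missing.size:
        k = int(missing[0]) + 1
        raise NotComputableError(
            f"centre {table.centre_id!r}: risk category {k} has no patients "
            "but positive weight; DRS rate undefined",
            centre_id=table.centre_id,
            category=k,
        )
    used = w > 0
    return float(np.dot(w[used], table.rates[used]))


def cmf(drs: float, overall_rate: float) -> float:
    """Comparative mortality figure: the DRS rate over the pooled rate r̄."""
    if overall_rate <= 0:
        raise ParameterError("overall rate must be positive to form a CMF")
    return drs / overall_rate


def smr(observed: float, expected: float) -> float:
    """Standardised mortality (event) ratio O / E, on the ratio scale."""
    if expected <= 0:
        raise ParameterError("expected events must be positive to form an SMR")
    return observed / expected


def direct_casemix_rate(
    centre_cells: list[CasemixCell],
    standard_weights: dict[tuple[str, ...], float],
    renormalise: bool = False,
) -> tuple[float, float]:
    """Conventional directly standardised rate over casemix cells.

    Only cells populated in this centre contribute; the returned
    ``effective_weight_sum`` is the total standard weight they carry. With
    ``renormalise=True`` the used weights are rescaled to sum to one — the
    partial fix that restores comparability of scale at the price of
    centre-specific weights.

    Returns
    -------
    (rate, effective_weight_sum)
    """
    total_w = sum(standard_weights.values())
    if abs(total_w - 1.0) > 1e-8:
        raise ValidationError(
            f"standard weights must sum to 1 over the pooled cell universe "
            f"(got {total_w!r})"
        )
    populated = [c for c in centre_cells if c.n > 0]
    if not populated:
        raise NotComputableError("centre has no populated casemix cells")
    try:
        used = [(standard_weights[c.key], c.d / c.n) for c in populated]
    except KeyError as exc:
        raise ValidationError(f"no standard weight for casemix cell {exc}") from exc
    ews = float(sum(w for w, _ in used))
    rate = float(sum(w * r for w, r in used))
    if renormalise:
        if ews <= 0:
            raise NotComputableError("effective weight sum is zero; cannot renormalise")
        rate /= ews
    return rate, ews


def _model_uses_continuous(model: RiskModel) -> bool:
    spec = getattr(model, "spec", None)
    return bool(spec is not None and spec.continuous)


def standardise_all(
    cohort: Cohort,
    model: RiskModel,
    scheme: RiskCategoryScheme,
    weights: CategoryWeights,
    *,
    include_dsr: bool | None = None,
) -> list[StandardisationResult]:
    """Run the full per-centre pipeline: SMR, DRS rate, CMF, conventional
    DSR (raw and weight-renormalised) and the theoretical standard errors,
    all from the same pooled model and category scheme.

    A measure that is undefined for a centre (e.g. DRS with an empty
    positively-weighted category) is carried as ``None`` with the reason in
    ``notes``; the rest of the batch is unaffected. ``include_dsr`` defaults
    to True exactly when the model uses no continuous covariates — a
    conventional cell-based DSR is meaningless once a continuous covariate
    enters the casemix model.
    """
    from .uncertainty import se_cmf_theoretical, se_smr_theoretical

    risks = model.predict(cohort)
    rbar = cohort.overall_rate
    if include_dsr is None:
        include_dsr = bool(cohort.spec.factors) and not _model_uses_continuous(model)
    if include_dsr:
        pooled_cells = tabulate_casemix(cohort)
        n_total = sum(c.n for c in pooled_cells)
        std_weights = {c.key: c.n / n_total for c in pooled_cells}

    results = []
    for cid in cohort.centre_ids():
        mask = cohort.centre_mask(cid)
        notes: list[str] = []
        res = StandardisationResult(
            centre_id=cid, n=int(mask.sum()), observed=int(cohort.events[mask].sum())
        )
        res.expected = expected_events(model, cohort, cid)
        res.smr = smr(res.observed, res.expected)
        res.se_smr = se_smr_theoretical(risks[mask], res.expected)

        table = centre_rate_table(cohort, scheme, risks, cid)
        try:
            res.drs_rate = drs_rate(table, weights)
            res.cmf = cmf(res.drs_rate, rbar)
            res.se_cmf = se_cmf_theoretical(table, weights, rbar)
        except NotComputableError as exc:
            notes.append(str(exc))

        if include_dsr:
            cells = tabulate_casemix(cohort, cid)
            try:
                res.dsr_raw, res.effective_weight_sum = direct_casemix_rate(
                    cells, std_weights, renormalise=False
                )
                res.dsr_renormalised, _ = direct_casemix_rate(
                    cells, std_weights, renormalise=True
                )
            except NotComputableError as exc:
                notes.append(str(exc))
        else:
            notes.append("conventional DSR not computed (continuous casemix covariates)")
        res.notes = "; ".join(notes)
        results.append(res)
    return results


@dataclass(frozen=True)
class SensitivityResult:
    """DRS CMFs per centre per requested K, with pairwise rank correlations."""

    cmfs: pd.DataFrame          # index centre_id, one column per K
    rank_correlations: pd.DataFrame  # Spearman rho, K × K
    not_computable: dict[int, list[str]]  # K -> centres with undefined CMF


def category_sensitivity(
    cohort: Cohort,
    model: RiskModel,
    K_list: list[int],
    *,
    method: str = "equal_observed_events",
    weight_source: str = "patient_proportion",
) -> SensitivityResult:
    """Recompute the DRS CMFs under several category counts and measure how
    stable the centre ranking is (Spearman rank correlation, average ranks
    for ties, between each pair of K values).

    Centres whose CMF is undefined at some K are dropped from the
    correlations involving that K, with a warning.
    """
    if any(k < 2 for k in K_list):
        raise ParameterError("category counts for sensitivity analysis must be ≥ 2")
    risks = model.predict(cohort)
    events = cohort.events
    rbar = cohort.overall_rate
    centres = cohort.centre_ids()

    cmf_cols: dict[int, list[float]] = {}
    not_comp: dict[int, list[str]] = {}
    for K in K_list:
        scheme = build_risk_categories(risks, events, method=method, K=K)
        w = category_weights(scheme, risks, events, source=weight_source)
        col, failed = [], []
        for cid in centres:
            table = centre_rate_table(cohort, scheme, risks, cid)
            try:
                col.append(cmf(drs_rate(table, w), rbar))
            except NotComputableError:
                col.append(np.nan)
                failed.append(cid)
        cmf_cols[K] = col
        if failed:
            not_comp[K] = failed
            warnings.warn(
                f"K={K}: DRS CMF undefined for centres {failed}; "
                "correlations use the remaining centres",
                stacklevel=2,
            )

    cmfs = pd.DataFrame(cmf_cols, index=pd.Index(centres, name="centre_id"))
    rho = pd.DataFrame(np.eye(len(K_list)), index=K_list, columns=K_list)
    for a, b in combinations(K_list, 2):
        pair = cmfs[[a, b]].dropna()
        r = stats.spearmanr(pair[a], pair[b]).statistic if len(pair) >= 2 else np.nan
        rho.loc[a, b] = rho.loc[b, a] = r
    return SensitivityResult(cmfs=cmfs, rank_correlations=rho, not_computable=not_comp)
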