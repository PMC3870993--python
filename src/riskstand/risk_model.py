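"""Pooled logistic casemix model and per-patient predicted risks.

The first step shared by indirect standardisation and direct risk
standardisation: fit one logistic regression to the dataset aggregated
across *all* centres (never per centre, and never with a centre term), and
score every patient with a predicted event probability p_i. Summing the p_i
over a centre gives that centre's expected events E_j; the ratio O_j / E_j
is the SMR.

Two model classes implement the same ``predict`` interface:

* :class:`LogisticRiskModel` — a maximum-likelihood logistic fit with
  reference-level dummy coding (reference = first level in sorted order)
  and optional interactions, up to a fully saturated factor model.
* :class:`CellRateModel` — a lookup of fixed casemix-cell-specific event
  probabilities (e.g. external standard rates, or pooled observed cell
  rates for classical indirect standardisation).

With standard rates derived from the pooled data and a saturated logistic
model, the two routes coincide: the logistic fit reproduces the observed
pooled cell rates, so expected events match classical indirect
standardisation exactly.
"""

from __future__ import annotations

import abc
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .data_model import Cohort, PatientRecord
from .errors import ConvergenceError, PredictionError, SpecificationError, ValidationError

__all__ = [
    "ModelSpec",
    "RiskModel",
    "LogisticRiskModel",
    "CellRateModel",
    "fit_risk_model",
    "predict_risk",
    "expected_events",
]

# Newton iterations on the logistic log-likelihood; tight tolerance so the
# score equation Σp_i = D holds well inside 1e-6·D.
_MAXITER = 100
_TOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the casemix model.

    ``interactions`` lists tuples of factor names whose dummy products enter
    the model; ``saturated=True`` expands to all interactions among the
    listed factors. Continuous covariates enter linearly on the logit scale.
    """

    factors: tuple[str, ...] = ()
    continuous: tuple[str, ...] = ()
    interactions: tuple[tuple[str, ...], ...] = ()
    saturated: bool = False

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "continuous", tuple(self.continuous))
        object.__setattr__(
            self, "interactions", tuple(tuple(t) for t in self.interactions)
        )
        for term in self.interactions:
            if len(term) < 2:
                raise SpecificationError(f"interaction {term} needs ≥2 factors")
            unknown = set(term) - set(self.factors)
            if unknown:
                raise SpecificationError(
                    f"interaction {term} references non-factor terms {sorted(unknown)}"
                )

    def expanded_interactions(self) -> tuple[tuple[str, ...], ...]:
        if self.saturated:
            out = []
            for r in range(2, len(self.factors) + 1):
                out.extend(itertools.combinations(self.factors, r))
            return tuple(out)
        return self.interactions

    def validate_against(self, cohort: Cohort) -> None:
        spec = cohort.spec
        if spec.centre_col in self.factors + self.continuous:
            raise SpecificationError(
                f"the centre identifier {spec.centre_col!r} must not enter the "
                "risk model; the model is fitted to the pooled data"
            )
        bad_f = set(self.factors) - set(spec.factors)
        bad_c = set(self.continuous) - set(spec.continuous)
        if bad_f or bad_c:
            raise SpecificationError(
                f"model terms not declared in the cohort: "
                f"factors {sorted(bad_f)}, continuous {sorted(bad_c)}"
            )


def _dummy_block(df: pd.DataFrame, factor: str, levels: list[str]) -> dict[str, np.ndarray]:
    """Non-reference dummy columns for one factor; errors on unseen levels."""
    values = df[factor].astype(str).str.strip()
    unseen = set(values.unique()) - set(levels)
    if unseen:
        raise PredictionError(
            f"factor {factor!r} has levels {sorted(unseen)} not seen when the "
            "model was fitted; refusing to fall back to the reference level"
        )
    return {
        f"{factor}={lev}": (values == lev).to_numpy(dtype=float) for lev in levels[1:]
    }


def _design(
    df: pd.DataFrame, spec: ModelSpec, levels: dict[str, list[str]]
) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    blocks: dict[str, dict[str, np.ndarray]] = {}
    for f in spec.factors:
        blocks[f] = _dummy_block(df, f, levels[f])
        cols.update(blocks[f])
    for c in spec.continuous:
        cols[c] = df[c].to_numpy(dtype=float)
    for term in spec.expanded_interactions():
        for combo in itertools.product(*(blocks[f].items() for f in term)):
            name = ":".join(n for n, _ in combo)
            arr = combo[0][1].copy()
            for _, a in combo[1:]:
                arr = arr * a
            cols[name] = arr
    names = list(cols)
    return np.column_stack([cols[n] for n in names]), names


class RiskModel(abc.ABC):
    """Common interface: a per-patient predicted event probability."""

    @abc.abstractmethod
    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted probabilities for each row of ``df``."""

    def predict(self, data) -> np.ndarray:
        """Predicted probabilities for a Cohort or DataFrame."""
        if isinstance(data, Cohort):
            return self.predict_frame(data.df)
        return self.predict_frame(data)


@dataclass
class LogisticRiskModel(RiskModel):
    """A fitted pooled logistic casemix model.

    ``coefficients`` maps design-column names (``Intercept``, ``factor=level``
    dummies, continuous names, ``a=x:b=y`` interaction products) to maximum
    likelihood estimates; ``coefficient_se`` holds the corresponding
    estimated standard errors.
    """

    spec: ModelSpec
    coefficients: dict[str, float]
    levels: dict[str, list[str]]
    fitted_on: dict
    coefficient_se: dict[str, float] = field(default_factory=dict)

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        X, names = _design(df, self.spec, self.levels)
        try:
            beta = np.array([self.coefficients[n] for n in names])
        except KeyError as exc:
            raise PredictionError(f"model lacks coefficient for term {exc}") from exc
        return expit(X @ beta)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": {
                "factors": list(self.spec.factors),
                "continuous": list(self.spec.continuous),
                "interactions": [list(t) for t in self.spec.interactions],
                "saturated": self.spec.saturated,
            },
            "coefficients": self.coefficients,
            "coefficient_se": self.coefficient_se,
            "levels": self.levels,
            "fitted_on": self.fitted_on,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticRiskModel":
        return cls(
            spec=ModelSpec(
                factors=tuple(d["spec"]["factors"]),
                continuous=tuple(d["spec"]["continuous"]),
                interactions=tuple(tuple(t) for t in d["spec"]["interactions"]),
                saturated=d["spec"]["saturated"],
            ),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            coefficient_se={k: float(v) for k, v in d.get("coefficient_se", {}).items()},
            levels={k: list(v) for k, v in d["levels"].items()},
            fitted_on=d["fitted_on"],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticRiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CellRateModel(RiskModel):
    """Fixed casemix-cell-specific event probabilities.

    The classical representation of a set of standard rates: every patient
    in a given casemix cell receives that cell's probability. Used both for
    externally specified standard rates and for classical indirect
    standardisation from pooled cell rates.
    """

    factors: tuple[str, ...]
    rates: dict[tuple[str, ...], float]

    def __post_init__(self):
        self.factors = tuple(self.factors)
        self.rates = {tuple(k): float(v) for k, v in self.rates.items()}
        for key, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"cell {key}: rate {r} outside [0,1]")

    @classmethod
    def from_pooled_cells(cls, cohort: Cohort) -> "CellRateModel":
        """Standard rates = observed pooled cell rates d/n."""
        from .data_model import tabulate_casemix

        cells = tabulate_casemix(cohort)
        return cls(
            factors=cohort.spec.factors, rates={c.key: c.d / c.n for c in cells}
        )

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        keys = list(
            zip(*(df[f].astype(str).str.strip() for f in self.factors))
        )
        out = np.empty(len(df))
        for i, key in enumerate(keys):
            try:
                out[i] = self.rates[key]
            except KeyError:
                raise PredictionError(
                    f"no standard rate for casemix cell {key}"
                ) from None
        return out


def _separating_terms(cohort: Cohort, spec: ModelSpec) -> list[str]:
    """Factor levels whose patients all share one outcome (separation candidates)."""
    culprits = []
    ev = cohort.events
    for f in spec.factors:
        vals = cohort.df[f]
        for lev, grp in pd.Series(ev).groupby(vals.to_numpy()):
            m = grp.mean()
            if m in (0.0, 1.0):
                culprits.append(f"{f}={lev}")
    return culprits


def fit_risk_model(cohort: Cohort, spec: ModelSpec, *, ridge: float = 0.0) -> LogisticRiskModel:
    """Fit the pooled logistic casemix model by maximum likelihood.

    The fit is deterministic given the cohort and spec (Newton iterations to
    a relative tolerance of 1e-10, at most 100 steps). Perfect separation or
    a rank-deficient design fails loudly with the candidate separating terms
    named; a small ridge penalty (``ridge`` > 0, default off) is available
    for deliberately degenerate synthetic inputs.
    """
    spec.validate_against(cohort)
    levels = {
        f: sorted(cohort.df[f].astype(str).str.strip().unique()) for f in spec.factors
    }
    X, names = _design(cohort.df, spec, levels)
    y = cohort.events.astype(float)
    fitted_on = cohort.fingerprint()

    if ridge > 0:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=ridge, L1_wt=0.0, maxiter=_MAXITER
        )
        params = np.asarray(res.params)
        ses = np.full(len(names), np.nan)
    else:
        model = sm.Logit(y, X)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = model.fit(method="newton", maxiter=_MAXITER, tol=_TOL, disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
            culprits = _separating_terms(cohort, spec)
            raise ConvergenceError(
                "logistic fit failed (perfect separation or rank-deficient "
                f"design); candidate separating terms: {culprits or 'none found'}"
            ) from exc
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError(
                f"logistic fit did not converge in {_MAXITER} iterations"
            )
        params = np.asarray(res.params)
        with np.errstate(invalid="ignore"):
            ses = np.asarray(res.bse)

    return LogisticRiskModel(
        spec=spec,
        coefficients=dict(zip(names, (float(b) for b in params))),
        coefficient_se=dict(zip(names, (float(s) for s in ses))),
        levels=levels,
        fitted_on=fitted_on,
    )


def predict_risk(model: RiskModel, record: PatientRecord) -> float:
    """Predicted event probability for a single patient record."""
    row = {**record.factors, **record.continuous}
    p = model.predict_frame(pd.DataFrame([row]))
    return float(p[0])


def expected_events(model: RiskModel, cohort: Cohort, centre_id) -> float:
    """Expected events E_j = Σ p_i over the patients of one centre.

    With the model fitted on the pooled cohort (intercept present), the
    score equation guarantees Σ_j E_j = D up to the fit tolerance.
    """
    mask = cohort.centre_mask(centre_id)
    return float(model.predict_frame(cohort.df[mask]).sum())
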