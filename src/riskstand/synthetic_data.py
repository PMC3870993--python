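"""Synthetic multi-centre cohorts with known structure.

Every standardisation method in this package can be exercised without any
real hospital data: a :class:`SimulationSpec` describes a set of centres
(sizes, casemix distributions over factor-level combinations, per-centre
performance), casemix-cell-specific event probabilities, optional
continuous covariates, and cells deliberately left empty per centre —
empty for a *structural* reason (the combination is impossible), an
*organisational* one (the centre does not treat such patients) or a
*random* one (sampling zero).

Centre performance acts multiplicatively on the *odds* of each cell's
event probability, which keeps probabilities inside (0, 1) for any
positive multiplier and matches the logistic analysis model. Where a
worked example prints cell rates directly (rather than odds shifts), a
centre can override its cell rates verbatim.

Two deterministic expected-value fixtures reproduce the classic textbook
pathologies without sampling noise: a three-cell direct-standardisation
example in which one hospital admits no children (so its effective weights
sum to 0.75 and its raw DSR flatters it), and a two-cell SMR example in
which two hospitals with identical cell-specific death rates get different
SMRs purely because their casemix differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_model import CasemixCell, Cohort, CovariateSpec, cohort_from_frame
from .errors import SpecificationError, ValidationError

__all__ = [
    "ContinuousCovariate",
    "CentreSpec",
    "SimulationSpec",
    "generate_cohort",
    "Table1Fixture",
    "table1_fixture",
    "Table2Fixture",
    "table2_fixture",
    "make_multicentre_spec",
]

EMPTY_CELL_REASONS = ("structural", "organisational", "random")


@dataclass(frozen=True)
class ContinuousCovariate:
    """A Normal(mean, sd) covariate entering the logit linearly.

    The slope is applied to the covariate centred at its mean, so cell
    event probabilities are the probabilities at an average patient and the
    overall rate stays close to the casemix mixture rate.
    """

    name: str
    mean: float
    sd: float
    coef: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError(f"covariate {self.name!r}: sd must be ≥ 0")


@dataclass(frozen=True)
class CentreSpec:
    """One centre: size, casemix mix, performance, forced-empty cells."""

    centre_id: str
    n: int
    casemix: dict[tuple[str, ...], float]
    multiplier: float = 1.0  # odds-scale performance (>1 = worse outcomes)
    cell_rates: dict[tuple[str, ...], float] = field(default_factory=dict)
    forbidden: dict[tuple[str, ...], str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "casemix", {tuple(k): float(v) for k, v in self.casemix.items()}
        )
        object.__setattr__(
            self, "cell_rates", {tuple(k): float(v) for k, v in self.cell_rates.items()}
        )
        object.__setattr__(
            self, "forbidden", {tuple(k): str(v) for k, v in self.forbidden.items()}
        )
        if self.n < 1:
            raise ValidationError(f"centre {self.centre_id!r}: n must be ≥ 1")
        if self.multiplier <= 0:
            raise ValidationError(f"centre {self.centre_id!r}: multiplier must be > 0")
        total = sum(self.casemix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"centre {self.centre_id!r}: casemix proportions sum to {total}, not 1"
            )
        for reason in self.forbidden.values():
            if reason not in EMPTY_CELL_REASONS:
                raise ValidationError(
                    f"empty-cell reason {reason!r} not in {EMPTY_CELL_REASONS}"
                )


@dataclass(frozen=True)
class SimulationSpec:
    """Generative description of a synthetic multi-centre cohort."""

    factor_names: tuple[str, ...]
    centres: tuple[CentreSpec, ...]
    standard_rates: dict[tuple[str, ...], float]
    continuous: tuple[ContinuousCovariate, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        object.__setattr__(self, "centres", tuple(self.centres))
        object.__setattr__(self, "continuous", tuple(self.continuous))
        object.__setattr__(
            self,
            "standard_rates",
            {tuple(k): float(v) for k, v in self.standard_rates.items()},
        )
        for key, r in self.standard_rates.items():
            if len(key) != len(self.factor_names):
                raise SpecificationError(
                    f"cell key {key} does not match factors {self.factor_names}"
                )
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"cell {key}: rate {r} outside [0,1]")
        for c in self.centres:
            unknown = set(c.casemix) - set(self.standard_rates)
            if unknown:
                raise SpecificationError(
                    f"centre {c.centre_id!r} uses cells with no standard rate: "
                    f"{sorted(unknown)}"
                )

    def covariate_spec(self) -> CovariateSpec:
        return CovariateSpec(
            factors=self.factor_names,
            continuous=tuple(c.name for c in self.continuous),
        )


def _cell_probability(spec: SimulationSpec, centre: CentreSpec, key) -> float:
    base = centre.cell_rates.get(key, spec.standard_rates[key])
    if base in (0.0, 1.0) or centre.multiplier == 1.0:
        p = base
    else:
        p = float(expit(logit(base) + np.log(centre.multiplier)))
    return p


def generate_cohort(spec: SimulationSpec) -> Cohort:
    """Draw a cohort from the spec; byte-identical given the same seed.

    Cell membership is multinomial over the centre's casemix restricted to
    non-forbidden cells (renormalised); events are Bernoulli in the cell
    probability shifted by the centre's odds multiplier and any continuous
    covariate effects.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for centre in spec.centres:
        keys = [k for k in centre.casemix if k not in centre.forbidden]
        probs = np.array([centre.casemix[k] for k in keys], dtype=float)
        if not keys or probs.sum() <= 0:
            raise SpecificationError(
                f"centre {centre.centre_id!r}: every casemix cell is forbidden"
            )
        probs = probs / probs.sum()
        counts = rng.multinomial(centre.n, probs)

        cell_of_record = np.repeat(np.arange(len(keys)), counts)
        base_p = np.array([_cell_probability(spec, centre, k) for k in keys])
        p = base_p[cell_of_record]

        cont_values = {}
        if spec.continuous:
            degenerate = (p == 0.0) | (p == 1.0)
            eta = np.where(degenerate, 0.0, logit(np.clip(p, 1e-15, 1 - 1e-15)))
            for cov in spec.continuous:
                x = rng.normal(cov.mean, cov.sd, size=centre.n)
                cont_values[cov.name] = x
                eta = eta + cov.coef * (x - cov.mean)
            p = np.where(degenerate, p, expit(eta))

        events = (rng.random(centre.n) < p).astype(np.int64)
        cols = {"centre": centre.centre_id, "event": events}
        for j, name in enumerate(spec.factor_names):
            cols[name] = [keys[c][j] for c in cell_of_record]
        cols.update(cont_values)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    return cohort_from_frame(df, spec.covariate_spec())


# ---------------------------------------------------------------------------
# Deterministic worked-example fixtures


@dataclass(frozen=True)
class Table1Fixture:
    """Direct-standardisation pathology: a hospital with no children.

    Age-specific death rates per 100 admissions are 20/10/20 for hospital 1
    (children/adults/elderly) and —/12/24 for hospital 2, which admits no
    children and is 20% worse cell-for-cell; national standard weights are
    0.25/0.50/0.25. Cell sizes of 100 reproduce the per-100 rates exactly.
    """

    cells: dict[str, list[CasemixCell]]
    standard_weights: dict[tuple[str, ...], float]


def table1_fixture() -> Table1Fixture:
    return Table1Fixture(
        cells={
            "hospital_1": [
                CasemixCell(("Children",), 100, 20),
                CasemixCell(("Adults",), 100, 10),
                CasemixCell(("Elderly",), 100, 20),
            ],
            "hospital_2": [
                CasemixCell(("Adults",), 100, 12),
                CasemixCell(("Elderly",), 100, 24),
            ],
        },
        standard_weights={("Children",): 0.25, ("Adults",): 0.50, ("Elderly",): 0.25},
    )


@dataclass(frozen=True)
class Table2Fixture:
    """SMR non-comparability: identical performance, different casemix.

    Both hospitals kill 0.8 of high-risk and 0.2 of low-risk patients;
    national standard rates are 0.9 and 0.1. Hospital A admits 40% high
    risk, hospital B 30%. Expected-value arithmetic (per patient):
    O_A = 0.44, E_A = 0.42 (SMR 1.048); O_B = 0.38, E_B = 0.34 (SMR 1.118).
    """

    groups: tuple[str, str] = ("high_risk", "low_risk")
    standard_rates: dict[tuple[str, ...], float] = field(
        default_factory=lambda: {("high_risk",): 0.9, ("low_risk",): 0.1}
    )
    death_rates: dict[tuple[str, ...], float] = field(
        default_factory=lambda: {("high_risk",): 0.8, ("low_risk",): 0.2}
    )
    proportions: dict[str, dict[tuple[str, ...], float]] = field(
        default_factory=lambda: {
            "hospital_A": {("high_risk",): 0.4, ("low_risk",): 0.6},
            "hospital_B": {("high_risk",): 0.3, ("low_risk",): 0.7},
        }
    )

    def observed_per_patient(self, hospital: str) -> float:
        """O per patient: Σ proportion × death rate."""
        return sum(p * self.death_rates[k] for k, p in self.proportions[hospital].items())

    def expected_per_patient(self, hospital: str) -> float:
        """E per patient: Σ proportion × standard rate."""
        return sum(
            p * self.standard_rates[k] for k, p in self.proportions[hospital].items()
        )

    def as_simulation_spec(self, n_per_centre: int, seed: int = 0) -> SimulationSpec:
        """Stochastic version: sample patients from the same structure."""
        return SimulationSpec(
            factor_names=("risk_group",),
            centres=tuple(
                CentreSpec(
                    centre_id=h,
                    n=n_per_centre,
                    casemix=props,
                    cell_rates=dict(self.death_rates),
                )
                for h, props in self.proportions.items()
            ),
            standard_rates=dict(self.standard_rates),
            seed=seed,
        )


def table2_fixture() -> Table2Fixture:
    return Table2Fixture()


# ---------------------------------------------------------------------------
# A ready-made multi-centre emergency-admissions-like scenario


def make_multicentre_spec(
    n_centres: int = 9,
    n_per_centre: int = 2000,
    *,
    seed: int = 0,
    include_age: bool = True,
    multiplier_sd: float = 0.15,
    base_rates: tuple[float, ...] = (0.02, 0.06, 0.15),
    mean_casemix: tuple[float, ...] = (0.50, 0.35, 0.15),
) -> SimulationSpec:
    """A severity-graded multi-centre cohort at emergency-admission scale.

    Three severity strata with event probabilities ``base_rates`` and mean
    mix ``mean_casemix`` give an overall event rate near 5–6%. Each centre
    gets its own casemix (Dirichlet around the mean mix, concentration 60)
    and its own performance (log-normal odds multiplier, sd
    ``multiplier_sd``); optionally an age covariate, Normal(70, 15) years,
    with slope 0.03 per year on the logit, spreads risk continuously within
    strata.
    """
    if len(base_rates) != len(mean_casemix):
        raise SpecificationError("base_rates and mean_casemix lengths differ")
    rng = np.random.default_rng([int(seed), 911])
    levels = [f"severity_{i + 1}" for i in range(len(base_rates))]
    standard = {(lev,): r for lev, r in zip(levels, base_rates)}
    centres = []
    for j in range(n_centres):
        mix = rng.dirichlet(60 * np.asarray(mean_casemix))
        centres.append(
            CentreSpec(
                centre_id=f"centre_{j + 1:02d}",
                n=n_per_centre,
                casemix={(lev,): float(m) for lev, m in zip(levels, mix)},
                multiplier=float(np.exp(rng.normal(0.0, multiplier_sd))),
            )
        )
    continuous = (
        (ContinuousCovariate("age", mean=70.0, sd=15.0, coef=0.03),)
        if include_age
        else ()
    )
    return SimulationSpec(
        factor_names=("severity",),
        centres=tuple(centres),
        standard_rates=standard,
        continuous=continuous,
        seed=seed,
    )
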