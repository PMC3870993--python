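"""YAML configuration: column roles, model terms, categorisation choices,
bootstrap settings, and simulation specs.

The config file is the single source of truth for a run; command-line
flags override individual fields. Casemix cells are written as lists of
factor levels (one per factor, in order), e.g. ``cell: [Adults]`` or
``cell: [Adults, Emergency]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data_model import CovariateSpec
from .errors import SpecificationError
from .risk_model import ModelSpec
from .synthetic_data import CentreSpec, ContinuousCovariate, SimulationSpec
from .uncertainty import BootstrapConfig

__all__ = ["RunConfig", "load_run_config", "load_simulation_spec"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the data itself."""

    covariates: CovariateSpec
    model: ModelSpec
    K: int = 10
    category_method: str = "equal_observed_events"
    weight_source: str = "patient_proportion"
    bootstrap: BootstrapConfig | None = None
    scale: str = "ratio"  # "ratio" (1.03) or "percent" (103)
    missing_values: tuple[str, ...] = ("",)

    def __post_init__(self):
        if self.scale not in ("ratio", "percent"):
            raise SpecificationError(f"scale must be 'ratio' or 'percent', got {self.scale!r}")


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise SpecificationError(f"config {ctx!r} section lacks required field {key!r}")
    return d[key]


def run_config_from_dict(d: dict) -> RunConfig:
    cols = _require(d, "columns", "top-level")
    covariates = CovariateSpec(
        factors=tuple(cols.get("factors", ())),
        continuous=tuple(cols.get("continuous", ())),
        centre_col=cols.get("centre", "centre"),
        event_col=cols.get("event", "event"),
    )
    m = d.get("model", {})
    model = ModelSpec(
        factors=tuple(m.get("factors", covariates.factors)),
        continuous=tuple(m.get("continuous", covariates.continuous)),
        interactions=tuple(tuple(t) for t in m.get("interactions", ())),
        saturated=bool(m.get("saturated", False)),
    )
    cat = d.get("categories", {})
    bs = d.get("bootstrap")
    return RunConfig(
        covariates=covariates,
        model=model,
        K=int(cat.get("K", 10)),
        category_method=cat.get("method", "equal_observed_events"),
        weight_source=cat.get("weight_source", "patient_proportion"),
        bootstrap=(
            BootstrapConfig(
                replicates=int(bs.get("replicates", 1000)), seed=int(bs.get("seed", 0))
            )
            if bs
            else None
        ),
        scale=d.get("scale", "ratio"),
        missing_values=tuple(d.get("missing_values", ("",))),
    )


def load_run_config(path: str | Path) -> RunConfig:
    return run_config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _cell_key(entry, n_factors: int, ctx: str) -> tuple[str, ...]:
    key = tuple(str(x) for x in (entry if isinstance(entry, (list, tuple)) else [entry]))
    if len(key) != n_factors:
        raise SpecificationError(f"{ctx}: cell {key} does not name one level per factor")
    return key


def simulation_spec_from_dict(d: dict) -> SimulationSpec:
    factors = tuple(_require(d, "factors", "simulation"))
    nf = len(factors)
    standard = {
        _cell_key(e["cell"], nf, "standard_rates"): float(e["rate"])
        for e in _require(d, "standard_rates", "simulation")
    }
    centres = []
    for c in _require(d, "centres", "simulation"):
        centres.append(
            CentreSpec(
                centre_id=str(_require(c, "id", "centre")),
                n=int(_require(c, "n", "centre")),
                casemix={
                    _cell_key(e["cell"], nf, "casemix"): float(e["proportion"])
                    for e in _require(c, "casemix", "centre")
                },
                multiplier=float(c.get("multiplier", 1.0)),
                cell_rates={
                    _cell_key(e["cell"], nf, "cell_rates"): float(e["rate"])
                    for e in c.get("cell_rates", ())
                },
                forbidden={
                    _cell_key(e["cell"], nf, "forbidden"): str(e["reason"])
                    for e in c.get("forbidden", ())
                },
            )
        )
    continuous = tuple(
        ContinuousCovariate(
            name=str(e["name"]), mean=float(e["mean"]), sd=float(e["sd"]),
            coef=float(e["coef"]),
        )
        for e in d.get("continuous", ())
    )
    return SimulationSpec(
        factor_names=factors,
        centres=tuple(centres),
        standard_rates=standard,
        continuous=continuous,
        seed=int(d.get("seed", 0)),
    )


def load_simulation_spec(path: str | Path) -> SimulationSpec:
    return simulation_spec_from_dict(yaml.safe_load(Path(path).read_text()) or {})
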