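"""Standard errors for the SMR and the DRS CMF.

Theoretical standard errors treat everything defined on the pooled data —
expected events E_j, category weights w_k, and the overall rate r̄ — as
fixed constants, leaving only binomial outcome variation:

* SE(SMR_j)  = sqrt(Σ_{i∈j} p_i (1 − p_i)) / E_j
* SE(CMF_j)  = sqrt(Σ_k w_k² · p_jk (1 − p_jk) / n_jk) / r̄

The empirical alternative is a simple within-centre bootstrap: resample
each centre's patients with replacement (risk and outcome together), keep
the pooled model, category boundaries, weights and r̄ frozen at the
original fit, recompute the statistic per replicate, and take the standard
deviation of the replicates about their mean.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .categorisation import CategoryWeights, RiskCategoryScheme
from .data_model import Cohort
from .errors import ParameterError, ValidationError
from .risk_model import RiskModel
from .standardisers import CentreRateTable

__all__ = [
    "BootstrapConfig",
    "BootstrapEstimate",
    "se_smr_theoretical",
    "se_cmf_theoretical",
    "bootstrap_se",
]

# cap on index-matrix elements held at once while bootstrapping
_CHUNK_ELEMENTS = 2_000_000


@dataclass(frozen=True)
class BootstrapConfig:
    """Within-centre resampling with replacement.

    One master ``seed``; each centre draws from its own child stream derived
    from (seed, centre id), so adding or removing a centre leaves the other
    centres' draws untouched.
    """

    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ParameterError("bootstrap needs at least 2 replicates")

    def rng_for(self, centre_id) -> np.random.Generator:
        child = zlib.crc32(str(centre_id).encode("utf-8"))
        return np.random.default_rng([int(self.seed), child])


@dataclass(frozen=True)
class BootstrapEstimate:
    """Bootstrap SE for one centre, with replicate bookkeeping.

    ``n_failed`` counts replicates where the statistic was undefined (a
    positively-weighted category emptied under resampling); those replicates
    are excluded. ``unreliable`` flags centres where more than 10% failed.
    """

    se: float
    n_replicates: int
    n_failed: int = 0

    @property
    def unreliable(self) -> bool:
        return self.n_failed > 0.1 * self.n_replicates


def se_smr_theoretical(risks, expected: float) -> float:
    """Binomial-variance SE of the SMR, with E treated as fixed."""
    if expected <= 0:
        raise ParameterError("expected events must be positive")
    p = np.asarray(risks, dtype=float)
    return float(np.sqrt(np.sum(p * (1.0 - p))) / expected)


def se_cmf_theoretical(
    table: CentreRateTable, weights: CategoryWeights, overall_rate: float
) -> float:
    """Binomial-variance SE of the DRS CMF, with w and r̄ treated as fixed.

    Undefined (raises) when a positively-weighted category is empty — the
    same condition under which the CMF itself is undefined.
    """
    if overall_rate <= 0:
        raise ParameterError("overall rate must be positive")
    w = weights.weights
    if len(w) != len(table.n):
        raise ValidationError("weights and rate table disagree on K")
    used = w > 0
    if (table.n[used] == 0).any():
        from .errors import NotComputableError

        raise NotComputableError(
            f"centre {table.centre_id!r}: empty positively-weighted category; "
            "SE(CMF) undefined"
        )
    n, p = table.n[used], table.rates[used]
    var = np.sum(w[used] ** 2 * p * (1.0 - p) / n)
    return float(np.sqrt(var) / overall_rate)


def _bootstrap_centre(
    rng: np.random.Generator,
    events: np.ndarray,
    risks: np.ndarray,
    cats: np.ndarray,
    weights: np.ndarray,
    statistic: str,
    B: int,
    overall_rate: float,
) -> tuple[np.ndarray, int]:
    """Replicate statistics for one centre; returns (valid values, n_failed)."""
    n = len(events)
    K = len(weights)
    pos = weights > 0
    chunk = max(1, _CHUNK_ELEMENTS // max(n, 1))
    vals: list[np.ndarray] = []
    n_failed = 0
    done = 0
    while done < B:
        R = min(chunk, B - done)
        idx = rng.integers(0, n, size=(R, n))
        if statistic == "smr":
            O = events[idx].sum(axis=1)
            E = risks[idx].sum(axis=1)
            ok = E > 0
            n_failed += int((~ok).sum())
            vals.append(O[ok] / E[ok])
        else:  # cmf
            c = cats[idx]
            offsets = (np.arange(R)[:, None] * K + c).ravel()
            n_bk = np.bincount(offsets, minlength=R * K).reshape(R, K)
            d_bk = np.bincount(
                offsets, weights=events[idx].ravel().astype(float), minlength=R * K
            ).reshape(R, K)
            ok = (n_bk[:, pos] > 0).all(axis=1)
            n_failed += int((~ok).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                rates = np.where(n_bk > 0, d_bk / np.maximum(n_bk, 1), 0.0)
            drs = rates[ok][:, pos] @ weights[pos]
            vals.append(drs / overall_rate)
        done += R
    return np.concatenate(vals) if vals else np.empty(0), n_failed


def bootstrap_se(
    cohort: Cohort,
    model: RiskModel,
    scheme: RiskCategoryScheme,
    weights: CategoryWeights,
    statistic: Literal["smr", "cmf"],
    config: BootstrapConfig,
) -> dict[str, BootstrapEstimate]:
    """Within-centre bootstrap SE of the SMR or DRS CMF for every centre.

    Patient rows (risk, outcome, category) are resampled with replacement
    within each centre; the model, scheme, weights and r̄ stay frozen at the
    original fit. The SE is the standard deviation (divisor B−1) of the
    replicate statistics about the replicate mean. Deterministic given the
    config seed.
    """
    if statistic not in ("smr", "cmf"):
        raise ParameterError(f"unknown bootstrap statistic {statistic!r}")
    risks = model.predict(cohort)
    cats = scheme.assign_indices(risks)
    events = cohort.events.astype(float)
    rbar = cohort.overall_rate
    w = weights.weights

    out: dict[str, BootstrapEstimate] = {}
    for cid in cohort.centre_ids():
        mask = cohort.centre_mask(cid)
        vals, n_failed = _bootstrap_centre(
            config.rng_for(cid),
            events[mask],
            risks[mask],
            cats[mask],
            w,
            statistic,
            config.replicates,
            rbar,
        )
        se = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
        out[cid] = BootstrapEstimate(
            se=se, n_replicates=config.replicates, n_failed=n_failed
        )
    return out
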