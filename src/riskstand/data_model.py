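"""Domain types, patient-level data ingestion and result serialisation.

The in-memory container for patient-level data is a pandas ``DataFrame``
wrapped in a :class:`Cohort`, which pins down the roles of the columns
(centre identifier, binary event indicator, categorical casemix factors,
continuous covariates) and enforces the domain invariants at construction.

Rows with any missing declared value are deleted listwise on ingestion and
the deleted count is retained on the cohort, so incomplete-case handling is
explicit rather than silent.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyDataError, FormatError, ValidationError

__all__ = [
    "CovariateSpec",
    "PatientRecord",
    "Cohort",
    "CasemixCell",
    "StandardisationResult",
    "read_cohort",
    "write_cohort",
    "cohort_from_frame",
    "tabulate_casemix",
    "write_results",
    "read_results",
    "results_frame",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Declares which columns play which role in a patient-level table.

    Parameters
    ----------
    factors
        Names of categorical casemix columns. Levels are compared as exact
        strings after whitespace trimming; no fuzzy matching.
    continuous
        Names of continuous covariate columns (real-valued).
    centre_col, event_col
        Names of the centre-identifier and binary-event columns.
    """

    factors: tuple[str, ...] = ()
    continuous: tuple[str, ...] = ()
    centre_col: str = "centre"
    event_col: str = "event"

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "continuous", tuple(self.continuous))
        names = [self.centre_col, self.event_col, *self.factors, *self.continuous]
        if len(set(names)) != len(names):
            raise ValidationError(f"covariate roles overlap: {names}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.factors + self.continuous

    @property
    def columns(self) -> tuple[str, ...]:
        return (self.centre_col, self.event_col) + self.covariates


@dataclass(frozen=True)
class PatientRecord:
    """One patient: centre, binary event, and covariate values."""

    centre_id: str
    event: int
    factors: dict[str, str] = field(default_factory=dict)
    continuous: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event!r}")


class Cohort:
    """Patient-level records across all centres (the pooled dataset).

    Everything downstream — the pooled risk model, the risk categories, the
    standard weights, the overall rate r̄ — is defined on this aggregate.
    """

    def __init__(self, df: pd.DataFrame, spec: CovariateSpec, n_dropped: int = 0):
        missing = [c for c in spec.columns if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table lacks required columns: {missing}")
        df = df.loc[:, list(spec.columns)].reset_index(drop=True)
        events = df[spec.event_col].to_numpy()
        if not np.isin(events, (0, 1)).all():
            bad = sorted(set(events) - {0, 1})
            raise ValidationError(f"event values outside {{0,1}}: {bad}")
        if len(df) == 0:
            raise EmptyDataError("cohort has no records")
        self.df = df
        self.spec = spec
        self.n_dropped = int(n_dropped)

    # -- basic aggregates -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of records, N."""
        return len(self.df)

    @property
    def n_events(self) -> int:
        """Total observed events, D."""
        return int(self.df[self.spec.event_col].sum())

    @property
    def overall_rate(self) -> float:
        """Pooled event rate r̄ = D / N."""
        return self.n_events / self.n

    @property
    def events(self) -> np.ndarray:
        return self.df[self.spec.event_col].to_numpy(dtype=np.int64)

    @property
    def centres(self) -> np.ndarray:
        return self.df[self.spec.centre_col].to_numpy()

    def centre_ids(self) -> list[str]:
        """Distinct centre identifiers, in order of first appearance."""
        return list(dict.fromkeys(self.df[self.spec.centre_col]))

    def centre_mask(self, centre_id) -> np.ndarray:
        mask = self.centres == centre_id
        if not mask.any():
            raise KeyError(f"centre {centre_id!r} not present in cohort")
        return mask

    def subset(self, centre_id) -> "Cohort":
        return Cohort(self.df[self.centre_mask(centre_id)], self.spec)

    def iter_records(self) -> Iterator[PatientRecord]:
        s = self.spec
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield PatientRecord(
                centre_id=d[s.centre_col],
                event=int(d[s.event_col]),
                factors={f: d[f] for f in s.factors},
                continuous={c: float(d[c]) for c in s.continuous},
            )

    def fingerprint(self) -> dict:
        """Small summary used to tag fitted models with their data."""
        return {"n": self.n, "d": self.n_events, "covariates": list(self.spec.covariates)}

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return (
            f"Cohort(n={self.n}, events={self.n_events}, "
            f"centres={len(self.centre_ids())}, dropped={self.n_dropped})"
        )


@dataclass(frozen=True)
class CasemixCell:
    """One combination of casemix factor levels: patient count and events."""

    key: tuple[str, ...]
    n: int
    d: int

    def __post_init__(self):
        if not 0 <= self.d <= self.n:
            raise ValidationError(f"cell {self.key}: d={self.d} outside [0, n={self.n}]")

    @property
    def rate(self) -> float | None:
        """Observed event rate d/n, or None for an empty cell."""
        return None if self.n == 0 else self.d / self.n


# ---------------------------------------------------------------------------
# Ingestion


def _clean_str(series: pd.Series) -> pd.Series:
    return series.astype("string").str.strip()


def read_cohort(
    path: str | Path,
    spec: CovariateSpec,
    *,
    missing_values: Sequence[str] = ("",),
    sep: str = ",",
) -> Cohort:
    """Read a delimited patient-level file into a validated :class:`Cohort`.

    Missing values (empty string or any configured sentinel) in a declared
    column cause listwise deletion of the row; the number of deleted rows is
    recorded on ``Cohort.n_dropped``.

    Raises
    ------
    FormatError
        A declared column is absent from the file.
    ValidationError
        Event values outside {0,1}, or unparseable continuous values.
    EmptyDataError
        No complete rows remain.
    """
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise EmptyDataError(f"{path}: {exc}") from exc
    missing_cols = [c for c in spec.columns if c not in raw.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    raw = raw.loc[:, list(spec.columns)]
    for col in spec.columns:
        raw[col] = _clean_str(raw[col])

    sentinels = set(missing_values) | {""}
    incomplete = raw.isin(sentinels).any(axis=1) | raw.isna().any(axis=1)
    df = raw.loc[~incomplete].copy()
    n_dropped = int(incomplete.sum())
    if len(df) == 0:
        raise EmptyDataError(f"{path}: no complete rows (dropped {n_dropped})")

    ev = df[spec.event_col]
    if not ev.isin(("0", "1")).all():
        bad = sorted(set(ev) - {"0", "1"})
        raise ValidationError(f"{path}: event column contains non-binary values {bad}")
    df[spec.event_col] = ev.astype(np.int64)
    for col in spec.continuous:
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ValidationError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    return Cohort(df, spec, n_dropped=n_dropped)


def write_cohort(cohort: Cohort, path: str | Path, *, sep: str = ",") -> None:
    """Write the patient-level table as delimited text (inverse of
    :func:`read_cohort` up to column dtypes)."""
    cohort.df.to_csv(path, sep=sep, index=False,
                     float_format=lambda x: repr(float(x)))


def cohort_from_frame(df: pd.DataFrame, spec: CovariateSpec) -> Cohort:
    """Build a :class:`Cohort` from an in-memory frame, trimming factor levels."""
    df = df.copy()
    df[spec.centre_col] = _clean_str(df[spec.centre_col])
    for col in spec.factors:
        df[col] = _clean_str(df[col])
    for col in spec.continuous:
        df[col] = df[col].astype(float)
    df[spec.event_col] = df[spec.event_col].astype(np.int64)
    return Cohort(df, spec)


# ---------------------------------------------------------------------------
# Casemix tabulation


def tabulate_casemix(cohort: Cohort, centre_id=None) -> list[CasemixCell]:
    """Cross-tabulate records into casemix cells (one per observed level
    combination of the categorical factors), optionally for a single centre.

    Continuous covariates cannot be cell-tabulated and are excluded; a cohort
    with no categorical factors cannot be tabulated at all.
    """
    if not cohort.spec.factors:
        raise ValidationError(
            "casemix tabulation needs at least one categorical factor; "
            "continuous covariates cannot be tabulated into cells"
        )
    df = cohort.df
    if centre_id is not None:
        df = df[cohort.centre_mask(centre_id)]
    grouped = df.groupby(list(cohort.spec.factors), sort=True, observed=True)[
        cohort.spec.event_col
    ].agg(["size", "sum"])
    cells = []
    for key, row in grouped.iterrows():
        key = key if isinstance(key, tuple) else (key,)
        cells.append(CasemixCell(key=tuple(key), n=int(row["size"]), d=int(row["sum"])))
    return cells


# ---------------------------------------------------------------------------
# Results


@dataclass
class StandardisationResult:
    """Per-centre standardised measures with their uncertainties.

    ``None`` marks a statistic that is genuinely undefined for this centre
    (e.g. a raw directly standardised rate when casemix cells are missing);
    it is never conflated with zero. ``notes`` records why.
    """

    centre_id: str
    n: int
    observed: int
    expected: float | None = None
    smr: float | None = None
    se_smr: float | None = None
    se_smr_bootstrap: float | None = None
    drs_rate: float | None = None
    cmf: float | None = None
    se_cmf: float | None = None
    se_cmf_bootstrap: float | None = None
    dsr_raw: float | None = None
    dsr_renormalised: float | None = None
    effective_weight_sum: float | None = None
    notes: str = ""


RESULT_COLUMNS = [f.name for f in dataclasses.fields(StandardisationResult)]

_FLOAT_RESULT_COLUMNS = [
    c for c in RESULT_COLUMNS if c not in ("centre_id", "n", "observed", "notes")
]


def results_frame(results: Iterable[StandardisationResult]) -> pd.DataFrame:
    """Results as a tidy one-row-per-centre frame (None → missing)."""
    rows = [dataclasses.asdict(r) for r in results]
    if not rows:
        raise EmptyDataError("no results to tabulate")
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Iterable[StandardisationResult], path: str | Path) -> None:
    """Write one row per centre as CSV; undefined statistics become empty
    fields (missing, not zero). Floats keep full precision (repr round-trip).
    """
    df = results_frame(results)
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_results(path: str | Path) -> list[StandardisationResult]:
    """Inverse of :func:`write_results` (empty fields → None)."""
    df = pd.read_csv(path, dtype={"centre_id": str, "notes": str},
                     keep_default_na=False, float_precision="round_trip")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        kwargs = {"centre_id": d["centre_id"], "n": int(d["n"]), "observed": int(d["observed"]),
                  "notes": d.get("notes", "")}
        for c in _FLOAT_RESULT_COLUMNS:
            v = d[c]
            if v == "" or (isinstance(v, float) and math.isnan(v)):
                kwargs[c] = None
            else:
                kwargs[c] = float(v)
        out.append(StandardisationResult(**kwargs))
    return out
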