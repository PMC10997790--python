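"""Patient cohort I/O, validation, and design-matrix encoding.

A cohort is a table of adult TBI patients with the four admission
covariates (age, GCS-motor, pupillary reaction, Marshall CT class) and the
observed 8-level GOSE outcome. The CSV schema is fixed:

    patient_id,age,gcs_motor,pupils,marshall,gose

Missing values are written as empty strings and read from empty strings or
"NA". Categorical covariates are dummy-coded against declared reference
levels (gcs_motor=1, pupils=both, marshall=diffuse_I by default); age is
continuous and optionally standardized with training-partition statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GOSE_LEVELS",
    "GCS_MOTOR_LEVELS",
    "PUPILS_LEVELS",
    "MARSHALL_LEVELS",
    "COHORT_COLUMNS",
    "PatientRecord",
    "Cohort",
    "EncodingSpec",
    "DesignMatrix",
    "SchemaError",
    "ValidationError",
    "EncodingError",
    "read_cohort",
    "write_cohort",
    "complete_cases",
    "encode_design",
]

GOSE_LEVELS: tuple[int, ...] = tuple(range(1, 9))
GCS_MOTOR_LEVELS: tuple[int, ...] = tuple(range(1, 7))
PUPILS_LEVELS: tuple[str, ...] = ("both", "one", "none")
MARSHALL_LEVELS: tuple[str, ...] = (
    "diffuse_I",
    "diffuse_II",
    "diffuse_III",
    "diffuse_IV",
    "evacuated_mass",
    "non_evacuated_mass",
)
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "gcs_motor",
    "pupils",
    "marshall",
    "gose",
)
MODEL_FIELDS: tuple[str, ...] = ("age", "gcs_motor", "pupils", "marshall", "gose")

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


class SchemaError(ValueError):
    """CSV header does not match the cohort schema."""


class ValidationError(ValueError):
    """A field value violates the cohort invariants."""


class EncodingError(ValueError):
    """A record carries a categorical level unknown to the encoding spec."""


class PatientRecord(NamedTuple):
    """One patient row; model fields may be ``None`` (missing)."""

    patient_id: str
    age: float | None
    gcs_motor: int | None
    pupils: str | None
    marshall: str | None
    gose: int | None


@dataclass
class Cohort:
    """Ordered collection of patient records backed by a DataFrame.

    Parameters
    ----------
    data
        DataFrame with the columns of :data:`COHORT_COLUMNS`. Missing model
        fields are NaN/None.
    name
        Free-text cohort label.
    profile
        Optional generator profile tag ("uppsala", "leuven", "protect",
        "custom") for cohorts produced by :mod:`gosepred.synthetic`.
    """

    data: pd.DataFrame
    name: str = ""
    profile: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort data missing columns: {missing}")
        self.data = self.data.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)
        _validate_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def gose(self) -> np.ndarray:
        """Observed GOSE as a float array (NaN where missing)."""
        return self.data["gose"].to_numpy(dtype=float)

    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    age=None if pd.isna(row.age) else float(row.age),
                    gcs_motor=None if pd.isna(row.gcs_motor) else int(row.gcs_motor),
                    pupils=None if pd.isna(row.pupils) else str(row.pupils),
                    marshall=None if pd.isna(row.marshall) else str(row.marshall),
                    gose=None if pd.isna(row.gose) else int(row.gose),
                )
            )
        return out

    @classmethod
    def from_records(
        cls,
        records: Iterable[PatientRecord | Mapping],
        name: str = "",
        profile: str | None = None,
    ) -> "Cohort":
        rows = []
        for rec in records:
            if isinstance(rec, PatientRecord):
                rows.append(rec._asdict())
            else:
                rows.append(dict(rec))
        frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
        return cls(data=frame, name=name, profile=profile)

    def subset(self, index: Sequence[int] | np.ndarray, name: str | None = None) -> "Cohort":
        """Positional subset preserving the given order."""
        frame = self.data.iloc[list(index)].reset_index(drop=True)
        return Cohort(data=frame, name=name or self.name, profile=self.profile)

    def subset_ids(self, patient_ids: Sequence[str], name: str | None = None) -> "Cohort":
        """Subset by patient_id, in the order given (repeats allowed)."""
        pos = {pid: i for i, pid in enumerate(self.data["patient_id"])}
        try:
            index = [pos[str(p)] for p in patient_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown patient_id {exc}") from exc
        frame = self.data.iloc[index].reset_index(drop=True)
        if len(set(patient_ids)) != len(patient_ids):
            frame = frame.copy()
            frame["patient_id"] = [
                f"{pid}#{k}" if k else pid
                for k, pid in zip(
                    frame.groupby("patient_id").cumcount(), frame["patient_id"]
                )
            ]
        return Cohort(data=frame, name=name or self.name, profile=self.profile)


def _parse_value(field_name: str, raw: object, row_label: object):
    """Coerce one raw CSV cell; raise ValidationError naming the row."""
    if raw is None or pd.isna(raw):
        return None
    text = str(raw).strip()
    if text in _MISSING_TOKENS:
        return None
    try:
        if field_name == "age":
            value = float(text)
            if value < 18:
                raise ValidationError(
                    f"row {row_label}: age {value} below adult minimum of 18"
                )
            return value
        if field_name in ("gcs_motor", "gose"):
            value = int(float(text))
            levels = GCS_MOTOR_LEVELS if field_name == "gcs_motor" else GOSE_LEVELS
            if value not in levels:
                raise ValidationError(
                    f"row {row_label}: {field_name}={value} outside "
                    f"{levels[0]}-{levels[-1]}"
                )
            return value
        if field_name == "pupils":
            if text not in PUPILS_LEVELS:
                raise ValidationError(
                    f"row {row_label}: pupils={text!r} not in {PUPILS_LEVELS}"
                )
            return text
        if field_name == "marshall":
            if text not in MARSHALL_LEVELS:
                raise ValidationError(
                    f"row {row_label}: marshall={text!r} not in {MARSHALL_LEVELS}"
                )
            return text
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {row_label}: cannot parse {field_name}={text!r}"
        ) from exc
    return text


def _validate_frame(frame: pd.DataFrame) -> None:
    ids = frame["patient_id"].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()[:5]
        raise ValidationError(f"duplicate patient_id values: {list(dupes)}")

    def _first_bad(mask: pd.Series) -> int:
        return int(np.flatnonzero(mask.to_numpy())[0])

    age = pd.to_numeric(frame["age"], errors="coerce")
    bad = frame["age"].notna() & age.isna()
    if bad.any():
        raise ValidationError(f"row {_first_bad(bad)}: cannot parse age")
    low = age.notna() & (age < 18)
    if low.any():
        i = _first_bad(low)
        raise ValidationError(f"row {i}: age {age.iloc[i]} below adult minimum of 18")
    for field_name, levels in (("gcs_motor", GCS_MOTOR_LEVELS), ("gose", GOSE_LEVELS)):
        vals = pd.to_numeric(frame[field_name], errors="coerce")
        bad = frame[field_name].notna() & (vals.isna() | ~vals.isin(levels))
        if bad.any():
            i = _first_bad(bad)
            raise ValidationError(
                f"row {i}: {field_name}={frame[field_name].iloc[i]} outside "
                f"{levels[0]}-{levels[-1]}"
            )
    for field_name, levels in (("pupils", PUPILS_LEVELS), ("marshall", MARSHALL_LEVELS)):
        bad = frame[field_name].notna() & ~frame[field_name].isin(levels)
        if bad.any():
            i = _first_bad(bad)
            raise ValidationError(
                f"row {i}: {field_name}={frame[field_name].iloc[i]!r} not in {levels}"
            )


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    name: str | None = None,
) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row. Column order is free; resolution is by
        name (optionally through ``schema``).
    schema
        Optional mapping from canonical field name to the column name used
        in the file, e.g. ``{"gose": "outcome"}``. Unmapped fields use
        their canonical names.
    name
        Cohort label; defaults to the file stem.

    Raises
    ------
    SchemaError
        A required column is absent from the header.
    ValidationError
        A field value is unparseable or out of range; the message names
        the offending row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {f: f for f in COHORT_COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    frame = pd.DataFrame()
    frame["patient_id"] = raw[colmap["patient_id"]].astype(str)
    for field_name in MODEL_FIELDS:
        parsed = [
            _parse_value(field_name, v, row_label=i)
            for i, v in enumerate(raw[colmap[field_name]])
        ]
        if field_name in ("gcs_motor", "gose"):
            frame[field_name] = pd.array(parsed, dtype="Int64")
        elif field_name == "age":
            frame[field_name] = pd.array(parsed, dtype="Float64")
        else:
            frame[field_name] = pd.Series(parsed, dtype=object)
    label = name if name is not None else getattr(path, "stem", str(path))
    return Cohort(data=frame, name=str(label))


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort CSV in the fixed column order, missing as empty."""
    out = cohort.data.copy()
    for col in ("gcs_motor", "gose"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["age"] = out["age"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    for col in ("pupils", "marshall"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) or v is None else str(v))
    out.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def complete_cases(cohort: Cohort) -> Cohort:
    """Restrict to records with all five model fields present.

    Preserves record order and logs the number removed. Idempotent.
    """
    mask = np.ones(len(cohort), dtype=bool)
    for field_name in MODEL_FIELDS:
        mask &= ~cohort.data[field_name].isna().to_numpy()
    removed = int((~mask).sum())
    if removed:
        logger.info(
            "complete_cases: removed %d of %d records with missing model fields",
            removed,
            len(cohort),
        )
    frame = cohort.data.loc[mask].reset_index(drop=True)
    return Cohort(data=frame, name=cohort.name, profile=cohort.profile)


@dataclass(frozen=True)
class EncodingSpec:
    """Covariate encoding: dummy coding against reference levels.

    ``gcs_categorical`` switches GCS-motor between dummy indicators
    (default) and a single numeric column. ``standardize_age`` centers and
    scales age using ``age_mean``/``age_sd``; when those are ``None`` they
    are computed from the cohort being encoded (the training partition)
    and frozen into the spec attached to the returned design matrix.
    """

    gcs_categorical: bool = True
    standardize_age: bool = False
    age_mean: float | None = None
    age_sd: float | None = None
    references: Mapping[str, object] = field(
        default_factory=lambda: {
            "gcs_motor": 1,
            "pupils": "both",
            "marshall": "diffuse_I",
        }
    )

    @property
    def columns(self) -> list[str]:
        """Design-matrix column names, in fixed order."""
        cols = ["age"]
        if self.gcs_categorical:
            cols += [
                f"gcs_motor_{lvl}"
                for lvl in GCS_MOTOR_LEVELS
                if lvl != self.references["gcs_motor"]
            ]
        else:
            cols += ["gcs_motor"]
        cols += [
            f"pupils_{lvl}" for lvl in PUPILS_LEVELS if lvl != self.references["pupils"]
        ]
        cols += [
            f"marshall_{lvl}"
            for lvl in MARSHALL_LEVELS
            if lvl != self.references["marshall"]
        ]
        return cols

    def to_json(self) -> str:
        payload = {
            "gcs_categorical": self.gcs_categorical,
            "standardize_age": self.standardize_age,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "references": dict(self.references),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EncodingSpec":
        payload = json.loads(text)
        return cls(
            gcs_categorical=payload["gcs_categorical"],
            standardize_age=payload["standardize_age"],
            age_mean=payload["age_mean"],
            age_sd=payload["age_sd"],
            references=payload["references"],
        )


@dataclass
class DesignMatrix:
    """Encoded covariates aligned row-for-row with a cohort."""

    X: np.ndarray
    columns: list[str]
    spec: EncodingSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def __len__(self) -> int:
        return self.X.shape[0]


def encode_design(
    cohort: Cohort,
    spec: EncodingSpec | None = None,
) -> DesignMatrix:
    """Encode a complete-case cohort into a numeric design matrix.

    One row per record. Categorical covariates become 0/1 dummies for every
    non-reference level; age is passed through or standardized per spec.

    Raises
    ------
    EncodingError
        A record carries a level not covered by the spec, or a model
        covariate is missing (cohort not complete-case).
    """
    spec = spec or EncodingSpec()
    frame = cohort.data
    for field_name in ("age", "gcs_motor", "pupils", "marshall"):
        if frame[field_name].isna().any():
            raise EncodingError(
                f"cannot encode: missing {field_name} values; run complete_cases first"
            )
    for field_name, levels in (
        ("gcs_motor", GCS_MOTOR_LEVELS),
        ("pupils", PUPILS_LEVELS),
        ("marshall", MARSHALL_LEVELS),
    ):
        if spec.references[field_name] not in levels:
            raise EncodingError(
                f"reference level {spec.references[field_name]!r} unknown for {field_name}"
            )

    age = frame["age"].to_numpy(dtype=float)
    if spec.standardize_age:
        mean = spec.age_mean
        sd = spec.age_sd
        if mean is None or sd is None:
            mean = float(np.mean(age))
            sd = float(np.std(age, ddof=1)) if len(age) > 1 else 1.0
            spec = replace(spec, age_mean=mean, age_sd=sd)
        if sd == 0:
            raise EncodingError("age standard deviation is zero; cannot standardize")
        age = (age - mean) / sd

    n = len(cohort)
    cols: dict[str, np.ndarray] = {"age": age}
    if spec.gcs_categorical:
        gcs = frame["gcs_motor"].to_numpy(dtype=int)
        for lvl in GCS_MOTOR_LEVELS:
            if lvl != spec.references["gcs_motor"]:
                cols[f"gcs_motor_{lvl}"] = (gcs == lvl).astype(float)
    else:
        cols["gcs_motor"] = frame["gcs_motor"].to_numpy(dtype=float)
    for field_name, levels in (("pupils", PUPILS_LEVELS), ("marshall", MARSHALL_LEVELS)):
        values = frame[field_name].astype(str).to_numpy()
        for lvl in levels:
            if lvl != spec.references[field_name]:
                cols[f"{field_name}_{lvl}"] = (values == lvl).astype(float)

    order = spec.columns
    X = np.column_stack([cols[c] for c in order]) if n else np.empty((0, len(order)))
    return DesignMatrix(X=X.astype(float), columns=order, spec=spec)
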