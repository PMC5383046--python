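"""Demographic and vital-sign features.

ED triage vitals arrive dirty: values can be missing, physiologically
impossible (a heart rate of 811, a pain score of 1000), or alphanumeric
("101.9 rectally").  The cleaning contract is deliberately simple and drops
no rows: parse the leading number, replace anything missing or outside a
predefined physiologic range with a normal value (no imputation indicator),
then min-max scale onto [0,1] over that range.  Acuity (5-level Emergency
Severity Index) is expanded to five indicators to let a linear model capture
its non-linearity; gender is a 0/1 indicator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "VitalSpec",
    "DEFAULT_VITAL_SPECS",
    "parse_numeric",
    "impute",
    "normalize",
    "VitalsVectorizer",
    "build_vitals_vector",
]


@dataclass(frozen=True)
class VitalSpec:
    """Physiologic range and normal value for one continuous field."""

    name: str
    physiologic_min: float
    physiologic_max: float
    normal_value: float

    def __post_init__(self) -> None:
        if not self.physiologic_min < self.physiologic_max:
            raise ValueError(f"{self.name}: physiologic_min must be < physiologic_max")
        if not (self.physiologic_min <= self.normal_value <= self.physiologic_max):
            raise ValueError(f"{self.name}: normal_value outside physiologic range")


# Ranges and normals are configurable; the heart-rate upper bound of 400 and
# normal of 80 are the anchoring clinical facts, the rest are textbook values.
# Age is essentially never missing, so its "normal" (median of range) is a
# defensive fallback only.
DEFAULT_VITAL_SPECS: dict[str, VitalSpec] = {
    s.name: s
    for s in [
        VitalSpec("age", 0.0, 120.0, 60.0),
        VitalSpec("temp", 80.0, 110.0, 98.0),
        VitalSpec("heart_rate", 20.0, 400.0, 80.0),
        VitalSpec("resp_rate", 4.0, 80.0, 16.0),
        VitalSpec("spo2", 50.0, 100.0, 99.0),
        VitalSpec("sbp", 40.0, 300.0, 120.0),
        VitalSpec("dbp", 20.0, 200.0, 70.0),
        VitalSpec("pain", 0.0, 10.0, 0.0),
    ]
}

CONTINUOUS_FIELDS = tuple(DEFAULT_VITAL_SPECS)

_LEADING_NUMBER = re.compile(r"\s*[+-]?(\d+\.?\d*|\.\d+)")


def parse_numeric(raw) -> float:
    """Extract the leading decimal number of a raw field; NaN if none.

    "101.9 rectally" parses to 101.9; empty or non-numeric-leading strings
    (and None/NaN) parse to NaN.  Total function.
    """
    if raw is None:
        return math.nan
    if isinstance(raw, (int, float)):
        return float(raw)
    m = _LEADING_NUMBER.match(str(raw))
    return float(m.group(0)) if m else math.nan


def impute(value: float, spec: VitalSpec) -> float:
    """Replace missing or out-of-physiologic-range values with the normal.

    In-range values pass through unchanged; no indicator is recorded.
    Idempotent.
    """
    if value is None or math.isnan(value):
        return spec.normal_value
    if value < spec.physiologic_min or value > spec.physiologic_max:
        return spec.normal_value
    return float(value)


def normalize(value: float, spec: VitalSpec) -> float:
    """Min-max scale an in-range value onto [0,1] over the physiologic range."""
    if value < spec.physiologic_min or value > spec.physiologic_max:
        raise ValueError(
            f"{spec.name}: value {value} outside physiologic range; impute first"
        )
    return (value - spec.physiologic_min) / (spec.physiologic_max - spec.physiologic_min)


ACUITY_LEVELS = (1, 2, 3, 4, 5)


class VitalsVectorizer(BaseEstimator, TransformerMixin):
    """Transform raw triage records into the normalized vitals block.

    Input is a DataFrame with the triage-record schema (raw string or
    numeric vitals, ``gender``, ``acuity``).  Output is a dense array with
    one [0,1] column per continuous field, a male indicator, and five acuity
    indicators (one-hot).  Stateless beyond its configuration — ``fit`` only
    validates, so train/test processing is identical by construction and no
    record is ever dropped.

    Parameters
    ----------
    specs : mapping field name -> VitalSpec, default physiologic table.
    default_acuity : int
        Level assigned when acuity is missing or unparseable (modal ESI 3).
    male_value : str
        Gender string coded as 1.
    """

    def __init__(self, specs=None, default_acuity: int = 3, male_value: str = "M"):
        self.specs = specs
        self.default_acuity = default_acuity
        self.male_value = male_value

    def _specs(self) -> dict[str, VitalSpec]:
        return dict(self.specs) if self.specs is not None else dict(DEFAULT_VITAL_SPECS)

    def fit(self, X: pd.DataFrame, y=None):
        specs = self._specs()
        missing = [f for f in specs if f not in X.columns]
        if missing:
            raise ValueError(f"records lack vital columns: {missing}")
        self.feature_names_ = (
            list(specs)
            + ["male"]
            + [f"acuity_{k}" for k in ACUITY_LEVELS]
        )
        return self

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        specs = self._specs()
        n = len(X)
        out = np.empty((n, len(specs) + 1 + len(ACUITY_LEVELS)))
        for j, (name, spec) in enumerate(specs.items()):
            col = X[name].map(parse_numeric).to_numpy(dtype=float)
            bad = np.isnan(col) | (col < spec.physiologic_min) | (col > spec.physiologic_max)
            col[bad] = spec.normal_value
            out[:, j] = (col - spec.physiologic_min) / (
                spec.physiologic_max - spec.physiologic_min
            )
        out[:, len(specs)] = (
            X["gender"].astype(str).str.upper() == str(self.male_value).upper()
        ).to_numpy(dtype=float)
        acuity = X["acuity"].map(parse_numeric).to_numpy(dtype=float)
        acuity[~np.isin(acuity, ACUITY_LEVELS)] = self.default_acuity
        base = len(specs) + 1
        for k, level in enumerate(ACUITY_LEVELS):
            out[:, base + k] = (acuity == level).astype(float)
        return out


def build_vitals_vector(record, specs=None) -> np.ndarray:
    """Vitals block for a single record (see :class:`VitalsVectorizer`)."""
    frame = record if isinstance(record, pd.DataFrame) else pd.DataFrame([record])
    vec = VitalsVectorizer(specs=specs).fit(frame).transform(frame)
    return vec[0] if not isinstance(record, pd.DataFrame) else vec
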