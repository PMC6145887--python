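"""Anthropometrics: growth indexes, LMS z-scores and conditional weight gain.

The growth index for a child under two is weight (kg) divided by recumbent
length (cm).  Weight- and length-for-age z-scores (WAZ, LAZ) are computed
against a sex- and age-specific LMS reference, and the conditional weight
gain (CWG) z-score is the standardized residual of a cohort-level regression
of six-month WAZ on birth WAZ with length and precise age covariates.  A CWG
z-score >= 0 defines rapid infant weight gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    InvalidArgumentError,
    OutOfRangeError,
    SingularDesignError,
)

SEXES = ("male", "female")
MEASURES = ("weight", "length")


@dataclass(frozen=True)
class Visit:
    age_days: int
    weight_kg: float
    length_cm: float


@dataclass
class AnthroRecord:
    """One child's sparse series of (age, weight, length) measurements."""

    child_id: str
    sex: str
    visits: list[Visit]

    def __post_init__(self):
        if self.sex not in SEXES:
            raise InvalidArgumentError(f"sex must be one of {SEXES}, got {self.sex!r}")
        ages = [v.age_days for v in self.visits]
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise InvalidArgumentError(
                f"visit ages must be strictly increasing for child {self.child_id}"
            )
        for v in self.visits:
            if v.weight_kg <= 0 or v.length_cm <= 0:
                raise InvalidArgumentError(
                    f"weight and length must be positive (child {self.child_id}, "
                    f"age {v.age_days})"
                )

    @property
    def ages(self) -> np.ndarray:
        return np.array([v.age_days for v in self.visits], dtype=float)


class GrowthReference:
    """Sex- and age-specific LMS (skewness/median/variation) triplets.

    Holds one LMS table per (sex, measure) with ``measure`` in
    ``{"weight", "length"}``; parameters are linearly interpolated in age.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "measure", "age_days", "L", "M", "S"}
        if not required.issubset(frame.columns):
            raise InvalidArgumentError(f"reference needs columns {sorted(required)}")
        if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
            raise InvalidArgumentError("reference requires M > 0 and S > 0")
        self.frame = frame.sort_values(["sex", "measure", "age_days"]).reset_index(drop=True)
        self._tables = {
            key: grp[["age_days", "L", "M", "S"]].to_numpy(dtype=float)
            for key, grp in self.frame.groupby(["sex", "measure"], sort=True)
        }

    @classmethod
    def read(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def age_range(self, sex: str, measure: str) -> tuple[float, float]:
        tab = self._table(sex, measure)
        return float(tab[0, 0]), float(tab[-1, 0])

    def _table(self, sex: str, measure: str) -> np.ndarray:
        try:
            return self._tables[(sex, measure)]
        except KeyError:
            raise InvalidArgumentError(
                f"reference has no table for sex={sex!r}, measure={measure!r}"
            ) from None

    def lms(self, sex: str, measure: str, age_days: float,
            interpolate: bool = True) -> tuple[float, float, float]:
        tab = self._table(sex, measure)
        ages = tab[:, 0]
        if age_days < ages[0] or age_days > ages[-1]:
            raise OutOfRangeError(
                f"age {age_days} outside reference range [{ages[0]}, {ages[-1]}]"
            )
        if interpolate:
            L = float(np.interp(age_days, ages, tab[:, 1]))
            M = float(np.interp(age_days, ages, tab[:, 2]))
            S = float(np.interp(age_days, ages, tab[:, 3]))
        else:
            i = int(np.argmin(np.abs(ages - age_days)))
            L, M, S = (float(v) for v in tab[i, 1:4])
        return L, M, S


def growth_index(record: AnthroRecord) -> pd.DataFrame:
    """Weight-for-length growth index at each visit (kg/cm)."""
    if not record.visits:
        raise InvalidArgumentError(f"child {record.child_id} has no visits")
    return pd.DataFrame(
        {
            "age_days": [v.age_days for v in record.visits],
            "index": [v.weight_kg / v.length_cm for v in record.visits],
        }
    )


def lms_zscore(value: float, age_days: float, sex: str, reference: GrowthReference,
               measure: str = "weight", interpolate: bool = True) -> float:
    """LMS z-score: ``((value/M)^L - 1) / (L*S)``, log form in the L -> 0 limit."""
    if value <= 0:
        raise InvalidArgumentError("measurement value must be positive")
    L, M, S = reference.lms(sex, measure, age_days, interpolate=interpolate)
    ratio = value / M
    if abs(L) < 1e-12:
        return float(np.log(ratio) / S)
    return float((ratio ** L - 1.0) / (L * S))


@dataclass
class CWGResult:
    """Per-child conditional weight gain z-scores and rapid-gain flags."""

    table: pd.DataFrame  # columns: child_id, cwg_z, rapid
    design_columns: tuple[str, ...]
    coefficients: pd.Series = field(repr=False, default=None)

    @property
    def cwg_z(self) -> pd.Series:
        return self.table.set_index("child_id")["cwg_z"]

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def cwg_zscores(waz_birth, waz_6m, laz_birth, laz_6m, age_at_6m,
                child_ids=None, laz_occasions: str = "both") -> CWGResult:
    """Conditional weight gain z-scores for a cohort.

    Fits one OLS regression of six-month WAZ on birth WAZ, LAZ and the precise
    age at the six-month visit, then standardizes the residuals to mean 0 and
    standard deviation 1 (sample sd, n-1 denominator).  ``laz_occasions``
    selects which LAZ measurement(s) enter the design ("both", "birth" or
    "six_month"); both occasions are used by default.
    """
    waz0 = np.asarray(waz_birth, dtype=float)
    waz6 = np.asarray(waz_6m, dtype=float)
    laz0 = np.asarray(laz_birth, dtype=float)
    laz6 = np.asarray(laz_6m, dtype=float)
    age6 = np.asarray(age_at_6m, dtype=float)
    n = waz0.size
    if not (waz6.size == laz0.size == laz6.size == age6.size == n):
        raise InvalidArgumentError("cohort vectors must share one length")
    if child_ids is None:
        child_ids = [f"c{i:04d}" for i in range(n)]

    cols = {"intercept": np.ones(n), "waz_birth": waz0}
    if laz_occasions in ("both", "birth"):
        cols["laz_birth"] = laz0
    if laz_occasions in ("both", "six_month"):
        cols["laz_6m"] = laz6
    if laz_occasions not in ("both", "birth", "six_month"):
        raise InvalidArgumentError(f"unknown laz_occasions {laz_occasions!r}")
    cols["age_6m"] = age6
    design = pd.DataFrame(cols)
    if n < design.shape[1] + 1:
        raise InvalidArgumentError(
            f"need at least {design.shape[1] + 1} complete children, got {n}"
        )
    if not np.all(np.isfinite(design.to_numpy())) or not np.all(np.isfinite(waz6)):
        raise InvalidArgumentError("non-finite values in CWG inputs")

    Xm = design.to_numpy()
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify collinear columns via pivoted QR diagonal
        _, R, piv = _qr_pivoted(Xm)
        diag = np.abs(np.diag(R))
        bad = [design.columns[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-10 * diag.max()]
        bad += [design.columns[p] for p in piv[len(diag):]]
        raise SingularDesignError(
            f"CWG design is rank deficient (rank {rank} < {Xm.shape[1]})",
            columns=bad,
        )
    beta, *_ = np.linalg.lstsq(Xm, waz6, rcond=None)
    resid = waz6 - Xm @ beta
    sd = float(np.std(resid, ddof=1))
    if sd < 1e-12:
        raise DegenerateFitError(
            "residual standard deviation is zero: WAZ at six months is an exact "
            "linear function of the covariates"
        )
    z = resid / sd
    table = pd.DataFrame({"child_id": child_ids, "cwg_z": z, "rapid": z >= 0})
    return CWGResult(table=table, design_columns=tuple(design.columns),
                     coefficients=pd.Series(beta, index=design.columns))


def _qr_pivoted(X):
    import scipy.linalg as sla

    Q, R, piv = sla.qr(X, pivoting=True, mode="economic")
    return Q, R, piv


def classify_rapid(result: CWGResult) -> tuple[list[str], list[str]]:
    """Partition children into (rapid, non-rapid) by CWG z-score >= 0."""
    t = result.table
    rapid = t.loc[t["cwg_z"] >= 0, "child_id"].tolist()
    non_rapid = t.loc[t["cwg_z"] < 0, "child_id"].tolist()
    return rapid, non_rapid


def records_to_frame(records: list[AnthroRecord]) -> pd.DataFrame:
    """Long-format anthropometry table (child_id, sex, age_days, weight_kg, length_cm)."""
    rows = [
        (r.child_id, r.sex, v.age_days, v.weight_kg, v.length_cm)
        for r in records
        for v in r.visits
    ]
    return pd.DataFrame(rows, columns=["child_id", "sex", "age_days", "weight_kg", "length_cm"])


def frame_to_records(frame: pd.DataFrame) -> list[AnthroRecord]:
    records = []
    for child_id, grp in frame.groupby("child_id", sort=True):
        grp = grp.sort_values("age_days")
        sex = grp["sex"].iloc[0]
        visits = [
            Visit(int(a), float(w), float(l))
            for a, w, l in zip(grp["age_days"], grp["weight_kg"], grp["length_cm"])
        ]
        records.append(AnthroRecord(str(child_id), sex, visits))
    return records


def read_anthropometry(path) -> list[AnthroRecord]:
    return frame_to_records(pd.read_csv(path))


def write_anthropometry(records: list[AnthroRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def cohort_zscores(records: list[AnthroRecord], reference: GrowthReference,
                   birth_age: float = 0.0, six_month_age: float = 182.0,
                   tolerance: float = 60.0) -> pd.DataFrame:
    """WAZ/LAZ at birth and at the visit nearest six months, per child.

    Children lacking a visit within ``tolerance`` days of ``six_month_age``
    (or a birth visit) are excluded.
    """
    rows = []
    for rec in records:
        ages = rec.ages
        if ages.size == 0 or ages[0] != birth_age:
            continue
        i6 = int(np.argmin(np.abs(ages - six_month_age)))
        if abs(ages[i6] - six_month_age) > tolerance or i6 == 0:
            continue
        v0, v6 = rec.visits[0], rec.visits[i6]
        rows.append(
            {
                "child_id": rec.child_id,
                "waz_birth": lms_zscore(v0.weight_kg, v0.age_days, rec.sex, reference, "weight"),
                "laz_birth": lms_zscore(v0.length_cm, v0.age_days, rec.sex, reference, "length"),
                "waz_6m": lms_zscore(v6.weight_kg, v6.age_days, rec.sex, reference, "weight"),
                "laz_6m": lms_zscore(v6.length_cm, v6.age_days, rec.sex, reference, "length"),
                "age_6m": float(v6.age_days),
            }
        )
    return pd.DataFrame(rows)
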