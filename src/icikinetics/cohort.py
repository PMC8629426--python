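"""Longitudinal lesion and burden data: containers, CSV readers/writers,
lesion-volume estimation, and per-patient burden normalization.

Two CSV dialects are supported (header row mandatory, UTF-8, decimal point):

* lesion-level: ``patient_id, scan_time_days, lesion_id, long_axis_mm,
  short_axis_mm`` -- one row per indexed lesion per scan. Lesion volumes are
  estimated as spheres on the geometric mean of the long and short axes, then
  summed per scan over the patient's fixed indexed-lesion set.
* burden-level: ``patient_id, time_days, burden_norm`` -- normalized burden
  rho'(t) directly, one row per scan.

Times are real-valued days relative to the first checkpoint-inhibitor dose;
negative times denote pretreatment scans. Cohort-level metadata (cohort name,
per-patient histology) lives in a YAML sidecar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import diameter_to_volume

__all__ = [
    "LESION_COLUMNS",
    "BURDEN_COLUMNS",
    "LesionMeasurement",
    "PatientSeries",
    "Cohort",
    "MissingBaselineError",
    "InconsistentLesionSetError",
    "lesion_volume",
    "aggregate_burden",
    "normalize_series",
    "read_lesion_table",
    "write_lesion_table",
    "load_lesion_cohort",
    "load_burden_cohort",
    "write_burden_cohort",
    "read_cohort_metadata",
    "write_cohort_metadata",
]

LESION_COLUMNS = ["patient_id", "scan_time_days", "lesion_id", "long_axis_mm", "short_axis_mm"]
BURDEN_COLUMNS = ["patient_id", "time_days", "burden_norm"]


class MissingBaselineError(ValueError):
    """No usable scan at t = 0; the patient cannot be normalized."""


class InconsistentLesionSetError(ValueError):
    """A patient's indexed-lesion set differs between scans."""


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion's long/short axes (mm) at one scan."""

    patient_id: str
    scan_time: float  # days from first dose; negative = pretreatment
    lesion_id: str
    long_axis: float
    short_axis: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.scan_time):
            raise ValueError("scan_time must be finite")
        if self.short_axis < 0 or self.long_axis < self.short_axis:
            raise ValueError(
                f"need long_axis >= short_axis >= 0, got "
                f"({self.long_axis}, {self.short_axis})"
            )

    @property
    def volume(self) -> float:
        return lesion_volume(self.long_axis, self.short_axis)


def lesion_volume(long_axis: float, short_axis: float) -> float:
    """Sphere volume (mm^3) on the geometric-mean diameter of the two axes."""
    if long_axis < 0 or short_axis < 0:
        raise ValueError("axes must be >= 0")
    return diameter_to_volume(math.sqrt(long_axis * short_axis))


@dataclass(frozen=True)
class PatientSeries:
    """One patient's normalized burden time series.

    ``times`` are on-treatment days (strictly increasing, first element 0 with
    burden exactly 1); an optional pretreatment point (t < 0, normalized by the
    same baseline volume) is kept separately.
    """

    patient_id: str
    times: np.ndarray
    burdens: np.ndarray
    pretreatment: tuple[float, float] | None = None
    histology: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        burdens = np.asarray(self.burdens, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "burdens", burdens)
        if times.shape != burdens.shape or times.ndim != 1 or times.size == 0:
            raise ValueError("times and burdens must be matching 1-D arrays")
        if times[0] != 0.0 or burdens[0] != 1.0:
            raise ValueError("series must start at (t=0, burden=1)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(burdens < 0) or not np.all(np.isfinite(burdens)):
            raise ValueError("burdens must be finite and >= 0")
        if self.pretreatment is not None:
            t_pre, b_pre = self.pretreatment
            if t_pre >= 0:
                raise ValueError("pretreatment time must be < 0")
            if b_pre < 0:
                raise ValueError("pretreatment burden must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def n_post_baseline(self) -> int:
        return int(np.sum(self.times > 0))

    @property
    def last_burden(self) -> float:
        return float(self.burdens[-1])

    @property
    def span_days(self) -> float:
        return float(self.times[-1])

    def replace_observations(self, times: np.ndarray, burdens: np.ndarray) -> "PatientSeries":
        return PatientSeries(
            patient_id=self.patient_id,
            times=times,
            burdens=burdens,
            pretreatment=self.pretreatment,
            histology=self.histology,
            cohort=self.cohort,
        )


@dataclass
class Cohort:
    """A named collection of :class:`PatientSeries` with unique patient ids."""

    patients: list[PatientSeries] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientSeries]:
        return iter(self.patients)

    def __getitem__(self, patient_id: str) -> PatientSeries:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]


def aggregate_burden(
    measurements: Iterable[LesionMeasurement] | pd.DataFrame,
) -> pd.Series:
    """Sum lesion volumes per scan time for one patient.

    Every indexed lesion must be measured at every scan (the indexed set is
    fixed over follow-up); violations raise
    :class:`InconsistentLesionSetError`. Returns total volume (mm^3) indexed
    by scan time, sorted ascending.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.rename(
            columns={"scan_time_days": "scan_time", "long_axis_mm": "long_axis",
                     "short_axis_mm": "short_axis"}
        )
        rows = [
            LesionMeasurement(str(r.patient_id), float(r.scan_time), str(r.lesion_id),
                              float(r.long_axis), float(r.short_axis))
            for r in df.itertuples(index=False)
        ]
    else:
        rows = list(measurements)
    if not rows:
        raise ValueError("no lesion measurements given")
    pids = {r.patient_id for r in rows}
    if len(pids) > 1:
        raise ValueError(f"aggregate_burden expects one patient, got {sorted(pids)}")

    by_scan: dict[float, dict[str, float]] = {}
    for r in rows:
        scan = by_scan.setdefault(r.scan_time, {})
        if r.lesion_id in scan:
            raise ValueError(
                f"lesion {r.lesion_id!r} measured twice at t={r.scan_time}"
            )
        scan[r.lesion_id] = r.volume
    lesion_sets = {frozenset(v) for v in by_scan.values()}
    if len(lesion_sets) > 1:
        raise InconsistentLesionSetError(
            f"indexed-lesion set varies across scans for patient {rows[0].patient_id!r}"
        )
    totals = {t: sum(v.values()) for t, v in by_scan.items()}
    out = pd.Series(totals, name="total_volume_mm3").sort_index()
    out.index.name = "scan_time_days"
    return out


def normalize_series(
    volumes: pd.Series | Mapping[float, float],
    patient_id: str,
    histology: str = "",
    cohort: str = "",
) -> PatientSeries:
    """Normalize raw per-scan volumes to burden rho' (volume at t=0 is 1).

    ``volumes`` maps scan time (days) to total volume. Exactly one
    pretreatment scan (the one immediately preceding t = 0) is kept; earlier
    pretreatment scans are ignored with a warning. A missing or zero baseline
    raises :class:`MissingBaselineError` (such patients are excluded, as in
    cohorts lacking pretreatment/baseline measurements).
    """
    s = pd.Series(dict(volumes) if not isinstance(volumes, pd.Series) else volumes)
    s = s.astype(float).sort_index()
    times = s.index.to_numpy(dtype=float)
    if 0.0 not in times:
        raise MissingBaselineError(f"patient {patient_id!r}: no scan at t = 0")
    v0 = float(s.loc[0.0])
    if not (v0 > 0):
        raise MissingBaselineError(f"patient {patient_id!r}: baseline volume is {v0}")

    neg = times[times < 0]
    pretreatment = None
    if neg.size:
        t_pre = float(neg.max())
        if neg.size > 1:
            warnings.warn(
                f"patient {patient_id!r}: ignoring {neg.size - 1} scan(s) before "
                f"the pretreatment scan at t={t_pre:g}",
                stacklevel=2,
            )
        pretreatment = (t_pre, float(s.loc[t_pre]) / v0)

    on = s.loc[s.index >= 0]
    return PatientSeries(
        patient_id=patient_id,
        times=on.index.to_numpy(dtype=float),
        burdens=on.to_numpy(dtype=float) / v0,
        pretreatment=pretreatment,
        histology=histology,
        cohort=cohort,
    )


# ---------------------------------------------------------------------------
# CSV / YAML input-output
# ---------------------------------------------------------------------------

def read_lesion_table(path: str | Path) -> pd.DataFrame:
    """Read a lesion-level CSV; a missing short axis falls back to the long
    axis (uniaxial report) with a warning."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LESION_COLUMNS if c not in df.columns and c != "short_axis_mm"]
    if missing:
        raise ValueError(f"lesion CSV missing columns: {missing}")
    if "short_axis_mm" not in df.columns:
        df["short_axis_mm"] = np.nan
    n_missing = int(df["short_axis_mm"].isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} lesion row(s) without short axis; using short = long",
            stacklevel=2,
        )
        df["short_axis_mm"] = df["short_axis_mm"].fillna(df["long_axis_mm"])
    df["patient_id"] = df["patient_id"].astype(str)
    df["lesion_id"] = df["lesion_id"].astype(str)
    return df[LESION_COLUMNS]


# %.17g keeps full float64 precision so written cohorts round-trip exactly
_FLOAT_FMT = "%.17g"


def write_lesion_table(df: pd.DataFrame, path: str | Path) -> None:
    df[LESION_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort_metadata(path: str | Path) -> dict:
    """YAML sidecar: ``{name: <cohort name>, histology: {patient_id: label}}``."""
    with open(path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}
    meta.setdefault("name", "")
    meta.setdefault("histology", {})
    return meta


def write_cohort_metadata(cohort: Cohort, path: str | Path) -> None:
    meta = {
        "name": cohort.name,
        "histology": {p.patient_id: p.histology for p in cohort if p.histology},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def _apply_metadata(metadata: str | Path | Mapping | None) -> dict:
    if metadata is None:
        return {"name": "", "histology": {}}
    if isinstance(metadata, (str, Path)):
        return read_cohort_metadata(metadata)
    meta = dict(metadata)
    meta.setdefault("name", "")
    meta.setdefault("histology", {})
    return meta


def load_lesion_cohort(
    path: str | Path,
    metadata: str | Path | Mapping | None = None,
) -> Cohort:
    """Build a normalized :class:`Cohort` from a lesion-level CSV."""
    df = read_lesion_table(path)
    meta = _apply_metadata(metadata)
    patients = []
    for pid, grp in df.groupby("patient_id", sort=True):
        totals = aggregate_burden(grp)
        patients.append(
            normalize_series(
                totals, str(pid),
                histology=str(meta["histology"].get(str(pid), "")),
                cohort=str(meta["name"]),
            )
        )
    return Cohort(patients=patients, name=str(meta["name"]))


def load_burden_cohort(
    path: str | Path,
    metadata: str | Path | Mapping | None = None,
) -> Cohort:
    """Build a :class:`Cohort` from a burden-level CSV.

    Rows with negative time are pretreatment scans. If the baseline burden is
    not exactly 1 the whole series is renormalized by it, with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BURDEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"burden CSV missing columns: {missing}")
    meta = _apply_metadata(metadata)
    patients = []
    for pid, grp in df.groupby(df["patient_id"].astype(str), sort=True):
        s = pd.Series(
            grp["burden_norm"].to_numpy(dtype=float),
            index=grp["time_days"].to_numpy(dtype=float),
        ).sort_index()
        if 0.0 not in s.index:
            raise MissingBaselineError(f"patient {pid!r}: no scan at t = 0")
        b0 = float(s.loc[0.0])
        if not (b0 > 0):
            raise MissingBaselineError(f"patient {pid!r}: baseline burden is {b0}")
        if b0 != 1.0:
            warnings.warn(
                f"patient {pid!r}: baseline burden {b0:g} != 1; renormalizing",
                stacklevel=2,
            )
        patients.append(
            normalize_series(
                s, str(pid),
                histology=str(meta["histology"].get(str(pid), "")),
                cohort=str(meta["name"]),
            )
        )
    return Cohort(patients=patients, name=str(meta["name"]))


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Burden-level table (one row per scan, pretreatment rows included)."""
    rows = []
    for p in cohort:
        if p.pretreatment is not None:
            rows.append((p.patient_id, p.pretreatment[0], p.pretreatment[1]))
        rows.extend(zip([p.patient_id] * p.n_points, p.times, p.burdens))
    return pd.DataFrame(rows, columns=BURDEN_COLUMNS)


def write_burden_cohort(
    cohort: Cohort,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the burden-level CSV (and optionally the YAML sidecar).

    Floats are written at full round-trip precision.
    """
    cohort_to_frame(cohort).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if metadata_path is not None:
        write_cohort_metadata(cohort, metadata_path)
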