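"""Reading, writing and validation of longitudinal PK datasets.

The on-disk layout is the rectangular, NONMEM-style CSV convention:
one row per event, with columns ID, TIME, AMT, EVID, DV followed by
covariate columns.  Dose rows are identified by EVID == 1 when an EVID
column exists, otherwise by a nonzero AMT (the event column wins when
both are present).  Times are absolute hours; covariates must be
constant within a subject.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DoseRecord",
    "ObservationRecord",
    "PKDataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "DEFAULT_COLUMNS",
]

DEFAULT_COLUMNS = {"id": "ID", "time": "TIME", "amt": "AMT", "evid": "EVID", "dv": "DV"}

#: sentinels accepted for a missing concentration value
_MISSING_SENTINELS = {"", ".", "NA", "nan"}


class DatasetError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class DoseRecord:
    """A single dosing event. ``duration == 0`` denotes an IV bolus."""

    subject_id: str
    time: float
    amount: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise DatasetError(f"dose amount must be > 0 (got {self.amount})")
        if self.duration < 0 or self.time < 0:
            raise DatasetError("dose time and duration must be >= 0")


@dataclass(frozen=True)
class ObservationRecord:
    """A timed concentration measurement (``missing_flag`` marks BQL/absent DV)."""

    subject_id: str
    time: float
    dv: float
    missing_flag: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetError("observation time must be >= 0")
        if not self.missing_flag and self.dv < 0:
            raise DatasetError(f"negative concentration {self.dv} without missing flag")


@dataclass
class PKDataset:
    """A validated longitudinal dosing/concentration dataset.

    Records are kept sorted by (subject, time); covariates are
    subject-constant maps ``subject_id -> {name: value}``.
    """

    subjects: list[str]
    doses: list[DoseRecord]
    observations: list[ObservationRecord]
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    covariate_kinds: dict[str, str] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        """Number of non-missing observations (the *n* of AIC/BIC/MPE/RMSE)."""
        return sum(not o.missing_flag for o in self.observations)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_kinds)

    def validate(self) -> "PKDataset":
        """Check every structural invariant; raise :class:`DatasetError` otherwise."""
        order = {s: i for i, s in enumerate(self.subjects)}
        for rec in list(self.doses) + list(self.observations):
            if rec.subject_id not in order:
                raise DatasetError(f"record for unknown subject {rec.subject_id!r}")
        for seq, label in ((self.doses, "doses"), (self.observations, "observations")):
            keys = [(order[r.subject_id], r.time) for r in seq]
            if keys != sorted(keys):
                raise DatasetError(f"{label} not sorted by (subject, time)")
        first_dose = {}
        for d in self.doses:
            first_dose.setdefault(d.subject_id, d.time)
        for o in self.observations:
            t0 = first_dose.get(o.subject_id)
            if t0 is None or t0 > o.time:
                raise DatasetError(
                    f"subject {o.subject_id!r} has an observation at t={o.time} "
                    "before any dose"
                )
        for name in self.covariate_kinds:
            for s in self.subjects:
                val = self.covariates.get(s, {}).get(name)
                if val is None or pd.isna(val):
                    raise DatasetError(f"covariate {name!r} missing for subject {s!r}")
        return self

    def covariate_frame(self) -> pd.DataFrame:
        """Per-subject covariate table (rows in subject order)."""
        return pd.DataFrame(
            {name: [self.covariates[s][name] for s in self.subjects]
             for name in self.covariate_kinds},
            index=pd.Index(self.subjects, name="ID"),
        )

    def covariate_median(self, name: str) -> float:
        """Median over subjects (not observations) — the default reference value."""
        return float(self.covariate_frame()[name].median())


def _infer_kind(series: pd.Series) -> str:
    vals = set(series.unique())
    if len(vals) <= 4 and all(float(v).is_integer() for v in vals):
        return "discrete"
    return "continuous"


def read_dataset(source, column_map: dict[str, str] | None = None) -> PKDataset:
    """Read a NONMEM-style CSV into a validated :class:`PKDataset`.

    Parameters
    ----------
    source : file-like or path
        Comma-separated text with a header row.
    column_map : dict, optional
        Overrides for the reserved column names, keys among
        ``{"id", "time", "amt", "evid", "dv"}``.  Any column that is not
        reserved is treated as a covariate.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(source, dtype={cols["id"]: str}, float_precision="round_trip",
                     keep_default_na=False, na_values=list(_MISSING_SENTINELS))
    for key in ("id", "time", "dv"):
        if cols[key] not in df.columns:
            raise DatasetError(f"required column {cols[key]!r} not found")
    has_evid = cols["evid"] in df.columns
    has_amt = cols["amt"] in df.columns
    if not (has_evid or has_amt):
        raise DatasetError("need an EVID or AMT column to identify dose rows")

    reserved = {cols[k] for k in cols}
    cov_names = [c for c in df.columns if c not in reserved]
    dur_col = "DUR" if "DUR" in df.columns else None
    if dur_col:
        cov_names.remove(dur_col)

    subjects = list(dict.fromkeys(df[cols["id"]]))
    doses: list[DoseRecord] = []
    observations: list[ObservationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rd = dict(zip(df.columns, row))
        sid = rd[cols["id"]]
        t = float(rd[cols["time"]])
        if t < 0:
            raise DatasetError(f"row {i}: negative time {t}")
        if has_evid and not pd.isna(rd[cols["evid"]]):
            is_dose = int(rd[cols["evid"]]) == 1
        else:
            amt = rd.get(cols["amt"], 0)
            is_dose = (not pd.isna(amt)) and float(amt) != 0
        if is_dose:
            doses.append(DoseRecord(
                subject_id=sid, time=t, amount=float(rd[cols["amt"]]),
                duration=float(rd[dur_col]) if dur_col and not pd.isna(rd[dur_col]) else 0.0,
            ))
        else:
            dv = rd[cols["dv"]]
            missing = pd.isna(dv) or (isinstance(dv, str) and dv.strip() in _MISSING_SENTINELS)
            observations.append(ObservationRecord(
                subject_id=sid, time=t,
                dv=0.0 if missing else float(dv), missing_flag=bool(missing),
            ))

    covariates: dict[str, dict[str, float]] = {s: {} for s in subjects}
    kinds: dict[str, str] = {}
    for name in cov_names:
        per_subj = df.groupby(cols["id"], sort=False)[name]
        if (per_subj.nunique(dropna=False) > 1).any():
            bad = per_subj.nunique(dropna=False).idxmax()
            raise DatasetError(
                f"covariate {name!r} varies within subject {bad!r} "
                "(time-varying covariates are not supported)"
            )
        firsts = per_subj.first()
        kinds[name] = _infer_kind(firsts.astype(float))
        for s in subjects:
            covariates[s][name] = float(firsts[s])

    order = {s: i for i, s in enumerate(subjects)}
    doses.sort(key=lambda d: (order[d.subject_id], d.time))
    observations.sort(key=lambda o: (order[o.subject_id], o.time))
    ds = PKDataset(subjects=subjects, doses=doses, observations=observations,
                   covariates=covariates, covariate_kinds=kinds)
    return ds.validate()


def write_dataset(ds: PKDataset, sink) -> None:
    """Write ``ds`` as NONMEM-style CSV; ``read_dataset`` round-trips it exactly."""
    cov_names = ds.covariate_names
    rows = []
    for s in ds.subjects:
        events = [("dose", d) for d in ds.doses if d.subject_id == s]
        events += [("obs", o) for o in ds.observations if o.subject_id == s]
        # doses sort before observations at equal times so re-reading validates
        events.sort(key=lambda e: (e[1].time, 0 if e[0] == "dose" else 1))
        for kind, rec in events:
            row = {"ID": s, "TIME": rec.time}
            if kind == "dose":
                row.update(AMT=rec.amount, EVID=1, DV=".", DUR=rec.duration)
            else:
                row.update(AMT=0.0, EVID=0,
                           DV="." if rec.missing_flag else repr(rec.dv), DUR=0.0)
            for c in cov_names:
                row[c] = ds.covariates[s][c]
            rows.append(row)
    header = ["ID", "TIME", "AMT", "EVID", "DV", "DUR"] + cov_names
    frame = pd.DataFrame(rows, columns=header)
    frame.to_csv(sink, index=False)


def dataset_to_string(ds: PKDataset) -> str:
    buf = io.StringIO()
    write_dataset(ds, buf)
    return buf.getvalue()
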