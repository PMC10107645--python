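"""Partly-interval-censored survival data with time-varying covariates.

Each subject carries a censoring interval [yL, yR] that is one of

* an exact event time     (yL == yR, finite),
* a right-censoring time  (yR == inf),
* a left-censoring time   (yL == 0),
* an interval censoring   (0 < yL < yR < inf),

together with p time-fixed covariates x and q time-varying covariates z(t)
that are piecewise constant between subject-specific change times
0 = t_0 < t_1 < ... ; on [t_a, t_{a+1}) the covariate vector equals row a
of ``z_values`` (left-closed, right-open convention).  Beyond the last
change time the last value is carried forward.

The on-disk dialect is a comma-separated long format with one row per
covariate-constancy interval: columns ``id, tstart, tstop, yL, yR,
censor_type, x1..xp, z1..zq``.  Infinite right endpoints are written as
``Inf`` (an empty field is also accepted on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CENSOR_TYPES = ("event", "right", "left", "interval")


class FormatError(ValueError):
    """Malformed long-format input (gaps, overlaps, bad censor codes)."""


@dataclass
class SubjectRecord:
    """One subject's censoring interval, covariates and z trajectory."""

    yL: float
    yR: float
    censor_type: str
    x: np.ndarray            # (p,)
    change_times: np.ndarray  # (ni,) starts of constancy intervals, t0 = 0
    z_values: np.ndarray      # (ni, q) row a holds z on [t_a, t_{a+1})
    subject_id: object = None

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.change_times = np.atleast_1d(
            np.asarray(self.change_times, dtype=float))
        self.z_values = np.asarray(self.z_values, dtype=float)
        if self.z_values.ndim == 1:
            self.z_values = self.z_values[:, None]
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self):
        if self.censor_type not in CENSOR_TYPES:
            raise FormatError(f"unknown censor_type {self.censor_type!r}")
        yL, yR = self.yL, self.yR
        if self.censor_type == "event":
            if not (np.isfinite(yL) and yL == yR and yL > 0):
                raise FormatError("event requires 0 < yL == yR < inf")
        elif self.censor_type == "right":
            if not (np.isfinite(yL) and yL > 0 and np.isinf(yR)):
                raise FormatError("right censoring requires finite yL, yR=inf")
        elif self.censor_type == "left":
            if not (yL == 0 and np.isfinite(yR) and yR > 0):
                raise FormatError("left censoring requires yL=0, finite yR")
        else:
            if not (0 < yL < yR < np.inf):
                raise FormatError("interval censoring requires 0 < yL < yR < inf")
        ct = self.change_times
        if ct[0] != 0.0:
            raise FormatError("first change time must be 0")
        if np.any(np.diff(ct) <= 0):
            raise FormatError("change times must be strictly increasing")
        if self.z_values.shape[0] != ct.size:
            raise FormatError("z_values rows must match change_times")

    # -- derived quantities ----------------------------------------------

    @property
    def p(self) -> int:
        return self.x.size

    @property
    def q(self) -> int:
        return self.z_values.shape[1]

    @property
    def ni(self) -> int:
        return self.change_times.size

    @property
    def y(self) -> float:
        """Largest finite endpoint of [yL, yR] (the follow-up horizon)."""
        return self.yL if np.isinf(self.yR) else self.yR

    def covariate_at(self, t: float) -> np.ndarray:
        """z(t): value of the half-open interval containing t.

        Right-continuous piecewise constant; last value carried forward
        beyond the final change time.
        """
        a = int(np.searchsorted(self.change_times, t, side="right")) - 1
        a = max(0, min(a, self.ni - 1))
        return self.z_values[a]


def covariate_at(subject: SubjectRecord, t: float) -> np.ndarray:
    return subject.covariate_at(t)


@dataclass
class SurvDataset:
    """A list of subjects sharing covariate dimensions p and q."""

    subjects: list = field(default_factory=list)

    def __post_init__(self):
        if self.subjects:
            p, q = self.subjects[0].p, self.subjects[0].q
            for s in self.subjects:
                if s.p != p or s.q != q:
                    raise FormatError("subjects disagree on p or q")

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return self.subjects[0].p

    @property
    def q(self) -> int:
        return self.subjects[0].q

    @property
    def N(self) -> int:
        """Total long-format row count, sum of ni over subjects."""
        return sum(s.ni for s in self.subjects)

    @property
    def n0(self) -> int:
        """Non-right-censored subject count (drives basis dimension)."""
        return sum(1 for s in self.subjects if s.censor_type != "right")

    def censor_counts(self) -> dict:
        out = {c: 0 for c in CENSOR_TYPES}
        for s in self.subjects:
            out[s.censor_type] += 1
        return out

    def observed_times(self) -> np.ndarray:
        """All finite positive interval endpoints (basis support data)."""
        ts = []
        for s in self.subjects:
            for v in (s.yL, s.yR):
                if np.isfinite(v) and v > 0:
                    ts.append(v)
        return np.asarray(ts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.subjects):
            sid = s.subject_id if s.subject_id is not None else i
            stops = np.append(s.change_times[1:], s.y)
            for a in range(s.ni):
                row = {
                    "id": sid,
                    "tstart": s.change_times[a],
                    "tstop": stops[a],
                    "yL": s.yL,
                    "yR": s.yR,
                    "censor_type": s.censor_type,
                }
                for j in range(s.p):
                    row[f"x{j + 1}"] = s.x[j]
                for b in range(s.q):
                    row[f"z{b + 1}"] = s.z_values[a, b]
                rows.append(row)
        return pd.DataFrame(rows)


def write_long_format(dataset: SurvDataset, path, header_comment: str | None = None):
    """Write the CSV long-format dialect (``Inf`` for infinite yR)."""
    df = dataset.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, na_rep="Inf")


def read_long_format(path) -> SurvDataset:
    """Read the CSV long format, validating the per-subject invariants."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"id", "tstart", "tstop", "yL", "yR", "censor_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    xcols = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    zcols = sorted((c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    subjects = []
    for sid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("tstart")
        tstart = grp["tstart"].to_numpy(dtype=float)
        tstop = grp["tstop"].to_numpy(dtype=float)
        if not np.allclose(tstart[1:], tstop[:-1], atol=1e-12):
            bad = int(grp.index[np.argmax(~np.isclose(tstart[1:], tstop[:-1]))] + 1)
            raise FormatError(
                f"subject {sid!r}: gapped or overlapping intervals near row {bad}")
        yR_raw = grp["yR"].iloc[0]
        yR = np.inf if (pd.isna(yR_raw) or str(yR_raw).strip().lower()
                        in ("inf", "+inf", "infinity")) else float(yR_raw)
        yL = float(grp["yL"].iloc[0])
        ct = str(grp["censor_type"].iloc[0]).strip().lower()
        x = grp[xcols].iloc[0].to_numpy(dtype=float) if xcols else np.empty(0)
        z = grp[zcols].to_numpy(dtype=float) if zcols else np.empty((len(grp), 0))
        try:
            subjects.append(SubjectRecord(
                yL=yL, yR=yR, censor_type=ct, x=x,
                change_times=tstart, z_values=z, subject_id=sid))
        except FormatError as e:
            raise FormatError(f"subject {sid!r}: {e}") from e
    return SurvDataset(subjects=subjects)
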