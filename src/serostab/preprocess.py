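"""Outcome and protein-matrix preprocessing.

Timed function tests (time to stand, time to climb four stairs, time to
run/walk 10 m) are converted to velocities (reciprocal time; 10 m divided by
time for the run/walk test), repeated visits are summarized by their mean
with a per-subject coefficient of variation, the positive relative-abundance
(RFU) protein matrix is log2-transformed, and extreme values are flagged —
but never removed — based on distance from the column mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProteinProfile",
    "times_to_velocity",
    "summarize_repeats",
    "cohort_cv_summary",
    "log_transform",
    "flag_outliers",
]

#: Distance divided by observed time per timed test; 1 yields "rise/s" units.
VELOCITY_DISTANCE = {"TTSTAND": 1.0, "TTCLIMB": 1.0, "TTRW": 10.0}


@dataclass
class ProteinProfile:
    """Subjects × proteins relative-abundance matrix with annotations.

    ``abundance`` holds positive RFU values (subjects in rows, aptamer
    targets in columns); ``annotations`` maps each target to a UniProt
    accession and gene symbol; ``log_abundance`` is populated by
    :func:`log_transform`.
    """

    abundance: pd.DataFrame
    annotations: pd.DataFrame
    log_abundance: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if (self.abundance.values <= 0).any():
            n_bad = int((self.abundance.values <= 0).sum())
            raise ValueError(f"abundance must be strictly positive ({n_bad} offenders)")
        if len(self.annotations) != self.abundance.shape[1]:
            raise ValueError(
                f"annotation rows ({len(self.annotations)}) != protein count "
                f"({self.abundance.shape[1]})"
            )
        if self.abundance.index.duplicated().any():
            dup = self.abundance.index[self.abundance.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dup}")

    @property
    def subjects(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.abundance.columns)


def times_to_velocity(time_s, distance: float = 1.0):
    """Convert timed-test seconds to velocity: ``distance / time``.

    ``distance`` defaults to 1 (rise/s for stand and climb tests) and should
    be 10 for the 10 m run/walk test. Scalar or array input; nonpositive
    times are rejected, naming the offending entries.
    """
    t = np.asarray(time_s, dtype=float)
    if (t <= 0).any():
        bad = np.argwhere(t <= 0).ravel().tolist()
        raise ValueError(f"nonpositive time(s) at position(s) {bad}: {t[t <= 0]}")
    out = distance / t
    return float(out) if np.isscalar(time_s) or t.ndim == 0 else out


def summarize_repeats(series: pd.DataFrame) -> pd.DataFrame:
    """Summarize repeated visits per (subject, outcome).

    ``series`` is long-format with columns (subject_id, outcome, visit,
    value). Returns one row per (subject_id, outcome) with the mean over
    available visits, per-subject %CV (100 · sample sd / mean) and the
    number of visits used. Missing visits simply shrink the average; a zero
    mean with nonzero spread leaves %CV undefined (NaN, with a warning).
    """
    required = {"subject_id", "outcome", "visit", "value"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"outcome series missing columns: {sorted(missing)}")
    rows = []
    for (subj, outcome), grp in series.groupby(["subject_id", "outcome"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"no visits for subject {subj!r}, outcome {outcome!r}")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if mean == 0.0 and sd > 0.0:
            warnings.warn(
                f"%CV undefined for {subj}/{outcome}: zero mean with nonzero sd"
            )
            cv = np.nan
        else:
            cv = 0.0 if sd == 0.0 else 100.0 * sd / abs(mean)
        rows.append((subj, outcome, mean, cv, len(vals)))
    return pd.DataFrame(
        rows, columns=["subject_id", "outcome", "mean", "pct_cv", "n_visits"]
    )


def cohort_cv_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level %CV report: mean and sd of per-subject %CV per outcome.

    Mirrors a repeated-measures reliability table: one row per outcome with
    the across-subject mean and standard deviation of the per-subject
    coefficient of variation.
    """
    if summaries["subject_id"].nunique() < 2:
        raise ValueError("cohort %CV summary needs at least 2 subjects")
    rows = []
    for outcome, grp in summaries.groupby("outcome", sort=True):
        cv = grp["pct_cv"].to_numpy(dtype=float)
        cv = cv[np.isfinite(cv)]
        rows.append(
            (
                outcome,
                float(np.mean(cv)),
                float(np.std(cv, ddof=1)) if len(cv) > 1 else 0.0,
                len(cv),
            )
        )
    return pd.DataFrame(rows, columns=["outcome", "mean_pct_cv", "sd_pct_cv", "n"])


def log_transform(profile: ProteinProfile) -> ProteinProfile:
    """Populate ``log_abundance`` with elementwise log2 of the RFU matrix.

    Downstream correlations are computed on the log scale; the base is
    immaterial for correlation-based analysis. Nonpositive entries are
    rejected with their locations.
    """
    vals = profile.abundance.values
    if (vals <= 0).any():
        idx = np.argwhere(vals <= 0)
        offenders = [
            (profile.abundance.index[i], profile.abundance.columns[j])
            for i, j in idx[:10]
        ]
        raise ValueError(f"nonpositive abundance entries, e.g. {offenders}")
    return ProteinProfile(
        abundance=profile.abundance,
        annotations=profile.annotations,
        log_abundance=pd.DataFrame(
            np.log2(vals), index=profile.abundance.index,
            columns=profile.abundance.columns,
        ),
    )


def flag_outliers(matrix: pd.DataFrame, z_threshold: float = 5.0) -> list[tuple]:
    """Flag entries more than ``z_threshold`` column sds from the column mean.

    Flags are informational only — the pipeline never removes or transforms
    flagged values; they are reported so an analyst can inspect them.
    Constant columns produce no flags.
    """
    if matrix.shape[0] < 3:
        raise ValueError("outlier flagging needs at least 3 subjects")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(vals - mean) / sd
    z[:, sd == 0] = 0.0
    flags = np.argwhere(z > z_threshold)
    return [(matrix.index[i], matrix.columns[j]) for i, j in flags]
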