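"""Long-format longitudinal survival data: container, I/O, counting-process
conversion, and descriptive / missingness summaries.

The central object is :class:`PanelDataset`: one row per subject-visit, with
per-subject event time and event indicator repeated on every row, baseline
covariates constant within subject, and time-varying biomarkers that may be
missing (missing cells are NaN; the missingness mask is derived from NaN-ness,
so mask and values can never disagree).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class SchemaError(ValueError):
    """A mandatory column is absent or misdeclared."""


class PanelValidationError(ValueError):
    """The data violate a PanelDataset invariant."""


@dataclass(frozen=True)
class PanelSchema:
    """Column mapping for a long-format panel file.

    Parameters
    ----------
    id, time, event_time, event : str
        Names of the subject identifier, visit time (months), per-subject
        event/censoring time and event indicator (1 = event) columns.
    baseline : tuple of str
        Subject-level covariates, constant within subject (e.g. age, bmi,
        gleason, drug).
    time_varying : tuple of str
        Visit-level biomarkers (e.g. psa, alk_phos); these may contain NaN.
    categorical : tuple of str
        Subset of the covariates that are categories rather than numbers.
    """

    id: str = "id"
    time: str = "time"
    event_time: str = "event_time"
    event: str = "event"
    baseline: tuple[str, ...] = ("age", "bmi", "gleason", "drug")
    time_varying: tuple[str, ...] = ("psa", "alk_phos")
    categorical: tuple[str, ...] = ("gleason", "drug")

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.id, self.time, self.event_time, self.event)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.baseline) + tuple(self.time_varying)


@dataclass(frozen=True)
class MissingnessReport:
    variable: str
    n_observed: int
    n_missing: int
    percent_missing: float  # to one decimal
    n_subjects_complete: int

    @property
    def n_total(self) -> int:
        return self.n_observed + self.n_missing


@dataclass
class GroupComparisonTable:
    """Table-1-style group comparison: one row per variable (or level)."""

    table: pd.DataFrame  # columns: variable, level, <group cells...>, p_value
    group_sizes: dict[str, int]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class PanelDataset:
    """Validated long-format longitudinal survival dataset."""

    def __init__(self, frame: pd.DataFrame, schema: PanelSchema | None = None,
                 validate: bool = True):
        self.schema = schema or PanelSchema()
        self.frame = frame.reset_index(drop=True)
        if validate:
            self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        s, f = self.schema, self.frame
        missing_cols = [c for c in s.mandatory if c not in f.columns]
        if missing_cols:
            raise SchemaError(f"mandatory column(s) missing: {missing_cols}")
        for v in s.variables:
            if v not in f.columns:
                raise SchemaError(f"declared variable {v!r} not in data")
        if len(f) == 0:
            raise PanelValidationError("empty dataset")
        if (f[s.time] < 0).any():
            raise PanelValidationError("negative visit time")
        bad = f[f[s.time] > f[s.event_time]]
        if len(bad):
            subj = bad[s.id].iloc[0]
            raise PanelValidationError(
                f"subject {subj!r} has a visit after its event/censoring time")
        if not f[s.event].isin([0, 1]).all():
            raise PanelValidationError("event indicator must be 0/1")
        per = f.groupby(s.id)[[s.event_time, s.event]].nunique()
        if (per > 1).any().any():
            raise PanelValidationError(
                "event_time/event must be constant within subject")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.frame[self.schema.id].nunique()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def miss_mask(self, variable: str) -> pd.Series:
        """Boolean series, True where the value is observed (r=1)."""
        if variable not in self.frame.columns:
            raise KeyError(f"unknown variable {variable!r}")
        return self.frame[variable].notna()

    def subject_table(self) -> pd.DataFrame:
        """One row per subject: id, event_time, event, baseline covariates,
        and first-visit values of the time-varying covariates."""
        s = self.schema
        cols = [s.id, s.event_time, s.event, *s.baseline, *s.time_varying]
        cols = [c for c in cols if c in self.frame.columns]
        f = self.frame.sort_values([s.id, s.time], kind="mergesort")
        return f.groupby(s.id, as_index=False, sort=False)[cols].first()

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.frame.copy(), self.schema, validate=False)

    def with_frame(self, frame: pd.DataFrame, validate: bool = False) -> "PanelDataset":
        return PanelDataset(frame, self.schema, validate=validate)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_panel_csv(path, schema: PanelSchema | None = None) -> PanelDataset:
    """Read a long-format CSV into a validated :class:`PanelDataset`.

    Missing cells in the file (empty fields) become NaN, i.e. mask r=0.
    """
    schema = schema or PanelSchema()
    frame = pd.read_csv(path)
    return PanelDataset(frame, schema)


def write_panel_csv(data: PanelDataset, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Counting-process conversion
# ---------------------------------------------------------------------------

def to_counting_process(data: PanelDataset, covariates: list[str] | None = None,
                        carry: str = "locf") -> pd.DataFrame:
    """Convert visit rows into (start, stop] risk intervals.

    Per subject, consecutive visit times t_1 < t_2 < ... bound half-open
    intervals (t_k, t_{k+1}]; the last interval ends at the subject's
    event/censoring time, where the event flag (if any) is placed. Covariate
    values are carried forward from the visit opening each interval (LOCF).

    Raises if any requested covariate still contains missing values: run the
    imputation first (or restrict to complete data).
    """
    if carry != "locf":
        raise NotImplementedError(
            f"carry rule {carry!r} not supported; only 'locf' is implemented")
    s = data.schema
    covariates = list(covariates) if covariates is not None else list(s.variables)
    for c in covariates:
        if c not in data.frame.columns:
            raise KeyError(f"unknown covariate {c!r}")
        if data.frame[c].isna().any():
            raise ValueError(
                f"covariate {c!r} contains missing values; impute before "
                "counting-process conversion")

    f = data.frame.sort_values([s.id, s.time], kind="mergesort").reset_index(drop=True)
    grp = f.groupby(s.id, sort=False)
    start = f[s.time].to_numpy(float)
    stop = grp[s.time].shift(-1).to_numpy()
    last = np.isnan(stop)
    stop[last] = f.loc[last, s.event_time].to_numpy(float)
    event = np.where(last, f[s.event].to_numpy(int), 0)

    out = pd.DataFrame({
        s.id: f[s.id].to_numpy(),
        "start": start,
        "stop": stop,
        "event": event,
    })
    for c in covariates:
        out[c] = f[c].to_numpy()
    # a visit exactly at the event/censoring time opens no interval; its
    # event flag (if any) belongs to the preceding interval
    zero = out["stop"] <= out["start"]
    if zero.any():
        moved = out.loc[zero & (out["event"] == 1), s.id]
        out = out[~zero].copy()
        if len(moved):
            for subj in moved:
                rows = out.index[out[s.id] == subj]
                if len(rows) == 0:
                    raise PanelValidationError(
                        f"subject {subj!r} has no positive-length risk interval")
                out.loc[rows[-1], "event"] = 1
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def missingness_summary(data: PanelDataset, variable: str) -> MissingnessReport:
    """Count observed/missing records for one longitudinal variable.

    A subject is "complete" when the variable is observed at every one of its
    scheduled visits.
    """
    observed = data.miss_mask(variable)
    n_obs = int(observed.sum())
    n_mis = int((~observed).sum())
    total = n_obs + n_mis
    pct = round(100.0 * n_mis / total, 1)
    complete = observed.groupby(data.frame[data.schema.id]).all()
    return MissingnessReport(variable, n_obs, n_mis, pct, int(complete.sum()))


def complete_data_grouping(data: PanelDataset, variable: str,
                           labels: tuple[str, str] = ("Complete", "Missing")) -> pd.Series:
    """Subject partition by complete vs any-missing follow-up of `variable`."""
    observed = data.miss_mask(variable)
    complete = observed.groupby(data.frame[data.schema.id]).all()
    return complete.map({True: labels[0], False: labels[1]})


@dataclass(frozen=True)
class CohortSummary:
    n_subjects: int
    n_records: int
    n_events: int
    event_percent: float  # to one decimal
    median_time_to_event: float
    mean_time_to_event: float
    sd_time_to_event: float


def cohort_summary(data: PanelDataset) -> CohortSummary:
    """Headline cohort counts: size, event fraction, time-to-event location."""
    s = data.schema
    subj = data.subject_table()
    ev = subj[s.event].to_numpy(int)
    times = subj.loc[ev == 1, s.event_time].to_numpy(float)
    n_ev = int(ev.sum())
    return CohortSummary(
        n_subjects=len(subj),
        n_records=data.n_records,
        n_events=n_ev,
        event_percent=round(100.0 * n_ev / len(subj), 1),
        median_time_to_event=float(np.median(times)) if n_ev else float("nan"),
        mean_time_to_event=float(np.mean(times)) if n_ev else float("nan"),
        sd_time_to_event=float(np.std(times, ddof=1)) if n_ev > 1 else float("nan"),
    )


def _fmt(x: float, nd: int = 1) -> str:
    return f"{x:.{nd}f}"


def descriptive_table(data: PanelDataset, grouping: pd.Series,
                      styles: dict[str, str] | None = None) -> GroupComparisonTable:
    """Group-comparison table (baseline characteristics by subject partition).

    `grouping` maps subject id -> group label and must cover every subject.
    `styles` maps variable -> one of {"mean", "median", "category"}; variables
    not listed default to "category" if declared categorical, else "mean".
    Tests: Welch t (mean), Mann-Whitney (median), Pearson chi-square without
    continuity correction (category). Display rounding: one decimal for
    percentages; two decimals for continuous summaries.
    """
    s = data.schema
    subj = data.subject_table().set_index(s.id)
    grouping = grouping.reindex(subj.index)
    if grouping.isna().any():
        raise ValueError("grouping must assign every subject to a group")
    groups = list(pd.unique(grouping))
    sizes = {g: int((grouping == g).sum()) for g in groups}
    if any(v == 0 for v in sizes.values()):
        raise ValueError("empty group in grouping")

    styles = dict(styles or {})
    rows = []
    for var in s.variables:
        style = styles.get(
            var, "category" if var in s.categorical else "mean")
        vals = {g: subj.loc[grouping == g, var].dropna() for g in groups}
        if style == "category":
            counts = pd.crosstab(subj[var], grouping)
            counts = counts.reindex(columns=groups, fill_value=0)
            if counts.shape[0] > 1 and all(counts.sum() > 0):
                chi2, p, _, _ = stats.chi2_contingency(
                    counts.to_numpy(), correction=False)
            else:
                p = float("nan")
            first = True
            for level, row in counts.iterrows():
                cells = {
                    g: f"{int(row[g])} ({_fmt(100.0 * row[g] / sizes[g])})"
                    for g in groups
                }
                rows.append({"variable": var, "level": str(level), **cells,
                             "p_value": p if first else np.nan})
                first = False
        elif style == "median":
            cells = {}
            for g in groups:
                v = vals[g]
                q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
                cells[g] = f"{_fmt(med, 2)} ({_fmt(q1, 2)};{_fmt(q3, 2)})"
            try:
                _, p = stats.mannwhitneyu(vals[groups[0]], vals[groups[1]],
                                          alternative="two-sided")
            except ValueError:
                p = 1.0  # identical constant samples
            rows.append({"variable": var, "level": "", **cells, "p_value": p})
        else:  # mean
            cells = {
                g: f"{_fmt(vals[g].mean(), 2)} ({_fmt(vals[g].std(ddof=1), 2)})"
                for g in groups
            }
            _, p = stats.ttest_ind(vals[groups[0]], vals[groups[1]],
                                   equal_var=False)
            rows.append({"variable": var, "level": "", **cells,
                         "p_value": float(p)})
    table = pd.DataFrame(rows)
    return GroupComparisonTable(table=table, group_sizes=sizes)
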