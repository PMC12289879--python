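"""Proper multiple imputation of an incomplete longitudinal biomarker under
MAR, with survival-aware predictors.

The imputation model is a Bayesian normal linear regression on the log scale
(optionally with a per-subject random intercept): the missing biomarker is
regressed on declared predictors plus derived survival predictors — the
subject's event indicator, the Nelson-Aalen cumulative hazard evaluated at
the subject's event/censoring time, and optionally log follow-up time.
Including these outcome summaries keeps the imputation model compatible with
a proportional-hazards analysis model, which is what makes the downstream
pooled hazard ratios approximately unbiased under MAR.

Each of the m chains iterates the draw (parameters from their approximate
posterior, then missing values from the predictive distribution), recording a
per-iteration trace of the imputed-value mean and SD. With a single
incomplete variable the conditional model does not depend on previous
imputations, so iterations are independent redraws; the chained structure is
retained for the trace diagnostics and for parity with multi-variable use.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelDataset, PanelSchema, write_panel_csv
from .survival import nelson_aalen

# derived survival-predictor column names
EVENT_IND = "event_ind"
NA_CUMHAZ = "na_cumhaz"
LOG_TIME = "log_event_time"
INT_EVENT = "interval_event"
INT_CUMHAZ = "interval_cumhaz"


@dataclass(frozen=True)
class ImputationModelSpec:
    """Specification of the imputation model for one incomplete variable.

    Parameters
    ----------
    target : str
        The incomplete time-varying variable (imputed on the log scale when
        ``log_transform``; values must be positive where observed).
    predictors : tuple of str
        Fully observed covariates entering the linear predictor; categorical
        columns are dummy-coded automatically.
    use_event_indicator, use_cumhaz, use_log_time : bool
        Survival-aware predictors: the event indicator, the Nelson-Aalen
        cumulative hazard at the subject's own event/censoring time, and the
        log of that time.
    random_intercept : {"none", "subject"}
        Optional per-subject random intercept in the imputation model.
    m : int
        Number of completed datasets (chains); at least 2 for pooling.
    iterations : int
        Chained-equation iterations per chain.
    """

    target: str = "alk_phos"
    predictors: tuple[str, ...] = ("age", "bmi", "gleason", "drug", "psa")
    log_transform: bool = True
    use_event_indicator: bool = True
    use_cumhaz: bool = True
    use_log_time: bool = False
    use_interval_event: bool = True
    use_interval_cumhaz: bool = True
    include_missingness_indicator: bool = False
    random_intercept: str = "none"
    m: int = 5
    iterations: int = 20

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m >= 2 is required for Rubin pooling")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.target in self.predictors:
            raise ValueError("target cannot be among its own predictors")
        if self.random_intercept not in ("none", "subject"):
            raise ValueError("random_intercept must be 'none' or 'subject'")


@dataclass
class ImputedStack:
    """m completed copies of a panel plus the chain history."""

    datasets: list[PanelDataset]
    trace: pd.DataFrame  # chain, iteration, mean, sd (log-scale imputations)
    spec: ImputationModelSpec
    seed: int | None
    target: str
    missing_index: np.ndarray  # row positions (in frame) that were imputed

    @property
    def m(self) -> int:
        return len(self.datasets)

    def to_csv_dir(self, path) -> None:
        """Serialize: one CSV per completed copy, trace CSV, JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, ds in enumerate(self.datasets):
            write_panel_csv(ds, path / f"imputed_{i + 1}.csv")
        self.trace.to_csv(path / "trace.csv", index=False)
        manifest = {
            "spec": dataclasses.asdict(self.spec),
            "seed": self.seed,
            "target": self.target,
            "m": self.m,
            "n_imputed_cells": int(len(self.missing_index)),
            "files": [f"imputed_{i + 1}.csv" for i in range(self.m)],
            "trace": "trace.csv",
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


DERIVED_COLUMNS = (EVENT_IND, NA_CUMHAZ, LOG_TIME, INT_EVENT, INT_CUMHAZ)


def augment_survival_predictors(data: PanelDataset) -> PanelDataset:
    """Add outcome-derived predictor columns for survival-aware imputation.

    Subject-level (repeated on every record): the event indicator, the
    Nelson-Aalen cumulative hazard evaluated at the subject's own
    event/censoring time, and the log of that time.

    Record-level: each visit row opens a risk interval (its visit time up to
    the next visit or the event/censoring time); ``interval_event`` flags
    whether the subject's event fell inside that interval and
    ``interval_cumhaz`` is the Nelson-Aalen increment across it. For a
    time-varying covariate these carry the risk information accrued while
    the record's value actually drives the hazard, which the subject-level
    summaries only approximate.

    Re-running replaces the columns (idempotent).
    """
    s = data.schema
    subj = data.subject_table()
    T = subj[s.event_time].to_numpy(float)
    ev = subj[s.event].to_numpy(int)
    if (T <= 0).any():
        raise ValueError("log event/censoring time requires strictly "
                         "positive event times")
    na = nelson_aalen(T, ev)
    derived = pd.DataFrame({
        s.id: subj[s.id].to_numpy(),
        EVENT_IND: ev.astype(float),
        NA_CUMHAZ: na.at(T),
        LOG_TIME: np.log(T),
    })
    frame = data.frame.drop(columns=list(DERIVED_COLUMNS), errors="ignore")
    frame = frame.merge(derived, on=s.id, how="left")

    # record-level interval predictors
    order = frame.sort_values([s.id, s.time], kind="mergesort")
    grp = order.groupby(s.id, sort=False)
    nxt = grp[s.time].shift(-1)
    iv_end = np.minimum(nxt.fillna(order[s.event_time]).to_numpy(float),
                        order[s.event_time].to_numpy(float))
    is_last = nxt.isna().to_numpy()
    d_int = (is_last & (order[s.event].to_numpy(int) == 1)).astype(float)
    dH = na.at(iv_end) - na.at(order[s.time].to_numpy(float))
    frame.loc[order.index, INT_EVENT] = d_int
    frame.loc[order.index, INT_CUMHAZ] = dH
    return PanelDataset(frame, data.schema, validate=False)


def _design_matrix(frame: pd.DataFrame, predictors: list[str],
                   categorical: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(frame))]
    names = ["(intercept)"]
    for p in predictors:
        col = frame[p]
        if p in categorical or col.dtype == object or isinstance(
                col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), prefix=p,
                                     prefix_sep="=", drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                names.append(c)
        else:
            cols.append(col.to_numpy(float))
            names.append(p)
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        kept: list[int] = []
        bad = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(names[j])
            else:
                kept.append(j)
        raise ValueError(f"singular predictor matrix; dependent columns: {bad}")


class _NormalEngine:
    """Bayesian normal linear regression (noninformative prior), fitted once;
    each draw samples sigma^2 from a scaled inverse chi-square, coefficients
    from their normal given sigma^2, then the missing values from the
    predictive normal."""

    def __init__(self, y, obs, X, subj_codes, mis_idx):
        yo, Xo = y[obs], X[obs]
        self.n, self.k = Xo.shape
        XtX_inv = np.linalg.inv(Xo.T @ Xo)
        self.beta_hat = XtX_inv @ (Xo.T @ yo)
        resid = yo - Xo @ self.beta_hat
        self.rss = float(resid @ resid)
        self.df = max(self.n - self.k, 1)
        self.L = np.linalg.cholesky(XtX_inv)
        self.X_mis = X[mis_idx]

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        sigma2 = self.rss / rng.chisquare(self.df)
        beta = self.beta_hat + np.sqrt(sigma2) * (
            self.L @ rng.standard_normal(self.k))
        return (self.X_mis @ beta
                + np.sqrt(sigma2) * rng.standard_normal(len(self.X_mis)))


class _RandomInterceptEngine:
    """Per-subject random-intercept imputation model.

    REML point estimates are computed once; each draw perturbs the variance
    components by chi-square approximations to their sampling distributions,
    draws fixed effects from their normal, draws each subject's intercept
    from its conditional normal given that subject's observed residuals
    (prior N(0, sigma_u^2) for subjects with nothing observed), and finally
    the missing values from the predictive normal.
    """

    def __init__(self, y, obs, X, subj_codes, mis_idx):
        import statsmodels.api as sm

        yo, Xo, go = y[obs], X[obs], subj_codes[obs]
        self.k = Xo.shape[1]
        model = sm.MixedLM(yo, Xo, groups=go)
        fit = None
        err: Exception | None = None
        for method in (None, "bfgs", "powell"):
            try:
                with np.errstate(all="ignore"):
                    import warnings as _w
                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        fit = (model.fit(reml=True) if method is None
                               else model.fit(reml=True, method=method))
                break
            except (np.linalg.LinAlgError, ValueError) as e:  # optimizer path
                err = e
        if fit is None:
            raise RuntimeError(
                f"random-intercept imputation model failed to fit: {err}")
        self.fe = np.asarray(fit.fe_params)
        self.cov_fe = np.asarray(fit.cov_params())[:self.k, :self.k]
        self.L_fe = np.linalg.cholesky(self.cov_fe)
        self.sigma2_e = float(fit.scale)
        self.sigma2_u = max(float(np.asarray(fit.cov_re)[0, 0]), 1e-10)
        self.df_e = max(len(yo) - self.k, 1)
        self.df_u = max(len(np.unique(go)) - 1, 1)
        self.yo, self.Xo, self.go = yo, Xo, go
        self.n_groups = int(subj_codes.max()) + 1
        self.X_mis = X[mis_idx]
        self.g_mis = subj_codes[mis_idx]

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        s2e = self.sigma2_e * self.df_e / rng.chisquare(self.df_e)
        s2u = self.sigma2_u * self.df_u / rng.chisquare(self.df_u)
        beta = self.fe + self.L_fe @ rng.standard_normal(self.k)
        resid = self.yo - self.Xo @ beta
        counts = np.bincount(self.go, minlength=self.n_groups)
        sums = np.bincount(self.go, weights=resid, minlength=self.n_groups)
        prec = 1.0 / s2u + counts / s2e
        mean = (sums / s2e) / prec
        u = mean + rng.standard_normal(self.n_groups) / np.sqrt(prec)
        return (self.X_mis @ beta + u[self.g_mis]
                + np.sqrt(s2e) * rng.standard_normal(len(self.X_mis)))


def impute_mar(data: PanelDataset, spec: ImputationModelSpec,
               seed: int | None = None) -> ImputedStack:
    """Multiple imputation of `spec.target` under MAR.

    Returns an :class:`ImputedStack` of m completed copies on the original
    scale. Observed entries are never modified. Deterministic for a fixed
    (data, spec, seed).
    """
    s = data.schema
    work = data
    need_derived = (spec.use_event_indicator or spec.use_cumhaz
                    or spec.use_log_time or spec.use_interval_event
                    or spec.use_interval_cumhaz)
    if need_derived:
        work = augment_survival_predictors(work)
    frame = work.frame

    y_raw = frame[spec.target].to_numpy(float)
    obs = ~np.isnan(y_raw)
    n_obs = int(obs.sum())
    mis_idx = np.where(~obs)[0]
    if n_obs < 10:
        raise ValueError(
            f"target {spec.target!r} has only {n_obs} observed values; "
            "at least 10 are required")

    predictors = list(spec.predictors)
    if spec.use_event_indicator:
        predictors.append(EVENT_IND)
    if spec.use_cumhaz:
        predictors.append(NA_CUMHAZ)
    if spec.use_log_time:
        predictors.append(LOG_TIME)
    if spec.use_interval_event:
        predictors.append(INT_EVENT)
    if spec.use_interval_cumhaz:
        predictors.append(INT_CUMHAZ)
    if spec.include_missingness_indicator:
        frame = frame.copy()
        frame["__miss_ind__"] = (~obs).astype(float)
        predictors.append("__miss_ind__")
    for p in predictors:
        if p not in frame.columns:
            raise KeyError(f"predictor {p!r} not in data")
        if frame[p].isna().any():
            raise ValueError(f"predictor {p!r} has missing values; only the "
                             "target may be incomplete")

    if spec.log_transform:
        if (y_raw[obs] <= 0).any():
            raise ValueError("log transform requires positive observed values")
        y = np.where(obs, np.log(y_raw, where=obs, out=np.zeros_like(y_raw)),
                     np.nan)
    else:
        y = y_raw.copy()

    X, names = _design_matrix(frame, predictors, s.categorical)
    _check_full_rank(X[obs], names)
    subj_codes, _ = pd.factorize(frame[s.id])

    # degenerate case: nothing to impute
    if len(mis_idx) == 0:
        empty = pd.DataFrame(columns=["chain", "iteration", "mean", "sd"])
        return ImputedStack([data.copy() for _ in range(spec.m)], empty,
                            spec, seed, spec.target, mis_idx)

    engine_cls = (_RandomInterceptEngine if spec.random_intercept == "subject"
                  else _NormalEngine)
    engine = engine_cls(y, obs, X, subj_codes, mis_idx)

    streams = np.random.SeedSequence(seed).spawn(spec.m)
    datasets = []
    trace_rows = []
    for chain, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        y_imp = None
        for it in range(spec.iterations):
            y_imp = engine.draw(rng)
            trace_rows.append({
                "chain": chain, "iteration": it,
                "mean": float(np.mean(y_imp)),
                "sd": float(np.std(y_imp, ddof=1)) if len(y_imp) > 1 else 0.0,
            })
        completed = data.frame.copy()
        vals = np.exp(y_imp) if spec.log_transform else y_imp
        col = completed[spec.target].to_numpy(float)
        col[mis_idx] = vals
        completed[spec.target] = col
        datasets.append(PanelDataset(completed, s, validate=False))
    trace = pd.DataFrame(trace_rows)
    return ImputedStack(datasets, trace, spec, seed, spec.target, mis_idx)


@dataclass
class TraceDiagnostics:
    trace: pd.DataFrame
    between_var: float
    within_var: float
    non_mixing: bool


def trace_diagnostics(stack: ImputedStack) -> TraceDiagnostics:
    """Between/within-chain comparison of the final-quarter trace means.

    Flags non-mixing when the between-chain variance of final-quarter means
    exceeds three times the average within-chain variance.
    """
    tr = stack.trace
    if len(tr) == 0:
        return TraceDiagnostics(tr, 0.0, 0.0, False)
    n_iter = int(tr["iteration"].max()) + 1
    if n_iter < 2:
        raise ValueError("trace diagnostics need at least 2 iterations")
    cut = max(n_iter - max(n_iter // 4, 1), 0)
    tail = tr[tr["iteration"] >= cut]
    chain_means = tail.groupby("chain")["mean"].mean()
    within = tail.groupby("chain")["mean"].var(ddof=1).mean()
    between = float(chain_means.var(ddof=1))
    within = float(within) if np.isfinite(within) else 0.0
    non_mixing = bool(between > 3.0 * within) if within > 0 else \
        bool(between > 0)
    return TraceDiagnostics(tr, between, within, non_mixing)
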