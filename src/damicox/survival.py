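"""Nonparametric survival estimators, time-dependent Cox regression on
counting-process (start, stop] data, and proportional-hazards diagnostics.

The Cox fitter maximises the partial likelihood by Newton-Raphson with
step-halving, supports Efron (default) and Breslow tie corrections, reports
Wald inference from the inverse observed information, and a Breslow estimate
of the baseline cumulative hazard. The proportional-hazards check is the
Grambsch-Therneau score test on scaled Schoenfeld residuals against a
transform of event time (identity, rank, or Kaplan-Meier).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ConvergenceError(RuntimeError):
    pass


class CollinearityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Nonparametric estimators
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    label: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "at_risk": self.at_risk, "events": self.events,
            "group": self.label,
        })

    def at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


@dataclass
class CumulativeHazard:
    times: np.ndarray
    hazard: np.ndarray

    def at(self, t) -> np.ndarray:
        """Step-function evaluation H(t) = sum over event times <= t."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        h = np.concatenate([[0.0], self.hazard])
        return h[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "cum_hazard": self.hazard})


def _risk_counts(times: np.ndarray, events: np.ndarray):
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")
    et = np.unique(times[events == 1])
    order = np.sort(times)
    n_at_risk = len(times) - np.searchsorted(order, et, side="left")
    d = np.array([int(((times == t) & (events == 1)).sum()) for t in et])
    return et, n_at_risk, d


def kaplan_meier(times, events, groups=None):
    """Kaplan-Meier product-limit estimator Π(1 - d_i/n_i).

    With `groups`, returns a dict label -> :class:`SurvivalCurve`.
    """
    if groups is not None:
        groups = np.asarray(groups)
        times = np.asarray(times, float)
        events = np.asarray(events, int)
        out = {}
        for g in pd.unique(groups):
            m = groups == g
            c = kaplan_meier(times[m], events[m])
            c.label = str(g)
            out[g] = c
        return out
    et, n, d = _risk_counts(times, events)
    surv = np.cumprod(1.0 - d / n) if len(et) else np.array([])
    return SurvivalCurve(et, surv, n, d)


def nelson_aalen(times, events) -> CumulativeHazard:
    """Nelson-Aalen cumulative hazard Ĥ(t) = Σ_{t_i <= t} d_i/n_i."""
    et, n, d = _risk_counts(times, events)
    return CumulativeHazard(et, np.cumsum(d / n) if len(et) else np.array([]))


# ---------------------------------------------------------------------------
# Cox model on counting-process data
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    covariates: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_iter: int
    n_events: int
    n_obs: int
    ties: str
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def confint(self, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.beta - z * self.se)
        hi = np.exp(self.beta + z * self.se)
        return lo, hi

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = np.divide(self.beta, se, out=np.zeros_like(se), where=se > 0)
        p = 2 * stats.norm.sf(np.abs(z))
        lo, hi = self.confint()
        return pd.DataFrame({
            "coef": self.beta, "se": se, "p": p,
            "hr": self.hazard_ratios, "hr_lo": lo, "hr_hi": hi,
        }, index=self.covariates)

    @property
    def baseline(self) -> CumulativeHazard:
        return CumulativeHazard(self.baseline_times, self.baseline_cumhaz)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        # identify a minimal set of dependent columns by incremental rank
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = Xc[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept):
                bad.append(names[j])
            else:
                kept.append(j)
        raise CollinearityError(f"collinear design columns: {bad}")


class _PartialLikelihood:
    """Efron/Breslow partial likelihood and derivatives on (start, stop] rows,
    using suffix cumulative sums over stop- and start-sorted orders so each
    evaluation is O(n p^2 + k d p^2)."""

    def __init__(self, start, stop, event, X, ties="efron"):
        self.start = np.asarray(start, float)
        self.stop = np.asarray(stop, float)
        self.event = np.asarray(event, int)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.ties = ties
        if (self.stop <= self.start).any():
            raise ValueError("rows with stop <= start")
        dmask = self.event == 1
        self.d_idx = np.where(dmask)[0]
        if len(self.d_idx) == 0:
            raise ValueError("no events in data")
        # tie groups over distinct event times
        dt = self.stop[self.d_idx]
        order = np.argsort(dt, kind="mergesort")
        self.d_idx = self.d_idx[order]
        dt = dt[order]
        self.etimes, first = np.unique(dt, return_index=True)
        self.k = len(self.etimes)
        self.dcounts = np.diff(np.append(first, len(dt)))
        # expansion indices for the Efron inner sum (l = 0..d-1 per time)
        self.exp_time = np.repeat(np.arange(self.k), self.dcounts)
        if ties == "efron":
            self.exp_frac = np.concatenate(
                [np.arange(d) / d for d in self.dcounts])
        elif ties == "breslow":
            self.exp_frac = np.zeros(int(self.dcounts.sum()))
        else:
            raise ValueError(f"unknown ties method {ties!r}")
        # sort orders for suffix sums
        self.ord_stop = np.argsort(self.stop, kind="mergesort")
        self.ord_start = np.argsort(self.start, kind="mergesort")
        self.stop_sorted = self.stop[self.ord_stop]
        self.start_sorted = self.start[self.ord_start]
        # positions of event times within the sorted arrays
        self.pos_stop = np.searchsorted(self.stop_sorted, self.etimes, "left")
        self.pos_start = np.searchsorted(self.start_sorted, self.etimes, "left")
        iu = np.triu_indices(self.p)
        self._iu = iu

    def _suffix(self, arr):
        """Suffix sums with a trailing zero row: out[i] = sum(arr[i:])."""
        out = np.zeros((arr.shape[0] + 1,) + arr.shape[1:])
        out[:-1] = np.cumsum(arr[::-1], axis=0)[::-1]
        return out

    def risk_sums(self, w):
        """S0, S1, S2 over the risk set {start < t <= stop} at each event time."""
        X, p = self.X, self.p
        wX = w[:, None] * X
        # packed upper-triangular of w * x x^T
        wXX = wX[:, self._iu[0]] * X[:, self._iu[1]]

        s0_stop = self._suffix(w[self.ord_stop])
        s1_stop = self._suffix(wX[self.ord_stop])
        s2_stop = self._suffix(wXX[self.ord_stop])
        s0_start = self._suffix(w[self.ord_start])
        s1_start = self._suffix(wX[self.ord_start])
        s2_start = self._suffix(wXX[self.ord_start])

        S0 = s0_stop[self.pos_stop] - s0_start[self.pos_start]
        S1 = s1_stop[self.pos_stop] - s1_start[self.pos_start]
        S2p = s2_stop[self.pos_stop] - s2_start[self.pos_start]
        S2 = np.zeros((self.k, p, p))
        S2[:, self._iu[0], self._iu[1]] = S2p
        S2[:, self._iu[1], self._iu[0]] = S2p
        return S0, S1, S2

    def death_sums(self, w):
        wd = w[self.d_idx]
        Xd = self.X[self.d_idx]
        seg = np.repeat(np.arange(self.k), self.dcounts)
        S0d = np.bincount(seg, weights=wd, minlength=self.k)
        S1d = np.zeros((self.k, self.p))
        for j in range(self.p):
            S1d[:, j] = np.bincount(seg, weights=wd * Xd[:, j], minlength=self.k)
        S2d = np.zeros((self.k, self.p, self.p))
        for a, b in zip(*self._iu):
            v = np.bincount(seg, weights=wd * Xd[:, a] * Xd[:, b], minlength=self.k)
            S2d[:, a, b] = v
            S2d[:, b, a] = v
        return S0d, S1d, S2d

    def eval(self, beta, with_hessian=True):
        eta = self.X @ beta if self.p else np.zeros(self.n)
        w = np.exp(eta)
        S0, S1, S2 = self.risk_sums(w)
        S0d, S1d, S2d = self.death_sums(w)
        t, fr = self.exp_time, self.exp_frac
        phi = S0[t] - fr * S0d[t]
        if (phi <= 0).any():
            raise ConvergenceError("non-positive risk-set mass")
        ll = float(eta[self.d_idx].sum() - np.log(phi).sum())
        N1 = S1[t] - fr[:, None] * S1d[t]
        mu = N1 / phi[:, None]
        grad = self.X[self.d_idx].sum(axis=0) - mu.sum(axis=0)
        if not with_hessian:
            return ll, grad, None
        N2 = S2[t] - fr[:, None, None] * S2d[t]
        info = (N2 / phi[:, None, None]).sum(axis=0) - np.einsum(
            "kj,kl->jl", mu, mu)
        return ll, grad, info

    def breslow_baseline(self, beta):
        w = np.exp(self.X @ beta) if self.p else np.ones(self.n)
        S0, _, _ = self.risk_sums(w)
        return self.etimes, np.cumsum(self.dcounts / S0)

    def riskset_moments(self, beta):
        """Per-event-time Efron/Breslow-averaged covariate means at beta."""
        w = np.exp(self.X @ beta) if self.p else np.ones(self.n)
        S0, S1, _ = self.risk_sums(w)
        S0d, S1d, _ = self.death_sums(w)
        t, fr = self.exp_time, self.exp_frac
        phi = S0[t] - fr * S0d[t]
        mu = (S1[t] - fr[:, None] * S1d[t]) / phi[:, None]
        # average the l-adjusted means within each tie group
        mubar = np.zeros((self.k, self.p))
        for j in range(self.p):
            mubar[:, j] = np.bincount(t, weights=mu[:, j], minlength=self.k)
        mubar /= self.dcounts[:, None]
        return mubar


def fit_cox_td(data: pd.DataFrame, covariates: list[str],
               ties: str = "efron", tol: float = 1e-9,
               max_iter: int = 100) -> CoxFit:
    """Fit a Cox model with time-varying covariates on counting-process rows.

    `data` needs columns start, stop, event plus the design columns named in
    `covariates` (already numeric / dummy-coded). Newton-Raphson from beta=0
    with step-halving on likelihood decrease; convergence when the relative
    log-likelihood change falls below `tol`. |beta| > 15 flags a likely
    monotone likelihood.
    """
    X = data[list(covariates)].to_numpy(float) if covariates else \
        np.empty((len(data), 0))
    _check_design(X, list(covariates))
    pl = _PartialLikelihood(data["start"], data["stop"], data["event"], X,
                            ties=ties)
    p = X.shape[1]
    beta = np.zeros(p)
    ll0, _, _ = pl.eval(beta, with_hessian=False)
    warnings: list[str] = []
    if p == 0:
        bt, bh = pl.breslow_baseline(beta)
        return CoxFit([], beta, np.zeros((0, 0)), ll0, ll0, True, 0,
                      int(pl.dcounts.sum()), pl.n, ties, bt, bh)
    ll, grad, info = pl.eval(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix: {e}") from e
        ll_old = ll
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            try:
                ll_new, grad_new, info_new = pl.eval(cand)
            except (ConvergenceError, FloatingPointError):
                factor /= 2
                continue
            if np.isfinite(ll_new) and ll_new >= ll_old - 1e-12:
                break
            factor /= 2
        else:
            warnings.append("step-halving failed to improve the likelihood")
            break
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if abs(ll - ll_old) < tol * (abs(ll_old) + tol):
            converged = True
            break
    if np.abs(beta).max() > 15:
        warnings.append(
            "a coefficient exceeds 15 in absolute value: likely monotone "
            "likelihood / divergence")
        converged = False
    cov = np.linalg.inv(info)
    bt, bh = pl.breslow_baseline(beta)
    return CoxFit(list(covariates), beta, cov, ll, ll0, converged, it,
                  int(pl.dcounts.sum()), pl.n, ties, bt, bh, warnings)


# ---------------------------------------------------------------------------
# Schoenfeld residuals and the proportional-hazards score test
# ---------------------------------------------------------------------------

@dataclass
class PHTestResult:
    table: pd.DataFrame          # covariate, rho, chi2, p
    global_chi2: float
    global_p: float
    df: int
    transform: str

    def __repr__(self):
        return (f"PHTestResult(global chi2={self.global_chi2:.3f}, "
                f"df={self.df}, p={self.global_p:.4f}, "
                f"transform={self.transform!r})")


def schoenfeld_residuals(fit: CoxFit, data: pd.DataFrame):
    """Per-event Schoenfeld residuals x_i - xbar(t_i) at the fitted beta.

    Returns (event_times, residual matrix of shape n_events x p); tied events
    share the tie-averaged risk-set mean (Efron) or the plain mean (Breslow).
    """
    X = data[fit.covariates].to_numpy(float)
    pl = _PartialLikelihood(data["start"], data["stop"], data["event"], X,
                            ties=fit.ties)
    mubar = pl.riskset_moments(fit.beta)
    seg = np.repeat(np.arange(pl.k), pl.dcounts)
    resid = X[pl.d_idx] - mubar[seg]
    times = pl.stop[pl.d_idx]
    return times, resid


def _time_transform(times: np.ndarray, kind: str):
    if kind == "identity":
        return times.astype(float)
    if kind == "rank":
        return stats.rankdata(times).astype(float)
    raise ValueError(f"unknown time transform {kind!r}")


def schoenfeld_test(fit: CoxFit, data: pd.DataFrame,
                    transform: str = "identity") -> PHTestResult:
    """Grambsch-Therneau score test of proportional hazards.

    Correlates scaled Schoenfeld residuals with a transform g(t) of event
    time (identity, rank, or km); near-zero slopes support proportionality.
    """
    if not fit.covariates:
        raise ValueError("PH test requires at least one covariate")
    times, resid = schoenfeld_residuals(fit, data)
    d = len(times)
    if transform == "km":
        # 1 - KM evaluated just before each event time, from subject-level
        # durations (max stop) and event indicators
        id_col = data.columns[0]
        per = data.sort_values("stop").groupby(id_col)
        dur = per["stop"].max().to_numpy(float)
        ev = per["event"].max().to_numpy(int)
        km = kaplan_meier(dur, ev)
        g = 1.0 - km.at(times - 1e-12)
    else:
        g = _time_transform(times, transform)
    u = g - g.mean()
    ssu = float((u ** 2).sum())
    if ssu <= 0:
        raise ValueError("degenerate time transform (all event times equal)")
    V = fit.cov
    scaled = d * (resid @ V)  # scaled residuals up to the +beta constant
    num = u @ scaled          # d * u' (S V)
    stat = num ** 2 / (d * np.diag(V) * ssu)
    pvals = stats.chi2.sf(stat, 1)
    with np.errstate(invalid="ignore"):
        rho = np.array([
            np.corrcoef(u, scaled[:, j])[0, 1] if np.std(scaled[:, j]) > 0
            else np.nan
            for j in range(resid.shape[1])
        ])
    z = u @ resid
    global_stat = float(d * z @ V @ z / ssu)
    global_p = float(stats.chi2.sf(global_stat, len(fit.covariates)))
    table = pd.DataFrame({
        "covariate": fit.covariates, "rho": rho, "chi2": stat, "p": pvals,
    })
    return PHTestResult(table, global_stat, global_p, len(fit.covariates),
                        transform)


# ---------------------------------------------------------------------------
# Covariate-adjusted survival curves
# ---------------------------------------------------------------------------

def adjusted_survival_curves(fit: CoxFit,
                             profiles: dict[str, dict[str, float]]
                             ) -> dict[str, SurvivalCurve]:
    """S(t | x) = exp(-H0(t) exp(beta' x)) for each requested profile.

    Each profile must give a value for every design column of the fit.
    """
    out = {}
    for label, prof in profiles.items():
        unknown = set(prof) - set(fit.covariates)
        if unknown:
            raise KeyError(f"profile {label!r} has unknown covariates: "
                           f"{sorted(unknown)}")
        missing = set(fit.covariates) - set(prof)
        if missing:
            raise KeyError(f"profile {label!r} lacks covariates: "
                           f"{sorted(missing)}")
        x = np.array([prof[c] for c in fit.covariates])
        lp = float(x @ fit.beta)
        surv = np.exp(-fit.baseline_cumhaz * np.exp(lp))
        out[label] = SurvivalCurve(
            fit.baseline_times, surv,
            np.full_like(fit.baseline_times, np.nan),
            np.full_like(fit.baseline_times, np.nan), label=label)
    return out
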