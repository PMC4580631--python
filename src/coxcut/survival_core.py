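"""Survival-analysis primitives on counting-process rows.

The Cox partial-likelihood machinery is implemented here directly (rather
than delegated) because the change-point selection downstream compares
partial-likelihood values across different time-splittings of the treatment
variable: the likelihood itself is the quantity of interest, so its
computation must expose Breslow and Efron tie handling, case weights, and
the optimum log partial likelihood.  Risk sets use left-open/right-closed
intervals: a row (start, stop] is at risk at event time t iff
start < t <= stop.

Kaplan–Meier estimation is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


# ---------------------------------------------------------------------------
# Result containers

@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""
    names: list
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_events: int
    n_rows: int
    n_iter: int
    converged: bool
    ties: str
    cov: np.ndarray
    flags: list = field(default_factory=list)
    robust_se: np.ndarray | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def _se(self) -> np.ndarray:
        return self.robust_se if self.robust_se is not None else self.se

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        s = self._se()
        with np.errstate(over="ignore"):
            return np.exp(self.coef - 1.96 * s), np.exp(self.coef + 1.96 * s)

    @property
    def p(self) -> np.ndarray:
        s = self._se()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / s
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame({
            "covariate": self.names, "coef": self.coef, "se": self._se(),
            "hr": self.hr, "hr_ci_low": lo, "hr_ci_high": hi, "p": self.p,
        })

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        lo, hi = self.ci
        return {"coef": self.coef[i], "se": self._se()[i], "hr": self.hr[i],
                "ci_low": lo[i], "ci_high": hi[i], "p": self.p[i]}


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk accounting."""
    label: object
    days: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    def survival_at(self, day: float) -> float:
        idx = np.searchsorted(self.days, day, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


# ---------------------------------------------------------------------------
# Kaplan–Meier

def km_estimate(rows: pd.DataFrame, group_by: str | None = None,
                time_col: str = "followup_days",
                event_col: str = "event") -> list[KMCurve]:
    """Kaplan–Meier curves, optionally one per level of ``group_by``."""
    if len(rows) == 0:
        raise ValueError("km_estimate: empty input")
    if (rows[time_col] <= 0).any():
        raise ValueError("km_estimate: follow-up times must be positive")
    groups = [(None, rows)] if group_by is None \
        else list(rows.groupby(group_by, observed=True))
    curves = []
    for label, grp in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(grp[time_col], grp[event_col])
        tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
            else kmf.event_table
        days = tab.index.to_numpy(dtype=float)
        surv = kmf.survival_function_at_times(days).to_numpy()
        curves.append(KMCurve(
            label=label, days=days, survival=surv,
            at_risk=tab["at_risk"].to_numpy(),
            events=tab["observed"].to_numpy(),
            censored=tab["censored"].to_numpy()))
    return curves


# ---------------------------------------------------------------------------
# Cox partial likelihood on counting-process rows

def _prepare(cp_rows: pd.DataFrame, covariates, weight_col):
    start = cp_rows["start"].to_numpy(dtype=float)
    stop = cp_rows["stop"].to_numpy(dtype=float)
    event = cp_rows["event"].to_numpy(dtype=int)
    X = cp_rows[list(covariates)].to_numpy(dtype=float)
    w = (np.ones(len(cp_rows)) if weight_col is None
         else cp_rows[weight_col].to_numpy(dtype=float))
    if (stop <= start).any():
        raise ValueError("cox_fit: rows must satisfy stop > start")
    if weight_col is not None and ((w <= 0) | ~np.isfinite(w)).any():
        raise ValueError("cox_fit: weights must be positive and finite")
    return start, stop, event, X, w


class _PartialLikelihood:
    """Vectorized (weighted) Cox partial likelihood with its derivatives."""

    def __init__(self, start, stop, event, X, w, ties):
        self.X, self.w, self.ties = X, w, ties
        self.n, self.p = X.shape
        ev = event == 1
        if not ev.any():
            raise ValueError("cox_fit: no events in data")
        self.t = np.unique(stop[ev])
        self.m = len(self.t)
        # risk-range of each row over event-time indices: [a, b)
        self.a = np.searchsorted(self.t, start, side="right")
        self.b = np.searchsorted(self.t, stop, side="right")
        self.ev_rows = np.flatnonzero(ev)
        self.ev_j = np.searchsorted(self.t, stop[self.ev_rows])
        we = w[self.ev_rows]
        self.D = np.bincount(self.ev_j, weights=we, minlength=self.m)
        self.d_count = np.bincount(self.ev_j, minlength=self.m)
        self.sum_wx_ev = (we[:, None] * X[self.ev_rows]).sum(axis=0)
        # flattened (event time, tie index) pairs for Efron corrections
        if ties == "efron":
            self.ef_j = np.repeat(np.arange(self.m), self.d_count)
            self.ef_phi = np.concatenate(
                [np.arange(d) / d for d in self.d_count if d > 0])
        # upper-triangle index for second-moment accumulation
        self.iu, self.ju = np.triu_indices(self.p)

    @staticmethod
    def _scatter(idx, contrib, length):
        """Column-wise bincount accumulation (fast scatter-add)."""
        if contrib.ndim == 1:
            return np.bincount(idx, weights=contrib, minlength=length)
        out = np.empty((length,) + contrib.shape[1:])
        flat = contrib.reshape(len(contrib), -1)
        for k in range(flat.shape[1]):
            out.reshape(length, -1)[:, k] = np.bincount(
                idx, weights=flat[:, k], minlength=length)
        return out

    def _cum(self, contrib):
        """Difference-array accumulation of per-row contributions onto the
        event-time axis (rows contribute to times in their risk range)."""
        dif = self._scatter(self.a, contrib, self.m + 1) \
            - self._scatter(self.b, contrib, self.m + 1)
        return np.cumsum(dif, axis=0)[: self.m]

    def _tie_sum(self, contrib):
        """Per-event-time sums over tied event rows."""
        return self._scatter(self.ev_j, contrib, self.m)

    def _tri(self, flat):
        """Rebuild (..., p, p) symmetric matrices from triangular columns."""
        full = np.zeros(flat.shape[:-1] + (self.p, self.p))
        full[..., self.iu, self.ju] = flat
        full[..., self.ju, self.iu] = flat
        return full

    def evaluate(self, beta, need_hessian=True):
        X, w = self.X, self.w
        eta = X @ beta
        r = w * np.exp(np.clip(eta, -500, 500))
        rX = r[:, None] * X
        rXX = r[:, None] * (X[:, self.iu] * X[:, self.ju]) \
            if need_hessian else None
        S0 = self._cum(r)
        S1 = self._cum(rX)
        S2 = self._tri(self._cum(rXX)) if need_hessian else None

        we = w[self.ev_rows]
        ll = float((we * eta[self.ev_rows]).sum())
        U = self.sum_wx_ev.copy()
        H = np.zeros((self.p, self.p)) if need_hessian else None

        if self.ties == "breslow":
            ll -= float((self.D * np.log(S0)).sum())
            U -= (self.D[:, None] * S1 / S0[:, None]).sum(axis=0)
            if need_hessian:
                xbar = S1 / S0[:, None]
                H = np.einsum("j,jkl->kl", self.D, S2 / S0[:, None, None]) \
                    - np.einsum("j,jk,jl->kl", self.D, xbar, xbar)
        else:  # efron
            E0 = self._tie_sum(r[self.ev_rows])
            E1 = self._tie_sum(rX[self.ev_rows])
            E2 = self._tri(self._tie_sum(rXX[self.ev_rows])) \
                if need_hessian else None
            j, phi = self.ef_j, self.ef_phi
            wgt = self.D[j] / self.d_count[j]       # mean event weight
            den = S0[j] - phi * E0[j]
            num1 = S1[j] - phi[:, None] * E1[j]
            ll -= float((wgt * np.log(den)).sum())
            U -= (wgt[:, None] * num1 / den[:, None]).sum(axis=0)
            if need_hessian:
                num2 = S2[j] - phi[:, None, None] * E2[j]
                xb = num1 / den[:, None]
                H = np.einsum("j,jkl->kl", wgt / den, num2) \
                    - np.einsum("j,jk,jl->kl", wgt, xb, xb)
        return ll, U, H


def cox_fit(cp_rows: pd.DataFrame, covariates, ties: str = "efron",
            tol: float = 1e-8, max_iter: int = 100,
            weight_col: str | None = None, robust: bool = False) -> CoxFit:
    """Newton–Raphson maximization of the Cox partial likelihood.

    ``cp_rows`` must carry counting-process columns (start, stop, event)
    plus the covariates.  Convergence is declared when the log-likelihood
    improves by less than ``tol``; overshooting steps are halved.  Standard
    errors come from the inverse observed information; with
    ``robust=True`` a sandwich (infinitesimal-jackknife) variance grouped
    by ``subject_id`` is added — exact for Breslow ties, a Breslow-score
    approximation under Efron.
    """
    covariates = list(covariates)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown ties method {ties!r}")
    start, stop, event, X, w = _prepare(cp_rows, covariates, weight_col)
    for k, name in enumerate(covariates):
        if np.ptp(X[:, k]) == 0.0:
            raise ValueError(f"cox_fit: covariate {name!r} is constant")

    pl = _PartialLikelihood(start, stop, event, X, w, ties)
    p = len(covariates)
    beta = np.zeros(p)
    ll, U, H = pl.evaluate(beta)
    ll_null = ll
    flags: list[str] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, U, rcond=None)[0]
            flags.append("singular_information")
        new_beta = beta + step
        ll_new = pl.evaluate(new_beta, need_hessian=False)[0]
        halvings = 0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-12) and halvings < 25:
            step *= 0.5
            new_beta = beta + step
            ll_new = pl.evaluate(new_beta, need_hessian=False)[0]
            halvings += 1
        improvement = ll_new - ll
        beta = new_beta
        ll, U, H = pl.evaluate(beta)
        if 0 <= improvement < tol:
            converged = True
            break
    if not converged:
        flags.append("no_convergence")
    if np.abs(beta).max() > 20:
        flags.append("possible_separation")
        converged = False

    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        flags.append("singular_information")
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    fit = CoxFit(names=covariates, coef=beta, se=se, loglik=ll,
                 loglik_null=ll_null, n_events=int(event.sum()),
                 n_rows=len(cp_rows), n_iter=n_iter, converged=converged,
                 ties=ties, cov=cov, flags=flags)
    if robust:
        resid = _score_residuals(pl, beta, cp_rows["subject_id"].to_numpy())
        meat = resid.T @ resid
        sandwich = cov @ meat @ cov
        fit.robust_se = np.sqrt(np.clip(np.diag(sandwich), 0, None))
        if ties == "efron":
            fit.flags.append("robust_se_breslow_approx")
    return fit


def _score_residuals(pl: _PartialLikelihood, beta, subject_ids) -> np.ndarray:
    """Per-subject score residuals (Breslow form), for sandwich variance."""
    X, w = pl.X, pl.w
    eta = X @ beta
    r = w * np.exp(np.clip(eta, -500, 500))
    S0 = pl._cum(r)
    S1 = pl._cum(r[:, None] * X)
    xbar = S1 / S0[:, None]
    # prefix sums over event times of D/S0 and D*xbar/S0
    P0 = np.concatenate([[0.0], np.cumsum(pl.D / S0)])
    P1 = np.vstack([np.zeros(pl.p),
                    np.cumsum(pl.D[:, None] * xbar / S0[:, None], axis=0)])
    A = P0[pl.b] - P0[pl.a]
    B = P1[pl.b] - P1[pl.a]
    resid = -r[:, None] * (X * A[:, None] - B)
    resid[pl.ev_rows] += w[pl.ev_rows, None] * (
        X[pl.ev_rows] - xbar[pl.ev_j])
    frame = pd.DataFrame(resid)
    frame["_sid"] = subject_ids
    return frame.groupby("_sid", sort=False).sum().to_numpy()


# ---------------------------------------------------------------------------
# Time-splitting the variable of interest

def expand_time_split(rows: pd.DataFrame, variable: str,
                      cutoffs) -> pd.DataFrame:
    """Expand analysis rows into counting-process rows with interval copies
    of ``variable``.

    With cutoffs (c1 < ... < c_{n-1}) the follow-up axis is partitioned
    into n left-open/right-closed intervals P_1=(0,c1], ..., P_n; each
    subject contributes one row per interval its follow-up overlaps, the
    event sits on the final row, and the interval copy ``{variable}_p{k}``
    equals the subject's ``variable`` inside P_k and 0 elsewhere.  The
    original ``variable`` column is retained (its value is the sum of the
    copies on each row), as are all other columns.
    """
    cutoffs = [float(c) for c in cutoffs]
    if any(c2 <= c1 for c1, c2 in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    if cutoffs and cutoffs[0] <= 0:
        raise ValueError("cutoffs must be positive")
    fup = rows["followup_days"].to_numpy(dtype=float)
    if (fup <= 0).any():
        raise ValueError("followup_days must be positive")
    max_fup = fup.max()
    if cutoffs and cutoffs[-1] >= max_fup:
        raise ValueError(
            f"cutoff {cutoffs[-1]} is not inside (0, max follow-up "
            f"{max_fup})")

    bounds = np.array([0.0] + cutoffs)          # interval lower bounds
    n_int = len(bounds)
    # number of intervals each subject overlaps
    k_per = np.searchsorted(bounds, fup, side="left")  # fup > bounds[k-1]
    rep = np.repeat(np.arange(len(rows)), k_per)
    interval = np.concatenate([np.arange(k) for k in k_per]) if len(rows) \
        else np.array([], dtype=int)

    out = rows.iloc[rep].reset_index(drop=True).copy()
    starts = bounds[interval]
    uppers = np.append(bounds[1:], np.inf)[interval]
    stops = np.minimum(uppers, fup[rep])
    last = interval == (k_per[rep] - 1)
    out["start"] = starts
    out["stop"] = stops
    out["event"] = np.where(last, rows["event"].to_numpy()[rep], 0)
    x = rows[variable].to_numpy(dtype=float)[rep]
    for k in range(n_int):
        out[f"{variable}_p{k + 1}"] = np.where(interval == k, x, 0.0)
    return out


def split_covariate_names(variable: str, n_intervals: int) -> list[str]:
    return [f"{variable}_p{k + 1}" for k in range(n_intervals)]


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostic (Schoenfeld score test)

def ph_diagnostic(fit: CoxFit, cp_rows: pd.DataFrame,
                  alpha: float = 0.05,
                  weight_col: str | None = None) -> pd.DataFrame:
    """Score test of proportional hazards on scaled Schoenfeld residuals.

    For each covariate, tests a linear trend of the scaled Schoenfeld
    residuals in event time (Grambsch–Therneau, identity time transform,
    averaged-information approximation).  Verdict is "violated" when
    p < alpha, "ok" otherwise; with fewer than two events the test is
    undefined and flagged.
    """
    start, stop, event, X, w = _prepare(cp_rows, fit.names, weight_col)
    n_events = int(event.sum())
    if n_events < 2:
        return pd.DataFrame({"covariate": fit.names, "chi2": np.nan,
                             "p": np.nan, "verdict": "undefined"})
    pl = _PartialLikelihood(start, stop, event, X, w, "breslow")
    eta = X @ fit.coef
    r = w * np.exp(np.clip(eta, -500, 500))
    S0 = pl._cum(r)
    S1 = pl._cum(r[:, None] * X)
    xbar = S1 / S0[:, None]
    # one Schoenfeld residual per event row, at that row's event time
    resid = w[pl.ev_rows, None] * (X[pl.ev_rows] - xbar[pl.ev_j])
    g = stop[pl.ev_rows]
    gc = g - g.mean()
    d = len(pl.ev_rows)
    # scaled residuals s*_k = d·cov(β̂)·r_k; slope score test per covariate:
    # T_j = [Σ(g-ḡ)s*_j]² / (d·cov_jj·Σ(g-ḡ)²)  ~  χ²(1)
    s_star = d * (resid @ fit.cov.T)
    num = (gc[:, None] * s_star).sum(axis=0) ** 2
    den = d * np.diag(fit.cov) * (gc ** 2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = num / den
    p = stats.chi2.sf(chi2, df=1)
    verdict = np.where(p < alpha, "violated", "ok")
    return pd.DataFrame({"covariate": fit.names, "chi2": chi2, "p": p,
                         "verdict": verdict})


def cp_table(cp_rows: pd.DataFrame, path) -> None:
    """Serialize counting-process rows as a delimited table."""
    cp_rows.to_csv(path, index=False)
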