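"""Detection-dynamics analysis pipeline.

Trial categorization (hit / miss / false alarm / correct rejection, with
sub-cut-off guesses dismissed), per-subject d' with a mixed-effect summary,
and time-to-event analysis of detection times with a Cox proportional
hazards model carrying a shared gamma frailty per subject:

    h(t | x, w) = w * h0(t) * exp(x beta),   w ~ Gamma(1/theta, theta)

The frailty fit maximizes the penalized partial log-likelihood in
(beta, xi = log w) with the gamma penalty (1/theta) * sum(xi - e^xi);
the frailty variance theta is profiled on the marginal likelihood obtained
by integrating the gamma frailty out of the Breslow-baseline full
likelihood.  Ties are handled with the Breslow approximation throughout.

Time origin is target onset (600 ms into the trial) with administrative
censoring at 11.4 s; catch trials never enter the survival dataset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from lifelines import KaplanMeierFitter, NelsonAalenFitter

CUTOFF_MS = {"I": 1600.0, "II": 700.0, "III": 1100.0}
TRIAL_MS = 12000.0
ONSET_MS = 600.0
HORIZON_S = (TRIAL_MS - ONSET_MS) / 1000.0

TermSpec = str | tuple[str, ...]


# ---------------------------------------------------------------------------
# Categorization and d'

def categorize(records: pd.DataFrame, experiment: str) -> pd.DataFrame:
    """Label every trial.

    hit: target trial with a response in [cut-off, 12000] ms; guess: target
    trial with a faster response (dismissed from all later analysis); miss:
    target trial without a valid response; false alarm: catch trial with
    any response; correct rejection otherwise.  Hits get
    ``time_from_onset_ms`` = response - 600.
    """
    if experiment not in CUTOFF_MS:
        raise ValueError(f"unknown experiment {experiment!r}")
    cutoff = CUTOFF_MS[experiment]
    df = records.copy()
    rt = df["response_time_ms"]
    responded = rt.notna()
    target = df["target_present"].astype(bool)
    cat = np.where(
        target,
        np.where(responded & (rt >= cutoff) & (rt <= TRIAL_MS), "hit",
                 np.where(responded & (rt < cutoff), "guess", "miss")),
        np.where(responded, "false_alarm", "correct_rejection"),
    )
    df["category"] = cat
    df["time_from_onset_ms"] = np.where(df["category"] == "hit",
                                        rt - ONSET_MS, np.nan)
    return df


def drop_first_block(records: pd.DataFrame) -> pd.DataFrame:
    """Discard block-1 trials (training-to-task carry-over); idempotent."""
    return records.loc[records["block"] != 1].copy()


def survival_data(categorized: pd.DataFrame) -> pd.DataFrame:
    """Target trials as time-to-event rows: detection time from target
    onset in seconds, misses censored at 11.4 s, guesses excluded."""
    df = categorized.loc[categorized["target_present"].astype(bool)]
    df = df.loc[df["category"].isin(["hit", "miss"])].copy()
    hit = df["category"] == "hit"
    df["time_s"] = np.where(hit, df["time_from_onset_ms"] / 1000.0, HORIZON_S)
    df["event"] = hit.astype(int)
    return df


def edge_corrected_rate(count: int, n: int) -> float:
    """Log-linear edge correction (count + 0.5) / (n + 1), strictly in (0,1)."""
    if n <= 0:
        raise ValueError("need at least one trial")
    return (count + 0.5) / (n + 1.0)


def dprime_table(categorized: pd.DataFrame,
                 condition_col: str = "uncertainty") -> pd.DataFrame:
    """Per subject x masker-uncertainty condition: edge-corrected HR and
    FAR and d' = z(HR) - z(FAR).

    d' is only defined per masker condition because false alarms exist only
    on catch trials, which carry masker but no target properties.
    """
    rows = []
    grouped = categorized.groupby(["subject_id", condition_col], sort=True)
    for (subj, cond), g in grouped:
        counts = g["category"].value_counts()
        hits, misses = counts.get("hit", 0), counts.get("miss", 0)
        fa, cr = counts.get("false_alarm", 0), counts.get("correct_rejection", 0)
        n_t, n_c = hits + misses, fa + cr
        if n_t == 0 or n_c == 0:
            rows.append(dict(subject_id=subj, **{condition_col: cond},
                             hr=np.nan, far=np.nan, dprime=np.nan,
                             n_target=n_t, n_catch=n_c, defined=False))
            continue
        hr = edge_corrected_rate(hits, n_t)
        far = edge_corrected_rate(fa, n_c)
        rows.append(dict(subject_id=subj, **{condition_col: cond},
                         hr=hr, far=far,
                         dprime=stats.norm.ppf(hr) - stats.norm.ppf(far),
                         n_target=n_t, n_catch=n_c, defined=True))
    return pd.DataFrame(rows)


@dataclass
class LmmResult:
    """Fixed-effect test from the random-intercept mixed model for d'."""

    f_stat: float
    df1: int
    df2: int
    p_value: float
    coefficients: pd.Series
    singular: bool


def lmm_dprime(dp: pd.DataFrame, factor: str = "uncertainty",
               response: str = "dprime") -> LmmResult:
    """Random-intercept linear mixed model (REML) of d' on the masker
    condition, with the between-within denominator df convention
    (df2 = N - n_subjects - df1)."""
    import statsmodels.formula.api as smf

    data = dp.dropna(subset=[response]).copy()
    if data["subject_id"].nunique() < 2 or data[factor].nunique() < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    model = smf.mixedlm(f"{response} ~ C({factor})", data,
                        groups=data["subject_id"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    names = res.model.exog_names
    idx = [i for i, n in enumerate(names) if n.startswith(f"C({factor})")]
    q = len(idx)
    L = np.zeros((q, len(names)))
    for r, i in enumerate(idx):
        L[r, i] = 1.0
    b = res.fe_params.to_numpy()
    V = res.cov_params().to_numpy()[: len(names), : len(names)]
    lb = L @ b
    try:
        f_stat = float(lb @ np.linalg.solve(L @ V @ L.T, lb)) / q
        singular = False
    except np.linalg.LinAlgError:
        f_stat, singular = np.nan, True
    df2 = int(len(data) - data["subject_id"].nunique() - q)
    p = float(stats.f.sf(f_stat, q, df2)) if not singular else np.nan
    return LmmResult(f_stat=f_stat, df1=q, df2=df2, p_value=p,
                     coefficients=res.fe_params, singular=singular)


def km_nelson_aalen(times: np.ndarray, events: np.ndarray
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Product-limit survival and Nelson-Aalen cumulative hazard step
    functions with right censoring (via lifelines)."""
    km = KaplanMeierFitter().fit(times, events)
    na = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(times, events)
    surv = km.survival_function_.reset_index()
    surv.columns = ["time", "survival"]
    cumhaz = na.cumulative_hazard_.reset_index()
    cumhaz.columns = ["time", "cumhaz"]
    return surv, cumhaz


# ---------------------------------------------------------------------------
# Design construction (treatment contrasts, lowest level as reference)

@dataclass
class DesignInfo:
    terms: list[TermSpec]
    levels: dict[str, list]
    columns: list[str]
    term_columns: dict[str, list[int]] = field(default_factory=dict)

    @property
    def factors(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            for f in ((t,) if isinstance(t, str) else t):
                if f not in seen:
                    seen.append(f)
        return seen

    def row(self, pattern: dict) -> np.ndarray:
        """Design row for one covariate pattern."""
        out = np.zeros(len(self.columns))
        col = 0
        for term in self.terms:
            factors = (term,) if isinstance(term, str) else term
            non_ref = [self.levels[f][1:] for f in factors]
            for combo in itertools.product(*non_ref):
                val = 1.0
                for f, lev in zip(factors, combo):
                    if pattern[f] != lev:
                        val = 0.0
                        break
                out[col] = val
                col += 1
        return out

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for term in self.terms:
            factors = (term,) if isinstance(term, str) else term
            non_ref = [self.levels[f][1:] for f in factors]
            for combo in itertools.product(*non_ref):
                ind = np.ones(len(df))
                for f, lev in zip(factors, combo):
                    ind = ind * (df[f].to_numpy() == lev)
                cols.append(ind)
        return np.column_stack(cols) if cols else np.empty((len(df), 0))


def build_design(df: pd.DataFrame, terms: list[TermSpec],
                 levels: dict[str, list] | None = None) -> DesignInfo:
    term_keys = [t if isinstance(t, str) else ":".join(t) for t in terms]
    if len(set(term_keys)) != len(term_keys):
        raise ValueError("duplicate terms")
    if levels is None:
        levels = {}
        for t in terms:
            for f in ((t,) if isinstance(t, str) else t):
                if f not in levels:
                    levels[f] = sorted(df[f].unique().tolist())
    columns, term_columns = [], {}
    col = 0
    for t, key in zip(terms, term_keys):
        factors = (t,) if isinstance(t, str) else t
        non_ref = [levels[f][1:] for f in factors]
        idxs = []
        for combo in itertools.product(*non_ref):
            columns.append(":".join(f"{f}[{lev}]" for f, lev in zip(factors, combo)))
            idxs.append(col)
            col += 1
        term_columns[key] = idxs
    return DesignInfo(terms=list(terms), levels=levels, columns=columns,
                      term_columns=term_columns)


# ---------------------------------------------------------------------------
# Cox partial likelihood with optional gamma frailty (Breslow ties)

class _PartialLikelihood:
    """Breslow partial log-likelihood, gradient and Hessian over sorted data."""

    def __init__(self, time: np.ndarray, event: np.ndarray, X: np.ndarray):
        order = np.argsort(time, kind="stable")
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.X = X[order]
        self.order = order
        self.n, self.p = self.X.shape
        ev_times = self.time[self.event]
        self.uniq_times, self.d = np.unique(ev_times, return_counts=True)
        # first sorted index in the risk set of each unique event time
        self.risk_start = np.searchsorted(self.time, self.uniq_times, side="left")
        self.x_event_sum = self.X[self.event].sum(axis=0)

    def _suffix(self, arr: np.ndarray) -> np.ndarray:
        return np.cumsum(arr[::-1], axis=0)[::-1]

    def loglik(self, eta_sorted: np.ndarray) -> float:
        w = np.exp(eta_sorted)
        s0 = self._suffix(w)[self.risk_start]
        return float(eta_sorted[self.event].sum() - np.sum(self.d * np.log(s0)))

    def loglik_grad_hess(self, eta_sorted: np.ndarray
                         ) -> tuple[float, np.ndarray, np.ndarray]:
        w = np.exp(eta_sorted)
        s0 = self._suffix(w)[self.risk_start]
        wX = w[:, None] * self.X
        s1 = self._suffix(wX)[self.risk_start]
        m = s1 / s0[:, None]
        # S2: suffix sums of w * x x^T
        wXX = wX[:, :, None] * self.X[:, None, :]
        s2 = self._suffix(wXX)[self.risk_start]
        ll = float(eta_sorted[self.event].sum() - np.sum(self.d * np.log(s0)))
        grad = self.x_event_sum - (self.d[:, None] * m).sum(axis=0)
        hess = -(self.d[:, None, None]
                 * (s2 / s0[:, None, None]
                    - m[:, :, None] * m[:, None, :])).sum(axis=0)
        return ll, grad, hess

    def breslow(self, eta_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unique event times and baseline hazard increments d_k / S0_k."""
        w = np.exp(eta_sorted)
        s0 = self._suffix(w)[self.risk_start]
        return self.uniq_times, self.d / s0


@dataclass
class FrailtyFit:
    """Fitted (frailty) Cox model."""

    beta: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    theta: float
    frailty: pd.Series          # xi = log w per subject (empty if no frailty)
    baseline_times: np.ndarray
    baseline_increments: np.ndarray
    loglik_penalized: float
    loglik_marginal: float
    loglik_partial_null: float  # partial loglik at beta = 0, xi = 0
    edf_fixed: float
    edf_frailty: float
    edf_by_term: dict[str, float]
    design: DesignInfo
    group_col: str | None
    n: int
    n_events: int
    score_norm: float
    converged: bool

    @property
    def baseline_cumhaz(self) -> np.ndarray:
        return np.cumsum(self.baseline_increments)

    def cumhaz_at(self, t: np.ndarray) -> np.ndarray:
        """Breslow baseline cumulative hazard H0(t) (right-continuous step)."""
        idx = np.searchsorted(self.baseline_times, np.asarray(t, float),
                              side="right")
        H = np.concatenate([[0.0], self.baseline_cumhaz])
        return H[idx]

    def linear_predictor(self, pattern: dict) -> float:
        return float(self.design.row(pattern) @ self.beta.to_numpy())


def _newton_penalized(pl: _PartialLikelihood, n_fixed: int, theta: float,
                      start: np.ndarray | None = None,
                      tol: float = 1e-9, max_iter: int = 60
                      ) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, float]:
    """Maximize partial loglik + gamma penalty on the trailing frailty
    coefficients.  Returns (params, penalized loglik, grad, hess, sup-norm)."""
    p = pl.p
    params = np.zeros(p) if start is None else start.copy()
    frail = np.arange(n_fixed, p)

    def penalty(par):
        if len(frail) == 0 or theta == 0:
            return 0.0
        xi = par[frail]
        return float((xi - np.exp(xi)).sum() / theta)

    ll_pen = None
    for _ in range(max_iter):
        eta = pl.X @ params
        ll, grad, hess = pl.loglik_grad_hess(eta)
        if len(frail) and theta > 0:
            xi = params[frail]
            grad[frail] += (1.0 - np.exp(xi)) / theta
            hess[frail, frail] -= np.exp(xi) / theta
        ll_pen = ll + penalty(params)
        sup = float(np.max(np.abs(grad))) if p else 0.0
        if sup < tol:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, -grad, rcond=None)[0]
        # step-halving on the penalized objective
        scale = 1.0
        for _ in range(30):
            cand = params + scale * step
            cand_ll = pl.loglik(pl.X @ cand) + penalty(cand)
            if cand_ll >= ll_pen - 1e-12:
                break
            scale *= 0.5
        params = params + scale * step
    eta = pl.X @ params
    ll, grad, hess = pl.loglik_grad_hess(eta)
    if len(frail) and theta > 0:
        xi = params[frail]
        grad[frail] += (1.0 - np.exp(xi)) / theta
        hess[frail, frail] -= np.exp(xi) / theta
    ll_pen = ll + penalty(params)
    sup = float(np.max(np.abs(grad))) if p else 0.0
    return params, ll_pen, grad, hess, sup


def _marginal_loglik(pl: _PartialLikelihood, params: np.ndarray,
                     n_fixed: int, theta: float,
                     subj_sorted: np.ndarray | None) -> float:
    """Gamma-frailty marginal log-likelihood at the Breslow baseline of the
    fitted (penalized) model; theta = 0 gives the plain-Cox limit."""
    eta_full = pl.X @ params
    times, inc = pl.breslow(eta_full)
    eta_fixed = pl.X[:, :n_fixed] @ params[:n_fixed]
    base = float(np.sum(pl.d * np.log(inc)) + eta_fixed[pl.event].sum())
    H = np.concatenate([[0.0], np.cumsum(inc)])
    H_at = H[np.searchsorted(times, pl.time, side="right")]
    a_row = np.exp(eta_fixed) * H_at
    if subj_sorted is None:
        return base - float(a_row.sum())
    subjects, inv = np.unique(subj_sorted, return_inverse=True)
    A = np.bincount(inv, weights=a_row, minlength=len(subjects))
    dsub = np.bincount(inv, weights=pl.event.astype(float),
                       minlength=len(subjects))
    if theta == 0:
        return base - float(A.sum())
    inv_t = 1.0 / theta
    terms = (gammaln(inv_t + dsub) - gammaln(inv_t) + dsub * math.log(theta)
             - (inv_t + dsub) * np.log1p(theta * A))
    return base + float(terms.sum())


def cox_frailty_fit(
    data: pd.DataFrame,
    terms: list[TermSpec],
    duration_col: str = "time_s",
    event_col: str = "event",
    group_col: str | None = None,
    theta: float | None = None,
    levels: dict[str, list] | None = None,
    theta_bounds: tuple[float, float] = (1e-4, 5.0),
) -> FrailtyFit:
    """Fit the (gamma-frailty) Cox PH model.

    ``theta=None`` with a ``group_col`` profiles the frailty variance on the
    marginal likelihood; ``theta=0`` or ``group_col=None`` gives the plain
    Cox fit; a positive ``theta`` is used as fixed.  Factors are coded as
    treatment contrasts against the lowest level.
    """
    design = build_design(data, terms, levels=levels)
    X_fixed = design.matrix(data)
    n_fixed = X_fixed.shape[1]
    time = data[duration_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if group_col is not None:
        subjects = sorted(data[group_col].unique().tolist())
        Z = np.column_stack([(data[group_col] == s).to_numpy(float)
                             for s in subjects])
        X = np.hstack([X_fixed, Z])
    else:
        subjects = []
        X = X_fixed
    pl = _PartialLikelihood(time, event, X)
    subj_sorted = (data[group_col].to_numpy()[pl.order]
                   if group_col is not None else None)

    cache: dict[float, tuple] = {}
    warm = {"params": None}

    def fit_at(th: float):
        if th in cache:
            return cache[th]
        if group_col is None or th == 0:
            # plain Cox: frailty pinned at zero
            pl_fixed = _PartialLikelihood(time, event, X_fixed)
            params_f, llp, grad, hess, sup = _newton_penalized(
                pl_fixed, n_fixed, 0.0,
                start=(warm["params"][:n_fixed] if warm["params"] is not None
                       else None))
            params = np.concatenate([params_f, np.zeros(len(subjects))])
            lm = _marginal_loglik(pl, params, n_fixed, 0.0, subj_sorted)
            res = (params, llp, grad, hess, sup, lm, pl_fixed)
        else:
            params, llp, grad, hess, sup = _newton_penalized(
                pl, n_fixed, th, start=warm["params"])
            lm = _marginal_loglik(pl, params, n_fixed, th, subj_sorted)
            res = (params, llp, grad, hess, sup, lm, pl)
        cache[th] = res
        warm["params"] = params
        return res

    if group_col is None:
        theta_hat = 0.0
    elif theta is not None:
        theta_hat = float(theta)
    else:
        lo, hi = np.log(theta_bounds[0]), np.log(theta_bounds[1])
        opt = optimize.minimize_scalar(
            lambda lt: -fit_at(float(np.exp(lt)))[5],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-3})
        theta_hat = float(np.exp(opt.x))
        # a boundary solution indistinguishable from no frailty collapses to 0
        if (fit_at(theta_hat)[5] <= fit_at(0.0)[5] + 1e-8
                and theta_hat <= theta_bounds[0] * 1.01):
            theta_hat = 0.0

    params, llp, grad, hess, sup, lm, pl_used = fit_at(theta_hat)
    if theta_hat == 0.0 and group_col is not None:
        # recompute hessian/edf on the fixed-effect block only
        info_pen = -fit_at(0.0)[3]
        info_unpen = info_pen
        p_all = n_fixed
    else:
        info_pen = -hess
        eta = pl_used.X @ params
        _, _, hess_unpen = pl_used.loglik_grad_hess(eta)
        info_unpen = -hess_unpen
        p_all = pl_used.p
    cov_all = np.linalg.inv(info_pen)
    edf_vec = np.diag(cov_all @ info_unpen)
    edf_fixed = float(edf_vec[:n_fixed].sum())
    edf_frailty = float(edf_vec[n_fixed:p_all].sum()) if p_all > n_fixed else 0.0
    edf_by_term = {key: float(edf_vec[idxs].sum())
                   for key, idxs in design.term_columns.items()}

    beta = pd.Series(params[:n_fixed], index=design.columns)
    se = pd.Series(np.sqrt(np.diag(cov_all)[:n_fixed]), index=design.columns)
    cov = pd.DataFrame(cov_all[:n_fixed, :n_fixed],
                       index=design.columns, columns=design.columns)
    if group_col is not None and theta_hat > 0:
        frailty = pd.Series(params[n_fixed:], index=subjects)
    else:
        frailty = pd.Series(np.zeros(len(subjects)), index=subjects)
    eta_full = pl.X @ np.concatenate(
        [params[:n_fixed],
         frailty.to_numpy() if len(subjects) else np.empty(0)])
    b_times, b_inc = pl.breslow(eta_full)
    ll0 = pl.loglik(np.zeros(pl.n))
    return FrailtyFit(
        beta=beta, se=se, cov=cov, theta=theta_hat, frailty=frailty,
        baseline_times=b_times, baseline_increments=b_inc,
        loglik_penalized=llp, loglik_marginal=lm, loglik_partial_null=ll0,
        edf_fixed=edf_fixed, edf_frailty=edf_frailty, edf_by_term=edf_by_term,
        design=design, group_col=group_col, n=pl.n,
        n_events=int(event.sum()), score_norm=sup,
        converged=sup < 1e-6,
    )


def anova_effects(
    data: pd.DataFrame,
    terms: list[TermSpec],
    duration_col: str = "time_s",
    event_col: str = "event",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Sequential (type-I) likelihood-ratio chi-square per model term.

    Nested fits add one term at a time; with a frailty group each fit
    profiles its own variance and the comparison uses the marginal
    likelihood with effective (possibly non-integer) degrees of freedom.
    A final row tests the frailty term itself against the plain Cox fit.
    """
    rows = []
    prev_ll, prev_edf = None, 0.0
    full_fit = None
    for k in range(1, len(terms) + 1):
        fit = cox_frailty_fit(data, terms[:k], duration_col=duration_col,
                              event_col=event_col, group_col=group_col)
        ll = fit.loglik_marginal if group_col else (
            fit.loglik_penalized)
        edf = fit.edf_fixed + fit.edf_frailty
        if prev_ll is None:
            # null reference: no fixed terms (frailty only if grouped)
            if group_col:
                null = cox_frailty_fit(
                    data.assign(_one=0.0), [],
                    duration_col=duration_col, event_col=event_col,
                    group_col=group_col)
                prev_ll, prev_edf = null.loglik_marginal, null.edf_frailty
            else:
                prev_ll, prev_edf = fit.loglik_partial_null, 0.0
        chi2 = 2.0 * (ll - prev_ll)
        df = edf - prev_edf
        term = terms[k - 1]
        key = term if isinstance(term, str) else ":".join(term)
        rows.append(dict(term=key, chi2=max(chi2, 0.0), df=df,
                         p=float(stats.chi2.sf(max(chi2, 0.0), max(df, 1e-9)))))
        prev_ll, prev_edf = ll, edf
        full_fit = fit
    if group_col:
        plain = cox_frailty_fit(data, terms, duration_col=duration_col,
                                event_col=event_col, group_col=group_col,
                                theta=0.0)
        chi2 = 2.0 * (full_fit.loglik_marginal - plain.loglik_marginal)
        df = max(full_fit.edf_frailty, 1e-9)
        rows.append(dict(term="frailty", chi2=max(chi2, 0.0), df=df,
                         p=float(stats.chi2.sf(max(chi2, 0.0), df))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimated marginal means, Tukey adjustment, compact letter display

@dataclass
class EmmGrid:
    """Estimated marginal means on the log-hazard scale."""

    table: pd.DataFrame          # factors..., emmean, se, asymp_lcl, asymp_ucl
    cov: np.ndarray              # covariance of the emmeans
    factors: list[str]


def emmeans_log_hazard(fit: FrailtyFit, factors: list[str]) -> EmmGrid:
    """Marginal means of the linear predictor for each cell of ``factors``,
    averaging over a balanced grid of the remaining model factors; SEs via
    the delta method.  With treatment contrasts the reference cell sits at
    exactly 0 with SE 0."""
    design = fit.design
    model_factors = design.factors
    for f in factors:
        if f not in model_factors:
            raise ValueError(f"factor {f!r} not in the model")
    others = [f for f in model_factors if f not in factors]
    cells = list(itertools.product(*[design.levels[f] for f in factors]))
    L = np.zeros((len(cells), len(design.columns)))
    for i, cell in enumerate(cells):
        base = dict(zip(factors, cell))
        grid = list(itertools.product(*[design.levels[f] for f in others]))
        rows = []
        for combo in grid:
            pattern = dict(base)
            pattern.update(dict(zip(others, combo)))
            rows.append(design.row(pattern))
        L[i] = np.mean(rows, axis=0)
    b = fit.beta.to_numpy()
    V = fit.cov.to_numpy()
    emm = L @ b
    cov = L @ V @ L.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    table = pd.DataFrame(cells, columns=factors)
    table["emmean"] = emm
    table["se"] = se
    z = stats.norm.ppf(0.975)
    table["asymp_lcl"] = emm - z * se
    table["asymp_ucl"] = emm + z * se
    return EmmGrid(table=table, cov=cov, factors=list(factors))


def tukey_pairwise(emm: EmmGrid) -> pd.DataFrame:
    """All pairwise contrasts with Tukey (studentized-range) adjusted
    p-values for a family of k estimates."""
    t = emm.table
    k = len(t)
    if k < 2:
        raise ValueError("need at least two cells")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = t["emmean"].iloc[i] - t["emmean"].iloc[j]
            var = (emm.cov[i, i] + emm.cov[j, j] - 2 * emm.cov[i, j])
            if var <= 1e-14:
                p = 1.0 if abs(diff) < 1e-12 else 0.0
                z = np.inf if p == 0.0 else 0.0
            else:
                z = abs(diff) / math.sqrt(var)
                p = float(stats.studentized_range.sf(z * math.sqrt(2.0),
                                                     k, 1e7))
            rows.append(dict(i=i, j=j, estimate=diff, z=z,
                             p_adj=min(max(p, 0.0), 1.0)))
    return pd.DataFrame(rows)


def _insert_absorb(k: int, significant: set[tuple[int, int]]) -> list[set]:
    letters: list[set] = [set(range(k))]
    for (i, j) in sorted(significant):
        new: list[set] = []
        for grp in letters:
            if i in grp and j in grp:
                new.append(grp - {i})
                new.append(grp - {j})
            else:
                new.append(grp)
        # absorb subsets
        new.sort(key=len, reverse=True)
        kept: list[set] = []
        for grp in new:
            if grp and not any(grp <= other for other in kept):
                kept.append(grp)
        letters = kept
    # every cell must carry at least one letter
    for c in range(k):
        if not any(c in grp for grp in letters):
            letters.append({c})
    return letters


def check_cld_consistency(letter_sets: list[set],
                          significant: set[tuple[int, int]], k: int) -> bool:
    """CLD contract: two cells share a letter iff their difference is not
    significant (each letter set is a clique of the non-significance graph
    and every non-significant pair is covered)."""
    for grp in letter_sets:
        for i in grp:
            for j in grp:
                if i < j and (i, j) in significant:
                    return False
    for i in range(k):
        for j in range(i + 1, k):
            if (i, j) not in significant:
                if not any(i in g and j in g for g in letter_sets):
                    return False
    return True


_SYMBOLS = "abcdefghijklmnopqrstuvwxyz0123456789"


def tukey_cld(emm: EmmGrid, alpha: float = 0.05
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compact letter display from Tukey-adjusted all-pairwise comparisons
    (insert-and-absorb).  Returns (emm table with '.group', pairwise table).
    """
    pairs = tukey_pairwise(emm)
    significant = {(int(r.i), int(r.j)) for r in pairs.itertuples()
                   if r.p_adj < alpha}
    k = len(emm.table)
    letters = _insert_absorb(k, significant)
    if not check_cld_consistency(letters, significant, k):
        raise RuntimeError("compact letter display inconsistent with "
                           "pairwise significance graph")
    letters.sort(key=lambda g: min(g))
    out = emm.table.copy()
    groups = ["" for _ in range(k)]
    for sym, grp in zip(_SYMBOLS, letters):
        for c in sorted(grp):
            groups[c] += sym
    out[".group"] = groups
    return out, pairs


# ---------------------------------------------------------------------------
# Diagnostics and predicted curves

def cox_snell(fit: FrailtyFit, data: pd.DataFrame,
              duration_col: str = "time_s", event_col: str = "event"
              ) -> pd.DataFrame:
    """Cox-Snell residuals r_i = Hhat(t_i | x_i, xi_i); for a
    well-specified model their Nelson-Aalen cumulative hazard follows the
    identity line."""
    eta = fit.design.matrix(data) @ fit.beta.to_numpy()
    if fit.group_col is not None and len(fit.frailty):
        xi = data[fit.group_col].map(fit.frailty).fillna(0.0).to_numpy()
        eta = eta + xi
    H = fit.cumhaz_at(data[duration_col].to_numpy(float))
    return pd.DataFrame({
        "residual": np.exp(eta) * H,
        "event": data[event_col].to_numpy(int),
    })


def cox_snell_slope(residuals: pd.DataFrame) -> float:
    """Through-origin slope of the Nelson-Aalen cumulative hazard of the
    residuals against the residuals themselves (1.0 = well specified)."""
    na = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(
        residuals["residual"], residuals["event"])
    ch = na.cumulative_hazard_.reset_index()
    ch.columns = ["r", "cumhaz"]
    ch = ch[ch["r"] > 0]
    return float((ch["r"] * ch["cumhaz"]).sum() / (ch["r"] ** 2).sum())


def predict_curves(
    fit: FrailtyFit,
    pattern: dict,
    t_grid: np.ndarray | None = None,
    conditional: bool = False,
    bandwidth_s: float = 0.5,
) -> pd.DataFrame:
    """Hazard h(t|x) and detection CDF F(t|x) on a time grid from target
    onset.

    By default the gamma frailty is marginalized through its Laplace
    transform (population-averaged curves); ``conditional=True`` evaluates
    at xi = 0.  The hazard smooths the Breslow increments with a Gaussian
    kernel.  Beyond the last event time the cumulative hazard is clamped
    and rows are flagged ``extrapolated``.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, HORIZON_S, 229)
    t_grid = np.asarray(t_grid, float)
    eta = fit.linear_predictor(pattern)
    H0 = fit.cumhaz_at(t_grid)
    risk = np.exp(eta)
    # kernel-smoothed baseline hazard
    tk, inc = fit.baseline_times, fit.baseline_increments
    diffs = (t_grid[:, None] - tk[None, :]) / bandwidth_s
    h0 = (np.exp(-0.5 * diffs**2) / math.sqrt(2 * math.pi) / bandwidth_s
          ) @ inc
    theta = fit.theta
    if theta > 0 and not conditional:
        S = (1.0 + theta * risk * H0) ** (-1.0 / theta)
        hazard = risk * h0 / (1.0 + theta * risk * H0)
    else:
        S = np.exp(-risk * H0)
        hazard = risk * h0
    out = pd.DataFrame({
        "time_s": t_grid,
        "cumhaz": risk * H0,
        "cdf": 1.0 - S,
        "hazard": hazard,
        "extrapolated": t_grid > (tk[-1] if len(tk) else 0.0),
    })
    return out


def flag_high_far_subjects(dp: pd.DataFrame, n_sd: float = 2.0) -> list:
    """Reproducible outlier rule standing in for by-eye screening: subjects
    whose mean FAR exceeds the across-subject mean by ``n_sd`` SDs."""
    per_subj = dp.groupby("subject_id")["far"].mean()
    bound = per_subj.mean() + n_sd * per_subj.std(ddof=1)
    return per_subj.index[per_subj > bound].tolist()
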