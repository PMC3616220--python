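"""Survival machinery: Kaplan-Meier, log-rank, Cox proportional hazards.

All three estimators are implemented here from first principles rather than
delegated, since they are the quantitative core of every downstream analysis:

* :func:`kaplan_meier` — the product-limit estimator S(t) = prod (1 - d_i/n_i)
  over event times; censored observations leave the curve flat.
* :func:`logrank_test` — the Mantel-Cox test for g >= 2 groups: at each event
  time a hypergeometric observed-minus-expected contribution, summed and
  referred to a chi-square with g - 1 degrees of freedom.
* :func:`cox_fit` — Newton-Raphson maximization of the Cox partial likelihood
  with Efron (default) or Breslow handling of tied event times.  Wald
  confidence intervals and p-values; hard failure (not a silent huge
  coefficient) on monotone likelihoods.

Follow-up time is in months throughout; the event flag is 1 for
cancer-related death and 0 for censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "NonConvergenceError",
    "records_to_frame",
    "records_from_frame",
    "kaplan_meier",
    "logrank_test",
    "cox_fit",
    "cox_interaction",
]


class NonConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (e.g. monotone likelihood)."""


@dataclass
class SurvivalRecord:
    """One subject: follow-up time (months), event flag, optional covariates."""

    sample_id: str
    time: float
    event: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"{self.sample_id}: time must be finite and >= 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1")


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "time_months": r.time, "event": r.event}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Build records from a TSV-style frame (sample_id, time_months, event, ...)."""
    covar_cols = [c for c in df.columns
                  if c not in ("sample_id", "time_months", "event")]
    return [
        SurvivalRecord(
            sample_id=str(row["sample_id"]),
            time=float(row["time_months"]),
            event=int(row["event"]),
            covariates={c: float(row[c]) for c in covar_cols},
        )
        for _, row in df.iterrows()
    ]


def kaplan_meier(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit estimate: columns time, survival, n_at_risk, n_events.

    Rows are the distinct event times in increasing order; the curve starts
    at S = 1 and only drops at event times.
    """
    if not records:
        raise ValueError("no records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    out = []
    s = 1.0
    n = len(times)
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += int(events[j])
            j += 1
        n_at_risk = n - i
        if d > 0:
            s *= 1.0 - d / n_at_risk
            out.append((t, s, n_at_risk, d))
        i = j
    return pd.DataFrame(out, columns=["time", "survival", "n_at_risk", "n_events"])


def logrank_test(groups: list[list[SurvivalRecord]]) -> tuple[float, float]:
    """Mantel-Cox log-rank test across g >= 2 groups -> (chi2, p).

    With zero events in all groups combined there is no information; by
    convention chi2 = 0 and p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    g = len(groups)
    times = [np.array([r.time for r in grp]) for grp in groups]
    events = [np.array([r.event for r in grp]) for grp in groups]
    all_event_times = np.unique(
        np.concatenate([t[e == 1] for t, e in zip(times, events)])
        if any(e.sum() for e in events) else np.array([])
    )
    if all_event_times.size == 0:
        return 0.0, 1.0

    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for t in all_event_times:
        n_j = np.array([(tj >= t).sum() for tj in times], dtype=float)
        d_j = np.array(
            [((tj == t) & (ej == 1)).sum() for tj, ej in zip(times, events)],
            dtype=float,
        )
        n_tot = n_j.sum()
        d_tot = d_j.sum()
        if n_tot <= 1 or d_tot == 0:
            continue
        O += d_j
        E += d_tot * n_j / n_tot
        frac = n_j / n_tot
        mult = d_tot * (n_tot - d_tot) / (n_tot - 1)
        V += mult * (np.diag(frac) - np.outer(frac, frac))

    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=g - 1))
    return chi2, p


@dataclass
class CoxFit:
    """Cox model fit: per-covariate estimates plus fit diagnostics."""

    covariate_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    ties: str
    n: int
    n_events: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "beta": self.beta,
                "hr": self.hr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "se": self.se,
                "wald_p": self.wald_p,
            },
            index=self.covariate_names,
        )

    def __getitem__(self, name: str) -> dict[str, float]:
        i = self.covariate_names.index(name)
        ci = self.ci95
        return {
            "beta": float(self.beta[i]),
            "hr": float(self.hr[i]),
            "ci_low": float(ci[i, 0]),
            "ci_high": float(ci[i, 1]),
            "wald_p": float(self.wald_p[i]),
        }


def _partial_loglik(beta, times, events, X, ties):
    """Log partial likelihood, score vector and information matrix.

    Samples must be pre-sorted by time ascending.  Risk-set aggregates
    S0 = sum w, S1 = sum w x, S2 = sum w x x' are suffix sums over the sorted
    order; tied event times are handled per the Efron or Breslow correction.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guards exp overflow; cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    # suffix sums: risk set for time t = all i with times[i] >= t
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))

    i = 0
    while i < n:
        t = times[i]
        j = i
        while j < n and times[j] == t:
            j += 1
        tied = [k for k in range(i, j) if events[k] == 1]
        d = len(tied)
        if d > 0:
            s0_r, s1_r, s2_r = S0[i], S1[i], S2[i]
            xs = X[tied]
            ll += float(eta[tied].sum())
            if ties == "breslow":
                fracs = np.zeros(d)
            else:  # efron
                fracs = np.arange(d) / d
            s0_d = w[tied].sum()
            s1_d = wx[tied].sum(axis=0)
            s2_d = wxx[tied].sum(axis=0)
            score += xs.sum(axis=0)
            for frac in fracs:
                denom = s0_r - frac * s0_d
                num1 = s1_r - frac * s1_d
                num2 = s2_r - frac * s2_d
                m = num1 / denom
                ll -= np.log(denom)
                score -= m
                info += num2 / denom - np.outer(m, m)
        i = j
    return ll, score, info


def cox_fit(
    records: list[SurvivalRecord],
    covariate_names: list[str],
    ties: str = "efron",
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson Cox proportional-hazards fit.

    Convergence when the maximal absolute score falls below 1e-8 or the
    log-partial-likelihood change below 1e-10 (at most *max_iter* steps).
    Monotone likelihoods (perfect separation) raise
    :class:`NonConvergenceError` rather than returning a huge coefficient.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    if not covariate_names:
        raise ValueError("need at least one covariate")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if events.sum() == 0:
        raise ValueError("need at least one event")
    try:
        X = np.array(
            [[r.covariates[c] for c in covariate_names] for r in records],
            dtype=float,
        )
    except KeyError as exc:
        raise ValueError(f"covariate missing from a record: {exc}") from None
    for k, c in enumerate(covariate_names):
        if np.ptp(X[:, k]) == 0:
            raise ValueError(f"covariate {c!r} is constant")

    order = np.argsort(times, kind="stable")
    times, events, X = times[order], events[order], X[order]
    # center covariates for numerical stability; beta is unchanged
    X = X - X.mean(axis=0)
    x_sd = X.std(axis=0)

    p = X.shape[1]
    beta = np.zeros(p)
    ll, score, info = _partial_loglik(beta, times, events, X, ties)
    ll0 = ll
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise NonConvergenceError("singular information matrix") from None
        # step-halving if the likelihood does not improve
        new_beta = beta + step
        new_ll, new_score, new_info = _partial_loglik(
            new_beta, times, events, X, ties
        )
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _partial_loglik(
                new_beta, times, events, X, ties
            )
            halvings += 1
        delta_ll = new_ll - ll
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(beta) * x_sd) > 50:
            raise NonConvergenceError(
                "coefficient diverging: likely monotone likelihood "
                "(perfect separation)"
            )
        if np.max(np.abs(score)) < 1e-8 or abs(delta_ll) < 1e-10:
            converged = True
            break
    if not converged:
        raise NonConvergenceError(f"no convergence in {max_iter} iterations")
    if np.max(np.abs(beta) * x_sd) > 10:
        # likelihood flattened out at an implausibly extreme coefficient
        # (> 10 per covariate SD, HR > e^10): monotone likelihood, not a
        # real optimum
        raise NonConvergenceError(
            "monotone likelihood (perfect separation): coefficient "
            "escaped to an extreme value"
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        covariate_names=list(covariate_names),
        beta=beta,
        se=se,
        loglik=float(ll),
        loglik_null=float(ll0),
        converged=True,
        ties=ties,
        n=len(records),
        n_events=int(events.sum()),
    )


def cox_interaction(
    records: list[SurvivalRecord], a: str, b: str, ties: str = "efron"
) -> CoxFit:
    """Fit a Cox model with main effects a, b and their product term a:b."""
    inter = f"{a}:{b}"
    augmented = []
    for r in records:
        cov = dict(r.covariates)
        cov[inter] = cov[a] * cov[b]
        augmented.append(
            SurvivalRecord(r.sample_id, r.time, r.event, covariates=cov)
        )
    prod = np.array([r.covariates[inter] for r in augmented])
    if np.ptp(prod) == 0:
        raise ValueError(f"interaction column {inter!r} is constant")
    return cox_fit(augmented, [a, b, inter], ties=ties)
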