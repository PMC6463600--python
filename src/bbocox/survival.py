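"""Survival-analysis core: Cox proportional hazards, Harrell's C, Kaplan-Meier,
log-rank and Pearson chi-squared.

The Cox fitter maximises the Breslow (default) or Efron approximation of the
partial likelihood by Newton-Raphson with step halving.  Risk-set sums are
computed on a cohort pre-sorted by descending follow-up time, so repeated fits
on covariate subsets of one cohort (the hot path of the subset search) share
the sorting and grouping work through :class:`CoxData`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxData",
    "CoxFit",
    "ConcordanceResult",
    "KMCurve",
    "TestResult",
    "DegenerateDesignError",
    "ConcordanceUndefinedError",
    "fit_cox",
    "null_log_partial_likelihood",
    "concordance",
    "km_curve",
    "logrank_test",
    "chisq_test",
]

Z_95 = 1.959964  # two-sided 95% normal quantile

RESERVED_COLUMNS = ("patient_id", "time", "event")


class DegenerateDesignError(ValueError):
    """Design matrix unusable: constant or collinear covariate columns."""


class ConcordanceUndefinedError(ValueError):
    """No usable pairs; carries the (all-zero numerator) counts in ``result``."""

    def __init__(self, message: str, result: "ConcordanceResult"):
        super().__init__(message)
        self.result = result


def covariate_columns(cohort: pd.DataFrame) -> list[str]:
    """All cohort columns that are covariates (everything but id/time/event)."""
    return [c for c in cohort.columns if c not in RESERVED_COLUMNS]


@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    concordant: int
    discordant: int
    tied_predictions: int
    usable_pairs: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray


@dataclass
class CoxFit:
    subset: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray  # shape (d, 2)
    p_wald: np.ndarray
    log_partial_likelihood: float
    linear_predictor: np.ndarray  # in original row order
    converged: bool
    diverged: bool
    n_iterations: int
    ties_method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": list(self.subset),
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci95[:, 0],
                "ci_high": self.ci95[:, 1],
                "p": self.p_wald,
            }
        )


class CoxData:
    """Pre-sorted survival data shared across subset fits on one cohort.

    Sorting descending by time makes every risk set a prefix of the sorted
    arrays, so Breslow sums reduce to cumulative sums evaluated at the end of
    each tied-time segment.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, X: np.ndarray,
                 names: tuple[str, ...]):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        X = np.asarray(X, dtype=float)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be equal-length vectors")
        if np.any(time <= 0):
            raise ValueError("all times must be positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event must be 0/1")
        self.n = time.size
        self.names = tuple(names)
        # stable sort, descending time
        self.order = np.argsort(-time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order]
        self.X = np.ascontiguousarray(X[self.order])
        self.inverse_order = np.empty(self.n, dtype=int)
        self.inverse_order[self.order] = np.arange(self.n)

        # tied-time segments (descending): segment ends are risk-set sizes - 1
        change = np.nonzero(np.diff(self.time))[0]
        seg_ends = np.concatenate([change, [self.n - 1]])
        seg_starts = np.concatenate([[0], change + 1])
        # events per segment
        ev_cum = np.concatenate([[0], np.cumsum(self.event)])
        d_seg = ev_cum[seg_ends + 1] - ev_cum[seg_starts]
        keep = d_seg > 0
        self.seg_starts = seg_starts[keep]   # per event time, descending time
        self.seg_ends = seg_ends[keep]
        self.d_k = d_seg[keep].astype(float)
        self.n_event_times = self.seg_ends.size
        # reduceat boundaries for prefix sums at segment ends; an extra
        # boundary truncates the tail of subjects below the last event time
        if self.n_event_times and self.seg_ends[-1] + 1 < self.n:
            self._red_idx = np.concatenate([[0], self.seg_ends + 1])
            self._n_red_segments = self.n_event_times + 1
        else:
            self._red_idx = np.concatenate([[0], self.seg_ends[:-1] + 1])
            self._n_red_segments = self.n_event_times
        # event rows grouped by segment, for Efron tie sums
        self._event_rows = np.nonzero(self.event)[0]

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame,
                    columns: list[str] | None = None) -> "CoxData":
        cols = columns if columns is not None else covariate_columns(cohort)
        return cls(
            cohort["time"].to_numpy(),
            cohort["event"].to_numpy(),
            cohort[list(cols)].to_numpy(dtype=float),
            tuple(cols),
        )

    def subset_index(self, subset: tuple[str, ...]) -> np.ndarray:
        lookup = {name: j for j, name in enumerate(self.names)}
        try:
            return np.array([lookup[s] for s in subset], dtype=int)
        except KeyError as e:  # pragma: no cover - caller contract
            raise KeyError(f"unknown covariate {e.args[0]!r}") from None

    def prefix_at_events(self, values: np.ndarray) -> np.ndarray:
        """Prefix sums of per-subject values at each event-time risk set."""
        flat = values.reshape(self.n, -1)
        seg = np.add.reduceat(flat, self._red_idx, axis=0)
        out = np.cumsum(seg[: self.n_event_times], axis=0)
        return out.reshape((self.n_event_times,) + values.shape[1:])


def _breslow_ll_grad_hess(data: CoxData, Xs: np.ndarray, beta: np.ndarray):
    eta = Xs @ beta
    eta -= eta.max()  # guard exp overflow; cancels in ratios and is added back
    w = np.exp(eta)
    s0 = data.prefix_at_events(w)
    xw = Xs * w[:, None]
    s1 = data.prefix_at_events(xw)
    outer = np.einsum("ni,nj->nij", Xs, xw)
    s2 = data.prefix_at_events(outer)

    ev = data.event.astype(bool)
    sum_x_events = Xs[ev].sum(axis=0)

    ll = eta[ev].sum() - float(data.d_k @ np.log(s0))
    mean1 = s1 / s0[:, None]
    grad = sum_x_events - data.d_k @ mean1
    h_k = s2 / s0[:, None, None] - np.einsum("ki,kj->kij", mean1, mean1)
    hess = -np.einsum("k,kij->ij", data.d_k, h_k)
    return ll, grad, hess


def _efron_ll_grad_hess(data: CoxData, Xs: np.ndarray, beta: np.ndarray):
    eta = Xs @ beta
    eta -= eta.max()
    w = np.exp(eta)
    s0 = data.prefix_at_events(w)
    xw = Xs * w[:, None]
    s1 = data.prefix_at_events(xw)
    outer = np.einsum("ni,nj->nij", Xs, xw)
    s2 = data.prefix_at_events(outer)

    d = Xs.shape[1]
    ll = 0.0
    grad = np.zeros(d)
    hess = np.zeros((d, d))
    ev_mask = data.event.astype(bool)
    for k in range(data.n_event_times):
        rows = np.arange(data.seg_starts[k], data.seg_ends[k] + 1)
        erows = rows[ev_mask[rows]]
        dk = erows.size
        t0 = w[erows].sum()
        t1 = xw[erows].sum(axis=0)
        t2 = outer[erows].sum(axis=0)
        ll += eta[erows].sum()
        grad += Xs[erows].sum(axis=0)
        frac = np.arange(dk) / dk
        for f in frac:
            a0 = s0[k] - f * t0
            a1 = s1[k] - f * t1
            a2 = s2[k] - f * t2
            ll -= np.log(a0)
            m1 = a1 / a0
            grad -= m1
            hess -= a2 / a0 - np.outer(m1, m1)
    return ll, grad, hess


_TIES_KERNELS = {"breslow": _breslow_ll_grad_hess, "efron": _efron_ll_grad_hess}

DIVERGENCE_BOUND = 15.0


def fit_cox(
    cohort: pd.DataFrame | CoxData,
    subset: list[str] | tuple[str, ...],
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 25,
) -> CoxFit:
    """Fit a Cox proportional-hazards model on the named covariate subset.

    Newton-Raphson on the Breslow (default) or Efron partial likelihood;
    step-halving whenever a full step decreases the likelihood.  Variances
    come from the inverse observed information.  Monotone-likelihood
    divergence (|beta| exceeding ``DIVERGENCE_BOUND``) and non-convergence
    are flagged on the returned fit rather than raised; a constant covariate
    or singular information is a :class:`DegenerateDesignError`.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("empty covariate subset; use the null-model path")
    if ties not in _TIES_KERNELS:
        raise ValueError(f"unknown ties method {ties!r}")
    data = cohort if isinstance(cohort, CoxData) else CoxData.from_cohort(
        cohort, list(subset))
    idx = data.subset_index(subset)
    Xs = np.ascontiguousarray(data.X[:, idx])

    spans = Xs.max(axis=0) - Xs.min(axis=0)
    if np.any(spans == 0):
        bad = [subset[j] for j in np.nonzero(spans == 0)[0]]
        raise DegenerateDesignError(f"constant covariate(s) in subset: {bad}")
    if data.d_k.size == 0:
        raise DegenerateDesignError("cohort has no events")

    kernel = _TIES_KERNELS[ties]
    d = len(subset)
    beta = np.zeros(d)
    ll, grad, hess = kernel(data, Xs, beta)
    converged = False
    diverged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise DegenerateDesignError(
                f"singular information matrix for subset {list(subset)} "
                "(collinear covariates)") from None
        new_beta = beta + step
        new_ll, new_grad, new_hess = kernel(data, Xs, new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess = kernel(data, Xs, new_beta)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > DIVERGENCE_BOUND:
            diverged = True
            break
    else:
        n_iter = max_iter
    if not diverged and np.max(np.abs(grad)) < tol:
        converged = True

    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(d, np.nan)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        ci95 = np.column_stack(
            [np.exp(beta - Z_95 * se), np.exp(beta + Z_95 * se)])
    eta_sorted = Xs @ beta
    return CoxFit(
        subset=subset,
        beta=beta,
        se=se,
        hr=np.exp(beta),
        ci95=ci95,
        p_wald=p,
        log_partial_likelihood=float(ll),
        linear_predictor=eta_sorted[data.inverse_order],
        converged=converged,
        diverged=diverged,
        n_iterations=n_iter,
        ties_method=ties,
    )


def null_log_partial_likelihood(data: CoxData | pd.DataFrame,
                                ties: str = "breslow") -> float:
    """Breslow/Efron log partial likelihood of the null model (eta = 0)."""
    if isinstance(data, pd.DataFrame):
        data = CoxData.from_cohort(data)
    sizes = (data.seg_ends + 1).astype(float)  # risk-set sizes
    if ties == "breslow":
        return float(-(data.d_k * np.log(sizes)).sum())
    # Efron at eta = 0: tie-group weight equals the event count d_k
    ll = 0.0
    for k in range(data.n_event_times):
        dk = int(data.d_k[k])
        ll -= sum(np.log(sizes[k] - l) for l in range(dk))
    return float(ll)


def concordance(
    time: np.ndarray,
    event: np.ndarray,
    risk: np.ndarray,
    mode: str = "harrell",
) -> ConcordanceResult:
    """Harrell's concordance between risk scores and censored survival times.

    A pair (i, j) is usable when the observed times differ and the member
    with the smaller time experienced the event; it is concordant when that
    member also carries the larger risk score.  ``mode="harrell"`` credits
    risk ties 0.5, ``mode="strict"`` credits them 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    if not (time.shape == event.shape == risk.shape):
        raise ValueError("time, event and risk must have equal length")
    if mode not in ("harrell", "strict"):
        raise ValueError(f"unknown mode {mode!r}")

    ev = np.nonzero(event == 1)[0]
    # broadcast events against all subjects: pair (i, j) usable iff t_j > t_i
    later = time[None, :] > time[ev, None]
    usable = int(later.sum())
    ri = risk[ev, None]
    rj = risk[None, :]
    concordant = int(((ri > rj) & later).sum())
    discordant = int(((ri < rj) & later).sum())
    tied = usable - concordant - discordant
    result_counts = dict(concordant=concordant, discordant=discordant,
                         tied_predictions=tied, usable_pairs=usable)
    if usable == 0:
        raise ConcordanceUndefinedError(
            "no usable pairs (no events, or all times tied)",
            ConcordanceResult(c=float("nan"), **result_counts),
        )
    credit = concordant + (0.5 * tied if mode == "harrell" else 0.0)
    return ConcordanceResult(c=credit / usable, **result_counts)


def km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator over distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty input")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, start = np.unique(t, return_index=True)
    counts = np.diff(np.concatenate([start, [t.size]]))
    ev_cum = np.concatenate([[0], np.cumsum(e)])
    d = ev_cum[start + counts] - ev_cum[start]
    n_at_risk = t.size - start  # subjects with time >= uniq
    keep = d > 0
    times = uniq[keep]
    d = d[keep]
    at_risk = n_at_risk[keep]
    survival = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=times, survival=survival, at_risk=at_risk, n_events=d)


def logrank_test(time: np.ndarray, event: np.ndarray,
                 group: np.ndarray) -> TestResult:
    """k-group log-rank test (hypergeometric variance), df = k - 1."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels, gidx = np.unique(group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")

    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_j = float(at_risk.sum())
        d_j = float(((time == t) & (event == 1)).sum())
        n_gj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(gidx[(time == t) & (event == 1)], minlength=k).astype(float)
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            c = d_j * (n_j - d_j) / (n_j - 1.0)
            frac = n_gj / n_j
            V += c * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    return TestResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def chisq_test(table: np.ndarray) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate table: zero row or column margin")
    expected = np.outer(rows, cols) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return TestResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))
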