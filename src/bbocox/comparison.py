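"""Model ladder: univariate Cox fits, fully adjusted model, stepwise
selection at several entry levels, and the BBO-selected model, all compared
by in-sample Harrell's C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bbo import BBORun
from .survival import (
    ConcordanceUndefinedError,
    CoxData,
    CoxFit,
    DegenerateDesignError,
    concordance,
    covariate_columns,
    fit_cox,
    null_log_partial_likelihood,
)

__all__ = [
    "StepwiseResult",
    "ComparisonReport",
    "univariate_table",
    "fit_full_model",
    "stepwise_select",
    "model_c_statistic",
    "compare_models",
]

STEPWISE_ALPHAS = (0.05, 0.1, 0.2)


def univariate_table(cohort: pd.DataFrame, ties: str = "breslow") -> pd.DataFrame:
    """One single-covariate Cox fit per covariate: HR, 95% CI, Wald p.

    Constant covariates are kept in the table but flagged and left unfitted.
    """
    data = CoxData.from_cohort(cohort)
    rows = []
    for name in data.names:
        row: dict = {"covariate": name, "flag": ""}
        try:
            fit = fit_cox(data, (name,), ties=ties)
            row.update(
                beta=fit.beta[0], se=fit.se[0], hr=fit.hr[0],
                ci_low=fit.ci95[0, 0], ci_high=fit.ci95[0, 1],
                p=fit.p_wald[0],
            )
            if fit.diverged:
                row["flag"] = "diverged"
            elif not fit.converged:
                row["flag"] = "not_converged"
        except DegenerateDesignError:
            row.update(beta=np.nan, se=np.nan, hr=np.nan,
                       ci_low=np.nan, ci_high=np.nan, p=np.nan,
                       flag="constant")
        rows.append(row)
    return pd.DataFrame(rows)


def fit_full_model(cohort: pd.DataFrame, ties: str = "breslow") -> CoxFit:
    """Fully adjusted Cox model on every covariate column."""
    data = CoxData.from_cohort(cohort)
    spans = data.X.max(axis=0) - data.X.min(axis=0)
    constant = [n for n, s in zip(data.names, spans) if s == 0]
    if constant:
        raise DegenerateDesignError(f"constant covariate column(s): {constant}")
    centered = data.X - data.X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < len(data.names):
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(centered, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [data.names[j] for j in piv[diag < diag[0] * 1e-10]]
        raise DegenerateDesignError(f"collinear covariate column(s): {bad}")
    return fit_cox(data, data.names, ties=ties)


@dataclass
class StepwiseResult:
    alpha: float
    selected: tuple[str, ...]
    trace: list[tuple[str, str, float]]  # (action, covariate, p-value)
    final_fit: CoxFit | None  # None when nothing was selected


def stepwise_select(cohort: pd.DataFrame, alpha: float,
                    ties: str = "breslow",
                    entry_test: str = "lr") -> StepwiseResult:
    """Stepwise Cox selection with equal entry and stay thresholds.

    Forward step: among covariates not yet in the model, add the one with
    the smallest entry p-value (likelihood-ratio against the current model
    by default, ``entry_test="wald"`` for the Wald z of the candidate in
    the augmented fit) if it is <= alpha.  Backward step: repeatedly drop
    the worst included covariate whose Wald p exceeds alpha.  Iterate to a
    fixed point; deterministic for a given cohort.

    Because the entry and stay tests differ, a covariate can qualify for
    entry yet fail to stay; selection therefore stops (as in classical
    stepwise implementations) when the variable just entered is removed
    again, and a visited-state guard ends any longer add/remove cycle at
    its first repetition.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if entry_test not in ("lr", "wald"):
        raise ValueError(f"unknown entry_test {entry_test!r}")
    data = CoxData.from_cohort(cohort)
    candidates = [n for n in data.names
                  if np.ptp(data.X[:, data.subset_index((n,))[0]]) > 0]
    selected: list[str] = []
    trace: list[tuple[str, str, float]] = []
    current_ll = null_log_partial_likelihood(data, ties=ties)
    current_fit: CoxFit | None = None
    seen_states: set[frozenset] = {frozenset()}

    while True:
        changed = False
        just_added: str | None = None
        # forward
        best_p, best_name, best_fit = np.inf, None, None
        for name in candidates:
            if name in selected:
                continue
            try:
                fit = fit_cox(data, tuple(selected) + (name,), ties=ties)
            except DegenerateDesignError:
                continue
            if fit.diverged or not fit.converged:
                continue
            if entry_test == "lr":
                lr = 2.0 * (fit.log_partial_likelihood - current_ll)
                p = float(stats.chi2.sf(max(lr, 0.0), 1))
            else:
                p = float(fit.p_wald[-1])
            if p < best_p:
                best_p, best_name, best_fit = p, name, fit
        if best_name is not None and best_p <= alpha:
            selected.append(best_name)
            trace.append(("add", best_name, best_p))
            current_fit = best_fit
            current_ll = best_fit.log_partial_likelihood
            just_added = best_name
            changed = True
        # backward: drop worst Wald p > alpha, repeatedly
        stop = False
        while selected:
            fit = (current_fit if current_fit is not None
                   and tuple(current_fit.subset) == tuple(selected)
                   else fit_cox(data, tuple(selected), ties=ties))
            current_fit = fit
            current_ll = fit.log_partial_likelihood
            worst = int(np.argmax(fit.p_wald))
            if fit.p_wald[worst] > alpha:
                name = fit.subset[worst]
                selected.remove(name)
                trace.append(("remove", name, float(fit.p_wald[worst])))
                current_fit = None
                current_ll = (null_log_partial_likelihood(data, ties=ties)
                              if not selected else
                              fit_cox(data, tuple(selected),
                                      ties=ties).log_partial_likelihood)
                changed = True
                if name == just_added:
                    stop = True  # the entering variable failed to stay
                    break
            else:
                break
        state = frozenset(selected)
        if state in seen_states:
            stop = True
        seen_states.add(state)
        if stop or not changed:
            break

    # final pure-removal sweep so the returned model satisfies its own stay
    # criterion even when selection stopped on an entry/removal cycle
    while selected:
        fit = fit_cox(data, tuple(selected), ties=ties)
        worst = int(np.argmax(fit.p_wald))
        if fit.p_wald[worst] <= alpha:
            break
        name = fit.subset[worst]
        selected.remove(name)
        trace.append(("remove", name, float(fit.p_wald[worst])))

    final_fit = (fit_cox(data, tuple(selected), ties=ties)
                 if selected else None)
    return StepwiseResult(alpha=alpha, selected=tuple(selected),
                          trace=trace, final_fit=final_fit)


def model_c_statistic(cohort: pd.DataFrame, fit: CoxFit | None,
                      mode: str = "harrell") -> float:
    """In-sample C of a fitted model's linear predictor (0.5 for the empty
    model, by the chance-discrimination convention)."""
    if fit is None:
        return 0.5
    try:
        return concordance(cohort["time"].to_numpy(),
                           cohort["event"].to_numpy(),
                           fit.linear_predictor, mode=mode).c
    except ConcordanceUndefinedError:
        return float("nan")


@dataclass
class ComparisonReport:
    models: dict[str, dict] = field(default_factory=dict)
    # each entry: {"selected": [...], "c": float, "table": DataFrame-as-records}

    def to_frame(self) -> pd.DataFrame:
        """Publication-shaped table: one block of columns per model, the
        C-statistic row first, then HR and p per covariate."""
        all_covs: list[str] = []
        for m in self.models.values():
            for c in m["selected"]:
                if c not in all_covs:
                    all_covs.append(c)
        rows = [{"row": "c_statistic",
                 **{label: m["c"] for label, m in self.models.items()}}]
        for cov in all_covs:
            row: dict = {"row": cov}
            for label, m in self.models.items():
                rec = next((r for r in m["table"] if r["covariate"] == cov), None)
                row[f"{label}"] = rec["hr"] if rec else np.nan
                row[f"{label}_p"] = rec["p"] if rec else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(self.models, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls(models=json.loads(text))


def _fit_record(fit: CoxFit | None) -> list[dict]:
    if fit is None:
        return []
    out = []
    for j, name in enumerate(fit.subset):
        out.append({
            "covariate": name,
            "beta": float(fit.beta[j]),
            "hr": float(fit.hr[j]),
            "ci_low": float(fit.ci95[j, 0]),
            "ci_high": float(fit.ci95[j, 1]),
            "p": float(fit.p_wald[j]),
        })
    return out


def compare_models(cohort: pd.DataFrame, bbo_run: BBORun,
                   alphas: tuple[float, ...] = STEPWISE_ALPHAS,
                   ties: str = "breslow") -> ComparisonReport:
    """Fit the full, stepwise (one per alpha) and BBO-selected models on one
    cohort and report each model's covariates, HR table and in-sample C."""
    report = ComparisonReport()

    def add(label: str, fit: CoxFit | None, selected: tuple[str, ...],
            error: str | None = None):
        report.models[label] = {
            "selected": list(selected),
            "c": model_c_statistic(cohort, fit),
            "table": _fit_record(fit),
            **({"error": error} if error else {}),
        }

    try:
        full = fit_full_model(cohort, ties=ties)
        add("full", full, full.subset)
    except DegenerateDesignError as e:
        add("full", None, (), error=str(e))

    for alpha in alphas:
        sw = stepwise_select(cohort, alpha, ties=ties)
        add(f"stepwise_{alpha:g}", sw.final_fit, sw.selected)

    if bbo_run.best_subset:
        try:
            bbo_fit = fit_cox(cohort, bbo_run.best_subset, ties=ties)
        except DegenerateDesignError as e:
            bbo_fit = None
            add("bbo", None, bbo_run.best_subset, error=str(e))
        else:
            add("bbo", bbo_fit, bbo_run.best_subset)
    else:
        add("bbo", None, ())
    return report
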