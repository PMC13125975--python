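"""Tuning-parameter search, predictive evaluation and selection-rate metrics.

The tuning parameters (lambda_loc, lambda_disp) are chosen on a two-dimensional grid
(given on the log scale) by maximizing the predictive log-likelihood of a validation
sample, with adaptive weights computed once from the unpenalized training fit and
warm starts along the grid. Predictive performance is summarized by the predictive
deviance and the ranked probability score (RPS); simulation experiments are
summarized by per-covariate selection rates (TPR/FNR/TNR/FPR) and fusion recovery.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ClusteredOrdinalData
from .likelihood import QuadratureConfig, marginal_category_probabilities, total_log_likelihood
from .penalized import (
    FitControl,
    FitResult,
    PenaltyConfig,
    SelectionSets,
    adaptive_weights,
    fit_penalized,
    fit_unpenalized,
)


def predictive_log_likelihood(fit: FitResult, newdata: ClusteredOrdinalData,
                              quad: QuadratureConfig | None = None) -> float:
    """Marginal log-likelihood of new data at the fitted parameters.

    Clusters in ``newdata`` are integrated over the random-effect distribution
    whether or not they appeared in training (marginal, not EB-conditional,
    prediction).
    """
    if len(newdata.x_columns) != len(fit.x_columns) or len(newdata.z_columns) != len(fit.z_columns):
        raise ValueError("newdata design does not match the fitted model's schema")
    return total_log_likelihood(newdata, fit.spec, fit.params, quad)


def cluster_predictive_log_likelihood(fit: FitResult, newdata: ClusteredOrdinalData,
                                      quad: QuadratureConfig | None = None) -> np.ndarray:
    """Per-cluster marginal log-likelihoods of new data at the fitted parameters."""
    from .likelihood import LoglikEvaluator, _params_arrays

    ev = LoglikEvaluator(newdata, fit.spec, quad or QuadratureConfig())
    _, thr, beta, alpha, Sigma = _params_arrays(newdata, fit.spec, fit.params)
    return ev.cluster_loglik(thr, beta, alpha, Sigma)[0]


def predictive_deviance(fit: FitResult, newdata: ClusteredOrdinalData,
                        quad: QuadratureConfig | None = None) -> float:
    """Minus two times the predictive log-likelihood."""
    return -2.0 * predictive_log_likelihood(fit, newdata, quad)


def ranked_probability_score(fit: FitResult, newdata: ClusteredOrdinalData,
                             quad: QuadratureConfig | None = None,
                             n_points: int = 15) -> float:
    """Average ranked probability score of the fitted model on new data.

    For each observation the predicted cumulative distribution (marginal over the
    random effects) is compared with the observed step function:
    RPS = mean_ij sum_r (P(y_ij <= r) - I(y_ij <= r))^2. Lower is better; the final
    summand (r = k) is always zero and is included as written.
    """
    probs = marginal_category_probabilities(fit.spec, fit.params, newdata.X, newdata.Z, n_points)
    cum = np.cumsum(probs, axis=1)
    k = fit.spec.k
    obs = (newdata.y[:, None] <= np.arange(1, k + 1)[None, :]).astype(float)
    return float(((cum - obs) ** 2).sum(axis=1).mean())


@dataclass
class TuningResult:
    """Grid-search outcome: per-point predictive log-likelihoods and the chosen pair."""

    grid: list            # (log_lambda_loc, log_lambda_disp) pairs
    predictive_loglik: np.ndarray
    best_pair: tuple      # (lambda_loc, lambda_disp) on the natural scale
    best_fit: FitResult
    fits: list            # per-grid-point FitResult (selection populated)
    unpenalized: FitResult
    penalty: PenaltyConfig
    argmax_pair: tuple | None = None  # pair attaining the maximum predictive loglik


def tune_grid(
    train: ClusteredOrdinalData,
    valid: ClusteredOrdinalData,
    spec,
    quad: QuadratureConfig | None = None,
    log_lambda_grid: Sequence[tuple] | None = None,
    penalty_template: PenaltyConfig | None = None,
    unpenalized: FitResult | None = None,
    control: FitControl | None = None,
    selection_rule: str = "within_se",
    se_factor: float = 1.0,
    prune: bool = True,
) -> TuningResult:
    """Two-dimensional tuning-parameter search by predictive log-likelihood.

    ``log_lambda_grid`` lists (log lambda_loc, log lambda_disp) pairs; the default is
    the integer grid {-10,...,-1} x {-10,...,-1}. Adaptive weights come from the
    unpenalized training fit (computed here unless passed in) and are reused across
    the grid; fits are warm-started from the previous grid point.

    The returned pair depends on ``selection_rule``:

    ``"within_se"`` (default)
        the sparsest pair (largest lambda_loc + lambda_disp, then largest
        lambda_disp) whose predictive log-likelihood deficit relative to the best
        grid point is within ``se_factor`` standard errors, where the SE of the
        deficit is estimated from the per-cluster log-likelihood differences. This
        is the one-standard-error rule familiar from penalized regression; the
        plain argmax is noise-dominated here because dropping a whole truly-inert
        dispersion block changes the validation log-likelihood by far less than its
        sampling error.
    ``"max"``
        the argmax, with exact ties broken toward the sparser pair.
    """
    quad = quad or QuadratureConfig()
    control = control or FitControl()
    if log_lambda_grid is None:
        log_lambda_grid = [(a, b) for a in range(-10, 0) for b in range(-10, 0)]
    log_lambda_grid = [tuple(gp) for gp in log_lambda_grid]
    if selection_rule not in ("within_se", "max"):
        raise ValueError("selection_rule must be 'within_se' or 'max'")
    if unpenalized is None:
        unpenalized = fit_unpenalized(train, spec, quad, control=control, compute_se=False)
    if penalty_template is None:
        penalty_template = adaptive_weights(unpenalized)
    ordered = sorted(range(len(log_lambda_grid)), key=lambda i: log_lambda_grid[i])
    fits: list = [None] * len(log_lambda_grid)
    n_grid = len(log_lambda_grid)
    pred = np.full(n_grid, -np.inf)
    cluster_pred = np.full((n_grid, valid.n_clusters), -np.inf)
    prev_loc_start = unpenalized.params  # warm start entering each lambda_loc block
    prev = unpenalized.params
    prev_ll = None
    saturated = False  # within the current lambda_loc row: everything penalized is zero
    last_i = None
    for i in ordered:
        ll_l, ll_d = log_lambda_grid[i]
        if prev_ll is not None and ll_l != prev_ll:
            prev = prev_loc_start  # new lambda_loc row: restart from the row head
            saturated = False
        if saturated and last_i is not None:
            # larger lambda_disp cannot change an already fully shrunk fit
            fits[i] = fits[last_i]
            cluster_pred[i] = cluster_pred[last_i]
            pred[i] = pred[last_i]
            if prev_ll is None or ll_l != prev_ll:
                prev_loc_start = fits[i].params
                prev_ll = ll_l
            continue
        config = penalty_template.with_lambdas(np.exp(ll_l), np.exp(ll_d))
        fit = fit_penalized(train, spec, quad, config, init=prev, control=control)
        fits[i] = fit
        last_i = i
        if fit.convergence["success"] and np.isfinite(fit.loglik):
            cl = cluster_predictive_log_likelihood(fit, valid, quad)
            cluster_pred[i] = cl
            pred[i] = cl.sum()
        else:
            warnings.warn(f"grid point {log_lambda_grid[i]} did not converge; excluded from argmax")
        if prune:
            # once the whole dispersion component is shrunk to zero, larger
            # lambda_disp at this lambda_loc cannot change the fit or selection
            saturated = bool(np.all(np.abs(fit.params.alpha) < penalty_template.zero_tolerance))
        if prev_ll is None or ll_l != prev_ll:
            prev_loc_start = fit.params
            prev_ll = ll_l
        prev = fit.params

    def sparsity(i):
        return (log_lambda_grid[i][0] + log_lambda_grid[i][1], log_lambda_grid[i][1])

    best_val = pred.max()
    argmax_i = max((i for i in range(n_grid) if pred[i] >= best_val - 1e-9), key=sparsity)
    if selection_rule == "max":
        best_i = argmax_i
    else:
        n = valid.n_clusters
        eligible = []
        for i in range(n_grid):
            if not np.isfinite(pred[i]):
                continue
            d = cluster_pred[argmax_i] - cluster_pred[i]
            se = float(np.std(d, ddof=1) * np.sqrt(n)) if n > 1 else 0.0
            if d.sum() <= se_factor * se + 1e-9:
                eligible.append(i)
        best_i = max(eligible, key=sparsity)
    return TuningResult(
        grid=list(log_lambda_grid), predictive_loglik=pred,
        best_pair=(float(np.exp(log_lambda_grid[best_i][0])), float(np.exp(log_lambda_grid[best_i][1]))),
        best_fit=fits[best_i], fits=fits, unpenalized=unpenalized, penalty=penalty_template,
        argmax_pair=(float(np.exp(log_lambda_grid[argmax_i][0])), float(np.exp(log_lambda_grid[argmax_i][1]))),
    )


def coefficient_path(
    train: ClusteredOrdinalData,
    spec,
    quad: QuadratureConfig | None = None,
    vary: str = "location",
    fixed_other: float = 0.0,
    grid: Sequence[float] | None = None,
    penalty_template: PenaltyConfig | None = None,
    unpenalized: FitResult | None = None,
    control: FitControl | None = None,
) -> pd.DataFrame:
    """Coefficient paths over one penalty parameter (the other held fixed).

    ``grid`` lists lambda values on the natural scale, fitted in ascending order with
    warm starts from the unpenalized solution. Returns a long-format table with
    columns (lambda, component, term, estimate) suitable for path plots.
    """
    quad = quad or QuadratureConfig()
    control = control or FitControl()
    if vary not in ("location", "dispersion"):
        raise ValueError("vary must be 'location' or 'dispersion'")
    if grid is None:
        grid = np.exp(np.arange(-10.0, 0.0))
    grid = np.sort(np.asarray(grid, dtype=float))
    if unpenalized is None:
        unpenalized = fit_unpenalized(train, spec, quad, control=control, compute_se=False)
    if penalty_template is None:
        penalty_template = adaptive_weights(unpenalized)
    rows = []
    prev = unpenalized.params
    for lam in grid:
        ll, ld = (lam, fixed_other) if vary == "location" else (fixed_other, lam)
        fit = fit_penalized(train, spec, quad, penalty_template.with_lambdas(ll, ld),
                            init=prev, control=control)
        prev = fit.params
        for c, val in zip(fit.x_columns, fit.params.beta):
            rows.append({"lambda": lam, "component": "location", "term": c.name, "estimate": val})
        for c, val in zip(fit.z_columns, fit.params.alpha):
            rows.append({"lambda": lam, "component": "dispersion", "term": c.name, "estimate": val})
    return pd.DataFrame(rows)


def plot_coefficient_paths(path: pd.DataFrame, outfile=None):
    """One panel per component of coefficient paths over log(lambda)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    components = path["component"].unique()
    fig, axes = plt.subplots(1, len(components), figsize=(6 * len(components), 4), squeeze=False)
    for ax, comp in zip(axes[0], components):
        sub = path[path["component"] == comp]
        for term, grp in sub.groupby("term"):
            ax.plot(np.log(grp["lambda"]), grp["estimate"], label=term)
        ax.set_xlabel("log(lambda)")
        ax.set_ylabel("coefficient")
        ax.set_title(comp)
        ax.legend(fontsize=7)
    fig.tight_layout()
    if outfile:
        fig.savefig(outfile, dpi=120)
        plt.close(fig)
    return fig


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(AIC, BIC) = deviance + {2, log(N)} x number of parameters."""
    return (fit.deviance + 2.0 * fit.n_parameters,
            fit.deviance + np.log(fit.n_obs) * fit.n_parameters)


# ---------------------------------------------------------------------------
# selection rates over simulation replications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthPattern:
    """True sparsity/fusion structure for selection-rate computation.

    ``location_nonzero``/``dispersion_nonzero`` name covariates with true effects in
    the respective component; ``dispersion_zero`` names covariates whose entire block
    is truly zero there. ``fused_pair`` optionally designates (covariate, level_u,
    level_v) in the location term that truly share one coefficient (and differ from
    all other levels).
    """

    location_nonzero: frozenset
    dispersion_nonzero: frozenset
    location_zero: frozenset = frozenset()
    dispersion_zero: frozenset = frozenset()
    fused_pair: tuple | None = None


@dataclass
class SelectionRates:
    """Per covariate x component selection rates plus fusion recovery."""

    table: pd.DataFrame          # covariate, component, rate_type, rate
    fusion_recovery: float | None

    def rate(self, covariate: str, component: str, rate_type: str) -> float:
        t = self.table
        row = t[(t.covariate == covariate) & (t.component == component) & (t.rate_type == rate_type)]
        if row.empty:
            raise KeyError((covariate, component, rate_type))
        return float(row.rate.iloc[0])


def _covariate_selected(selection: SelectionSets, component: str, covariate: str,
                        columns) -> bool:
    """A covariate counts as selected if any of its design columns survives."""
    excluded = selection.excluded(component)
    names = [c.name for c in columns if c.covariate == covariate]
    if not names:
        raise KeyError(f"covariate {covariate!r} has no columns in the {component} design")
    return any(name not in excluded for name in names)


def _pair_correctly_fused(selection: SelectionSets, covariate: str, pair) -> bool:
    groups = selection.fused_groups_location.get(covariate)
    if groups is None:
        return False
    lu, lv = pair
    for group in groups:
        if lu in group and lv in group:
            return len(group) == 2  # exactly the designated pair, nothing else
    return False


def selection_rates(
    replicated_selections: Sequence[SelectionSets],
    truth: TruthPattern,
    x_columns,
    z_columns,
) -> SelectionRates:
    """Aggregate selection sets over replications into TPR/FNR/TNR/FPR.

    TPR of a truly nonzero covariate is the fraction of replications in which it was
    selected (any of its columns kept); TNR of a truly zero covariate block is the
    fraction in which the whole block was excluded. Fusion recovery is the fraction
    in which the designated level pair forms exactly one fused group.
    """
    if not replicated_selections:
        raise ValueError("need at least one replication")
    rows = []
    n = len(replicated_selections)
    plan = [
        ("location", x_columns, truth.location_nonzero, truth.location_zero),
        ("dispersion", z_columns, truth.dispersion_nonzero, truth.dispersion_zero),
    ]
    for component, columns, nonzero, zero in plan:
        for cov in sorted(nonzero):
            hits = sum(_covariate_selected(s, component, cov, columns) for s in replicated_selections)
            rows.append({"covariate": cov, "component": component, "rate_type": "TPR", "rate": hits / n})
            rows.append({"covariate": cov, "component": component, "rate_type": "FNR", "rate": 1 - hits / n})
        for cov in sorted(zero):
            miss = sum(not _covariate_selected(s, component, cov, columns) for s in replicated_selections)
            rows.append({"covariate": cov, "component": component, "rate_type": "TNR", "rate": miss / n})
            rows.append({"covariate": cov, "component": component, "rate_type": "FPR", "rate": 1 - miss / n})
    fusion = None
    if truth.fused_pair is not None:
        cov, lu, lv = truth.fused_pair
        fused = sum(_pair_correctly_fused(s, cov, (lu, lv)) for s in replicated_selections)
        fusion = fused / n
    return SelectionRates(table=pd.DataFrame(rows), fusion_recovery=fusion)
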