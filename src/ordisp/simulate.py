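"""Synthetic clustered ordinal data and selection-rate experiments.

The generator draws clustered data from any of the three model variants at known
parameters: cluster random intercepts from N(0, Sigma_b), two continuous covariates
uniform on [-1, 1], one 4-level ordinal covariate uniform over its levels (with the
first level as reference), identical location and dispersion designs (z = x), and
responses sampled from the model's category probabilities. The default configuration
is the benchmark design used throughout this package: k = 3 response categories,
thresholds (-1, 1), beta = (-0.2, 0.2, -0.5, 0.5, 0.5), alpha = (-0.4, 0.4, 0, 0, 0)
and Sigma_b = [[0.10, 0.02], [0.02, 0.10]], with setting 1 (n=50 clusters of 25) and
setting 2 (n=30 clusters of 40). Under this truth the third and fourth level of the
ordinal covariate share one location effect and the covariate has no dispersion
effect, which is what the selection experiment is designed to recover.

``run_selection_experiment`` repeats, per replication: draw a training and an
equal-sized validation sample, fit the unpenalized model, build adaptive weights,
tune (lambda_loc, lambda_disp) on the grid by validation predictive log-likelihood,
and record the selected model. Replication seeds are spawned deterministically from
the master seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ClusteredOrdinalData, CovariateSchema, encode_covariates
from .evaluation import SelectionRates, TruthPattern, selection_rates, tune_grid
from .likelihood import QuadratureConfig
from .models import LOCATION_SCALE, LOCATION_SHIFT, ModelSpec, Parameters, logistic_cdf
from .penalized import FitControl, fit_unpenalized


@dataclass(frozen=True)
class SimulationConfig:
    """Generating truth and dimensions for synthetic clustered ordinal data."""

    n_clusters: int = 50
    cluster_size: int = 25
    k: int = 3
    thresholds: tuple = (-1.0, 1.0)
    beta: tuple = (-0.2, 0.2, -0.5, 0.5, 0.5)
    alpha: tuple = (-0.4, 0.4, 0.0, 0.0, 0.0)
    Sigma_b: tuple = ((0.10, 0.02), (0.02, 0.10))
    variant: str = LOCATION_SHIFT
    ordinal_level_count: int = 4
    seed: int = 0

    def __post_init__(self):
        expected = 2 + self.ordinal_level_count - 1
        if len(self.beta) != expected or len(self.alpha) != expected:
            raise ValueError(f"beta/alpha must have {expected} entries (x1, x2, ordinal dummies)")

    @property
    def schemas(self) -> tuple:
        return (
            CovariateSchema("x1", "continuous"),
            CovariateSchema("x2", "continuous"),
            CovariateSchema("x3", "ordinal", tuple(range(1, self.ordinal_level_count + 1))),
        )


def setting_config(setting: int = 1, variant: str = LOCATION_SHIFT, **overrides) -> SimulationConfig:
    """The two benchmark settings: (1) n=50, Ni=25; (2) n=30, Ni=40."""
    if setting == 1:
        base = SimulationConfig(n_clusters=50, cluster_size=25, variant=variant)
    elif setting == 2:
        base = SimulationConfig(n_clusters=30, cluster_size=40, variant=variant)
    else:
        raise ValueError("setting must be 1 or 2")
    return replace(base, **overrides)


def true_parameters(config: SimulationConfig) -> Parameters:
    return Parameters(
        thresholds=np.asarray(config.thresholds, dtype=float),
        beta=np.asarray(config.beta, dtype=float),
        alpha=np.asarray(config.alpha, dtype=float),
        Sigma_b=np.asarray(config.Sigma_b, dtype=float),
    )


def truth_pattern(config: SimulationConfig) -> TruthPattern:
    """Selection truth of the default benchmark coefficients."""
    beta = np.asarray(config.beta)
    alpha = np.asarray(config.alpha)
    names = ["x1", "x2", "x3"]
    blocks = {"x1": [0], "x2": [1], "x3": list(range(2, len(beta)))}
    loc_nonzero = frozenset(n for n in names if np.any(beta[blocks[n]] != 0))
    disp_nonzero = frozenset(n for n in names if np.any(alpha[blocks[n]] != 0))
    loc_zero = frozenset(names) - loc_nonzero
    disp_zero = frozenset(names) - disp_nonzero
    fused_pair = None
    # designate a truly fused adjacent level pair of the ordinal covariate, if any
    levels = np.concatenate([[0.0], beta[blocks["x3"]]])
    for u in range(1, len(levels) - 1):
        if levels[u + 1] == levels[u] and levels[u] != 0:
            fused_pair = ("x3", u + 1, u + 2)
            break
    return TruthPattern(
        location_nonzero=loc_nonzero, dispersion_nonzero=disp_nonzero,
        location_zero=loc_zero, dispersion_zero=disp_zero, fused_pair=fused_pair,
    )


def _category_probs(config: SimulationConfig, design: np.ndarray, b_loc, b_disp) -> np.ndarray:
    """Per-row category probabilities at the truth; rows with invalid ordering get NaN."""
    thr = np.asarray(config.thresholds, dtype=float)
    k = config.k
    u = design @ np.asarray(config.beta) + b_loc
    d = design @ np.asarray(config.alpha) + b_disp
    r = np.arange(1, k)
    loc = thr[None, :] - u[:, None]
    if config.variant == "cumulative_re":
        eta = loc
    elif config.variant == LOCATION_SCALE:
        eta = loc / np.exp(d)[:, None]
    else:
        eta = loc + (r - k / 2.0)[None, :] * d[:, None]
        bad = np.any(np.diff(np.concatenate([eta, np.full((len(u), 1), np.inf)], axis=1), axis=1) <= 0, axis=1) \
            if k > 2 else np.zeros(len(u), bool)
        # ordering violated -> mark row invalid
        eta = np.where(bad[:, None], np.nan, eta)
    cdf = np.concatenate([np.zeros((len(u), 1)), logistic_cdf(eta), np.ones((len(u), 1))], axis=1)
    return np.diff(cdf, axis=1)


def _draw_b(rng, Sigma, n):
    if np.max(np.abs(Sigma)) < 1e-14:
        return np.zeros((n, 2))
    return rng.multivariate_normal(np.zeros(2), Sigma, size=n, method="cholesky")


def draw_random_effects(config: SimulationConfig, seed: int) -> np.ndarray:
    """Cluster random intercepts (n_clusters, 2) drawn from N(0, Sigma_b)."""
    Sigma = np.asarray(config.Sigma_b, dtype=float)
    return _draw_b(np.random.default_rng(seed), Sigma, config.n_clusters)


def simulate_dataset(config: SimulationConfig, seed: int | None = None,
                     random_effects: np.ndarray | None = None) -> ClusteredOrdinalData:
    """Draw one clustered dataset from the configured truth; reproducible from seed.

    ``random_effects`` fixes the cluster intercepts (used to draw several samples
    from the same clusters, e.g. a validation sample sharing the training clusters);
    by default they are drawn fresh. Observations whose drawn covariates violate the
    threshold ordering of the location-shift variant are redrawn; if more than 10%
    of initial draws violate the ordering the truth is considered inconsistent and
    an error is raised.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, m = config.n_clusters, config.cluster_size
    Sigma = np.asarray(config.Sigma_b, dtype=float)
    if random_effects is None:
        b = _draw_b(rng, Sigma, n)
    else:
        b = np.asarray(random_effects, dtype=float)
        if b.shape != (n, 2):
            raise ValueError(f"random_effects must have shape ({n}, 2)")
    total = n * m
    cluster = np.repeat(np.arange(n), m)

    def draw_covariates(size):
        x1 = rng.uniform(-1.0, 1.0, size)
        x2 = rng.uniform(-1.0, 1.0, size)
        x3 = rng.integers(1, config.ordinal_level_count + 1, size)
        return x1, x2, x3

    def design_of(x1, x2, x3):
        dummies = (x3[:, None] == np.arange(2, config.ordinal_level_count + 1)[None, :]).astype(float)
        return np.column_stack([x1, x2, dummies])

    x1, x2, x3 = draw_covariates(total)
    probs = _category_probs(config, design_of(x1, x2, x3), b[cluster, 0], b[cluster, 1])
    invalid = np.isnan(probs[:, 0])
    if invalid.mean() > 0.10:
        raise ValueError(
            f"truth violates threshold ordering for {invalid.mean():.1%} of draws; "
            "the configured parameters are inconsistent with the location-shift constraint"
        )
    rounds = 0
    while invalid.any():
        rounds += 1
        if rounds > 1000:
            raise RuntimeError("could not redraw covariates satisfying the threshold ordering")
        idx = np.flatnonzero(invalid)
        nx1, nx2, nx3 = draw_covariates(idx.size)
        x1[idx], x2[idx], x3[idx] = nx1, nx2, nx3
        sub = _category_probs(config, design_of(nx1, nx2, nx3), b[cluster[idx], 0], b[cluster[idx], 1])
        probs[idx] = sub
        invalid[idx] = np.isnan(sub[:, 0])
    u = rng.uniform(size=total)
    y = 1 + (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
    raw = pd.DataFrame({"cluster": cluster + 1, "y": y, "x1": x1, "x2": x2, "x3": x3})
    return encode_covariates(raw, config.schemas, standardize=False, k=config.k)


@dataclass
class ExperimentResult:
    """Replicated selection experiment: per-replication records and aggregate rates."""

    config: SimulationConfig
    replications: int
    n_failed: int
    selections: list
    chosen_lambdas: list           # (lambda_loc, lambda_disp) per replication
    estimates: pd.DataFrame        # rep, component, term, estimate (standardized), estimate_natural, truth
    rates: SelectionRates
    truth: TruthPattern


def _standardize_pair(train_raw: ClusteredOrdinalData, valid_raw: ClusteredOrdinalData, config):
    train = encode_covariates(train_raw.raw, config.schemas, standardize=True, k=config.k)
    valid = encode_covariates(valid_raw.raw, config.schemas,
                              standardization=train.standardization, k=config.k)
    return train, valid


def run_selection_experiment(
    config: SimulationConfig,
    replications: int = 100,
    log_lambda_grid: Sequence[tuple] | None = None,
    quad: QuadratureConfig | None = None,
    seed: int = 0,
    control: FitControl | None = None,
    standardize: bool = True,
    selection_rule: str = "within_se",
    se_factor: float = 1.0,
    progress: bool = False,
) -> ExperimentResult:
    """Replicated variable-selection experiment at the configured truth.

    Per replication a fresh training and validation sample are drawn, covariates are
    standardized on the training sample (the record reused for validation), the
    tuning grid is searched by predictive log-likelihood, and the selected model is
    recorded. Replication-level failures are excluded from the rates with a count.
    """
    quad = quad or QuadratureConfig()
    # one-sided gradients and a tighter iteration cap: adequate for warm-started
    # penalized fits and much cheaper over a full tuning grid
    control = control or FitControl(fd_scheme="forward", maxiter=100)
    if log_lambda_grid is None:
        log_lambda_grid = [(a, b) for a in range(-10, -1) for b in range(-10, -1)]
    spec = ModelSpec(variant=config.variant, k=config.k)
    truth = truth_pattern(config)
    true_par = true_parameters(config)
    children = np.random.SeedSequence(seed).spawn(replications)
    selections, lambdas, rows = [], [], []
    n_failed = 0
    x_cols = z_cols = None
    for rep, child in enumerate(children):
        s_b, s_train, s_valid = (int(v) for v in child.generate_state(3) % (2**31))
        # validation shares the training clusters (same random intercepts, fresh
        # covariates/responses), mirroring splits where every cluster is in all parts
        b = draw_random_effects(config, s_b)
        train = simulate_dataset(config, s_train, random_effects=b)
        valid = simulate_dataset(config, s_valid, random_effects=b)
        if standardize:
            train, valid = _standardize_pair(train, valid, config)
        try:
            unpen = fit_unpenalized(train, spec, quad, control=control, compute_se=False)
            tuning = tune_grid(train, valid, spec, quad, log_lambda_grid,
                               unpenalized=unpen, control=control,
                               selection_rule=selection_rule, se_factor=se_factor)
        except Exception as exc:  # pragma: no cover - defensive
            import warnings

            warnings.warn(f"replication {rep} failed: {exc}")
            n_failed += 1
            continue
        best = tuning.best_fit
        x_cols, z_cols = best.x_columns, best.z_columns
        selections.append(best.selection)
        lambdas.append(tuning.best_pair)
        record = train.standardization or {}
        for comp, cols, est, tru in (
            ("location", best.x_columns, best.params.beta, true_par.beta),
            ("dispersion", best.z_columns, best.params.alpha, true_par.alpha),
        ):
            for c, e, t in zip(cols, est, tru):
                sd = record.get(c.name, (0.0, 1.0))[1]
                rows.append({
                    "rep": rep, "component": comp, "term": c.name,
                    "estimate": e, "estimate_natural": e / sd, "truth": t,
                })
        if progress:
            print(f"replication {rep + 1}/{replications} done", flush=True)
    if not selections:
        raise RuntimeError("all replications failed")
    rates = selection_rates(selections, truth, x_cols, z_cols)
    return ExperimentResult(
        config=config, replications=replications, n_failed=n_failed,
        selections=selections, chosen_lambdas=lambdas,
        estimates=pd.DataFrame(rows), rates=rates, truth=truth,
    )


def rates_table(result: ExperimentResult) -> pd.DataFrame:
    """Wide covariate x component rate table mirroring the benchmark layout."""
    t = result.rates.table
    wide = t.pivot_table(index="covariate", columns=["component", "rate_type"], values="rate")
    wide.columns = [f"{c}_{r}" for c, r in wide.columns]
    out = wide.reset_index()
    if result.rates.fusion_recovery is not None:
        out.attrs["fusion_recovery"] = result.rates.fusion_recovery
    return out


def bias_summary(result: ExperimentResult) -> pd.DataFrame:
    """Per-replication shrinkage/bias of the truly nonzero coefficients.

    For each replication: mean over nonzero location coefficients of
    sign(truth) * (truth - estimate) (positive = shrunk toward zero) and mean over
    nonzero dispersion coefficients of |estimate| - |truth| (positive = magnitude
    biased upward). Estimates are on the natural (de-standardized) scale.
    """
    est = result.estimates
    out = []
    for rep, grp in est.groupby("rep"):
        loc = grp[(grp.component == "location") & (grp.truth != 0)]
        disp = grp[(grp.component == "dispersion") & (grp.truth != 0)]
        out.append({
            "rep": rep,
            "location_shrinkage": float(np.mean(np.sign(loc.truth) * (loc.truth - loc.estimate_natural))),
            "dispersion_magnitude_bias": float(np.mean(np.abs(disp.estimate_natural) - np.abs(disp.truth))),
        })
    return pd.DataFrame(out)
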