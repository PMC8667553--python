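"""Model assessment: hazard scores, concordance, congruence, repeated-split
protocols, hyperparameter search, paired t-tests and FDR correction.

Conventions
-----------
Concordance (Harrell's c): a pair (i, j) is comparable when the subject with
the strictly earlier time had an event, or when the times are tied and
exactly one subject had an event (the event subject is taken as the earlier
one, since the censored time is only a lower bound).  Tied event times with
both events, censored-before-event pairs and censored-censored pairs are not
comparable.  Tied hazard scores on a comparable pair count 0.5.

Congruence: Tucker's coefficient φ(u, v) = Σu_k v_k / √(Σu_k²·Σv_k²),
averaged over all unordered pairs of coefficient vectors; a pair involving
an all-zero vector contributes φ = 0 and is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .data import (
    LatentDesign,
    PathwayCollection,
    SurvivalDataset,
    build_latent_design,
    standardize,
)
from .fitter import FitConfig, FitResult, fit_pair, fit_single
from .objectives import PenaltyConfig, cox_nll_grad

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "SearchSpec",
    "hazard_scores",
    "concordance_index",
    "tucker_congruence",
    "paired_t_test",
    "fdr_correct",
    "lambda_max",
    "default_lambda_grid",
    "grid_search_lambda",
    "random_search_multitask",
    "repeated_split_eval",
]


@dataclass
class EvalReport:
    """Per-split test c-values plus stability and significance summaries."""

    c_values: np.ndarray
    congruence_mean: float | None = None
    betas: list[np.ndarray] = field(default_factory=list, repr=False)
    selection_counts: dict[str, int] = field(default_factory=dict)
    paired_diffs: np.ndarray | None = None
    t_statistic: float | None = None
    p_value: float | None = None
    fdr_adjusted_p: float | None = None

    @property
    def mean_c(self) -> float:
        return float(np.mean(self.c_values))


@dataclass
class SearchSpec:
    """Hyperparameter-search and resampling protocol.

    Defaults: 10-fold cross-validated grid search for λ; 100 random 80–20
    training-test splits single-task and 30 multi-task; in the multi-task
    random search, 30 triples with λ_j ~ N(λ_j⁰, (0.1·λ_j⁰)²) (clipped to a
    small positive floor) and μ ~ |N(0, 0.5²)| (half-normal, sd 0.5).
    """

    lambda_grid: np.ndarray | None = None
    lambda_grid_size: int = 10
    lambda_grid_span: float = 1e-3
    n_folds: int = 10
    n_splits: int = 100
    n_splits_multitask: int = 30
    split_fraction: float = 0.8
    n_random_draws: int = 30
    lambda_prior_sd_fraction: float = 0.1
    mu_half_normal_sd: float = 0.5
    seed: int = 0


def hazard_scores(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-sample linear predictor x_i·β; higher predicts earlier events."""
    return np.asarray(X) @ np.asarray(beta, dtype=float)


def concordance_index(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell concordance of hazard scores against censored outcomes.

    Vectorized O(n²) pair counting under the module's comparability and tie
    conventions; raises if no pair is comparable.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("scores, time and event must have equal length")
    dt = t[:, None] - t[None, :]          # t_i - t_j
    earlier = (dt < 0) & e[:, None]       # i strictly earlier with event
    tied_time = (dt == 0) & e[:, None] & ~e[None, :]  # tie, i event, j censored
    comparable = earlier | tied_time      # ordered pairs: i the "earlier event"
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (need an event preceding another subject)")
    ds = s[:, None] - s[None, :]
    concordant = (comparable & (ds > 0)).sum()
    tied_score = (comparable & (ds == 0)).sum()
    return float((concordant + 0.5 * tied_score) / n_comp)


def tucker_congruence(betas: list[np.ndarray]) -> float:
    """Mean pairwise Tucker congruence φ over ≥ 2 equal-length vectors."""
    if len(betas) < 2:
        raise ValueError("need at least two coefficient vectors")
    arrs = [np.asarray(b, dtype=float) for b in betas]
    norms = [np.linalg.norm(a) for a in arrs]
    phis = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            if norms[i] == 0.0 or norms[j] == 0.0:
                logger.warning("zero coefficient vector in congruence pair (%d, %d)", i, j)
                phis.append(0.0)
            else:
                phis.append(float(arrs[i] @ arrs[j] / (norms[i] * norms[j])))
    return float(np.mean(phis))


def paired_t_test(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample t-test of paired differences against zero mean."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 2:
        raise ValueError("need at least two paired differences")
    if np.std(diffs, ddof=1) == 0.0:
        raise ValueError("paired differences have zero variance; t-test undefined")
    res = stats.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue)


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Hyperparameter search


def lambda_max(
    data: SurvivalDataset,
    design: LatentDesign | None = None,
    weight_exponent: float = 0.5,
) -> float:
    """Smallest λ at which β = 0 is stationary (all groups zeroed).

    From the subgradient condition at the origin: a group g stays at zero
    iff ‖∇ℓ(0)_g‖₂ ≤ λ·|g|^w, so λ_max = max_g ‖∇ℓ(0)_g‖₂ / |g|^w.  For
    plain lasso this reduces to ‖∇ℓ(0)‖_∞.
    """
    X = design.latent_matrix if design is not None else data.expression
    g0 = cox_nll_grad(np.zeros(X.shape[1]), X, data.time, data.event)
    if design is None:
        return float(np.abs(g0).max())
    weights = design.group_sizes.astype(float) ** weight_exponent
    norms = np.asarray([np.linalg.norm(g0[a:b]) for a, b in design.group_slices])
    return float((norms / weights).max())


def default_lambda_grid(lam_max: float, n_points: int = 10, span: float = 1e-3) -> np.ndarray:
    """Log-spaced grid over [λ_max·span, λ_max]."""
    return np.geomspace(lam_max * span, lam_max, n_points)


def _cv_mean_c_single(
    data: SurvivalDataset,
    pathways: PathwayCollection | None,
    penalty: PenaltyConfig,
    fit_cfg: FitConfig,
    n_folds: int,
    seed: int,
) -> float:
    """Mean validation c-value of a single-cohort fit over K folds."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cs = []
    for k, (tr, va) in enumerate(kf.split(np.arange(data.n_samples))):
        train, test = data.subset(tr), data.subset(va)
        train_std, _ = standardize(train)
        test_std, _ = standardize(test, reference=train)
        if test.event.sum() == 0 or train.event.sum() == 0:
            logger.warning("fold %d has no events; skipped", k)
            continue
        design = build_latent_design(train_std, pathways) if pathways is not None else None
        res = fit_single(None if design is not None else train_std.expression,
                         train.time, train.event, penalty,
                         replace(fit_cfg, seed=fit_cfg.seed + k), design=design)
        Xt = (build_latent_design(test_std, pathways).latent_matrix
              if pathways is not None else test_std.expression)
        try:
            cs.append(concordance_index(hazard_scores(res.beta.values, Xt),
                                        test.time, test.event))
        except ValueError:
            continue
    if not cs:
        raise RuntimeError("every cross-validation fold failed")
    return float(np.mean(cs))


def grid_search_lambda(
    data: SurvivalDataset,
    pathways: PathwayCollection | None,
    spec: SearchSpec,
    penalty: PenaltyConfig | None = None,
    fit_cfg: FitConfig | None = None,
) -> float:
    """K-fold cross-validated grid search for λ, maximizing validation c.

    The grid defaults to 10 log-spaced points below the closed-form λ_max of
    the full data; ties break toward the larger (sparser) λ.
    """
    penalty = penalty or PenaltyConfig()
    fit_cfg = fit_cfg or FitConfig()
    grid = spec.lambda_grid
    if grid is None:
        std, _ = standardize(data)
        design = build_latent_design(std, pathways) if pathways is not None else None
        grid = default_lambda_grid(lambda_max(std, design, penalty.group_weight_exponent),
                                   spec.lambda_grid_size, spec.lambda_grid_span)
    grid = np.sort(np.asarray(grid, dtype=float))
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    best_lam, best_c = None, -np.inf
    for lam in grid:
        c = _cv_mean_c_single(data, pathways, replace(penalty, lambda_=float(lam)),
                              fit_cfg, spec.n_folds, spec.seed)
        if c > best_c or (c == best_c and best_lam is not None and lam > best_lam):
            best_lam, best_c = float(lam), c
    return best_lam


def _cv_c_pair(
    data1: SurvivalDataset,
    data2: SurvivalDataset,
    pathways: PathwayCollection,
    penalty1: PenaltyConfig,
    penalty2: PenaltyConfig,
    fit_cfg: FitConfig,
    n_folds: int,
    seed: int,
) -> tuple[float, float]:
    """Per-task mean validation c of the coupled fit over K parallel folds."""
    kf1 = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    kf2 = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
    cs1, cs2 = [], []
    folds = zip(kf1.split(np.arange(data1.n_samples)), kf2.split(np.arange(data2.n_samples)))
    for k, ((tr1, va1), (tr2, va2)) in enumerate(folds):
        t1, v1 = data1.subset(tr1), data1.subset(va1)
        t2, v2 = data2.subset(tr2), data2.subset(va2)
        t1s, _ = standardize(t1)
        t2s, _ = standardize(t2)
        d1 = build_latent_design(t1s, pathways)
        d2 = build_latent_design(t2s, pathways)
        r1, r2 = fit_pair(d1, t1.time, t1.event, d2, t2.time, t2.event,
                          penalty1, penalty2, replace(fit_cfg, seed=fit_cfg.seed + 2 * k))
        for (val, tr, res, cs) in ((v1, t1, r1, cs1), (v2, t2, r2, cs2)):
            vs, _ = standardize(val, reference=tr)
            Xv = build_latent_design(vs, pathways).latent_matrix
            try:
                cs.append(concordance_index(hazard_scores(res.beta.values, Xv),
                                            val.time, val.event))
            except ValueError:
                continue
    if not cs1 or not cs2:
        raise RuntimeError("cross-validation failed for one of the cohorts")
    return float(np.mean(cs1)), float(np.mean(cs2))


def random_search_multitask(
    data1: SurvivalDataset,
    data2: SurvivalDataset,
    pathways: PathwayCollection,
    spec: SearchSpec,
    base_lambda1: float,
    base_lambda2: float,
    fit_cfg: FitConfig | None = None,
    penalty_template: PenaltyConfig | None = None,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Random search over (λ1, λ2, μ) for the coupled model.

    Draws ``n_random_draws`` triples — λ_j from N(base λ_j, (0.1·λ_j)²)
    clipped at a 1e-6 floor, μ from a half-normal with sd 0.5 — scores each
    by per-task cross-validated mean c, and returns the best triple per task
    as ``(best_for_task1, best_for_task2)``.
    """
    fit_cfg = fit_cfg or FitConfig()
    tmpl = penalty_template or PenaltyConfig()
    rng = np.random.default_rng(spec.seed)
    lam1s = np.clip(rng.normal(base_lambda1, spec.lambda_prior_sd_fraction * base_lambda1,
                               spec.n_random_draws), 1e-6, None)
    lam2s = np.clip(rng.normal(base_lambda2, spec.lambda_prior_sd_fraction * base_lambda2,
                               spec.n_random_draws), 1e-6, None)
    mus = np.abs(rng.normal(0.0, spec.mu_half_normal_sd, spec.n_random_draws))
    best = [(-np.inf, None), (-np.inf, None)]
    for lam1, lam2, mu in zip(lam1s, lam2s, mus):
        p1 = replace(tmpl, lambda_=float(lam1), mu=float(mu))
        p2 = replace(tmpl, lambda_=float(lam2), mu=float(mu))
        c1, c2 = _cv_c_pair(data1, data2, pathways, p1, p2, fit_cfg,
                            spec.n_folds, spec.seed)
        triple = (float(lam1), float(lam2), float(mu))
        if c1 > best[0][0]:
            best[0] = (c1, triple)
        if c2 > best[1][0]:
            best[1] = (c2, triple)
    return best[0][1], best[1][1]


def repeated_split_eval(
    data: SurvivalDataset,
    pathways: PathwayCollection | None,
    spec: SearchSpec,
    penalty: PenaltyConfig,
    fit_cfg: FitConfig | None = None,
) -> EvalReport:
    """Repeated random train-test splits of one cohort.

    Per split: standardize on the training part, fit there, score the test
    part with training-set standardization, and record the test c-value;
    the fitted βs are collected (in a shared latent coordinate system, which
    deterministic design construction guarantees) for Tucker congruence.
    Splits whose test part has no events are skipped and logged.  Split k
    uses seed ``spec.seed + k`` for both the split and the fit.
    """
    fit_cfg = fit_cfg or FitConfig()
    n = data.n_samples
    n_train = int(round(spec.split_fraction * n))
    cs, betas = [], []
    counts: dict[str, int] = {}
    for k in range(spec.n_splits):
        rng = np.random.default_rng(spec.seed + k)
        perm = rng.permutation(n)
        train, test = data.subset(perm[:n_train]), data.subset(perm[n_train:])
        if train.event.sum() == 0 or test.event.sum() == 0:
            logger.warning("split %d has no events in train or test; skipped", k)
            continue
        train_std, _ = standardize(train)
        test_std, _ = standardize(test, reference=train)
        design = build_latent_design(train_std, pathways) if pathways is not None else None
        res = fit_single(None if design is not None else train_std.expression,
                         train.time, train.event, penalty,
                         replace(fit_cfg, seed=fit_cfg.seed + k), design=design)
        Xt = (build_latent_design(test_std, pathways).latent_matrix
              if pathways is not None else test_std.expression)
        try:
            cs.append(concordance_index(hazard_scores(res.beta.values, Xt),
                                        test.time, test.event))
        except ValueError:
            logger.warning("split %d has no comparable test pairs; skipped", k)
            continue
        betas.append(res.beta.values)
        for name in res.selected_groups:
            counts[name] = counts.get(name, 0) + 1
    congr = tucker_congruence(betas) if len(betas) >= 2 else None
    return EvalReport(
        c_values=np.asarray(cs),
        congruence_mean=congr,
        betas=betas,
        selection_counts=counts,
    )


def nonoverlapping_pair_diffs(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Differences over non-overlapping index pairs (1,2), (3,4), ...

    Used for the congruence t-test, where each fitted β may enter only one
    congruence pair: φ(β_1, β_2), φ(β_3, β_4), ... are compared between
    methods a and b.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n = min(len(a), len(b))
    return (a - b)[: n - (n % 2)]


def congruence_of_pairs(betas: list[np.ndarray]) -> np.ndarray:
    """Tucker φ over the non-overlapping pairs (β1,β2), (β3,β4), ..."""
    phis = []
    for i in range(0, len(betas) - 1, 2):
        phis.append(tucker_congruence([betas[i], betas[i + 1]]))
    return np.asarray(phis)
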