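"""PRS construction: repeated logistic regression (RLR), logistic ridge
regression (LRR) and a neural-network bottleneck extractor (ANN).

All three approaches produce a per-sample score on (or comparable to) the
log-odds scale: ``PRS = sum_k beta_k x_k`` for the linear methods, and for
the ANN the genotype pathway's additive contribution to the pre-sigmoid
logit.  The LRR and ANN models adjust for age and the first two genotype
principal components during fitting, but covariate terms never enter the
score itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._ann import MLP
from .containers import GenotypeMatrix, status_to_binary

__all__ = [
    "PRSWeights",
    "ANNConfig",
    "ANNModel",
    "CVResult",
    "compute_pcs",
    "fit_rlr",
    "fit_lrr",
    "fit_ann",
    "score_prs",
    "score_ann",
    "cross_validate",
    "training_mask",
    "add_interaction_pseudo_snp",
]

DEFAULT_COVARIATES = ("age", "pc1", "pc2")


@dataclass
class PRSWeights:
    method: str  # "rlr" | "lrr"
    snp_ids: list[str]
    effect_alleles: list[str]
    betas: np.ndarray
    covariate_betas: dict[str, float] | None = None
    intercept: float = 0.0
    lam: float | None = None
    training_case_set: str = "overall"
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.betas) != len(self.snp_ids):
            raise ValueError("betas length must match snp_ids")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")


def hidden_width(n_inputs: int) -> int:
    """Hidden-layer width rule: round(sqrt(n_inputs)) + 2 (7 for 24 SNPs)."""
    return int(round(math.sqrt(n_inputs))) + 2


@dataclass(frozen=True)
class ANNConfig:
    """Defaults follow the tuned values for a 24-SNP panel: 60 epochs of
    mini-batch Adam at 0.01 (batch size 32), 3 hidden layers, dropout 0.4,
    leaky-ReLU slope 0.01, and a distinct linear bottleneck of width 6.
    Set ``batch_size=0`` for full-batch training."""

    n_hidden_layers: int = 3
    dropout_rate: float = 0.4
    n_iterations: int = 60
    learning_rate: float = 0.01
    bottleneck_dim: int = 6
    leaky_slope: float = 0.01
    batch_size: int = 32
    bottleneck_is_last_hidden: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0,1)")
        if min(self.n_hidden_layers, self.n_iterations, self.bottleneck_dim) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class ANNModel:
    net: MLP
    config: ANNConfig
    snp_ids: list[str]
    effect_alleles: list[str]
    covariates: tuple[str, ...]
    x_mean: np.ndarray
    x_std: np.ndarray
    c_mean: np.ndarray
    c_std: np.ndarray
    training_case_set: str = "overall"

    def _standardize(self, dosages: np.ndarray) -> np.ndarray:
        return (dosages - self.x_mean) / self.x_std

    def _standardize_cov(self, C: np.ndarray) -> np.ndarray:
        return (C - self.c_mean) / self.c_std


@dataclass
class CVResult:
    grid: list
    mean_losses: list[float]
    chosen_index: int
    seed: int

    @property
    def chosen(self):
        return self.grid[self.chosen_index]


# ---------------------------------------------------------------------------
# principal components


def compute_pcs(g: GenotypeMatrix, k: int = 2) -> np.ndarray:
    """Top-k sample scores of the column-standardized dosage matrix.

    Zero-variance SNPs are dropped before the decomposition; each component's
    largest-magnitude SNP loading is oriented positive so signs are
    deterministic.  Requires at least ``k`` polymorphic SNPs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(g.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("compute_pcs requires an imputed (no-missing) matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    poly = sd > 0
    if poly.sum() < k:
        raise ValueError(f"only {int(poly.sum())} polymorphic SNPs; need {k}")
    Z = (X[:, poly] - mu[poly]) / sd[poly]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def attach_pcs(g: GenotypeMatrix, t: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Convenience: fill ``pc1``/``pc2`` columns of the sample table."""
    pcs = compute_pcs(g, k)
    t = t.copy()
    for j in range(min(k, 2)):
        t[f"pc{j + 1}"] = pcs[:, j]
    return t


# ---------------------------------------------------------------------------
# training masks


def training_mask(t: pd.DataFrame, case_set: str) -> np.ndarray:
    """Boolean row mask: all controls plus the requested case stratum
    (``overall`` keeps every case, ``er_pos``/``er_neg`` keep only that
    subtype's cases)."""
    status = t["status"].to_numpy()
    if case_set == "overall":
        return np.ones(len(t), dtype=bool)
    if case_set not in ("er_pos", "er_neg"):
        raise ValueError(f"unknown case_set {case_set!r}")
    want = "positive" if case_set == "er_pos" else "negative"
    er = t["er_status"].to_numpy()
    return (status == "control") | ((status == "case") & (er == want))


def add_interaction_pseudo_snp(
    g: GenotypeMatrix, snp_i: str, snp_j: str
) -> GenotypeMatrix:
    """Append the dosage product of two SNPs as an extra pseudo-SNP column.

    This is how an identified SNP x SNP interaction enters the ridge score:
    the product term is penalized and scored exactly like a 25th SNP.  The
    pseudo-SNP id is ``"<i>x<j>"`` and its allele labels are taken from the
    first member.
    """
    ki, kj = g.snp_index(snp_i), g.snp_index(snp_j)
    product = (g.dosages[:, ki] * g.dosages[:, kj])[:, None]
    return GenotypeMatrix(
        list(g.sample_ids),
        list(g.snp_ids) + [f"{snp_i}x{snp_j}"],
        np.hstack([g.dosages, product]),
        list(g.effect_alleles) + [g.effect_alleles[ki]],
        list(g.other_alleles) + [g.other_alleles[ki]],
    )


# ---------------------------------------------------------------------------
# RLR


def fit_rlr(g: GenotypeMatrix, t: pd.DataFrame, case_set: str = "overall") -> PRSWeights:
    """One unadjusted univariate logistic regression per SNP; the fitted
    per-dosage log-OR is the SNP's weight.  SNPs with separation or
    non-convergence fall back to a lightly penalized fit and are flagged."""
    mask = training_mask(t, case_set)
    y = status_to_binary(t)[mask]
    X = g.dosages[mask]
    if np.isnan(X).any():
        raise ValueError("fit_rlr requires an imputed matrix")
    betas = np.empty(g.n_snps)
    flags: dict[str, str] = {}
    for k in range(g.n_snps):
        x = X[:, k]
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=100)
            if not np.isfinite(fit.params[1]) or not fit.mle_retvals.get("converged", True):
                raise RuntimeError("non-convergence")
            betas[k] = fit.params[1]
        except Exception:
            lr = LogisticRegression(C=100.0, max_iter=1000)
            lr.fit(x[:, None], y)
            betas[k] = lr.coef_[0, 0]
            flags[g.snp_ids[k]] = "penalized_fallback"
    return PRSWeights(
        method="rlr",
        snp_ids=list(g.snp_ids),
        effect_alleles=list(g.effect_alleles),
        betas=betas,
        training_case_set=case_set,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# LRR


def _ridge_logit_fit(
    X_snp: np.ndarray, X_cov: np.ndarray, y: np.ndarray, lam: float
) -> np.ndarray:
    """Minimize NLL + (lam/2)*||beta_snp||^2; covariates and intercept are
    unpenalized.  Returns the full parameter vector
    [beta_snp..., beta_cov..., intercept]."""
    m, q = X_snp.shape[1], X_cov.shape[1]
    X = np.hstack([X_snp, X_cov, np.ones((len(y), 1))])

    def objective(w: np.ndarray):
        eta = X @ w
        # stable log(1+exp(eta)) - y*eta
        nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (p - y)
        pen = 0.5 * lam * np.sum(w[:m] ** 2)
        grad_pen = np.concatenate([lam * w[:m], np.zeros(q + 1)])
        return nll + pen, grad + grad_pen

    w0 = np.zeros(m + q + 1)
    res = minimize(objective, w0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"ridge logistic fit diverged at lambda={lam}")
    return res.x


def fit_lrr(
    g: GenotypeMatrix,
    t: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    lambda_grid: Sequence[float] = (0.1, 1.0, 3.0, 10.0, 30.0, 100.0),
    case_set: str = "overall",
    folds: int = 10,
    seed: int = 0,
) -> tuple[PRSWeights, CVResult]:
    """Multivariate logistic ridge regression over the full panel.

    All SNPs enter one model with an L2 penalty on their coefficients only;
    age and the two leading principal components are unpenalized covariates.
    The penalty is chosen as the argmin of mean 10-fold cross-validated
    log-loss (ties resolve toward the stronger penalty), then the model is
    refit on the full training set.
    """
    if not len(lambda_grid):
        raise ValueError("lambda_grid must be nonempty")
    mask = training_mask(t, case_set)
    y = status_to_binary(t)[mask]
    X_snp = g.dosages[mask]
    if np.isnan(X_snp).any():
        raise ValueError("fit_lrr requires an imputed matrix")
    X_cov = t.loc[mask, list(covariates)].to_numpy(dtype=float)
    if np.isnan(X_cov).any():
        raise ValueError("covariates contain missing values (are PCs attached?)")

    grid = sorted(set(float(l) for l in lambda_grid), reverse=True)  # simpler first

    def fit_predict(tr: np.ndarray, va: np.ndarray, lam: float) -> np.ndarray:
        w = _ridge_logit_fit(X_snp[tr], X_cov[tr], y[tr], lam)
        eta = X_snp[va] @ w[: X_snp.shape[1]] + X_cov[va] @ w[X_snp.shape[1]:-1] + w[-1]
        return 1.0 / (1.0 + np.exp(-eta))

    cv = cross_validate(fit_predict, y, grid, folds=folds, seed=seed)
    lam = cv.chosen
    w = _ridge_logit_fit(X_snp, X_cov, y, lam)
    m = X_snp.shape[1]
    weights = PRSWeights(
        method="lrr",
        snp_ids=list(g.snp_ids),
        effect_alleles=list(g.effect_alleles),
        betas=w[:m],
        covariate_betas=dict(zip(covariates, w[m:-1])),
        intercept=float(w[-1]),
        lam=float(lam),
        training_case_set=case_set,
    )
    return weights, cv


# ---------------------------------------------------------------------------
# ANN


def fit_ann(
    g: GenotypeMatrix,
    t: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    config: ANNConfig = ANNConfig(),
    case_set: str = "overall",
    tune_grids: dict[str, Sequence] | None = None,
    folds: int = 10,
) -> tuple[ANNModel, CVResult]:
    """Train the bottleneck network, optionally tuning (n_iterations,
    n_hidden_layers, dropout_rate) by 10-fold cross-validated log-loss.

    Dosages and covariates are z-scored with training-set statistics (stored
    on the model); training is full-batch and bit-reproducible from
    ``config.seed``.
    """
    mask = training_mask(t, case_set)
    y = status_to_binary(t)[mask]
    X = g.dosages[mask]
    if np.isnan(X).any():
        raise ValueError("fit_ann requires an imputed matrix")
    C = t.loc[mask, list(covariates)].to_numpy(dtype=float)
    x_mean, x_std = X.mean(axis=0), X.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    c_mean, c_std = C.mean(axis=0), C.std(axis=0)
    c_std = np.where(c_std > 0, c_std, 1.0)
    Xs = (X - x_mean) / x_std
    Cs = (C - c_mean) / c_std

    def make_and_train(cfg: ANNConfig, Xtr, Ctr, ytr) -> MLP:
        width = hidden_width(Xtr.shape[1])
        bdim = width if cfg.bottleneck_is_last_hidden else cfg.bottleneck_dim
        net = MLP(
            n_snps=Xtr.shape[1],
            n_cov=Ctr.shape[1],
            n_hidden_layers=cfg.n_hidden_layers,
            hidden_width=width,
            bottleneck_dim=bdim,
            leaky_slope=cfg.leaky_slope,
            seed=cfg.seed,
        )
        net.train(
            Xtr, Ctr, ytr,
            n_epochs=cfg.n_iterations,
            learning_rate=cfg.learning_rate,
            dropout_rate=cfg.dropout_rate,
            seed=cfg.seed + 1,
            batch_size=cfg.batch_size,
        )
        return net

    if tune_grids:
        grid_cfgs = [
            replace(config, n_iterations=ni, n_hidden_layers=nh, dropout_rate=dr)
            for ni in tune_grids.get("n_iterations", [config.n_iterations])
            for nh in tune_grids.get("n_hidden_layers", [config.n_hidden_layers])
            for dr in tune_grids.get("dropout_rate", [config.dropout_rate])
        ]
    else:
        grid_cfgs = [config]

    def fit_predict(tr: np.ndarray, va: np.ndarray, cfg: ANNConfig) -> np.ndarray:
        net = make_and_train(cfg, Xs[tr], Cs[tr], y[tr])
        return 1.0 / (1.0 + np.exp(-net.logit(Xs[va], Cs[va])))

    if len(grid_cfgs) > 1:
        cv = cross_validate(fit_predict, y, grid_cfgs, folds=folds, seed=config.seed)
        chosen = cv.chosen
    else:
        cv = CVResult(grid=grid_cfgs, mean_losses=[float("nan")], chosen_index=0,
                      seed=config.seed)
        chosen = config

    net = make_and_train(chosen, Xs, Cs, y)
    model = ANNModel(
        net=net,
        config=chosen,
        snp_ids=list(g.snp_ids),
        effect_alleles=list(g.effect_alleles),
        covariates=tuple(covariates),
        x_mean=x_mean,
        x_std=x_std,
        c_mean=c_mean,
        c_std=c_std,
        training_case_set=case_set,
    )
    return model, cv


# ---------------------------------------------------------------------------
# scoring


def _check_panel(snp_ids, effect_alleles, g: GenotypeMatrix) -> None:
    if list(snp_ids) != list(g.snp_ids):
        missing = set(snp_ids) ^ set(g.snp_ids)
        raise ValueError(f"panel mismatch; differing SNPs: {sorted(missing)[:10]}")
    bad = [
        s for s, ea, ga in zip(snp_ids, effect_alleles, g.effect_alleles) if ea != ga
    ]
    if bad:
        raise ValueError(f"effect-allele mismatch at {bad[:10]}")


def score_prs(weights: PRSWeights, g: GenotypeMatrix) -> np.ndarray:
    """``PRS = sum_k beta_k x_k`` per sample; covariate betas are excluded."""
    _check_panel(weights.snp_ids, weights.effect_alleles, g)
    if np.isnan(g.dosages).any():
        raise ValueError("score_prs requires an imputed matrix")
    return g.dosages @ weights.betas


def score_ann(model: ANNModel, g: GenotypeMatrix, t: pd.DataFrame | None = None) -> np.ndarray:
    """Genotype-pathway score (dropout off): bottleneck activations times
    their output weights plus the output bias.  Because the covariate output
    weights are simply omitted, this equals the full logit minus the
    covariate terms; the sample table is accepted for interface symmetry but
    never influences the score."""
    _check_panel(model.snp_ids, model.effect_alleles, g)
    if np.isnan(g.dosages).any():
        raise ValueError("score_ann requires an imputed matrix")
    return model.net.genotype_score(model._standardize(g.dosages))


def predict_proba_ann(model: ANNModel, g: GenotypeMatrix, t: pd.DataFrame) -> np.ndarray:
    """Full-model case probability (genotype pathway + covariates)."""
    _check_panel(model.snp_ids, model.effect_alleles, g)
    C = t[list(model.covariates)].to_numpy(dtype=float)
    logit = model.net.logit(model._standardize(g.dosages), model._standardize_cov(C))
    return 1.0 / (1.0 + np.exp(-logit))


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    fit_predict: Callable[[np.ndarray, np.ndarray, object], np.ndarray],
    y: np.ndarray,
    grid: Sequence,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold mean validation log-loss over a tuning grid.

    ``fit_predict(train_idx, val_idx, grid_point)`` must return validation
    case probabilities.  Every sample lands in exactly one validation fold;
    ties at the minimum resolve to the earliest grid entry, so callers order
    their grids simplest-model-first.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    y = np.asarray(y, dtype=float)
    if len(y) < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    mean_losses = []
    for point in grid:
        losses = []
        for tr, va in splits:
            p = np.clip(fit_predict(tr, va, point), 1e-12, 1 - 1e-12)
            losses.append(-np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p)))
        mean_losses.append(float(np.mean(losses)))
    chosen = int(np.argmin(mean_losses))
    return CVResult(grid=grid, mean_losses=mean_losses, chosen_index=chosen, seed=seed)
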