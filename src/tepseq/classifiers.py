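"""PSO-SVM and elastic-net case/control classifiers.

The PSO-SVM follows the TEP protocol's search space: a particle swarm
(canonical global-best updates, 100 particles x 10 iterations by default)
minimises 1 - AUC on the evaluation partition over five parameters -- the
two RUV retention thresholds, the number of top-ranked biomarker genes, and
the cost and gamma of an RBF-kernel SVM.  The SVM is fit on the training
partition with class-probability outputs (Platt scaling).

The elastic net is a penalised logistic regression over an (alpha, lambda)
grid selected by cross-validated AUC (10-fold or leave-one-out), with
optional majority-class down-sampling inside each cross-validation loop.

Both classifiers serialise to a self-contained JSON model carrying the
training-derived normalisation context, so prediction on new samples never
refits normalisation and never reads their labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from tepseq import io as tio
from tepseq.evaluation import roc_auc
from tepseq.normalization import (NormContext, RUVModel, apply_removal, compute_tmm_factors,
                                  cpm_log2, fit_ruv, removal_mask, score_factor_pvalues)

#: Searched parameters, in particle-position order.  Thresholds move on a
#: log10 scale, SVM cost/gamma on a log2 scale, gene count on a linear scale
#: (rounded at evaluation time).
PSO_PARAMS = ("log10_p_class", "log10_p_confounder", "n_genes", "log2_cost", "log2_gamma")

def _fit_svc(svc: SVC, x: np.ndarray, y: np.ndarray) -> SVC:
    with warnings.catch_warnings():
        # probability=True is the Platt-scaling interface this pipeline needs
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(x, y)
    return svc


DEFAULT_BOUNDS = {
    "log10_p_class": (-3.0, np.log10(0.5)),
    "log10_p_confounder": (-3.0, np.log10(0.5)),
    "n_genes": (5.0, 200.0),
    "log2_cost": (-5.0, 15.0),
    "log2_gamma": (-15.0, 3.0),
}


@dataclass
class PSOConfig:
    n_particles: int = 100
    n_iterations: int = 10
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"degenerate bounds for {name}")


@dataclass
class ClassifierModel:
    """A trained classifier plus everything needed to apply it blind.

    ``kind`` is ``"pso_svm"`` or ``"elastic_net"``.  The SVM is stored as
    its (standardised) training matrix and hyperparameters and is refit
    deterministically on load; the elastic net stores its coefficients.
    """

    kind: str
    gene_ids: list[str]  # features entering the decision function, ranked
    params: dict
    norm_ctx: NormContext | None = None
    ruv: RUVModel | None = None
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    training_meta: dict = field(default_factory=dict)
    _svc: SVC | None = field(default=None, repr=False, compare=False)

    @property
    def selected_genes(self) -> list[str]:
        if self.kind == "elastic_net":
            coef = np.asarray(self.params["coef"], dtype=float)
            return [g for g, c in zip(self.gene_ids, coef) if c != 0.0]
        return list(self.gene_ids)

    def _fitted_svc(self) -> SVC:
        if self._svc is None:
            svc = SVC(C=self.params["cost"], gamma=self.params["gamma"], kernel="rbf",
                      probability=True, random_state=int(self.params["random_state"]))
            _fit_svc(svc, np.asarray(self.params["X_train"], dtype=float),
                     np.asarray(self.params["y_train"], dtype=int))
            self._svc = svc
        return self._svc

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Case probability from a standardised feature matrix (n x genes)."""
        if self.kind == "pso_svm":
            return self._fitted_svc().predict_proba(x)[:, 1]
        z = x @ np.asarray(self.params["coef"], dtype=float) + self.params["intercept"]
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        params = {k: v for k, v in self.params.items()}
        return {
            "kind": self.kind, "gene_ids": self.gene_ids, "params": params,
            "norm_ctx": None if self.norm_ctx is None else self.norm_ctx.to_dict(),
            "ruv": None if self.ruv is None else self.ruv.to_dict(),
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_scale": None if self.scaler_scale is None else self.scaler_scale.tolist(),
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            kind=d["kind"], gene_ids=list(d["gene_ids"]), params=dict(d["params"]),
            norm_ctx=None if d.get("norm_ctx") is None else NormContext.from_dict(d["norm_ctx"]),
            ruv=None if d.get("ruv") is None else RUVModel.from_dict(d["ruv"]),
            scaler_mean=None if d.get("scaler_mean") is None else np.asarray(d["scaler_mean"]),
            scaler_scale=None if d.get("scaler_scale") is None else np.asarray(d["scaler_scale"]),
            training_meta=dict(d.get("training_meta", {})),
        )

    def save(self, path) -> None:
        tio.write_json(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        return cls.from_dict(tio.read_json(path))


# --------------------------------------------------------------------------
# gene ranking

def rank_candidate_genes(expr_train: pd.DataFrame, labels) -> pd.DataFrame:
    """Rank genes by decreasing |Welch t| between cases and controls.

    Ties (including zero-variance, zero-difference genes) break by gene
    identifier so the ordering is fully deterministic.
    """
    y = np.asarray(labels)
    is_case = y == "case" if y.dtype.kind in "OUS" else y.astype(bool)
    if is_case.all() or not is_case.any():
        raise ValueError("both classes required to rank genes")
    x = expr_train.to_numpy(dtype=float)
    a, b = x[:, is_case], x[:, ~is_case]
    n1, n0 = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    se = np.sqrt(a.var(axis=1, ddof=1) / n1 + b.var(axis=1, ddof=1) / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    out = pd.DataFrame({"gene_id": expr_train.index, "statistic": t})
    out = out.sort_values(["gene_id"]).sort_values(
        "statistic", key=lambda s: -s.abs(), kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# --------------------------------------------------------------------------
# particle swarm

def pso_optimize(objective, cfg: PSOConfig, bounds: np.ndarray | None = None
                 ) -> tuple[np.ndarray, float, list[float]]:
    """Canonical global-best PSO minimisation within box bounds.

    ``objective`` maps a position vector to a scalar fitness; non-finite
    values are penalised with fitness 1.  Returns (best position, best
    fitness, per-iteration global-best trace).  Deterministic given the
    config seed.
    """
    if bounds is None:
        bounds = np.array([cfg.bounds[p] for p in cfg.bounds], dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = len(lo)
    rng = np.random.default_rng(cfg.seed)
    x = rng.uniform(lo, hi, size=(cfg.n_particles, d))
    v = np.zeros_like(x)

    def safe_eval(pos: np.ndarray) -> float:
        val = objective(pos)
        return float(val) if np.isfinite(val) else 1.0

    fitness = np.array([safe_eval(xi) for xi in x])
    pbest, pbest_f = x.copy(), fitness.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    trace = [gbest_f]

    for _ in range(cfg.n_iterations):
        r1 = rng.random((cfg.n_particles, d))
        r2 = rng.random((cfg.n_particles, d))
        v = (cfg.inertia * v + cfg.cognitive * r1 * (pbest - x)
             + cfg.social * r2 * (gbest[None, :] - x))
        x = np.clip(x + v, lo, hi)
        fitness = np.array([safe_eval(xi) for xi in x])
        improved = fitness < pbest_f
        pbest[improved] = x[improved]
        pbest_f[improved] = fitness[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        trace.append(gbest_f)
    return gbest, gbest_f, trace


# --------------------------------------------------------------------------
# PSO-SVM training

def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def train_pso_svm(counts: pd.DataFrame, meta: pd.DataFrame, pso_cfg: PSOConfig | None = None,
                  ruv_k: int = 10) -> ClassifierModel:
    """Train the PSO-SVM on the training/evaluation partitions of ``meta``.

    Input is RUV-corrected, TMM-normalised, cpm-log2 transformed counts with
    age, library size and hospital of origin as candidate RUV confounders.
    The normalisation context and RUV factor model are fit on the training
    and evaluation samples only; each particle re-applies the dual-threshold
    RUV selection with its own thresholds, takes its top-n ranked genes,
    fits an RBF SVM on the training partition and is scored by 1 - AUC on
    the evaluation partition.
    """
    pso_cfg = pso_cfg or PSOConfig()
    meta = meta.set_index("sample_id", drop=False)
    train_ids = meta.index[meta["partition"] == "training"].tolist()
    eval_ids = meta.index[meta["partition"] == "evaluation"].tolist()
    if not train_ids or not eval_ids:
        raise ValueError("training and evaluation partitions must be non-empty")
    for ids, name in ((train_ids, "training"), (eval_ids, "evaluation")):
        if meta.loc[ids, "group"].nunique() < 2:
            raise ValueError(f"{name} partition needs both classes")

    fit_ids = train_ids + eval_ids
    ctx = compute_tmm_factors(counts[fit_ids], training_ids=fit_ids)
    expr = cpm_log2(counts[fit_ids], ctx)
    k_eff = max(0, min(ruv_k, len(fit_ids) - 1, counts.shape[0] - 1))
    ruv = fit_ruv(expr, k_eff)
    confounders = {
        "age": meta.loc[fit_ids, "age"].to_numpy(dtype=float),
        "lib_size": counts[fit_ids].sum(axis=0).to_numpy(dtype=float),
        "hospital": meta.loc[fit_ids, "hospital"].to_numpy(),
    }
    pvals = score_factor_pvalues(ruv, meta.loc[fit_ids, "group"].to_numpy(), confounders)
    y_train = (meta.loc[train_ids, "group"] == "case").to_numpy()
    y_eval = (meta.loc[eval_ids, "group"] == "case").to_numpy()

    cache: dict[bytes, tuple[pd.DataFrame, pd.DataFrame]] = {}

    def corrected_and_ranking(mask: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
        key = mask.tobytes()
        if key not in cache:
            corrected = apply_removal(expr, ruv, mask)
            ranking = rank_candidate_genes(corrected[train_ids],
                                           meta.loc[train_ids, "group"].to_numpy())
            cache[key] = (corrected, ranking)
        return cache[key]

    n_max = counts.shape[0]

    def build(position: np.ndarray):
        p_class = 10.0 ** position[0]
        p_conf = 10.0 ** position[1]
        n_genes = int(np.clip(round(position[2]), 1, n_max))
        cost = 2.0 ** position[3]
        gamma = 2.0 ** position[4]
        mask = removal_mask(pvals, p_class, p_conf)
        corrected, ranking = corrected_and_ranking(mask)
        genes = ranking["gene_id"].head(n_genes).tolist()
        x_tr = corrected.loc[genes, train_ids].to_numpy(dtype=float).T
        mean, scale = _standardize_fit(x_tr)
        svc = SVC(C=cost, gamma=gamma, kernel="rbf", probability=True,
                  random_state=pso_cfg.seed)
        _fit_svc(svc, (x_tr - mean) / scale, y_train.astype(int))
        return mask, genes, mean, scale, svc, corrected, (p_class, p_conf, cost, gamma)

    def objective(position: np.ndarray) -> float:
        try:
            mask, genes, mean, scale, svc, corrected, _ = build(position)
        except Exception:
            return 1.0
        x_ev = (corrected.loc[genes, eval_ids].to_numpy(dtype=float).T - mean) / scale
        proba = svc.predict_proba(x_ev)[:, 1]
        try:
            return 1.0 - roc_auc(y_eval, proba)
        except ValueError:
            return 1.0

    bounds = np.array([pso_cfg.bounds[p] for p in PSO_PARAMS], dtype=float)
    best_pos, best_fit, trace = pso_optimize(objective, pso_cfg, bounds)
    mask, genes, mean, scale, svc, corrected, (p_class, p_conf, cost, gamma) = build(best_pos)
    ruv.retained_mask = mask
    ruv.p_class_threshold = p_class
    ruv.p_confounder_threshold = p_conf
    ruv.confounder_names = list(confounders)

    x_tr = (corrected.loc[genes, train_ids].to_numpy(dtype=float).T - mean) / scale
    return ClassifierModel(
        kind="pso_svm", gene_ids=genes,
        params={"cost": cost, "gamma": gamma, "random_state": pso_cfg.seed,
                "X_train": x_tr.tolist(), "y_train": y_train.astype(int).tolist()},
        norm_ctx=ctx, ruv=ruv, scaler_mean=mean, scaler_scale=scale,
        training_meta={"seed": pso_cfg.seed, "best_fitness": best_fit, "trace": trace,
                       "partitions": {"training": train_ids, "evaluation": eval_ids},
                       "p_class_threshold": p_class, "p_confounder_threshold": p_conf},
    )


# --------------------------------------------------------------------------
# elastic net

def _lambda_grid(x: np.ndarray, y: np.ndarray, alpha: float, n_lambdas: int,
                 min_ratio: float) -> np.ndarray:
    """Data-derived lambda path, glmnet convention (largest kills all genes)."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(x.T @ resid).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambdas)


def _fit_en_point(x: np.ndarray, y: np.ndarray, alpha: float, lam: float,
                  warm: tuple[np.ndarray, float] | None = None,
                  max_iter: int = 3000, tol: float = 1e-9) -> tuple[np.ndarray, float]:
    """One (alpha, lambda) elastic-net logistic fit by accelerated proximal
    gradient (FISTA with adaptive restart), warm-startable along a path.

    Minimises (1/n) sum log(1+exp(eta)) - y*eta
              + lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)
    with an unpenalised intercept (the glmnet objective).
    """
    n, p = x.shape
    beta = np.zeros(p) if warm is None else warm[0].copy()
    b0 = 0.0 if warm is None else warm[1]
    l1, l2 = lam * alpha, lam * (1.0 - alpha)
    step_l = np.linalg.norm(x, 2) ** 2 / (4.0 * n) + l2 + 0.25

    def objective(be: np.ndarray, b_: float) -> float:
        eta = x @ be + b_
        return float(np.mean(np.logaddexp(0.0, eta) - y * eta)
                     + 0.5 * l2 * be @ be + l1 * np.abs(be).sum())

    bz, b0z, t = beta.copy(), b0, 1.0
    prev = objective(beta, b0)
    for it in range(max_iter):
        prob = 1.0 / (1.0 + np.exp(-(x @ bz + b0z)))
        grad = x.T @ (prob - y) / n + l2 * bz
        bn = bz - grad / step_l
        bn = np.sign(bn) * np.maximum(np.abs(bn) - l1 / step_l, 0.0)
        b0n = b0z - float(np.mean(prob - y)) / step_l
        tn = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        bz = bn + (t - 1.0) / tn * (bn - beta)
        b0z = b0n + (t - 1.0) / tn * (b0n - b0)
        beta, b0, t = bn, b0n, tn
        if it % 10 == 9:
            cur = objective(beta, b0)
            if abs(prev - cur) < tol * (abs(prev) + 1e-12):
                break
            if cur > prev:  # momentum overshoot: restart
                bz, b0z, t = beta.copy(), b0, 1.0
            prev = cur
    return beta, b0


def _en_predict_proba(x: np.ndarray, beta: np.ndarray, b0: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x @ beta + b0)))


def _downsample(idx: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Subsample the majority class among ``idx`` to the minority size."""
    pos = idx[y[idx] == 1]
    neg = idx[y[idx] == 0]
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, neg]))


def train_elastic_net(expr: pd.DataFrame, labels, cv_scheme: str = "kfold",
                      n_folds: int = 10, balance: str = "none", seed: int = 0,
                      l1_ratios: list[float] | None = None, n_lambdas: int = 50,
                      lambda_min_ratio: float = 1e-3) -> ClassifierModel:
    """Logistic elastic net over an (alpha, lambda) grid by cross-validated AUC.

    ``cv_scheme`` is ``"kfold"`` (default 10-fold, stratified) or
    ``"loocv"``; with LOOCV the AUC pools the single left-out predictions.
    ``balance="downsample"`` subsamples the majority class inside each CV
    training loop.  The best grid point is refit on all provided samples.
    """
    y = np.asarray(labels)
    y = (y == "case").astype(int) if y.dtype.kind in "OUS" else y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    if l1_ratios is None:
        l1_ratios = [round(0.1 * i, 1) for i in range(11)]

    x_raw = expr.to_numpy(dtype=float).T  # samples x genes
    mean, scale = _standardize_fit(x_raw)
    x = (x_raw - mean) / scale
    n = len(y)
    rng = np.random.default_rng(seed)

    if cv_scheme == "loocv":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif cv_scheme == "kfold":
        if n < n_folds:
            raise ValueError("fewer samples than folds")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(x, y))
    else:
        raise ValueError(f"unknown cv_scheme {cv_scheme!r}")

    lambdas = {a: _lambda_grid(x, y, a, n_lambdas, lambda_min_ratio) for a in l1_ratios}
    # held-out probabilities per grid point
    probs = {(a, li): np.full(n, np.nan) for a in l1_ratios for li in range(n_lambdas)}
    for tr, te in folds:
        if balance == "downsample":
            tr = _downsample(np.asarray(tr), y, rng)
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a CV training fold lost one class")
        for a in l1_ratios:
            warm = None
            for li, lam in enumerate(lambdas[a]):
                warm = _fit_en_point(x[tr], y[tr], a, lam, warm)
                probs[(a, li)][te] = _en_predict_proba(x[te], *warm)

    def cv_auc(a: float, li: int) -> float:
        p = probs[(a, li)]
        if cv_scheme == "loocv":
            return roc_auc(y, p)
        aucs = []
        for tr, te in folds:
            te = np.asarray(te)
            if len(np.unique(y[te])) == 2:
                aucs.append(roc_auc(y[te], p[te]))
        return float(np.mean(aucs)) if aucs else np.nan

    best = None
    for a in l1_ratios:
        for li in range(n_lambdas):
            auc = cv_auc(a, li)
            if np.isnan(auc):
                continue
            # ties prefer stronger regularisation (smaller li), smaller alpha
            key = (auc, -li, -a)
            if best is None or key > best[0]:
                best = (key, a, li)
    if best is None:
        raise ValueError("cross-validation produced no valid AUC")
    _, alpha, li = best
    lam = float(lambdas[alpha][li])
    coef, intercept = _fit_en_point(x, y, alpha, lam)

    return ClassifierModel(
        kind="elastic_net", gene_ids=list(expr.index),
        params={"coef": coef.tolist(), "intercept": float(intercept),
                "alpha": alpha, "lambda": lam},
        scaler_mean=mean, scaler_scale=scale,
        training_meta={"seed": seed, "cv_scheme": cv_scheme, "balance": balance,
                       "cv_auc": float(best[0][0]), "n_samples": n},
    )


# --------------------------------------------------------------------------
# prediction

def predict_proba(model: ClassifierModel, counts_new: pd.DataFrame,
                  meta_new: pd.DataFrame | None = None) -> pd.Series:
    """Case probability for new samples using the stored training context.

    New samples are TMM-normalised against the frozen reference, cpm-log2
    transformed, RUV-corrected by projection with the stored factor basis,
    and scored.  Labels of the new samples are never read (the interface
    does not accept them).
    """
    if counts_new.shape[1] == 0:
        raise ValueError("no samples to predict")
    if model.norm_ctx is None:
        raise ValueError("model carries no normalisation context")
    needed = model.norm_ctx.gene_ids
    missing = set(needed) - set(counts_new.index)
    if missing:
        raise ValueError(f"{len(missing)} model genes missing from input")
    counts_new = counts_new.loc[needed]
    expr = cpm_log2(counts_new, model.norm_ctx)
    if model.ruv is not None and model.ruv.retained_mask is not None:
        expr = apply_removal(expr, model.ruv)
    x = expr.loc[model.gene_ids].to_numpy(dtype=float).T
    if model.scaler_mean is not None:
        x = (x - model.scaler_mean) / model.scaler_scale
    scores = model.decision_scores(x)
    return pd.Series(scores, index=counts_new.columns, name="case_probability")
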