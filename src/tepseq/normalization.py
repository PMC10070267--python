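"""Subset-aware TMM normalisation and RUV unwanted-variation removal.

TMM (trimmed mean of M-values) scaling factors are computed against a
reference sample chosen from a designated *training* subset only, and the
factor normalisation constant is the geometric mean over training samples.
Validation or external samples can then be normalised against the frozen
training-derived reference without ever influencing the training factors
(no leakage from validation into training).

RUV ("remove unwanted variation") estimates latent factors by singular
value decomposition of the gene-centred log-expression of the training
samples.  Factors are removed only when they look technical rather than
biological, via a dual t-test rule: a factor is regressed out iff

(a) its association p-value with case-control status exceeds
    ``p_class_threshold`` (it does not carry class signal), AND
(b) its association p-value with at least one nuisance covariate (age,
    library size, hospital of origin) is below ``p_confounder_threshold``.

Removal is an orthogonal projection in gene space, so it applies unchanged
to new samples and is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats


# --------------------------------------------------------------------------
# TMM

@dataclass
class NormContext:
    """Training-derived TMM normalisation state, reusable on new samples."""

    reference_sample_id: str
    tmm_factor: dict[str, float]
    training_sample_ids: list[str]
    trim_m: float = 0.30
    trim_a: float = 0.05
    prior_count: float = 1.0
    gene_ids: list[str] = field(default_factory=list)
    ref_counts: np.ndarray | None = None  # reference profile, frozen
    norm_const: float = 1.0  # geometric-mean normaliser from training factors

    def factor_for(self, counts_col: np.ndarray) -> float:
        """TMM factor of an arbitrary sample against the frozen reference."""
        raw = _tmm_pair(counts_col, self.ref_counts, self.trim_m, self.trim_a)
        return float(raw / self.norm_const)

    def to_dict(self) -> dict:
        return {
            "reference_sample_id": self.reference_sample_id,
            "tmm_factor": self.tmm_factor,
            "training_sample_ids": self.training_sample_ids,
            "trim_m": self.trim_m,
            "trim_a": self.trim_a,
            "prior_count": self.prior_count,
            "gene_ids": self.gene_ids,
            "ref_counts": None if self.ref_counts is None else self.ref_counts.tolist(),
            "norm_const": self.norm_const,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormContext":
        d = dict(d)
        if d.get("ref_counts") is not None:
            d["ref_counts"] = np.asarray(d["ref_counts"], dtype=float)
        return cls(**d)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float) -> float:
    """Weighted trimmed mean of M-values of one sample against a reference.

    Classical TMM: double trim on M (log-ratio) and A (log-abundance),
    inverse-(approximate-)variance weights, factor = 2**(weighted mean M).
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n_o, n_r = obs.sum(), ref.sum()
    if n_o <= 0 or n_r <= 0:
        raise ValueError("zero library size")
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    po, pr = obs[pos] / n_o, ref[pos] / n_r
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # delta-method variance of each M-value computed from proportions, so
    # factors are exactly invariant to rescaling any sample's counts
    w = (1.0 - po) / po + (1.0 - pr) / pr

    if np.allclose(m, m[0], atol=1e-10):  # identical composition
        return float(2.0 ** m[0]) if abs(m[0]) > 1e-10 else 1.0

    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        return 1.0
    w = w[keep]
    with np.errstate(divide="ignore"):
        inv_w = np.where(w > 0, 1.0 / w, 0.0)
    if inv_w.sum() == 0:
        return float(2.0 ** m[keep].mean())
    return float(2.0 ** (np.sum(m[keep] * inv_w) / np.sum(inv_w)))


def compute_tmm_factors(counts: pd.DataFrame, training_ids: list[str] | None = None,
                        trim_m: float = 0.30, trim_a: float = 0.05,
                        prior_count: float = 1.0) -> NormContext:
    """TMM factors for every sample, reference drawn from training samples only.

    The reference is the training sample whose upper-quartile cpm is closest
    to the mean training upper-quartile.  Factors are scaled so their
    geometric mean over the training samples is 1; adding or removing
    non-training samples therefore never changes training factors.
    """
    if counts.empty:
        raise ValueError("empty count matrix")
    all_ids = list(counts.columns)
    training_ids = list(training_ids) if training_ids is not None else all_ids
    if not training_ids or not set(training_ids) <= set(all_ids):
        raise ValueError("training_ids must be a non-empty subset of the samples")

    lib = counts.sum(axis=0)
    if (lib[training_ids] <= 0).any():
        raise ValueError("training sample with zero library size")
    uq = counts[training_ids].apply(lambda c: np.quantile(c / c.sum(), 0.75))
    ref_id = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_id].to_numpy(dtype=float)

    raw = {s: _tmm_pair(counts[s].to_numpy(dtype=float), ref, trim_m, trim_a)
           for s in all_ids}
    norm_const = float(np.exp(np.mean([np.log(raw[s]) for s in training_ids])))
    factors = {s: float(raw[s] / norm_const) for s in all_ids}

    return NormContext(
        reference_sample_id=str(ref_id), tmm_factor=factors,
        training_sample_ids=training_ids, trim_m=trim_m, trim_a=trim_a,
        prior_count=prior_count, gene_ids=list(counts.index),
        ref_counts=ref, norm_const=norm_const,
    )


def cpm_log2(counts: pd.DataFrame, ctx: NormContext) -> pd.DataFrame:
    """log2(cpm + prior) with TMM-adjusted effective library sizes.

    Samples absent from the context get a factor computed on the fly
    against the stored training reference (the context is never refit).
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    factors = np.array([
        ctx.tmm_factor[s] if s in ctx.tmm_factor
        else ctx.factor_for(counts[s].to_numpy(dtype=float))
        for s in counts.columns
    ])
    eff = lib * factors
    vals = np.log2(counts.to_numpy(dtype=float) / eff[None, :] * 1e6 + ctx.prior_count)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


# --------------------------------------------------------------------------
# RUV

@dataclass
class RUVModel:
    """SVD factor model of unwanted variation, fit on training samples."""

    k: int
    gene_ids: list[str]
    sample_ids: list[str]
    gene_means: np.ndarray  # (genes,) training means
    basis: np.ndarray  # (genes, k) left singular vectors, orthonormal
    singular_values: np.ndarray  # (k,)
    factor_scores: np.ndarray  # (samples, k) right singular vectors, orthonormal
    retained_mask: np.ndarray | None = None  # True -> factor regressed out
    p_class_threshold: float = 0.01
    p_confounder_threshold: float = 0.01
    confounder_names: list[str] = field(default_factory=list)
    factor_pvalues: dict | None = None  # per factor: p_class, p_<confounder>

    @property
    def factor_loadings(self) -> np.ndarray:
        """(genes, k) loadings so that centred expr ~= loadings @ scores.T."""
        return self.basis * self.singular_values[None, :]

    def scores_for(self, expr: pd.DataFrame) -> np.ndarray:
        """Project (possibly new) samples onto the fitted factor directions."""
        x = expr.loc[self.gene_ids].to_numpy(dtype=float) - self.gene_means[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            return (x.T @ self.basis) / np.where(self.singular_values > 0,
                                                 self.singular_values, 1.0)

    def to_dict(self) -> dict:
        return {
            "k": self.k, "gene_ids": self.gene_ids, "sample_ids": self.sample_ids,
            "gene_means": self.gene_means.tolist(), "basis": self.basis.tolist(),
            "singular_values": self.singular_values.tolist(),
            "factor_scores": self.factor_scores.tolist(),
            "retained_mask": None if self.retained_mask is None else self.retained_mask.tolist(),
            "p_class_threshold": self.p_class_threshold,
            "p_confounder_threshold": self.p_confounder_threshold,
            "confounder_names": self.confounder_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RUVModel":
        d = dict(d)
        d.pop("factor_pvalues", None)
        for key in ("gene_means", "basis", "singular_values", "factor_scores"):
            d[key] = np.asarray(d[key], dtype=float)
        if d.get("retained_mask") is not None:
            d["retained_mask"] = np.asarray(d["retained_mask"], dtype=bool)
        return cls(**d)


def fit_ruv(expr: pd.DataFrame, k: int) -> RUVModel:
    """First ``k`` singular components of the gene-centred expression matrix."""
    if k < 0:
        raise ValueError("k must be >= 0")
    n_genes, n_samples = expr.shape
    if k >= min(n_genes, n_samples) and k > 0:
        raise ValueError("k must be < min(genes, samples)")
    # contiguous copy: the fit must depend on values only, not memory layout
    x = np.ascontiguousarray(expr.to_numpy(dtype=float))
    means = x.mean(axis=1)
    xc = x - means[:, None]
    if k == 0:
        return RUVModel(k=0, gene_ids=list(expr.index), sample_ids=list(expr.columns),
                        gene_means=means, basis=np.zeros((n_genes, 0)),
                        singular_values=np.zeros(0), factor_scores=np.zeros((n_samples, 0)))
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    return RUVModel(k=k, gene_ids=list(expr.index), sample_ids=list(expr.columns),
                    gene_means=means, basis=u[:, :k], singular_values=s[:k],
                    factor_scores=vt[:k].T)


def _binary_t_p(scores: np.ndarray, groups: np.ndarray) -> float:
    """Two-sample Welch t-test p-value of factor scores between two groups."""
    a, b = scores[groups], scores[~groups]
    if len(a) < 2 or len(b) < 2 or (np.std(a) == 0 and np.std(b) == 0):
        return np.nan
    return float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)


def _assoc_p(scores: np.ndarray, values: np.ndarray) -> float:
    """Association p-value of factor scores with one covariate.

    Binary / categorical covariates use a two-sample t-test (each level vs
    the rest; minimum p over levels); continuous covariates use the t-test
    of the simple-regression slope.
    """
    values = np.asarray(values)
    if values.dtype.kind in "OUSb" or len(np.unique(values)) <= max(5, 2):
        levels = np.unique(values)
        if len(levels) < 2:
            return np.nan
        if len(levels) == 2:
            return _binary_t_p(scores, values == levels[0])
        ps = [_binary_t_p(scores, values == lev) for lev in levels]
        ps = [p for p in ps if not np.isnan(p)]
        return float(min(ps)) if ps else np.nan
    if np.std(values) == 0 or np.std(scores) == 0:
        return np.nan
    return float(scipy.stats.linregress(values.astype(float), scores).pvalue)


def score_factor_pvalues(model: RUVModel, class_labels: np.ndarray,
                         confounders: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-factor association p-values with class and each confounder."""
    labels = np.asarray(class_labels)
    is_case = labels == "case" if labels.dtype.kind in "OUS" else labels.astype(bool)
    rows = []
    for j in range(model.k):
        v = model.factor_scores[:, j]
        row = {"factor": j}
        if np.std(v) == 0:
            warnings.warn(f"RUV factor {j} is constant; association tests undefined")
            row["p_class"] = np.nan
            for name in confounders:
                row[f"p_{name}"] = np.nan
        else:
            row["p_class"] = _binary_t_p(v, is_case)
            for name, vals in confounders.items():
                row[f"p_{name}"] = _assoc_p(v, np.asarray(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def removal_mask(pvals: pd.DataFrame, p_class_threshold: float = 0.01,
                 p_confounder_threshold: float = 0.01) -> np.ndarray:
    """Dual-threshold retention rule: remove a factor iff it carries no
    class signal (p_class > a) and tracks at least one confounder (p < b)."""
    conf_cols = [c for c in pvals.columns if c.startswith("p_") and c != "p_class"]
    mask = np.zeros(len(pvals), dtype=bool)
    for i, row in pvals.iterrows():
        if np.isnan(row["p_class"]):
            continue  # constant factor: skipped
        conf_ps = np.array([row[c] for c in conf_cols], dtype=float)
        conf_ok = np.nanmin(conf_ps) < p_confounder_threshold if conf_cols and not np.isnan(conf_ps).all() else False
        mask[i] = (row["p_class"] > p_class_threshold) and conf_ok
    return mask


def apply_removal(expr: pd.DataFrame, model: RUVModel,
                  mask: np.ndarray | None = None) -> pd.DataFrame:
    """Regress the masked factors out of expression (gene-space projection).

    corrected = mean + (I - U_m U_m^T)(x - mean); idempotent, and valid for
    samples the model never saw.
    """
    mask = model.retained_mask if mask is None else mask
    if mask is None or model.k == 0 or not np.any(mask):
        return expr.copy()
    u = model.basis[:, np.asarray(mask, dtype=bool)]
    x = expr.loc[model.gene_ids].to_numpy(dtype=float)
    xc = x - model.gene_means[:, None]
    corrected = model.gene_means[:, None] + xc - u @ (u.T @ xc)
    return pd.DataFrame(corrected, index=model.gene_ids, columns=expr.columns)


def select_and_remove_ruv_factors(expr: pd.DataFrame, model: RUVModel,
                                  class_labels, confounders: dict,
                                  p_class_threshold: float = 0.01,
                                  p_confounder_threshold: float = 0.01
                                  ) -> tuple[pd.DataFrame, RUVModel]:
    """Apply the dual-threshold rule and regress out the flagged factors."""
    pvals = score_factor_pvalues(model, np.asarray(class_labels), confounders)
    mask = removal_mask(pvals, p_class_threshold, p_confounder_threshold)
    model.retained_mask = mask
    model.p_class_threshold = p_class_threshold
    model.p_confounder_threshold = p_confounder_threshold
    model.confounder_names = list(confounders)
    model.factor_pvalues = pvals.to_dict(orient="list")
    return apply_removal(expr, model, mask), model


def ruv_correct(expr: pd.DataFrame, class_labels, confounders: dict,
                k: int = 10, p_class_threshold: float = 0.01,
                p_confounder_threshold: float = 0.01,
                n_rounds: int = 2) -> tuple[pd.DataFrame, list[RUVModel]]:
    """Fit-select-remove, then re-estimate once on the corrected data.

    Two rounds by default: the second pass catches unwanted variation that
    the first projection uncovered; further iteration is not performed.
    """
    models: list[RUVModel] = []
    current = expr
    for _ in range(n_rounds):
        k_eff = min(k, min(current.shape) - 1)
        model = fit_ruv(current, max(k_eff, 0))
        current, model = select_and_remove_ruv_factors(
            current, model, class_labels, confounders,
            p_class_threshold, p_confounder_threshold)
        models.append(model)
        if model.retained_mask is None or not model.retained_mask.any():
            break
    return current, models
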