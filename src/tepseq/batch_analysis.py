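"""Confounding diagnostics: variance partitioning, differential expression,
ComBat batch correction, over-representation tests and contamination scores.

* ``variance_partition`` fits, per gene, a linear mixed model with age as a
  fixed effect and hospital / cancer status as random intercepts (the
  variancePartition convention: discrete design variables are random
  effects, the fixed-effect share is the variance of its fitted
  contribution), returning per-gene variance fractions that sum to one.
* ``nb_glm_de`` fits per-gene negative-binomial GLMs with log link and TMM
  offsets, vectorised across genes (all genes share the design matrix), and
  tests a contrast with a quasi-likelihood F-test.  Dispersions are
  method-of-moments estimates squeezed toward the dataset trend -- a
  deliberately simple moderation scheme.
* ``combat_correct`` is parametric empirical-Bayes ComBat (per-gene,
  per-batch location/scale adjustment), applied as an intercept model.
* ``ora_test`` is the hypergeometric over-representation test on
  user-supplied gene sets.
* ``contamination_scores`` summarises marker-module expression per sample
  (erythrocyte / lymphocyte admixture screening).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


@dataclass
class DesignSpec:
    """Model terms drawn from metadata columns.

    ``fixed`` enter the mean model (continuous as-is, categorical as
    treatment-coded dummies); ``random`` are random-intercept terms for the
    mixed model.  Encodes the study formulas ~age+group+hosp, ~age+hosp and
    ~Age + (1|hosp) + (1|cancer).
    """

    fixed: tuple[str, ...] = ("age", "group", "hospital")
    random: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        terms = list(self.fixed) + list(self.random)
        if len(set(terms)) != len(terms):
            raise ValueError("duplicated design term")

    def validate(self, meta: pd.DataFrame) -> None:
        for term in (*self.fixed, *self.random):
            if term not in meta.columns:
                raise ValueError(f"design term {term!r} not in metadata")


def build_design_matrix(meta: pd.DataFrame, terms: tuple[str, ...]
                        ) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded design matrix for the given terms."""
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["intercept"]
    for term in terms:
        v = meta[term]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(dtype=float))
            names.append(term)
        else:
            levels = sorted(v.astype(str).unique())
            # "control" is the natural reference level when present
            if "control" in levels:
                levels = ["control"] + [l for l in levels if l != "control"]
            for lev in levels[1:]:
                cols.append((v.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is not full rank")
    return x, names


# --------------------------------------------------------------------------
# variance partition

def variance_partition(expr: pd.DataFrame, meta: pd.DataFrame,
                       design: DesignSpec | None = None) -> pd.DataFrame:
    """Per-gene variance fractions from a linear mixed model.

    Defaults to age fixed + (1|hospital) + (1|cancer).  Returns a DataFrame
    indexed by gene with one ``fraction_<term>`` column per design term plus
    ``fraction_residual`` and a ``converged`` flag; fractions sum to 1.
    """
    design = design or DesignSpec(fixed=("age",), random=("hospital", "group"))
    design.validate(meta)
    for term in design.random:
        if meta[term].nunique() < 2:
            raise ValueError(f"random term {term!r} needs >= 2 levels")

    df = meta.reset_index(drop=True).copy()
    df["_one"] = 1
    vc = {term: f"0 + C({term})" for term in design.random}
    fixed_formula = "y ~ " + (" + ".join(design.fixed) if design.fixed else "1")

    pretty = {"group": "cancer", "hosp": "hospital"}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene in expr.index:
            df["y"] = expr.loc[gene].to_numpy(dtype=float)
            md = sm.MixedLM.from_formula(fixed_formula, groups="_one", vc_formula=vc, data=df)
            try:
                # powell is robust at the vcomp=0 boundary where
                # gradient-based optimizers stall on null genes
                fit = md.fit(reml=True, method="powell")
                converged = bool(fit.converged)
            except Exception:
                fit, converged = None, False
            row = {"gene_id": gene, "converged": converged}
            if fit is None:
                for term in (*design.fixed, *design.random):
                    row[f"fraction_{pretty.get(term, term)}"] = np.nan
                row["fraction_residual"] = np.nan
            else:
                comps: dict[str, float] = {}
                # statsmodels orders variance components by sorted vc name
                for i, term in enumerate(sorted(design.random)):
                    comps[term] = max(float(fit.vcomp[i]), 0.0)
                for term in design.fixed:
                    contrib = fit.fe_params.get(term, 0.0) * df[term].to_numpy(dtype=float)
                    comps[term] = float(np.var(contrib))
                resid = max(float(fit.scale), 0.0)
                total = sum(comps.values()) + resid
                for term, v in comps.items():
                    row[f"fraction_{pretty.get(term, term)}"] = v / total
                row["fraction_residual"] = resid / total
            rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


# --------------------------------------------------------------------------
# NB GLM differential expression

def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB2 deviance, rows = genes."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        r = 1.0 / phi
        term2 = (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * (term1 - term2).sum(axis=1)


def _nb_irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray, phi: np.ndarray,
             n_iter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS for per-gene NB GLMs sharing one design matrix.

    y: (G, n) counts; x: (n, p); offset: (n,) or (G, n); phi: (G,) dispersions.
    Returns (beta (G, p), mu (G, n)).
    """
    g, n = y.shape
    p = x.shape[1]
    offset = np.broadcast_to(np.atleast_2d(offset), (g, n))
    phi = phi[:, None]
    mu = np.maximum(y, 0.5).astype(float)
    eta = np.log(mu)
    beta = np.zeros((g, p))
    dev = _nb_deviance(y, mu, phi)
    for _ in range(n_iter):
        w = mu / (1.0 + phi * mu)
        z = eta - offset + (y - mu) / mu
        a = np.einsum("ni,gn,nj->gij", x, w, x)
        b = np.einsum("ni,gn->gi", x, w * z)
        a[:, np.arange(p), np.arange(p)] += 1e-10
        beta = np.linalg.solve(a, b[..., None])[..., 0]
        eta = beta @ x.T + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        new_dev = _nb_deviance(y, mu, phi)
        if np.all(np.abs(new_dev - dev) < tol * (np.abs(dev) + 1.0)):
            dev = new_dev
            break
        dev = new_dev
    return beta, mu


def estimate_dispersions(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
                         prior_df: float = 10.0) -> np.ndarray:
    """Method-of-moments per-gene dispersions squeezed toward the trend.

    A Poisson-limit fit supplies fitted means; the per-gene estimate
    phi = sum((y-mu)^2 - mu) / sum(mu^2) (floored at ~0) is shrunk toward
    the trimmed-mean dispersion with ``prior_df`` pseudo-residual-df.
    """
    g, n = y.shape
    p = x.shape[1]
    _, mu = _nb_irls(y, x, offset, np.full(g, 1e-4))
    num = ((y - mu) ** 2 - mu).sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    raw = np.maximum(num / np.maximum(den, 1e-12), 1e-6)
    trend = float(scipy.stats.trim_mean(raw, 0.125))
    df_res = max(n - p, 1)
    return (prior_df * trend + df_res * raw) / (prior_df + df_res)


def nb_glm_de(counts: pd.DataFrame, meta: pd.DataFrame,
              design: DesignSpec | None = None, contrast: str = "group",
              tmm_factors: dict[str, float] | None = None,
              ql_prior_df: float = 10.0) -> pd.DataFrame:
    """Per-gene NB GLM differential expression with a quasi-likelihood F-test.

    The contrast term's coefficients are dropped to form the reduced model;
    the deviance difference, scaled by a squeezed quasi-dispersion, is
    referred to an F distribution.  Returns log2 fold change (for a
    single-coefficient contrast), dispersion, statistic, p-value and BH FDR.
    """
    design = design or DesignSpec(fixed=("age", "group", "hospital"))
    design.validate(meta)
    if contrast not in design.fixed:
        raise ValueError(f"contrast {contrast!r} not a design term")
    x_full, names = build_design_matrix(meta, design.fixed)
    test_cols = [i for i, nm in enumerate(names)
                 if nm == contrast or nm.startswith(f"{contrast}[")]
    x_red = np.delete(x_full, test_cols, axis=1)

    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    factors = np.array([
        (tmm_factors or {}).get(s, 1.0) for s in counts.columns
    ])
    offset = np.log(lib * factors)

    phi = estimate_dispersions(y, x_full, offset)
    beta_full, mu_full = _nb_irls(y, x_full, offset, phi)
    _, mu_red = _nb_irls(y, x_red, offset, phi)

    dev_full = _nb_deviance(y, mu_full, phi[:, None])
    dev_red = _nb_deviance(y, mu_red, phi[:, None])
    lrt = np.maximum(dev_red - dev_full, 0.0)
    df1 = len(test_cols)
    n, p = x_full.shape
    df_res = max(n - p, 1)

    pearson = ((y - mu_full) ** 2 / (mu_full * (1.0 + phi[:, None] * mu_full))).sum(axis=1)
    s2 = pearson / df_res
    s2_mean = float(np.mean(s2))
    s2_sq = (ql_prior_df * s2_mean + df_res * s2) / (ql_prior_df + df_res)

    f_stat = (lrt / df1) / np.maximum(s2_sq, 1e-12)
    pvals = scipy.stats.f.sf(f_stat, df1, df_res + ql_prior_df)
    fdr = sm.stats.multipletests(pvals, method="fdr_bh")[1]

    log2fc = (beta_full[:, test_cols[0]] / np.log(2.0)) if df1 == 1 else np.full(len(y), np.nan)
    return pd.DataFrame({
        "log2fc": log2fc, "dispersion": phi, "statistic": f_stat,
        "pvalue": pvals, "fdr": fdr,
    }, index=counts.index)


# --------------------------------------------------------------------------
# ComBat

def combat_correct(expr: pd.DataFrame, batch_labels,
                   covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Parametric empirical-Bayes ComBat location/scale batch adjustment.

    Intercept model by default (no biological covariates retained).  A
    single batch returns the input unchanged with a warning.
    """
    batch = np.asarray(batch_labels)
    levels = sorted(pd.unique(batch).tolist())
    if len(levels) < 2:
        warnings.warn("single batch: ComBat is the identity")
        return expr.copy()
    counts_per = {lev: int((batch == lev).sum()) for lev in levels}
    if min(counts_per.values()) < 2:
        raise ValueError("each batch needs >= 2 samples")

    x = expr.to_numpy(dtype=float)
    n_genes, n = x.shape
    # design: batch dummies (+ optional covariates); full-rank batch coding
    b_mat = np.column_stack([(batch == lev).astype(float) for lev in levels])
    design = b_mat
    if covariates is not None:
        design = np.column_stack([b_mat, np.asarray(covariates, dtype=float)])

    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    n_b = np.array([counts_per[lev] for lev in levels], dtype=float)
    grand = (n_b / n) @ beta[:len(levels)]  # gene-wise grand mean
    stand_mean = np.tile(grand[:, None], (1, n))
    if covariates is not None:
        stand_mean += (np.asarray(covariates, dtype=float) @ beta[len(levels):]).T
    var_pooled = ((x - (design @ beta).T) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    z = (x - stand_mean) / np.sqrt(var_pooled)[:, None]

    x_adj = x.copy()
    for j, lev in enumerate(levels):
        sel = batch == lev
        zb = z[:, sel]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        # EB hyperpriors (method of moments)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        d_bar, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2 * s2 + d_bar ** 2) / s2 if s2 > 0 else 2.0
        b_prior = (d_bar * s2 + d_bar ** 3) / s2 if s2 > 0 else d_bar
        nb = sel.sum()
        g_star, d_star = g_hat.copy(), d_hat.copy()
        for _ in range(100):
            g_new = (t2 * nb * g_hat + d_star * g_bar) / (t2 * nb + d_star)
            ssd = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * ssd + b_prior) / (nb / 2.0 + a_prior - 1.0)
            if np.max(np.abs(g_new - g_star)) < 1e-8 and np.max(np.abs(d_new - d_star)) < 1e-8:
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        x_adj[:, sel] = ((z[:, sel] - g_star[:, None]) / np.sqrt(d_star)[:, None]
                         * np.sqrt(var_pooled)[:, None] + stand_mean[:, sel])
    return pd.DataFrame(x_adj, index=expr.index, columns=expr.columns)


# --------------------------------------------------------------------------
# over-representation and contamination

def ora_test(selected_genes, gene_set, universe) -> tuple[float, int]:
    """Hypergeometric upper-tail over-representation test.

    Returns (p-value, overlap count) for the observed overlap between the
    selected genes and the gene set, within the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected_genes) & universe
    gs = set(gene_set) & universe
    overlap = len(selected & gs)
    m, k_set, n_sel = len(universe), len(gs), len(selected)
    p = float(scipy.stats.hypergeom.sf(overlap - 1, m, k_set, n_sel))
    return min(p, 1.0), overlap


def contamination_scores(expr: pd.DataFrame, marker_sets: dict[str, list[str]]
                         ) -> pd.DataFrame:
    """Mean expression over each marker gene set, per sample."""
    out = {}
    for name, genes in marker_sets.items():
        genes = [g for g in genes if g in expr.index]
        if not genes:
            raise ValueError(f"marker set {name!r} has no genes in the matrix")
        out[name] = expr.loc[genes].mean(axis=0)
    return pd.DataFrame(out)
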