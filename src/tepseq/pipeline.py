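"""End-to-end experiments: multicentre training, blinded external validation.

``run_multicentre_experiment`` executes the full pipeline on synthetic data
(or user-supplied matrices): QC, stage-stratified partitioning with
age-matched controls, subset-aware TMM, PSO-SVM and elastic-net training,
internal-validation evaluation (all stages / early / late) and a
variance-partition summary.

``make_external_set`` draws a single-centre external validation cohort from
the same generative biology but a *fresh batch* (new hospital-effect
vectors and noise), modelling the observation that every new batch of the
assay behaves like a new distribution.  ``run_blinded_validation`` applies
a stored model to such a cohort without ever reading its labels; metrics
are computed only in a separate linking step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tepseq import io as tio
from tepseq.batch_analysis import DesignSpec, variance_partition
from tepseq.classifiers import (ClassifierModel, PSOConfig, predict_proba,
                                train_elastic_net, train_pso_svm)
from tepseq.evaluation import EvalConfig, stage_stratified_metrics
from tepseq.normalization import compute_tmm_factors, cpm_log2
from tepseq.partitioning import PartitionConfig, assign_partitions
from tepseq.qc import QCConfig, run_qc
from tepseq.synthetic_data import (DesignTable, SimConfig, attach_lib_size, balanced_design,
                                   build_confounded_design, simulate_counts)

#: Default single-centre external validation design (one hospital, fresh batch).
EXTERNAL_DESIGN = DesignTable(rows=(("NKI", 37, 36),))


@dataclass
class ExperimentReport:
    seed: int
    config: dict
    qc: dict
    partition_sizes: dict
    metrics: dict  # classifier -> subset -> metric dict
    variance_fractions: dict
    models: dict = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        return {"seed": self.seed, "config": self.config, "qc": self.qc,
                "partition_sizes": self.partition_sizes, "metrics": self.metrics,
                "variance_fractions": self.variance_fractions}


def default_recipe(confounded: bool = True) -> dict:
    """The study-condition recipe for synthetic experiments.

    The confounded recipe pairs a strong hospital effect on the platelet
    activation module with a weak case-control signal, under the skewed
    case/control-by-hospital design; the unconfounded recipe uses a
    balanced design, no hospital effect and a strong case signal.
    """
    if confounded:
        return {
            "design": "confounded",
            "sim": {"hospital_effect_sd": 0.6, "case_effect_sd": 0.05},
            "external_fresh_batch": True,
        }
    return {
        "design": "balanced",
        "sim": {"hospital_effect_sd": 0.0, "case_effect_sd": 0.5},
        "external_fresh_batch": False,
    }


def _sim_config(config: dict, seed: int) -> SimConfig:
    overrides = dict(config.get("sim", {}))
    overrides.setdefault("seed", seed)
    return SimConfig(**overrides)


def _design_table(config: dict) -> DesignTable:
    spec = config.get("design", "confounded")
    if spec == "confounded":
        return DesignTable()
    if spec == "balanced":
        return balanced_design(n_hospitals=4, cases_per_hospital=35, controls_per_hospital=35)
    if isinstance(spec, (list, tuple)):
        return DesignTable(rows=tuple(tuple(r) for r in spec))
    raise ValueError(f"unknown design spec {spec!r}")


def simulate_experiment_data(config: dict, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the multicentre cohort for a recipe; deterministic given seed."""
    table = _design_table(config)
    meta = build_confounded_design(table, seed=seed)
    cfg = _sim_config(config, seed)
    counts = simulate_counts(meta, cfg, seed=seed + 1)
    return counts, meta


def _stage_of(meta: pd.DataFrame, ids: pd.Index) -> np.ndarray:
    return meta.set_index("sample_id").loc[ids, "stage"].astype(str).to_numpy()


def run_multicentre_experiment(config: dict | None = None, seed: int = 0,
                               counts: pd.DataFrame | None = None,
                               meta: pd.DataFrame | None = None,
                               outdir: str | Path | None = None,
                               run_variance_partition: bool = True) -> ExperimentReport:
    """QC -> partition -> normalise -> train (PSO-SVM, EN) -> evaluate.

    When ``counts``/``meta`` are not given they are simulated from the
    recipe in ``config`` (default: the confounded multicentre recipe).
    """
    config = dict(config) if config else default_recipe(confounded=True)
    if counts is None or meta is None:
        counts, meta = simulate_experiment_data(config, seed)

    qc_cfg = QCConfig(**config.get("qc", {}))
    counts_qc, qc_report = run_qc(counts, qc_cfg)
    meta = meta[meta["sample_id"].isin(counts_qc.columns)].reset_index(drop=True)
    meta = attach_lib_size(meta, counts_qc)
    meta = assign_partitions(meta, PartitionConfig(seed=seed + 2))

    pso_over = dict(config.get("pso", {}))
    pso_over.setdefault("seed", seed + 3)
    pso_cfg = PSOConfig(**pso_over)
    model_svm = train_pso_svm(counts_qc, meta, pso_cfg, ruv_k=int(config.get("ruv_k", 10)))

    # EN trains on training+evaluation combined, TMM-cpm-log2 (no RUV by default)
    midx = meta.set_index("sample_id")
    fit_ids = midx.index[midx["partition"].isin(["training", "evaluation"])].tolist()
    ctx = compute_tmm_factors(counts_qc[fit_ids], training_ids=fit_ids)
    expr_fit = cpm_log2(counts_qc[fit_ids], ctx)
    en_kwargs = dict(config.get("en", {}))
    en_kwargs.setdefault("l1_ratios", [0.1, 0.5, 0.9])
    en_kwargs.setdefault("n_lambdas", 10)
    en_kwargs.setdefault("lambda_min_ratio", 0.01)
    model_en = train_elastic_net(expr_fit, midx.loc[fit_ids, "group"].to_numpy(),
                                 seed=seed + 4, **en_kwargs)
    model_en.norm_ctx = ctx

    eval_cfg = EvalConfig()
    internal_ids = midx.index[midx["partition"] == "internal_validation"]
    metrics: dict[str, dict] = {}
    predictions: dict[str, pd.Series] = {}
    for name, model in (("pso_svm", model_svm), ("elastic_net", model_en)):
        scores = predict_proba(model, counts_qc[list(internal_ids)])
        predictions[name] = scores
        labels = midx.loc[internal_ids, "group"].to_numpy()
        strat = stage_stratified_metrics(labels, scores.to_numpy(),
                                         _stage_of(meta, internal_ids), eval_cfg)
        metrics[name] = {"internal_" + k: m.as_dict() for k, m in strat.items()}

    vp_summary: dict = {}
    if run_variance_partition:
        ctx_all = compute_tmm_factors(counts_qc)
        expr_all = cpm_log2(counts_qc, ctx_all)
        rng = np.random.default_rng(seed + 5)
        n_vp = min(int(config.get("vp_genes", 100)), expr_all.shape[0])
        genes = sorted(rng.choice(expr_all.index, size=n_vp, replace=False).tolist())
        vp = variance_partition(expr_all.loc[genes], meta,
                                DesignSpec(fixed=("age",), random=("hospital", "group")))
        vp_summary = {c: float(vp[c].mean()) for c in vp.columns if c.startswith("fraction_")}

    part_sizes = meta.groupby(["partition", "group"]).size()
    report = ExperimentReport(
        seed=seed, config=config, qc=qc_report.as_dict(),
        partition_sizes={f"{p}/{g}": int(v) for (p, g), v in part_sizes.items()},
        metrics=metrics, variance_fractions=vp_summary,
        models={"pso_svm": model_svm, "elastic_net": model_en},
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_json(report.as_dict(), outdir / "report.json")
        tio.write_meta_tsv(meta, outdir / "meta.tsv")
        model_svm.save(outdir / "model_pso_svm.json")
        model_en.save(outdir / "model_elastic_net.json")
        for name, scores in predictions.items():
            pd.DataFrame({"sample_id": scores.index, "score": scores.to_numpy()}
                         ).to_csv(outdir / f"predictions_{name}.tsv", sep="\t", index=False)
    return report


def make_external_set(config: dict | None = None, seed: int = 1000,
                      design: DesignTable = EXTERNAL_DESIGN
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-centre external cohort: same biology, fresh batch by default.

    The simulation config (hence gene baselines and the case signal) is
    shared with the multicentre recipe via ``SimConfig.seed``; the batch
    randomness seed is new, so with ``external_fresh_batch`` the hospital
    effect vector differs from anything seen in training.
    """
    config = dict(config) if config else default_recipe(confounded=True)
    base_seed = int(config.get("base_seed", 0))
    meta = build_confounded_design(design, seed=seed)
    cfg = _sim_config(config, base_seed)
    batch_seed = seed + 1 if config.get("external_fresh_batch", True) else base_seed + 1
    counts = simulate_counts(meta, cfg, seed=batch_seed)
    return counts, meta


def run_blinded_validation(model: ClassifierModel, counts: pd.DataFrame,
                           meta_without_labels: pd.DataFrame) -> pd.DataFrame:
    """Prediction phase of blinded validation: no label access.

    Returns a predictions table (sample_id, score) with no label column.
    """
    if "group" in meta_without_labels.columns:
        raise ValueError("blinded metadata must not contain labels; drop 'group' first")
    scores = predict_proba(model, counts)
    return pd.DataFrame({"sample_id": scores.index, "score": scores.to_numpy()})


def link_and_evaluate(predictions: pd.DataFrame, label_table: pd.DataFrame,
                      eval_cfg: EvalConfig | None = None) -> dict:
    """Linking phase: join predictions to true labels, compute metrics."""
    merged = predictions.merge(label_table, on="sample_id", how="left", validate="1:1")
    if merged["group"].isna().any():
        raise ValueError("sample ids in predictions missing from label table")
    strat = stage_stratified_metrics(
        merged["group"].to_numpy(), merged["score"].to_numpy(),
        merged.get("stage", pd.Series([""] * len(merged))).astype(str).to_numpy(),
        eval_cfg or EvalConfig())
    return {"external_" + k: m.as_dict() for k, m in strat.items()}
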