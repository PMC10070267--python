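"""ROC/AUC evaluation with DeLong confidence intervals and confusion metrics.

AUC is the normalised Mann-Whitney U statistic (ties count one half).  The
DeLong variance is computed from placement values, giving a normal-theory
confidence interval truncated to [0, 1].  Confusion metrics derive from a
2x2 table at a fixed probability threshold (score >= threshold -> case).
Stage-stratified summaries reuse the same operations on case subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class EvalConfig:
    probability_threshold: float = 0.5
    ci_level: float = 0.95
    stage_groups: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 < self.probability_threshold < 1:
            raise ValueError("probability_threshold must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.stage_groups is None:
            self.stage_groups = {"early": ["I", "II"], "late": ["III", "IV"]}


@dataclass
class MetricsRecord:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    accuracy: float
    n_cases: int
    n_controls: int

    def as_dict(self) -> dict:
        return asdict(self)


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return labels == "case"
    return labels.astype(bool)


def roc_auc(labels, scores) -> float:
    """AUC as the normalised Mann-Whitney U statistic; ties count 0.5."""
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _placements(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per case) and V01 (per control)."""
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    cases, controls = scores[y], scores[~y]
    # psi(case, control) = 1 if case > control, 0.5 if tied, else 0
    cmp = (cases[:, None] > controls[None, :]).astype(float)
    cmp += 0.5 * (cases[:, None] == controls[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_variance(labels, scores) -> float:
    v10, v01 = _placements(labels, scores)
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return float(s10 / len(v10) + s01 / len(v01))


def delong_ci(labels, scores, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-theory confidence interval for the AUC, clipped to [0,1].

    With perfect separation the placement variance is zero and the interval
    collapses to the point estimate.
    """
    y = _as_binary(labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("DeLong CI needs >= 2 members per class")
    auc = roc_auc(labels, scores)
    var = delong_variance(labels, scores)
    if var <= 0:
        return (auc, auc)
    z = scipy.stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def confusion_metrics(labels, scores, cfg: EvalConfig | None = None) -> MetricsRecord:
    """Threshold predictions (score >= threshold -> case) and tabulate."""
    cfg = cfg or EvalConfig()
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes required")
    pred = scores >= cfg.probability_threshold
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    auc = roc_auc(labels, scores)
    ci = delong_ci(labels, scores, cfg.ci_level) if y.sum() >= 2 and (~y).sum() >= 2 else (auc, auc)
    return MetricsRecord(
        auc=auc, ci_low=ci[0], ci_high=ci[1],
        sensitivity=sens, specificity=spec, precision=prec, recall=sens,
        f1=f1, accuracy=(tp + tn) / len(y), n_cases=int(y.sum()), n_controls=int((~y).sum()),
    )


def roc_points(labels, scores) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) over all score cut-offs."""
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    tpr = np.concatenate([[0.0], np.cumsum(y_sorted) / y.sum()])
    fpr = np.concatenate([[0.0], np.cumsum(~y_sorted) / (~y).sum()])
    thr = np.concatenate([[np.inf], scores[order]])
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def stage_stratified_metrics(labels, scores, stages, cfg: EvalConfig | None = None
                             ) -> dict[str, MetricsRecord]:
    """Metrics for all stages and for each stage group (cases of the group
    plus all controls)."""
    cfg = cfg or EvalConfig()
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    stages = np.asarray(stages, dtype=object)
    out = {"all": confusion_metrics(y, scores, cfg)}
    for name, members in cfg.stage_groups.items():
        keep = ~y | np.isin(stages, members)
        if y[keep].any() and (~y[keep]).any():
            out[name] = confusion_metrics(y[keep], scores[keep], cfg)
    return out
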