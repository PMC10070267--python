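"""Post-alignment quality control for platelet count matrices.

Three filters, applied in order:

1. low-coverage genes: a gene is dropped when it has fewer than
   ``min_reads_per_gene`` reads in strictly more than ``min_fraction_below``
   of the samples (defaults: <30 reads in >90% of samples);
2. low-complexity samples: a sample is dropped when fewer than
   ``min_detected_rnas`` genes have at least one read (default 750);
3. outlier samples: leave-one-sample-out cross-correlation on log2(cpm+1) --
   a sample is dropped when the Pearson correlation between its profile and
   the median profile of the remaining samples falls below
   ``crosscorr_threshold`` (default 0.3).  The pass is iterated to a fixed
   point so the filter is idempotent.

An optional gene-exclusion list (e.g. mitochondrially encoded RNAs) is
applied before any statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class QCConfig:
    min_reads_per_gene: int = 30
    min_fraction_below: float = 0.90
    min_detected_rnas: int = 750
    crosscorr_threshold: float = 0.3
    excluded_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction_below < 1:
            raise ValueError("min_fraction_below must be in (0, 1)")
        if not -1 <= self.crosscorr_threshold <= 1:
            raise ValueError("crosscorr_threshold must be in [-1, 1]")


@dataclass
class QCReport:
    genes_removed: int = 0
    samples_removed_low_complexity: int = 0
    samples_removed_crosscorr: int = 0
    detected_rnas: dict = field(default_factory=dict)  # sample -> count
    crosscorr: dict = field(default_factory=dict)  # sample -> first-pass correlation
    removed_samples: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "genes_removed": self.genes_removed,
            "samples_removed_low_complexity": self.samples_removed_low_complexity,
            "samples_removed_crosscorr": self.samples_removed_crosscorr,
            "removed_samples": list(self.removed_samples),
        }


def _drop_excluded(counts: pd.DataFrame, cfg: QCConfig) -> pd.DataFrame:
    if cfg.excluded_genes:
        return counts.drop(index=[g for g in cfg.excluded_genes if g in counts.index])
    return counts


def filter_low_coverage_genes(counts: pd.DataFrame, cfg: QCConfig) -> pd.DataFrame:
    """Remove genes with < min_reads in strictly more than min_fraction of samples."""
    if counts.empty:
        raise ValueError("empty count matrix")
    counts = _drop_excluded(counts, cfg)
    frac_below = (counts.to_numpy() < cfg.min_reads_per_gene).mean(axis=1)
    keep = frac_below <= cfg.min_fraction_below
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return counts.loc[keep]


def detected_rna_counts(counts: pd.DataFrame) -> pd.Series:
    """Number of genes with at least one read, per sample."""
    return (counts > 0).sum(axis=0)


def filter_low_complexity_samples(counts: pd.DataFrame, cfg: QCConfig) -> pd.DataFrame:
    """Remove samples detecting fewer than ``min_detected_rnas`` genes."""
    counts = _drop_excluded(counts, cfg)
    detected = detected_rna_counts(counts)
    keep = detected >= cfg.min_detected_rnas
    if not keep.any():
        raise ValueError("detected-RNA filter removed every sample")
    return counts.loc[:, keep[keep].index]


def _log_cpm(counts: pd.DataFrame) -> np.ndarray:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    return np.log2(counts.to_numpy() / lib[None, :] * 1e6 + 1.0)


def loo_crosscorr(counts: pd.DataFrame) -> pd.Series:
    """Leave-one-out correlation of each sample with the median of the rest.

    Computed on log2(cpm+1).  The leave-one-out median profile is derived
    per sample; Pearson correlation against it is the outlier statistic.
    """
    x = _log_cpm(counts)
    n = x.shape[1]
    corr = np.empty(n)
    for j in range(n):
        others = np.delete(x, j, axis=1)
        ref = np.median(others, axis=1)
        xj = x[:, j]
        denom = xj.std() * ref.std()
        corr[j] = 0.0 if denom == 0 else float(np.corrcoef(xj, ref)[0, 1])
    return pd.Series(corr, index=counts.columns)


def filter_outlier_samples_crosscorr(counts: pd.DataFrame, cfg: QCConfig
                                     ) -> tuple[pd.DataFrame, QCReport]:
    """Iterated leave-one-out cross-correlation outlier removal."""
    counts = _drop_excluded(counts, cfg)
    if counts.shape[1] < 3:
        raise ValueError("cross-correlation filter needs at least 3 samples")
    report = QCReport()
    first_pass = True
    while True:
        corr = loo_crosscorr(counts)
        if first_pass:
            report.crosscorr = corr.to_dict()
            first_pass = False
        bad = corr.index[corr < cfg.crosscorr_threshold]
        if bad.empty:
            break
        report.samples_removed_crosscorr += len(bad)
        report.removed_samples.extend(bad)
        counts = counts.drop(columns=bad)
        if counts.shape[1] < 3:
            break
    return counts, report


def run_qc(counts: pd.DataFrame, cfg: QCConfig | None = None
           ) -> tuple[pd.DataFrame, QCReport]:
    """Full QC cascade: excluded genes, gene filter, sample filters."""
    cfg = cfg or QCConfig()
    counts = _drop_excluded(counts, cfg)
    n_genes_in, n_samples_in = counts.shape

    filtered = filter_low_coverage_genes(counts, cfg)
    detected = detected_rna_counts(filtered)
    filtered = filter_low_complexity_samples(filtered, cfg)
    n_low_complexity = n_samples_in - filtered.shape[1]

    filtered, report = filter_outlier_samples_crosscorr(filtered, cfg)
    report.genes_removed = n_genes_in - filtered.shape[0]
    report.samples_removed_low_complexity = n_low_complexity
    report.detected_rnas = detected.to_dict()
    return filtered, report
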