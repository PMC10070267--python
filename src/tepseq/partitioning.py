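"""Stage-stratified case allocation and age-matched control selection.

Cases are stratified by tumour stage and allocated at random to training /
evaluation / internal-validation subsets with a 40%/30%/30% schema, using
largest-remainder rounding within each stage (remainder ties broken in the
fixed order training > evaluation > internal validation).  Controls are
age-matched to the training and evaluation cases by greedy nearest-age
matching without replacement; the remaining controls form the
internal-validation control arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PARTITIONS = ("training", "evaluation", "internal_validation")


@dataclass
class PartitionConfig:
    fractions: tuple[float, float, float] = (0.40, 0.30, 0.30)
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")


def largest_remainder_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, ...]:
    """Integer partition sizes by largest-remainder rounding.

    Floors first, then the leftover units go to the largest fractional
    remainders; ties are broken by partition order (training first).
    """
    quotas = np.asarray(fractions, dtype=float) * n
    sizes = np.floor(quotas).astype(int)
    remainder = quotas - sizes
    leftover = n - sizes.sum()
    # stable sort on -remainder keeps partition order among ties
    order = np.argsort(-remainder, kind="stable")
    for idx in order[:leftover]:
        sizes[idx] += 1
    return tuple(int(s) for s in sizes)


def stratified_case_split(case_ids: list[str], stages: list[str],
                          cfg: PartitionConfig | None = None) -> dict[str, str]:
    """Allocate cases to partitions, stratified by stage.

    Returns sample_id -> partition name.  Within each stage the cases are
    shuffled by the seed, then sliced per the largest-remainder sizes.
    """
    cfg = cfg or PartitionConfig()
    if len(case_ids) == 0:
        raise ValueError("no cases to split")
    if len(case_ids) != len(stages):
        raise ValueError("one stage label per case required")
    rng = np.random.default_rng(cfg.seed)
    df = pd.DataFrame({"sample_id": case_ids, "stage": stages})
    assignment: dict[str, str] = {}
    for stage in sorted(df["stage"].unique()):
        ids = df.loc[df["stage"] == stage, "sample_id"].tolist()
        ids = [ids[i] for i in rng.permutation(len(ids))]
        sizes = largest_remainder_sizes(len(ids), cfg.fractions)
        start = 0
        for name, size in zip(PARTITIONS, sizes):
            for sid in ids[start:start + size]:
                assignment[sid] = name
            start += size
    return assignment


def match_age_controls(control_ages: dict[str, float],
                       case_ages_by_partition: dict[str, list[float]],
                       seed: int = 0) -> dict[str, str]:
    """Greedy nearest-age control matching without replacement.

    For the training and evaluation partitions each case, in seed-shuffled
    order, consumes the closest-aged remaining control; all unmatched
    controls go to internal validation.  Returns control_id -> partition.
    """
    demand = sum(len(v) for k, v in case_ages_by_partition.items()
                 if k in ("training", "evaluation"))
    if demand > len(control_ages):
        raise ValueError("fewer controls than training+evaluation cases")
    rng = np.random.default_rng(seed)
    pool = pd.Series(control_ages, dtype=float)
    assignment: dict[str, str] = {}
    for name in ("training", "evaluation"):
        ages = list(case_ages_by_partition.get(name, []))
        for i in rng.permutation(len(ages)):
            age = ages[i]
            # ties broken by control id order for determinism
            diffs = (pool - age).abs()
            best = diffs[diffs == diffs.min()].index.min()
            assignment[best] = name
            pool = pool.drop(best)
    for cid in pool.index:
        assignment[cid] = "internal_validation"
    return assignment


def assign_partitions(meta: pd.DataFrame, cfg: PartitionConfig | None = None) -> pd.DataFrame:
    """Partition a full metadata table (cases by stage, controls by age).

    Adds/overwrites the ``partition`` column and returns a copy.
    """
    cfg = cfg or PartitionConfig()
    meta = meta.copy()
    cases = meta[meta["group"] == "case"]
    controls = meta[meta["group"] == "control"]
    case_assign = stratified_case_split(cases["sample_id"].tolist(),
                                        cases["stage"].astype(str).tolist(), cfg)
    case_ages = {p: [] for p in PARTITIONS}
    for _, row in cases.iterrows():
        case_ages[case_assign[row["sample_id"]]].append(float(row["age"]))
    control_assign = match_age_controls(
        dict(zip(controls["sample_id"], controls["age"].astype(float))),
        case_ages, seed=cfg.seed)
    assignment = {**case_assign, **control_assign}
    meta["partition"] = meta["sample_id"].map(assignment)
    return meta
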