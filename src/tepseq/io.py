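"""Reading and writing of count matrices, sample metadata and configs.

Count matrices are genes x samples tables of non-negative integers
(intron-spanning read counts).  On disk they are plain TSV (gene ids in the
first column, sample ids in the header) or MatrixMarket with sidecar index
files.  Metadata is a TSV keyed by ``sample_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

META_COLUMNS = ["sample_id", "group", "hospital", "age", "partition", "lib_size"]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    return counts


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """Write counts as ``<prefix>.mtx`` plus gene/sample index sidecars."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), scipy.sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(counts.index) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(counts.columns) + "\n")


def read_counts_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)


def write_meta_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "hospital": str})
    return meta


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


class NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=NumpyJSONEncoder, indent=1)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
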