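"""Delimited-text readers and writers for every pipeline artifact.

All tables are tab-separated with a header row.  An expression study is a
matrix file (probes x samples, first columns ``probe_id`` and ``gene``)
with a YAML sidecar carrying dataset id, species, tissue, and the per-sample
age group — the same shape as a curated series-matrix table plus its
characteristics lines.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .deg import ExpressionStudy
from .errors import ValidationError


def write_table(df: pd.DataFrame, path: "str | Path", index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_study(study: ExpressionStudy, out_dir: "str | Path") -> tuple[Path, Path]:
    """Write one study as ``<id>.tsv`` plus ``<id>.meta.yaml``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = study.values.copy()
    matrix.insert(0, "gene", study.probe_to_gene)
    matrix.index.name = "probe_id"
    matrix_path = out_dir / f"{study.dataset_id}.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    meta = {
        "dataset_id": study.dataset_id,
        "species": study.species,
        "tissue": study.tissue,
        "age_group": {str(k): str(v) for k, v in study.age_group.items()},
    }
    meta_path = out_dir / f"{study.dataset_id}.meta.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return matrix_path, meta_path


def read_study(matrix_path: "str | Path") -> ExpressionStudy:
    """Read a study written by :func:`write_study` (sidecar found by name)."""
    matrix_path = Path(matrix_path)
    meta_path = matrix_path.with_suffix("").with_suffix(".meta.yaml")
    if not meta_path.exists():
        raise ValidationError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    gene = matrix.pop("gene")
    return ExpressionStudy(
        dataset_id=meta["dataset_id"],
        species=meta["species"],
        tissue=meta["tissue"],
        values=matrix,
        age_group=pd.Series(meta["age_group"]),
        probe_to_gene=gene,
    )


def read_studies_dir(directory: "str | Path") -> list[ExpressionStudy]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise ValidationError(f"no study matrices (*.tsv) found in {directory}")
    return [read_study(p) for p in paths]
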