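"""Reading and writing of pipeline artifacts.

Matrices are tab-separated with a header row and an id column; outcome
series are long-format CSV; models and manifests are JSON. Values
round-trip exactly (floats are written with full repr precision), and
malformed inputs (empty files, duplicate ids) are rejected with locations.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from serostab.biopsy import BiopsyExpression
from serostab.preprocess import ProteinProfile

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_protein_profile",
    "read_protein_profile",
    "write_outcomes",
    "read_outcomes",
    "write_biopsy",
    "read_biopsy",
    "write_json",
    "read_json",
    "sha256_of",
]


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index_label=index_label)
    return path


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix with an id column; reject empty or duplicated ids."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"no data columns in {path}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()]
        lines = [int(df.index.get_loc(d).start) + 2 if hasattr(df.index.get_loc(d), "start") else 0 for d in dup[:5]]
        raise ValueError(f"duplicate row ids in {path}: {list(dup[:5])} (lines ~{lines})")
    if df.columns.duplicated().any():
        dup = list(df.columns[df.columns.duplicated()][:5])
        raise ValueError(f"duplicate column ids in {path}: {dup}")
    return df


def write_protein_profile(profile: ProteinProfile, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": write_matrix_tsv(
            profile.abundance, out_dir / "protein_abundance.tsv", "subject_id"
        ),
        "annotations": write_matrix_tsv(
            profile.annotations, out_dir / "protein_annotations.tsv", "target"
        ),
    }
    return paths


def read_protein_profile(out_dir: str | Path) -> ProteinProfile:
    out_dir = Path(out_dir)
    abundance = read_matrix_tsv(out_dir / "protein_abundance.tsv")
    annotations = read_matrix_tsv(out_dir / "protein_annotations.tsv")
    return ProteinProfile(abundance=abundance, annotations=annotations)


def write_outcomes(series: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    series.to_csv(path, index=False)
    return path


def read_outcomes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing file: {path}")
    df = pd.read_csv(path)
    required = {"subject_id", "outcome", "visit", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"malformed outcome file {path}: missing {sorted(missing)}")
    return df


def write_biopsy(bexpr: BiopsyExpression, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": write_matrix_tsv(
            bexpr.expression, out_dir / "biopsy_expression.tsv", "probe_id"
        ),
        "metadata": Path(out_dir / "biopsy_metadata.csv"),
    }
    bexpr.metadata.to_csv(paths["metadata"], index_label="sample_id")
    if bexpr.probe_annotation is not None:
        paths["probes"] = write_matrix_tsv(
            bexpr.probe_annotation, out_dir / "biopsy_probes.tsv", "probe_id"
        )
    return paths


def read_biopsy(out_dir: str | Path) -> BiopsyExpression:
    out_dir = Path(out_dir)
    expr = read_matrix_tsv(out_dir / "biopsy_expression.tsv")
    meta = pd.read_csv(out_dir / "biopsy_metadata.csv", index_col=0)
    probes_path = out_dir / "biopsy_probes.tsv"
    probes = read_matrix_tsv(probes_path) if probes_path.exists() else None
    return BiopsyExpression(expression=expr, metadata=meta, probe_annotation=probes)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
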