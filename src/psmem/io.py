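"""Serialization helpers: deterministic TSV/JSON and NIfTI-1 round-trips."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["write_tsv", "read_tsv", "write_json", "read_json", "sha256_file",
           "write_nifti", "read_nifti"]


def write_tsv(df: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    return path


def read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_json(path: Path | str):
    return json.loads(Path(path).read_text())


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_nifti(data: np.ndarray, path: Path | str,
                affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return path


def read_nifti(path: Path | str) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())
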