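"""Bit-stable tabular IO and run manifests.

All stage outputs are TSV with a commented ``# key: value`` header block
carrying the seed and a digest of the inputs, and floats formatted to six
significant digits so reruns diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"


def write_tsv(df: pd.DataFrame, path, header: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def config_digest(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_manifest(path, *, seed: int, config: dict, inputs: dict, outputs: dict, status: str = "ok") -> Path:
    """Record seeds, config digest and input digests for reproducibility."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_digest": config_digest(config),
        "inputs": {k: (file_digest(v) if Path(str(v)).is_file() else str(v)) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "status": status,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_gitter_dat(path, plate_id: str, environment_id: str, timepoint_h: float) -> pd.DataFrame:
    """Read one gitter-style per-plate .dat file (one image, one timepoint).

    Expected whitespace-delimited columns: row, col, size, circularity; lines
    starting with '#' are comments.  Spots with circularity < 0.8 are flagged
    as failing the circularity QC, matching common colony-quantification
    practice.  Strain metadata must be joined from the design afterwards.
    """
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["row", "col", "colony_size", "circularity"],
    )
    out = pd.DataFrame(
        {
            "plate_id": plate_id,
            "row": df["row"].astype(int),
            "col": df["col"].astype(int),
            "environment_id": environment_id,
            "timepoint_h": float(timepoint_h),
            "colony_size": df["colony_size"].astype(float),
            "circularity_ok": df["circularity"].astype(float) >= 0.8,
        }
    )
    return out
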