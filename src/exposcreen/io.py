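"""CSV readers/writers, sidecars and run manifests.

Every pipeline output written through the CLI is accompanied by a JSON
manifest tying it to the command, configuration snapshot, SHA-256
digests of the inputs, the seed and the package version — enough to
re-run or audit any artifact.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
from typing import Sequence

import pandas as pd

from . import __version__
from .geo import ExposureMatrix, KernelConfig

__all__ = [
    "file_sha256",
    "read_exposure",
    "read_table",
    "write_exposure",
    "write_manifest",
]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_table(path, required_columns: Sequence[str], name: str) -> pd.DataFrame:
    """Read a CSV and fail early, naming any missing column."""
    df = pd.read_csv(path, dtype={"zip_id": str, "icd_code": str})
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} ({path}) is missing required column(s): {', '.join(missing)}")
    return df


def write_exposure(matrix: ExposureMatrix, csv_path) -> None:
    """Wide CSV (first column zip_id) plus a JSON provenance sidecar."""
    matrix.to_frame().to_csv(csv_path)
    config = matrix.config
    sidecar = {
        "medium": matrix.medium,
        "config": config.to_dict() if isinstance(config, KernelConfig) else config,
        "n_zips": len(matrix.zip_ids),
        "n_chemicals": len(matrix.chemical_ids),
    }
    with open(str(csv_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_exposure(csv_path, medium: str | None = None) -> ExposureMatrix:
    frame = pd.read_csv(csv_path, index_col="zip_id")
    frame.index = frame.index.astype(str)
    config = None
    sidecar_path = str(csv_path) + ".json"
    if os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        medium = medium or sidecar.get("medium")
        raw = sidecar.get("config")
        config = KernelConfig(**raw) if isinstance(raw, dict) else raw
    if medium is None:
        raise ValueError("medium not given and no sidecar found")
    return ExposureMatrix.from_frame(frame, medium=medium, config=config)


def write_manifest(
    out_path,
    command: str,
    config: dict,
    inputs: Sequence,
    outputs: Sequence,
    seed=None,
) -> str:
    """Write ``<out_path>.manifest.json`` describing one pipeline run."""
    manifest = {
        "command": command,
        "config": config,
        "inputs": {str(p): file_sha256(p) for p in inputs if p and os.path.exists(str(p))},
        "outputs": [str(p) for p in outputs],
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = str(out_path) + ".manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
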