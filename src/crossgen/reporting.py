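"""Result writing with manifest, checksums and seed provenance.

Every command writes its tables as CSV (UTF-8, comma separator, ``.``
decimal, header row) and its arrays as HDF5, together with a
``manifest.json`` recording the seed, package version, a hash of the
effective configuration and a SHA-256 checksum per file. An existing
manifest is never overwritten silently; ``verify_results`` re-hashes the
files and reports any corruption.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import h5py
import numpy as np
import pandas as pd

from .exceptions import ManifestError

__all__ = ["write_results", "verify_results", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config) -> str:
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_results(
    out_dir: Path | str,
    tables: Optional[Mapping[str, pd.DataFrame]] = None,
    arrays: Optional[Mapping[str, np.ndarray]] = None,
    config: Optional[dict] = None,
    seed: int = 0,
    force: bool = False,
) -> dict:
    """Write tables/arrays plus a checksummed manifest; return the manifest.

    Raises :class:`ManifestError` if a manifest already exists in
    ``out_dir`` and ``force`` is not set.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / MANIFEST_NAME
    if manifest_path.exists() and not force:
        raise ManifestError(
            f"{manifest_path} exists; pass force=True (--force) to overwrite"
        )
    files: dict[str, dict] = {}
    for name, df in (tables or {}).items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, encoding="utf-8")
        files[name] = {"path": path.name, "sha256": _sha256(path)}
    if arrays:
        path = out_dir / "arrays.h5"
        with h5py.File(path, "w") as f:
            for name, arr in arrays.items():
                f.create_dataset(name, data=np.asarray(arr))
        files["arrays"] = {"path": path.name, "sha256": _sha256(path)}
    manifest = {
        "seed": int(seed),
        "version": __version__,
        "config_hash": _config_hash(config or {}),
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def verify_results(out_dir: Path | str) -> list[str]:
    """Re-hash every file named in the manifest; return mismatch messages.

    An empty list means everything checks out. Missing manifest raises.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise ManifestError(f"no {MANIFEST_NAME} in {out_dir}")
    manifest = json.loads(manifest_path.read_text())
    problems = []
    for name, entry in manifest.get("files", {}).items():
        path = out_dir / entry["path"]
        if not path.exists():
            problems.append(f"{name}: file '{entry['path']}' is missing")
        elif _sha256(path) != entry["sha256"]:
            problems.append(f"{name}: checksum mismatch for '{entry['path']}'")
    return problems
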