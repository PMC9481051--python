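"""Result serialization: CSV tables plus a JSON provenance manifest."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, to_dict


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the effective configuration."""
    payload = json.dumps(to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  cfg: RunConfig | None = None,
                  extra: dict | None = None) -> list[Path]:
    """Write named tables as ``<name>.csv`` plus ``manifest.json``.

    Floats are written at repr precision; any rounding to significant
    figures is left to consumers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    manifest = {
        "tool": "planksim",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "tables": sorted(p.name for p in written),
    }
    if cfg is not None:
        manifest["config"] = to_dict(cfg)
        manifest["config_sha256"] = config_hash(cfg)
        manifest["velocity_dialect"] = cfg.growth.velocity_dialect
    if extra:
        manifest.update(extra)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    written.append(mpath)
    return written
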