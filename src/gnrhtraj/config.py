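"""Flat YAML configuration and run manifests.

Every CLI flag has a config twin; CLI values override config values. A run
manifest (parameters, seed, input hashes) is written beside outputs so any
result table can be traced back to exactly one invocation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from datetime import datetime, timezone
from pathlib import Path

import yaml

logger = logging.getLogger("gnrhtraj")


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped log lines to stderr (idempotent)."""
    if any(getattr(h, "_gnrhtraj", False) for h in logger.handlers):
        return
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    handler._gnrhtraj = True  # type: ignore[attr-defined]
    logger.addHandler(handler)
    logger.setLevel(level)


def load_config(path: str | Path | None) -> dict:
    """Load a flat key-value YAML config; missing path -> empty config."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def resolve(cli_values: dict, config: dict, defaults: dict) -> dict:
    """Merge defaults < config < explicit CLI values (None means unset)."""
    out = dict(defaults)
    for k, v in config.items():
        out[k] = v
    for k, v in cli_values.items():
        if v is not None:
            out[k] = v
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    params: dict,
    seed: int | None,
    inputs: list[str | Path] = (),
) -> Path:
    """Write a machine-readable manifest of one pipeline step."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote manifest %s", path)
    return path


def _jsonable(v):
    try:
        json.dumps(v)
        return v
    except TypeError:
        return str(v)
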