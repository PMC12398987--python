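"""Run manifests: provenance for every output directory.

A manifest records the command, the resolved configuration, the seeds,
and SHA-256 digests of every input file, so that a later consumer can
check - for example - that the cases evaluated as "unseen test data"
are not the file a model was trained on.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["file_digest", "write_manifest", "read_manifest"]

MANIFEST_NAME = "manifest.json"


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seeds: dict,
    inputs: dict[str, str | Path],
) -> Path:
    """Write ``manifest.json`` into ``out_dir``; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        from importlib.metadata import version
        tool_version = version("prosthoplan")
    except Exception:  # pragma: no cover
        tool_version = "unknown"
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {name: {"path": str(p), "sha256": file_digest(p)}
                   for name, p in inputs.items()},
        "tool_version": tool_version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / MANIFEST_NAME).read_text())
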