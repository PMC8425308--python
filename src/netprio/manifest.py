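"""Run manifests: one JSON record per run capturing everything needed to reproduce it."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, command: str, parameters: dict, inputs: dict | None = None,
                   rng_seeds: dict | None = None) -> dict:
    """Write a manifest JSON next to a run's outputs and return it.

    ``inputs`` maps labels to file paths; each gets a sha256 digest so reruns
    can verify they consumed identical data.
    """
    manifest = {
        "command": command,
        "parameters": parameters,
        "inputs": {k: {"path": str(v), "sha256": _digest(v)} for k, v in (inputs or {}).items()},
        "rng_seeds": rng_seeds or {},
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
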