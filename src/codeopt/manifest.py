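"""Run manifests: enough configuration echo to replay a run byte-for-byte."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

from . import __version__


def build_manifest(command: str, config: Mapping[str, Any],
                   derived_seeds: list | None = None) -> dict:
    man = {
        "tool": "codeopt",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": dict(config),
    }
    if derived_seeds is not None:
        man["derived_seeds"] = derived_seeds
    return man


def write_manifest(path: Path, manifest: Mapping[str, Any]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
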