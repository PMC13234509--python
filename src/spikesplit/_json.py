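"""Deterministic JSON writing shared by the CLI and pipeline."""

from __future__ import annotations

import json
from pathlib import Path


def dump_json(payload, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
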