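"""Reproducible JSON output.

All JSON artefacts are written with sorted keys and floats rounded to nine
significant digits so identical invocations produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path


def _round_floats(obj):
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return obj
        return float(f"{obj:.9g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def dumps_json(obj) -> str:
    return json.dumps(_round_floats(obj), sort_keys=True, indent=2) + "\n"


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(dumps_json(obj))


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
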