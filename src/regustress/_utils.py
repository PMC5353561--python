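"""Small shared helpers."""

from __future__ import annotations

import hashlib
import math
from pathlib import Path


def pct_display(fraction: float) -> int:
    """Round a fraction (0..1) to an integer percentage.

    Half values round away from zero, the convention that reproduces
    every printed regulon percentage (e.g. 20/26 -> 77, 12/13 -> 92).
    """
    pct = 100.0 * fraction
    return int(math.floor(pct + 0.5)) if pct >= 0 else int(math.ceil(pct - 0.5))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
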