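"""Small shared helpers."""

from __future__ import annotations

import hashlib
from pathlib import Path


def round12(x: float) -> float:
    """Round to 12 decimals so fixed-precision text artifacts round-trip exactly."""
    return round(float(x), 12)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
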