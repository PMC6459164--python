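"""Logging and deterministic seed derivation."""

from __future__ import annotations

import hashlib
import logging
import sys

_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def get_logger(name: str) -> logging.Logger:
    """Package logger writing to stderr with a timestamped level prefix."""
    logger = logging.getLogger(name)
    root = logging.getLogger("hdcn")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_FORMAT))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    return logger


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a stable sub-stream seed from a master seed and string tokens.

    Uses SHA-256 of the master seed and tokens so the result does not depend
    on iteration order or Python's per-process hash randomization. Always
    returns a non-negative int below 2**31.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
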