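"""Small shared helpers: print-style rounding and atomic file writes."""

from __future__ import annotations

import os
import tempfile
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, as spreadsheets print numbers.

    Python's builtin ``round`` uses banker's rounding; survey scorecards are
    produced in spreadsheets, so reproducing their printed intermediates
    needs half-up behaviour. Goes through ``repr`` so the decimal seen is
    the shortest representation of the float, not its binary expansion.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename, never partially."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise
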