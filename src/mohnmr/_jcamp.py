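"""Low-level JCAMP-DX codec: label parsing and ASDF numeric decoding.

Supports the encodings found in 1D NMR exports: AFFN (plain numbers), PAC,
and the compressed ASDF forms SQZ, DIF and DUP (including combined DIFDUP).
Only reading of compressed data is supported; writing always emits AFFN.
"""

from __future__ import annotations

import re
from typing import Iterator, List, Tuple

import numpy as np

__all__ = [
    "JcampParseError",
    "normalize_label",
    "split_records",
    "split_blocks",
    "decode_asdf_lines",
    "format_affn_xydata",
]


class JcampParseError(ValueError):
    """Raised when a JCAMP-DX file cannot be parsed."""


def normalize_label(label: str) -> str:
    """Normalize a data label: case and the characters ``space - / _`` are
    not significant per the standard; ``$`` (private) and ``.`` (vendor)
    prefixes are preserved."""
    return re.sub(r"[ \-/_]", "", label).upper()


def _strip_comment(line: str) -> str:
    # $$ starts an in-line comment
    idx = line.find("$$")
    return line if idx < 0 else line[:idx]


def split_records(text: str) -> List[Tuple[str, str, List[str]]]:
    """Split JCAMP text into labelled data records.

    Returns a list of ``(normalized_label, first_line_value, extra_lines)``
    tuples in file order.  ``extra_lines`` holds continuation lines (used by
    tabular data like XYDATA).
    """
    records: List[Tuple[str, str, List[str]]] = []
    current = None
    for raw in text.splitlines():
        line = _strip_comment(raw).rstrip()
        if line.startswith("##"):
            if current is not None:
                records.append(current)
            try:
                label, value = line[2:].split("=", 1)
            except ValueError as exc:
                raise JcampParseError(f"malformed label line: {raw!r}") from exc
            current = (normalize_label(label), value.strip(), [])
        elif current is not None:
            if line.strip():
                current[2].append(line)
        # leading junk before the first ## is ignored
    if current is not None:
        records.append(current)
    return records


def split_blocks(records):
    """Group records into blocks (``##TITLE`` .. ``##END``).

    Link blocks (compound files) are flattened: every block containing data
    is returned; pure link-level metadata is attached to no block.
    """
    blocks = []
    current = None
    for rec in records:
        label = rec[0]
        if label == "TITLE":
            if current:
                blocks.append(current)
            current = [rec]
        elif label == "END":
            if current:
                blocks.append(current)
                current = None
        elif current is not None:
            current.append(rec)
    if current:
        blocks.append(current)
    return blocks


# ---------------------------------------------------------------------------
# ASDF decoding
# ---------------------------------------------------------------------------

_SQZ_POS = "@ABCDEFGHI"  # 0..9
_SQZ_NEG = "abcdefghi"  # -1..-9
_DIF_POS = "%JKLMNOPQR"  # 0..9
_DIF_NEG = "jklmnopqr"  # -1..-9
_DUP = "STUVWXYZs"  # 1..9

_DIGIT = {}
for _i, _c in enumerate(_SQZ_POS):
    _DIGIT[_c] = ("sqz", _i, 1)
for _i, _c in enumerate(_SQZ_NEG, start=1):
    _DIGIT[_c] = ("sqz", _i, -1)
for _i, _c in enumerate(_DIF_POS):
    _DIGIT[_c] = ("dif", _i, 1)
for _i, _c in enumerate(_DIF_NEG, start=1):
    _DIGIT[_c] = ("dif", _i, -1)
for _i, _c in enumerate(_DUP, start=1):
    _DIGIT[_c] = ("dup", _i, 1)

_NUM_BODY = set("0123456789.")


def _tokenize_asdf(line: str) -> Iterator[Tuple[str, float]]:
    """Yield ``(kind, value)`` tokens, kind in {num, sqz, dif, dup, missing}."""
    i, n = 0, len(line)
    while i < n:
        c = line[i]
        if c in " \t,;":
            i += 1
            continue
        if c == "?":
            yield ("missing", np.nan)
            i += 1
            continue
        if c in _DIGIT:
            kind, first, sign = _DIGIT[c]
            j = i + 1
            while j < n and line[j] in _NUM_BODY:
                j += 1
            body = str(first) + line[i + 1 : j]
            yield (kind, sign * float(body))
            i = j
            continue
        if c in "+-" or c in _NUM_BODY:
            j = i + (1 if c in "+-" else 0)
            while j < n and line[j] in _NUM_BODY:
                j += 1
            # AFFN exponent
            if j < n and line[j] in "eE" and j + 1 < n and (
                line[j + 1].isdigit() or line[j + 1] in "+-"
            ):
                j += 2
                while j < n and line[j].isdigit():
                    j += 1
            tok = line[i:j]
            if tok in ("+", "-"):
                raise JcampParseError(f"dangling sign in data line: {line!r}")
            yield ("num", float(tok))
            i = j
            continue
        raise JcampParseError(f"unexpected character {c!r} in data line: {line!r}")


def decode_asdf_lines(lines: List[str]) -> np.ndarray:
    """Decode ``(X++(Y..Y))`` table lines into the ordinate vector.

    The leading abscissa of each line is dropped; DIF-mode line-start check
    values are verified (to integer precision) and dropped.
    """
    ys: List[float] = []
    last_kind = None  # kind of the last *data* op: 'num'/'sqz' or 'dif'
    last_val = 0.0  # value of the last op (absolute for num/sqz, delta for dif)
    in_dif = False  # previous line ended in DIF (or DUP-of-DIF) mode
    for line in lines:
        toks = list(_tokenize_asdf(line))
        if not toks:
            continue
        if toks[0][0] not in ("num", "sqz"):
            raise JcampParseError(f"data line must start with an abscissa: {line!r}")
        data = toks[1:]
        if in_dif and ys and data:
            kind, val = data[0]
            if kind in ("num", "sqz"):
                if abs(val - ys[-1]) > max(1e-6 * max(abs(val), 1.0), 0.5):
                    raise JcampParseError(
                        f"DIF check value mismatch: {val} vs {ys[-1]}"
                    )
                data = data[1:]
            # else: tolerate writers that omit the check value
        for kind, val in data:
            if kind == "missing":
                ys.append(np.nan)
                last_kind, last_val = "num", np.nan
            elif kind in ("num", "sqz"):
                ys.append(val)
                last_kind, last_val = "num", val
            elif kind == "dif":
                if not ys:
                    raise JcampParseError("DIF token before any ordinate")
                ys.append(ys[-1] + val)
                last_kind, last_val = "dif", val
            elif kind == "dup":
                if last_kind is None:
                    raise JcampParseError("DUP token with no preceding value")
                for _ in range(int(val) - 1):
                    if last_kind == "dif":
                        ys.append(ys[-1] + last_val)
                    else:
                        ys.append(last_val)
        in_dif = last_kind == "dif"
    return np.asarray(ys, dtype=float)


# ---------------------------------------------------------------------------
# AFFN writing
# ---------------------------------------------------------------------------


def format_affn_xydata(x: np.ndarray, y: np.ndarray, per_line: int = 6) -> List[str]:
    """Format an ``(X++(Y..Y))`` AFFN table, ``per_line`` ordinates per row."""
    lines = []
    for i in range(0, len(y), per_line):
        chunk = y[i : i + per_line]
        vals = " ".join(f"{v:.10G}" for v in chunk)
        lines.append(f"{x[i]:.10G} {vals}")
    return lines
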