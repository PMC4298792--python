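"""Genotype call codes shared across the package.

Genotypes of a bi-parental population are coded by parental origin:

====  =====  ====================================================
code  char   meaning
====  =====  ====================================================
0     A      homozygous for the reference (assembly) parent
1     B      homozygous for the other parent
2     H      heterozygous
3     U      unknown / missing
====  =====  ====================================================

No other states exist downstream of parsing.  All call containers in the
package hold ``numpy.int8`` arrays of these codes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

A = np.int8(0)
B = np.int8(1)
H = np.int8(2)
U = np.int8(3)

CALL_CHARS = np.array(["A", "B", "H", "U"])
_CHAR_TO_CODE = {"A": 0, "B": 1, "H": 2, "U": 3}


def from_strings(tokens: Iterable[str]) -> np.ndarray:
    """Convert an iterable of 'A'/'B'/'H'/'U' tokens to an int8 code array."""
    try:
        return np.array([_CHAR_TO_CODE[t] for t in tokens], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid genotype call {exc.args[0]!r}") from None


def to_strings(codes: Sequence[int] | np.ndarray) -> np.ndarray:
    """Convert an int8 code array back to 'A'/'B'/'H'/'U' characters."""
    return CALL_CHARS[np.asarray(codes, dtype=np.int8)]
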