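"""Amino-acid alphabet and integer encodings shared by the scoring modules.

Two encodings are used:

* the 20-state alphabet (MI and conservation): gaps and unknown residues
  carry no counts;
* the 21-state alphabet (DCA): the gap is an explicit 21st state and
  unknown residues are mapped onto it.
"""

from __future__ import annotations

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

#: integer code of the gap state in the 21-state (DCA) alphabet
GAP_STATE = 20
#: number of Potts states used by the DCA methods (20 aa + gap)
Q_DCA = 21

# internal codes: 0..19 amino acids, 20 gap, 21 unknown
_CODE = {aa: i for i, aa in enumerate(AA20)}
_CODE[GAP] = 20
_CODE[UNKNOWN] = 21

_LOOKUP = np.full(128, 21, dtype=np.int8)
for _c, _i in _CODE.items():
    _LOOKUP[ord(_c)] = _i

# BLOSUM62 marginal amino-acid frequencies (Robinson-style background used
# by substitution-matrix derivations), ordered as AA20.
BLOSUM62_BACKGROUND = np.array(
    [0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
     0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032]
)
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()


def normalize_residues(seq: str) -> str:
    """Upper-case, map '.' to '-', collapse non-standard letters to 'X'."""
    seq = seq.upper().replace(".", GAP)
    return "".join(c if (c in _CODE) else UNKNOWN for c in seq)


def encode(rows: list[str]) -> np.ndarray:
    """Encode normalized residue strings to an (n, L) int8 matrix.

    Codes: 0-19 amino acids in ``AA20`` order, 20 gap, 21 unknown ('X').
    """
    if not rows:
        return np.zeros((0, 0), dtype=np.int8)
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _LOOKUP[arr].reshape(len(rows), len(rows[0]))


def codes21(codes: np.ndarray) -> np.ndarray:
    """Map the internal codes onto the 21-state DCA alphabet (X -> gap)."""
    out = codes.astype(np.int8, copy=True)
    out[out == 21] = GAP_STATE
    return out
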