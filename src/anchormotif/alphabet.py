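"""Amino-acid alphabet, integer encoding, and background composition.

The package works on the 20 standard amino acids plus ``X`` for any
ambiguity code.  Sequences are encoded as ``int8`` arrays: codes 0-19 are
the standard residues in alphabetical order, 20 is ``X``, and 21 is a
padding sentinel used when ragged segment sets are packed into a matrix.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUES = 20
X_CODE = 20
PAD_CODE = 21

AA_TO_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Characters silently dropped during sanitization (gap/stop/whitespace
# symbols that are not residues at all).
_NON_RESIDUE = set("*-. \t\r\n")

# Average amino-acid frequencies of vertebrate proteins (Robinson &
# Robinson, as used for BLAST background models).  Serves as the default
# background composition for synthetic sequence generation.
BACKGROUND_FREQUENCIES = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

HYDROPHOBIC = "VILMFWC"
CHARGED = "KRDE"
POSITIVELY_CHARGED = "KR"


def sanitize(raw: str) -> tuple[str, int]:
    """Clean a raw sequence string.

    Uppercases, drops gap/stop symbols, and maps every letter outside the
    20-residue alphabet (B, J, O, U, Z, ...) to ``X``.  Returns the cleaned
    string and the number of characters that were mapped to ``X``.
    """
    out = []
    n_mapped = 0
    for ch in raw.upper():
        if ch in _NON_RESIDUE:
            continue
        if ch in AA_TO_CODE or ch == "X":
            out.append(ch)
        else:
            out.append("X")
            n_mapped += 1
    return "".join(out), n_mapped


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as an int8 code array ('X' -> 20)."""
    return np.fromiter(
        (AA_TO_CODE.get(ch, X_CODE) for ch in residues),
        dtype=np.int8,
        count=len(residues),
    )


def decode(codes: np.ndarray) -> str:
    return "".join(
        AMINO_ACIDS[c] if c < N_RESIDUES else "X" for c in np.asarray(codes)
    )


def composition_vector(frequencies: dict[str, float] | None = None) -> np.ndarray:
    """Length-20 frequency vector in alphabet order, normalised to sum 1."""
    freqs = BACKGROUND_FREQUENCIES if frequencies is None else frequencies
    vec = np.zeros(N_RESIDUES, dtype=float)
    for aa, f in freqs.items():
        if aa not in AA_TO_CODE:
            raise ValueError(f"unknown residue {aa!r} in composition")
        if f < 0:
            raise ValueError(f"negative frequency for {aa!r}")
        vec[AA_TO_CODE[aa]] = f
    total = vec.sum()
    if total <= 0:
        raise ValueError("composition must have positive total mass")
    return vec / total


def restricted_composition(
    alphabet: str, base: dict[str, float] | None = None
) -> np.ndarray:
    """Background composition restricted to ``alphabet`` and renormalised.

    This is how implant flank distributions are derived: keep the background
    frequency of each allowed residue and rescale so they sum to one.
    """
    vec = composition_vector(base)
    mask = np.zeros(N_RESIDUES, dtype=bool)
    for aa in alphabet:
        if aa not in AA_TO_CODE:
            raise ValueError(f"unknown residue {aa!r} in alphabet")
        mask[AA_TO_CODE[aa]] = True
    restricted = np.where(mask, vec, 0.0)
    total = restricted.sum()
    if total <= 0:
        raise ValueError("restricted alphabet has zero background mass")
    return restricted / total
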