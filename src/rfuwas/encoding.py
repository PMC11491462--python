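"""Numeric embeddings of CDR3 amino-acid sequences.

TCR beta-chain CDR3 loops are short amino-acid strings (typically 8-25
residues).  To cluster repertoires into repertoire functional units (RFUs)
each sequence must be mapped to a fixed-length real vector.  The encoder is
pluggable: any object with an ``encode`` method and a ``dim`` attribute can
be used, so centroid matrices produced by external embedding models can be
plugged in unchanged.

The default :class:`AtchleyEncoder` places the five Atchley physicochemical
factors of each residue into a center-padded frame of ``max_length``
positions (pad = zero vector) and appends a normalized length feature,
giving dimension ``5 * max_length + 1``.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Atchley et al. five-factor solution of 54 amino-acid indices:
# I polarity/hydrophobicity, II secondary structure, III molecular size,
# IV codon composition, V electrostatic charge.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}


class AtchleyEncoder:
    """Default CDR3 encoder: Atchley factors in a center-padded frame.

    Parameters
    ----------
    max_length : int, default 25
        Hard upper bound on CDR3 length; sequences longer than this raise
        ``ValueError``.  25 covers the observed beta-chain CDR3 length
        distribution.

    Attributes
    ----------
    dim : int
        Embedding dimension, ``5 * max_length + 1`` (the trailing feature
        is length / max_length).
    """

    def __init__(self, max_length: int = 25):
        if max_length < 1:
            raise ValueError("max_length must be positive")
        self.max_length = int(max_length)
        self.dim = 5 * self.max_length + 1
        self._table = np.array([ATCHLEY_FACTORS[a] for a in AMINO_ACIDS])
        self._index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    def encode(self, sequence: str) -> np.ndarray:
        """Embed one CDR3 amino-acid string as a ``dim``-vector."""
        if not sequence:
            raise ValueError("empty CDR3 sequence")
        L = len(sequence)
        if L > self.max_length:
            raise ValueError(
                f"CDR3 length {L} exceeds max_length={self.max_length}"
            )
        vec = np.zeros(self.dim)
        offset = (self.max_length - L) // 2  # center padding
        for i, aa in enumerate(sequence):
            j = self._index.get(aa)
            if j is None:
                raise ValueError(f"illegal amino-acid character {aa!r} in {sequence!r}")
            vec[5 * (offset + i): 5 * (offset + i) + 5] = self._table[j]
        vec[-1] = L / self.max_length
        return vec

    def encode_many(self, sequences) -> np.ndarray:
        """Embed an iterable of sequences as an (n, dim) array."""
        return np.array([self.encode(s) for s in sequences]).reshape(-1, self.dim)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AtchleyEncoder(max_length={self.max_length})"


def encode_cdr3(sequence: str, encoder: AtchleyEncoder | None = None) -> np.ndarray:
    """Encode a single CDR3 sequence with ``encoder`` (default Atchley)."""
    if encoder is None:
        encoder = AtchleyEncoder()
    return encoder.encode(sequence)
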