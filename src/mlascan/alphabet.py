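"""Shared sequence alphabets and fast codon translation tables.

Symbol order is fixed package-wide: the 20 amino acids in one-letter
alphabetical order followed by the stop symbol ``*``. All count, frequency
and fitness matrices use this order for their 21 columns.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

#: 21-symbol protein alphabet: 20 amino acids + stop, in fixed column order.
AA_SYMBOLS: str = "ACDEFGHIKLMNPQRSTVWY*"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_SYMBOLS)}
N_SYMBOLS: int = len(AA_SYMBOLS)

DNA_BASES: str = "ACGT"
DNA_COMPLEMENT: dict[str, str] = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 32 NNS degenerate codons (N = any base, S = G or C), sorted.
NNS_CODONS: tuple[str, ...] = tuple(
    sorted(a + b + s for a, b, s in itertools.product(DNA_BASES, DNA_BASES, "GC"))
)


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code; stop renders as ``*``."""
    return str(Seq(codon).translate())


#: amino acid encoded by each NNS codon
NNS_TRANSLATION: dict[str, str] = {c: translate_codon(c) for c in NNS_CODONS}

# ---------------------------------------------------------------------------
# byte-level lookup tables for vectorized read handling

# ASCII base -> 0..3 index; anything else (incl. N) -> 255
BASE_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    BASE_TO_INDEX[ord(_b)] = _i
    BASE_TO_INDEX[ord(_b.lower())] = _i

# ASCII base -> complement ASCII byte (non-ACGT maps to 'N')
COMPLEMENT_BYTE = np.full(256, ord("N"), dtype=np.uint8)
for _b, _c in DNA_COMPLEMENT.items():
    COMPLEMENT_BYTE[ord(_b)] = ord(_c)
    COMPLEMENT_BYTE[ord(_b.lower())] = ord(_c)

# codon index (16*a + 4*b + c over base indices) -> ASCII amino-acid byte
CODON_TO_AA = np.zeros(64, dtype=np.uint8)
for _a, _b, _c in itertools.product(range(4), repeat=3):
    _codon = DNA_BASES[_a] + DNA_BASES[_b] + DNA_BASES[_c]
    CODON_TO_AA[16 * _a + 4 * _b + _c] = ord(translate_codon(_codon))

#: ASCII amino-acid byte -> column index in the 21-symbol alphabet; 255 = invalid
AA_BYTE_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _a, _i in AA_INDEX.items():
    AA_BYTE_TO_INDEX[ord(_a)] = _i


def seq_to_bytes(seq: str) -> np.ndarray:
    """ASCII byte vector for a sequence string."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def reads_to_matrix(reads: list[str]) -> np.ndarray:
    """Pack equal-length reads into an (n_reads, length) ASCII byte matrix."""
    if not reads:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(reads[0])
    for r in reads:
        if len(r) != length:
            raise ValueError("all reads must have equal length to be packed")
    buf = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8)
    return buf.reshape(len(reads), length)


def matrix_to_reads(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`reads_to_matrix`."""
    if mat.size == 0:
        return []
    raw = mat.tobytes()
    length = mat.shape[1]
    return [raw[i * length : (i + 1) * length].decode("ascii") for i in range(mat.shape[0])]


def translate_matrix(mat: np.ndarray) -> np.ndarray:
    """Vectorized translation of an (n, 3k) ASCII base matrix.

    Returns an (n, k) ASCII amino-acid byte matrix; codons containing any
    non-ACGT base translate to ``X`` (outside the 21-symbol alphabet, so
    downstream counting discards such reads as ambiguous).
    """
    n, width = mat.shape
    if width % 3:
        raise ValueError("matrix width must be divisible by 3")
    idx = BASE_TO_INDEX[mat].reshape(n, width // 3, 3).astype(np.int32)
    bad = (idx == 255).any(axis=2)
    idx[idx == 255] = 0
    codon = 16 * idx[:, :, 0] + 4 * idx[:, :, 1] + idx[:, :, 2]
    aa = CODON_TO_AA[codon]
    aa[bad] = ord("X")
    return aa
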