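"""Shared sequence primitives: alphabets, translation and scoring tables.

Internal coordinates are 0-based half-open throughout the package; GFF3 and
reports are emitted 1-based inclusive.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

#: canonical amino-acid order used for every 20-vector in the package
AA = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA)}

#: index of the unknown residue (ambiguous codons translate to X)
X_IDX = 20
#: index of the stop symbol
STOP_IDX = 21

_EXTENDED = AA + "X*"


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string as indices into ``AA`` (X=20, *=21).

    Residues outside the extended alphabet (B, Z, U...) map to X.
    """
    out = np.full(len(seq), X_IDX, dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        if c == "*":
            out[i] = STOP_IDX
        else:
            out[i] = AA_INDEX.get(c, X_IDX)
    return out


def _build_blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    table = np.zeros((22, 22), dtype=np.float64)
    for i, a in enumerate(_EXTENDED):
        for j, b in enumerate(_EXTENDED):
            aa = a if a in m.alphabet else "X"
            bb = b if b in m.alphabet else "X"
            table[i, j] = m[aa, bb]
    return table


#: BLOSUM62 indexed by ``encode_protein`` codes (rows/cols 0..21)
BLOSUM62 = _build_blosum62()

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a DNA string with the standard code; ambiguous codons -> X.

    Trailing bases not forming a full codon are ignored.
    """
    n = len(dna) - len(dna) % 3
    if n <= 0:
        return ""
    return str(Seq(dna[:n]).translate())


def six_frames(chrom_seq: str):
    """Yield ``(strand, frame, protein)`` for all six reading frames.

    ``frame`` is the 0-based offset into the strand's own 5'->3' sequence
    (for '-', into the reverse complement).
    """
    rc = revcomp(chrom_seq)
    for frame in range(3):
        yield "+", frame, translate(chrom_seq[frame:])
        yield "-", frame, translate(rc[frame:])


def aa_to_genomic(strand: str, frame: int, aa_start: int, aa_end: int, chrom_len: int):
    """Map an aa interval on a translated frame to genomic (0-based half-open)."""
    g0 = frame + 3 * aa_start
    g1 = frame + 3 * aa_end
    if strand == "+":
        return g0, g1
    return chrom_len - g1, chrom_len - g0


_N_RUN = re.compile(r"[Nn]{20,}")


def n_runs(seq: str, min_len: int = 20):
    """Return (start, end) of runs of >= min_len ambiguous 'N' bases."""
    if min_len == 20:
        return [(m.start(), m.end()) for m in _N_RUN.finditer(seq)]
    pat = re.compile(r"[Nn]{%d,}" % min_len)
    return [(m.start(), m.end()) for m in pat.finditer(seq)]


def percent_identity(a: str, b: str) -> float:
    """Ungapped percent identity of two equal-length strings (0-100)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        return 0.0
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / len(a)
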