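"""Multiple sequence alignment: provider interface and built-in aligner.

The built-in provider is a classic progressive aligner: a k-mer distance
matrix feeds an average-linkage guide tree, and profiles are merged bottom-up
by profile-profile global alignment (Gotoh affine gaps, BLOSUM62 expected
column score).  External aligners can be plugged in as providers mapping
``{id: sequence} -> {id: aligned row}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._seq import AA_INDEX, BLOSUM62

GAP = "-"


class EmptyAlignmentError(ValueError):
    pass


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def coverage(self) -> np.ndarray:
        """Per-column non-gap fraction."""
        if not self.rows:
            return np.empty(0)
        mat = np.array([[c != GAP for c in row] for row in self.rows])
        return mat.mean(axis=0)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(ncol, 20) residue frequency profile; gaps contribute nothing."""
    ncol = len(rows[0])
    f = np.zeros((ncol, 20))
    for row in rows:
        for j, c in enumerate(row):
            idx = AA_INDEX.get(c)
            if idx is not None:
                f[j, idx] += 1
    return f / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str], gap_open: float = 11.0, gap_extend: float = 1.0):
    """Global profile-profile alignment (Gotoh); returns merged row lists."""
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    S = fa @ BLOSUM62[:20, :20] @ fb.T  # (n, m) expected column scores
    n, m = S.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (A consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        Si = S[i - 1]
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + Si[j - 1]
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend, X[i, j - 1] - gap_open)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    cols = []  # (consume_a, consume_b)
    while i > 0 or j > 0:
        if i == 0:
            cols.append((False, True))
            j -= 1
            continue
        if j == 0:
            cols.append((True, False))
            i -= 1
            continue
        if state == 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            cols.append((True, True))
            i -= 1
            j -= 1
        elif state == 1:
            opts = [M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open]
            state = int(np.argmax(opts))
            cols.append((True, False))
            i -= 1
        else:
            opts = [M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend, X[i, j - 1] - gap_open]
            state = [0, 2, 1][int(np.argmax(opts))]
            cols.append((False, True))
            j -= 1
    cols.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for take_a, take_b in cols:
        for r, row in enumerate(rows_a):
            out_a[r].append(row[ia] if take_a else GAP)
        for r, row in enumerate(rows_b):
            out_b[r].append(row[ib] if take_b else GAP)
        ia += take_a
        ib += take_b
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def builtin_align(sequences: dict[str, str]) -> dict[str, str]:
    """Progressive alignment: k-mer guide tree + profile-profile merges."""
    ids = list(sequences)
    seqs = [sequences[i].upper() for i in ids]
    n = len(ids)
    if n == 1:
        return {ids[0]: seqs[0]}
    if n == 2:
        a, b = _align_profiles([seqs[0]], [seqs[1]])
        return {ids[0]: a[0], ids[1]: b[0]}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i], seqs[j])
    Z = linkage(squareform(d, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(n)
    }
    for k, (a, b, _dist, _size) in enumerate(Z):
        ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
        ra, rb = _align_profiles(ca[1], cb[1])
        clusters[n + k] = (ca[0] + cb[0], ra + rb)
    merged_ids, merged_rows = clusters.popitem()[1]
    aligned = dict(zip(merged_ids, merged_rows))
    return {i: aligned[i] for i in ids}


def align(sequences: dict[str, str], provider=builtin_align) -> Msa:
    """Align a set of protein sequences with the given provider."""
    ids = list(sequences)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences to align")
    aligned = provider(dict(sequences))
    rows = [aligned[i] for i in ids]
    for sid, row in zip(ids, rows):
        if row.replace(GAP, "") != sequences[sid].upper():
            raise AssertionError(f"provider dropped residues of {sid}")
    return Msa(ids=ids, rows=rows)


def filter_sites(msa: Msa, min_coverage: float = 0.95) -> Msa:
    """Drop columns with coverage strictly below ``min_coverage``.

    Column order is preserved; the filter is idempotent.
    """
    cov = msa.coverage
    keep = [j for j in range(msa.n_columns) if cov[j] >= min_coverage - 1e-12]
    if not keep:
        raise EmptyAlignmentError("site-coverage filter removed every column")
    rows = ["".join(row[j] for j in keep) for row in msa.rows]
    return Msa(ids=list(msa.ids), rows=rows)
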