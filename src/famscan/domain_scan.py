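"""Candidate family-region discovery and triage.

The discovery step is a six-frame translated similarity search (seed-and-extend
with BLOSUM62 and Karlin-Altschul statistics) of family seed proteins against a
genome.  Hits are merged into candidate regions, and each region is triaged
with a position-specific scoring matrix (PSSM) built from the seed alignment:

* ``no_domain``        -- homology to a seed but no family-domain match,
* ``nonfunctional``    -- domain present but disrupted (internal stop codon or
                          a truncated domain open reading frame),
* ``possibly_assembly``-- the disruption coincides with a run of assembly-gap
                          'N' bases (refinement of nonfunctional),
* ``functional``       -- intact domain and open reading frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import (
    AA,
    AA_INDEX,
    BLOSUM62,
    STOP_IDX,
    X_IDX,
    aa_to_genomic,
    encode_protein,
    n_runs,
    revcomp,
    six_frames,
    translate,
)

#: PSSM contribution of an ambiguous residue (X) and of a stop codon, in bits.
X_SCORE = 0.0
STOP_SCORE = -6.0

#: internal stops are only called this many residues away from an HSP edge,
#: guarding against read-through of a terminator during X-drop extension.
STOP_EDGE_MARGIN = 10

TRIAGE_CLASSES = ("no_domain", "nonfunctional", "functional", "possibly_assembly")


class InsufficientSeedsError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class DomainProfile:
    """Per-position log-odds profile (bits) for the family domain."""

    columns: np.ndarray  # (length, 20)
    threshold: float
    source_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    @property
    def consensus_self_score(self) -> float:
        return float(self.columns.max(axis=1).sum())

    def scoring_table(self) -> np.ndarray:
        """(length, 22) table extending the columns with X and stop scores."""
        tab = np.empty((self.length, 22), dtype=np.float64)
        tab[:, :20] = self.columns
        tab[:, X_IDX] = X_SCORE
        tab[:, STOP_IDX] = STOP_SCORE
        return tab


@dataclass(frozen=True)
class Hsp:
    """High-scoring segment pair from the translated search.

    Genomic coordinates are 0-based half-open on the forward strand; ``frame``
    is the offset (0..2) into the strand's own 5'->3' sequence.
    """

    query_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    frame: int
    score: float
    bitscore: float
    evalue: float
    identity_pct: float
    q_start: int = 0
    q_end: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("Hsp start must be < end")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        if self.evalue < 0 or not (0 <= self.identity_pct <= 100):
            raise ValueError("invalid Hsp statistics")


@dataclass(frozen=True)
class GenomeRegion:
    region_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    hsps: tuple[Hsp, ...] = ()
    triage_class: str | None = None
    disruption_evidence: str | None = None


@dataclass(frozen=True)
class ScanParams:
    word_size: int = 4
    max_evalue: float = 1e-3
    xdrop: float = 20.0
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041


@dataclass(frozen=True)
class DomainMatch:
    """Best ungapped local profile-to-frame match inside a region."""

    score: float
    strand: str
    frame: int
    prof_start: int
    prof_end: int
    aa_start: int
    aa_end: int
    covered: int  # profile positions matched by standard residues
    has_stop: bool


def evalue(score: float, m: int, n: int, params: ScanParams = ScanParams()) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    return params.ka_k * m * n * math.exp(-params.ka_lambda * score)


def bitscore(score: float, params: ScanParams = ScanParams()) -> float:
    return (params.ka_lambda * score - math.log(params.ka_k)) / math.log(2.0)


# ---------------------------------------------------------------------------
# profile construction


def build_profile(
    seed_alignment: dict[str, str] | list[tuple[str, str]],
    pseudocount: float = 0.1,
    threshold_fraction: float = 0.6,
) -> DomainProfile:
    """Build a log-odds PSSM from an aligned seed protein set.

    Columns with >= 50 % residue occupancy define the profile span.  Scores are
    ``log2((f + pc*bg) / ((1+pc)*bg))`` with uniform background ``bg = 1/20``;
    the detection threshold defaults to 0.6x the consensus self-score.
    """
    items = list(seed_alignment.items()) if isinstance(seed_alignment, dict) else list(seed_alignment)
    if len(items) < 3:
        raise InsufficientSeedsError("at least 3 seed sequences are required")
    ids = tuple(sid for sid, _ in items)
    rows = [seq.upper() for _, seq in items]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("seed alignment rows must have equal length")

    nseq = len(rows)
    bg = 1.0 / 20.0
    columns = []
    for j in range(width):
        residues = [r[j] for r in rows if r[j] in AA_INDEX]
        if len(residues) < 0.5 * nseq:
            continue
        counts = np.zeros(20)
        for c in residues:
            counts[AA_INDEX[c]] += 1
        freq = counts / counts.sum()
        ratio = (freq + pseudocount * bg) / ((1.0 + pseudocount) * bg)
        # keep scores finite even at pseudocount 0 (unobserved residues)
        col = np.log2(np.maximum(ratio, 2.0**-30))
        columns.append(col)
    if not columns:
        raise ValueError("no profile columns with >= 50 % occupancy")
    cols = np.array(columns)
    threshold = threshold_fraction * float(cols.max(axis=1).sum())
    return DomainProfile(columns=cols, threshold=threshold, source_ids=ids)


# ---------------------------------------------------------------------------
# ungapped local profile matching (per-diagonal max-sum)


def best_profile_match(profile_table: np.ndarray, codes: np.ndarray):
    """Best ungapped local alignment of a PSSM against an encoded protein.

    Returns ``(score, prof_start, prof_end, seq_start, seq_end)`` of the
    maximum-sum contiguous diagonal segment (Kadane over all diagonals),
    or ``None`` for an empty sequence.
    """
    L = profile_table.shape[0]
    S = codes.shape[0]
    if S == 0:
        return None
    M = profile_table[:, codes]  # (L, S)
    width = S + L - 1
    shifted = np.full((L, width), -np.inf)
    for p in range(L):
        shifted[p, L - 1 - p : L - 1 - p + S] = M[p]
    run = np.full(width, -np.inf)
    best = -np.inf
    best_p = best_col = 0
    for p in range(L):
        row = shifted[p]
        run = np.where(run > 0, run + row, row)
        run[np.isnan(run)] = -np.inf
        j = int(np.argmax(run))
        if run[j] > best:
            best, best_p, best_col = float(run[j]), p, j
    if not np.isfinite(best):
        return None
    # backtrack along the winning diagonal to find the segment start
    d = best_col - (L - 1)  # seq_pos - prof_pos offset
    p = best_p
    total = 0.0
    start_p = best_p
    acc = 0.0
    while p >= 0:
        s = d + p
        if s < 0 or s >= S:
            break
        acc += M[p, s]
        if acc >= best - 1e-9:
            start_p = p
        p -= 1
    prof_start, prof_end = start_p, best_p + 1
    seq_start, seq_end = d + start_p, d + best_p + 1
    return best, prof_start, prof_end, seq_start, seq_end


def _match_region_frames(region_seq: str, profile: DomainProfile):
    """Best DomainMatch of the profile over all six frames of a sequence."""
    table = profile.scoring_table()
    best: DomainMatch | None = None
    for strand, frame, prot in six_frames(region_seq):
        codes = encode_protein(prot)
        hit = best_profile_match(table, codes)
        if hit is None:
            continue
        score, p0, p1, s0, s1 = hit
        span = codes[s0:s1]
        covered = int(np.sum((span != X_IDX) & (span != STOP_IDX)))
        has_stop = bool(np.any(span == STOP_IDX))
        m = DomainMatch(score, strand, frame, p0, p1, s0, s1, covered, has_stop)
        if best is None or m.score > best.score:
            best = m
    return best


# ---------------------------------------------------------------------------
# six-frame seed-and-extend scan


def _word_hash(codes: np.ndarray, w: int) -> np.ndarray:
    """Rolling base-23 hash of all w-mers (exact; codes < 23)."""
    if codes.shape[0] < w:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(codes.shape[0] - w + 1, dtype=np.int64)
    for k in range(w):
        h = h * 23 + codes[k : codes.shape[0] - w + 1 + k]
    return h


def _extend(qcodes: np.ndarray, tcodes: np.ndarray, qpos: int, tpos: int, w: int, xdrop: float):
    """Ungapped X-drop extension of a word hit; returns (score, q0, q1, t0, t1)."""
    diag_score = float(BLOSUM62[qcodes[qpos : qpos + w], tcodes[tpos : tpos + w]].sum())
    # extend right
    best = cur = diag_score
    qi, ti = qpos + w, tpos + w
    best_q1, best_t1 = qi, ti
    while qi < len(qcodes) and ti < len(tcodes):
        cur += BLOSUM62[qcodes[qi], tcodes[ti]]
        qi += 1
        ti += 1
        if cur > best:
            best, best_q1, best_t1 = cur, qi, ti
        elif best - cur > xdrop:
            break
    # extend left
    total_best = best
    cur = best
    qi, ti = qpos, tpos
    best_q0, best_t0 = qpos, tpos
    while qi > 0 and ti > 0:
        qi -= 1
        ti -= 1
        cur += BLOSUM62[qcodes[qi], tcodes[ti]]
        if cur > total_best:
            total_best, best_q0, best_t0 = cur, qi, ti
        elif total_best - cur > xdrop:
            break
    return total_best, best_q0, best_q1, best_t0, best_t1


def scan_translated(
    genome: dict[str, str],
    profile: DomainProfile,
    queries: dict[str, str],
    params: ScanParams = ScanParams(),
) -> list[Hsp]:
    """Search seed proteins against all six reading frames of a genome.

    Each reported HSP carries ``evalue = K*m*n*exp(-lambda*S)`` with ``m`` the
    query length and ``n`` the total number of translated residues searched.
    """
    if not queries:
        raise ValueError("empty query set")
    if not genome:
        return []
    w = params.word_size
    qcodes = {qid: encode_protein(seq) for qid, seq in queries.items()}

    frames = []  # (chrom, strand, frame, codes)
    n_total = 0
    for chrom, seq in genome.items():
        for strand, frame, prot in six_frames(seq):
            codes = encode_protein(prot)
            n_total += codes.shape[0]
            frames.append((chrom, strand, frame, codes))

    # index query words (skip words containing X)
    word_index: dict[int, list[tuple[str, int]]] = {}
    for qid, qc in qcodes.items():
        hashes = _word_hash(qc, w)
        for qpos, h in enumerate(hashes):
            if np.any(qc[qpos : qpos + w] >= X_IDX):
                continue
            word_index.setdefault(int(h), []).append((qid, qpos))
    if not word_index:
        return []
    qwords = np.fromiter(word_index.keys(), dtype=np.int64)

    hsps: list[Hsp] = []
    for chrom, strand, frame, tcodes in frames:
        chrom_len = len(genome[chrom])
        thash = _word_hash(tcodes, w)
        if thash.shape[0] == 0:
            continue
        mask = np.isin(thash, qwords)
        positions = np.nonzero(mask)[0]
        done: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for tpos in positions:
            for qid, qpos in word_index[int(thash[tpos])]:
                diag = int(tpos) - qpos
                spans = done.setdefault((qid, diag), [])
                if any(s <= tpos < e for s, e in spans):
                    continue
                score, q0, q1, t0, t1 = _extend(
                    qcodes[qid], tcodes, qpos, int(tpos), w, params.xdrop
                )
                spans.append((t0, t1))
                e = evalue(score, len(qcodes[qid]), n_total, params)
                if e > params.max_evalue:
                    continue
                qseg = qcodes[qid][q0:q1]
                tseg = tcodes[t0:t1]
                ident = 100.0 * float(np.mean(qseg == tseg)) if len(qseg) else 0.0
                g0, g1 = aa_to_genomic(strand, frame, t0, t1, chrom_len)
                hsps.append(
                    Hsp(
                        query_id=qid,
                        chromosome=chrom,
                        start=g0,
                        end=g1,
                        strand=strand,
                        frame=frame,
                        score=float(score),
                        bitscore=bitscore(score, params),
                        evalue=e,
                        identity_pct=ident,
                        q_start=q0,
                        q_end=q1,
                    )
                )
    hsps.sort(key=lambda h: (h.chromosome, h.start, h.end, h.strand, h.query_id))
    return hsps


# ---------------------------------------------------------------------------
# region merging and triage


def merge_regions(hsps: list[Hsp], max_gap: int = 10_000) -> list[GenomeRegion]:
    """Merge same-chromosome, same-strand HSPs within ``max_gap`` bp.

    Regions are disjoint per (chromosome, strand) and sorted by coordinate.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.chromosome, h.strand), []).append(h)
    regions: list[GenomeRegion] = []
    for (chrom, strand), members in groups.items():
        members.sort(key=lambda h: (h.start, h.end))
        cluster: list[Hsp] = []
        for h in members:
            if cluster and h.start - max(x.end for x in cluster) > max_gap:
                regions.append(_make_region(chrom, strand, cluster))
                cluster = []
            cluster.append(h)
        if cluster:
            regions.append(_make_region(chrom, strand, cluster))
    regions.sort(key=lambda r: (r.chromosome, r.start, r.end, r.strand))
    return [replace(r, region_id=f"region-{i + 1:04d}") for i, r in enumerate(regions)]


def _make_region(chrom: str, strand: str, cluster: list[Hsp]) -> GenomeRegion:
    return GenomeRegion(
        region_id="region-0000",
        chromosome=chrom,
        start=min(h.start for h in cluster),
        end=max(h.end for h in cluster),
        strand=strand,
        hsps=tuple(cluster),
    )


def _footprint_has_internal_stop(region: GenomeRegion, genome: dict[str, str]) -> bool:
    chrom_seq = genome[region.chromosome]
    for h in region.hsps:
        seg = chrom_seq[h.start : h.end]
        prot = translate(seg if h.strand == "+" else revcomp(seg))
        inner = prot[STOP_EDGE_MARGIN : len(prot) - STOP_EDGE_MARGIN]
        if "*" in inner:
            return True
    return False


def triage_region(
    region: GenomeRegion,
    genome: dict[str, str],
    profile: DomainProfile,
    truncation_coverage: float = 0.8,
    pad: int = 60,
) -> GenomeRegion:
    """Assign the triage class of a candidate region.

    ``no_domain`` when the best six-frame PSSM match scores below the profile
    threshold; otherwise the best match is inspected for disruptions: an
    internal stop codon (in the matched window or in a supporting HSP
    footprint), a truncated domain (matched standard-residue coverage below
    ``truncation_coverage`` of the profile length) or an overlap with a run of
    >= 20 'N' bases (class ``possibly_assembly``).  A region whose matched
    window crosses such an N run is never called functional, because its
    translation there is ambiguous.
    """
    if region.chromosome not in genome:
        raise CoordinateError(f"unknown chromosome {region.chromosome!r}")
    chrom_seq = genome[region.chromosome]
    if region.start < 0 or region.end > len(chrom_seq):
        raise CoordinateError("region outside chromosome bounds")
    if not region.hsps:
        raise ValueError("region has no supporting Hsps")

    lo = max(0, region.start - pad)
    hi = min(len(chrom_seq), region.end + pad)
    seq = chrom_seq[lo:hi]
    match = _match_region_frames(seq, profile)
    if match is None or match.score < profile.threshold:
        return replace(region, triage_class="no_domain", disruption_evidence=None)

    g0, g1 = aa_to_genomic(match.strand, match.frame, match.aa_start, match.aa_end, len(seq))
    gap_hit = any(g0 < e and s < g1 for s, e in n_runs(seq))
    coverage = match.covered / profile.length
    internal_stop = match.has_stop or _footprint_has_internal_stop(region, genome)
    truncated = coverage < truncation_coverage

    if not (internal_stop or truncated or gap_hit):
        return replace(region, triage_class="functional", disruption_evidence=None)
    if gap_hit:
        return replace(region, triage_class="possibly_assembly", disruption_evidence="gap_overlap")
    evidence = "internal_stop" if internal_stop else "truncation"
    return replace(region, triage_class="nonfunctional", disruption_evidence=evidence)


def triage_all(regions, genome, profile, **kw) -> list[GenomeRegion]:
    return [triage_region(r, genome, profile, **kw) for r in regions]
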