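"""Cross-species homology scoring and one-to-one ortholog calling.

Protein pairs are scored with local (Smith-Waterman) alignment under BLOSUM62
with affine gaps (11/1) and Karlin-Altschul expectation values.  Pairs passing
the retention filter (E < 1e-20 and percent identity > 40, both strict) feed a
reciprocal-best-hit (RBH) call: gene A of the focal species and gene B of
species X are one-to-one orthologs iff B is A's best retained match in X and A
is B's best retained match in the focal species; genes with retained pairs but
no reciprocal best are homologs only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .domain_scan import ScanParams, bitscore, evalue

ONE_TO_ONE = "1to1"
HOMOLOG_ONLY = "hom"
NONE_CELL = "none"


@dataclass(frozen=True)
class PairScore:
    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    score: float
    bitscore: float
    evalue: float
    homology_pct: float  # percent identity over the aligned region

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def _make_aligner(params: ScanParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(params.gap_open)
    aligner.extend_gap_score = -(params.gap_extend)
    return aligner


def _identity_pct(alignment) -> float:
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0
    return 100.0 * counts.identities / columns


def score_pair(
    gene_a: str,
    seq_a: str,
    gene_b: str,
    seq_b: str,
    species_a: str = "A",
    species_b: str = "B",
    params: ScanParams = ScanParams(),
) -> PairScore:
    """Best local alignment of one ordered protein pair."""
    aligner = _make_aligner(params)
    score = float(aligner.score(seq_a, seq_b))
    aln = next(iter(aligner.align(seq_a, seq_b)))
    return PairScore(
        gene_a=gene_a,
        gene_b=gene_b,
        species_a=species_a,
        species_b=species_b,
        score=score,
        bitscore=bitscore(score, params),
        evalue=evalue(score, len(seq_a), len(seq_b), params),
        homology_pct=_identity_pct(aln),
    )


def score_all_pairs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    species_a: str = "A",
    species_b: str = "B",
    params: ScanParams = ScanParams(),
    min_raw_score: float = 0.0,
) -> list[PairScore]:
    """Score every cross pair, keeping the best local alignment per pair."""
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    aligner = _make_aligner(params)
    out: list[PairScore] = []
    for ga, sa in proteome_a.items():
        for gb, sb in proteome_b.items():
            score = float(aligner.score(sa, sb))
            if score < min_raw_score:
                continue
            e = evalue(score, len(sa), len(sb), params)
            aln = next(iter(aligner.align(sa, sb)))
            out.append(
                PairScore(ga, gb, species_a, species_b, score, bitscore(score, params), e, _identity_pct(aln))
            )
    return out


def filter_homologs(
    scores: list[PairScore],
    max_evalue: float = 1e-20,
    min_homology: float = 40.0,
) -> list[PairScore]:
    """Retain pairs with evalue strictly below and identity strictly above cutoffs."""
    return [s for s in scores if s.evalue < max_evalue and s.homology_pct > min_homology]


def _best_match(candidates: list[PairScore], key_gene: str, forward: bool) -> str | None:
    """Best partner of ``key_gene``: max bitscore, then min evalue, then id."""
    pool = [s for s in candidates if (s.gene_a if forward else s.gene_b) == key_gene]
    if not pool:
        return None
    best = min(pool, key=lambda s: (-s.bitscore, s.evalue, s.gene_b if forward else s.gene_a))
    return best.gene_b if forward else best.gene_a


def call_orthologs(retained: list[PairScore]):
    """Reciprocal-best-hit calls from retained pair scores (one species pair).

    Returns ``(pairs, cells)`` where ``pairs`` is the list of one-to-one
    ``(gene_a, gene_b)`` tuples and ``cells`` maps every gene (both sides) to
    ``'1to1'`` or ``'hom'``; genes absent from ``retained`` have no entry
    (matrix cell ``'none'``).
    """
    genes_a = sorted({s.gene_a for s in retained})
    genes_b = sorted({s.gene_b for s in retained})
    pairs = []
    for ga in genes_a:
        gb = _best_match(retained, ga, forward=True)
        if gb is not None and _best_match(retained, gb, forward=False) == ga:
            pairs.append((ga, gb))
    in_pair_a = {a for a, _ in pairs}
    in_pair_b = {b for _, b in pairs}
    cells = {}
    for g in genes_a:
        cells[("a", g)] = ONE_TO_ONE if g in in_pair_a else HOMOLOG_ONLY
    for g in genes_b:
        cells[("b", g)] = ONE_TO_ONE if g in in_pair_b else HOMOLOG_ONLY
    return pairs, cells


def build_orthology_matrix(
    focal: dict[str, str],
    others: dict[str, dict[str, str]],
    focal_name: str = "GV",
    params: ScanParams = ScanParams(),
    max_evalue: float = 1e-20,
    min_homology: float = 40.0,
) -> pd.DataFrame:
    """Three-state gene x species matrix for the focal proteome.

    Cell values: ``1to1`` (reciprocal best), ``hom`` (retained pair but not
    reciprocal best), ``none`` (no retained pair).
    """
    genes = sorted(focal)
    matrix = pd.DataFrame(NONE_CELL, index=genes, columns=sorted(others))
    for sp_name in sorted(others):
        scores = score_all_pairs(focal, others[sp_name], focal_name, sp_name, params)
        retained = filter_homologs(scores, max_evalue, min_homology)
        _, cells = call_orthologs(retained)
        for g in genes:
            cell = cells.get(("a", g))
            if cell:
                matrix.loc[g, sp_name] = cell
    return matrix
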