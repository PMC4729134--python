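"""Gene models: GFF3 I/O, translation, structure comparison, exon validation.

Models hold exon/CDS intervals as 0-based half-open genomic tuples ordered in
transcript orientation (5'->3'; descending genomic coordinates on the minus
strand).  GFF3 emitted by :func:`write_gff` is 1-based inclusive and round-trips
through :func:`read_gff` field-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp, translate

log = logging.getLogger(__name__)

STATUSES = ("gene", "putative", "hypothetical")


class GffParseError(ValueError):
    pass


class NotComparableError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


def _transcript_sort(intervals, strand):
    return sorted(intervals, key=lambda iv: iv[0], reverse=(strand == "-"))


@dataclass
class GeneModel:
    locus_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    phases: list[int] = field(default_factory=list)
    status: str = "gene"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.exons = _transcript_sort([tuple(e) for e in self.exons], self.strand)
        self.cds = _transcript_sort([tuple(c) for c in self.cds], self.strand)
        if not self.phases:
            self.phases = [0] * len(self.cds)
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.locus_id}: overlapping exons")
        for c in self.cds:
            if not any(s <= c[0] and c[1] <= e for s, e in self.exons):
                raise ValueError(f"{self.locus_id}: CDS {c} outside exons")

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class CurationDiff:
    locus_id: str
    verdict: str  # confirmed | curated | discarded
    changed_exons: int = 0
    reason: str = ""

    def __post_init__(self):
        if self.verdict == "discarded" and not self.reason:
            raise ValueError("discarded verdict requires a reason")


@dataclass
class ExonSupport:
    exon: tuple[int, int]
    median_depth: float
    supported: bool


# ---------------------------------------------------------------------------
# GFF3


def write_gff(models, path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        s, e = m.span
        lines.append(
            "\t".join(
                [
                    m.chromosome,
                    "famscan",
                    "gene",
                    str(s + 1),
                    str(e),
                    ".",
                    m.strand,
                    ".",
                    f"ID={m.locus_id};status={m.status}",
                ]
            )
        )
        for x0, x1 in sorted(m.exons):
            lines.append(
                "\t".join(
                    [m.chromosome, "famscan", "exon", str(x0 + 1), str(x1), ".", m.strand, ".", f"Parent={m.locus_id}"]
                )
            )
        phase_by_cds = {c: p for c, p in zip(m.cds, m.phases)}
        for c0, c1 in sorted(m.cds):
            ph = phase_by_cds[(c0, c1)]
            lines.append(
                "\t".join(
                    [m.chromosome, "famscan", "CDS", str(c0 + 1), str(c1), ".", m.strand, str(ph), f"Parent={m.locus_id}"]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff(path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels (gene/mRNA anchors, exon/CDS parts)."""
    anchors: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    parts: list[tuple[str, str, int, int, int, str]] = []  # parent, type, s, e, phase-line
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(f"line {lineno}: expected 9 tab-separated columns")
            chrom, _src, ftype, start, end, _score, strand, phase, attrs = cols
            try:
                s0, e1 = int(start) - 1, int(end)
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: bad coordinates") from exc
            if s0 < 0 or e1 <= s0:
                raise GffParseError(f"line {lineno}: invalid interval {start}..{end}")
            a = _parse_attributes(attrs)
            if ftype in ("gene", "mRNA", "region"):
                fid = a.get("ID")
                if fid is None:
                    raise GffParseError(f"line {lineno}: {ftype} without ID")
                if "Parent" in a:
                    parent_of[fid] = a["Parent"]
                else:
                    anchors[fid] = {
                        "chromosome": chrom,
                        "strand": strand,
                        "status": a.get("status", "gene"),
                        "exons": [],
                        "cds": [],
                        "phases": [],
                    }
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent")
                if parent is None:
                    raise GffParseError(f"line {lineno}: {ftype} without Parent")
                ph = int(phase) if phase.isdigit() else 0
                parts.append((parent, ftype, s0, e1, ph, f"line {lineno}"))
    models: dict[str, dict] = {}
    for parent, ftype, s0, e1, ph, where in parts:
        top = parent
        seen = set()
        while top in parent_of and top not in seen:
            seen.add(top)
            top = parent_of[top]
        if top not in anchors:
            raise GffParseError(f"{where}: unknown Parent {parent!r}")
        rec = models.setdefault(top, anchors[top])
        if ftype == "exon":
            rec["exons"].append((s0, e1))
        else:
            rec["cds"].append((s0, e1))
            rec["phases"].append(ph)
    out = []
    for locus_id, rec in models.items():
        phase_by_cds = {c: p for c, p in zip(rec["cds"], rec["phases"])}
        cds_sorted = _transcript_sort(rec["cds"], rec["strand"])
        out.append(
            GeneModel(
                locus_id=locus_id,
                chromosome=rec["chromosome"],
                strand=rec["strand"],
                exons=rec["exons"],
                cds=cds_sorted,
                phases=[phase_by_cds[c] for c in cds_sorted],
                status=rec["status"],
            )
        )
    out.sort(key=lambda m: (m.chromosome, m.span[0], m.locus_id))
    return out


# ---------------------------------------------------------------------------
# translation


def translate_model(model: GeneModel, genome: dict[str, str]):
    """Translate the spliced CDS with the standard genetic code.

    Returns ``(protein, flags)``; a single terminal stop is stripped and
    recorded as ``complete``.  ``internal_stop`` flags any remaining '*'.
    """
    if not model.cds:
        raise ValueError(f"{model.locus_id}: no CDS to translate")
    chrom = genome.get(model.chromosome)
    if chrom is None:
        raise CoordinateError(f"unknown chromosome {model.chromosome!r}")
    for s, e in model.cds:
        if s < 0 or e > len(chrom):
            raise CoordinateError(f"{model.locus_id}: CDS outside chromosome")
    segs = []
    for s, e in model.cds:  # already transcript-ordered
        seg = chrom[s:e]
        segs.append(seg if model.strand == "+" else revcomp(seg))
    mrna = "".join(segs)
    offset = model.phases[0] if model.phases else 0
    protein = translate(mrna[offset:])
    complete = protein.endswith("*")
    if complete:
        protein = protein[:-1]
    flags = {
        "internal_stop": "*" in protein,
        "no_start": not protein.startswith("M"),
        "complete": complete,
        "length": len(protein),
    }
    return protein, flags


# ---------------------------------------------------------------------------
# structure comparison


def _count_changed(a: set, b: set) -> int:
    only_a = sorted(a - b)
    only_b = sorted(b - a)
    used = set()
    changed = 0
    for iv in only_a:
        match = next(
            (j for j in only_b if j not in used and iv[0] < j[1] and j[0] < iv[1]),
            None,
        )
        if match is not None:
            used.add(match)
        changed += 1
    changed += sum(1 for j in only_b if j not in used)
    return changed


def compare_structures(model_a: GeneModel, model_b: GeneModel) -> CurationDiff:
    """Compare two models of the same locus: confirmed iff intervals identical."""
    if model_a.chromosome != model_b.chromosome or model_a.strand != model_b.strand:
        raise NotComparableError("models on different chromosome or strand")
    sa, sb = model_a.span, model_b.span
    if sa[1] <= sb[0] or sb[1] <= sa[0]:
        raise NotComparableError("models do not overlap")
    exons_a, exons_b = set(model_a.exons), set(model_b.exons)
    cds_a, cds_b = set(model_a.cds), set(model_b.cds)
    if exons_a == exons_b and cds_a == cds_b:
        return CurationDiff(model_a.locus_id, "confirmed", 0)
    changed = _count_changed(exons_a, exons_b)
    return CurationDiff(
        model_a.locus_id,
        "curated",
        changed_exons=changed,
        reason=f"{changed} exon(s) differ" if changed else "CDS intervals differ",
    )


# ---------------------------------------------------------------------------
# coverage validation


def validate_exons_with_coverage(
    model: GeneModel,
    coverage: dict[str, np.ndarray],
    min_depth: float = 5,
):
    """Check each exon against an expression depth track.

    An exon is supported iff its median per-base depth is >= ``min_depth``
    (median, robust to edge tapering).  Missing track regions count as depth 0.
    Returns ``(per-exon ExonSupport list, model_flagged)``.
    """
    track = coverage.get(model.chromosome)
    verdicts = []
    for s, e in model.exons:
        if track is None or s >= len(track):
            log.warning("%s: no coverage for %s:%d-%d, treating as depth 0", model.locus_id, model.chromosome, s, e)
            depths = np.zeros(e - s)
        else:
            depths = np.asarray(track[s:e], dtype=float)
            if len(depths) < e - s:
                log.warning("%s: coverage track truncated over exon %d-%d", model.locus_id, s, e)
                depths = np.concatenate([depths, np.zeros((e - s) - len(depths))])
        med = float(np.median(depths)) if len(depths) else 0.0
        verdicts.append(ExonSupport((s, e), med, med >= min_depth))
    flagged = any(not v.supported for v in verdicts)
    return verdicts, flagged


# ---------------------------------------------------------------------------
# BedGraph coverage tracks


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Write per-base depth arrays as run-length-encoded BedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    track = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "depth"])
    for row in df.itertuples(index=False):
        if row.chrom in track:
            track[row.chrom][row.start : row.end] = row.depth
    return track
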