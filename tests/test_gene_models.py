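"""GFF3 round-trips, translation, curation diffs, coverage validation."""

import numpy as np
import pytest

from famscan.gene_models import (
    CurationDiff,
    GeneModel,
    GffParseError,
    NotComparableError,
    compare_structures,
    read_bedgraph,
    read_gff,
    translate_model,
    validate_exons_with_coverage,
    write_bedgraph,
    write_gff,
)
from famscan.syndata import coverage_from_models
from famscan._seq import revcomp


def test_single_exon_coordinate_convention(tmp_path):
    m = GeneModel("g1", "chr1", "+", exons=[(99, 400)], cds=[(99, 400)])
    path = tmp_path / "m.gff3"
    write_gff([m], path)
    text = path.read_text()
    assert text.startswith("##gff-version 3")
    assert "\t100\t400\t" in text  # 1-based inclusive on disk
    back = read_gff(path)[0]
    assert back.exons == [(99, 400)]


def test_minus_strand_exons_in_transcript_order():
    m = GeneModel("g1", "chr1", "-", exons=[(100, 200), (300, 400)])
    assert m.exons == [(300, 400), (100, 200)]  # 5'->3' on minus strand


def test_round_trip_of_random_models_is_field_identical(tmp_path):
    rng = np.random.default_rng(0)
    models = []
    for i in range(50):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        pos = 1000 * i
        exons = []
        for _ in range(n_ex):
            s = pos + int(rng.integers(0, 200))
            e = s + int(rng.integers(30, 120))
            exons.append((s, e))
            pos = e + int(rng.integers(20, 80))
        models.append(GeneModel(f"g{i}", f"chr{1 + i % 3}", strand, exons=exons, cds=list(exons)))
    path = tmp_path / "many.gff3"
    write_gff(models, path)
    back = read_gff(path)
    key = lambda m: m.locus_id
    for a, b in zip(sorted(models, key=key), sorted(back, key=key)):
        assert (a.locus_id, a.chromosome, a.strand, a.exons, a.cds, a.phases, a.status) == (
            b.locus_id,
            b.chromosome,
            b.strand,
            b.exons,
            b.cds,
            b.phases,
            b.status,
        )


def test_malformed_gff_reports_line_number(tmp_path):
    path = tmp_path / "bad.gff3"
    path.write_text("##gff-version 3\nchr1\tx\tgene\t1\t100\t.\t+\t.\tID=g\nnot-a-gff-line\n")
    with pytest.raises(GffParseError, match="line 3"):
        read_gff(path)


# ---------------------------------------------------------------------------
# translation


def test_translate_simple_cds():
    genome = {"chr1": "ATGGCTTAA"}
    m = GeneModel("g", "chr1", "+", exons=[(0, 9)], cds=[(0, 9)])
    protein, flags = translate_model(m, genome)
    assert protein == "MA"
    assert not flags["internal_stop"] and flags["complete"]


def test_translate_flags_internal_stop():
    genome = {"chr1": "ATGTAAGCTGCT"}
    m = GeneModel("g", "chr1", "+", exons=[(0, 12)], cds=[(0, 12)])
    protein, flags = translate_model(m, genome)
    assert flags["internal_stop"]


def test_translate_minus_strand_matches_revcomp():
    """Translating a minus-strand model equals translating its lifted
    plus-strand reverse complement."""
    cds = "ATGGCTAGGTGCTTTAAGTAA"
    genome = {"chr1": "CCCC" + revcomp(cds) + "GGGG"}
    m = GeneModel("g", "chr1", "-", exons=[(4, 4 + len(cds))], cds=[(4, 4 + len(cds))])
    protein, flags = translate_model(m, genome)
    lifted = {"chr1": "CCCC" + cds + "GGGG"}
    m2 = GeneModel("g", "chr1", "+", exons=[(4, 4 + len(cds))], cds=[(4, 4 + len(cds))])
    protein2, _ = translate_model(m2, lifted)
    assert protein == protein2 == "MARCFK"


def test_translations_match_generator_truth(small_genome):
    for m in small_genome.gff:
        klass = next(g.klass for g in small_genome.truth.planted_genes if g.locus_id == m.locus_id)
        protein, flags = translate_model(m, small_genome.genome)
        if klass in ("functional", "truncated"):
            assert protein == small_genome.truth.proteins[m.locus_id]
        if klass == "internal_stop":
            assert flags["internal_stop"]


def test_translate_out_of_bounds_cds():
    from famscan.gene_models import CoordinateError

    m = GeneModel("g", "chr1", "+", exons=[(0, 30)], cds=[(0, 30)])
    with pytest.raises(CoordinateError):
        translate_model(m, {"chr1": "ATG"})


# ---------------------------------------------------------------------------
# structure comparison


def test_identical_models_confirmed():
    a = GeneModel("g", "chr1", "+", exons=[(0, 100), (200, 300)], cds=[(0, 100), (200, 300)])
    d = compare_structures(a, a)
    assert d.verdict == "confirmed" and d.changed_exons == 0


def test_extended_exon_counts_one_change():
    a = GeneModel("g", "chr1", "+", exons=[(0, 100), (200, 300)])
    b = GeneModel("g", "chr1", "+", exons=[(0, 100), (200, 312)])
    d = compare_structures(a, b)
    assert d.verdict == "curated" and d.changed_exons == 1


def test_non_overlapping_models_not_comparable():
    a = GeneModel("g", "chr1", "+", exons=[(0, 100)])
    b = GeneModel("g", "chr1", "+", exons=[(500, 600)])
    with pytest.raises(NotComparableError):
        compare_structures(a, b)


def test_changed_exons_equals_symdiff_oracle():
    """Over random perturbations, changed_exons equals a brute-force count of
    modified + inserted + deleted exons (symmetric difference with overlap
    pairing)."""
    rng = np.random.default_rng(4)
    for _ in range(30):
        exons = []
        pos = 0
        for _ in range(int(rng.integers(2, 6))):
            s = pos + int(rng.integers(50, 150))
            e = s + int(rng.integers(60, 200))
            exons.append((s, e))
            pos = e
        perturbed = []
        for s, e in exons:
            roll = rng.random()
            if roll < 0.3:
                perturbed.append((s, e + 3 * int(rng.integers(1, 5))))  # extend
            elif roll < 0.4:
                pass  # drop exon
            else:
                perturbed.append((s, e))
        if not perturbed or not (set(p for p in perturbed) & set(exons) or any(
            p[0] < exons[-1][1] and exons[0][0] < p[1] for p in perturbed
        )):
            continue
        a = GeneModel("g", "chr1", "+", exons=exons)
        b = GeneModel("g", "chr1", "+", exons=perturbed)
        d = compare_structures(a, b)
        # oracle: pair up overlapping intervals of the symmetric difference
        only_a = [iv for iv in exons if iv not in perturbed]
        only_b = [iv for iv in perturbed if iv not in exons]
        paired = 0
        used = set()
        for iv in only_a:
            for j, jv in enumerate(only_b):
                if j not in used and iv[0] < jv[1] and jv[0] < iv[1]:
                    used.add(j)
                    paired += 1
                    break
        oracle = len(only_a) + len(only_b) - paired
        if exons == perturbed:
            assert d.verdict == "confirmed"
        else:
            assert d.changed_exons == oracle


def test_discarded_requires_reason():
    with pytest.raises(ValueError):
        CurationDiff("g", "discarded", 0, "")


# ---------------------------------------------------------------------------
# coverage validation


def test_uniform_depth_supports_all_exons():
    m = GeneModel("g", "chr1", "+", exons=[(10, 50), (80, 120)])
    track = {"chr1": np.full(200, 100.0)}
    verdicts, flagged = validate_exons_with_coverage(m, track)
    assert all(v.supported for v in verdicts) and not flagged


def test_zero_depth_exon_flags_model():
    m = GeneModel("g", "chr1", "+", exons=[(10, 50), (80, 120)])
    track = {"chr1": np.zeros(200)}
    track["chr1"][10:50] = 30
    verdicts, flagged = validate_exons_with_coverage(m, track)
    assert verdicts[0].supported and not verdicts[1].supported and flagged


def test_truth_tracks_give_perfect_support(small_genome, tmp_path):
    """On tracks built from truth exons, support recall is 1 and no exon
    outside the truth is supported (checked via a shifted decoy model)."""
    lengths = {c: len(s) for c, s in small_genome.genome.items()}
    track = coverage_from_models(small_genome.gff, lengths, depth=50)
    path = tmp_path / "cov.bedgraph"
    write_bedgraph(track, path)
    track2 = read_bedgraph(path, lengths)
    for m in small_genome.gff:
        _, flagged = validate_exons_with_coverage(m, track2, min_depth=5)
        assert not flagged  # recall = 1.0
    m0 = small_genome.gff[0]
    span = m0.span
    decoy = GeneModel("x", m0.chromosome, "+", exons=[(span[1] + 1000, span[1] + 1400)])
    verdicts, flagged = validate_exons_with_coverage(decoy, track2, min_depth=5)
    assert flagged and not verdicts[0].supported  # false-support = 0
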