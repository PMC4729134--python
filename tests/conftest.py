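import pytest

from famscan import syndata
from famscan.domain_scan import build_profile, merge_regions, scan_translated, triage_all


@pytest.fixture(scope="session")
def small_genome():
    """Small planted genome exercising every triage class."""
    cfg = syndata.GenomeConfig(
        seed=1,
        chromosomes=2,
        chrom_length=200_000,
        functional=3,
        internal_stop=2,
        truncated=2,
        gap_disrupted=1,
        decoy=1,
        min_spacing=15_000,
    )
    return syndata.generate_genome(cfg)


@pytest.fixture(scope="session")
def small_scan(small_genome):
    """Profile, HSPs and triaged regions of the small genome."""
    profile = build_profile(small_genome.seed_alignment)
    hsps = scan_translated(small_genome.genome, profile, small_genome.seed_proteins)
    regions = triage_all(merge_regions(hsps), small_genome.genome, profile)
    return profile, hsps, regions


EXPECTED_CLASS = {
    "functional": "functional",
    "internal_stop": "nonfunctional",
    "truncated": "nonfunctional",
    "gap_disrupted": "possibly_assembly",
    "decoy": "no_domain",
}


def region_of(gene, regions):
    hits = [
        r
        for r in regions
        if r.chromosome == gene.chromosome
        and r.strand == gene.strand
        and r.start < gene.end
        and gene.start < r.end
    ]
    return hits[0] if hits else None
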