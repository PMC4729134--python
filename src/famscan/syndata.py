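"""Synthetic genomes, proteomes, clade sets and expression data with truth.

Every generator is driven by a single integer seed through one
``numpy.random.Generator`` instance, so identical configurations produce
bit-identical outputs.  The generated material mirrors the study conditions of
a genome-wide gene-family survey: a small genome with planted family genes and
pseudogene classes (internal stop, truncation, assembly-gap disruption),
multi-species proteomes with a known one-to-one ortholog map, clade-structured
protein sets, and multi-platform expression matrices with planted co-regulated
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import AA, percent_identity
from .gene_models import GeneModel

#: archetypal plant family-domain consensus (MADS-domain-like, 60 aa)
DEFAULT_DOMAIN = "MGRGRVELKRIENKINRQVTFAKRRNGLLKKAYELSVLCDAEVALIIFSNRGKLYEFCS"

GENE_CLASSES = ("functional", "internal_stop", "truncated", "gap_disrupted", "decoy")

#: small Plant Ontology vocabulary used for synthetic condition annotation
PO_TERMS = (
    ("leaf", "PO:0025034"),
    ("root", "PO:0009005"),
    ("flower", "PO:0009046"),
    ("seed", "PO:0009010"),
    ("fruit", "PO:0009001"),
    ("shoot apex", "PO:0000037"),
)

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "N": ("AAT", "AAC"),
    "D": ("GAT", "GAC"),
    "C": ("TGT", "TGC"),
    "Q": ("CAA", "CAG"),
    "E": ("GAA", "GAG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "K": ("AAA", "AAG"),
    "M": ("ATG",),
    "F": ("TTT", "TTC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
}


class SizingError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedGene:
    locus_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    klass: str


@dataclass
class SyntheticTruth:
    planted_genes: list[PlantedGene] = field(default_factory=list)
    ortholog_map: set = field(default_factory=set)
    clade_map: dict[str, str] = field(default_factory=dict)
    coexpr_groups: list[frozenset] = field(default_factory=list)
    rng_seed: int = 0
    proteins: dict[str, str] = field(default_factory=dict)
    zero_variance: set = field(default_factory=set)

    def validate(self, chrom_lengths: dict[str, int] | None = None) -> None:
        if chrom_lengths:
            for g in self.planted_genes:
                if not (0 <= g.start < g.end <= chrom_lengths[g.chromosome]):
                    raise AssertionError(f"{g.locus_id} outside chromosome")
        for pair in self.ortholog_map:
            if len(tuple(pair)) != 2:
                raise AssertionError("ortholog_map entries must be pairs")
        seen = set()
        for grp in self.coexpr_groups:
            if seen & grp:
                raise AssertionError("coexpr_groups must be disjoint")
            seen |= grp


def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate_protein(rng, protein: str, rate: float) -> str:
    out = []
    aas = list(AA)
    for c in protein:
        if rng.random() < rate:
            choices = [a for a in aas if a != c]
            out.append(choices[rng.integers(0, len(choices))])
        else:
            out.append(c)
    return "".join(out)


def _backtranslate(rng, protein: str) -> str:
    return "".join(_CODONS[c][rng.integers(0, len(_CODONS[c]))] for c in protein)


# ---------------------------------------------------------------------------
# genome generator


@dataclass(frozen=True)
class GenomeConfig:
    seed: int = 0
    chromosomes: int = 2
    chrom_length: int = 500_000
    functional: int = 5
    internal_stop: int = 2
    truncated: int = 2
    gap_disrupted: int = 1
    decoy: int = 0
    domain_consensus: str = DEFAULT_DOMAIN
    tail_length: int = 120
    mutation_rate: float = 0.02
    min_spacing: int = 25_000
    n_run_length: int = 24  # bp of 'N' replacing domain codons in gap class
    truncation_keep: float = 0.75  # fraction of the domain retained (< 0.8 coverage cutoff)
    seed_count: int = 4  # seed proteins emitted for scanning/profile

    def __post_init__(self):
        if len(self.domain_consensus) < 50:
            raise ConfigError("domain consensus must be >= 50 aa")


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    truth: SyntheticTruth
    gff: list[GeneModel]
    seed_proteins: dict[str, str]
    seed_alignment: dict[str, str]  # domain-only rows for profile building
    config: GenomeConfig


def generate_genome(config: GenomeConfig) -> SyntheticGenome:
    """Plant family genes of each triage class into i.i.d. uniform background.

    Functional genes carry an intact domain + tail CDS; internal-stop genes a
    single TAA substitution >= 30 codons from either CDS end; truncated genes
    only ``truncation_keep`` of the domain; gap-disrupted genes an intact CDS
    whose central domain codons are replaced by a run of 'N'; decoys keep the
    tail homology but a randomized domain (< 25 % identity to the consensus).
    """
    rng = np.random.default_rng(config.seed)
    dom = config.domain_consensus
    L = len(dom)
    family = dom + _random_protein(rng, config.tail_length)

    seeds = {
        f"seed{i + 1}": _mutate_protein(rng, family, config.mutation_rate)
        for i in range(max(3, config.seed_count))
    }
    seed_alignment = {sid: seq[:L] for sid, seq in seeds.items()}

    classes = (
        ["functional"] * config.functional
        + ["internal_stop"] * config.internal_stop
        + ["truncated"] * config.truncated
        + ["gap_disrupted"] * config.gap_disrupted
        + ["decoy"] * config.decoy
    )
    order = rng.permutation(len(classes))
    classes = [classes[i] for i in order]

    max_gene_len = 3 * (len(family) + 1)
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.chromosomes)]
    capacity = config.chromosomes * max(
        0, (config.chrom_length - config.min_spacing) // (max_gene_len + config.min_spacing)
    )
    if len(classes) > capacity:
        raise SizingError(
            f"cannot place {len(classes)} genes with spacing {config.min_spacing} "
            f"on {config.chromosomes} x {config.chrom_length} bp"
        )

    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom_bytes = {
        c: bytearray(alphabet[rng.integers(0, 4, size=config.chrom_length)].tobytes())
        for c in chrom_names
    }

    cursors = {c: 0 for c in chrom_names}
    truth = SyntheticTruth(rng_seed=config.seed)
    gff: list[GeneModel] = []

    for i, klass in enumerate(classes):
        locus = f"SYNG{i + 1:04d}"
        protein = _mutate_protein(rng, family, config.mutation_rate)
        if klass == "truncated":
            keep = int(round(config.truncation_keep * L))
            protein = protein[:keep]
        elif klass == "decoy":
            while True:
                decoy_dom = _random_protein(rng, L)
                if percent_identity(decoy_dom, dom) < 25.0:
                    break
            protein = decoy_dom + protein[L:]
        cds = _backtranslate(rng, protein) + "TAA"
        if klass == "internal_stop":
            ncod = len(cds) // 3
            pos = int(rng.integers(30, ncod - 30))
            cds = cds[: 3 * pos] + "TAA" + cds[3 * pos + 3 :]
        elif klass == "gap_disrupted":
            ncod_gap = max(7, config.n_run_length // 3)  # >= 20 bp of N
            c0 = 3 * (L // 2 - ncod_gap // 2)
            cds = cds[:c0] + "N" * (3 * ncod_gap) + cds[c0 + 3 * ncod_gap :]

        chrom = chrom_names[i % config.chromosomes]
        start = cursors[chrom] + config.min_spacing + int(rng.integers(0, config.min_spacing // 4 + 1))
        end = start + len(cds)
        if end > config.chrom_length:
            raise SizingError(f"chromosome {chrom} too short at gene {locus}")
        cursors[chrom] = end
        strand = "+" if rng.random() < 0.5 else "-"
        insert = cds if strand == "+" else _revcomp_with_n(cds)
        chrom_bytes[chrom][start:end] = insert.encode()
        truth.planted_genes.append(PlantedGene(locus, chrom, start, end, strand, klass))
        truth.proteins[locus] = protein
        if klass != "decoy":
            gff.append(
                GeneModel(
                    locus_id=locus,
                    chromosome=chrom,
                    strand=strand,
                    exons=[(start, end)],
                    cds=[(start, end)],
                    status="gene",
                )
            )

    genome = {c: b.decode() for c, b in chrom_bytes.items()}
    truth.validate({c: config.chrom_length for c in chrom_names})
    return SyntheticGenome(genome, truth, gff, seeds, seed_alignment, config)


def _revcomp_with_n(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# proteome generator


@dataclass(frozen=True)
class ProteomeConfig:
    seed: int = 0
    species: int = 2
    one_to_one: int = 3
    homolog_families: int = 0
    family_size: int = 3
    species_specific: int = 2
    length: int = 200
    ortho_mutation: float = 0.10  # per-residue substitution from the ancestor
    family_mutation: float = 0.20

    def __post_init__(self):
        if self.species < 1:
            raise ConfigError("need at least one species")
        # two independent copies at rate r have expected identity
        # (1-r)^2 + r^2/19; the one-to-one band must stay above 60 %
        r = self.ortho_mutation
        if (1 - r) ** 2 + r * r / 19 <= 0.60:
            raise ConfigError("ortho_mutation too high for the > 60 % identity band")
        if self.length < 50:
            raise ConfigError("proteins shorter than 50 aa cannot hold the identity bands")


@dataclass
class SyntheticProteomes:
    proteomes: dict[str, dict[str, str]]  # species -> gene id -> protein
    truth: SyntheticTruth
    config: ProteomeConfig


def generate_proteomes(config: ProteomeConfig) -> SyntheticProteomes:
    """Multi-species proteomes with planted one-to-one orthologs.

    One-to-one groups descend from a shared ancestor (mutual identity > 60 %);
    homolog-only families expand within species from a family ancestor;
    species-specific genes are independent random proteins (< 30 % identity to
    anything else).  ``truth.ortholog_map`` records the planted one-to-one
    pairs only (as frozensets of ``(species, gene)``).
    """
    rng = np.random.default_rng(config.seed)
    species = [f"sp{i + 1}" for i in range(config.species)]
    proteomes: dict[str, dict[str, str]] = {s: {} for s in species}
    truth = SyntheticTruth(rng_seed=config.seed)

    for g in range(config.one_to_one):
        anc = _random_protein(rng, config.length)
        members = []
        while True:
            members = [
                (s, f"{s}_oo{g + 1}", _mutate_protein(rng, anc, config.ortho_mutation))
                for s in species
            ]
            ok = all(
                percent_identity(a[2], b[2]) > 60.0
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            )
            if ok:
                break
        for s, gid, seq in members:
            proteomes[s][gid] = seq
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                truth.ortholog_map.add(frozenset({(a[0], a[1]), (b[0], b[1])}))

    for f in range(config.homolog_families):
        anc = _random_protein(rng, config.length)
        for s in species:
            for k in range(config.family_size):
                gid = f"{s}_fam{f + 1}_{k + 1}"
                proteomes[s][gid] = _mutate_protein(rng, anc, config.family_mutation)

    for s in species:
        for k in range(config.species_specific):
            proteomes[s][f"{s}_uniq{k + 1}"] = _random_protein(rng, config.length)

    truth.validate()
    return SyntheticProteomes(proteomes, truth, config)


# ---------------------------------------------------------------------------
# clade-structured protein sets (for tree building and clade assignment)


@dataclass(frozen=True)
class CladeConfig:
    seed: int = 0
    clades: int = 3
    genes_per_clade: int = 4
    anchors_per_clade: int = 2
    length: int = 150
    within_divergence: float = 0.05
    between_divergence: float = 0.35


@dataclass
class SyntheticClades:
    sequences: dict[str, str]
    clade_map: dict[str, str]  # every sequence id -> clade label
    anchors: dict[str, str]  # anchor id -> clade label
    config: CladeConfig


def generate_clades(config: CladeConfig) -> SyntheticClades:
    """Protein sets with planted clade structure and labeled anchor leaves."""
    rng = np.random.default_rng(config.seed)
    root = _random_protein(rng, config.length)
    sequences: dict[str, str] = {}
    clade_map: dict[str, str] = {}
    anchors: dict[str, str] = {}
    for c in range(config.clades):
        label = f"clade{c + 1}"
        ancestor = _mutate_protein(rng, root, config.between_divergence)
        for k in range(config.genes_per_clade):
            gid = f"{label}_g{k + 1}"
            sequences[gid] = _mutate_protein(rng, ancestor, config.within_divergence)
            clade_map[gid] = label
        for k in range(config.anchors_per_clade):
            aid = f"{label}_anchor{k + 1}"
            sequences[aid] = _mutate_protein(rng, ancestor, config.within_divergence)
            clade_map[aid] = label
            anchors[aid] = label
    return SyntheticClades(sequences, clade_map, anchors, config)


# ---------------------------------------------------------------------------
# expression generator


@dataclass(frozen=True)
class ExpressionConfig:
    seed: int = 0
    platforms: tuple = (("nimblegen", "array"), ("rnaseq", "count"))
    conditions_per_platform: int = 10
    replicates: int = 3
    group_sizes: tuple = (3, 3)
    singletons: int = 4
    constant_genes: int = 0
    noise_sd: float = 0.2
    array_low: float = 5.0
    array_high: float = 12.0

    def __post_init__(self):
        kinds = {k for _, k in self.platforms}
        if not kinds <= {"array", "count"}:
            raise ConfigError("platform kinds must be 'array' or 'count'")
        if len(self.platforms) * self.conditions_per_platform < 2:
            raise ConfigError("need at least 2 conditions for downstream clustering")


@dataclass
class SyntheticExpression:
    matrices: dict[str, "pd.DataFrame"]  # platform -> genes x samples
    sample_map: "pd.DataFrame"  # sample, condition, platform, tissue, po_term
    condition_po: dict[str, str]
    truth: SyntheticTruth
    config: ExpressionConfig


def generate_expression(config: ExpressionConfig):
    """Per-platform expression matrices with planted co-regulated groups.

    Genes in a planted group share one latent per-condition profile (plus
    i.i.d. Gaussian noise of ``noise_sd`` on the log2 scale); singleton genes
    get independent profiles.  Array platforms carry log2 intensities, count
    platforms carry read counts ``round(2^x - 1)`` of the same latent scale.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    n_group_genes = int(sum(config.group_sizes))
    gene_ids = [f"g{i + 1:03d}" for i in range(n_group_genes + config.singletons + config.constant_genes)]

    groups: list[frozenset] = []
    cursor = 0
    profile_of: dict[str, int] = {}
    n_profiles = 0
    for size in config.group_sizes:
        members = gene_ids[cursor : cursor + size]
        groups.append(frozenset(members))
        for m in members:
            profile_of[m] = n_profiles
        n_profiles += 1
        cursor += size
    for k in range(config.singletons):
        gid = gene_ids[cursor]
        groups.append(frozenset({gid}))
        profile_of[gid] = n_profiles
        n_profiles += 1
        cursor += 1
    constant_ids = gene_ids[cursor:]
    for gid in constant_ids:
        groups.append(frozenset({gid}))

    truth = SyntheticTruth(rng_seed=config.seed, coexpr_groups=groups, zero_variance=set(constant_ids))

    matrices: dict[str, pd.DataFrame] = {}
    sample_rows = []
    condition_po: dict[str, str] = {}
    lo, hi = config.array_low, config.array_high
    for pname, kind in config.platforms:
        conds = [f"{pname}_c{j + 1:02d}" for j in range(config.conditions_per_platform)]
        latent = rng.uniform(lo, hi, size=(n_profiles, len(conds)))
        cols = {}
        for j, cond in enumerate(conds):
            tissue, po = PO_TERMS[j % len(PO_TERMS)]
            condition_po[cond] = po
            for r in range(config.replicates):
                sample = f"{cond}_r{r + 1}"
                sample_rows.append(
                    {"sample": sample, "condition": cond, "platform": pname, "tissue": tissue, "po_term": po}
                )
                vals = np.empty(len(gene_ids))
                for gi, gid in enumerate(gene_ids):
                    if gid in truth.zero_variance:
                        x = (lo + hi) / 2.0
                    else:
                        x = latent[profile_of[gid], j] + rng.normal(0.0, config.noise_sd)
                    vals[gi] = x
                if kind == "count":
                    vals = np.maximum(0, np.rint(np.exp2(vals) - 1.0))
                else:
                    vals = np.round(vals, 4)
                cols[sample] = vals
        matrices[pname] = pd.DataFrame(cols, index=gene_ids)

    sample_map = pd.DataFrame(sample_rows)
    truth.validate()
    return SyntheticExpression(matrices, sample_map, condition_po, truth, config)


# ---------------------------------------------------------------------------
# writers (FASTA / TSV / BedGraph-ready tracks)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def coverage_from_models(models, chrom_lengths: dict[str, int], depth: float = 50.0):
    """Per-base depth tracks covering every exon of the given models."""
    track = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for m in models:
        for s, e in m.exons:
            track[m.chromosome][s:e] = depth
    return track
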