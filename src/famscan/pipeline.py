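"""Pipeline orchestration, catalog summaries and paralogous-segment mapping.

``run_pipeline`` composes the stages end-to-end on synthetic inputs (genome
scan + triage, gene-model translation, optional orthology and expression
stages) and writes every stage output under a run directory together with a
machine-readable manifest of parameters and content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import atlas as atlas_mod
from . import syndata
from .domain_scan import ScanParams, build_profile, merge_regions, scan_translated, triage_all
from .gene_models import translate_model, write_gff
from .orthology import build_orthology_matrix

log = logging.getLogger(__name__)

UNPLACED_CHROMOSOMES = {"chr00", "chrun", "chruk", "un", "chrukn"}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "famscan_run"
    genome: syndata.GenomeConfig | None = None
    proteomes: syndata.ProteomeConfig | None = None
    expression: syndata.ExpressionConfig | None = None
    max_gap: int = 10_000
    max_evalue: float = 1e-3
    ortho_max_evalue: float = 1e-20
    ortho_min_homology: float = 40.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("seed", "outdir", "max_gap", "max_evalue", "ortho_max_evalue", "ortho_min_homology"):
            if key in raw:
                kwargs[key] = raw[key]
        if "genome" in raw:
            kwargs["genome"] = syndata.GenomeConfig(seed=raw.get("seed", 0), **raw["genome"])
        if "proteomes" in raw:
            kwargs["proteomes"] = syndata.ProteomeConfig(seed=raw.get("seed", 0), **raw["proteomes"])
        if "expression" in raw:
            kwargs["expression"] = syndata.ExpressionConfig(seed=raw.get("seed", 0), **raw["expression"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    catalog: pd.DataFrame
    regions: list
    manifest: dict
    outdir: Path
    truth: syndata.SyntheticTruth | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_regions_gff(regions, path) -> None:
    lines = ["##gff-version 3"]
    for r in regions:
        attrs = f"ID={r.region_id};triage_class={r.triage_class or 'pending'}"
        if r.disruption_evidence:
            attrs += f";evidence={r.disruption_evidence}"
        lines.append(
            "\t".join(
                [r.chromosome, "famscan", "region", str(r.start + 1), str(r.end), ".", r.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the synthetic end-to-end pipeline and write a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _jsonable(config), "stages": {}, "outputs": {}}

    genome_cfg = config.genome or syndata.GenomeConfig(seed=config.seed)
    syn = syndata.generate_genome(genome_cfg)
    syndata.write_fasta(syn.genome, outdir / "genome.fasta")
    write_gff(syn.gff, outdir / "genes.gff3")

    profile = build_profile(syn.seed_alignment)
    params = ScanParams(max_evalue=config.max_evalue)
    hsps = scan_translated(syn.genome, profile, syn.seed_proteins, params)
    regions = triage_all(merge_regions(hsps, config.max_gap), syn.genome, profile)
    write_regions_gff(regions, outdir / "regions.gff3")
    manifest["stages"]["scan"] = {"hsps": len(hsps), "regions": len(regions)}

    rows = []
    models = {m.locus_id: m for m in syn.gff}
    for g in syn.truth.planted_genes:
        region = next(
            (
                r
                for r in regions
                if r.chromosome == g.chromosome and r.strand == g.strand and r.start < g.end and g.start < r.end
            ),
            None,
        )
        protein, flags = (None, {})
        if g.locus_id in models:
            protein, flags = translate_model(models[g.locus_id], syn.genome)
        rows.append(
            {
                "locus_id": g.locus_id,
                "symbol": g.locus_id,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "planted_class": g.klass,
                "triage_class": region.triage_class if region else "missed",
                "evidence": region.disruption_evidence if region else None,
                "internal_stop": flags.get("internal_stop"),
                "protein_length": flags.get("length"),
            }
        )
    catalog = pd.DataFrame(rows)
    catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)

    if config.proteomes is not None:
        prot = syndata.generate_proteomes(config.proteomes)
        species = sorted(prot.proteomes)
        focal = species[0]
        others = {s: prot.proteomes[s] for s in species[1:]}
        matrix = build_orthology_matrix(
            prot.proteomes[focal],
            others,
            focal_name=focal,
            max_evalue=config.ortho_max_evalue,
            min_homology=config.ortho_min_homology,
        )
        matrix.to_csv(outdir / "orthology_matrix.tsv", sep="\t")
        manifest["stages"]["orthology"] = {
            "focal": focal,
            "one_to_one_cells": int((matrix == "1to1").to_numpy().sum()),
        }

    if config.expression is not None:
        expr = syndata.generate_expression(config.expression)
        kind = {p: k for p, k in expr.config.platforms}
        conds = []
        for pname, mat in expr.matrices.items():
            sub = expr.sample_map[expr.sample_map["platform"] == pname]
            conds.append(
                (
                    pname,
                    atlas_mod.average_replicates(mat, sub),
                )
            )
        values = pd.concat([c for _, c in conds], axis=1)
        atl = atlas_mod.ExpressionAtlas(
            values=values,
            platform={c: p for p, tab in conds for c in tab.columns},
            kind={c: kind[p] for p, tab in conds for c in tab.columns},
            po=expr.condition_po,
        )
        atl.values.to_csv(outdir / "atlas.tsv", sep="\t")
        _, status = atlas_mod.call_expression(atl)
        status.to_frame("status").to_csv(outdir / "atlas_status.tsv", sep="\t")
        smoothed = atlas_mod.smooth_background(atl)
        collapsed = atlas_mod.collapse_redundant_conditions(smoothed)
        result = atlas_mod.group_coexpressed(collapsed)
        with open(outdir / "coexpr_groups.tsv", "w") as fh:
            fh.write("gene\tgroup\n")
            for gene, grp in sorted(result.group_of().items()):
                fh.write(f"{gene}\t{grp}\n")
        (outdir / "coexpr_dendrogram.nwk").write_text(atlas_mod.dendrogram_newick(result) + "\n")
        manifest["stages"]["atlas"] = {
            "conditions": int(values.shape[1]),
            "collapsed_conditions": int(collapsed.values.shape[1]),
            "groups": len(result.groups),
        }

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(catalog=catalog, regions=regions, manifest=manifest, outdir=outdir, truth=syn.truth)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


# ---------------------------------------------------------------------------
# catalog summaries


def summarize_catalog(catalog: pd.DataFrame) -> dict:
    """Exact counts over a catalog table.

    Expects at least ``locus_id`` and ``chromosome`` columns; counts loci,
    distinct numbered chromosomes, unplaced loci (chr00/chrUn) and, when the
    columns exist, per-subclass and new-gene counts.
    """
    if catalog.empty:
        raise ValueError("catalog is empty")
    chroms = catalog["chromosome"].astype(str)
    unplaced_mask = chroms.str.lower().isin(UNPLACED_CHROMOSOMES)
    numbered = sorted(set(chroms[~unplaced_mask]))
    summary = {
        "n_loci": int(len(catalog)),
        "distinct_numbered_chromosomes": len(numbered),
        "numbered_chromosomes": numbered,
        "n_unplaced": int(unplaced_mask.sum()),
        "per_chromosome": chroms.value_counts().to_dict(),
    }
    if "subclass" in catalog.columns:
        summary["per_subclass"] = catalog["subclass"].value_counts().to_dict()
    if "new_gene" in catalog.columns:
        summary["n_new_genes"] = int(catalog["new_gene"].sum())
    return summary


def map_paralog_segments(catalog: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Subfamilies with members in both halves of a paralogous segment pair.

    ``segments`` columns: pair_id, chrom_a, start_a, end_a, chrom_b, start_b,
    end_b (1 bp overlap of the gene span counts as membership).  The catalog
    needs chromosome/start/end plus a ``subfamily`` column.
    """
    required = {"pair_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"}
    if not required <= set(segments.columns):
        raise ValueError(f"segment table missing columns {sorted(required - set(segments.columns))}")
    rows = []
    for seg in segments.itertuples(index=False):
        in_a = catalog[
            (catalog["chromosome"] == seg.chrom_a)
            & (catalog["start"] < seg.end_a)
            & (catalog["end"] > seg.start_a)
        ]
        in_b = catalog[
            (catalog["chromosome"] == seg.chrom_b)
            & (catalog["start"] < seg.end_b)
            & (catalog["end"] > seg.start_b)
        ]
        for fam in sorted(set(in_a["subfamily"]) & set(in_b["subfamily"])):
            rows.append(
                {
                    "subfamily": fam,
                    "pair_id": seg.pair_id,
                    "genes_a": ",".join(sorted(in_a[in_a["subfamily"] == fam]["locus_id"])),
                    "genes_b": ",".join(sorted(in_b[in_b["subfamily"] == fam]["locus_id"])),
                }
            )
    return pd.DataFrame(rows, columns=["subfamily", "pair_id", "genes_a", "genes_b"])
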