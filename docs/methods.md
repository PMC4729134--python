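# Methods

This note documents the models and procedures implemented in famscan, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the published workflow left the design
open.

## Candidate-region discovery

The discovery stage is a six-frame translated similarity search of family
seed proteins against a genome, built as classic seed-and-extend: exact
4-residue word hits (rolling base-23 hash) are extended without gaps under
BLOSUM62 with an X-drop of 20, one extension per (query, diagonal) span.
Extension is ungapped because the search targets near-verbatim family copies
and pseudogenes, not spliced alignments; gapped scoring (affine 11/1) is used
in the protein–protein kernel of the orthology stage instead.  Every HSP
carries raw score S, bit score `(λS − ln K)/ln 2` and expectation
`E = K·m·n·e^(−λS)` with the gapped BLOSUM62 defaults λ = 0.267,
K = 0.041, where m is the query length and n the total number of translated
residues searched (all six frames, all chromosomes).  HSPs with E above the
discovery cutoff (default 1e−3) are dropped.

A *candidate region* is a maximal cluster of same-chromosome, same-strand
HSPs whose genomic intervals lie within 10 kb of each other.  The 10-kb merge
radius matches the span of a typical family locus; the original survey never
formalized its region definition, so this is an explicit operationalization,
not a claim about the published rule.

## Triage

The family-domain profile is a per-column log-odds PSSM over the seed
alignment: columns with ≥ 50 % residue occupancy score
`log2((f + p·bg)/((1 + p)·bg))` with uniform background bg = 1/20 and
pseudocount weight p = 0.1 (scores clamped finite at −30 bits for
unobserved residues when p = 0).  The detection threshold defaults to 0.6×
the consensus self-score (the sum of per-column maxima).

Each region (padded by 60 bp) is translated in six frames and the profile is
matched by the best ungapped local alignment over all diagonals (per-diagonal
maximum-sum segment).  Ambiguous residues (X, from N-containing codons)
contribute 0 bits and stop codons −6 bits, so a match can bridge short gaps
and single premature stops while recording them.  Triage then proceeds:

* best match below threshold in all frames → `no_domain`;
* a stop codon inside the matched window, or inside the translated footprint
  of a supporting HSP (ignoring 10 residues at each footprint edge, which
  guards against X-drop read-through of the natural terminator) →
  `nonfunctional` with evidence `internal_stop`;
* matched standard-residue coverage below 80 % of the profile length →
  `nonfunctional` with evidence `truncation`;
* if the matched window overlaps a run of ≥ 20 'N' bases, the region is
  classified `possibly_assembly` (a refinement of nonfunctional) regardless of
  coverage, because the translation across the gap is ambiguous and the locus
  cannot be confirmed functional.

The 80 % truncation cutoff is a design choice: the source workflow says only
"truncation", and 80 % keeps near-complete domains functional while cleanly
separating the generator's planted truncations (75 % of the domain).

## Gene models

Models store exon/CDS intervals 0-based half-open in transcript orientation;
GFF3 is read and written 1-based inclusive and round-trips identically.
Translation uses the standard genetic code, strips one terminal stop, and
flags internal stops, missing start codons and CDS length.  Structure
comparison calls a model `confirmed` only on identical exon and CDS interval
sets; otherwise `changed_exons` counts modified exons once (overlap-paired
symmetric difference) plus insertions and deletions.  Exon validation against
a per-base depth track uses the *median* depth per exon (robust to edge
tapering; the source states no statistic) with a default minimum of 5;
missing track regions count as depth 0 with a warning.

## Orthology

All cross-species pairs are scored with local Smith–Waterman alignment
(Bio.Align.PairwiseAligner, BLOSUM62, gap open/extend 11/1) and
Karlin–Altschul expectations on m·n of the pair.  Retention requires
E < 1e−20 *and* percent identity over the aligned region > 40, both strict —
"homology" is read as identity; positives-based similarity would be the main
alternative reading.  One-to-one orthologs are reciprocal best hits with the
tie-break chain bit score → E-value → lexicographic gene id (the published
definition is silent on ties; determinism requires fixing one).  Genes with
retained pairs but no reciprocal best are homolog-only; all others are `none`.

Note a structural fact exploited by the tests: within any retained homolog
family the globally best cross-species pair is necessarily reciprocal (scores
are symmetric), so paralog expansions always produce one incidental
one-to-one pair per family.  Exact planted-map recovery is therefore assessed
on configurations of one-to-one groups plus species-specific genes, whose
identity bands (> 60 % within groups, < 30 % elsewhere) are separated by well
over 20 points.

## Phylogeny

The built-in aligner is progressive: 3-mer distance, average-linkage guide
tree, profile–profile global alignment (Gotoh affine 11/1, expected BLOSUM62
column score).  Any external aligner can be substituted through the provider
interface.  Columns with site coverage strictly below 0.95 are removed before
tree building; the filter is idempotent.

Pairwise distances are maximum-likelihood estimates under the JTT empirical
model: the published exchangeabilities and frequencies define a reversible
rate matrix normalized to one expected substitution per site; P(t) = e^{Qt}
comes from a symmetric eigendecomposition and the per-pair likelihood
`Σ C_ab log(π_a P_ab(t))` is maximized over t ∈ [1e−6, 10] by bounded Brent
search.  Distances agree with R phangorn's `dist.ml(model="JTT")` to the
optimizer tolerance (~1e−4).  NJ trees (dendropy) are built on the original
alignment's distances and on 100 bootstrap column resamples; branch support
is the replicate frequency of each partition, and the reported tree is the
majority-rule-extended consensus assembled greedily from partitions in
frequency order.  NJ over JTT distances stands in for full
maximum-likelihood topology search: it is deterministic and desk-scale, and
clade recovery — not topology identity with any published tree — is the
supported claim.  Branches with support strictly below 30 collapse to
polytomies (leaf set unchanged).

Clade assignment is root-free: for every unlabeled leaf, over all branches of
the collapsed tree consider the partition side containing the leaf and at
least one anchor; the smallest such side wins, and its label is assigned only
if its anchors carry a single label, otherwise the leaf is `unplaced`.

## Nomenclature

Rule precedence per locus: conserved prior symbol (dot-number style
normalized to serial letters) → species prefix + Arabidopsis ortholog symbol
→ subfamily + serial letter (MIKC^C) → subclass prefix (`MADSD`, `MADS1A`,
`MADS1G`) + clade digit + serial letter.  Serial letters run a–z, aa, ab …
and are attributed in genomic order (chromosome, then start) instead of the
published "attributed randomly": determinism is worth the departure, and any
fixed permutation is as arbitrary as a random one.  Symbols are unique per
catalog; duplicated prior symbols raise a conflict listing the loci.

## Expression atlas

Replicates of a condition are averaged arithmetically.  Calls per cell:
log2 array intensity > 8 `expressed` (strict), in [5, 8] `detected`, < 5
`background`; read counts ≥ 10 `expressed` (inclusive), 1–9 `detected`, 0
`background`.  The array background bound reuses the log2 = 5 smoothing
floor — the published figure colors background but never states its bound,
and tying it to the stated floor is the least arbitrary choice.  Gene status
is `gene` / `putative` / `hypothetical` for any-expressed / only-detected /
neither.  PO attribution is the union of PO terms of expressed conditions.

For co-expression, array values are floored at log2 = 5 and counts enter as
`log2(reads + 1)` with the same floor (the source clusters mixed platforms on
log2 values without stating the count transform).  Both clustering tiers use
Pearson distance d = 1 − r with average linkage: conditions with d < 0.05
are first averaged into pseudo-conditions within their platform, then genes
with d < 0.15 form groups.  Both thresholds are strict, so the flat cut is
applied at t·(1 − 1e−9) (scipy merges at ≤ t).  Zero-variance profiles have
no defined correlation and are assigned distance 2 to everything, forcing
singletons.

## Synthetic data

The generators emulate the study's inputs with known truth; all randomness
flows from one integer seed through a single numpy Generator, so outputs are
bit-identical across reruns.

* **Genome.** Background DNA is i.i.d. uniform ACGT — the simplest null for
  a similarity scan, with no repeats, GC structure, introns or codon bias.
  Planted genes are single-exon CDSs of a family protein (59-aa MADS-like
  domain consensus + 120 random tail residues) with 2 % per-residue
  substitutions, back-translated with uniformly random synonymous codons and
  spaced ≥ 25 kb apart.  Pseudogene classes: one codon substituted to TAA at
  least 30 codons from either CDS end (internal stop — the domain stays
  detectable while translation fails); the domain cut to 75 % (truncation —
  below the 80 % coverage rule but far above the 0.6 detection threshold);
  24 bp of the central domain replaced by 'N' (gap disruption — satisfies the
  ≥ 20 bp rule while leaving the domain clearly detectable); a randomized
  domain with < 25 % consensus identity on a homologous tail (decoy, the
  "homology but no domain" class).  These widths were chosen once so that
  each class sits unambiguously inside its intended triage band at any seed.
* **Proteomes.** One-to-one groups descend from shared ancestors (10 %
  per-copy substitution ⇒ pairwise identity ≈ 80 %, always > 60 %);
  homolog-only families expand within species; species-specific genes are
  independent random proteins (< 30 % identity to anything).
* **Clade sets.** A random root protein diverges 35 % into clade ancestors
  and 5 % within clades, with labeled anchor leaves per clade.
* **Expression.** Each platform (array-type log2 in [5, 12], count-type
  `round(2^x − 1)`) gets per-condition latent profiles shared within planted
  co-expression groups plus Gaussian noise (default SD 0.2); replicates map
  3 per condition; conditions cycle through a small Plant Ontology
  vocabulary.

Because of these simplifications, passing tests demonstrate the correctness
of the algorithms and their thresholds, not performance on real genomes:
real discovery must contend with introns, repeat-induced false seeds,
diverged paralogs near the detection threshold and platform batch effects,
none of which the null background generates.

## Problem sizes

The shipped tests and the acceptance script run the discovery stage on a
2-Mb genome with 20 planted genes, orthology on 20 × 20-gene proteomes,
trees on 4–18 leaves × 100 bootstrap replicates, and atlases of ~10 genes ×
60 samples; the whole suite completes in well under a minute of compute.
These sizes exercise every code path while keeping runs reproducible on a
single CPU.

## Known limitations

* Ungapped HSP extension cannot follow frameshifted or spliced family copies;
  a spliced gene would surface as several regions on one strand.
* The triage never re-opens merged regions: two family loci within 10 kb on
  one strand would be triaged as a single region.
* The consensus tree carries supports but no branch lengths; clade
  assignment is topological only.
* The nomenclature catalog assumes subclass and clade calls are already
  settled; it does not revisit them from the tree.
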