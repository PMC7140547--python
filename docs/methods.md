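# Methods

## The procedure

`dbconcord` treats a reference database as a *manifest*: one record per
reference (assembly), each with an accession, an NCBI taxID, and either
a list of sequences — (id, length in bp, role ∈ {chromosome, contig,
scaffold}) — or a declared NCBI assembly level.  The analysis has four
stages, each a module:

1. **Taxonomy** (`taxonomy`).  A taxdump snapshot (nodes.dmp /
   names.dmp / merged.dmp / delnodes.dmp, pipe-delimited dialect) is
   loaded into a validated node graph.  An input taxID resolves through
   the merged map transitively (chains `a→b→c` reach the terminus; a
   cycle in the map is a load-time error) to one of four statuses:
   found, merged, deleted, unknown.  Rank projection walks parent
   pointers from the resolved node (inclusive) toward the root and
   returns the first node whose rank matches the request, comparing
   rank labels case-insensitively after trimming because dump files are
   lowercase while user manifests may not be.  A node below species
   whose lineage contains no species node is representable; its
   exclusion happens during harmonization, not here.

2. **Harmonization** (`concordance.project_to_rank`).  Every record
   lands in exactly one of: the database's taxon set at the requested
   rank, or an exclusion tagged `unknown_taxid`, `deleted_taxid`, or
   `no_ancestor_at_rank`.  Duplicates collapse under set semantics, so
   a species and its strains count once.  Strain-level concordance is
   not computed at all: databases disagree on whether an entry is a
   strain or an unranked isolate, so no common strain coordinate
   exists — the rank floor of the analysis is species.

3. **Overlap partition** (`concordance.venn_partition`).  Each element
   of the union is assigned to the cell keyed by the exact subset of
   databases containing it.  Cell keys use the canonical input order of
   the databases, making reports byte-deterministic.  A taxon excluded
   in one database but present in another enters the union through the
   including databases only.  Exactly-k counts, per-database coverage
   of the union, and the all-N consensus derive from the cells.
   Coverage is kept both unrounded and as the nearest-integer percent,
   since the field reports integers.

4. **Composition** (`composition`).  Per-sequence roles decide the
   completeness class when present (all chromosomes → complete, none →
   fragmented, both → mixed); otherwise the declared assembly level
   maps as Complete Genome → complete, Chromosome → mixed,
   Scaffold/Contig → fragmented ("Chromosome" means at least one
   assembled chromosome, with the rest of the genome typically in
   fragments).  Scaffolds are grouped with contigs everywhere —
   fragmented assemblies are treated as sets of contigs without
   separating the two — and lengths are raw residue counts; internal
   runs of N are not detected or subtracted.  Length statistics pool
   the contig/scaffold sequences of fragmented and mixed references;
   chromosome sequences never enter.  Percentages are per reference by
   default; passing a taxonomy aggregates per taxon instead (a taxon is
   complete if any of its references is, else mixed if any is mixed),
   for the per-species reading of composition.  The
   `complete_only_projection` variant restricts harmonization to
   complete references, giving the consensus-of-complete-genomes
   analysis.

## Synthetic data: what it emulates, what it does not

The generator (`synthetic`) plants the exact quantities the pipeline
estimates, then lets tests demand their recovery:

- a genus → species → strain taxonomy emitted in the exact taxdump
  dialect (default 48 genera, species per genus ~ 1 + Poisson(3),
  strains per species ~ Poisson(1));
- N catalogues whose species-level overlap partition is planted either
  as a full cell-count vector or as an exactly-k vector with random
  cell assignment (default: 4 databases, exactly-k {4:5, 3:18, 2:19,
  1:99} — the shape of the published four-way fungal species partition
  at one-tenth scale);
- per-record completeness drawn from planted fractions (default 0.14
  complete / 0.81 fragmented / 0.05 mixed, the fungal range);
- contig counts ~ 1 + Poisson(19) per fragmented record, lengths
  lognormal with log-mean ln(5·10⁵) − 0.5 and log-sd 1.0, i.e. mean
  exp(μ + σ²/2) = 500 kbp, the order of the published fungal contig
  means; 10% of fragment sequences are labelled scaffold;
- two realism features that must be invisible to a correct pipeline:
  records may cite a strain child instead of its species
  (`strain_emission_fraction`), and species ids may be redirected
  through merged.dmp aliases (`merged_fraction`).  Setting
  `strain_rank="no rank"` instead attaches the strain nodes directly to
  the genus, reproducing the unranked-isolate situation in which a
  record has no species ancestor and must be excluded.

Randomness is split into independent named streams
(taxonomy/assignment/composition/emission/merged/lengths) spawned from
one seed, so toggling strain emission or merged aliasing perturbs no
other draw — the invariance tests compare partitions for *equality*,
not approximately.  Within a stream, draws are ordered databases →
records → sequences, making all outputs byte-reproducible.

What passing these tests shows: the plumbing is exact — resolution,
projection, partitioning and classification introduce zero distortion,
and the estimators are unbiased at the planted sampling noise.  What it
does not show: real catalogues have taxID annotation errors,
assembly-level metadata that disagrees with the deposited sequences,
and length distributions far heavier-tailed and more multimodal than a
single lognormal; recovery on synthetic data bounds software error, not
data error.

## Numerical and design choices

- Percentages use exact floating arithmetic and sum to 100 within
  rounding; reported integer percents use banker's-free `round()`.
- Histograms default to 50 equal-width bins from 0 to the observed
  maximum (configurable); a single observation yields one occupied bin.
- Degenerate inputs fail loudly: empty manifests, unions of size zero,
  manifests with no contig/scaffold sequences, and all-unclassifiable
  manifests raise rather than returning NaNs.
- Tie-breaks: FASTA role rules apply in order, first keyword match
  wins, fall-through default is contig (most microbial references are
  fragmented, so the conservative default errs toward fragmented).
- Record-level roles take precedence over a declared assembly level
  when both are present: observed sequence structure beats metadata.
- Accessions compare case-sensitively; the same accession may appear in
  two different manifests (they are different databases) but not twice
  in one.

## Problem sizes used in tests and the acceptance script

The published-arithmetic check runs at full published scale (42,337
bacterial species) since partitioning is linear in the union.  The
synthetic recovery study uses 3 catalogues, a planted exactly-k vector
{3:400, 2:600, 1:1000} (union 2000 species, ~1100 references per
catalogue, ~11,000 contigs in the profiled catalogue), sized so that the
binomial 99% interval at n≈1100 and the ±3-standard-error band at
n≈11,000 are tight enough to detect a misrouted class or a wrong length
model while the whole run stays in seconds.  The brute-force oracle
comparison uses 100 instances with N ≤ 5 and unions up to 500.

## Known limitations

- No strain-level comparison, by design (see above).
- Sequence content is ignored except for optional random-ACGT FASTA
  emission; references sharing a taxID are never compared by identity.
- The taxdump snapshot is the caller's responsibility; results are only
  comparable across databases harmonized against the same snapshot.
- Assembly-quality metrics beyond the trichotomy (N50, BUSCO) are out
  of scope.
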