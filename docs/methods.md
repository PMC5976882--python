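# Methods

This note documents the models, algorithms and numerical choices behind
each `maglink` stage, what the synthetic-data generator does and does
not emulate, and the problem sizes the shipped tests and acceptance
script use.

## Synthetic communities

The generator produces communities whose every downstream quantity is
analytically known, so the analysis stages can be validated without
external data.

**Genomes and divergence.** Genomes are i.i.d. base sequences with a
configurable GC fraction (P(G)=P(C)=gc/2). Divergence is
substitution-only: `mutate_genome(parent, d, seed)` substitutes
*exactly* `round(d·L)` positions chosen without replacement, each to a
uniformly random different base. Two consequences drive the test
design: the true nucleotide identity of a parent/mutant pair is
`100·(1−d)` with no sampling noise, and sequences never change length.
Indels, rearrangements and horizontal transfer are not modelled; the
ANI stage handles gaps (the aligner is affine-gap), but its calibration
guarantees are stated for the substitution-only regime.

**Community structure.** Each population descends from its own
ancestor; ancestors are mutants of one shared root at
`between_divergence`, members are mutants of their ancestor at
`within_divergence`. Two members of one population then differ at
≈ `2·w·(1−w)` (e.g. ANI ≈ 98 at w = 0.01) and members of different
populations at ≈ `2·b` plus the within terms (ANI ≈ 80 at b = 0.10) —
comfortably either side of the 97% population cutoff whenever
`b ≫ w`. Defaults: 3 populations × 2 members, w = 0.01, b = 0.10,
20 kb genomes.

**Pathway planting.** `pathway_truth` maps (population, metabolite) to
presence. A planted prototroph receives every gene family of every
step; a planted auxotroph receives the pathway minus *all alternatives
of one randomly chosen step* — deleting a single family would leave a
multi-alternative step satisfied and the planted absence would not be
an absence. The shipped panel uses single-family steps (plus one
two-alternative step in the sulfur pathway), with placeholder family
ids named after canonical bacterial genes; curating real KO-level
definitions is the user's job.

**Reads.** Per-genome read counts are multinomial in the planted
proportions; start positions are uniform; each base is substituted
with probability `error_rate` (default 0.005). Reads are forward-strand
and fixed-length; quality profiles, indel errors, chimeras and
paired-end structure are out of scope, so read-level results say
nothing about mapper behaviour on real error profiles.

**Time series.** Latent Gaussian vectors are equicorrelated at
`block_rho` within a planted block and independent across blocks
(a Gaussian copula); marginals are log-normal (σ = 1, per-taxon
log-means drawn N(0,1)); each sample row is closed to relative
abundances. Closure divides all taxa by a shared sample sum, which
attenuates rank correlations when the simulated taxa dominate the
composition. As in real lake metagenomes, where binned MAGs recruit
only a minor share of reads, each sample carries a constant unbinned
remainder (`background_factor = 9` times the expected summed biomass
of the simulated taxa, reported in the `unbinned` column). The closure
divisor is then nearly constant and the planted Spearman structure
survives closure to good approximation (empirically, median
|ρ̂ − 0.8| ≈ 0.05 at n = 45). Samples are labelled with weekly
ISO-8601 dates. Seasonal trends, autocorrelation and zero-inflation
are not modelled; partner-recovery results therefore certify the
correlation machinery, not its behaviour on sparse, autocorrelated
real series.

All randomness flows through one explicit integer seed per operation;
the pipeline derives per-stage seeds from the master seed with numpy's
`SeedSequence` and records them in the run manifest.

## Read recruitment

Reads are competitively assigned to the genome sharing the most
canonical k-mers (k = 21 by default; canonical = lexicographic min of
forward and reverse-complement encodings, so strand is irrelevant).
Ties for the maximum and zero-hit reads are counted as unassigned and
excluded from the denominator — the simplest competitive-assignment
contract; fractional splitting is deliberately not the default.
Recruitment fractions are assigned counts over the assigned total; the
major-member rule keeps MAGs recruiting *strictly more than* 1%
(a MAG at exactly 1% is excluded), and the contig filter keeps contigs
*strictly longer than* 1,000 bp. At ≤85% pairwise ANI between
candidate genomes, a 21-mer survives in a diverged genome with
probability ≈ 0.85²¹ ≈ 3%, so misassignment is negligible and
estimated fractions track the multinomial truth within sampling error.

## ANI and discrete populations

The ANI method follows the classical fragment convention: the query is
cut into consecutive non-overlapping 1,020-bp fragments (the trailing
partial fragment is dropped); each fragment is aligned to the
reference; fragments aligning at identity ≥ 0.30 over ≥ 0.70 of their
length are retained; ANI(query→reference) is the mean identity of
retained fragments and the aligned fraction is the share retained.
Pair values are the mean of the two directions (the defined one if only
one direction aligns, undefined/NA otherwise).

**Alignment.** Candidate diagonals come from shared 15-mers (both
strands); up to three diagonal candidates, separated by more than the
band width, are extended with a banded affine Smith–Waterman
(band 32; match +1, mismatch −1, gap open −5, gap extend −2 — a gap of
length g costs 5 + 2g). Among co-optimal local alignments the aligner
deterministically prefers higher score, then more matches, then more
columns, then larger query span; the four objectives are packed into a
single int64 per DP cell, so the optimum is a plain `max` and the
reported identity (matches/columns) is a well-defined quantity. The
test suite holds this against an exhaustive full-matrix
Smith–Waterman with the same convention: on ≤2-kb pairs the two agree
exactly. For substitution-only pairs at L = 100 kb the estimated ANI
sits within ±0.05 of the analytic `100·(1−d)` for d ≤ 0.10 (the
guarantee is stated as ±0.3). Two unrelated random 100-kb sequences
share too few isolated 15-mers to survive extension and retention, so
their ANI is undefined (NA), which every threshold treats as
below-cutoff.

**Clustering.** Discrete populations are the connected components of
the graph with an edge wherever ANI ≥ 97% — single linkage, because
"clustered together" grouping is transitive. The comparison is
inclusive (≥) by default; a strict (>) operator is available and logs
a warning, since the two conventions disagree only on pairs exactly at
the cutoff. Population ids are the lexicographically smallest member
id, making the output order-independent. Cross-environment matching
reports, per culture genome, the best environment hit and a status:
`distinct` below 90% (or undefined), `matched` at ≥97%, `ambiguous`
between.

## Auxotrophy and complementarity

A pathway definition is an ordered list of steps, each a set of
alternative gene families (OR semantics). Completeness is the fraction
of steps with at least one alternative annotated; "full pathway" means
completeness = 1.0 exactly, and that is the prototroph criterion by
default (a relaxed threshold exists for noisy annotations but is not
the default). Function markers (catalase-peroxidase, sulfate
reduction) are present iff the annotation intersects the marker's
family set; reduced sulfur is deliberately modelled both as a
multi-step assimilatory pathway and as a marker, since a provider may
supply either the pathway products (sulfide, cysteine) or the redox
capability itself.

Per metabolite and culture, the complementarity graph has an edge from
every prototroph to every auxotroph — so |edges| =
#prototrophs × #auxotrophs, verified by enumeration over all 2ⁿ
presence patterns for n ≤ 5. A culture with no prototroph is `omitted`
(no internal donor exists), which coincides exactly with the
sufficiency report's `externally-required` status. By default the
graphs are built over major members only, mirroring how such diagrams
are drawn for a culture's dominant organisms; a flag admits all
members. Partial pathway evidence is carried as a per-node completeness
fraction, never as partial edges — the donor/recipient rule is binary.

## Cooccurrence correlation

Spearman ρ is Pearson correlation on average ranks (scipy's `rankdata`
ties convention), computed for all focal × partner pairs at once.
Significance is a permutation test: the focal rank matrix's sample
order is permuted (one permutation applied to all focal vectors per
draw — the marginal null per pair is unchanged), two-sided exceedance
with add-one correction, `p = (#{|ρ_perm| ≥ |ρ_obs|} + 1)/(B + 1)`,
B = 999 by default. Benjamini–Hochberg adjustment runs over all finite
p-values of the matrix jointly (statsmodels implementation, oracle-
checked against a hand-written step-up rule). Constant vectors have
undefined rank correlation and propagate as NA, excluded from BH. The
whole significance layer — including the default partner criterion
ρ ≥ 0.5, q ≤ 0.05, positive sign — is artifact policy, configurable
and not a claim about any published dataset.

Normalisation for count tables divides by genome length (longer
genomes recruit more reads at equal organism abundance), then closes
each sample row; all-zero samples are dropped with a warning. Display
order sorts rows and columns independently by average-linkage
hierarchical clustering of the (1 − ρ) matrix (missing entries imputed
at distance 2, i.e. ρ = −1; row/row dissimilarity is the Euclidean
distance between rows of that matrix). Ids are sorted before
clustering, so the ordering is invariant to input order. The
promiscuity summary counts significant positive partners and their
distinct taxonomy groups per focal MAG; a focal MAG is promiscuous
when its partners span ≥2 groups, at least one differing from its own.

## Pangenome

The core genome is the set of families present in ≥ `core_fraction`
of genomes (default 1.0, the strict core — the usual convention when
the softness of a published core is unspecified). The flexible share
is `100·(1 − core_size/mean_genome_size)` with the mean taken as the
arithmetic mean of per-genome family counts when not supplied. The
module consumes gene-family identifiers as given; ortholog clustering
is out of scope.

## Pipeline, formats, determinism

The `run` subcommand executes
simulate → recruit → ani → cluster → pathways → complement → cooccur →
pangenome from one YAML config, validated before any stage runs
(errors name the offending key). All tables are TSV with one header
row and `NA` as the only missing token; genomes and reads are FASTA
(read origins ride in the header after an `origin=` token); graphs are
GraphML; the pathway panel is YAML. Every writer has a reader and the
pair round-trips. The JSON run manifest records the config snapshot,
per-stage seeds, output digests, tool version and timestamps;
re-running with the same config and seed reproduces every stage output
byte-identically (timestamps live only in the manifest).

## Problem sizes used by tests and the acceptance script

Chosen so the full suite exercises every guarantee at meaningful scale
on a single CPU: ANI calibration at L = 100 kb (4 divergences);
DP-oracle equality on 1,020–1,032-bp pairs including a 12-bp gap;
population recovery over 20 seeds at L = 10 kb (3 × 2 genomes);
complementarity enumeration over all 62 patterns (n ≤ 5); recruitment
with 10⁵ 150-bp reads over six 20-kb genomes at planted proportions
{0.5, 0.3, 0.15, 0.04, 0.005, 0.005}; partner recovery at n = 45
samples, block ρ = 0.8 (6 focal, 20 partner taxa, 3 blocks); the null
false-partner rate over 100 seeds × 50 independent partners; and the
demo pipeline run twice for byte-identity.

## Known limitations

- ANI values from fragment schemes are method-dependent; absolute
  values from other tools (whole-genome aligners, sketching methods)
  can differ by a few tenths of a percent, so cross-tool comparisons
  should use one method throughout.
- The k-mer pseudo-mapper is a competitive assigner, not an aligner;
  it is adequate for well-separated genomes (≤85–90% ANI) and makes no
  claims at near-population boundaries, for repeats, or under heavy
  sequencing error.
- Auxotrophy calls inherit all annotation noise; a single missed gene
  call flips a prototroph to auxotroph under the strict rule. The
  completeness threshold exists precisely for that case.
- Correlation is pairwise and compositionality-naive by design;
  SparCC-style compositional corrections and time-lagged analyses are
  out of scope.
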