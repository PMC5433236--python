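# Methods

This note records the models and procedures `quatscreen` implements, the
defaults it ships with and why, the numerical conventions that matter for
reproducibility, and what the synthetic fixtures do and do not emulate.

## Profile models and the genome screen

Protein families (CutC, CntA, their partners CutD/CntB, and rplB) are
represented as profile hidden Markov models built from seed protein
alignments. Model construction, scoring (`hmmsearch`-style local bit
scores) and alignment (`hmmalign`) are delegated to the HMMER3 engine
through pyhmmer; the package's surface is engine-agnostic, and the heuristic
acceleration filters are disabled during scoring so every sequence receives
its exact bit score deterministically. Models are refined by realigning
the seeds to the current model and rebuilding, three cycles by default;
seeds whose score falls below a floor are dropped with a warning. Models
serialize to the HMMER3 text format plus a JSON sidecar (seed ids, refine
cycles).

The screen scores every encoded protein of every genome, keeps the top N
(default 3000; ties broken by genome id and locus for determinism),
collapses identical amino-acid strings to unique proteins (dereplication;
the representative comes from the lexicographically smallest genome id),
and evaluates each unique on:

* **Coverage** — fraction of model match columns occupied after
  `hmmalign`; sequences under 0.8 are set aside as partial.
* **Signature residues** — per-rule check of the residue aligned to a
  stated model column; a deletion at the column fails the rule. The
  bundled rule file carries the carnitine-oxygenase bridging-glutamate
  rule (E at the column homologous to E205); the choline TMA-lyase rule
  set is left to the user because signature columns are specific to the
  user's seed alignment.
* **Phylogenetic distance** — p-distances over shared aligned columns
  (gap-gap columns ignored, residue-vs-gap counted as a difference), a
  neighbor-joining tree, and the cophenetic (path-length) distance of
  every tip to the top-scoring tip. On additive distance matrices NJ path
  lengths reproduce the input exactly, which the tests exploit. Negative
  path lengths (an NJ artifact on non-additive data) are clamped to zero.
* **Synteny** — a partner-gene model is scored against the features on
  the hit's contig; the partner is found iff some other feature reaches
  the partner cutoff within ≤10 intervening locus indices (boundary: 11
  fails). Partner cutoffs are expressed as a fraction of the top partner
  score (defaults 0.5; the published cutD/cntB screens used 51% and 26%).

**Automatic cutoff.** Ranked scores are scanned for the consecutive pair
maximizing the relative drop (s_i − s_{i+1})/s_i, and the cutoff is the
median (mean) of the framing pair. The scan covers interior ranks only:
neither the single top score nor the single bottom score anchors a drop.
The rationale: the drop of interest separates the true family from the
homolog continuum, whereas the relative-drop statistic diverges as scores
approach zero, so the last ranked pair would otherwise dominate whenever
the candidate list extends into noise. Equal scores throughout raise an
error and require a manual cutoff.

**Assembly.** Targets are the above-cutoff uniques; with the optional
phylogeny filter, an above-cutoff candidate is excluded only when its
cophenetic distance to the top sequence exceeds a quantile (default 0.95)
of the target distances *and* its synteny check failed — both conditions
are logged. This mirrors the way a small phylogenetically distant,
non-syntenic group can sit above a score cutoff and still not belong to
the family. Multi-copy genomes are reported (copy number per genome,
genomes with more than one non-identical copy flagged), never filtered.
Outgroups are the top-scoring below-cutoff uniques — 300 by unique protein
(amplicon reference panel) and 500 by unique nucleotide sequence
(metagenome reference set), both configurable. Target references receive
90% complete-linkage nucleotide cluster labels computed on their
codon-expanded model alignment; taxonomy is user-supplied metadata.

## Primer arithmetic

Degeneracy is the product over positions of IUPAC set sizes, with inosine
contributing a factor of one (it is a single synthesized base that pairs
universally; in matching it accepts any template base at zero mismatches).
Template ambiguity codes match a primer symbol when the two base sets
intersect. In-silico PCR pairs forward sites with downstream
reverse-complement reverse sites, reports the inter-primer sequence
(product sizes exclude both primers), and caps products at 5000 nt to
avoid genome-spanning artifacts. Coverage is the fraction of unique
references amplified with the stated mismatch allowance (default one per
primer, both template strands scanned). Primer trimming requires a
forward site at the 5' end and a reverse site at the 3' end of a merged
read; anything else is discarded and tallied, and retained inserts carry
no residual primer site.

## Frameshift-aware correction

Each merged amplicon is aligned against every protein in the target +
outgroup panel with a dynamic program over three states (emission,
read-codon insertion, reference-residue deletion). Emission columns
consume a full codon (scored by BLOSUM62 against the reference residue,
stops scored as the matrix's `*` row) or a frameshifted 2-nt / 4-nt codon
at a fixed penalty. Defaults: gap open/extend −11/−1, frameshift −12 per
event, bacterial genetic code; all configurable. The alignment is
**global in the read and local in the reference**: a corrector must
return the entire corrected read, and letting the aligner trim
read ends around near-terminal indels would silently delete sequence and
inflate downstream pairwise distances. Scores ≤ 0 are treated as failed
alignments.

Repair: a 2-nt column is padded with the base whose completed codon
scores best against the aligned reference residue; a 4-nt column drops
the base whose remaining codon scores best; ties go to the
lexicographically smallest codon, making corrections deterministic. The
best-scoring reference wins (ties: higher protein identity, then
lexicographic reference id). Protein identity is matches over all
alignment columns. A read is retained iff its winner is a target
reference and its corrected frame is stop-free; rejections are tallied
per sample as non-target / stop-codon / failed-alignment, and samples
rejecting more than half their reads are flagged for review.

## Clustering, rarefaction, diversity

Amplicons are clustered at nucleotide identity cutoffs (default 0.99,
0.98, 0.95, 0.90) with **complete linkage**: every within-cluster pair
meets the cutoff, and remaining cluster pairs cannot merge. The merge
order is deterministic (ascending complete-linkage distance, ties by
smallest member ids), which is why the agglomeration is implemented in
the package rather than through a library whose tie behavior is
unspecified. Distances ignore gap-gap columns and count residue-vs-gap
as a difference.

Each amplicon's codon row is obtained by composing its correction
alignment (read → closest reference) with the reference panel's model
alignment (reference residue → model match column), rather than
realigning every corrected read to the model individually. The
composition is deterministic and places reads corrected against the same
reference identically; per-read realignment of error-bearing sequences
was observed to jitter residues between match and insert states, which
complete linkage — sensitive to a single bad pair — amplifies into
spurious satellite clusters. Reference sequences can be co-clustered
(trimmed to the model region) to label clusters by reference membership;
they contribute no counts.

Clusters below 5 total counts are dropped. Rarefaction draws without
replacement (multivariate hypergeometric, numpy Generator seeded by the
user), so equal seeds give bit-identical tables. Diversity summaries
report total clusters, per-sample richness mean ± sd, and
prevalence-category shares (<10%, 10–50%, 50–90%, >90% of samples) of
clusters and of sequences per cutoff. Best-match identity is the maximum
nucleotide identity of each read to any target reference (edlib
alignment; matches over alignment columns).

## Co-occurrence and ordination

Relative cluster abundances per sample feed pairwise Spearman
correlations (midrank ties, t-approximation p-values — the study scale of
~50 samples makes the approximation adequate and permutation unnecessary)
restricted to clusters present in ≥50% of samples; Benjamini-Hochberg
q-values are computed over all tested pairs; an edge requires ρ ≥ 0.5,
p < 0.01 and q < 0.01. Fewer than 4 samples is an error. Constant
abundance vectors are untestable and recorded as ρ=0, p=1. Ordination is
non-metric MDS (scikit-learn, random init, seeded, 16 restarts) on
Bray-Curtis dissimilarities, reporting normalized (Kruskal) stress.

## Metagenome quantification

Reads pass QC when ≥50% of bases reach Q30 (FASTA passes through). The
similarity search is pluggable: the default shells out to blastn
(pre-formatted temporary database, tabular output), whose local
alignments score partially overlapping reads on the overlapping region as
the ≥70 bp / ≥70% identity filters require; an internal k-mer-seeded
edlib engine is available for fully embedded reads, and pre-computed
BLAST outfmt-6 tables are accepted directly. Each read keeps its top hit
(by e-value, ties by bitscore then reference id). Hits to outgroup
references are recorded and excluded from abundance — this is what keeps
diverged non-target homologs from inflating counts.

Abundance arithmetic: per gene g, a_g = retained read count divided by the
median target reference length (bp); rplB likewise; pathway percent =
100 · median(a_g1, a_g2) / a_rplB. A pathway is reported only when both
of its genes have ≥1 retained read and rplB is detected; otherwise
percent is 0 with a detected=false flag. Per-taxon abundances take the
median across the pathway's genes of the length-normalized counts binned
by the top-hit reference's 90% cluster (cutC/D) or genus (cntA/B); the
median is taken **after** length correction (the order is a stated
choice, configurable by computing from the returned per-gene counts).
rplB references are extracted per genome as the best-scoring feature
reaching half the top rplB score; genomes without one are listed.

## Synthetic fixtures

Generators are pure functions of (spec, seed) built on
`numpy.random.default_rng`; truth records serialize to JSON.

* **Genomes**: random-protein CDS backbones (uniform synonymous codon
  usage, random strands, random spacers) with planted target/partner
  cassettes at controlled locus separations (including the 10/11
  boundary), decoy homologs mutated to a stated identity band with every
  signature column scrambled, and an rplB analog in every genome. One
  planted cassette per genome keeps separations exact.
* **Amplicons**: reads drawn from reference regions with per-base
  substitutions and insertions/deletions at stated rates; the truth
  records per-read error events, indel positions, and whether the
  planted errors create a stop codon in the restored frame — the latter
  defines the composition a stop-codon filter is *expected* to retain,
  since stop formation depends on each population's sequence and is not
  a property of the pipeline under test. Constant base qualities
  (quality modeling is not a test target).
* **Metagenomes**: uniform fragmentation of an equal-abundance community
  at a stated coverage; the analytic expectation recorded for a pathway
  carried single-copy by a fraction f of genomes is 100·f.
* **Abundance matrices**: log-normal counts; clusters within a planted
  block are monotone transforms of one latent series (Spearman ρ exactly
  1 on the underlying abundances); prevalence is controlled by zeroing
  clusters in a fraction of samples.

What the fixtures do **not** emulate: real error-rate heterogeneity and
quality-score structure, chimeras, GC/coverage biases, conserved-domain
architecture of real enzymes (family structure is i.i.d. mutation around
a random ancestor), and real taxonomic label structure. Passing the
planted-truth suites therefore demonstrates the correctness of the
computations under controlled conditions, not field performance on real
gut sequencing data.

## Problem sizes and determinism

The test suite runs the full database screen on 12-genome fixtures with
57 planted candidates (20 seeds), the frameshift oracle on ~1000
read-reference pairs, clustering oracles on 100 ten-sequence sets,
co-occurrence calibration on 50 fifty-sample matrices, the metagenome
estimator on 20–40-genome communities at 20× coverage (10 seeds per
carrier fraction), and the end-to-end amplicon run on 3 samples × 400
reads over four populations — sizes chosen so each property is measured
with adequate statistical power while the suite stays interactive. All
stochastic stages take explicit integer seeds; reruns with equal seeds
reproduce counts, cluster assignments and output files exactly.

## Known limitations

* The cutoff detector assumes a genuine score gap exists; families
  sampled continuously down to noise need a manual cutoff.
* Frameshift repair restores the reference-preferred codon, so the
  corrected sequence at a frameshift column is reference-informed; with
  dense errors inside a frameshifted codon the repaired residue may
  differ from the original molecule.
* The internal search engine aligns reads as infixes of references and
  therefore undercounts boundary-overlapping reads; it is intended for
  contained-read scenarios, and blastn is the default for quantification.
* Gene-targeted assembly of metagenome reads is out of scope; the
  estimator is read counting against references.
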