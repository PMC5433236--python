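# quatscreen

Tools for quantifying and characterizing the trimethylamine (TMA)-producing
bacteria of the human gut microbiota through their pathway genes.

TMA is produced by gut bacteria from dietary quaternary amines — mainly
choline, via the glycyl-radical choline TMA-lyase CutC and its activator
CutD, and carnitine, via the Rieske-type oxygenase/reductase pair CntA/CntB
— and its host-oxidized form TMAO is associated with atherosclerosis and
cardiovascular disease. TMA producers are a low-abundance, polyphyletic
functional guild, so 16S rRNA profiles cannot resolve them; they have to be
detected through the pathway genes themselves. `quatscreen` implements a
function-targeted workflow for that purpose:

* **Reference-database construction** (`quatscreen.dbbuild`): a
  multi-parametric screen of annotated genomes with profile hidden Markov
  models (built and iteratively refined from seed alignments via pyhmmer),
  combining model similarity, model coverage (≥80%), conserved signature
  residues (e.g. the CntA "bridging" glutamate E205), cophenetic distance
  to the top-scoring sequence on a neighbor-joining tree, and synteny with
  the pathway partner gene (cutD/cntB within ≤10 intervening loci). A
  score cutoff is placed automatically at the largest relative drop of the
  ranked bit scores; everything above it becomes the target reference set,
  and the top-scoring below-cutoff uniques are kept as an outgroup that
  lets downstream classification *reject* near-miss homologs.
* **Degenerate-primer toolkit** (`quatscreen.primers`): IUPAC/inosine
  degeneracy arithmetic, site finding with mismatch allowances, in-silico
  PCR, database coverage, and primer trimming. The published cutC/cntA
  assay primers ship with the package.
* **Functional-amplicon profiling** (`quatscreen.amplicon`): paired-read
  merging (Q25), frameshift-aware translated alignment of each read against
  the target + outgroup protein panel (BLOSUM62, affine gaps, fixed
  frameshift penalty; the dynamic program is global in the read so the
  whole read is repaired), stop-codon and non-target rejection, codon-aware
  complete-linkage clustering at 99/98/95/90% nucleotide identity,
  ≥5-count cluster filtering, seeded rarefaction, diversity and prevalence
  summaries, best-match identity to references, Spearman/Benjamini-Hochberg
  co-occurrence networks (ρ≥0.5, p<0.01, q<0.01, prevalence≥50%) and
  Bray-Curtis NMDS ordination.
* **Metagenome quantification** (`quatscreen.metagenome`): quality filter
  (≥50% of bases ≥Q30), top-hit nucleotide search of shotgun reads against
  target + outgroup references (blastn), 70 bp/70% identity filters, the
  both-genes-of-a-pathway rule, and pathway abundance as the median of the
  two genes' length-normalized counts relative to the length-normalized
  count of the single-copy gene *rplB*, expressed as a percentage of the
  community; reads are binned taxonomically by their top-hit reference's
  90% cluster or genus.
* **Synthetic fixtures** (`quatscreen.simulate`): deterministic generators
  for genomes with planted gene cassettes and decoy homologs, amplicon
  reads with controlled substitution/indel error, metagenomes with known
  carrier fractions, and abundance matrices with planted correlation
  blocks — every generator returns a ground-truth record.

## Worked example

Build a database from synthetic genomes with planted cutC-like cassettes,
then check the published primers against it:

```bash
quatscreen simulate genomes --seed 3 --out fixtures/genomes
quatscreen build-db \
    --genomes fixtures/genomes \
    --seed-aln fixtures/genomes/target_seeds.faa \
    --partner-seed-aln fixtures/genomes/partner_seeds.faa \
    --gene target --top-n 57 --out db
quatscreen primer-check --db db
```

The build step prints

```
database written to db (7 targets, cutoff 317.2)
```

meaning seven unique proteins scored above the automatically placed
bit-score cutoff of 317.2 (the largest relative drop of the ranked scores)
and passed the coverage filter; `db/candidates.tsv` holds the full
per-candidate record (score, coverage, cophenetic distance to the top
sequence, partner-gene synteny and locus separation, signature-residue
flags, target/below-cutoff status). `primer-check` reports, per primer,
the number of concrete oligonucleotides its degenerate sequence encodes —
for the bundled assay primers

```
cutC_F  TTYGCIGGITAYCARCCNTT  degeneracy=32
cutC_R  GNGGYTCIACRCAICCCAT   degeneracy=16
cntA_F  TAYCAYGCITGGRCITTYAARCT  degeneracy=32
cntA_R  RCAGTGRTARCAYTCSAKRTAGTTRTCRAC  degeneracy=512
```

— and the fraction of database references amplified in silico with one
mismatch allowed per primer (zero for this synthetic fixture, whose genes
do not carry the published primer sites; against a real cutC/cntA
database the same computation gives the assay coverage).

Amplicon and metagenome workflows run the same way from the shell
(`quatscreen profile-amplicons`, `quatscreen quantify-metagenome`), or
programmatically through `quatscreen.amplicon.run_amplicon_pipeline` and
`quatscreen.metagenome.quantify_pathway`.

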