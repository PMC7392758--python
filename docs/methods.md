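# Methods

This note documents the models, defaults, and design choices behind
`pseudopan`, in the order the pipeline runs.

## The synthetic strain panel

The generator (`pseudopan.simulate.SimConfig`, `simulate_dataset`) is a
first-class, tested model of a multi-strain pseudogene survey, not a test
fixture. Its defaults are the study conditions for every downstream
claim.

**Genomes and coordinates.** All strain genomes derive from one ancestral
coordinate frame (default 2 chromosomes × 8 Mb) partitioned into 50 kb
blocks. Each non-reference strain inserts 0–300 bp between blocks, so
orthologous loci have strain-specific coordinates while staying aligned
block-wise; elements never span block boundaries, which keeps liftover
exact away from gaps. Liftover maps are emitted for every ordered strain
pair as length-preserving block tables. Alignment failure is modelled as
~2 kb unmapped gaps whose per-strain genome fraction scales with tree
distance from the reference (mean 2% by default, configurable down to 0
for noise-free experiments), so locus-conservation fractions decline
with divergence.

**Strain tree.** Default is a random ultrametric 8-leaf tree, depth 1.0
time units, with one designated outgroup splitting at the root and
ingroup coalescences evenly spaced (±0.015 jitter), guaranteeing internal
branches of at least ~0.1 time units (0.01 substitutions/site at the
default substitution rate, which keeps every branch informative for tree
recovery). A pectinate ("ladder") shape is available for emulating a
panel of progressively more distant relatives; the analysis drivers use
it so divergence-time gradients exist.

**Births.** Processed pseudogenes arise per gene as a Poisson process
with rate proportional to parent expression (log-normal FPKM, weakly
decreasing in paralog count so that large families make few processed
copies per member); duplicated pseudogenes with rate proportional to
1 + paralogs/2. Events on a branch are inherited by every descendant
strain as one ortholog class; a stem branch above the root (1.0 time
units) supplies universally conserved classes. Absolute rates are
auto-calibrated at simulate time so that the expected per-strain record
count hits `expected_pseudogenes_per_strain` (default 1,200, a
scaled-down analogue of real per-strain automatic call counts) at a 4:1
processed:duplicated ratio. Retrotransposition bursts are (age, weight)
pairs; default ages are found by inverting the K2P expected p-distance so
the expected percent identity at each burst equals 92.5 and 97.

**Sequences and disablements.** Pseudogene sequences start as a slice of
the parent gene (coverage drawn in [0.55, 1]) and evolve neutrally under
K2P (κ = 2, 0.1 substitutions/site/time) down the tree, so identity to
the parent encodes birth age and between-strain divergence encodes the
tree. Stop gains, deletions and insertions are separate Poisson
processes (0.001 / 0.0005 / 0.00025 per site per time — the stop >
deletion > insertion ordering); stop gains overwrite a frame-0 codon,
indels are logged without being applied by default so orthologous
sequences stay alignment-free across strains (supergene concatenation
therefore needs no aligner; an `apply_indels` mode exists).

**Annotation channels.** The "manual" channel is truth with 30% per-record
dropout and carries annotation ids; the "auto" channel drops records at a
5% false-negative rate times a transcript-deflation retention
(`exp(-0.15 · distance-to-reference)` · assembly quality 0.95 outside the
reference), adds 5% random-interval false positives, and carries no ids.
Per-strain annotation imprecision extends boundaries by up to
min(12% of length, 120 bp) per end, and 12% of records are truncated by
10–45% in a given strain — the fragmentary calls whose reciprocal overlap
falls below 0.9 and that only the relaxed lower-bound sweep recovers.
Genomic placement is randomised independently of birth age so gaps and
rearrangements hit old and young classes alike.

**Expression, essentiality, tracks.** A configurable fraction of
pseudogenes (default 15%) is transcribed; transcribed records draw FPKM
strictly above the detection cutoff by construction, so the called
fraction is binomial around the configured rate. Essentiality labels are
assigned with P(essential | parent) three times P(essential | non-parent),
normalised to the overall essential fraction (0.25). Haplotype tracks
segment each chromosome into ~20 blocks labelled with subspecies at the
93.4/5.4/0.3-style weights; mappability tracks leave ~5% of each
chromosome unmappable in 2 kb islands.

**What the generator does not model**, hence what green tests do not
show about real data: no real sequence composition or repeat content, no
introgression beyond haplotype labels, no within-strain indel divergence
by default, no chromosome-scale rearrangements (locus changes come only
from alignment gaps), orthologous boundaries that always overlap unless
truncated, and annotation ids that are perfectly consistent where
present.

## Annotation merging

Pairing between channels is one-to-one by maximal overlap (ties: smaller
start coordinate), with ≥ 1 bp same-chromosome overlap required; Level-1
records take the union of the two intervals. Overlap is strand-blind;
strand is recorded but not used for matching. The false-positive filter
keeps records with length in [100, 5000] bp inclusive (the bounds
themselves are kept), percent identity ≥ 40 and query coverage ≥ 0.5 —
the similarity/coverage floors are explicit stand-ins, configurable,
since no canonical values exist. Haplotype assignment merges
same-label overlapping/abutting segments first, then labels each record
by maximal base-pair overlap (ties: lexicographically smaller label).

## Complement estimation

`M(P,i) = N(P,i) / (D(i)·C)` with `D(i) = N(T,i)/N(T,ref)` and
`C = (N(P,cal)/N(P,ref))/(N(T,cal)/N(T,ref))`. Composing the three steps
for the calibration strain returns `N(P,ref)` exactly (tested to 1e-12
relative). A shared pipeline-efficiency factor affecting calibration and
test strains (but not the reference anchor) cancels out of every strain
estimate; the reference's own corrected total is `N(P,ref)/C` by
construction. Estimates are real numbers; a presentation flag rounds
half-to-even. Counts are taken after the false-positive filter by
default (configurable, since the order is a genuinely open choice).

## Unitary calling

All five filters are evaluated for every candidate, so the accepted set
is provably invariant to filter order; a rejected candidate reports the
first failing filter in the canonical order (known pseudogene → parent
orthology → coding/ncRNA overlap → minimum length → conservation of
location). Overlap thresholds are 1 bp throughout. Paralog presence sets
a flag without removal (a strict mode removes flagged candidates, off by
default), and the final human-inspection step is replaced by an emitted
review report of alignment statistics — no silent auto-accept tier.
Candidates whose chromosomes appear in no query-organism annotation
track are rejected as likely belonging to the functional organism's
coordinate space.

## Pangenome

Reciprocal overlap is min(overlap/lifted-length, overlap/native-length).
A match needs reciprocal overlap ≥ 0.9 with ≥ 1 bp raw overlap, same
parent, same biotype, equal annotation ids where both records carry one,
length ratio ≥ 0.5, and exon counts differing by ≤ 1 (the last two are
explicit stand-ins for unstated compatibility notions and are
configurable). Lifted records landing on coding/ncRNA loci are excluded.
Collapse is union-find over the match graph; entries containing two or
more records of one strain are flagged multi-matching but counted once.
In the bound sweep only the locus-overlap threshold moves; at threshold
0 any ≥ 1 bp annotated overlap disqualifies a record from being
strain-specific, making the 0.9 count the upper and the 0 count the
lower bound (monotone by construction, since the match set grows as the
threshold falls).

## Trees and ages

Binary clustering uses Jaccard distance with average linkage (no
canonical method exists for presence/absence strain clustering; this is
the package's choice). Supergenes sample floor(fraction · N) of the
universally conserved classes without replacement at a fixed seed and
concatenate them in reference genomic order, identical in every strain.
TN93 distances use base frequencies pooled from the two sequences,
exclude non-ACGT sites pairwise, and return a configurable saturation
ceiling (default 5.0 for matrix use) when a logarithm argument is
non-positive; the implementation is cross-checked against an independent
counting-formula oracle and against R `ape`'s `dist.dna(model="TN93")`.
Tree inference is canonical neighbour joining (negative branch estimates
clamp to 0 with a warning; rooted afterwards on the stated outgroup) —
a deliberate replacement of likelihood search, since the acceptance
surface is topology recovery on synthetic truth, for which NJ on TN93
distances suffices; it is cross-checked against `skbio.tree.nj`. Age
histograms use 0.5-percent-identity bins; modes are `scipy.signal`
peaks ranked by prominence. The divergence curve is fitted as
`t = a + b·ln(f)` by least squares — the inverse-logarithmic form is an
explicit choice, as no closed form is canonical.

## Transcription and essentiality

Quantification keeps only exon pieces strictly longer than 100 bp after
intersection with the uniquely-mappable track; a pseudogene with no
surviving piece is excluded. All FPKM cutoffs are strict
(FPKM > cutoff). The parent contrast is Mann–Whitney with mid-rank ties
(Welch t available). The essentiality models enter expression as
log(FPKM+1) — the transform is a package choice. The linear probability
model is closed-form OLS; the probit is Fisher-scoring Newton–Raphson
(tolerance 1e-8, 100 iterations max) with perfect separation raised as
an error rather than returned as runaway coefficients, the marginal
effect evaluated as Φ at covariate means with parent status toggled, and
delta-method standard errors for that effect. Both are cross-checked
against StatsModels and, for the probit, against an iterative
grid-refinement likelihood oracle.

## Numerical and scaling choices

Default test/analysis problem sizes (8 strains, 300–400 genes,
1,000–1,500 records per strain, 20-seed replications for tree recovery
and burst detection) were chosen so the full suite and the
reproduction script each complete in minutes on one CPU while leaving
every per-branch signal above the level the recovery properties assume
(≥ 50 informative entries per internal branch for binary clustering,
≥ 50 kb supergenes, branch lengths ≥ 0.01 substitutions/site). All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed-seed runs are byte-identical end to
end, including the pipeline manifest hashes.

## Known limitations

The estimator has no uncertainty quantification. The unitary caller
works on planted scenarios and file inputs, not on raw homology search
output. Locus "changes" in the generator come only from alignment gaps,
not relocations, so the divergence curve's dynamic range is small at
desk scale. Multi-matching pangenome entries do not arise in the default
generator (distinct loci per class); the flag is exercised by unit
fixtures. Bootstrap support values and likelihood-based tree search are
out of scope.
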