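# pseudopan

Pseudogenes — gene copies disabled by stop gains, frameshifts, and decay —
are near-neutral markers of genome remodelling. In a panel of closely
related inbred mouse strains they record when each retrotransposition or
duplication event happened, which lineages inherited it, and how strain
genomes have rearranged since. `pseudopan` is a toolkit for the
computational pipeline behind that kind of multi-strain pseudogene
survey, exercised end-to-end on a synthetic strain panel with known
ground truth:

- **Synthetic data generator** (`pseudopan.simulate`) — pseudogene births
  placed on the branches of a known strain tree (clade-shared classes are
  inherited by every descendant), expression-weighted retrotransposition
  with burst epochs, K2P sequence divergence, disablement accumulation,
  two noisy annotation channels, liftover maps with unmapped gaps,
  expression/essentiality/haplotype/mappability tracks, and a truth table
  for every downstream stage.
- **Annotation merging** (`pseudopan.annotate`) — automatic and
  lifted-manual call channels merged into confidence levels (Level 1
  both, Level 2 manual-only, Level 3 automatic-only; 1 bp minimum
  overlap, union boundaries), a false-positive filter (100 bp–5 kb,
  similarity/coverage floors), and majority-overlap haplotype labels.
- **Complement estimation** (`pseudopan.count_model`) — corrects raw
  automatic counts for transcript-annotation depth via a deflation factor
  `D(i) = N(T,i)/N(T,ref)`, a calibration correction
  `C = (N(P,cal)/N(P,ref)) / (N(T,cal)/N(T,ref))` measured on a strain
  expected to match the reference, and the corrected total
  `M(P,i) = N(P,i) / (D(i)·C)`.
- **Unitary pseudogene calling** (`pseudopan.unitary`) — the cross-organism
  filter cascade (known pseudogenes, parent orthology, coding/ncRNA
  overlap, minimum length, conservation of location) with full per-candidate
  filter traces, plus stop-codon gain-of-function reversion detection.
- **Pangenome construction** (`pseudopan.pangenome`) — all-against-all
  liftover ortholog matching (reciprocal overlap ≥ 0.9, same parent,
  biotype, annotation id, length, structure), union-find collapse into
  pangenome entries, conservation classes (universal / group /
  strain-specific), and upper/lower strain-specific bounds by relaxing
  the locus-overlap cut-off to zero.
- **Phylogenetics** (`pseudopan.phylo`) — strain trees from binary
  presence/absence profiles (Jaccard + average linkage) and from
  per-strain supergenes (concatenated conserved-pseudogene sequences,
  Tamura–Nei 1993 distances, canonical neighbour joining), percent-identity
  age distributions with mode detection, locus-conservation fractions and
  the inverse-logarithmic divergence-time fit `t = a + b·ln(f)`.
- **Transcription & essentiality** (`pseudopan.activity`) — strict FPKM
  cutoffs after uniquely-mappable-exon filtering (> 100 bp), Mann–Whitney
  parent-expression contrasts, paralog-versus-pseudogene-count fits, and
  linear-probability plus Newton–Raphson probit models of gene
  essentiality with parent-status marginal effects.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
8-strain panel (one outgroup; a ladder of progressively more distant
relatives of the reference-like strain) and write tables under
`results/`:

```bash
cd analysis
python 01_simulate_dataset.py
python 02_merge_annotations.py
python 05_build_pangenome.py
python 06_phylogeny.py
```

Output from the run above:

```
confidence-level mix across strains (L1 both / L2 manual-only / L3 auto-only): [0.581, 0.154, 0.265]
3973 pangenome entries from 8144 records (0 multi-matching)
  universal          132  (3.3%)
  group              851  (21.4%)
  strain_specific   2990  (75.3%)
mean strain-specific pseudogenes per strain: upper bound 374 (overlap >= 0.9), lower bound 291 (any overlap disqualifies)
binary presence/absence tree: RF distance to truth = 0
supergene tree: 192 of 385 conserved pseudogenes sampled, 271,851 bp per strain, RF to truth = 0
age-distribution modes (percent identity, by prominence): [96.75, 92.75] -- bursts were placed at [92.5, 97.0]
```

Reading this: both channel agreement levels and the pangenome
conservation mix are non-degenerate; relaxing the 0.9 reciprocal-overlap
cut-off recovers ~80 falsely strain-specific calls per strain (fragmentary
annotations whose orthologs overlap by less than 90%); both tree signals
reconstruct the true strain topology exactly (Robinson–Foulds distance
0); and the two retrotransposition bursts planted at 92.5% and 97%
identity are recovered as histogram modes within half a bin.

The same operations are available from the command line
(`pseudopan simulate|merge|estimate|unitary|pangenome|tree|ages|loci|pipeline`);
`pseudopan pipeline --seed 1 --out run/` executes every stage and writes
a manifest with content hashes, byte-identical across reruns with the
same seed.

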