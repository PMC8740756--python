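# Methods

`sedadna` implements the computational stages of a microstratigraphic
sedimentary ancient-DNA (aDNA) study: resin-impregnated sediment blocks are
micro-drilled on a grid across their cut face, each milligram-scale sample
yields a library of short DNA fragments, and the analysis asks *which*
mammalian taxa left DNA, *whether* that DNA is ancient, *how* it is arranged
spatially on the block face, and — where hominin DNA is present — which
mtDNA lineage and which sex it represents. Because the package ships no
sequencing data, a first-class synthetic-data module generates every input
with a complete truth record, and the test suite measures parameter
recovery against that truth.

## Damage model and authentication

Post-mortem cytosine deamination converts C to U (read as T) preferentially
in the single-stranded overhangs at fragment ends. For single-stranded
library preparations both fragment ends carry the signal on the read
strand. The simulator converts each read-strand C at 0-based distance *d*
from the nearer end with probability

    p(d) = p0 · exp(−λ d),

then applies uniform sequencing error to all bases. Defaults p0 = 0.3,
λ = 0.3, error 10⁻³ — a strongly damaged Pleistocene-like profile with a
realistic decay shape; both are exposed in `SimulationConfig`. Real damage
profiles are not exactly exponential (they reflect overhang-length
distributions), and the simulator makes no attempt at nicking or
double-stranded-prep G→A asymmetry; passing recovery tests therefore show
the estimators are correct for this family of profiles, not that λ has a
biochemical meaning.

Authentication works on per-position terminal C→T frequencies with 95%
binomial confidence intervals (Wilson by default, Clopper–Pearson as an
option; Wilson behaves better at small counts). A fragment set is called
ancient when the *lower* CI bound at position 1 exceeds 10% at **both**
ends — the bound, not the point estimate, is compared, which is what makes
12/100 (12%) fail the test while 30/100 passes. Fragments are reduced to
the *deaminated* subset — a C→T mismatch within the three terminal bases of
either end — before consensus building and nuclear analyses, removing
undamaged present-day contamination at the cost of ~70% of genuinely
ancient fragments. Length/quality filtering keeps fragments with length
≥ 35 and mapping score ≥ 25 (boundaries inclusive).

## Taxonomic assignment

Fragments are assigned against a panel of circular mitogenomes with a
two-rank species→family taxonomy. The aligner is deliberately **ungapped**:
exact 8-mer seeds propose placements on a wrap-margin linearisation of each
circular genome (both orientations), candidates are scored by mismatch
count, and a full sliding-window scan backstops the seeding whenever the
pigeonhole guarantee (placements with ≤ ⌊L/k⌋−1 mismatches are always
seeded) cannot rule a species out of contention. An edit-distance aligner
is the wrong tool here: a terminal C→T mismatch and a terminal gap have
equal edit cost, and choosing the gap silently deletes the damage signal
the authentication stage measures — we measured a drop of the position-1
C→T frequency from 0.27 (truth) to 0.11 through an infix edit-distance
aligner before settling on the ungapped design.

All species within one mismatch (configurable margin) of the best score
vote; the fragment is assigned to the family only if every candidate
belongs to it (lowest-common-ancestor collapse) and the best identity is
≥ 0.90. Ambiguity across families yields "unassigned" — at 10%
between-family divergence roughly 4% of 50 bp fragments genuinely tie
across families (a ≤1-mismatch alien placement has Poisson(≈5) tail
probability ~4%), so abstention at that rate is the correct behaviour, not
a defect. Tie handling is order-free: permuting the panel changes nothing.

Per-spot profiles report fragment counts, deaminated counts, counts per
milligram (using the resin-corrected effective sediment mass when the
quantification stage provides one), and a per-family ancient flag from the
two-ended CI test. "Dominant" families hold ≥ 10% (inclusive) of a spot's
identified fragments.

## Spatial dispersion

For each taxon detected at ≥ 3 spots, the Clark–Evans nearest-neighbor
index is

    Rn = D_obs / (0.5 · √(a / n)),

with D_obs the mean distance (cm) from each positive spot to the nearest
other positive spot, a the sampled area (cm², an explicit input), and n
the number of positive spots. Anchors: 0 for coincident points, 1 under
complete spatial randomness, 2/√(√3/2) ≈ 2.149 for the interior of a
triangular lattice (the maximum). Coordinates are stored in mm and
converted to cm internally so the area units stay consistent.

No edge correction is applied to block data — n is small and the plain
statistic is what the anchors refer to; a toroidal metric is available for
calibration, where the CSR and lattice anchors are exact. Because drilled
spots sit on a discrete grid, the observed Rn is additionally referred to
a permutation null that redraws n positive spots uniformly from the actual
spot coordinates; the two-sided p-value uses |Rn − 1| as the discrepancy.
One consequence worth knowing: on a *regular* grid the pitch bounds
nearest-neighbor distances from below, so no subset of grid spots can be
much more compact than a random subset — strong clustering significance is
only observable on irregular spot layouts or as Rn ≈ 0 (co-located
positives).

## mtDNA consensus, trees, lineages

Deaminated fragments are de-duplicated (identical start/end/strand/sequence
collapse to one molecule — the package's operational definition of "unique"
fragments) and piled onto the circular reference. A base is called where
coverage ≥ 2 and the modal base holds ≥ 66% of observations (ties → N);
everything else is N. Internal consistency is assessed at positions with
≥ 10-fold coverage: support < 80% flags a possible second mtDNA, and the
report notes what fraction of the minor allele sits within three bases of
fragment ends, where residual deamination — not a second individual — is
the usual explanation.

Distances are pairwise differences over co-called (non-N) positions,
normalised by the number compared. Trees come from a canonical Saitou–Nei
neighbor joining with deterministic label-order tie-breaks; negative branch
lengths are clamped to zero with the deficit moved to the sister branch so
the joined pair's path length is preserved. Bootstrap support resamples
alignment columns with replacement (default 500 replicates) and reports the
percentage of replicates containing each original bipartition. NJ is
consistent on additive matrices; the tests verify exact topology recovery
on 100 random 5–8 taxon trees and cross-check against an independent
implementation.

Lineage assignment counts fragment votes at diagnostic mtDNA positions
(modern human / Neanderthal / Denisovan / Sima de los Huesos states).
Sites whose discriminating substitution is C↔T or G↔A are excluded by
default because deamination fabricates exactly those alleles; a toggle
restores them. The call is the majority lineage of informative votes with
a Wilson CI on its share; exact splits report as "mixed".

## Nuclear analyses

With Sx X-chromosome and Sa autosomal target sites, the expected fraction
of fragments hitting X is Sx/(Sx + 2·Sa) for one X copy (male) and
Sx/(Sx + Sa) for two (female) — equal capture efficiency per site is
assumed. The observed fraction of deaminated fragments gets a Wilson 95%
CI; the call is the expectation the CI contains (undetermined if it
contains both, nearest expectation if it contains neither — a large sample
lands a hair outside its own expectation ~5% of the time and should not be
discarded for it). Faunal mis-mapping is the fraction of fragments
carrying the non-hominin allele at diagnostic sites, screened strictly
below 2%. Library-level damage screening applies the two-ended CI test per
library and merges the passing libraries of a sample.

## Quantification

Yields are molecules per milligram of *sediment*: drilled mass is
multiplied by the sediment/resin ratio (dehydrated mass before
impregnation ÷ drilled mass after; a ratio > 1 is physically suspect and
flagged). Library efficiency is the conversion rate of a synthetic
spike-in oligonucleotide of known copy number; values above 1 are
rejected. The simulator draws per-sample molecule counts as
truth-per-mg × effective mass × layer efficiency × lognormal noise
(σ = 0.3), with per-layer efficiencies (demo: 0.1 for an inhibited layer
vs 0.8 for a clean one) driving both the yield and the spike-in recovery,
so the layer contrast is recoverable end to end.

## Synthetic data: what it emulates and what it does not

The generator produces: a mitogenome panel (root genome mutated into
family ancestors at half the between-family divergence, species at half
the within-family divergence; within-family identity strictly above
between-family identity or the config is rejected); a 24-spot alternating
grid of "regular" (30.1 mg) and "micro" (3.4 mg) samples at 8 mm pitch
over a 14 cm² face, split across two layers; per-spot fragment libraries
(counts Poisson in mass × 10 fragments/mg, lengths 34 + Geometric(0.1)
with minimum 35, both strands, circular wrap) with 10% undamaged
contaminant; per-taxon spatial structure as Thomas-style cluster disks,
Bernoulli presence, or an alternating sub-grid; a nuclear site panel with
per-sex fragment draws and a configurable faunal mis-mapping rate; and
spike-in/quantification tables. Everything derives from one master seed
with per-component substreams (`default_rng([seed, sha256(key)])`), so
datasets are byte-reproducible and adding a spot does not perturb the
others.

Not emulated: base-quality strings, adapter read-through, indels,
reference bias, overhang-length-dependent damage, inter-site fragment
length differences, and real taxonomic structure deeper than two ranks.
Tests passing on this generator demonstrate correctness of the estimators
under the stated model, not performance on any particular archaeological
site.

## Numerical and design choices

- All binomial CIs at 95%, Wilson unless stated; undefined frequencies
  (zero opportunities) propagate as NaN and "insufficient data" verdicts.
- Boundary conventions: length ≥ 35 and score ≥ 25 kept; ≥ 66% calls;
  < 80% flags; ≥ 10% dominance; < 2% mis-mapping passes.
- Consensus ties and multi-modal positions are N, never arbitrary.
- The demo pipeline (simulate → report, 16.5 kb genomes, ~3,400 fragments,
  24 spots) runs in well under a minute on one CPU; test-suite simulations
  use 2–5 kb genomes so the whole suite stays fast.
- Permutation p-values use the add-one estimator (1 + #extreme)/(n + 1),
  never exactly zero.

## Known limitations

- The ungapped aligner will misplace fragments containing true indels
  relative to the panel; for mtDNA at the divergences simulated this is
  negligible, but real cross-family assignments would need a gapped
  (BLAST-class) stage.
- Sex calling assumes equal X/autosome capture efficiency; real probe sets
  need control individuals, supported as an optional expectations table.
- The permutation null conditions on spot geometry but not on per-spot
  detection sensitivity (mass differences are ignored for presence).
- No maximum-likelihood phylogenetics, no population split-time estimation,
  and no external reference genomes are shipped.
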