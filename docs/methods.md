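# Methods

This note describes the analysis implemented by `motupipe` in enough detail
to reproduce every number the pipeline prints.

## Problem setting

A barcode survey of a speciose taxon collects, for each specimen, a
cytochrome c oxidase subunit I (COI) sequence of roughly 650 bp together
with a morphology-based species assignment ("morphospecies") and a
collection locality. The analytical question is how many molecular
operational taxonomic units (MOTUs, here called haplogroups) the survey
contains, how they distribute over the morphospecies, and what that implies
about undescribed diversity. The pipeline answers it in six stages.

## 1. Quality control

COI is protein-coding in the vertebrate mitochondrial code (NCBI
translation table 2, stop codons TAA, TAG, AGA, AGG), so intact barcodes
translate without internal stops.

- **Reading frame.** For each sequence the three forward offsets are
  scanned and the frame with the fewest unambiguous in-frame stop codons is
  chosen; ties break to the smallest offset. Codons containing any
  ambiguity character never count as stops. If every forward frame carries
  3 or more stops the reverse complement is tried and kept if it has fewer.
- **Stop-codon filter.** Any internal stop in the chosen frame excludes the
  sequence as a likely nuclear pseudogene copy (NUMT) or sequencing
  artefact. A stop that is the final complete codon is treated as a
  legitimate terminal stop.
- **Length filter.** After alignment, a sequence must carry strictly more
  than 500 resolved sites (characters other than gap or N). 500 is chosen
  so that the 0.1%-resolution distance reporting is meaningful and roughly
  three quarters of the full barcode is present.
- **Contamination filter.** From the distance matrix, a specimen is flagged
  as a probable cross-contaminant when its nearest neighbour belongs to a
  different morphospecies at under 2.0% while its nearest conspecific lies
  beyond 10.0%. Both conditions must hold: the first alone describes any
  cryptic-species boundary, the second alone any deep split. Specimens
  whose morphospecies has no other sampled member are never flagged (no
  conspecific evidence exists either way). Flagged specimens are excluded
  but their evidence is reported in full.

## 2. Translation-guided alignment

COI barcodes are essentially indel-free, so the alignment problem reduces
to finding each sequence's codon offset. Each sequence is translated in its
detected frame; the longest stop-free sequence (ties broken by id) anchors
the alignment; every other translation is aligned to the anchor's by global
pairwise protein alignment (match 2, mismatch −1, gap open −8, gap extend
−1, end gaps free), and the resulting amino-acid offsets and gaps are
applied back to the nucleotides as codon-width blocks, so the reading frame
survives. A sequence whose translation is identical to the anchor's over
less than 50% of its own length cannot be anchored (it is probably not the
target marker) and aborts the run with its id named. Finally, alignment
columns with non-gap coverage below 50% are trimmed so ragged ends do not
leak into the length filter.

## 3. p-distances

The distance between two aligned sequences is the uncorrected p-distance in
percent — 100 × mismatches / compared sites — under pairwise deletion: a
site is compared only when both sequences carry an unambiguous A, C, G or
T there. No substitution-model correction is applied; at barcode depths the
raw proportion is the conventional currency and keeps the 2% threshold
comparable across studies. A pair with zero comparable sites is an error,
not a zero. All downstream computation uses unrounded distances; rounding
to one decimal (halves away from zero) happens only when tables are
written.

## 4. Threshold delimitation

Haplogroups are the connected components of the graph joining two specimens
iff their p-distance is **strictly below** the threshold (default 2.0%) —
single-linkage clustering with a hard cut. The strictness matters at the
boundary: two clusters whose minimum separation is exactly 2.0% remain
distinct candidate species, while a cluster whose maximum internal
difference is 1.9% stays one group. Groups are labelled
`"<morphospecies> Group k"` in order of first appearance, attributing a
group to the morphospecies of its first member. A mean silhouette score
over the partition (on the precomputed distance matrix, singletons scoring
0) is available as a partition-quality diagnostic of the same kind that
likelihood-based barcode binning procedures optimize.

## 5. Phenogram

A neighbour-joining tree is built from the p-distance matrix by the
canonical Saitou–Nei agglomeration: at each step the pair minimizing the
Q-criterion is joined (ties to the lowest index pair); a negative branch
length is clamped to zero with the deficit transferred to its sister so the
path length between the joined nodes is preserved; the final edge is split
evenly. The result is a **phenogram** — a visual summary of distance
structure, not a phylogeny: no rooting, no support values, no monophyly
claims. For display, each haplogroup is condensed to one pseudo-leaf
labelled with locality, n, and within-group variation; monophyly is
assessed in the unrooted sense (some edge separates exactly the group), and
a group that is not monophyletic in the tree is reported rather than
collapsed.

## 6. Tables, census and extrapolation

Following common barcoding usage, a group's **variation** is the maximum
pairwise p-distance among its members (not a statistical variance);
singletons show "n/a". Between-group tables report the minimum (optionally
minimum/maximum, rendered "min/max") over all cross-group pairs, per
species and globally, rounded to one decimal at write time only.

The census counts haplogroups per morphospecies; the excess of haplogroups
over morphospecies is the number of **additional candidate species**.
Scaling a known regional richness estimate by the haplogroup-to-
morphospecies ratio gives a projected richness. This is a deliberate
back-of-the-envelope figure — it assumes unsampled species split at the
sampled rate and carries no confidence interval.

## Synthetic data

Because real surveys have no ground truth, the package ships a generator
whose outputs are arithmetically predictable. Geometry is a star, not a
coalescent: a root sequence (uniform stop-free codons), per-species
ancestors at a fixed radius (default 10% of sites), per-group founders at
controlled radii, and members radiating from founders. All substitution
site sets within one species are drawn disjointly, so every pairwise
distance is an exact sum of substitution counts — no back-mutation noise —
and every within/between value in every table can be predicted before the
data are generated. Substitutions are biased 8:1:1 toward third : second :
first codon positions and redrawn whenever they would create a stop codon
(a safe base always exists), so the data stay cleanly translatable at any
divergence.

Founder radii solve r_i = t_i − t_min/2 for per-group minimum-separation
targets t_i; all targets are met exactly when at least two groups share the
smallest target (the default configurations are built that way), and a
uniquely smallest target is overshot, which the generator verifies and
records. Default sequences are 217 codons (651 nt, a typical barcode
length); configurations that must realize exact round percentages (e.g. a
pair at exactly 2.0%) use 1000 codons so the percentage is an integer
substitution count. The default survey-like configuration plants 122
specimens in 12 morphospecies and 30 haplogroups — single-group species,
two-group splits, two four-group complexes, an eight-group complex with
separations from 2.4% to 19.9%, and one pair of groups separated by exactly
2.0% — plus two pseudogene-like sequences, one cross-species contaminant
and one truncated sequence.

What the generator does **not** emulate: realistic coalescent genealogies,
transition/transversion bias, rate variation among lineages, indels, or
geographic correlation of haplotypes. It is a test harness with exact
arithmetic, not a population-genetic simulator.

## Numerical choices

- Distances are computed on uint8-encoded arrays with boolean masks;
  results are exact rational multiples of 100/sites.
- Rounding uses `Decimal(repr(value))` with ROUND_HALF_UP so printed values
  honour the decimal literal, and applies at the presentation layer only.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived seeds stay below 2^31.
- Standard primitives come from established libraries (Biopython for
  IO/translation/protein alignment, scipy for connected components,
  scikit-learn for silhouettes, scikit-bio for tree structure); the
  delimitation logic, p-distance, NJ agglomeration and generator arithmetic
  are implemented here and cross-checked in the test suite against naive
  independent reimplementations.

## Limitations

- A fixed global threshold cannot resolve groups whose within-group
  variation exceeds their separation from a sibling; such geometries are
  rejected by the generator and undetectable by the method.
- Single-linkage chains: intermediate haplotypes can merge otherwise
  distinct groups.
- The contamination rule cannot flag a contaminated specimen whose
  morphospecies has no other sampled member.
- The richness projection inherits every bias of the sampled
  morphospecies set.
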