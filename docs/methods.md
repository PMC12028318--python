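# Methods

This note documents the models, conventions and numerical choices behind
phagekit, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying conventions were genuinely
open.

## Specificity scoring

The Paired Difference Index of an entity (phage over hosts, or host over
phages) is the mean difference between its highest log₁₀ titer score and
each of its other scores, `Σ_{i=2..N}(P₁ − P_i)/(N − 1)` with scores in
descending order. Two policy axes are explicit in `ScoringPolicy`:

* **Non-infections** (resistant, impaired, not-assessed cells). `FLOOR`
  (default) scores them at the detection limit, i.e. log-score 0;
  `DROP` excludes them from both the sum and the denominator, reading
  null titers as non-assigned. Under `DROP`, an entity with fewer than
  two usable counterparts is returned flagged (`undefined_reason`), not
  as a silent NaN. Impaired cells (clearing without viable progeny)
  score like resistant cells — no productive infection occurred — but
  the state is preserved in the data model for reporting.
* **Normalization.** With `normalize` (default) scores are divided by
  the row maximum, bounding PDI in [0, 1] and making 1 − PDI a usable
  susceptibility score; without it the PDI is in raw log₁₀ units. The
  normalized PDI is *not* invariant to multiplying all titers by a
  common factor (normalizing shifted logarithms changes their ratios);
  the raw-log PDI is.
* **Detection floor.** `floor_value` (PFU/ml, default 1) clamps titers
  from below. By default scores are log titers *relative* to the floor
  (`subtract_floor=True`), so a non-infection scores exactly 0 and a
  fully resistant host gets susceptibility 0, which the three-class
  partition requires. With `subtract_floor=False` the absolute-log
  convention is used instead: a non-infection keeps the nonzero share
  `log₁₀(floor)` under normalization, which matters for assays whose
  detection limit is well above 1 PFU/ml (plaque assays typically
  resolve down to ~10² PFU/ml). Under the default convention a host
  infected by exactly one phage scores 0; under the absolute-log
  convention it scores in (0, 0.5) for a high titer. Both conventions
  are tested; neither is asserted to be the one behind any published
  number.

A row with no positive titer at all has PDI 1 by convention (maximal
specialization; for hosts, susceptibility exactly 0). This is forced by
the resistant class: the logarithm of an all-zero row is otherwise
undefined.

Host classes: score 0 → resistant; 0 < score < 0.5 → slightly
susceptible; score ≥ 0.5 → susceptible (boundary inclusive).

## Neighborhood ecology

Patristic distances are leaf-to-leaf path sums of branch lengths;
missing branch lengths are an error (no silent default of 1). The
k-nearest-neighbor profile (k = 6 by default) excludes the focal strain
and breaks distance ties toward the lexicographically smaller taxon id,
making the profile deterministic and input-order invariant. "Trait
specificity" is operationalized as the fraction of the k neighbors
sharing the focal strain's trait value; the statistic is pluggable
(`statistic=` callable) because fraction, indicator and entropy variants
are all defensible. Class association uses the tie-corrected
Kruskal–Wallis test with all pairwise two-sided Mann–Whitney U
post-hocs; post-hoc p-values are reported raw and Benjamini–Hochberg
adjusted (the correction choice is a reporting default, not baked in).

## Pangenome construction

Proteins are compared with local (Smith–Waterman) alignment, BLOSUM62,
gap open 11 / extend 1; ambiguous residues (X, B, Z) score 0. Identity
is matched columns over aligned columns and coverage is the aligned span
over the length of the shorter protein — matching the phrasing of the
downstream cutoffs (identity > 20%, coverage of the shortest protein
> 50%). A shared 6-mer prefilter skips pairs that cannot plausibly
align; unrelated random proteins share essentially no 6-mers, while
homologs above the identity cutoff share many, so the prefilter does not
change results for pairs that matter (verified in tests). A loader for
precomputed tabular hits supports exact replication of external search
pipelines, whose internals are not reproduced bit-exactly here.

Best hits per (gene, other genome) are ranked by score, then identity,
then lexicographic target id — deterministic across runs. BBH edges
require mutuality plus both cutoffs; families are connected components
over all genes (unmatched genes become singletons), so families
partition the gene set by construction. Core = member in every genome;
single-copy = exactly one member per represented genome.

The adjacency graph counts, for every genome, each rank-consecutive gene
pair as one unit of weight on the edge between their families. Strand is
ignored (adjacency is about gene order, not orientation) and genomes are
linear by default (`circular=True` adds the wrap edge); for linear
genomes total weight equals Σ(n_genes − 1), an invariant used as a
self-check. Tandem members of one family produce self-loops.

Intergenomic-similarity classification applies single-linkage clustering
(connected components of the ≥ t graph) at 50/70/95% for
family/genus/species; nesting of the three partitions is then automatic.
The similarity matrix itself is an input — its computation (BLAST-based
intergenomic similarity) is out of scope.

Dollo reconstruction places each family's single gain on the branch
above the MRCA of its carriers and losses on the maximal subtrees below
the gain containing no carrier, which minimizes losses given one gain.
Branches are identified by their subtended leaf set. The input tree must
be rooted (bifurcating root); families absent everywhere are an error.

## Recombination and divergence

Family divergence is the mean over unordered pairs of percent identity
on mutually non-gap columns; pairs with no shared column are excluded
with a warning. The divergence threshold defaults to 95% and the taxon
subset is configurable (typically all taxa minus a declared outgroup).

Recombination events arrive as a GFF dialect with 1-based inclusive
coordinates on the concatenated codon alignment; internally coordinates
are 0-based half-open, and the conversion is an exact bijection
(property-tested). Branch type is inferred from the `taxa` attribute
(>1 taxon → internal, 1 → terminal, absent → unknown). An event counts
for a family iff their intervals share at least one column; no minimum
overlap fraction is imposed. Mapping uses untrimmed alignment
coordinates (the dN/dS trimming below does not shift event
coordinates).

The counting dN/dS is Nei–Gojobori (1986): codon columns with ≥ 20%
gapped codons are removed; synonymous/nonsynonymous site counts per
codon are normalized to sum to 3, single-step neighbors that are stop
codons count as nonsynonymous; differences average over all minimal
mutational pathways; pooled pairwise proportions get the Jukes–Cantor
correction. dS = 0 yields a flagged undefined ratio rather than an
infinity. This estimator is an explicit stand-in for codon-model fits:
external per-family estimates can be ingested from a TSV and are never
asserted to match the counting values. In-frame stop codons are an
error naming the sequence and codon.

The association report combines (i) a two-sided Mann–Whitney U on event
counts between divergent and non-divergent families and (ii) Spearman
correlations of identity against event counts and against dN/dS, with
raw and BH-adjusted p-values. Degenerate inputs (a constant variable, an
empty divergence group) produce flagged NaNs plus a warning, not
exceptions.

## Life history

Adsorption: free fractions are `value / input_titer`; the first-order
rate is the negated slope of an ordinary least-squares fit of
ln(fraction) on time over positive fractions, reported with R².
Fractions above 1 are counting noise and are retained with a warning.

One-step growth: replicates must share a time grid (interpolation is
refused — silently resampling counts would fabricate data) and are
averaged before change-point detection. The rise index is the first
point exceeding `rise_factor` (default 2) times the running mean of all
earlier points; the baseline is the mean over all pre-rise points (a
multi-point mean, since a single-point baseline is noise-limited). The
first plateau is the earliest maximal run of ≥ 2 consecutive post-rise
points whose relative spread (range/mean) stays within `plateau_tol`
(default 0.15). Burst = plateau mean / baseline; latent period = time of
the last pre-rise point + adsorption duration. "First plateau" and
"initial increase" have no standard operational definition, so
`rise_factor` and `plateau_tol` are explicit documented parameters
rather than hidden heuristics. Burst is invariant to uniform count
scaling by construction.

## Synthetic generators

One integer seed drives one named substream per generator
(`default_rng([seed, stream])`), so the generators are mutually
independent and byte-reproducible.

*Infection matrix* (default 18 phages × 157 hosts, 1/6 specialists,
host mix 40% resistant / 30% slightly susceptible / 30% susceptible,
titer noise 0.3 log₁₀ units): generalists infect every susceptible host
around 10⁶ PFU/ml; each slightly susceptible host is reached by two
generalists around 10³·⁵; specialists infect a subset sized at 10% of
the panel around 10⁸. Titers are log-normal, clipped to the observed
10²–10⁸ PFU/ml range; resistant hosts get no positive entry, with a
fraction of their cells in the impaired state. These defaults emulate a
modular assay matrix in which broad-host-range phages score PDIs near
0.7 and specialists near 0.9, and class recovery from titers alone is
essentially perfect at assay-scale noise. Not emulated: phylogenetic
autocorrelation of host susceptibility, partial assay coverage, or
titer-dependent assay dropout — so passing recovery tests demonstrates
the scoring logic, not robustness to those real-data features.

*Genomes* (default 18 taxa, 250 core + 40 accessory families,
0.02 substitutions/site root-to-tip, 9 recombination events): a random
birth–death tree scaled to the requested height; codon sequences (gene
lengths 60–140 codons) evolved by per-site substitution with
stop-creating changes rejected; accessory families on two island
positions (mid- and late-genome by default, mirroring a conserved
backbone with a couple of variable regions), gained and lost on
scripted branches chosen so the script *is* the canonical Dollo solution
of the induced presence pattern; recombination injections replace a
recipient clade's gene with the allele of an unsampled donor lineage
(the family ancestor evolved along a ghost branch, 0.15 subs/site by
default), so injected families carry excess divergence, and each event
is recorded with exact concatenated-alignment coordinates. Not
emulated: indels (alignments are trivially column-correct), codon-usage
bias, rate heterogeneity, partial-gene recombination tracts, or
annotation errors — BBH recovery being exact at these settings shows the
graph pipeline is correct, not that real annotation noise is survivable.

*Kinetics* (default burst 38, latent period 35 min, adsorption rate
0.5/min, adsorption step 5 min, four replicates on a 0–120 min grid in
10-min steps): growth curves hold the infection-center baseline until
the end of the latent period, rise along a smoothstep over 20 min to a
plateau at baseline × burst, with multiplicative log-normal noise;
adsorption curves decay exponentially from the input titer. The default
trait values sit in the middle of the ranges reported for large-genome
vibriophages. Not emulated: lysis-from-without, asynchronous bursts, or
secondary infection cycles (the plateau is flat by construction).

## Problem sizes and tolerances

The acceptance-style checks run at the generator defaults: 1000 random
rows for the PDI-vs-brute-force agreement (tolerance 1e-12, pure
floating-point noise); 18 genomes × 290 families for exact BBH recovery;
all 2⁶ presence patterns on each of 10 random 6-leaf trees against an
exhaustive minimum-loss search; 10⁴ random events against a per-column
overlap count; 200 seeded kinetic simulations at 10% noise with a
median-absolute-error bound of 10% of truth. Unit tests use smaller
collections (5–12 taxa) of the same structure. The all-vs-all stage at
the 18-genome scale takes tens of seconds on one core with the 6-mer
prefilter.

## Known limitations

* The built-in aligner is not a replacement for a sensitivity-tuned
  search tool on real proteomes with low-identity homologs; for those,
  load external tabular hits.
* The counting dN/dS underestimates rates at saturation and ignores
  transition/transversion and codon-frequency biases by design.
* Dollo parsimony cannot represent horizontal re-acquisition of a lost
  family; such histories are reconstructed as a deeper gain with more
  losses.
* Published study counts (gene-family totals, per-phage PDIs on the
  published matrix, recombined-core-gene counts) require the deposited
  genomes and the published figure source data; the pipeline computes
  them when those inputs are supplied but the repository does not
  include them.
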