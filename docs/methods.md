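# Methods

This note documents the models, conventions and numerical choices behind
`museumharvest`. The package implements the informatics side of "museum
harvesting": recovering cytochrome c oxidase subunit I (COI) barcodes from
pooled, sample-tagged amplicon reads of pinned museum specimens, and using
the recovered barcodes to assign taxonomy to unidentified records.

## Coordinate and sequence conventions

All positions are 0-based, half-open intervals on a canonical 658-bp COI
barcode frame. Consensus sequences are over `{A,C,G,T,N}`; "sequence
length" always means the count of non-N bases, and an *acceptable* barcode
has more than 300 of them (i.e. ≥ 301 non-N bases). An N-padded sequence
can therefore never qualify on padding alone; note that other databases may
count length differently.

## Plate model

Specimens are arrayed in an 8×12 grid (rows A–H, columns 1–12) mirroring a
96-well plate. 95 squares hold specimens; one square is reserved for a
negative control. The control defaults to H12 — the 96th square in
row-major order — because the protocol reserves "the 96th square" without
naming it; the choice is configurable and only conventions depend on it.
Sample IDs are `plate_code + "-" + row + zero-padded column`
(`CCDB-31120-A01`); the codec is a bijection over valid plate codes × 96
wells. Taxonomy is stored as seven Linnaean ranks (phylum, class, order,
family, subfamily, genus, species) with subfamily optional, since many
dipteran classifications skip it. Specimen age is `analysis_year −
collection_year` with `analysis_year` defaulting to 2017.

## Amplicon panels and tag sets

Two presets ship:

* `sanger2` — two overlapping amplicons of insert length 307 bp
  (`[0,307)`) and 407 bp (`[251,658)`), the classic two-fragment design;
* `ngs_tiled` — six short overlapping amplicons
  (`[0,120) [110,230) [220,340) [330,450) [440,560) [550,658)`) tiling the
  frame, the failure-tracking design for degraded templates.

Preset primers are deterministic synthetic placeholders (real panels
publish their primer sequences separately); they exist so simulation and
tests are self-contained, and are swappable via YAML for real data.

Sample tags ("UMIs" in the indexing sense: one tag pair per sample, not
per molecule) are 8-mers, 96 per direction, asymmetric dual-tagging: well
*i* in row-major order gets forward tag *i* and reverse tag *i*, so of the
96×96 possible pairs only the 96 diagonal pairs are valid and any
off-diagonal decode is evidence of tag jumping. The shipped tag set is
generated by seeded rejection sampling with a guaranteed minimum pairwise
Hamming distance of `2·tolerance + 1` within each direction, which makes
decoding under ≤ `tolerance` mismatches provably unique. The default
tolerance is 1 mismatch, the standard choice for short sample tags; the
distance property is validated at load time for whatever tolerance the
caller requests.

## Read simulator

The simulator stands in for voucher specimens and the wet protocol.

**Barcode phylogeny.** Sequences descend from one random 658-bp ancestor:
genus founders mutate the ancestor by `genus_divergence` (default 6%),
species founders mutate their genus by `species_divergence` (default 2%),
individuals mutate their species by `individual_divergence` (default
0.4%). These defaults put intra-species p-distance well below 2% and
inter-genus distance above 5% by construction, matching the thresholds the
classifier is built around; a configuration whose finer-rank divergence is
not strictly below the coarser rank's is rejected.

**Degradation.** An amplicon survives PCR from a specimen of age *t* years
with probability `2^(−t / half_life_years)` — the standard exponential
fragmentation assumption for degraded DNA. The default half-life is 40
years: at the mean specimen age of the motivating study (~38 years) this
yields ≈ 50% per-amplicon survival, the recovery level observed at that
age. Since no quantitative degradation parameters are published for this
material, the value is illustrative, not calibrated.

**Errors and read anatomy.** Surviving amplicons emit `depth` reads of the
form `UMI_f + fwd_primer + insert + revcomp(rev_primer) + revcomp(UMI_r)`,
with independent per-base substitutions (default 0.5%) and geometric(0.5)
length indels (default 0.1% initiation per base) applied across the whole
read — consistent with circular-consensus reads at ≥ 99% predicted
accuracy. Quality strings are flat at the Phred equivalent of the total
error rate. About half of all reads are emitted reverse-complemented.
Collection years default to uniform draws over 1901–2017, the observed
range in the motivating study. All randomness flows from explicit seeds;
no global RNG state is touched.

**What the simulator does not model:** quality-correlated errors, chimeras,
PCR bias among amplicons, co-amplified contaminants other than the explicit
negative-control donor mechanism, heteroplasmy and NUMTs. Passing tests on
this generator therefore demonstrate the pipeline's logic (partitioning,
positioning, consensus arithmetic, thresholds), not its robustness to every
artefact of real museum data.

## Assembly pipeline

Six stages, each conserving reads (`kept + rejected = input`):

1. **Filter** — keep reads with mean QV ≥ 20 and length ≥ 100 bp. The
   mean per-read QV is the filtering statistic, consistent with the
   "predicted accuracy" semantics of circular-consensus reads.
2. **Demultiplex** — decode the terminal 8-mers on both strands; a read is
   assigned iff exactly one strand yields a tag pair present in the well
   assignment. Decoding is a partition: every read lands in exactly one
   sample bin or is logged `no_tag`/`tag_conflict`.
3. **Taxonomy screen** — each read's nearest reference must belong to the
   specimen's expected order and lie within `order_filter_max_distance`
   (default 0.25). The nearest candidate is found with a bounded
   edit-distance scan (edlib, infix mode, both strands) and the decision is
   then made on the exact p-distance to that single candidate; the bounded
   scan is an engineering shortcut, the accepted/rejected decision always
   rests on the p-distance. The default threshold accommodates the
   untrimmed primer/tag flanks, which inflate read-to-reference distance by
   up to ~0.15 for the shortest amplicons.
4. **Amplicon assignment** — search both strands for the best
   forward/reverse primer pair within a mismatch budget of 10% of primer
   length (edlib with IUPAC equivalences); ties between amplicons are
   ambiguous and unassigned.
5. **Positioning (alignment-free)** — trim tags/primers, orient to the
   frame strand, and anchor the fragment at its amplicon's known start
   coordinate. No pairwise alignment is performed anywhere in this step. A
   fragment with a deletion simply covers fewer columns than its amplicon
   interval; insertions shift downstream bases out of register within that
   fragment. This is a deliberate fidelity/simplicity trade-off that keeps
   the method strictly reference- and alignment-free; at indel rates ≥ 1%
   per base it measurably erodes per-column accuracy, and the majority vote
   across overlapping fragments is what keeps the consensus correct.
6. **Consensus with N-fill** — per frame column, the strict-plurality base
   among covering fragments (coverage ≥ `consensus_min_depth`, default 1)
   is emitted; ties emit N; zero-coverage columns strictly inside the
   covered span emit N so the final sequence is contiguous; the sequence
   runs from the first to the last covered column. Minimum depth 1 reflects
   the protocol's practice of assembling whatever fragments were recovered.

Validation then flags a consensus `contaminated` when its nearest reference
belongs to a different order than expected — an automated stand-in for the
manual neighbour-joining/database-query review of the original protocol.

## Divergence, clusters and assignment

**p-distance** is the proportion of differing sites among compared
positions of a globally aligned pair with free end gaps; columns containing
a gap or any non-ACGT symbol are excluded from numerator and denominator.
Equal-length pairs are compared site-by-site (their end-gap-free optimum
for the high-identity pairs the thresholds care about); unequal-length
pairs are aligned with match +1, mismatch −1, gap open −2.5, extend −0.5,
end gaps free, and the pair is ordered canonically before alignment so the
measure is exactly symmetric. Zero comparable sites raise an explicit
undefined-distance error.

**BIN-proxy clustering.** Reference and query sequences are clustered by
single linkage: connected components of the graph with an edge wherever
p-distance < 2.2%. **This is not the RESL algorithm** that mints real
Barcode Index Numbers; it is a deterministic proxy adequate for
library-building logic. Cluster labels are the lexicographically smallest
member id, so labels are stable across runs.

**Two-route taxonomy assignment**, in strict order:

1. *BIN taxonomy match* — if the query's cluster contains identified
   references (named at least to genus), copy their taxonomy truncated to
   the deepest rank on which all identified members agree.
2. *ID-engine thresholds* — otherwise rank references by p-distance; best
   divergence < 2% supports a species-level candidate, < 5% a genus-level
   candidate, ≥ 5% nothing. Thresholds are strict (`<`), so exactly 2.0%
   caps at genus. Among the top 20 matches (ties at the cutoff included)
   that fall inside the governing threshold, the deepest conflict-free rank
   is assigned, never exceeding the candidate rank.

Because the BIN route runs first, no query is ever assigned by both routes,
and a species-level ID-engine assignment can only occur for queries outside
every identified cluster.

## Reporting

Percentages are computed from integer counts and rounded half-up to one
decimal, so printed values are exact functions of the counts. A genus
counts as successful when at least one of its specimens has an acceptable
barcode. The age–length relationship is ordinary least squares of non-N
consensus length on specimen age, flagged records excluded by default,
with the two-sided slope p-value from the standard t statistic; a constant
response returns R² = 0 by definition. Failure-tracking accounting
requires the rerun cohort to be a subset of the first stage's failures and
the two recovered sets to be disjoint, so combined counts are sums and
count conservation holds by construction.

## Problem sizes used in tests and the acceptance script

The shipped checks use one 95-specimen array for the end-to-end identity
and demultiplexing checks (~10,000 corrupted reads for the latter), 12
specimens for the N-fill check, 75 fixtures for the classifier threshold
bands, and 200 specimens with ages 0–120 years at read depth 2 for the
age-degradation regression. These sizes give stable outcomes (binomial
noise well below the asserted margins) while keeping a full run in tens of
seconds on one CPU.

## Known limitations

* Anchored (unaligned) positioning loses register within a fragment after
  an indel; a realigning consensus would be more accurate but would no
  longer be alignment-free.
* The single-linkage cluster proxy can chain through intermediate
  sequences in ways RESL would split, and vice versa.
* The order-level screen depends on the reference library containing
  relatives of the target taxa; with a sparse library, genuine reads fall
  outside the screen distance and are discarded as unclassifiable.
* Success percentages of the motivating study that depend on its physical
  specimens are reproduced as arithmetic from its printed counts, not
  regenerated from sequence data.
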