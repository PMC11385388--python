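# Methods

This note documents the models, algorithms and numerical choices behind
`strep16s`, in the order the pipeline runs, together with what the
synthetic world does and does not establish.

## Sequence QC

**Length and alphabet.** Sequences are uppercased with U→T replacement;
records containing symbols outside the IUPAC DNA alphabet are dropped
with a per-record tag rather than corrected. The full-length rule keeps
records of ≥ 1200 bp (inclusive at the boundary): the complete gene is
~1550 bp and 1200 bp captures all hypervariable regions while excluding
region-targeted amplicons.

**Ambiguity cutoff.** Per-sequence ambiguity counts in public 16S
collections are overwhelmingly zero with a heavy pathological tail. We
model them as negative binomial, fitted by the method of moments
(p = m/v, r = m²/(v−m); Poisson fallback when v ≤ m, the constant value
when v = 0) and discard records above the fitted quantile
(default 0.999). The quantile, not the resulting integer cutoff, is the
tunable; `ambiguity_threshold_override` pins an exact integer when a
published cutoff must be reproduced. Caveat: re-running QC refits the
cutoff on the already-truncated counts, which could in principle shrink
it below the surviving maximum; with the default quantile this does not
happen on the simulated world (idempotence is asserted in the tests),
but a pipeline wanting idempotence by construction should pin the first
run's fitted cutoff via the override.

**Dereplication.** Two records merge iff their sequence strings are
byte-identical. The representative is the longest member with ties
broken by lexicographically smallest id (identical strings always tie,
so effectively the smallest id); the full member map is kept so species
labels of removed duplicates can be credited to the representative
downstream — without this, multi-species zOTUs are systematically
undercounted.

**Chimera detection.** A transparent stand-in for UCHIME-de-novo.
Records are processed in decreasing abundance (dereplication class size;
ties by id). For a query, candidate parents are earlier records already
flagged clean, selected by shared k-mer count (k = 12) both over the
whole query and per query quarter — the segmented selection matters:
ranking by whole-query overlap alone lets close relatives of one flank
crowd the other parent out of the candidate list. The query is chimeric
iff there are parents A ≠ B and a breakpoint b with prefix identity to A
and suffix identity to B both ≥ `id_two` (0.99) while no single parent
explains the whole query at > `id_one` (0.97). Identity here is the
fraction of matched query positions (per-position match profiles from a
global alignment; a direct comparison when lengths are equal).

*Detectability envelope.* With breakpoint fraction f and parent
divergence d, the best single parent matches a chimera at
1 − d·min(f, 1−f); the `id_one` condition therefore requires
d ≥ (1 − id_one)/min(f, 1−f) ≈ 10% divergence for breakpoints at 0.3L.
This is not a defect of the breakpoint test: chimeras of near-identical
parents are informationally invisible to any de novo detector. The
chimera benchmark consequently plants parents ≥ 12% diverged, and the
cohort generator anchors its chimeras on "deep lineages" kept mutually
≥ 12% apart — more divergent than real within-genus 16S, a deliberate
deviation so that planted chimeras are detectable in principle.

## Pairwise identity and clustering

**Identity definition.** Identity is the matched-column fraction of an
optimal global alignment under match +1, mismatch −1, gap open −2, gap
extension −1; by default terminal gap columns are excluded from the
denominator (the usual usearch/vsearch `--id` reading; the
full-alignment mode is kept for sensitivity analyses). Consequence worth
knowing: a clean truncation of a longer sequence has identity 1.0 in the
default mode, so a strictly non-redundant set can still lose members at
the 100% clustering threshold.

**Exact fast path.** For equal-length sequences with d mismatches the
ungapped alignment scores L − 2d, while any alignment whose path leaves
a diagonal band of half-width B must spend > B insertions and > B
deletions, losing those aligned pairs and paying two gap openings:
score ≤ L − 3(B+1) − 2. Hence with B = max(4, ⌈(2d−5)/3⌉) the optimum
over the band (a numba-compiled banded Gotoh DP) is certified to be the
global optimum. When the ungapped score attains it — essentially always
for substitution-dominated data — identity is the Hamming identity (the
ungapped alignment is then chosen as the optimal-alignment
representative; it has no terminal gaps, so both identity modes agree).
Otherwise, and for unequal lengths, Biopython's `PairwiseAligner`
produces an optimal alignment whose column counts are used directly.
The banded score is verified against Biopython in the tests, and
identities on short sequences against an exhaustive enumeration of all
optimal alignments.

**Greedy clustering.** Records (dereplicated) are processed in
deterministic order — decreasing length, ties by id — and each joins
the first centroid at ≥ threshold identity, else founds a new cluster.
A sweep (98.0–100.0% in 0.1% steps, inclusive) shares one identity
cache, making its cost proportional to the number of distinct pairs
inspected. Note that first-fit greedy clustering does **not** guarantee
that cluster counts grow monotonically with the threshold: with
identities id(r1,r2)=.985, id(r2,r3)=id(r2,r4)=.999 and all other pairs
at .97, the 98% threshold yields three clusters but 99% yields two,
because raising the threshold frees r2 to found a centroid that then
absorbs r3 and r4. Monotonicity is an empirical regularity of real 16S
data (and holds on the simulated world), not a theorem; the test suite
asserts it for the stated world only.

**Composition statistics.** After propagating taxIDs from dereplicated
duplicates, each cluster reports member count, distinct species-level
taxIDs, and unclassified flags; per-threshold ECDFs of the taxID counts
reproduce the characteristic ordering in which looser thresholds carry
more taxa per cluster.

## Genome side

**Extraction.** Any rRNA/gene/misc feature whose qualifier values
mention "16S" case-insensitively is extracted (annotation practice
varies between gene=, product= and note=); minus-strand features are
reverse complemented; copies are aggregated per assembly (one file per
assembly). A genome is retained only when it has ≥ 1 copy and every
copy is ≥ 1200 bp with zero ambiguity symbols — a single bad copy
excludes the genome, since partial copies inflate apparent intragenomic
diversity.

**Fragment ANI.** ANIb-style: the query is cut into consecutive 1020 bp
fragments (the final fragment absorbs the remainder, so fragments tile
the genome exactly and self-comparison gives coverage 100). Each
fragment is aligned by seed-and-extend: exact 13-mers sampled every 3
positions vote for a (strand, diagonal) against an index of both subject
strands; the winning diagonal's window is compared gap-free and the
maximal-scoring segment (+1/−1, vectorised Kadane) is the local
alignment, with a Smith–Waterman fallback on a padded window whenever
the gap-free segment explains the fragment at < 70% identity (this
covers indel-containing data; the generator's mutation model is
substitutions-only by design, keeping identity targets analytic).
Fragments are kept if ≥ 30% identity over ≥ 70% of the fragment;
identity is the unweighted mean over kept fragments and coverage the
kept aligned length over the query length. Seeding bounds sensitivity:
below ~70% identity the expected seed count per fragment drops toward
zero, which is also what keeps unrelated genome pairs at ~0 coverage.
Directed results are symmetrised as mean identity and min coverage —
conservative for genus calls, since a pair is congeneric only if both
genomes are substantially covered. Thresholds are inclusive: ≥ 95%
identity for species, ≥ 50% coverage for genus.

**Network.** Nodes are retained genomes; an edge means ≥ 1 shared
byte-identical variant (weight = number of shared variants, carried but
not used in classification). Components are classified from all member
pairs with genus failures dominating species failures (multi_genus >
multi_species_single_genus > single_species). Every non-singleton
component can emit a spanning-tree certificate of witness variants,
re-verified in the tests. "Identical" means byte-identical full-length
strings, matching the strictness of the genome-side filter.

## The synthetic world

**Genome model.** Coverage cannot be moved by substitutions, so genomes
are block-structured: `[A | B | C | D | 16S cassette]` with A shared by
all genera, B by one genus, C by one species and D genome-private.
Block sizes are solved from the coverage targets (between-genus 35%,
within-genus 72%, within-species 93% — near the extremes reported for
real cohorts) counting the always-alignable 16S cassette at its expected
size; per-branch substitution rates are solved from the identity targets
(within species 98%, between species within genus 88%, between genera
80%) with the near-identical cassette's upward pull corrected for.
Rates compose multiplicatively down the hierarchy
((1−r_branch)² per split), so realized identities land within a few
tenths of a point of the targets; back-mutation corrections (~r²/3) are
below the testing tolerance and ignored.

**16S cassette.** All loci descend from one master 1540 bp sequence:
12 substitutions per genus, 6 per species, 1–2 for intragenomic
variants; loci sit in a tandem cassette after the backbone with 100 bp
random spacers, ~30% of loci on the minus strand. Copy numbers are
drawn from a distribution over 1–12 with mode 6 (26% six, 63% below,
11% above, matching the reported shape for the genus); genomes carrying
planted multi-variant structures draw conditionally on having enough
copies, a small and tested distortion of the histogram.

**Planted contradictions.** With probability 0.5 per adjacent species
pair (first pair forced), the second species adopts the first species'
core variant in all its genomes — merging the two species into one
network component of class multi_species_single_genus; a config knob
plants the same across genera (multi_genus). One species is arranged as
a non-clique (variant sets {v1}, {v1,v2}, {v2}, {v2}). Genome-level QC
noise (4% no-16S, 15% with a partial or ambiguous copy) skips the
species carrying the protected planted structures. Ground truth for the
partition, clique flags and component classes is computed inside the
generator by union-find and exhaustive pair checks over the planted
variant incidence — no graph library involved — so pipeline recovery is
a genuine two-route check.

**Database model.** 800 records by default: ten deep-lineage anchors
(duplicated so they outrank chimeras in abundance), and ordinary records
drawn uniformly over species and their variant pools with Poisson(1)
strain substitutions, 12% truncations (300–1199 bp), 30% planted exact
duplicates, 5% chimeras (deep-lineage parents, breakpoints 0.3–0.7),
ambiguity counts ~ NB(r=0.05, p=0.02) (82% of records clean; true 0.999
quantile = 135, the mostly-clean-with-pathological-tail character the
quantile cutoff exists for). Exact coincidences between independently
drawn records are recorded as redundant in the truth table, because
dereplication cannot distinguish them from planted duplicates. Label
noise is a single categorical per record: 3% synonyms (every valid name
has one synonym so the rate is injected exactly), 1% single-character
typos (epithets are kept pairwise Levenshtein > 5 apart so a typo always
has a unique nearest name), 45% unclassified ("Streptomyces sp."), 2%
names absent from the table, 2% foreign higher-rank lineages, 1%
genus–species conflicts.

**What a green test establishes — and what it does not.** The world is
substitution-only (no indels, no rearrangements), its deep 16S lineages
are more divergent than real congeneric 16S, its genomes have uniform
base composition and no gene content, and its noise classes are mutually
exclusive per record. Green tests therefore establish that the
algorithms implement their stated rules exactly and recover planted
structure when effect sizes clear the stated margins (ANI ≥ 2 points
from thresholds, chimera parents inside the detectability envelope);
they do not establish calibration against real survey data, chimera
sensitivity for closely related parents, or ANI accuracy in the presence
of indels and repeats.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| QC min_length | 1200 bp | captures all hypervariable regions of the ~1550 bp gene |
| ambiguity quantile | 0.999 | flags only the pathological tail of the NB fit |
| chimera id_two / id_one | 0.99 / 0.97 | flank match vs best-single-parent margin; sets the detectability envelope |
| identity scoring | +1/−1/−2/−1 | usearch-like; fixed so banded-DP certificates hold |
| sweep grid | 98–100% step 0.1 | brackets the historical 97% species proxy up to zOTUs |
| ANI fragment | 1020 bp | ANIb convention |
| fragment keep rule | ≥30% id over ≥70% | ANIb convention; rejects spurious seed hits |
| species / genus thresholds | ≥95% id / ≥50% cov | standard whole-genome circumscription heuristics |
| seed k-mer / stride | 13 / 3 | ≥ ~6 expected seeds per fragment down to ~75% identity |
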