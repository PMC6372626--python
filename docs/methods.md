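# Methods

`ubcgenomics` implements the downstream inference layer of a somatic
whole-genome study of urothelial bladder carcinoma: given per-sample SNV
and SV calls, a reference sequence, a callable-coverage mask, copy-number
segments, and regulatory annotations, it extracts mutational signatures,
scans for recurrently mutated noncoding tiles, and detects kataegis,
breakage-fusion-bridge (BFB) events, SV formation mechanisms, SV-burden
genome subtypes, and recurrently SV-disrupted genes.  Read alignment and
variant calling are upstream of this package; their outputs are its
inputs.

## Coordinates, masks, and rate denominators

All internal interval arithmetic is 0-based half-open; SNV and breakend
positions are 1-based (VCF convention) and converted only at file
boundaries.  The coverage mask is the set of positions that passed the
upstream depth filter (tumor > 14x and matched normal > 8x in the
defining study design); the package treats it as given rather than
recomputing depth, and every mutation-rate denominator — tile effective
lengths, kataegis flank lengths, genome-wide rates — is a callable length
from this mask.

## Mutational signatures

Substitutions are tabulated into 96 channels (six pyrimidine-represented
substitutions x 16 flanking contexts, conventional catalog order; purine
references are folded onto the reverse complement).  De novo signatures
come from NMF of the 96 x S count matrix with multiplicative updates
minimizing the generalized Kullback–Leibler divergence, a small 1e-12
pseudocount in update denominators, random uniform initialization,
convergence when the relative divergence decrease falls below `tol`
(default 1e-6) or after 1,000 iterations, and the best of `n_restarts`
(default 10) final divergences kept.  Signature columns are normalized to
sum to one with compensating scaling of exposures.  A Frobenius objective
is available behind a flag.

Rank selection runs NMF for each k in a range (2–15 by default).  Each
restart factorizes a *multinomial bootstrap resample* of the spectrum;
restarts on the identical matrix reconverge to near-identical factors
even above the true rank, so resampling is what exposes unstable
components.  The pooled signature vectors are clustered into k groups
(k-means on L2-normalized vectors) and **stability is the minimum over
clusters of the mean cosine silhouette within the cluster**.  The overall
mean silhouette was tried first and rejected: it is dominated by the k−1
reproducible signatures and stayed above 0.8 for ranks past the truth,
whereas the weakest cluster is exactly what rank overshoot degrades (in
rank-3 simulations, min-cluster silhouette is ~0.999 at k = 3 and ≤ 0.46
at k > 3).  The chosen rank is the largest k with stability ≥ 0.8
(configurable); the full stability/error table is always returned so a
caller can override.  Reconstruction error is reported against the
original (un-resampled) spectrum.  Extracted signatures are matched to a
reference catalog by cosine similarity, ties broken by first reference
column.

## Noncoding recurrence scan

The genome is divided into coterminous 1 kb tiles (terminal remainder
kept).  SNVs and SV breakends (each junction contributes up to two
breakend events) are pooled across samples; events outside the callable
mask are excluded, and the per-tile distinct-sample count is reported
descriptively.  Each tile with at least one event is tested against two
backgrounds:

* **local** — the 1 Mb flanking region (500 kb each side, truncated at
  chromosome ends, tile excluded from count and length);
* **global** — the whole callable genome.

Under the null each pooled event lands in the tile with probability
p0 = effective tile length / effective total length, so the tile count is
Binomial(k_total, p0) and the p-value is the exact upper tail.
Benjamini–Hochberg adjustment is applied separately per approach across
all tested tiles (zero-count tiles are excluded from the family — their
p = 1 only dilutes ranks — and this is visible in the output);
significance requires adjusted p < alpha (default 0.05) in **both**
approaches.  Blacklist base pairs are removed from the working mask
(events and lengths), and tiles overlapping a blacklist interval are
removed before testing.  Surviving tiles are annotated with overlapping
regulatory classes and target genes; a flag restricts testing to
annotated tiles only.  The binomial-tail formulation is this package's
explicit interpretation of the cohort-recurrence test; tests verify it
against brute-force pmf summation to 1e-12.

Note one approximate invariance: duplicating the genome (two identical
chromosomes) leaves each tile's global p-value unchanged only in the
Poisson limit, since k_total doubles while p0 halves; at cohort-scale
counts the drift is ~1%.

## Kataegis

Three conjunctive rules per sample: (1) a maximal run of ≥ 6 consecutive
mutations with every intermutation distance ≤ 1 kb; (2) the cluster rate
significantly higher than both the pooled 50 kb flanks and the sample's
genome-wide rate — two one-sided binomial tests at alpha = 0.05, no
multiplicity correction (the rate test is one screen inside a conjunction
of three filters; alpha configurable); (3) at least one same-sample SV
breakend within 50 kb of the cluster span ("surrounded by breakpoints" is
not quantified in the source description; one breakend within a
configurable window is this package's reading, and requiring flanking on
both sides can be emulated by post-filtering on the reported
`nearest_sv_distance`).  Flank windows are clipped at chromosome ends; a
cluster whose flanks have zero callable length skips the flank test and
is decided by the genome test, flagged in the output.  Every emitted
event is re-checkable by an independent validator that recounts mutations
and sums binomial pmfs explicitly.

## SV mechanisms, subtypes, gene recurrence

Mechanism per junction, in precedence order: TEI (call type, or an
insertion with a breakend in a transposable-element annotation); VNTR
(call type, or a breakend in a VNTR annotation); FoSTeS/MMBIR when the
event has more than two junctions (homology alone cannot separate
template switching from alt-EJ, and the upstream caller encodes the
multi-junction structure); NHEJ for 0–2 bp homology or a 1–10 bp
untemplated insertion (codes −1…−10); alt-EJ for 3–100 bp homology;
otherwise unclassified.

Genome subtypes are evaluated in rule order: **stable** (< 50
rearrangements), **locally rearranged** (≥ 50 with > 25% of events on one
chromosome), **unstable** (> 200), else **scattered** (50–200).  The
ordering resolves the overlapping published ranges — a genome with 250
events and 30% on one chromosome is locally rearranged here.  Exactly 50
events with ≤ 25% concentration is scattered; exactly 200 is scattered.
For the concentration, each SV counts once per distinct chromosome it
touches (translocations count for both) over a denominator of the
per-sample SV count.

A gene is hit by a tumor when ≥ 1 breakend falls in the gene interval;
recurrent means ≥ 5 tumors, significant means ≥ 10% of the cohort (both
configurable).  Duplicate gene names are unioned with a warning.

## Breakage-fusion-bridge

Fold-back inversions (same chromosome, equal breakend orientations) with
breakend separation < 20 kb are scored per junction: copy-number change
is the fold change (max of ratio and inverse) between the length-weighted
mean copy ratios of the two 100 kb windows flanking the junction
midpoint, and telomere distance is the smaller breakend distance to
either chromosome terminus.  A junction passes with fold change ≥ 2.0 and
telomere distance ≤ 5 Mb — both quantifications of qualitative published
standards ("significant copy-number change", "adjacent to the telomere")
and both configurable.  Telomere adjacency is applied to the junctions
themselves rather than the amplified region (the published wording is
ambiguous).  An event needs ≥ 2 passing junctions per sample and
chromosome.  Every emitted event re-validates all four standards through
an independent checker.

## Synthetic cohorts

The generator produces, from one integer seed, a reference genome
(i.i.d. uniform A/C/G/T), a fully callable mask, SNV and SV catalogs,
copy-number segments, and a truth label for every record.  Uniform
sequence is deliberate: every downstream statistic conditions on the
provided sequence, so real-genome context biases (GC structure, repeats,
replication timing) are unnecessary for correctness testing — and their
absence is exactly what passing tests do *not* establish about real data,
along with purity/subclonality effects and caller artifacts, none of
which are modeled.  Mutations are assigned a 96-channel first (sample
mixture over reference signatures, then channel within signature) and
then a uniformly chosen context-matching site, so planted spectra are
exact.  Hotspot tiles receive extra uniform mutations at
(multiplier − 1) x background; kataegis specs plant evenly spaced runs
verbatim and can request a supporting same-sample breakend within a given
distance.  SVs realize an exact target-chromosome fraction, draw junction
homology inside each truth mechanism's defining range, and fold-back
pairs emit two same-orientation inversion junctions (< 20 kb separation)
near a chromosome end together with stepped copy-ratio segments
(4.0 / 2.0 / 1.0) whose boundaries sit at the junction midpoints, so each
junction shows a ≥ 2-fold flank change.  Randomness is hierarchical
(fixed per-purpose, per-sample streams from the global seed), so adding
samples never perturbs earlier samples, and reruns are byte-identical.

The default cohort (`default_cohort_config`) is a desk-scale analogue of
the study cohort: 65 tumors over 10 chromosomes x 1 Mb; background
2.8e-6 substitutions/bp/sample (the mean burden of ~8,400 per ~3 Gb
genome); one 1 kb hotspot at 70x background (the multiplier implied by
the most recurrent noncoding site being mutated in 13 of 65 tumors);
kataegis planted in 45% of samples; fold-back pairs in 5 samples; and
per-sample SV burdens drawn so ~48% of genomes are stable, with the
remainder split 15/25/12 (%) among locally rearranged, scattered, and
unstable (the stable fraction is the published figure; the split of the
remainder is this package's choice).  Ten chromosomes are used because a
scattered genome (max chromosome fraction ≤ 0.25) cannot be planted
reliably on four equal chromosomes.  The signature stage of
`scripts/acceptance.py` instead preserves the per-sample mutation
*count* (~8,400 on the 10 Mb reference), because NMF consumes counts,
not rates.

## Numerical and degenerate-input choices

Binomial tails use exact survival functions; a region with zero callable
length and nonzero events is an error (inconsistent mask).  Zero-width
kataegis spans are widened to 1 bp.  NMF ties across restarts resolve to
the first minimum; cosine matching ties resolve to the first reference.
BH ties receive equal adjusted values (standard step-up).  Fold-back
junctions lacking copy-number coverage are excluded with a warning; a
sample with fold-backs but no segments at all is an error.  Loaders never
drop records silently — every skip (non-SNV rows, edge mutations without
trinucleotide context) increments a reported counter.

## Known limitations

Simulated genomes are small and uniform; detector thresholds tuned for
3 Gb genomes (e.g. the 5 Mb telomere margin) are trivially satisfied on
megabase-scale test chromosomes, so tests of telomere logic use larger
simulated chromosomes explicitly.  Kataegis "surrounded by" and the BFB
copy-number/telomere quantifications are single-number readings of
qualitative criteria.  Mechanism classification trusts the upstream
caller's homology and junction-count features; it does not reconstruct
them from reads.  Chromothripsis scoring, per-mutation signature
attribution, covariate-adjusted recurrence backgrounds, and
survival/expression analyses are out of scope.
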