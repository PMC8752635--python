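# Methods

`tlsmut` implements the computational core of a clone-sequencing mutagenesis
analysis: isogenic unique-mutation calling with ancestral-clone calibration,
96-channel trinucleotide mutation spectra with context-specific counters and
cross-genome normalisation, NMF signature extraction and refitting, and the
classification of immunoglobulin VL1 amplicon variants into point mutations
and pseudogene-templated gene conversions. A synthetic-data module generates
all inputs with exact truth tables, so every stage can be validated by
parameter recovery.

## Mutation spectra (`tlsmut.spectra`)

Coordinates are 1-based and fully closed; indels use VCF-style anchored
alleles. Single-base substitutions are reported on the pyrimidine strand:
purine-reference records are mapped to the reverse complement with flanks
complemented and swapped, giving the standard 96 channels (6 substitution
classes x 16 flank combinations, COSMIC ordering: C>A, C>G, C>T, T>A, T>C,
T>G, flanks alphabetical).

Context counters are double-strand collapsed, which is the only symmetric
choice when the strand of reported counts is unspecified:

* **NCC>NAC** — C>A substitutions with a 3' C on the pyrimidine strand
  (equivalently GGN>GTN on the opposite strand). This motif captures
  mutagenesis across intrastrand GG/AG dinucleotide adducts such as those
  formed by cisplatin.
* **T insertions after GG** — single-T insertions whose two reference bases
  5' of the insertion point are GG, plus the strand mirror (single-A
  insertions 5' of CC). The insertion point sits between the anchor base and
  the next reference base.
* **Deletion sizes** — binned 1 / 2 / 3+ bp; very short deletions at adduct
  motifs are a translesion-synthesis footprint, while 3+ bp deletions point
  to end-joining.

Cross-genome adjustment multiplies each channel by the ratio of
pyrimidine-collapsed triplet occurrences in a destination versus a source
genome and renormalises to the original total, enabling comparisons between
spectra observed on one genome (e.g. chicken) and signatures defined on
another (e.g. human). The operation is the identity for equal tables and
invariant to uniform rescaling of the destination table.

Records whose context overlaps an N or a contig edge are skipped with a
warning in batch spectrum building but raise in single-record
classification; a reference-allele mismatch against the supplied genome
always raises.

## Unique-mutation calling (`tlsmut.calling`)

The caller assumes a batch of isogenic samples: one ancestral clone and
descendant clones whose newly arisen mutations are each private to one
sample. For each site and sample the top non-reference allele is a
candidate if

1. its count and frequency reach `min_alt_count` (default 3) and
   `min_alt_freq` (default 0.2, admitting heterozygous variants at ~0.5);
2. every other sample is clean: reference-allele frequency at least
   `min_other_ref_freq` (default 0.9) — this removes germline and shared
   variants;
3. the Fisher confidence score passes the (calibrated) threshold. The score
   is -log10 of the one-sided Fisher's exact p-value comparing the focal
   sample's alt/ref counts against the *noisiest* other sample (lowest
   reference frequency; ties broken by higher depth, then sample id — a
   deterministic worst-case comparison).

The published statistic of the original isogenic caller is not restated in
the literature this re-implements; the cleanness-plus-Fisher formulation
above reproduces the documented behaviour (sample-unique calls, tunable
stringency, ancestral calibration) with every threshold exposed.

**Ancestral calibration.** The ancestral clone carries no unique mutations
by construction, so any ancestral call is a false positive. The score
threshold is calibrated as the smallest value at which each ancestral
sample retains at most 5 SBS and 1 indel call — separate thresholds for the
two classes because their budgets differ. Calibration sweeps the observed
score values (plus 0 and max+1), so the returned threshold is the smallest
achievable one; a sample with more above-limit infinite scores than the
budget raises with diagnostics. Calibration is applied per batch; a single
global calibration is a matter of passing all batches at once.

**Mapping-quality filter.** Supporting reads with MQ < 40 are discounted; a
call survives if the retained reads still satisfy the count and frequency
thresholds (quorum rule — the alternative all-reads rule would discard true
mutations with a single stray low-MQ read, which contamination makes
common). Discounted reads also leave the depth denominator.

**Coverage-jump filter.** A jump is an adjacent-position depth change of at
least 5. A call is dropped when jumps occur on *both* sides within a 200 bp
window, read as symmetric ±100 bp half-windows around the site; such
double-edged steps mark misalignment or cross-species contamination blocks.
One-sided jumps (ordinary read-edge effects) do not drop calls. Windows
truncated by contig edges are evaluated on the available range with a
warning.

## Signature analysis (`tlsmut.signatures`)

De novo extraction factorises the samples-by-96 count matrix under the
generalised Kullback–Leibler objective with multiplicative updates
(`sklearn` NMF, `solver="mu"`), 200 iterations, tolerance 1e-6, best of
`n_runs` (default 30) random restarts seeded from a master seed —
bit-reproducible for a fixed seed. Signature columns are normalised to sum
1 with exposures rescaled into mutation-count units.

**Rank selection.** For each candidate rank k the signatures of all
restarts are pooled, clustered by average linkage at cosine distance and
cut into k clusters; the mean silhouette of that clustering is the
stability of rank k (~1 when every restart reproduces the same k
signatures, dropping sharply once k exceeds the reproducible rank). The
chosen rank is the largest k before the first stability drop greater than
δ (default 0.05), ties towards smaller k; without such a drop the most
stable k wins. The cophenetic correlation coefficient of each rank's
run-signature dendrogram is reported alongside for inspection, and a
`stable` flag (stability >= 0.9 at the chosen rank) marks inputs with no
reproducible factorisation, such as pure noise. An earlier design that
built the consensus from sample co-assignment to dominant signatures was
abandoned: on planted-rank cohorts the restart consensus is nearly
deterministic at *every* rank (cophenetic 0.95–1.0 throughout), so its
curve carries no usable drop; the run-signature silhouette separates the
planted rank cleanly (drop of 0.1–0.2 at k_true+1 across seeds).

**Refitting.** A spectrum is normalised and fitted on a fixed signature set
by non-negative least squares; exposures are reported as fractions of the
fitted total with the reconstruction-versus-observation cosine. Signatures
contributing 5% or less are eliminated and the remainder refitted,
iterating until all retained contributions are strictly above the cutoff
("detected" = retained; the strict inequality means an exactly-5%
contribution is removed, applied with a 1e-9 absolute tolerance so that a
boundary value is not kept by floating-point accident). Cross-species
refits should pass spectra through the cross-genome adjustment first.

## Immunoglobulin VL1 assay (`tlsmut.ig`)

Merged amplicon reads (nominally 269 bp, analysed region 233 bp) are
aligned globally against the pre-expansion reference (Needleman–Wunsch,
match +2, mismatch −1, gap open −5, gap extend −1; configurable). Reads
below 80% identity are rejected as foreign. Substitutions inside the
analysed region are kept if their base quality is strictly above 30; indels
are flagged but excluded from classification.

Classification against the pseudogene donors:

* a variant is "on" a donor when the donor's aligned base equals the
  observed base;
* donor-matching variants are chained transitively: a variant joins the
  chain when it is at most 9 bp (absolute reference-position distance) from
  the previous member and shares at least one donor with all members so
  far. Chains of 2+ variants are **GC** events with compatible donors equal
  to the intersection of member donor sets; isolated donor-matching
  variants are **ambiguous** (this also covers pairs on different donors or
  farther than 9 bp apart);
* variants on no donor are **point mutations**, subtyped PM_AT / PM_CG by
  the reference base pair. Every filtered variant belongs to exactly one
  event. The 9 bp rule is defined pairwise in the source assay; transitive
  chaining is this package's documented extension to 3+ variant clusters.

**Tract lengths.** The maximum possible copied length of a GC event is
delimited, per compatible donor, by the closest donor-specific positions
outside the event at which the read still carries the reference base;
missing delimiters fall back to the analysed-region boundary ±1. The
default length is exclusive of the delimiters (v − u − 1; an inclusive
variant is available behind a flag), and the minimum over compatible donors
is reported (shortest-tract rule). Note the reported minimum is
deliberately conservative: when several donors are compatible it can be
shorter than the true donor's copied tract, while the per-donor value is a
guaranteed upper bound on what that donor could have contributed — the
acceptance checks therefore verify the bound against the generating donor.

Event rates are per sequenced read pair: category count / total read pairs
per sample. Ambiguous events are reported separately from PM and GC totals.

## Synthetic data (`tlsmut.simulate`)

The generators define the study conditions; all are deterministic under a
seed and emit truth tables.

* **Genomes** — i.i.d. bases at a configurable GC fraction (default 0.42,
  chicken-like), length >= 1 kb.
* **Clone sets** — each descendant clone receives Poisson-distributed
  unique SBS (default mean 200 per clone, a desk-scale stand-in for the few
  hundred substitutions accumulated over a ~50-day / ~100-generation
  culture) placed by rejection sampling at genome positions whose collapsed
  triplet matches the channel drawn from the configured signature mixture —
  exact spectrum semantics at toy scale — plus ~10 insertions and ~10
  deletions (1–3 bp) at random positions. The ancestral clone carries
  nothing. Pileups are emitted at truth sites, noise-only sites (default
  2000) and contaminant-like sites (default 20, spurious ~30% variant
  evidence plus a ±60 bp coverage step of +8 that the jump filter should
  catch). Depth comes from a read-process coverage track (Poisson read
  starts, 150 bp reads: locally smooth, regionally Poisson(30)); carrier
  alt counts are Binomial(depth, 0.5) (heterozygous), other samples carry
  Binomial(depth, 0.5%) errors spread uniformly over non-reference bases.
  Mapping qualities follow a two-component mixture (90% at 60, 10% uniform
  20–39) to exercise the MQ filter.
* **Pseudogene sets** — donors differ from the reference at
  Bernoulli(divergence) positions (default 10 donors, divergence 0.08), with
  exact donor-specific maps.
* **Amplicon populations** — per read: a gene conversion with probability
  0.005 (donor tract of geometric length, mean 29 nt — the wild-type mean
  tract length — copied into the analysed region), a point mutation with
  probability 0.01 (90% at C/G reference pairs, emulating AID targeting;
  the planted base matches no donor), and base-call errors at 5e-5 per base
  (post-merge residual error of overlap-merged read pairs), 95% of which
  draw qualities below the Q30 filter. Planted variants carry qualities
  33–40. The per-read truth includes the realised planted variants *and*
  their expected event classification obtained by applying the category
  rules to the noise-free variant set — a planted tract that happens to
  cover fewer than two donor-specific positions genuinely carries no GC
  evidence, and the truth table says so rather than blaming the classifier.

What the generators do **not** model: real read alignment (pileups are
emitted directly), mapping artefacts beyond the stylised contaminant sites,
PCR jackpot errors and chimeras in the amplicon assay, adduct chemistry, or
clonal substructure. Passing recovery tests therefore demonstrates the
correctness of the statistical machinery under the stated noise model, not
robustness to every artefact of real sequencing data.

## Reporting (`tlsmut.report`)

Group summaries report mean and SEM (sd/sqrt(n); undefined and reported as
missing for n=1). Comparisons use the unpaired two-sided t-test — Welch by
default, since equal variances between genotypes is an unnecessary
assumption; a pooled-variance switch exists — or the Wilcoxon rank-sum
test (exact up to 25 observations per group without ties, normal
approximation otherwise). Two constant, equal groups report p = 1 by
convention (logged). No multiple-testing correction is applied. Percent
change is 100 x (ref − test)/ref, positive for reductions.

## Problem sizes and tolerances

The validation suite runs at desk scale, chosen to finish in minutes while
leaving comfortable statistical margins: Fisher-score oracle agreement over
all 2x2 tables with margins <= 30 (~250k tables, agreement to 1e-8 in
-log10 p); calibration verified over 100 random cohorts; end-to-end calling
on a 100 kb genome, 4 descendant clones, ~200 SBS each at 30x / 0.5% error
(precision and recall >= 0.95); NMF recovery on 30 spectra from 3 planted
signatures at Poisson mean 500 mutations (rank 3 selected, matched cosines
>= 0.95, exposure correlation >= 0.9); refit exactness to 1e-6 on noiseless
mixtures; immunoglobulin recovery on 10^4 reads (rates within 3 binomial SE
of the planted truth). `scripts/acceptance.py` recomputes all of these from
scratch for any seed.

## Known limitations

* The caller consumes per-site pileup summaries; it does not parse BAMs or
  generate pileups from alignments.
* Rank selection assumes the candidate range brackets the true rank and
  that restarts explore the solution space; heavily overlapping signatures
  lower the stability contrast.
* The amplicon aligner is applied read-by-read; paired-end merging and
  demultiplexing are upstream.
* Residual high-quality base-call errors are counted as point mutations, as
  in the source assay — the A/T point-mutation channel in particular should
  be read as an error-rate proxy.
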