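# Methods

## Scope and data model

The package analyses per-species transcriptome SNP data: a reference
transcriptome (FASTA), one embryo-pool variant set and one or more haploid
megagametophyte variant sets (VCF v4.2, one record per SNP, 1-based POS,
INFO key `SRC`), a per-transcript depth summary (TSV: `transcript_id`,
`mean_depth`, `n_bases_depth_ge10`), and optional gene→annotation tables
(TSV: `gene_id`, `species`, `orthogroup_id`, `family_id`, `process_id`).
Internally all coordinates are 0-based half-open; conversion happens only
at VCF I/O.

## Variant filtering

Megagametophyte tissue is haploid, so SNP calls inside it flag collapsed
paralogs. The paralog filter removes every embryo-pool record whose
(transcript, position) key occurs in any megagametophyte set — matching is
allele-blind, the conservative reading of "seen in at least one
megagametophyte". The operation is a set difference: idempotent, monotone
in the megagametophyte sets, and the identity when they are empty.
Upstream caller quality is represented only by the VCF FILTER column
(non-PASS records are dropped on read); re-deriving hard-filter thresholds
is out of scope.

Transcript eligibility requires mean depth ≥ 10, at least 300 bases at
depth ≥ 10, and a predicted CDS. The thresholds are config keys
(`min_mean_depth`, `min_bases_depth_ge10`) with those defaults.

## ORFs and site counting

The longest ATG-initiated reading frame is searched over all six frames;
3'-truncated ORFs (no stop before the transcript end) are allowed because
assembled transcripts are frequently incomplete. Ties prefer the forward
strand, then the smallest start. The minimum ORF length defaults to 30 nt.
Whether non-ATG starts should be permitted is genuinely open; ATG-only is
the simplest defensible rule and is configurable at the call site by
sequence preprocessing.

Site counting is Nei–Gojobori with equal mutation weights: each position of
a sense codon contributes s/3 synonymous sites, where s of its three
possible substitutions preserve the amino acid; La = 3·codons − Ls exactly.
Mutations to or from stop codons are nonsynonymous; the terminal stop codon
is excluded from the sites; codons containing N contribute nothing, and
SNPs falling in them are dropped with a logged warning rather than being
assigned a fabricated translation. The genetic code is selectable by NCBI
table number (default 1). A codon-usage-weighted (mutational-opportunity)
variant is deliberately not implemented.

## Selection statistics

The adjusted ratio ((A+0.5)/(La+1)) / ((S+0.5)/(Ls+1)) is applied to all
genes uniformly, not only to S = 0 genes — uniform use avoids a
discontinuity at S = 0; the raw ratio remains available from the same
counts.

The null test is a reconstruction. Under neutral allocation, each of a
gene's n SNPs is nonsynonymous with probability p0 = La/(La+Ls); with
k* the smallest nonsynonymous count whose adjusted ratio exceeds 1, the
reported probability is the exact binomial tail P(K ≥ max(A, k*)). For an
observed ratio ≤ 1 this is the unconditional chance of a ratio above 1; for
a ratio > 1 it is the usual one-sided exact binomial tail, so thresholding
at α is a conservative test (empirical type-I ≈ 0.03 at α = 0.05 — the
discreteness of small n makes exact tails conservative). Note that the
purely unconditional form P(ratio > 1) cannot work as a gene filter: the
ratio-above-1 threshold k* sits essentially at the null mean n·p0, so the
unconditional probability is ≈ 0.3–0.5 for every realistic (n, La, Ls) and
no gene could ever clear a 5% bar. A PSG is a gene with adjusted ratio > 1
and null probability < α (default 0.05, per-gene; Benjamini–Hochberg
adjustment is available but off by default, matching the per-gene 5% rule).
The PSG proportion of a species uses all tested ORFs as denominator. The
flag is named "PSG" by field convention; a high A/S ratio is equally
compatible with balancing selection, and no attempt is made to separate
the two.

## Diversity model

Per-transcript SNP counts are fitted by maximum-likelihood NB2 regression
(statsmodels) with log link on log(length), log(depth) and species
indicators; the dispersion α (var = μ + αμ²) is estimated. Both covariates
are estimated rather than fixed offsets, since detection efficiency need
not scale proportionally with either. Adjusted counts rescale each raw
count by exp(η_ref − η_i) on the length/depth part of the linear predictor,
with reference covariates the median length and depth: zeros stay zero,
counts at the reference are unchanged, and common rescaling of all depths
leaves species comparisons invariant.

Species grouping computes all pairwise two-sample Kolmogorov–Smirnov and
Cramér–von Mises p-values on the adjusted per-transcript counts of eligible
transcripts, joins pairs non-significant under **both** tests at α = 0.05,
and takes connected components ordered by decreasing mean. The both-tests
conjunction and α are options; the connected-components rule is a
reconstruction of how pairwise tests become a small number of groups.
Which CvM variant applies was unstated upstream; the standard two-sample
test is used. Tests run on adjusted counts (not rates or residuals),
matching the per-transcript framing of the summary table.

Reported summary cells are rounded at reporting time only: mean adjusted
SNPs per polymorphic transcript to 1 decimal, proportion of polymorphic
transcripts to 0.1%.

## Convergence

"Shared" means present in ≥ 2 species; an in-all-species count is reported
alongside. A species' element set at a level is the set of distinct
elements annotated to its genes; genes lacking annotation at a level are
excluded from that level's universe. Enrichment is a flat one-sided Fisher
exact test per term per species (hypergeometric tail), a deliberate
simplification of graph-decorrelated GO testing; the significance threshold
defaults to 0.005. Best-match pairing sorts hits by (E-value, −bitscore,
ids) and greedily pairs unclaimed queries and subjects, so a query whose
best subject is taken falls back to its next-best available subject; the
result is one-to-one and independent of input row order.

## Synthetic data generator

Each species gets transcripts of uniform random length (default 500–2500
nt) containing a designed internal ORF covering ~60% of the transcript
(ATG + random sense codons + stop, with an in-frame stop planted just
upstream so the designed ORF is the longest). Per-transcript depth is
gamma-distributed (default mean 40, shape 4 — leaving a realistic minority
of transcripts below the depth thresholds) with linear ramps at the ends so
the eligibility rule has work to do.

SNP totals per transcript are negative binomial with mean
rate × (w·La + Ls) × (depth/mean-depth)^0.3, where w is the nonsynonymous
multiplier (1 for background genes), and are allocated to nonsynonymous
opportunities with probability w·La/(w·La + Ls) — i.e. true PSGs receive
nonsynonymous SNPs at w times the baseline per-nonsynonymous-site rate,
which also raises their totals, as real positive selection would. Placement
within the ORF weights each position by its number of alternative bases
with the sampled effect; ref alleles are the transcript base and alts are
drawn from the substitutions with that effect. Default per-species rates
emulate published per-transcript magnitudes (6.0, 5.8, 5.3, 5.2, 5.3, 4.5,
4.5 SNPs per polymorphic transcript). The NB dispersion default (size 1.2)
was set by matching the published proportions of transcripts without SNPs:
an NB zero fraction at the published means reproduces the observed 8–29%
zero classes for size ≈ 0.7–1.8.

Paralogous false positives are added at a configurable fraction of the
embryo-pool SNPs (default 0.1), each echoed in at least one (on average
~two) megagametophyte libraries; megagametophyte sets contain exactly the
paralog sites, so the filter's ground truth is unambiguous.

The annotation model builds orthogroups, then families as a partition of
orthogroups, then processes over families (every family maps to ≥ 1
process). Shared elements are placed in every species and species-specific
elements in exactly one, which makes the realized shared fraction at each
level match the configured profile (default 0.65/0.97/0.91) up to rounding
and keeps the degenerate profiles exact. The trade-off is that
intermediate multi-species intersection cells are sparse relative to real
orthology data.

Not modelled: reads and base-calling error, within-pool allele frequencies,
linkage, demography, and interspecific divergence. Passing tests on this
generator therefore validate the statistical machinery — filtering
identities, count adjustment, test calibration, overlap accounting — not
robustness to alignment artefacts or frequency-dependent ascertainment.

## Power limits measured on the synthetic design

Two recovery experiments are intrinsically power-limited, and the measured
numbers should be read with that in mind:

* **PSG recall.** With baseline ~10 SNPs per gene, a tripled nonsynonymous
  rate gives a PSG ~25 SNPs with nonsynonymous fraction 0.9 versus null
  0.75. The most powerful α = 0.05 test of p0 = 0.75 vs p1 = 0.9 needs
  n ≈ 41 SNPs for 80% power (normal approximation:
  n = [(1.645·√(p0q0) + 0.84·√(p1q1))/0.15]²), so recall plateaus near
  0.4–0.5 at these settings while the false-positive rate stays below 1%.
  Recall above 80% requires either a multiplier ≥ 5 or roughly twice the
  SNP density.
* **Grouping recovery.** At n = 2000 transcripts per species, keeping the
  6.0-vs-5.8 pair together under both KS and CvM while separating the
  5.8-vs-5.3 pair cannot both be near-certain: the effect sizes differ only
  2.5-fold, and over the dispersion grid the joint recovery probability of
  the full three-way partition peaks around 0.8 (≈0.4 at the default
  dispersion 1.2). The published grouping operated at ~16–18k transcripts
  per species, a different power regime.

Neither experiment's parameters are tuned around these limits; they are
reported as measured.

## Numerical choices

Exact binomial tails use `scipy.stats.binom.sf`; Fisher tails use
`scipy.stats.hypergeom.sf` and are verified against exact integer
summation. Site-count conservation (La + Ls = 3·codons) holds to 1e-9 and
is exact in rational arithmetic. The NB fit raises on non-convergence and
on degenerate inputs (all-zero counts, zero-variance covariates).
Kruskal–Wallis uses tie correction; literally identical samples short-cut
to H = 0. All generator randomness derives from one seed through
`numpy.random.default_rng` substreams keyed by (seed, species), so a fixed
seed reproduces serialized datasets byte-for-byte. Experiment sizes in the
validation module (e.g. 10,000 calibration replicates, 100 grouping seeds,
5 × 200-gene recovery replicates, Fisher margins ≤ 50) keep each experiment
in the seconds-to-minutes range while holding Monte-Carlo error well below
the decision margins.
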