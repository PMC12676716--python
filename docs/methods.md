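# Methods

## Guide matching model

The guide is modelled as canonical SpCas9: a 20-nt spacer whose protospacer
must sit immediately 5' of an NGG PAM on the same strand. Matches are
scored by Hamming distance over the 20 spacer positions only — the PAM is
a hard gate and never contributes mismatches; indel ("bulge") tolerance is
out of scope. Both strands are scanned; a minus-strand hit's position is
reported on the reverse-complemented sequence's own 5'→3' orientation, so
hit coordinates are always protospacer-start coordinates on the hit
strand. Off-target screens default to two allowed mismatches, matching
Cas9's steep activity drop beyond two spacer mismatches; per-mismatch
counts are reported separately so stricter readings are recoverable.

Database bases outside `{A,C,G,T}` (including `N`) never match a spacer or
primer base, and a target-side `N` matches only an `N` in a degenerate
primer pattern. This is deliberately conservative: an unknown base in a
reference entry should not inflate conservation or coverage estimates.
Primer matching allows zero mismatches beyond the IUPAC degeneracy
expansion.

The selected spacer (`AAGTCAACTGTTAAATCTTG`) is parsed out of the sgRNA
specific oligo as the sub-sequence between the T7 promoter plus the
initiating G and the tracrRNA scaffold prefix: the initiating G belongs to
transcription start, not the spacer, so a 21-nt insert loses its leading G
and a 20-nt insert is taken verbatim. Oligo fusion uses the longest
suffix/prefix overlap (≥ 6 nt) between the specific oligo and the reverse
complement of the universal oligo; for the shipped oligos that linker is
8 nt and the fused template 121 nt. The fused length excludes any
amplification-primer extensions, which are not part of the shipped oligo
sequences.

Joint coverage declares a reference sequence usable by the whole nested
workflow iff it carries, in consistent order along one orientation, an
outer-forward site, inner-forward site, exact spacer+PAM site,
inner-reverse site and outer-reverse site; the reverse complement is also
tested so antisense-stored records are recognised. Sequences too short to
span the outer primers simply count as uncovered (a `min_length`
pre-filter is available but off by default), which is why primer+guide
coverage of fragmentary reference databases is much smaller than guide
conservation alone.

## Digestion model

Cleavage is blunt, between spacer positions 17 and 18 (3 bp 5' of the
PAM), at every exact spacer+PAM site on either strand; relaxed cutting at
mismatched sites is available for sensitivity analysis but off by default.
Partial digestion is one Bernoulli trial per molecule with success
probability `e` (the digestion efficiency); enzyme kinetics are out of
scope. A molecule survives into the sequenceable pool iff some fragment
retains an inner-forward site fully 5' of an inner-reverse site. Because
the guide cuts between the inner primer sites, a cut molecule is lost, and
removal-then-renormalisation gives the closed form for the expected
post-digestion share of a cuttable category at pre-digestion share `c`:

    post = c (1 - e) / (1 - c e)

All residual host signal in the treated arm is attributed to incomplete
digestion (`e < 1`); re-amplification of cut fragments is not modelled.

## Single-cell pipeline

Order of operations: contaminant / non-marine removal → per-sample
relative-abundance floor (entries contributing strictly less than 0.25% of
the sample's reads are zeroed; exactly 0.25% is kept) → sample exclusion
(depth below 10 000 reads or below the lower 10% type-7 quantile of all
depths) → SRS scaling to Cmin (default: the minimum depth after
filtering) → power transform `x^0.25`.

SRS ("scaling with ranked subsampling") multiplies each sample by
`Cmin/depth`, keeps integer parts, and hands the remaining
`Cmin − Σ floor` single counts to the ASVs with the largest fractional
parts; fractional-part ties are broken by a seeded uniform draw, so column
sums equal Cmin exactly for every seed. All stochastic steps (SRS
tie-breaks, depth subsampling, simulation) derive per-sample streams
deterministically from a single top-level seed and the sample id, so
results are reproducible and independent of sample order.

Classification: "chloroplast" and "mitochondria" are recognised by those
literal rank names anywhere in the lineage (the SILVA convention places
them at order and family rank); remaining ASVs are "bacteria" only with
domain Bacteria and a non-empty order annotation; everything else is
"other". For composition summaries, mitochondria are folded into "other"
(other = mitochondria + order-unannotated), and the three percentages sum
to 100 per sample. Richness is the per-sample count of detected (> 0)
ASVs of a category; Shannon uses the natural log; Bray–Curtis is
`Σ|a−b| / Σ(a+b)`.

Depth profiles re-sequence a sample in silico: for each depth in
{500, 1000, 5000, 10000}, 1000 replicates are drawn without replacement
(multivariate hypergeometric over ASV counts), and the mean/sd of category
read proportions and distinct-ASV counts are reported. The subsampling
unit is the read: drawing ASVs as units could not reproduce read-composition
curves.

The detection model is a Poisson log-link GLM, `log μ = b0 + b1·treated`,
fitted per bacterial family to per-sample detection counts (number of
distinct ASVs of the family observed in the sample; read counts are
available as an alternative response). Fitting goes through statsmodels'
IRLS (deviance tolerance 1e-8, 100 iterations max); for the
single-covariate model the MLE equals the ratio of arm means, which the
test suite uses as an independent closed-form oracle. `exp(b1)` is the
incidence rate ratio (IRR) with Wald 95% CI and p-value; a family with no
detections in exactly one arm is flagged as separated (IRR 0 or ∞, no
Wald CI), and |b1| > 30 is treated the same way. Raw Wald p-values are
reported without multiplicity adjustment.

The paired richness contrast computes `(treated − control) / control` per
cell and averages the per-pair lifts (group means of richness would
understate the per-cell effect); pairs lacking an arm or with zero control
richness are excluded with a warning. Welch t-tests compare each
category's proportions between arms.

## Synthetic-data generator

Each simulated cell draws a latent state shared by both of its libraries:
a chloroplast fraction `c` ~ Beta(mean 0.714, sd 0.143, moment-matched,
clamped to (0.001, 0.999)), an "other" fraction `o` ~ Beta(0.027, 0.021)
(split 60% mitochondrial, 40% order-unannotated), and per-cell log-normal
jitter on the strain's bacterial community weights. Control libraries are
multinomial draws at a log-normal depth (median 25 000, shape 0.30,
floored at 12 000 so the default depth filter cannot empty a dataset);
treated libraries multiply the chloroplast weight by `(1 − e)`,
renormalise, and redraw to a fresh depth — re-amplification after
digestion, matching the pool-depletion semantics. Paired samples share
`cell_id` and all latent draws; per-cell streams depend only on
(seed, cell id), so subsets of cells are reproducible.

A strain community is a fixed taxon list: eight named core genera shared
by all strains plus strain-specific picks (real phycosphere genera first,
synthetic fill beyond that). Strain A1 uses a two-compartment abundance
model — the core genera share a `core_frac` share of bacterial reads with
mild log-normal spread, the tail is a separate log-normal — reflecting a
few consistently abundant associates over a long rare tail; A2 and A5 use
a single long-tailed log-normal with stronger per-cell turnover.

### Calibration (frozen constants)

The composition parameters are read directly from the observed control
arm. The digestion efficiency `e = 0.938` solves
`E_c[c(1−e)/(1−ce)] = 0.175` with `c` integrated over the control Beta
spread (the point-value solution at `c = 0.714` would be 0.915; averaging
over the spread shifts it because the closed form is convex in `c`).
Community constants (`n_taxa`, tail shape, core share, per-cell jitter,
and the specific frozen community realisation) cannot be read off any
published table; `scripts/calibrate_presets.py` grid-searches them so that
the full default pipeline reproduces the observed per-strain bacterial
richness in both arms and the per-pair richness lift, and the winners are
frozen into `schoco.simulate.PRESETS`:

| preset | n_taxa | sigma | core_frac | cell_sigma | community_seed |
|---|---|---|---|---|---|
| tgravida-a1 | 28 | 1.7 | 0.9 | 0.6 | 7 |
| tgravida-a2 | 14 | 2.8 | — | 1.2 | 3 |
| tgravida-a5 | 14 | 2.4 | — | 1.2 | 6 |

The community realisation is part of the preset (a versioned constant):
leaving it to the run seed makes the dataset-level richness statistics
dominated by a single strain-profile draw that never averages out across
cells.

### What the generator does and does not emulate

It reproduces the category-composition contrast between arms, the paired
structure, long-tailed strain-specific communities with per-cell turnover,
and the detection-threshold mechanics that make bacterial richness rise
when chloroplast reads are depleted. It does not simulate sequence-level
reads (no error models or chimeras), PCR amplification bias, phylogenetic
structure of the toy reference databases, or cross-contamination. Two
known quantitative limitations: the treated-arm "other" share
(~9%) under-predicts the observed 11.5%, because proportional
renormalisation preserves the other:bacteria ratio across arms — the
observed excess likely reflects rare unannotated taxa crossing the 0.25%
detection floor only at treated coverage — so the treated bacterial share
runs ~1–3 points above 71%; and the A2 preset matches its richness means
but under-predicts the printed per-pair lift (~41% vs 53%). Passing tests
therefore demonstrate correctness of the pipeline mechanics and
recoverability of the modelled effects, not realism of any particular real
dataset.

## Numerical choices and problem sizes

Proportion invariants are checked to 1e-9; GLM deviance tolerance is 1e-8;
SRS column sums are exact by construction. The test suite and the
acceptance script run entirely on synthetic data at study scale (62 cell
pairs per dataset; five seeds for the richness-lift statistic; 1000
replicates for property checks), completing in well under a minute on one
CPU. The full-database specificity counts (conservation and off-target
totals over complete plastid/SSU reference databases) require those
databases on disk; the packaged toy database checks the same code paths
against planted ground truth instead.
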