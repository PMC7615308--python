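# Methods

## The measurement problem

WT1's +KTS and −KTS isoforms arise from two 5′ splice donors at the end
of *Wt1* exon 9 that differ by 9 nt and share the exon-10 acceptor. Two
complementary readouts distinguish them:

1. **Junction reads.** A spliced alignment across the exon-9/exon-10
   junction carries a gap whose donor-side coordinate names the isoform.
2. **Short-probe in situ dots.** A BaseScope-style assay renders each
   isoform's transcripts as discrete dots in a tissue section; the
   readout is summed dot area (µm²) per nucleus.

`ktsquant` implements both quantifiers plus the simulators that generate
ground-truthed inputs for them, and the statistics used to compare
genotypes.

## Genotype model and read simulation

A diploid genotype is a pair of alleles, each with an expression budget
*b* (default 1, in units of a wild-type allele):

- **WT** emits +KTS at rate *b·w* and −KTS at *b·(1−w)*, where *w* is
  `wt_plus_fraction` (default 0.5 — an even isoform split, consistent
  with total WT1 protein being unchanged when −KTS doubles in the +KTS
  knockout);
- **FRASIER** (intron-9 donor mutation) cannot take the +KTS donor. With
  `compensation` off it emits −KTS at *b·(1−w)* (the +KTS share is lost);
  with `compensation` on it reroutes its full budget into −KTS, at rate
  *b*. Compensation on is the biologically observed regime: total output
  of Frasier/Frasier equals wild-type while its −KTS output is doubled.
- **NULL** (whole-locus knockout) emits nothing.

This single mechanism reproduces the dosage series used in the allelic
comparisons: with *w* = 0.5 and compensation, expected −KTS output is
WT/WT = 1, FRASIER/NULL = 1 (at half the total output), and
FRASIER/FRASIER = 2 — the Frasier homozygote has exactly twice the
wild-type −KTS output and twice the compound heterozygote's.

Per cell, the read count is Poisson with mean `depth × total_rate / 2`,
so `depth` is calibrated to a two-WT-allele reference; each read is −KTS
with probability `rate_minus / total_rate` (binomial thinning), matching
the binomial ratio analysis applied downstream. Reads are emitted directly
as gapped alignments (no base-level sequence or aligner is simulated):
anchor lengths on each side of the gap are uniform on 10–30 nt, above the
default anchor filter, so error-free reads are always informative. The
error channel perturbs the donor-side gap edge by ±1–3 nt with probability
`error_rate`; such reads still reach the acceptor and are therefore
classified AMBIGUOUS, exercising the classifier's rejection logic without
a full sequencing-error model. Empirical junction-read depth per cell varies widely with platform and
sorting strategy; the default of 50 junction reads per cell is a
placeholder chosen so that per-cell ratio noise is binomially
non-trivial but small.

All randomness derives from one top-level seed via numpy `SeedSequence`
spawning, one child stream per cell (or per group), so output is
bit-identical across runs and platform-independent.

## Junction classification

Coordinates are 0-based half-open throughout; a splice gap is
`[first intronic base, first exonic base after the intron)` in genomic
order. On the plus strand the −KTS gap is `[donor_minus, acceptor)` and
the +KTS gap starts `alt_offset` (9) nt later. On the minus strand
"9 nt downstream" runs leftward: the gap is `[acceptor+1, donor_minus+1)`
and the +KTS donor edge sits at `donor_minus − alt_offset`. The strand and
the coordinates live in `JunctionSpec` (config, not code — the actual
genomic coordinates of the murine donors are deployment configuration).
At the SAM boundary, pysam handles the 1-based on-disk convention.

Decision rules, in order:

- wrong chromosome, no gap, or no single gap ending at the acceptor →
  `NON_JUNCTION` (multi-gap reads are evaluated only through the one gap
  that reaches the acceptor, if unique);
- gap matches the −KTS or +KTS interval exactly, anchors on both sides
  ≥ `min_anchor` (6) and mapq ≥ `min_mapq` (20) → `MINUS_KTS` /
  `PLUS_KTS`;
- gap reaches the acceptor from any other donor coordinate, or an exact
  match fails the anchor/mapq filters → `AMBIGUOUS`.

Ungapped reads lying within the 9-nt extension are *not* counted as +KTS
evidence by default — a contiguous read cannot exclude unspliced
(intronic) origin. `allow_contiguous_plus` enables them for assays where
intronic background is known to be negligible.

Counting: `NON_JUNCTION` is always excluded. With UMIs present,
deduplication is on by default (PCR duplicates would otherwise inflate
ratio confidence): reads sharing (cell, UMI) collapse to one unit with the
majority call, ties → `AMBIGUOUS`. The per-cell −KTS fraction is
`m/(m+p)` over informative units with a Wilson (default) or
Clopper–Pearson 95% interval from statsmodels; cells with no informative
units are flagged undefined rather than silently dropped. Group summaries
report mean units per cell and the pooled fraction `Σm/Σ(m+p)`, which
equals the informative-count-weighted mean of per-cell fractions.

## Scene simulation and image quantification

Scenes are 2D float images: elliptical nuclei in DAPI, circular
hard-edged dots in the MINUS/PLUS (and optionally MARKER) channels,
rendered additively with optional Gaussian noise (no point-spread
blurring — dot edges are sharp, which is what makes exact rasterised
truth possible). Each dot's truth assignment is the nucleus with the
nearest centroid, the same default rule the quantifier uses, so noise-free
scenes are exactly recoverable. The random-scene generator keeps nuclei
fully in frame and separated by more than twice (radius + dot offset),
which guarantees the nearest-centroid truth is unambiguous; it does not
emulate tissue realities such as touching or overlapping nuclei in dense
sections, out-of-focus signal, autofluorescence gradients, or intensity
variation between dots — passing the recovery tests therefore shows the
operator chain is correct, not that segmentation of real sections is
solved.

Nucleus segmentation: Gaussian smoothing (σ = 2 px) → Otsu (or fixed)
threshold → hole filling → Euclidean distance transform → peak seeding
(`peak_min_distance` = 5 px) → watershed → removal of regions below
50 px → contiguous relabelling. The distance map is smoothed (σ = 1 px)
before peak detection: discretisation plateaus along the medial ridge of
an elongated nucleus would otherwise seed spurious watershed splits,
while genuine necks between touching nuclei survive the smoothing.

Dot detection: threshold (Otsu or fixed) → 8-connected components →
minimum size 4 px → `area_um2 = area_px · pixel_size²`. Otsu is the
default for convenience on dense-signal images, but on a sparse-dot
channel whose background is pure noise Otsu places the cutoff inside the
noise distribution; for noisy synthetic scenes with unit-amplitude dots
the appropriate setting is a fixed threshold at half the dot amplitude
(0.5), which is what the recovery checks use.

Assignment: centroid containment first, then nearest nucleus centroid
within `max_dist_um` (default 10 µm — BaseScope signal is perinuclear and
a cap prevents cross-cell bleed), distance ties to the lowest label,
otherwise unassigned. The per-nucleus table carries an explicit
unassigned row per channel, so assigned + unassigned equals total
detected area exactly, by construction — checked to 1e-9 µm² (float
summation order) on randomised scenes.

Marker scoring: per-nucleus mean intensity, thresholded by a fixed cutoff
or Otsu over the per-nucleus means; the positive fraction carries an
exact binomial 95% CI. A flat set of means yields zero positives rather
than an arbitrary Otsu split.

## Statistics

- **Fold change**: ratio of group means of per-cell −KTS informative
  units (robust to unequal cell numbers, unlike pooled totals), with a
  percentile bootstrap CI (default 2000 resamples within each group) and
  a permutation p-value.
- **Permutation test**: two-sided on the mean difference;
  `p = (b+1)/(n_perm+1)` so p is never 0 and is monotone in the observed
  statistic for a fixed permutation set. An exhaustive mode enumerates
  all `C(n, n_a)` relabelings for small groups and returns the exact tail
  fraction.
- **Dose trend**: sum over dose-ordered group pairs of
  `sign(value_high − value_low)` across all cross-group value pairs
  (a Jonckheere–Terpstra-style concordance statistic), antisymmetric
  under dose reversal, with a permutation p-value as above.
- Planned contrasts are few, so no multiplicity correction is applied by
  default; Benjamini–Hochberg is available as a helper.

## Numerical and design notes

- Tie-breaks are deterministic everywhere (lowest label for equidistant
  assignments, AMBIGUOUS for UMI majority ties) so reruns are
  bit-identical.
- Degenerate inputs are states, not errors: silent genotypes warn and
  produce zero reads; blank images yield empty label maps; zero
  informative units or zero nuclei yield flagged-undefined estimates.
- How dot area "per nucleus" should be territorially attributed
  (nearest centroid vs Voronoi vs cytoplasm expansion) is genuinely open;
  nearest-centroid-with-cap was chosen as the simplest rule that is
  deterministic, parameter-light and exactly invertible on synthetic
  truth, and it is confined to one function (`assign_spots`) should a
  different rule be preferred.
- Whether published per-cell isoform ratios were computed on reads or
  UMI-collapsed units is not stated in the available text; both modes are
  supported (`dedup_umi`), defaulting to UMI units.
- Problem sizes in the test-suite and acceptance checks (200 cells/group
  at depth 100 for the fold-change comparison; 1,000 cells per fraction at
  depth 50 for ratio calibration; 10,000 reads for the classifier oracle;
  100 random scenes for conservation; 500 replicates for test
  calibration) were chosen so that each check's sampling error is well
  inside its assertion band.
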