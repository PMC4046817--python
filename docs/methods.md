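# Methods

## The analysis chain

The pipeline mirrors a genome-wide occupancy study of an archaeal
transcription factor done on two-colour tiling arrays: replicate ChIP
samples and one mock immunoprecipitation are hybridized against input DNA;
per-probe log2 ratios are normalized, smoothed and thresholded into
enriched regions; regions are annotated against ORFs and TSSs; a
binding-energy matrix predicts which regions (and which other genomic
windows) contain a recognizable binding word; a partner factor's regions
are intersected to classify co-occupancy; and two bench assays — gel-shift
titrations and qRT-PCR — are quantified by their standard estimators.

## Peak calling

* **Normalization** is duplicate averaging followed by median-centering of
  each array's log2 ratios. Nothing stronger is needed: the simulator has
  no dye or spatial bias, and median-centering is the scale-free, robust
  choice when the preprocessing of the original platform is not specified.
* **Smoothing** replaces each probe value by the median of all probe
  values within ±400 bp (window wrapping on circular genomes). A running
  median suppresses single-probe outliers completely (its breakdown point
  covers any minority of corrupted probes in the window) while preserving
  plateau heights.
* **Calling** takes maximal runs of probes with smoothed value ≥ y₀ = 1
  (i.e. 2-fold on the smoothed statistic). Consecutive passing probes more
  than `max_gap_bp` apart (default twice the probe spacing — bridging one
  missing or failing probe) split a run; runs with fewer than 3 passing
  probes are dropped. Region span is first passing-probe start to last
  passing-probe end.
* **Replicate combination** intersects the per-replicate region spans (the
  strictest reading of "present in all replicates") and then requires the
  per-replicate *maximum* smoothed log2 ratio over the candidate to exceed
  log2(fold_threshold) = 1 and the mock maximum to stay below y₀. Fold
  enrichment is 2^(mean of per-replicate maxima).

On smoothed scans with separated unimodal peaks — the caller's intended
input — region count is non-increasing in y₀ and every higher-threshold
region nests inside a lower-threshold one. On arbitrary unsmoothed signals
only the nesting holds: raising y₀ can split a bridged region in two.

## Binding-energy model

Energies are additive over motif positions and stored min-zero per
position, so the per-row argmin spells the consensus and any constant
offset of a user matrix is absorbed at load time. The theoretical
dissociation constant is the Boltzmann factor K_D(w) = K_D_cons·e^ε(w)
with ε in kT; temperature enters only through the kT unit of the supplied
matrix (no absolute-temperature parameter). Both strands are scanned
always, origin-spanning windows included on circular genomes; overlapping
± hits at one locus are both reported because real matrices are asymmetric
even when the consensus is palindromic. All threshold comparisons are
inclusive. The bundled matrix is **synthetic** — penalties invented for
demonstration, anchored at the published consensus word and a 63 nM
consensus-affinity magnitude; users supply their own measured matrix for
real work.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

| parameter | default | meaning |
|---|---|---|
| genome_length | 200 kb | circular chromosome (real target ≈ 3 Mb; scaled for test speed) |
| n_genes | 60 | non-overlapping ORFs (600–1200 bp), TSS 10–60 bp 5′ of each start |
| probe_step / probe_length | 25 / 50 bp | tiling density (~2× sparser than the real platform) |
| fragment_length | 500 bp | half-width of the triangular sonication kernel |
| peak_log2_amplitude | 2.5 | log2 ratio of a fully occupied site (2^2.5 ≈ 5.7-fold, mid-range of reported array folds) |
| noise_sd | 0.25 | per-probe log2 noise, drawn independently per probe, duplicate and array |
| protein_conc | 1 µM | sets occupancy = P/(K_D+P) of planted sites |
| n_replicates | 3 (+1 mock) | replicate structure of the study design |

Planted words are designed by greedy mutation of the consensus until the
realized K_D is within a factor 1.5 of the requested one (the bundled
matrix carries sub-0.4 kT penalties, so any reachable target can be
approached within ln 1.5). Signal is the occupancy-weighted sum of
triangular kernels — the simplest shape consistent with uniformly random
sonication breakpoints, and the distribution the study itself leaves
unspecified. Permissivity is a hard gate: a non-permissive site contributes
zero signal regardless of affinity, modelling chromatin that excludes the
factor in vivo. The mock array is pure noise.

What the generator does **not** model: sequence-composition realism
(repeats, IS elements), dye bias, spatial array artifacts, cross-reactive
mock signal, fragment-size heterogeneity, or occupancy competition between
overlapping sites. Passing tests therefore demonstrate the correctness of
the computational chain under the assumed noise model, not robustness to
platform-specific artifacts of real arrays.

## Quantitation

* **Isotherm fitting** uses the single-site hyperbola f = P/(K_D+P) by
  nonlinear least squares (initial guess: concentration nearest
  half-saturation), standard error from the fit covariance. A Hill
  exponent is available behind a flag but is off by default — the
  complexes quantified here involve at most two dimers and a plain K_D is
  the reported quantity. Titrations that never reach 30% saturation
  produce a warning rather than an error. At 3% densitometric noise on an
  8-point titration the estimator's relative error has a ~12% 95th
  percentile, so single-fit values should be read with that width in mind.
* **Relative expression** is 2^−ΔΔCt with per-biological-replicate pairing
  of target and reference Cq; per-replicate folds are averaged and their
  SD reported; significance is a two-sided Welch t-test on the two ΔCt
  groups (robust to unequal variances; the exact test flavour is a free
  choice here). No amplification-efficiency correction is applied — the
  estimator is deliberately the classic pure-base-2 method. The estimator
  is invariant to any constant added to all Cq values of one biological
  replicate, since the reference subtraction cancels it.
* **ChIP-qPCR enrichment** is 2^[(ΔCq_target) − (ΔCq_reference)] with
  ΔCq = Cq_input − Cq_IP against a spiked non-genomic reference fragment.

## Co-occupancy classes

Primary-factor regions are extended by 500 bp — half a sonication fragment,
the physical scale over which a crosslinked complex smears — before
intersection (the extension is a flag). Overlap percentage uses the
extended primary region as denominator. Classes I/II/III are assigned
strictly from the four evidence flags; any combination violating the
expected inverse-correlation pattern (e.g. both motifs present) is
surfaced as `unclassified`, never forced. The bundled curated survey keeps
footnoted motif annotations (`-*`) verbatim in a notes field without
inventing semantics for the footnote; its in vitro flags are reconstructed
from motif presence, which is exactly the inverse-correlation pattern the
survey reports.

## Numerical and convention choices

* All internal coordinates are 0-based half-open on a single chromosome;
  BED is native, GFF3 (1-based inclusive) converted only in `chiptile.io`.
* Region centers are floor midpoints — peaks have probe resolution, so
  sub-bp precision is meaningless. TSS distances are minimal circular
  distances, negative when the center lies 5′ of the gene; ties between
  equidistant TSSs go to the lower coordinate.
* Motif-scan ties in `best_hit_in_region` break by smaller start, then +
  strand.
* Degenerate inputs: regions narrower than the motif yield no hit;
  all-identical probe ratios center to zeros with a warning; unreachable
  planting targets raise an error naming the maximal attainable K_D.

## Problem sizes

Tests and the acceptance script run the full chain on 200 kb genomes
(8,000 probes × 2 duplicates × 4 arrays) over 10 seeds, exhaustive-oracle
comparisons on ≤ 2,000-probe scans and 5 kb sequences, 100-seed isotherm
and 200-seed ΔΔCt calibrations — sizes chosen so the whole suite completes
in well under a minute while leaving every statistical check
well-powered.

## Known limitations

* The co-occupancy pipeline proxies in vitro evidence by motif presence
  when no binding-assay table is supplied; real analyses should provide
  measured flags.
* The caller reports one region per contiguous super-threshold run; two
  sites closer than roughly a fragment length merge into one region.
* K_D calibration is entirely delegated to the user-supplied consensus
  anchor; theoretical K_D values are meaningful relative to each other,
  not absolutely, unless the anchor is measured.
* The circular-genome machinery assumes a single chromosome; multi-contig
  inputs are rejected rather than handled.
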