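# chiptile

Genome-wide occupancy analysis for archaeal transcription factors from
ChIP-chip tiling arrays, built around the Lrp-family regulator Ss-LrpB of
*Sulfolobus solfataricus* and its partner factor LysM.

The package is for researchers who want to reproduce, stress-test or adapt
this kind of analysis chain without access to the original arrays: every
input — genome, annotation, probe tables, binding-energy matrix, titrations,
Cq tables — can be simulated with planted ground truth, so each stage of the
pipeline is checkable against what was put in.

## What it computes

**Enriched-region calling.** Per array, technical duplicate probes are
averaged, log2(ChIP/input) ratios are median-centered, and each probe value
is replaced by the running median over ±400 bp. Maximal runs of probes with
smoothed value ≥ y₀ (default y₀ = 1) become candidate regions; a region is
retained only if the maximum smoothed log2 ratio exceeds log2(2) in **all**
replicates (fold enrichment > 2) and stays below y₀ in a mock
immunoprecipitation. Fold enrichment is reported as 2^(mean over replicates
of the per-replicate maxima).

**Binding-energy motif scanning.** A 15 × 4 position matrix gives additive
free-energy penalties ε in kT relative to the consensus word
(`TTGCAAAATTTGCAA` for this motif family). A word *w* scores
ε(w) = Σᵢ E[i, wᵢ], and its theoretical dissociation constant is the
Boltzmann relation

    K_D(w) = K_D(consensus) · e^ε(w)

Both strands of the (circular) genome are scanned; windows with
K_D ≤ 14 µM are reported genome-wide, in 200 bp windows upstream of each
ORF start, and within called regions.

**Annotation and co-occupancy.** Regions are classified by genomic context
(intergenic-overlap vs exclusively intragenic, subdivided by the number of
ORFs touched) and by signed circular distance from peak center to the
nearest TSS. Two factors' region sets are intersected (primary regions
extended by 500 bp) and each pair is assigned a co-occupancy class from
motif and in vitro evidence: class I (primary factor binds directly),
class II (partner binds directly), class III (neither — recruitment by a
third party), plus gene-level classes IV (bound in vivo by the primary
factor alone) and V (bound in vitro only — non-permissive chromatin).

**Wet-lab quantitation.** Gel-shift titrations are fitted with the
single-site isotherm f = P/(K_D + P); relative expression is estimated by
2^−ΔΔCt against a reference gene (*tbp*) with a Welch t-test on per-replicate
ΔCt values; ChIP-qPCR enrichment folds are computed against a spiked
reference fragment and compared to array folds by Spearman correlation.

## Worked example

Generate a study-scale synthetic dataset (200 kb circular genome, 60 ORFs,
six permissive planted sites of graded affinity plus two high-affinity sites
blocked by non-permissive chromatin, three ChIP replicates + mock) and run
the full analysis:

```sh
cd analysis
python 01_simulate_dataset.py
python 02_call_regions.py
```

`02_call_regions.py` prints:

```
6 enriched regions (threshold y0=1, fold>2 in 3/3 replicates, mock<y0):
  region1: [ 14700,  15275)  fold 2.62  center 14987 (planted 15000, error 13 bp, permissive=True)
  region2: [ 51750,  52250)  fold 2.45  center 51999 (planted 52000, error 1 bp, permissive=True)
  ...
sensitivity 6/6; regions written to results/regions.bed
```

Every permissive planted site is recovered within tens of base pairs (well
inside half a sonication fragment), with fold enrichments in the 2.2–10.8
range typical of such arrays, and no false regions. `03_scan_motifs.py`
then shows the permissivity contrast — the two blocked sites are found by
the scanner (they have consensus-grade K_D) but never by the caller:

```
  pos  70000  K_D    63.0 nM  permissive=False  in_scan=True   in_regions=False
```

`05_cobinding.py` reclassifies the bundled 29-record Ss-LrpB/LysM
co-occupancy survey from its evidence flags (10 class I, 5 class II,
14 class III, all agreeing with the curated classes), and
`06_quantify.py` recovers planted quantities:

```
isotherm fit: K_D = 61.6 +/- 3.0 nM (generated at 63 nM)
  crisprB       planted 0.5     estimated 0.5329 +/- 0.08 (p = 0.0012)
  lrpB          planted 0.0031  estimated 0.00304 +/- 0.0005 (p = 2.9e-06)
```

The same stages are available as CLI subcommands
(`chiptile simulate|callpeaks|scan|annotate|cobind|quant|run`); `chiptile
run --config config.yaml --outdir out` executes the whole chain from a flat
key/value config and writes a parameter-echoing run log.

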