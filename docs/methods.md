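# Methods

This note records how `resectseq` turns strand-specific end-capture
sequencing into resection statistics, what the synthetic-data generators
model, and every numerical convention the implementation commits to.

## 1. Signal model

S1-seq and Exo7/T-seq capture the free end left after single-stranded DNA
flanking a meiotic DSB is trimmed back to duplex: each sequenced read ends
at the nucleotide adjacent to the ligated adaptor, so a read endpoint marks
either a resection endpoint or an unresected break end. Because 5'-strand
loss proceeds away from the break on both sides, resection endpoints appear
on the **top strand to the right** of a hotspot center and on the **bottom
strand to the left**. Around a hotspot we therefore expect up to four
signal components:

1. **resection endpoints**, a broad peak ~0.3–2.5 kb from the center on
   the resection-polarity strand;
2. **central signal** from recombination intermediates (wild type) or
   unresected DSBs (initiation mutants), tightly clustered at the center;
3. a **strand offset of the central peak** when SPO11 cuts the same
   molecule more than once (end capture reports only the outermost ends,
   so the top-strand central peak shifts right and the bottom-strand peak
   left by half the cut spacing each);
4. flat **background**.

## 2. Profile construction

Given per-base strand-specific endpoint counts (bedGraph) and a hotspot
list (5-column BED; center = interval midpoint, score = hotspot strength):

- **Windowing.** A ±2,500 bp window (per-base) is extracted around every
  hotspot center on each strand. Hotspots whose window leaves the
  chromosome are skipped and logged.
- **Co-orientation.** Bottom-strand windows are mirrored (x → −x) onto the
  top-strand frame so leftward and rightward resection average together;
  each hotspot contributes two rows.
- **Averaging.** The genome-average profile is the column mean over rows
  (optionally strength-weighted).
- **Background subtraction.** The background level is the mean of the
  101-bp stretch ending at +2,500 bp (toward the interior for the
  bottom-strand frame at −2,500 bp); it is subtracted everywhere.
  Averaging over 101 bp rather than reading the single base at 2,500 bp
  stabilizes the estimate; `bg_halfwidth=0` reproduces the literal
  single-base reading.
- **Smoothing (display and mode only).** Hann window, 151 bp for
  co-oriented profiles and 51 bp for strand-offset profiles. The kernel is
  w(n) ∝ 1 − cos(2πn/(N−1)), normalized to unit sum, with edge
  renormalization by local kernel coverage so interior-supported signal
  totals are conserved to numerical precision.
- **Normalization.** `peak` divides by the maximum over [+100, +2,500];
  `auc` divides by the sum over [−1,000, +2,500]. Negative values are
  clamped to zero for display *after* these steps; metrics receive the
  unclamped subtracted profile and clamp internally where needed.

## 3. Summary statistics

- **Mean resection length.** The clamped co-oriented signal on
  [+100, +2,500) is split into 24 contiguous 100-nt bins; the mean is the
  bin-fraction-weighted average of bin midpoints (so the estimand is the
  binned conditional mean of tract lengths, not the raw sample mean). The
  statistic is NA with a `no-resection-signal` flag when the raw
  (unclamped) window sum is non-positive or below 5% of the raw profile
  total — raw sums are used for this detection test because clamping
  would rectify mean-zero sampling noise into apparent signal, making
  detection depend on sequencing depth.
- **Modal resection length.** Argmax of the 151-bp-Hann-smoothed profile
  on [+100, +2,500]; ties break toward the smallest position.
- **Central-to-resection AUC ratio.** Clamped sum over [−300, +100)
  divided by the clamped sum over [+100, +2,500); half-open windows so
  +100 is counted exactly once, on the resection side.
- **Strand center offset.** Both strand profiles are smoothed (51-bp
  Hann); the offset is the top-strand argmax minus the bottom-strand
  argmax within ±400 bp of the center, ties resolving toward the smallest
  magnitude. Positive = double-cut signature. A cross-correlation variant
  (`method="xcorr"`) reports the lag maximizing strand alignment.
- **Heatmaps.** Per-hotspot strand signal on ±2,000 bp in 40-bp bins,
  rows ordered by descending hotspot strength and normalized to unit sum;
  decile codes are assigned to the pooled nonzero bin values by rank,
  anchored at the top so the pooled maximum always lands in class 10 and
  class sizes differ by at most one.
- **Focus colocalization.** A focus is axis-associated when its minimum
  distance to any axis polyline is ≤450 nm (inclusive). Co-focus
  *fractions* use the per-focus nearest-neighbor rule at ≤320 nm;
  interfocus *distances* come from exclusive greedy pairing (closest
  unpaired A–B couple first, deterministic tie-breaks), one distance per
  physical pair. Conditions are compared with Welch's unequal-variance
  two-sided t test (Welch–Satterthwaite degrees of freedom).

## 4. Synthetic data generators

`SimParams` drives a four-class mixture over hotspots whose strengths are
log-normal and whose centers are uniform (optionally with a minimum
spacing; see limitations):

| parameter | default | meaning |
|---|---|---|
| `frac_resected` | 0.65 | tract endpoints at center ± d, d = `resection_min` + Gamma(`resection_shape`=13.4, `resection_scale`=82), resampled above `resection_max`=3,000 nt. The default law has mode ≈1,017 nt and mean ≈1,099 nt, a wild-type-like regime |
| `frac_unresected` | 0.0 | central reads with N(0, `central_sd`=50) dyad jitter; with probability `doublecut_prob` the molecule is double-cut with spacing = 30 + 10·k nt, k geometric with mean `doublecut_n_periods_mean`=1.5 (10-nt periodicity), and only the outermost ends are reported |
| `frac_intermediate` | 0.27 | symmetric central signal (stand-in for recombination intermediates; their true strand pattern is not modeled) |
| `frac_background` | 0.08 | uniform genome-wide, both strands |

Every dataset carries a `TruthRecord` with the realized tract lengths, the
truth-binned conditional mean (the mean-length estimand), realized
double-cut spacings, and the analytic noiseless central/resection ratio
(`expected_central_ratio`, integrating each class's placement law over the
metric windows).

`simulate_ssds_coverage` lays one fixed-length occupancy segment per tract
(`end-proximal`, `end-distal`, or `uniform`), preserving strand polarity —
coverage-style tracks for DMC1-, RAD51-, or RPA-like factors.

`FociSimParams` builds 2-D fields: wavy axis polylines (reflected random
walks), co-focus pairs seeded on axes with probability
`frac_axis_associated` (Gaussian placement jitter), partner foci one
folded-normal distance away in a uniform direction. The folded-normal
location is solved (Brent root-finding on the closed-form folded mean) so
the *realized* mean distance equals `interfocus_mean` exactly; targets
below the folded-normal floor sd·√(2/π) are unattainable and clamp to the
closest achievable mean.

## 5. Numerical conventions

- Window conventions: metric windows [−300, +100) and [+100, +2,500) are
  half-open; display/normalization windows [−1,000, +2,500] and AUC window
  [−1,500, +2,500] are inclusive.
- All argmax tie-breaks are deterministic (smallest position, or smallest
  magnitude for the strand offset).
- Identical parameters and seed give byte-identical outputs; every CLI
  stage writes a manifest with input SHA-256 digests.
- Raw tracks must be integer counts; RPM tracks (`--units rpm`) accept
  floats and scale by 10⁶/total mapped reads.
- MAPQ filtering of alignment tables is inclusive at the threshold
  (default ≥20).

## 6. Full-scale reproduction recipe (not desk-scale)

The genotype-level benchmark numbers (e.g. wild-type modal resection
length ≈1,015 nt, mean ≈1,100 nt) require the deposited mouse data and an
alignment step that exceed this package's test scale. To reproduce them:

1. Download raw S1-seq / Exo7/T-seq reads from GEO series **GSE266258**,
   **GSE266151**, and **GSE266271** (additional S1-seq / Exo7/T-seq data
   in GSE265863 and GSE229450; SSDS in the same series).
2. Align to the mouse genome (mm10) with a standard aligner; filter to
   MAPQ ≥ 20; reduce each read to its endpoint nucleotide adjacent to the
   adaptor, keeping strand; convert per-base endpoint counts to two
   bedGraph files (top/bottom strand) via
   `resectseq.endpoints_from_alignments` or `bedtools genomecov -dz`.
3. Take SPO11-oligo hotspot centers and strengths from **GSE84689**,
   formatted as the 5-column hotspot BED.
4. Run the pipeline per genotype:
   `resectseq profile --top ... --bottom ... --hotspots hotspots.bed
   --chrom-sizes mm10.chrom.sizes --units rpm --out prof/` followed by
   `resectseq metrics --profile prof/oriented_profile.tsv --top
   prof/top_profile.tsv --bottom prof/bottom_profile.tsv --out met/` and
   `resectseq compare --summaries ... --labels ...`.

## 7. Limitations

- The intermediate class's strand pattern is modeled as symmetric; the
  real strand disposition of recombination-intermediate signal is not.
- The metaplot estimators assume hotspot windows are isolated. Real mouse
  hotspot maps average ~1 hotspot per 180 kb; if hotspots are placed much
  denser than that (as the simulator permits), neighboring central peaks
  enter each other's windows and inflate apparent resection-window
  signal. `hotspot_min_spacing` enforces isolation in simulations.
- Greedy exclusive pairing underestimates interfocus distances when focus
  density approaches one pair per interfocus distance along an axis
  (partner stealing); keep per-cell focus counts realistic (hundreds, not
  thousands) and pool across cells.
- 2-D focus analysis ignores the axial (z) component of true 3-D
  distances, as do the maximum-intensity projections it models.
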