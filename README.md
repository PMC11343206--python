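# resectseq

Quantify meiotic DNA double-strand-break (DSB) end resection from
strand-specific end-capture sequencing (S1-seq, Exo7/T-seq), with SSDS
coverage profiling, super-resolution focus colocalization statistics, and
a matched synthetic-data generator with ground truth.

## Science

Meiotic recombination starts when SPO11 cuts the genome at hotspots. The
5'-terminated strands flanking each break are then nucleolytically resected,
exposing 3' single-stranded tails that drive homology search. End-capture
methods trim the single-stranded tails and sequence up to the resulting
duplex end, so **each read endpoint marks a resection endpoint** (or an
unresected break). Resection moves rightward on the top strand and leftward
on the bottom strand, which makes the signal strand-asymmetric around each
hotspot and lets a strand-aware pipeline separate:

- **resection endpoints**: a broad peak ~0.3–2.5 kb from hotspot centers,
- **central signal**: recombination intermediates or unresected breaks at
  the center,
- **double-cut offsets**: when SPO11 cuts a molecule more than once, only
  the outermost ends are captured, shifting the top- and bottom-strand
  central peaks apart,
- flat **background**.

`resectseq` builds co-oriented genome-average profiles from these tracks
and reduces them to four statistics:

- **mean resection length** — signal on [+100, +2500) bp split into 24
  100-nt bins; mean = Σ fᵢ·mᵢ over bin fractions fᵢ and midpoints mᵢ;
- **modal resection length** — argmax of the 151-bp Hann-smoothed profile
  on [+100, +2500];
- **central/resection AUC ratio** — area on [−300, +100) over area on
  [+100, +2500), an index of unresected/intermediate signal;
- **strand center offset** — distance between top- and bottom-strand
  central peaks (the double-cut signature).

It also scores SIM microscopy focus fields: axis association (≤450 nm to
an axis polyline), co-focus detection (≤320 nm), interfocus distance
statistics, and Welch's t test between conditions.

See `docs/methods.md` for every numerical convention.

## Worked example

Simulate a wild-type-like dataset (2,000 hotspots, 2×10⁶ reads), build
profiles, and compute the summary:

```bash
resectseq simulate --seed 0 --n-hotspots 2000 --total-reads 2000000 --out sim
resectseq profile --top sim/endpoints_top.bedgraph \
    --bottom sim/endpoints_bottom.bedgraph --hotspots sim/hotspots.bed \
    --chrom-sizes sim/chrom.sizes --out prof
resectseq metrics --profile prof/oriented_profile.tsv \
    --top prof/top_profile.tsv --bottom prof/bottom_profile.tsv --out met
head -6 met/summary.json
```

prints (exactly, for this seed):

```json
{
  "mean_length": 1084.961371241689,
  "modal_length": 1017.0,
  "central_ratio": 0.41036147070246454,
  "auc": 446.2294826732673,
  "strand_offset": -1.0,
```

The simulator's ground truth (`sim/truth.json`) for the same run records a
truth-binned conditional mean of 1098.74 nt and an analytic noiseless
central ratio of 0.4022 — the estimators recover the mean within ~14 nt
and the ratio within 0.009 at this depth. The default tract-length law,
Gamma(shape 13.4, scale 82), has mode ≈1,017 nt and mean ≈1,099 nt.

Focus fields work the same way (150 co-foci per cell is a realistic
spread density; see `docs/methods.md` on crowding):

```bash
printf 'foci:\n  n_cofoci: 150\n  n_lone_fociA: 5\n  n_lone_fociB: 10\n' > foci.yaml
resectseq simulate-foci --config foci.yaml --seed 0 --out fsim
resectseq foci --axes fsim/axes.csv --a fsim/fociA.csv --b fsim/fociB.csv --out fstats
```

`fstats/foci_stats.json` then reports, for this seed, an axis-associated
fraction of 0.890 (A channel), an interfocus mean of 98.61 nm with SD
64.45 nm over 136 exclusive pairs — against generator targets of 0.9
axis association and a 103.3 nm mean distance.

Python API equivalents are exposed at package level
(`resectseq.simulate_endpoint_dataset`, `extract_oriented_matrix`,
`average_profile`, `subtract_background`, `summarize_profiles`,
`analyze_field`, ...).

## Layout

- `src/resectseq/io.py` — bedGraph/BED/chrom.sizes/alignment-table I/O
- `src/resectseq/profiles.py` — window extraction, co-orientation,
  averaging, background subtraction, Hann smoothing, normalization,
  decile heatmaps
- `src/resectseq/metrics.py` — resection summary statistics
- `src/resectseq/simulate.py` — endpoint/SSDS/focus-field generators with
  ground truth
- `src/resectseq/foci.py` — axis association, co-focus pairing, Welch test
- `src/resectseq/cli.py` — `resectseq` command-line pipeline
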