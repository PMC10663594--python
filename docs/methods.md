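# Methods

This note documents the models behind `impedimap`, the defaults that
matter, what the synthetic plate emulates (and does not), and the
numerical choices made where the design was genuinely open.

## Measurement model

Each electrode is driven with a sum of four sine tones and the return
current is converted to a voltage by a transimpedance amplifier (TIA)
with feedback resistance R₂ = 18 MΩ. Per-field stimulation amplitudes
(V), lowest to highest tone:

| field | 250 Hz | 1 kHz | 4 kHz | 16 kHz |
|---|---|---|---|---|
| lateral (LF) / electrode (EF) | 0.20 | 0.08 | 0.04 | 0.02 |
| vertical (VF) | 0.25 | 0.10 | 0.04 | 0.025 |

Amplitudes fall with frequency because cell-membrane impedance is
capacitive; the scaling keeps TIA output amplitudes comparable across
tones. Demodulation is a plain FFT over one acquisition window with the
magnitude read at each tone's bin and converted back to impedance by
|Z| = V_stim · R₂ / V_out; a zero TIA output maps to an infinite-|Z|
flag rather than an exception.

**Window and conventions.** The window is exactly 4 ms — one period of
the 250 Hz tone — at a sample rate that is an integer multiple of
250 Hz (default 1 MHz for synthetic traces, ≥ 60× the top tone), so all
four tones are bin-aligned and there is no spectral leakage. Magnitudes
are reported as *peak* sinusoid amplitudes (a pure A·sin tone yields A),
not RMS; this is a convention of this implementation, not an instrument
fact. Phases are sine-referenced, wrapped to (−π, π], and NaN-flagged
where the bin magnitude is numerically zero (a zero-magnitude phase is
meaningless and reporting 0 would be misleading).

**Scan schedules.** The 64 × 64 array is read 16 electrodes at a time.
For VF, each of the 256 4 × 4 readout tiles is measured with a full
16 × 16 bias block centered on it; near the array edge the block is
clamped inside the array (the tile then sits off-center but the block is
never partial), giving 256 steps that cover each electrode exactly once.
For LF/EF, each step records the 16 electrodes of a 4 × 4 super-grid
with 16-electrode stride — the simplest pattern that satisfies the
≥ 12-electrode spacing needed to suppress cross-electrode coupling —
again 256 steps. The LF cross-electrode transfer (stimulate one
electrode, sense its neighbor) is abstracted: the simulator supplies the
neighbor-coupled trace directly and the demodulator is geometry-agnostic.

## Image features

* **Masks.** A reference scan in cell-free media calibrates each
  electrode. A pixel is *cell-covered* when its VF 4 kHz magnitude
  exceeds the per-pixel reference by `threshold_rel` (default 0.20, i.e.
  20 % above reference — a relative threshold, calibrated on simulator
  ground truth; no published numeric value exists). A pixel is *epoxy*
  (occluded by well-attachment adhesive) when its reference value
  deviates from the reference median by more than 50 %; epoxy pixels are
  excluded from every downstream statistic.
* **Confluence** is the percentage of non-epoxy electrodes in the cell
  mask. **Masked medians** summarize each parameter map over cell pixels
  only, which separates genuine barrier/adhesion changes from simple
  coverage loss. Wells with an empty mask propagate NaN sentinels rather
  than dropping rows, keeping plate tables rectangular.
* **Normalized RMS** (motility): RMS of the pixel-wise difference of two
  frames over non-epoxy pixels, divided by the cell-masked median of the
  current frame. The default frame lag is 1 (consecutive 15-min scans);
  a second trace at lag 4 (1 h) captures slower migratory movement and
  feeds the long-term-movement functional index. The statistic is
  scale-invariant by construction.
* **Dome detection.** Transepithelial water transport lifts epithelial
  sheets in transient domes (~150 µm) that appear as circular decreases
  in the LF 16 kHz attachment map. The detector (an artifact of this
  package — only the phenotype is published) median-filters the map
  (3 px), thresholds 25 % below the cell-masked median, labels connected
  components, and keeps regions with equivalent diameter 4–10 px
  (100–250 µm at 25 µm pitch). At the default multiplicative noise
  (σ = 0.05 lognormal) the 25 % depth gate leaves no false positives on
  uniform maps across 1000 seeds while still catching the simulator's
  50 %-deep domes.
* **Barrier normalization.** Electrode impedance times the effective
  electrode area (25 × 25 µm² = 6.25 × 10⁻⁶ cm²) gives an Ω·cm²
  resistance-area product directly comparable to trans-well TEER.

## Heterogeneity scoring

Per condition, per timepoint, the per-pixel normalized RMS values of 3
wells are pooled (plain concatenation, no per-well weighting). The
first-order 1-D Wasserstein distance of the experimental pool to each
pure-population reference pool is combined as
s_A = d_B / (d_A + d_B), s_B = 1 − s_A. This is the bounded reading of
"complement of the distance ratio": it pins the anchors — a pure
population scores 1 toward its own reference, and a 50/50 mixture of two
populations scores exactly 0.5 toward both, because the mixture CDF is
the midpoint of the reference CDFs so both distances equal half the
inter-reference distance regardless of distribution shape. (The
alternative 1 − d_A/d_B is unbounded and violates the anchors.) Scores
before +5 h after plating are flagged invalid: the attachment/spreading
transient dominates motility there. The window is a configuration value,
asserted rather than derived.

## Compound profiling

* **Normalization.** Every parameter trace is divided by its value at
  the scan nearest to 1 h before compound addition (required within half
  a scan interval; non-positive baselines exclude the well with a
  recorded reason) and resampled (nearest scan) onto 16 timepoints
  log-spaced over (t_add, t_add + 48 h], first point one scan interval
  after addition. Sixteen points resolve both sub-hour binding effects
  and slow 48 h trends while keeping the feature matrix small; the
  published analysis states log spacing but not the count. Confluence is
  normalized like the others for profiling, with the raw percent trace
  retained for the death metrics.
* **Phenoactivity** = √( Σ_{p,t} (x_pt − DMSO_pt)² / (n_p·n_t) ), the
  RMS residual against the mean vehicle profile over all parameters and
  timepoints — one concrete reading of a "modified residual sum of
  squares"; the normalization makes scores comparable across grid sizes.
  The activity gate is DMSO mean + 2σ. With the gate estimated from 78
  vehicle wells (the DMSO count a 13-plate screen pools) the measured
  null pass rate is ~2.7 % — slightly above the Gaussian 2.3 % because
  phenoactivity scores are mildly right-skewed and the gate itself is
  estimated from a finite sample.
* **Bio-basis** (11 metrics from 5 parameters): signed trapezoidal AUCs
  of (compound − DMSO), positive part for attachment↑ / barrier↑ /
  dynamicity↑ / flatness↑ and negative part (as magnitude) for
  detachment↓ / barrier-loss↓ / staticity↓ / cell-height↓; cell death =
  largest confluence deficit vs DMSO (percentage points); death rate =
  steepest confluence decline (%/h); plus phenoactivity. The
  parameter→metric routing (attachment/detachment ← LF 16 kHz, barrier ←
  VF 250 Hz, dynamicity/staticity ← RMS, flatness/height ← VF 16 kHz,
  death ← confluence) is an interpretation of the published radar-plot
  naming. The count reads as 10 summary metrics + phenoactivity = 11.
* **Functional indices** (7 per cell type): growth rate is the
  least-squares slope of confluence over the first 12 h; the six
  steady-state indices are means over 36–48 h of their mapped parameter
  (flatness ← VF 16 kHz, tissue barrier ← VF 250 Hz, cell-cell adhesion
  ← VF 1 kHz, attachment ← LF 16 kHz, short/long-term movement ← RMS at
  lag 1/lag 4). Indices are min-max scaled across the cell-type panel,
  so 0.5 is the *range midpoint* (not the median, despite the common
  informal reading). At least two cell types are required.
* **Clustering/classification.** Features are z-scored per column, PCA
  keeps the top 20 components, and Ward agglomerative clustering cuts
  the dendrogram either at a requested cluster count/distance threshold
  or, by default, inside the largest gap between consecutive merge
  distances (the natural cut for well-separated data; all-identical
  input collapses to one cluster). The LDA classifier is validated on a
  stratified 80/20 split with macro-averaged precision (per-class values
  are also emitted); a randomized-label control must fall to chance.
  Edge wells (plate columns 1 and 12) are excluded by role in the screen
  layout, and plate-level controls sit on the interior.

## Synthetic plate model

The simulator is the test substrate: it generates plates whose latent
truth is known exactly.

* **Growth** is seeded neighborhood colonization: new pixels attach to
  the colony frontier, with the expected pixel count following coupled
  logistic growth (shared carrying capacity, one rate per population) so
  co-cultures with a growth-rate advantage are taken over by the faster
  type. Seeding density maps to initial coverage via 40 000 cells/well ≙
  full coverage, so the default 15 000 cells/well starts near 37 %.
* **Latent drivers** per archetype: attachment rises with a saturating
  time constant and optionally collapses after a water-transport peak;
  barrier switches on when confluence crosses an onset threshold
  (tight-junction formation) and rises exponentially; flatness spikes
  shortly after plating (suspended cells settling and spreading) on top
  of a slow steady term; motility sets the amplitude of per-pixel
  frame-to-frame jitter; suspension archetypes have no barrier and
  minimal attachment. Compound kernels multiply these drivers (and
  viability, which scales realized pixel counts) after an onset delay;
  DMSO is the identity.
* **Rendering**: each map is a per-map base level × a per-pixel
  electrode relief (lognormal, σ = 0.1, drawn once per well — fixed
  electrode-to-electrode variation) × (1 + latent contrast) × lognormal
  measurement noise (σ = 0.05 per pixel per frame). Routing: barrier →
  VF 250 Hz, flatness → VF 16 kHz, attachment → LF 16 kHz (with dome
  discs stamped as 50 % depressions), cell-mask contrast → VF 4 kHz;
  remaining maps carry generic occupancy contrast. Doming events arrive
  as a Poisson process after the attachment peak with diameters 4–8 px
  and 1–3 h lifetimes. Raw traces can be synthesized per electrode as
  Σ_f (A_f/|Z_f|)·R₂·sin(2πft) + DC + noise, the exact inverse of the
  demodulator in the noiseless case (round-trip agreement ≤ 10⁻⁶
  relative).
* **What it does not emulate:** electrode–electrolyte electrochemistry
  (double layers, Debye capacitance), amplifier nonlinearity, real
  absolute signal magnitudes per cell type (published only graphically;
  archetype scales are package choices), optical ground truth, or
  single-cell behavior. Passing tests therefore demonstrate that the
  *analytics* recover known latent structure under a plausible noise
  model — not that the archetypes quantitatively match any real line.

## Problem sizes and determinism

All randomness flows from `numpy.random.SeedSequence` spawns of a single
root seed, so datasets are bit-reproducible and independent of well
iteration order. The benchmark experiments are sized for a desk run:
mixture scoring uses 3 wells × 4096 pixels per condition over 20 seeds;
the control-screen classification simulates 13 replicates of 5 control
kernels + DMSO at map level, rendering only the ~60 scans the profile
grid actually needs per well; the gate calibration runs 1000 Monte-Carlo
iterations at profile level (the map renderer would add nothing to a
pure score-distribution question). A full plate at instrument scale
(96 wells × 192 scans × 27 maps) streams through simulate → features →
profile well by well — only one well's movie is ever resident — in
about 9 minutes on one CPU, writing a ~14 GB container; tests exercise
the same path on plate slices.

## Known limitations

* The heterogeneity module recovers the mixture composition of two
  RMS-separable populations; it does not identify biology (e.g. EMT
  state) and degrades as the populations' motility distributions
  overlap.
* The dome detector is size- and depth-gated; domes outside 4–10 px or
  shallower than the 25 % gate are invisible, and overlapping domes
  merge into one component.
* Functional indices are only defined relative to a panel (min-max
  scaling); adding a cell type rescales everyone.
* The classifier workflow assumes classes are represented ≥ 2× so the
  stratified split is defined; single-replicate screens need the
  clustering path instead.
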