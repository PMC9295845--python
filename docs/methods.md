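# Methods

## The problem

EEG/EMG polysomnography is the gold standard for sleep/wake staging in
mice, but it requires electrode implantation surgery and days of recovery,
which makes it a poor fit for high-throughput screening. Video somnography
replaces it with a behavioral criterion: a mouse that has been continuously
immobile for long enough is asleep. `somnivid` implements such a pipeline
for singly housed mice filmed from above under infrared illumination,
together with the agreement metrics used to validate it against an EEG/EMG
reference and a synthetic cage simulator that provides exact ground truth.

## Pipeline

### Stage 1 — mouse detection

Each analysed frame is Gaussian-smoothed (σ = 2 px) and converted to an
absolute-deviation image `|frame − median(frame)|`. The median approximates
the background gray, so the same rule finds a dark mouse on light bedding
(light phase) and a bright mouse on a dark background (infrared dark
phase). Foreground is the union of

* an adaptive threshold (`deviation > local Gaussian mean + 5`, block
  51 px), which is sensitive to edges, and
* a global Otsu threshold on the deviation image, which captures blob
  interiors;

holes are filled and connected components smaller than 25 % of the expected
mouse area are discarded. Several regions of interest (ROIs) may survive —
food hoppers, water gel, and shadows produce stable blobs — deliberately,
so the true mouse region is never lost at this stage. A binary patch
classifier scores every candidate ROI and the highest-confidence one is
designated the mouse; ties are broken by larger area, then lower row index.
When no ROI survives, the last valid detection is carried forward for up to
2 s (and treated as evidence of immobility); longer gaps are flagged and
the affected samples are counted as *active*, because immobility cannot be
attested without seeing the animal.

The thresholding parameters (σ, block size, offset, minimum area) are
engineering choices exposed in `VisionParams`; nothing downstream is
sensitive to them on clean footage.

### Patch classifier

The classifier only needs to output a confidence in [0, 1] per cropped ROI,
so the backbone is pluggable. The default is logistic regression on 8×8
downsampled intensities plus intensity/shape statistics, trained by
minibatch SGD on the cross-entropy loss with a fixed learning rate of
0.001 for 50 epochs and an 80/20 train/validation split (batch 32,
momentum 0.9 where applicable — batch size and momentum are declared
defaults, not derived). A small MLP backbone on the same features is
included and used to check that staging is insensitive to the backbone
choice. A deep (ResNet-style) backbone slot exists but requires torch; no
parity with any externally trained network is claimed, since that depends
entirely on the training frames used.

Training patches for simulations are harvested exactly the way the detector
produces them at run time: ROI candidates are extracted from rendered
frames, cropped by bounding box, and labeled by whether the candidate
centroid lies on the true mouse position. (An earlier context-window
harvesting scheme produced a train/deploy distribution mismatch that made
the classifier confuse distractor blobs with the mouse; sampling the
deployment distribution removes it.)

### Stage 2 — activity judgment

Analysis runs at 1 sample/s (`sample_period_s`, configurable). For sample
`t`, the detection is compared against samples `t ± 1 … t ± m` (default
m = 2); each comparison yields

* `P_i` — |prediction-score change|,
* `M_i` — mask change, 1 − IoU of the two binary masks (∈ [0, 1]),
* `A_i` — Euclidean centroid displacement (px),
* `G_i` — |mean-gray change within the mask| (gray levels).

The mouse is **active** at `t` if any offset satisfies

```
P_i > 0.1  or  G_i > 3  or  A_i > 5  or  (G_i/255 + M_i + P_i)/3 > 0.5
```

The per-feature thresholds act on raw units. For the combined mean each
term is first rescaled to [0, 1]: `P_i` and `M_i` already are; `G_i` is
divided by 255. This makes the 0.5 cut interpretable, at the cost that —
with the default raw thresholds — the combined clause only fires when a raw
clause fires too; it becomes binding when the raw thresholds are raised.
An empty comparison set (lost detection at every offset) yields *inactive*
with a low-confidence flag.

### Stage 3 — sleep staging

* **Immobility rule**: every maximal run of ≥ 40 consecutive inactive
  seconds is labeled Sleep; everything else Wake. The inequality is strict
  at the sample level: a 39 s run is Wake.
* **Movement-merging filter**: every Wake run of ≤ 15 s flanked by Sleep on
  both sides is relabeled Sleep, re-scanning to a fixed point so chains
  like Sleep–Wake(10)–Sleep–Wake(10)–Sleep coalesce fully. This absorbs
  brief twitches and posture shifts during sleep which would otherwise
  fragment bouts. The threshold is swept over {0, 5, 10, 15, 20, 25, 30} s
  by `sweep_merge_threshold` to reproduce the filter-selection experiment.
* **Epoching**: the per-second hypnogram is reduced to 20 s epochs by
  majority vote; ties go to Wake (the conservative choice — the method's
  known bias is toward over-fragmenting sleep, not under-reporting wake);
  a trailing partial epoch is dropped.

Video staging is two-state only; NREM and REM cannot be separated from
immobility, so three-state references are collapsed (NREM ∪ REM → Sleep)
before comparison.

## Validation metrics

`compare_staging` computes epoch-by-epoch confusion counts with **Sleep as
the positive class** (the characteristic failure of immobility scoring —
sleep movements misread as waking — is then a sensitivity loss), plus sleep
bout counts from run-length encoding. The identities
`sensitivity = TP/(TP+FN)`, `specificity = TN/(TN+FP)`,
`accuracy = (TP+TN)/n` are asserted on construction.

EEG analytics operate on per-epoch tables of 1 Hz band powers over
1–30 Hz:

* **relative NREM δ power**: per-epoch Σ(1–4 Hz)/Σ(1–30 Hz) — the δ band is
  bins 1–4 inclusive, i.e. 4 of the 30 bins — averaged over NREM epochs per
  hour; hours without NREM are missing values.
* **state power spectra**: per-epoch bin powers normalized to percent of
  that epoch's 1–30 Hz total, averaged within state; each state's bins sum
  to 100 by construction.
* **wake→REM episode detection**: a REM run whose immediately preceding run
  is Wake (≥ one epoch by default) is a narcolepsy-like episode; healthy
  mice enter REM only from NREM.
* **rule-based EEG stager**: an explicitly simplified three-state stand-in
  (δ-ratio > 0.4 with EMG below the 50th percentile → NREM; θ-ratio
  (Σ6–9 Hz/Σ1–30 Hz) > 0.45 with EMG below the 10th percentile → REM; else
  Wake). Real EEG staging pipelines are semiautomated with manual
  correction; this stager makes no parity claim and exists so the
  three-state analytics are exercisable end to end.

## Synthetic cage simulator

The simulator is the test bed: it emits a ground-truth state sequence, a
rendered video, and reference hypnograms.

* **States**: alternating wake/sleep bouts; durations are shifted gamma
  (shape 2, minimum 20 s) with configurable means (default 300 s/300 s).
  The shape guarantees both sub-40 s and super-40 s immobility runs occur,
  exercising the sleep-rule boundary. The final bout is truncated so the
  sequence tiles the duration exactly.
* **Twitches**: brief movements during sleep, a Poisson process with
  exposure equal to sleep time (default rate 0.5/min of sleep, durations
  uniform 5–12 s). Counts per bout are exactly Poisson; the drawn events
  are placed without overlap by distributing the free interior time as
  Dirichlet-uniform gaps.
* **Trajectory**: during wake a persistent random walk at 40 px/s with wall
  reflection; during sleep the centroid is frozen at the sleep-onset
  anchor, jittered at `sleep_jitter_px` (default 0) except during twitches
  (`twitch_jitter_px`, default 8 px — above the 5 px activity threshold, so
  twitches register as movement, as intended).
* **Rendering**: 8-bit grayscale; background 180 (light) / 40 (dark
  phase), mouse an ellipse (semi-axes r, 0.6 r) of gray 120 oriented along
  its heading, plus three static distractors (food disk, water-gel
  rectangle, shadow). Values are arbitrary but frozen. Rendering is
  deterministic (no sensor noise), so a sleeping mouse with zero jitter
  produces pixel-identical frames; frames can be rendered lazily at
  arbitrary indices, which keeps multi-hour analyses in bounded memory.
* **Reference hypnograms**: majority vote per epoch; optionally a fraction
  of each sleep run is relabeled REM, at the run tail (physiological
  NREM→REM order) or at the run head directly after Wake (narcolepsy
  scenario); injected wake→REM onsets are recorded in the hypnogram
  metadata so detection tests can check exact recovery.
* **Spectral epochs**: synthetic 1 Hz band-power tables matching a
  hypnogram (1/f background, δ bump + low EMG for NREM, θ bump + atonia
  for REM, broadband + high EMG for Wake).

What the simulator does **not** emulate: sensor noise, illumination
gradients and flicker, bedding rearrangement, posture-dependent apparent
area changes, rearing/grooming (movement without locomotion), partial
occlusion by the hopper, or realistic micro-movement statistics — no public
characterization of real mouse sleep micro-movements exists, so twitch
parameters are stipulations. A green end-to-end test therefore establishes
the correctness of the algorithmic chain on a clean, known world, not
field performance on real footage.

## Numerical choices

* Coordinates 0-based row-major; bounding boxes half-open.
* Seconds-resolution staging; thresholds are compared with strict `>`
  (activity) and `≥`/`≤` (run lengths) exactly as stated above.
* Epoch majority ties → Wake; trailing partial epochs dropped and logged.
* All randomness flows through `numpy.random.default_rng(seed)`; fixed
  seeds give bit-identical ground truth, frames, and trained fallback
  classifiers.
* Degenerate inputs: flat frames yield no candidates (not an error); empty
  diff lists are low-confidence inactivity; traces shorter than 40 s stage
  as all-Wake with a warning; zero-power spectral epochs are excluded from
  ratios.

## Known limitations

* **Poisson twitch clustering bounds attainable accuracy.** With twitches
  as a Poisson process at 0.5/min of sleep, inter-twitch gaps are
  exponential (mean ≈ 120 s), so ≈ 28 % of gaps are shorter than the 40 s
  immobility rule. Two twitches bracketing a sub-40 s immobile fragment
  form a compound movement episode much longer than 15 s, which the merging
  filter cannot — and should not — absorb. On a 2 h default-world
  recording this costs roughly 5 percentage points of epoch accuracy
  (≈ 0.92–0.93 observed, specificity 1.0), entirely as sensitivity loss in
  twitch clusters. Isolated twitches are absorbed almost perfectly. Real
  mouse movement trains that are sparser or more regular than Poisson
  would score higher; the filter's bout-count repair (the reason the 15 s
  threshold exists) holds regardless.
* The activity window (m = 2 samples) smears each true movement by ±2 s,
  slightly shortening detected immobility runs at bout edges.
* Sleep bouts shorter than 40 s are invisible to the method by definition.
* The rule-based EEG stager and the synthetic spectra are caricatures for
  plumbing tests, not physiological models.
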