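# Methods

## The profiling model

A DNA-selective stain emits fluorescence proportional to DNA mass, so an
asynchronously cycling population produces a characteristic DNA-content
histogram: a 2N peak (G1), a 4N peak (G2/M, indistinguishable by DNA content
alone) at twice the 2N intensity, a plateau between them (S phase, partially
replicated genomes), and sub-2N debris (subG1, apoptotic fragmentation).
Each treated well is summarized as a four-phase fingerprint
⟨G1, S, G2/M, subG1⟩ in percent, and each compound is scored by the Cell
Cycle Index — the Euclidean norm of the fingerprint's componentwise
difference from the vehicle (DMSO) reference:

CCI = √(RG1² + RS² + RG2M² + RsG1²).

The CCI is direction-agnostic on purpose: a G1 arrester and an apoptosis
inducer can score equally; direction is recovered downstream by clustering
the fingerprints themselves. Hit calling uses a strict cutoff (CCI > 10 on
the percent scale). A pure transfer of *m* points between two phases gives
CCI = m·√2, which sets the intuition for the scale.

The reference fingerprint is the componentwise mean of the plate's DMSO
wells. Referencing per plate (rather than screen-wide) cancels plate-level
shifts in staining and cell density; with 16 DMSO wells the reference is
within ±1 point per phase of the underlying vehicle profile.

## Synthetic-data generator

The generator emulates what the screen's cytometer would hand the pipeline,
with full ground truth:

- Phase membership per well is multinomial(n_events, fractions).
- G1 intensities ~ Normal(μ, cv·μ) truncated positive (μ = 2N peak, default
  100 a.u.); G2/M ~ Normal(2μ, 2cv·μ); S uniform on [μ, 2μ] with
  multiplicative Normal(0, cv) noise; subG1 uniform on
  [0.25μ, μ(1 − 2cv)].
- Defaults: 5000 events/well (the event count per well is a free parameter
  of the emulation, not a measured instrument property), cv = 0.05 —
  mid-range for a plate cytometer (typical 0.03–0.08).
- The vehicle truth (54% G1, 10% S, 31% G2/M, 5% subG1) sits inside the
  ranges an untreated HeLa population shows (>50% G1, ~30% G2/M, ~10% S,
  <5% subG1).
- Per-well seeds derive from sha256(plate_seed | well_id) reduced to 31
  bits, so any well is reproducible in isolation and independent of
  simulation order.
- Viability plates: reading = viability·signal·(1 + Normal(0, cv)), floored
  at zero; DMSO wells have viability 1, positive controls 0.
- Dose-response plates evaluate a known 4PL curve on the canonical 8-point
  final-concentration grid 50, 12.5, 3.125, 0.781, 0.26, 0.065, 0.016,
  0.004 µM (the screen's stock serial dilution scaled by its 1/1000 plating
  dilution; the series is close to, but not exactly, 4-fold) with
  multiplicative noise.

What the generator does **not** model: doublets, optical artifacts, >4N
aneuploid populations, cell-count variation between wells, and any
correlation structure across wells. A green recovery test therefore
establishes correctness of the estimators under the stated noise model, not
robustness to instrument pathology.

## Gating

The screen's original analysis ran inside closed vendor software, so the
gating scheme here is defined from scratch and kept transparent:

1. Histogram with B = 128 half-open bins (last bin closed) over
   [0, 1.05 × 99.5th percentile]; 3-bin moving-average smoothing.
2. Peak pairing. The tallest smoothed local maximum anchors the pair: if a
   second maximum sits at 1.8–2.2× its position, tallest = 2N; otherwise, a
   maximum near half its position (≥8% of its height, and rising clearly
   above the connecting valley) marks a 4N-dominant well (strong G2/M
   arrest) and becomes the 2N mode; otherwise the 4N peak is synthesized at
   exactly 2× the 2N mode. Equal-height bimodal ties resolve to the leftmost
   mode as G1. Sub-bin peak positions come from a parabolic fit through the
   mode and its neighbors.
3. Peak widths from FWHM/2.355, measured above the local valley baseline
   (peaks ride on the S pedestal), with the smoothing + binning variance
   (≈ (10/12)·binwidth²) deconvolved, a fallback of cv_assumed × peak
   (cv_assumed = 0.05), and a structural cap of 0.15 × peak spacing so the
   2.5σ gates always fit between the peaks.
4. Gates: subG1 < b0 ≤ G1 < b1 ≤ S < b2 ≤ G2/M with
   b0 = g1 − k·σ1, b1 = g1 + k1·σ1, b2 = g2 − k2·σ2 and k = 2.5 by default.
   Events above 4N count as G2/M; every event is assigned, so fractions sum
   to one exactly.

**Bias-balanced inner boundaries.** S-phase DNA content is continuous with
both peaks, so any hard boundary trades S pedestal mass inside a peak band
against that peak's Gaussian tail outside it. A single symmetric k = 2.5
systematically under-counts S by ~3 points on a vehicle-like well. The
half-widths k1 and k2 are therefore solved per well from the flux balance

s_density · kx · σ = peak_mass · Φ(−kx),

with s_density and the peak masses taken from a provisional symmetric gate
(corrected for the clipped pedestal slices). This reduces per-phase bias to
≲0.01 at 5000 events without fitting any mixture model. The subG1 boundary
stays at k·σ1: debris below 2N has no comparable pedestal model.

Residual limitations: (i) in strongly S-arrested wells the pedestal
truncates exactly at the 4N peak, pulling the apparent 4N mode 1–2% low and
leaving an S/G2M split bias of up to ~5 points; resolving it would require
Dean–Jett–Fox-style mixture deconvolution, deliberately out of scope.
(ii) Per-event label accuracy of any hard gate saturates near ~99% even at
cv = 0.01, because ~1% of S events are intrinsically ambiguous next to the
peaks; fraction estimates are unbiased regardless since the fluxes cancel in
expectation. (iii) A pure-4N well with no 2N reference population is
genuinely ambiguous (DNA content has no absolute scale); the tallest peak is
then treated as 2N.

Plate QC: Z′ = 1 − 3(σp + σn)/|μp − μn| with sample (n−1) standard
deviations throughout; >0.5 marks a robust assay. The pipeline accepts any
well-role labeling for the two control groups.

## Viability and potency

Percent viability is 100 × reading / mean(DMSO readings) and may exceed 100.
A compound is cytotoxic when its viability falls below
mean(DMSO) − k·sd(DMSO) with k = 3 (sample sd; the DMSO statistics are
per-plate, consistent with the per-plate profile referencing). Potency is
the EC50 of a four-parameter logistic

response(d) = bottom + (top − bottom)/(1 + (d/EC50)^hill),

fit by least squares on log10 dose, parametrized as (bottom, span = top −
bottom ≥ 0, log10 EC50, hill > 0) — an inhibitory curve by construction.
EC50 is multi-started at the geometric dose mean and at every interior dose;
deterministic, which an 8-point design makes sufficient. A fit that does not
beat the flat (mean-only) model by at least 1% of residual sum of squares is
flagged `converged = False` (monotone-increasing data under the inhibitory
constraint lands here) and its best-RSS parameters are still reported.
ECf = EC50·(f/(100 − f))^(1/hill) generalizes to any percent effect (EC90 is
reported alongside EC50). Potency hits use strict EC50 < 20 µM.

## Clustering and display

Hit fingerprints are clustered on **raw** percentages (Euclidean distance)
with complete linkage; the per-drug Z-score transform (mean 0, sample sd 1
across the four phase values) is applied only afterwards, for the heatmap.
The "across the four phases" wording of the display normalization is read as
within-drug (row-wise); a column-wise flag is provided since only the
display, never the clustering, differs. The linkage is implemented directly
(Lance–Williams max-update) to guarantee deterministic tie-breaking — exact
height ties merge the lexicographically smallest cluster-id pair, and leaf
order traverses the smaller-id subtree first — so dendrograms, heatmap row
orders and Newick exports are bit-reproducible; scipy's implementation
serves as an independent cross-check in the tests, alongside a brute-force
oracle.

## Chemical similarity networks

2D chemical similarity uses the Tanimoto coefficient |A∩B|/|A∪B| over
user-supplied bit fingerprints (e.g. FP2); fingerprints are inputs rather
than computed here because reproducing specific published similarity values
depends on the exact fingerprinting implementation and structure sources.
Edges with similarity ≥ threshold (default 0.5; the published network's
threshold is not stated) form an undirected weighted graph with isolated
nodes retained, exported as GraphML and Cytoscape SIF.

## Numerical conventions

- Sample (n−1) standard deviation everywhere a spread is estimated.
- Percent scale (0–100) for fingerprints so CCI magnitudes are on the scale
  the screen reports; tables serialize at 2 decimals, internal math at full
  precision.
- Strict inequalities at every cascade cutoff (CCI > 10, viability < mean −
  3sd, EC50 < 20 µM).
- All randomness flows from explicit integer seeds; identical inputs and
  seeds reproduce byte-identical outputs across platforms.
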