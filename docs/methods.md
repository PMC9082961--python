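# Methods

## The measurement model

`leafvol` implements **volumetric leaf area** (VLA): the planform area of a
leaf sample — or of a whole pile of samples at once — estimated as

    VLA = (V_l − V_m) / T_l        [mm²]

where `V_l` is the measured sample volume (mm³), `T_l` the mean lamina
thickness (mm), and `V_m` an optional modelled midrib volume.  The idea is
that a flat blade's volume is (area × thickness), so dividing a hydrostatic
volume by a sampled thickness recovers the area without unfolding, flattening
and scanning every single leaf — the bottleneck of conventional optical
measurement, especially for dense piles of small tillering-stage wheat
leaves.

### Hydrostatic volumetry

Two weighing protocols yield `V_l`; both rest on Archimedes' principle (a
fully submerged, suspended object displaces its own volume of water):

* **Suspension technique.**  A beaker of water stands on a balance; the
  sample hangs fully submerged from an external holder inside a small cage
  ("retainer").  The balance change equals the weight of displaced water, so
  `V = ΔW / ρ_T`.  The retainer is measured alone first (`V_r = ΔW_r/ρ_T`)
  and subtracted: `V_l = ΔW_t/ρ_T − V_r`.
* **Specific Gravity Bench (SGB).**  The cage hangs from a load cell and is
  immersed by raising the water container.  With dry weights `W_r1` (cage)
  and `W_l1` (sample) and the underwater reading `W_T2` of the immersed set,
  buoyancy gives `W_T2 = W_l1 + W_r1 − (V_l + V_r)ρ_T`, hence

      V_l = (W_l1 + W_r1 − W_T2 − V_r·ρ_T) / ρ_T
          = (W_l1 − W_T2 + W_r2) / ρ_T            (if W_r2 was recorded)

  where `W_r2 = W_r1 − V_r·ρ_T` is the underwater weight of the empty cage.
  The two forms agree identically on consistent records — a property test
  asserts this over random records.

Water density `ρ_T` is linearly interpolated on an embedded 15–30 °C grid of
standard liquid-water reference values at 0.5 °C steps (≈0.997771 g/cm³ at
22 °C); out-of-range temperatures raise rather than extrapolate.

Replicated underwater weighings (the protocol repeats them to catch air
bubbles) are aggregated by a median-anchored rule: a replicate deviating
from the median by more than three times the set's median absolute deviation
is discarded, then the remainder is averaged.  A computed volume that is
negative within the balance-rounding bound is clamped to zero with a
warning; beyond the bound it raises `BubbleError` — numeric noise and
protocol failure are kept distinct.

### Midrib model

The midrib (the thick central vein) violates the flat-blade assumption.  Its
volume is modelled from the sample length `L` and the basal midrib diameter
`T_b.m` as a cylinder `V_m = L·π·(T_b.m/2)²` for cut pieces, or one third of
that (a cone tapering to nothing) for complete leaves; the default choice
follows whether the specimen is a complete leaf.  The ambiguous phrase
"thickness of leaf base" is resolved as the *midrib* basal diameter, which
is what the symbol definition states.

### Optical reference

Optical leaf area (OLA) counts foreground pixels of a flat-bed scan: at
`r` dpi there are `r/25.4` pixels per mm, so `OLA = 25.4²·SP/r²` =
`645.16·SP/r²` mm² (the constant is computed as `25.4²`, never hard-coded
rounded).  Segmentation either trusts a binary mask or thresholds the green
channel against the white background (default threshold 0.5 on normalized
contrast; a preset of 20/255 ≈ 0.078 mirrors the familiar magic-wand
tolerance).  The scanner is treated as metrically ideal — no distortion
model.

## Agreement statistics

* **NRMSE** = 100·RMSE/range(reference), in percent.
* **Regression**: ordinary least squares of the *reference on the method*
  (method on the x axis), so a method that systematically overestimates
  shows a slope below 1; a through-origin slope is reported alongside since
  it is not known whether published method-comparison fits were forced
  through the origin.
* **Bland–Altman**: differences method − reference; limits of agreement at
  bias ± 1.96·SD with the sample (n−1) SD.  The 1.96 multiplier and the
  (n−1) convention (used for all SDs and CVs in the package) are explicit
  assumptions.
* **CV tables**: per-group CV = 100·SD/mean; the "Mean" row averages group
  CVs while the pooled row is computed on the concatenated data — the two
  deliberately differ.
* **Correlation matrices**: pairwise Pearson r with two-sided t-test
  p-values flagged at 0.05 and 0.001; no multiple-testing correction.

## Resampling experiments

**Pile Analysis** groups measured samples into random piles (default 100
piles of 7), computes each pile's VLA as Σ(member volumes)/mean(member
thicknesses) and compares it against the summed member OLAs.  Dividing the
summed *areas* by mean thickness, a literal reading of some protocol
descriptions, is dimensionally inconsistent and breaks the observed ~1:1
OLA agreement; it remains available as `mode="area_sum"` for comparison but
the volume-sum form is the default.  "Without replacement" is interpreted
within a pile (members distinct, piles independent) — forming 100 piles of
7 from 14 samples is impossible under any other reading.  Pile mean
thickness is the unweighted mean of member thicknesses (no area weighting).

The **thickness-sampling experiment** draws 100 random groups of 5 from a
35-leaf thickness population and reports the percent difference between the
grand mean of group means and the true population mean — the error that
propagates one-to-one into pile-level area estimates.

## The synthetic-leaf generator

No raw data accompany the study this bench emulates, so all validation runs
on synthetic wheat leaves with exact ground truth:

* **Outline** `w(x) = W·(4u(1−u))^a`, `u = x/L`, default `a = 0.5`
  (lanceolate, max width mid-leaf); rectangular and triangular profiles
  exist for closed-form test geometries.  True area and volume come from
  adaptive quadrature at relative tolerance 1e-8 — the internal oracle
  against which both measurement paths are validated.
* **Lamina thickness**: piecewise linear through base/middle/tip values,
  matching the three-point micrometer scheme; the default within-leaf taper
  is 1.2:1.0:0.8 of the leaf mean (base thicker than tip).  A flat (1:1:1)
  taper turns VLA = V/T into an exact identity and is used for
  internal-consistency tests; with taper and asymmetric pieces, the
  unweighted scheme mean differs from the volume-consistent width-weighted
  mean by ~1–2%, a genuine feature of the field protocol that the noisy
  end-to-end tests retain.
* **Midrib**: an add-on volume equal to the cylinder/cone model, times a
  per-specimen mismatch factor (default uniform ±20%) emulating how far a
  real midrib departs from the idealised solid.  The estimator uses the
  model; the ground truth uses model × mismatch.
* **Populations**: log-normal marginals (positive support, right skew
  typical of size traits — a modeling choice, as the source data's
  distribution family is unknown) with means/CVs defaulting to seasonal
  wheat surveys (length CV ~21%, width ~19%, mean thickness ~12%, midrib
  diameters 12–24%), coupled by a Gaussian copula with a single
  equicorrelation knob (default 0.5, moderate positive dependence).
* **Study sets** (`sample_study_set`): 14 specimens per set, stratified
  log-uniform target areas spanning 60–3500 mm²; targets under 1000 mm² are
  cut as pieces from a larger parent leaf, the rest are complete leaves;
  each specimen's midrib is sized to a volume share drawn uniformly from
  2–8%.  Mean lamina thickness 0.25 mm with CV 12% (5% for the
  "within-harvest" correlation experiment).
* **Scans**: pixel-centre-in-silhouette rasterization (no anti-aliasing) at
  a seeded sub-pixel offset and a small random rotation (default ±2°,
  a hand-placed leaf on a platen); an optional grayscale mode renders the
  leaf in green on white to exercise the segmentation path.
* **Weighings**: balance readings are volume × density plus optional
  Gaussian noise, quantised to the instrument resolution (0.001 g balance;
  micrometer readings get 0.01 mm SD noise, the instrument resolution).
  2–3 replicates per record, as in the protocol.

All randomness flows from explicit seeds through `numpy.random.Generator`;
identical seeds give byte-identical outputs (PNG scans included).

### What the generator does not emulate

No venation, texture or colour variation beyond a flat green; no 3-D
curling, folding or overlap; no water absorption, surface-tension or
line-volume effects (the protocol treats these as negligible); no scanner
optics.  Passing tests therefore demonstrate the *arithmetic and
statistical* soundness of the chain — volumetry inverses, area conversion,
error propagation, resampling behaviour — not robustness to the botanical
messiness of real specimens.

## Problem sizes and numerical choices

The end-to-end agreement checks use 14-specimen sets (the bench's sample
count) averaged over 20 seeded replicates; the thickness experiment uses
200 seeded 35-leaf populations; the volume–area correlation 200 seeded
14-piece sets.  Scan-accuracy properties use 50–100 seeded placements.
Quadrature tolerances are 1e-8 relative; piece intervals are located by
Brent root-finding on the cumulative width integral (xtol 1e-9).  Specimens
larger than the configured platen (350 × 500 mm) raise a canvas error.
Micrometer sampling points for the every-2-cm scheme sit at the centres of
consecutive 2 cm stretches; pieces shorter than 2 cm get a single
mid-piece reading.

## Known limitations

* The agreement between VLA and OLA on synthetic data bounds only the
  method-internal error; real-leaf discrepancies (bubbles, partial drying,
  midrib model error beyond ±20%) can be larger.
* The lanceolate outline family cannot represent lobed or serrated leaves;
  the pixel-count conversion itself is shape-agnostic.
* CV-table and correlation-matrix operations are exercised on synthetic
  populations only; no field dataset ships with the package.
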