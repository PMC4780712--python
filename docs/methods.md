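# Methods

This note documents the models behind `cbctscatter`, the parameters that
matter, the numerical choices, and what the desk-scale validation does and
does not establish.

## Scanner model

A point source orbits the isocenter at SAD = 49.54 cm with a flat-panel
detector at SDD = 71.4 cm (magnification 1.441).  The panel is 384 rows ×
480 columns at 0.5 mm pitch (19.2 × 24 cm); 301 projections cover 360°.
Coordinates are right-handed with z along the rotation axis; detector row 0
sits at the −z edge; pixel indices are 0-based and index intervals half-open.
Gantry rotation is implemented by counter-rotating the phantom's insert
centers, which is exact for cylindrical bodies centered on the axis.

**Collimator.**  The axial beam is limited by a thin slit at distance
`collimator_distance` from the source.  That distance is not independently
known; it is calibrated once so that a 4 cm axial field of view at the
isocenter corresponds to a 14 mm slit (the anchor measurement for the
modeled scanner), giving 17.34 cm.  The 13 cm FOV then maps to ≈45.5 mm —
only approximately the 42 mm reported for the physical scanner; the two
published film measurements are mutually inconsistent with any single
thin-slit position, so the 4-cm point was chosen as the anchor and the
discrepancy documented rather than split.  Slit edges are ideal (no
penumbra, no transmission).  An "open" setting maps to the slit that
exactly covers the detector height (46.6 mm), which also serves as the
finite abscissa of the uncollimated point in slit-sweep fits.

**Spectrum.**  The polychromatic model is a Kramers continuum
(fluence ∝ (kVp − E)/E) for a tungsten anode in 2-keV bins, hardened by
aluminum-equivalent filtration through the package's own Al attenuation
table, plus the tungsten K lines (8% of unfiltered continuum fluence) when
kVp exceeds the K edge.  Defaults: 120 kVp, 10 mm Al (mean energy
61.4 keV).  A monoenergetic 60 keV mode exists for fast deterministic
tests.  The spectral *shape* is a modeling choice, not a measured tube
spectrum; everything downstream normalizes by flat fields from the same
engine, so conclusions depend on the shape only weakly.

## Attenuation data

Linear attenuation tables (photoelectric, Compton, Rayleigh) are generated
at import on a 10–150 keV grid (2 keV steps; kernels use a denser 0.5 keV
grid) from a compact parameterization:

* Compton: exact free-electron Klein–Nishina total cross-section per
  electron × mixture electron density;
* Rayleigh: per-atom σ ∝ Z^2.5 · E^−2;
* photoelectric: per-atom σ ∝ Z^4.5 · E^−3, with per-element correction
  factors for Cs (0.32) and I (0.31) anchoring the CsI scintillator to its
  standard above-K-edge cross-section.

The two power-law constants are anchored to the standard tabulated water
values at 60 keV (total 0.2059 cm²/g, coherent 0.0065 cm²/g).  Between 30
and 120 keV the water curve then tracks standard compilations to a few
percent; below ~25 keV it underestimates by up to ~10% (electron binding
and shell structure are not modeled), which is acceptable because the
filtered beam carries almost no fluence there.  K-edge discontinuities are
not modeled, so the CsI response is smooth through 33–36 keV.  Tissue
compositions follow ICRU-style recipes; densities follow the
tissue-equivalent electron-density plug set (lung inhale 0.20, lung exhale
0.50, adipose 0.95, breast 0.99, water 1.00, muscle 1.06, liver 1.07,
trabecular bone 1.16, dense bone 1.53/1.82/2.10 g/cm³ for nominal
800/1250/1750 mg/cc hydroxyapatite loadings).

## Monte Carlo engine

Histories are emitted uniformly over the illuminated detector-band
rectangle (ideal collimation; no heel effect or cos³ falloff — flat fields
from the same engine absorb the difference).  Free paths inside the body
cylinder use Woodcock delta-tracking against the per-energy majorant over
the phantom's materials; the air gap is treated as vacuum (air scatters
≲0.3% over these path lengths).  Compton scattering uses Kahn's rejection
sampling of the Klein–Nishina law on free electrons (no binding or Doppler
broadening — negligible at SPR-level tallies above 20 keV); Rayleigh uses
the Thomson angular law (atomic form factors omitted; this removes the
forward peaking of coherent scatter, a known approximation at the few-
percent level of the scatter channel); photoelectric absorption terminates
the history.  Photons below the 10 keV table floor are absorbed locally;
histories exceeding 1000 interactions are terminated and counted as
runaways (never observed in practice).

**Detector.**  Default model is a 0.6 mm CsI slab with full in-slab
transport: photoelectric events (or degradation below 10 keV) deposit the
photon at the interaction pixel; Compton/Rayleigh events in the slab are
labeled and followed; escapes are lost.  Quantum efficiency is ≈68% at
60 keV, falling with energy.  An `ideal` detector (every impinging photon
scores at its entry pixel) is available for oracle tests.  Signals are
photon-counting; energy-integrating weighting is out of scope.

**Channels and classification.**  A photon is *primary* iff it underwent no
Compton and no Rayleigh event in the phantom; detector-label-inclusive
classification is a flag (`classify_with_detector`).  `total = primary +
scatter` holds exactly per pixel by construction.

**Exposure convention.**  All histories are emitted into the collimated
band; with `fluence_normalized=True` each carries weight
band-area / open-area, making intensities comparable across collimations at
fixed tube output (the convention for slit sweeps and two-FOV pairs).  In
unweighted mode pixel values are raw detected counts and their sum equals
the number of detected photons.

**Seeding.**  A master seed plus the view index feed a `SeedSequence`-derived
per-view stream; identical seeds give bit-identical stacks.

## Analytic projector

Exact source→pixel intersection lengths with every cylinder (body, rods,
nested bone cores; innermost wins), Beer–Lambert attenuation summed over
the spectrum (hence beam hardening in polychromatic mode), optional Poisson
noise, and a synthetic scatter field: amplitude × open-field intensity ×
smooth low-frequency profile × slit response g(s).  The default
g(s) = ln(1 + s/s₀) makes fixtures exercise the log-fit estimator in its
favorable regime; a saturating-exponential alternative probes robustness.
This module claims no physical scatter accuracy — it exists for speed and
for ground truth.

## Two-FOV scatter correction

Per pixel, with total intensities y₁, y₂ at slits x₁ < x₂:

    a = (y₂ − y₁) / ln(x₂/x₁),    b = y₁ − a ln(x₁),

evaluated at a target slit, residual (raw − extrapolated) low-passed with
the truncated, renormalized 11×11 / σ = 5 px Gaussian (reflection borders),
clamped at zero, subtracted from the raw projection, floored at a small
positive count so the subsequent −ln stays defined.  Pixels with y₂ ≤ y₁
(noise implies non-positive slope) fall back to a = 0; their scatter
estimate comes from neighbors through the low-pass.  The corrected
acquisition is by default the small-FOV scan; correcting the large-FOV scan
is supported inside the overlap band, with outside rows left raw and
flagged.

**Extrapolation target.**  The log model diverges at x → 0, so the target
must be positive and is a required, logged parameter.  The package default
is 2.7 mm: extrapolating a 14/42 mm pair to 2.7 mm amplifies per-pixel
noise by ln(14/2.7)/ln(3) ≈ 1.5 (versus ≈3.0 at 0.5 mm) and, on the
two-point model, reproduces the workflow's expected intensity reduction;
pushing the target to the smallest simulated slit (0.5 mm) overshoots
whenever the true scatter-versus-slit relation decays more slowly than the
fitted logarithm at small openings — which the Monte Carlo characterization
here shows it does (scatter is nearly linear in beam height for these tall
phantoms and large air gaps).

## FDK reconstruction

Projections are flat-field normalized (p = −ln(I/I₀), transmissions clipped
at 10⁻⁶ by default), cosine-weighted, ramp-filtered row-wise (Ram-Lak via
FFT with zero-padding to the next power of two; no apodization by default,
Hamming optional), and backprojected with (SAD/L)² distance weighting on a
virtual detector through the isocenter.  The 360° orbit's two-fold ray
redundancy is handled by the factor Δβ/2.  HU calibration maps μ to
1000(μ − μ_w)/μ_w with μ_w measured from a water-only calibration
reconstruction (robust to beam hardening).  Desk-scale defaults reconstruct
a single central slice; the slice count and thickness are configurable.

## Evaluation conventions

Sample (n−1) standard deviations throughout.  Projection-domain ROI tallies
use the first view (gantry 0°).  The sweep's central ROI is the physical
footprint of the native 11×11-pixel ROI (5.5 mm square), converted to
whatever detector pitch is in use, so that downsampling does not change the
measured physics.  The CNR background ROI is placed automatically at the
most insert-free location of the water body.  The cupping index is the mean
over an edge band (0.65–0.80 of the body radius) minus the mean over a
central disc (0.15 radius), inserts excluded — ≈0 for artifact-free water,
positive under cupping.

## Desk-scale study sizes

Tests and examples run on a 4×-downsampled detector (96×120 at 2 mm) —
occasionally 8× — with 40–64 views and 10⁵–2×10⁷ histories per setting, and
reconstruct 96–128² central slices.  These sizes were chosen so the full
suite runs on one CPU in minutes while keeping Monte Carlo standard errors
small against the asserted margins.  The slit-sweep adequacy checks use
8×10⁶ (10 cm phantom) and 1.6×10⁷ (20 cm) histories per setting; the
end-to-end CNR study uses 1.2×10⁶ histories per view.

## What passing tests show — and what they do not

The Monte Carlo engine is validated against closed-form oracles
(Beer–Lambert transmission, Klein–Nishina moments, symmetry, linearity),
the analytic projector against fine-step ray sampling, and the correction
and FDK stages against fixtures with exact ground truth.  None of this
establishes agreement with a physical scanner: the synthetic data lack
detector glare and lag, focal-spot blur, heel effect, bow-tie filtration,
object positioning errors and housing backscatter.  Two observed
consequences matter when comparing with measured CBCT studies:

* **Log-fit adequacy depends on the phantom/geometry.**  For the 20-cm
  phantom the natural-log fit of central-ROI total intensity versus slit
  reaches R² ≈ 0.94–0.95; for the 10-cm phantom it plateaus near
  R² ≈ 0.89–0.91 at any photon budget, because the detected total is a
  beam-coverage ramp followed by scatter growing almost linearly in beam
  height (the 10-cm-tall phantom's scattering volume keeps growing over the
  whole slit range).  Published measurements on physical scanners report
  higher R² for small phantoms; reproducing that would require scanner
  details (collimator construction, detector glare) outside this model.
* **CNR gain from correction is bounded by the scatter contrast damage.**
  For a 10-cm phantom at a 4-cm FOV the central SPR is only ≈0.17, and
  substituting the true primary channel (perfect correction) raises the
  mean insert CNR by only ≈3%; any realistic correction adds more noise
  than that, so the corrected-beats-raw ordering reported for physical
  scanners (where contrast damage is far larger) does not emerge from
  phantom-only Monte Carlo at this scale.  The small-FOV-beats-large-FOV
  ordering, and the cupping reduction after correction, reproduce robustly.

## Known limitations

Analog Monte Carlo only (no variance reduction beyond source-band emission
and fluence weights); Thomson Rayleigh; no electron transport, fluorescence
escape or dose scoring; ideal slit collimation; smooth (edge-free) CsI
response; circular orbits only; no truncation compensation beyond
zero-extension; no iterative reconstruction.
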