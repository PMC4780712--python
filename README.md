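# cbctscatter

Scatter is the dominant artifact source in dental cone-beam CT (CBCT): with a
wide axial beam, scatter-to-primary ratios (SPR) reach 0.4–2.0, depressing CT
numbers toward the object center (cupping) and washing out low-contrast
detail.  `cbctscatter` is a Python toolkit for studying and correcting that
scatter on digital phantoms.  It is aimed at medical-physics researchers who
want a desk-scale, fully scripted counterpart to a Monte Carlo + scanner
study: every acquisition it analyzes is generated by its own engines, so
ground truth (the scatter-free primary channel) is always available.

The package provides:

* **Monte Carlo engine** (`cbctscatter.mc`) — photon transport through
  water-filled cylindrical phantoms with tissue-equivalent rod inserts
  (Woodcock delta-tracking; free-electron Klein–Nishina Compton sampling;
  Thomson Rayleigh; photoelectric absorption; optional CsI scintillator slab
  with full in-slab transport).  Every detected photon carries its
  interaction labels, so projections split exactly into *total = primary +
  scatter*.
* **Analytic projector** (`cbctscatter.analytic`) — exact Beer–Lambert line
  integrals (spectral summation, hence beam hardening) plus a parametric
  low-frequency scatter field; the fast fixture generator and oracle.
* **Two-FOV scatter correction** (`cbctscatter.correction`) — the
  projection-domain method: per-pixel natural-log fit
  `y = a·ln(x) + b` to two acquisitions with different axial collimation
  (slit sizes `x₁`, `x₂`), extrapolation toward a small slit where scatter is
  negligible, an 11×11 / σ = 5 px Gaussian low-pass of the residual as the
  scatter estimate, and subtraction.
* **FDK reconstruction** (`cbctscatter.recon`) — cosine weighting, Ram-Lak
  ramp filtering, distance-weighted backprojection for the circular orbit;
  HU calibration.
* **Evaluation** (`cbctscatter.evaluation`) — ROI statistics, SPR,
  log-fit diagnostics (R²), contrast-to-noise ratio
  `CNR = |CT# − CT#_water| / SD_water`, cupping index, line profiles.

The modeled scanner: SAD 49.54 cm, SDD 71.4 cm, 384×480 flat panel at
0.5 mm pitch, 301 views over 360°, 120 kVp with 10 mm Al-equivalent
filtration, axial collimation between 4 cm and 13 cm of field of view.

## Worked example

One Monte Carlo view of the 10-cm five-tissue phantom at a 14 mm slit
(`python examples/02_monte_carlo_view.py`):

```
emitted 500000 photons, detected 181318
total = primary + scatter per pixel: True
central ROI means: total 5.7, primary 4.3, scatter 1.3
SPR = scatter/primary = 0.308
list-mode records: 181318 photons, 7050 scattered in the phantom, mean detected energy 55.7 keV
```

About a third of the emitted photons reach and are absorbed by the detector;
at this narrow collimation the central scatter-to-primary ratio is ~0.3, and
the channel identity holds exactly because each photon is classified by its
own interaction history.

Scatter correction closing the loop on a contaminated water cylinder
(`python examples/05_fdk_cupping_and_cnr.py`):

```
effective water attenuation (scatter-free recon): 0.1991 /cm
scatter-free  central voxel     27.4 HU, cupping index    -3.1 HU
raw           central voxel   -880.2 HU, cupping index   164.8 HU
corrected     central voxel     65.2 HU, cupping index    -3.3 HU
```

Scatter depresses the cylinder center by almost 900 HU and produces a
165 HU cupping index; after the two-FOV correction the reconstruction sits
within ~40 HU of the scatter-free one and the cupping is gone.

The other examples cover geometry/materials/spectra (`01`), the
7-slit collimation sweep and its natural-log fit (`03`), and the correction
on fixtures with known ground truth (`04`).  A `cbctscatter` CLI exposes the
same pipeline (`simulate`, `sweep`, `fixtures`, `correct`, `reconstruct`,
`evaluate`, `demo`), e.g.:

```bash
cbctscatter demo --photons 200000 --views 24 --seed 1 --out run/
```

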