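# monolayer-mech

Quantitative analysis of collective epithelial monolayer migration and
cell mechanics: velocimetry statistics, segmentation-derived
morphometrics, single-cell tracking with mean-squared-displacement (MSD)
analysis, and a viscoelastic capped-shell model for AFM
force-relaxation curves.  A seeded synthetic-data generator provides
ground-truthed inputs for every stage, so the whole pipeline is testable
without raw microscopy or AFM data.

The package is aimed at quantitative cell biologists and biophysicists
studying wound-healing-style migration assays (e.g. MDCK monolayers
expanding into free space), monolayer jamming, and AFM force
spectroscopy on confluent cells.

## What it computes

**Velocimetry** (from gridded velocity fields, or image pairs via a
minimal PIV stage):

- order parameter ⟨cos α⟩, with α the angle between the local velocity
  and the migration direction (the outward edge normal): 1 = fully
  directed, 0 = no net edge-ward motion;
- speed/order profiles versus distance from the advancing edge;
- the 2-D spatial autocorrelation of the velocity fluctuations
  AC(r⃗) = ⟨v(r⃗′+r⃗)·v(r⃗′)⟩ (perpendicular component, mean-subtracted,
  normalized to AC(0) = 1), its radial average AC(r), and the
  correlation length

      L = ∫₀^R* r·AC(r) dr / ∫₀^R* AC(r) dr,

  integrated up to the first zero crossing R* of AC (the raw weighted
  integral ∫ r·AC dr is available behind a flag);
- window-based PIV displacements (32 px windows, 50% overlap, SNR /
  peak-height / 4σ global filters) with sub-pixel refinement.

**Morphometrics** (from integer label masks): per-cell projected area
(shoelace contour area after one-pixel outline subtraction), moments
centroid, aspect ratio (mean of the moments-equivalent-ellipse axis
ratio and the minimum-area rotated-rectangle side ratio), cell density,
and the Fisher–Pearson skewness g₁ of the area distribution — a
jamming/crowding readout.  Also the YAP nucleus/whole-cell intensity
ratio (values > 1 excluded as mis-segmentation) and cylinder cell-volume
arithmetic.

**Tracking**: optimal-assignment linking with a hard search radius,
gap memory and minimum track length; per-cell mean speeds; ensemble
MSD(τ) = ⟨|x(t+τ) − x(t)|²⟩ fitted by MSD(τ) = a·τⁿ in log-log space;
and motility (MSD at 60 min, exponent n) binned by cell area (100 µm²
bins) or aspect ratio (0.25 bins).

**Mechanics**: a liquid-filled cell capped by a spherical shell (base
radius R₁, contact angle φ) indented by a conical AFM tip (half-angle ϑ,
θ = 90° − ϑ) at constant height and constant enclosed volume.  The tip
force is

    F = 2π T(t) [ R₁²(R₁ sin φ + r₁ sin θ)/(R₁² − r₁²) − R₁ sin φ ],

with contact radius r₁ from the constant-volume shape solution, and the
shell tension relaxes through a power-law area compressibility modulus

    T(t) = T₀ + K_A⁰ (t/t₀)^(−β) · ε,

where ε is the apical area dilation, T₀ the prestress, and β the
fluidity (0 = elastic solid, 1 = Newtonian fluid).  The dwell segment is
fitted for (T₀, K_A⁰, β); membrane tension follows separately from the
tether rupture force, T_t = F_t²/(8π²κ) with κ = 2.7 × 10⁻¹⁹ J.
Cell-line geometry presets: `wt` (10 µm/10°), `ko` (8 µm/20°),
`dkd-small` (5 µm/31°), `dkd-large` (8 µm/2°).

## Worked example

`examples/velocity_correlation.py` generates twenty 128×128 velocity
fields (12.08 µm mesh) with a true correlation length of 30 µm and
10 µm/h drift toward the free edge, runs the autocorrelation chain and
prints:

```
true correlation length : 30.0 µm
recovered               : 28.6 µm (-4.8%)
mean order parameter    : 0.846
```

The recovered length is the first moment of the seed-averaged radial
autocorrelation — within the sampling error expected for this domain
size — and the order parameter reflects drift-dominated, edge-directed
flow.  The other scripts in `examples/` (`track_msd.py`,
`morphometrics.py`, `force_relaxation.py`, `yap_ratio.py`) each build a
small synthetic input, run one capability and explain the numbers; for
instance `force_relaxation.py` re-fits a noise-free relaxation curve and
prints the exactly recovered (T₀, K_A⁰, β) = (0.3500 mN/m, 0.0200 mN/m,
0.5000).

A multi-stage run driven by a config file:

```bash
monolayer-mech run --config examples/demo_config.yaml --out demo_out
```

writes every artifact (vector-field CSV, label TIFF, detections CSV,
force-curve CSV + JSON sidecar, per-stage result JSONs) together with
the resolved config and a SHA-256 manifest; re-running the same config
and seed reproduces the manifest bit-for-bit.

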