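# Methods

`fidmark` simulates a quality-assurance phantom study of implanted fiducial
markers — gold, carbon and polymer cylinders in a uniform soft-tissue block —
across the imaging modalities used for image-guided radiotherapy (kV CT, kV
cone-beam CT, planar kV and MV radiographs, megavoltage CT), and quantifies
marker visibility (contrast-to-noise ratio) and streak artifact (ring SD
profiles). This note documents the model, its parameters, and the design
choices where the design was genuinely open.

## Attenuation model

Only the two interactions that drive marker contrast are modeled:

* **Compton scattering**: per-electron Klein–Nishina total cross-section
  σ_KN(E) (closed form), so the Compton part of μ is proportional to the
  material's electron density n_e.
* **Photoelectric absorption**: k_pe · n_e · Z_eff³ / E³, the textbook
  Z³/E³ scaling with a single scale constant. k_pe is calibrated once so
  that soft tissue's photoelectric and Compton terms are equal at 26 keV,
  which gives tissue-like diagnostic-range behavior without external
  attenuation tables.

Coherent scattering, pair production, K-edges and characteristic lines are
omitted. Consequences worth knowing: gold's μ is overestimated a few-fold
at diagnostic energies (Z³ extrapolated to Z=79 overshoots the screened
reality) — irrelevant in practice because a 0.9 mm gold cylinder is
radio-opaque either way; and for E ≲ 25 keV the polymer (Z_eff = 6.6) falls
below soft tissue (Z_eff = 7.4), below the energies any simulated protocol
uses.

Material constants (overridable via TOML): gold Z=79, ρ=19.3; carbon Z=6,
ρ=1.8; polymer Z=6.6, ρ=1.2; soft tissue Z=7.4, ρ=1.0; electron densities
ρ·N_A·(Z/A) with standard Z/A values. The markers' true alloy/polymer
chemistry is proprietary; these are representative stand-ins.

## Spectra

kV tubes use a Kramers bremsstrahlung shape, weight ∝ (kVp − E)/E, in 1 keV
bins above a 10 keV cutoff, hardened by 2.5 mm aluminum-equivalent
filtration (Beer–Lambert with the same two-term μ for aluminum).
Megavoltage beams are monoenergetic at an effective energy (2 MeV planar
MV, 1 MeV MVCT): their contrast is Compton/density-driven, which a single
energy captures. Detectors are energy-integrating: the weight of bin i in
any transmission measurement is w_i·E_i.

## Phantom and geometry

The default phantom is a 30 × 31 × 15 cm soft-tissue block (2 cm bolus
layers, geometric bookkeeping only — the material is uniform) with nine
markers on a 3 × 3 grid, one row per material, 5 cm apart, in the central
plane (z = 75 mm), cylinder axes in-plane along +x. Dimensions: gold
0.9 × 3 mm, carbon 1 × 3 mm, polymer 1 × 5 mm. Coordinates are mm,
right-handed, origin at the phantom corner; a voxel's position is its
center.

Projections of this geometry are computed **analytically**: the background
box and each marker's in-plane footprint at height z (a rectangle of length
L and width 2√((d/2)² − (z − c_z)²)) have closed-form Radon transforms
(trapezoids). A dense voxel grid of the full phantom at marker-resolving
resolution would be ~2×10⁹ voxels; the analytic projector avoids it without
discretization error. Voxelized `MaterialVolume` inputs are also accepted
(projected with scikit-image's Radon transform) and agree with the analytic
path to within voxelization partial-volume error — this dual route is
exercised in the tests.

## Image formation

**Tomographic modalities** (CT, CBCT, MVCT) use parallel-beam geometry,
by default 720 views over 180°, detector bin = 0.5 mm, ramp (Ram-Lak)
filter without apodization, linear interpolation in backprojection.
A slice of thickness t averages the transmissions of N_sub =
min(51, max(3, ceil(t/0.1))) (odd) sub-slices — the partial-volume effect
for the ~1 mm markers. Log projections are linearized against a water
(soft-tissue) beam-hardening curve before reconstruction, as clinical
scanners do; the correction is exact only for the tissue background, so
high-Z streaks survive it while the background reconstructs flat (±2 HU;
without the correction the 30 cm phantom shows −160 HU offset and −29 HU
cupping at 80 kVp). HU = 1000·(μ̂ − μ_w)/μ_w with μ_w evaluated at the
spectrum's effective energy, and the output is clipped to the 12-bit
scanner range [−1024, 3071] (ring-artifact profiles are computed on the
unclipped reconstruction, since the clip flattens gold's bloomed core to
SD 0 at small radii). Reconstruction targets a 128² region of interest
(32 mm, 0.25 mm pixels) around each analyzed marker, backprojected
directly from the full non-truncated sinogram.

**Planar modalities** project along z with per-pixel polychromatic
transmission (0.5 mm pixels) and return log-attenuation display values,
−ln(counts/N₀), so attenuating markers are bright maxima as displayed
clinically.

**Noise** is Poisson on per-ray photon counts, with budgets:

| setting | default | rationale |
|---|---|---|
| CT/CBCT counts/ray | 1×10⁵ at 200 mAs, 2.5 mm; ∝ mAs × t | study condition |
| kV planar counts/pixel | 1×10⁶ at 200 mAs; ∝ mAs | flat-panel fluence; keeps carbon/polymer clearly identifiable on kV radiographs, as observed in the physical study |
| MV planar counts/pixel | 1×10⁴ per MU | calibrated to the reported gold CNR ≈ 6 at 2 MU |
| MVCT counts/ray | 2.0×10⁴ normal (4 mm), 2.5×10⁴ fine (2 mm) | calibrated to the reported gold CNR ≈ 18 / 23 |

Counts below 0.5 are clamped before the log (photon starvation). CBCT adds
a flat 20% scatter fraction and uses 80 mAs. CT tube load defaults to
200 mAs (unspecified in the original protocol list).

## Metrics

CNR = (S_max − S̄_bg)/σ_bg from a 15 × 15 cm ROI clipped to the image.
S_max is taken within 2.5 mm of the detected marker center in the sweep
pipeline — with 5 cm marker spacing the ROI necessarily contains the
neighboring markers, and a full-ROI max would report gold's peak for every
material. Background statistics exclude a 7.5 mm disk around *every*
marker (the marker's own artifact range) and use the sample SD. Marker
centers come from an intensity-weighted centroid of pixels above
background mean + 3 SD within a 5 mm search disk.

Ring artifact profiles: 1000 rings, radii 1–15 mm inclusive, 720 angular
samples per ring, bilinear interpolation, sample SD per ring; the artifact
index is the mean ring SD. Brute-force enumeration oracles for both
statistics are part of the test suite (agreement to 1e−10 relative).

A marker is "visible" when its mean CNR ≥ 4 (Rose criterion).

Note a property of the max-based statistic: over an n-pixel signal region
the expected maximum of pure noise is ≈ √(2 ln n)·σ, so CNR has a floor
of ≈ 2.7 for the 2.5 mm signal disk. Low-contrast markers (carbon/polymer
at MV energies; their CT slice-thickness curves) sit at or near this
floor, which is also what keeps their thickness dependence within ~15%.

## Sweeps and reproducibility

Presets mirror the study grids: CT 80–140 kVp at 1.25 mm; slice
thicknesses 0.625–5 mm at 120 kVp; planar kV 60–120 kVp at 200 mAs and
50–200 mAs at 80 kVp; CBCT 60–125 kV; MV 1–2 MU; MVCT normal/fine. Each
(value, realization) derives its Poisson seed as
`SeedSequence((base_seed, value_index, realization)).generate_state(1)[0] mod 2³¹`,
so results are independent of execution order and bit-reproducible. One
acquisition images all nine markers (noise shared across materials within
a realization); 5 realizations per setting estimate CNR dispersion.
Trend summaries report the least-squares slope sign of mean CNR and the
peak location (ties toward the smaller parameter value).

## Model behavior vs. the physical study

Most reported trends emerge from the model as-is: gold's CT CNR rises with
kVp while polymer's falls; carbon/polymer CNR is nearly flat (≈12–14%
variation) across slice thicknesses while gold's changes strongly; only
gold is visible on MV planar and MVCT images; gold's ring-SD artifact
exceeds carbon's and polymer's at every radius up to 5 mm on kV CT, and its
MVCT artifact index is ~8% of the kV-CT value.

Four behaviors of the real imaging chains are *not* reproduced by this
model, and the corresponding assertions in the acceptance test suite fail
by design rather than being weakened:

1. **Carbon's CT CNR slope vs kVp** comes out flat/slightly positive, not
   negative: in a two-term Z³/E³ model a denser low-Z marker *gains* HU
   contrast as the photoelectric deficit fades with energy, while photon
   penetration simultaneously lowers noise.
2. **Gold's slice-thickness CNR** increases monotonically instead of
   peaking at an interior thickness: its S_max stays pinned at the 3071 HU
   cap across the whole 0.625–5 mm grid (the unclipped bloom still exceeds
   the cap at 5 mm), so CNR simply follows the 1/√t noise. The physical
   scanner's much wider effective PSF/blooming (detector glare is outside
   this model's scope) is needed for the peak to detach.
3. **Gold's planar CNR vs kVp** rises to ~90 kVp and then falls: above
   ~100 kVp the model's gold transmission (~10⁻⁴) times the photon budget
   exceeds one count, the starvation clamp releases, and the physical
   contrast — which decreases with energy — takes over. Real detectors
   remain display-saturated over gold throughout the range.
4. The per-step "strictly increasing within 1 SE" form of the mAs trend is
   occasionally violated by carbon and polymer, whose CNR sits at the
   max-statistic noise floor; the regression slope over the full mAs grid
   is positive for all three materials.

## Limitations

Parallel-beam geometry (no fan/cone divergence); no detector lag, glare or
focal-spot blur; no coherent scatter or K-edges; CBCT is CT plus a flat
scatter term; MVCT is not a true helical fan-beam chain; absolute HU/CNR
values are calibration-dependent and only trends should be compared across
configurations. Synthetic phantoms are uniform: conclusions do not
transfer to markers near bone or lung.
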