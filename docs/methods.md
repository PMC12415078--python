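# Methods

`mechanospec` analyses co-localized Brillouin–Raman microspectroscopy maps of
3-D tissue models (tumor spheroids and organoids): it reduces raw VIPA
spectrometer readouts to calibrated Brillouin shift and linewidth, groups
the co-located Raman spectra into biochemical clusters, and compares the
viscoelastic parameters of those clusters. Because raw data of this kind are
rarely public, the package ships a first-class synthetic phantom generator
that emulates the statistical structure of such experiments, and the test
suite checks every stage by parameter recovery against the generator's
ground truth.

## Brillouin model

A single CCD readout contains four Lorentzian bands on a linear
pixel-to-frequency axis: the sample's Stokes and anti-Stokes bands at
±ν_B about the suppressed elastic line, and a methanol reference pair at
±3.81 GHz acquired in every spectrum through a parallel beam path. The
axis model is deliberately linear (default 512 pixels, 0.044 GHz/pixel,
elastic line at a configurable fractional pixel); VIPA dispersion
nonlinearity and free-spectral-range unfolding are out of scope — all
shifts of interest are well below FSR/2.

Per-spectrum calibration follows the standard reference-pair arithmetic:

    dispersion = 2 · ν_ref / (px_antiStokes − px_Stokes),
    elastic pixel = midpoint of the reference pair,

so the sample shift is the mean absolute frequency of the two sample bands
and the measured FWHM is the mean of the two fitted widths times the
dispersion.

Fitting proceeds in two stages. Windowed single-Lorentzian fits
(initialised from the smoothed argmax and half-maximum crossings) locate
each band; a joint least-squares fit of all four Lorentzians plus a common
offset then refines everything at once. The joint stage matters: Lorentzian
tails are heavy, and with sample and reference bands ~36 pixels apart the
neighbour's tail contributes several percent of peak intensity inside any
single-band window, which biases independent fits. With the joint model,
noiseless phantoms round-trip to machine precision (the tests require
1 × 10⁻⁶ GHz).

The measured band is the convolution of Lorentzian components, so FWHMs
add; the sample-intrinsic linewidth is recovered by subtracting the
instrument's Rayleigh-line FWHM (0.40 GHz for the spheroid-type
configuration, 0.33 GHz for the organoid-type one) from the measured FWHM.
A correction that lands at or below zero flags the point invalid rather
than clipping — downstream statistics must see honest exclusions, not
zeros. Additional plausibility guards flag fits where the joint refinement
moved the dispersion by more than 5 % against the windowed calibration or
produced a measured width above 3 GHz; at the noisiest acquisition setting
these guards exclude roughly 2–3 % of points, which mirrors the invalid-fit
exclusion any real reduction pipeline performs.

Viscoelastic quantities follow the longitudinal-modulus relations

    M′ = ρ λ² ν_B² / (4 n²),   M″ = ρ λ² ν_B Γ_B / (4 n²),
    BLT = Γ_B / ν_B = M″ / M′,

with ρ the mass density, n the refractive index and λ the excitation
wavelength (SI units inside `compute_moduli` only; GHz everywhere else).
The Brillouin loss tangent is independent of (n, ρ, λ), which the tests
assert by varying them. `nu_prefactor_difference` quantifies the
(n, ρ)-dependent factor of ν_B (∝ n/√ρ at fixed M′) between two materials;
for literature lipid vs. cholesterol constants it is ≈ 0.65 %, i.e. optical
contrast alone cannot explain a large shift difference between those
classes.

## Phantom generator

Geometries: raster maps (default 50 × 50 points, 2 µm step) model a disc of
tissue in medium with seeded minority-class blobs (lipid droplets,
glycogen-rich regions); line maps model co-localized Brillouin+Raman
acquisitions (1 × 50 at 1 µm for spheroid-like phantoms, 20 points at 5 µm
for organoid-like ones). Spheroid-type line maps contain no medium points —
a 50 µm line sits inside the tissue — while organoid-type lines include a
~15 % medium/blank fraction, which downstream analysis must find and
discard.

Each point draws (ν_B, Γ_B) from per-class normal distributions around the
class medians (default spreads 0.05 GHz, giving realistic histogram widths)
and renders a full CCD spectrum. Class medians default to values
characteristic of the respective biochemical groups in glioblastoma models
(cytoplasm ≈ 5.36/0.44, lipid droplets up to 5.39/0.59, protein+glycogen
≈ 5.38/0.51, organoid cholesterol-rich lipids 5.40/0.80, medium 5.10/0.25
GHz); these are generator settings whose recovery the tests check, not
claims about new data.

Raman spectra are sums of Gaussian bands plus a smooth polynomial baseline
and additive noise (default SD 2 % of the strongest band). Gaussian line
shapes were chosen over Lorentzian because condensed-phase Raman bands are
well approximated by them and because Lorentzian tails are fundamentally
ambiguous with a smooth baseline, which would make "recover the band areas"
an ill-posed target for any baseline estimator. Band tables use standard
assignments: protein profiles carry 1004 (phenylalanine), ~1100, 1250–1350
(amide III), 1450 and 1660 cm⁻¹ (amide I); lipids are dominated by
1440 cm⁻¹; glycogen contributes 865 and 942 cm⁻¹ on top of the protein
profile; cholesterol-rich lipids add the 700 cm⁻¹ ring vibration; the
intercellular-space profile is weak and amide-I-heavy. Relative amplitudes
beyond the diagnostic bands are free design parameters of the phantom; they
were set once so that the between-class spectral distances are comparable
across classes — the regime in which internal cluster-validity criteria
meaningfully recover the generating class count — and are exposed in
configuration for users who want harder or easier phantoms.

### Noise calibration

The Brillouin noise model has two calibrated components per acquisition
regime (`NOISE_LEVELS`):

1. **White CCD noise**, additive Gaussian, expressed as a fraction of the
   sample band amplitude. For this band geometry it produces fitted-
   parameter scatter with SD(Γ)/SD(ν) ≈ 1.54.
2. **Instrumental-width jitter**, a per-spectrum Gaussian perturbation of
   the Rayleigh broadening, modelling slow alignment drift between
   acquisitions. It moves the measured linewidth but not the shift.

Two components are necessary because measured repeatability on a sucrose
standard (ν_B = 5.5, Γ_B = 0.43 GHz) shows SD ratios of ≈ 2.4 (0.2 s
acquisitions: 21/51 MHz) and ≈ 3.6 (45 s: 5/18 MHz) — no single white-noise
scale can reproduce both SDs at once. `scripts/calibrate_noise.py` fits the
white-noise fraction to SD(ν_B) (the response is linear) and then assigns
the remaining Γ variance, in quadrature, to the width jitter. The frozen
defaults reproduce both regimes' SDs within a few percent (tests allow
20 %). The 150 s regime reuses the 45 s model: both are treated as fully
noise-suppressed acquisitions, and no separate repeatability measurement
distinguishes them.

## Raman preprocessing

Forward-only state machine: raw → baseline-corrected → normalized, with
cropping (default 600–1800 cm⁻¹, the fingerprint region) allowed at any
stage. The baseline estimator is asymmetric least squares (Whittaker
smoother, second-difference penalty; defaults λ = 1 × 10⁷, p = 0.001,
20 reweighting iterations on a 2 cm⁻¹ grid). The defaults recover synthetic
band areas to well under 5 % and shift peak positions by < 2 cm⁻¹; tests
assert this behaviour against generator truth rather than any particular
baseline algorithm identity. Area normalization divides by the intensity
sum over the analysis range (a trapezoidal-integral switch is provided;
both are scale-invariant). Spectra whose corrected signal never clears the
noise are flagged `blank`; spectra with non-positive total area are flagged
`failed` and rescaled by their L1 norm so they remain on a comparable scale
— such points are expected to collect into the off-target cluster that the
analysis later discards, rather than being silently dropped.

## Clustering

K-means (Lloyd's algorithm, k-means++ initialisation, best of `n_init = 20`
restarts, fixed seed) with the Euclidean metric on the normalized spectra.
Clusters are renumbered by descending size so reports are stable
("cluster 0 = dominant component"). The cluster count is chosen by
evaluating Silhouette (maximise), Davies–Bouldin (minimise) and
Calinski–Harabasz (maximise) over a k range and taking a majority vote,
ties broken toward the smaller k; the full criterion table is always
returned because the final arbiter in practice is the biochemistry of the
centroid spectra, which is human judgment outside this package's scope.
Per-point silhouette values use the standard (b − a)/max(a, b) definition,
with the value 0 assigned to singleton-cluster points by convention.

`discard_offtarget_cluster` removes clusters that are not tissue: a cluster
is discarded when its centroid matches a supplied medium reference spectrum
(cosine similarity above 0.95) or shows no detectable bands (maximum peak
prominence below a floor, default 20 % of the largest centroid prominence
in the model). Remaining clusters are re-indexed; discarded points carry
label −1 and are excluded from statistics.

## Statistics

Brillouin fits and cluster labels join one-to-one by point id; invalid fits
and discarded clusters are excluded with counts recorded. Per-cluster
summaries are medians (ν_B, Γ_B, BLT). BLT is computed per point and then
medianized, matching the ratio's pointwise definition; the ratio of medians
is reported alongside since the two aggregations differ slightly. Group
comparisons are heteroscedastic throughout: Welch's t-test for two groups,
Welch's ANOVA (Welch 1951; formulas documented in the code) for three or
more, and the Games–Howell procedure (via pingouin) for pairwise post-hoc
comparisons, with the method name recorded in every output. The Welch
implementation is cross-checked in the tests against an independent
brute-force implementation at 1 × 10⁻¹⁰. Shift–width association uses the
Pearson correlation per cluster; weak correlation indicates that linewidth
variation is dominated by heterogeneous broadening (sub-resolution
mixtures) rather than viscosity. Histograms use fixed 0.05 GHz bins
anchored at 0 GHz with half-open [lo, hi) intervals, making counts
bit-reproducible.

## Pipeline, formats, determinism

`run_pipeline` chains simulate/load → fit → preprocess → cluster → discard
→ statistics, writes CSV tables with provenance headers (version, seed,
config hash — hashing excludes I/O paths so identical analyses hash
identically), a JSON test summary, the resolved configuration and a
structured per-stage point-count log. Phantom maps are stored in an HDF5
container (`/brillouin/raw`, `/raman/raw`, `/truth`). Everything is
deterministic under a fixed seed, down to byte-identical report tables.

## Problem sizes and what the tests show

Default test and acceptance problem sizes match the emulated designs: 10
line maps × 50 points per spheroid-like dataset, 16 × 20 for the
organoid-like one, 8 raster maps × 2500 points for pooled histograms,
400–500 Monte-Carlo replicates for repeatability, 100 seeds for the
exhaustive k-means cross-check (n = 8 toys, where exhaustive set-partition
enumeration is feasible). Passing tests demonstrate correct recovery of
the generator's structure under its noise model; they do not demonstrate
performance on real spectrometer data, whose baselines, cosmic-ray spikes,
wavenumber miscalibration and class imbalance the phantom deliberately
does not emulate (despiking and wavenumber calibration are explicit
non-goals).

## Known limitations

- Linear frequency axis only; no VIPA nonlinearity, no FSR unfolding.
- Reference-band identification relies on metadata hints (phantoms) or an
  outermost-symmetric-pair heuristic (generic input); instruments with
  different band orderings need explicit hints.
- The medium/blank Raman model is baseline + noise; real culture medium has
  weak bands that would make the discard step easier, not harder.
- Cluster-count selection by majority vote is one defensible aggregation of
  three criteria; the criterion table is emitted precisely because no
  aggregation rule is canonical.
- No nested/mixed-effects modelling of map-level structure: points are
  treated as exchangeable within clusters.
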