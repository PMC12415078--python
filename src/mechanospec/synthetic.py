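"""Synthetic spheroid/organoid phantom generator.

Phantoms emulate the statistical structure of co-localized Brillouin-Raman
maps of 3-D glioblastoma models: a disc of tissue in culture medium, raster
Brillouin maps (50 x 50 points, 2 um step), co-localized Brillouin+Raman
line maps (1 x 50 at 1 um for spheroids, 20 points at 5 um for organoids),
per-class Brillouin parameters drawn around published-style medians, and
Raman component spectra built from diagnostic bands (700 cm-1 cholesterol
ring, 865/942 cm-1 glycogen, 1440 cm-1 CH2 lipids, amide I/III protein
bands).

Every spectrum carries its generating ground truth in metadata, so the
fitting, preprocessing, clustering and statistics stages can all be tested
for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .brillouin import BrillouinRawSpectrum, METHANOL_SHIFT_GHZ, lorentzian
from .raman import RamanSpectrum

__all__ = [
    "TissueClassProfile", "PhantomConfig", "StudyDesign", "SpectralMap",
    "generate_brillouin_spectrum", "generate_raman_spectrum",
    "generate_phantom_map", "count_observations",
    "spheroid_profiles", "organoid_profiles",
    "u87_line_config", "ht18584_line_config", "organoid_line_config",
    "spheroid_map_config", "NOISE_LEVELS", "RAMAN_NOISE_SD",
]

# Per-regime noise model: (ccd_noise_fraction, width_jitter_GHz).
#
# The first component is additive white CCD noise (as a fraction of the
# sample band amplitude); it perturbs the fitted band centres and widths
# jointly, with SD(Gamma)/SD(nu) ~ 1.5 for this band geometry.  The second
# component is a per-spectrum jitter of the instrumental broadening
# (alignment drift of the Rayleigh width between acquisitions), which
# perturbs the measured linewidth but not the shift, and is needed because
# the measured repeatability shows a larger Gamma/nu SD ratio than white
# noise alone can produce.  Both components are calibrated by Monte-Carlo
# (scripts/calibrate_noise.py) so that fitted-parameter SDs on a sucrose
# standard (nu_B = 5.5 GHz, Gamma_B = 0.43 GHz) match the measured
# repeatability: ~21/51 MHz (nu/Gamma) at 0.2 s and ~5/18 MHz at 45 s.
NOISE_LEVELS: dict[str, tuple[float, float]] = {
    "0.2s": (0.0868, 0.0421),
    "45s": (0.0207, 0.0167),
    "150s": (0.0207, 0.0167),  # same model as 45 s, fully noise-suppressed
}

# Raman additive noise SD as a fraction of the strongest band amplitude.
RAMAN_NOISE_SD = 0.02

# ---------------------------------------------------------------------------
# Raman component band tables: (center cm-1, FWHM cm-1, relative amplitude).
# Only the diagnostic bands (700, 865, 942, ~1100, 1250-1350, 1440 cm-1) are
# load-bearing for the analysis; the remaining assignments (1004 cm-1
# phenylalanine, ~1660 cm-1 amide I, 1745 cm-1 ester C=O) follow standard
# biological Raman band tables.

PROTEIN_BANDS = (
    (1004.0, 8.0, 0.50),   # phenylalanine ring breathing
    (1100.0, 28.0, 0.22),  # C-N / C-C stretch
    (1250.0, 38.0, 0.30),  # amide III
    (1320.0, 30.0, 0.28),
    (1450.0, 26.0, 0.45),  # CH2/CH3 deformation
    (1660.0, 36.0, 0.80),  # amide I
)
GLYCOGEN_BANDS = (
    (865.0, 18.0, 0.90),
    (942.0, 18.0, 1.00),
)
LIPID_BANDS = (
    (1080.0, 26.0, 0.25),
    (1300.0, 24.0, 0.38),  # CH2 twist
    (1440.0, 20.0, 1.00),  # CH2 scissoring -- dominant lipid marker
    (1660.0, 30.0, 0.40),  # C=C stretch
    (1745.0, 16.0, 0.20),  # ester carbonyl
)
CHOLESTEROL_LIPID_BANDS = (
    (700.0, 12.0, 0.65),   # cholesterol ring vibration
    (1300.0, 24.0, 0.30),
    (1440.0, 20.0, 0.90),
    (1670.0, 26.0, 0.30),
)
# second protein component seen in organoids: amide III and ~1100 cm-1
# regions differ from the cytoplasmic profile
PROTEIN2_BANDS = (
    (1004.0, 8.0, 0.45),
    (1100.0, 28.0, 0.65),
    (1250.0, 38.0, 0.06),
    (1320.0, 30.0, 0.65),
    (1450.0, 26.0, 0.40),
    (1660.0, 36.0, 0.65),
)
# weak, amide-I-heavy profile for intercellular spaces (highly diluted protein)
INTERCELLULAR_BANDS = (
    (1004.0, 8.0, 0.06),
    (1250.0, 50.0, 0.08),
    (1450.0, 30.0, 0.12),
    (1660.0, 45.0, 0.55),
)

_BLANK_NAMES = {"medium", "blank"}


@dataclass(frozen=True)
class TissueClassProfile:
    """Ground-truth description of one biochemical class.

    ``gamma_B_median`` is the sample-intrinsic linewidth, before the
    instrumental broadening that the generator adds and the fitting stage
    removes.  ``raman_bands`` is a tuple of (center cm-1, FWHM cm-1,
    relative amplitude); it may be empty only for the medium/blank class.
    """

    name: str
    nu_B_median: float
    gamma_B_median: float
    nu_B_spread: float = 0.05
    gamma_B_spread: float = 0.05
    raman_bands: tuple = ()

    def __post_init__(self):
        if self.nu_B_median <= 0 or self.gamma_B_median <= 0:
            raise ValueError("medians must be positive")
        if any(a < 0 for _, _, a in self.raman_bands):
            raise ValueError("band amplitudes must be non-negative")
        if not self.raman_bands and self.name not in _BLANK_NAMES:
            raise ValueError(
                f"profile {self.name!r} has no Raman bands; only "
                "medium/blank profiles may be band-free")

    @property
    def is_blank(self) -> bool:
        return not self.raman_bands


def spheroid_profiles(cell_line: str = "U87-MG") -> dict[str, TissueClassProfile]:
    """Class profiles for spheroid phantoms of one cell line.

    Per-class Brillouin medians follow the published per-cluster values for
    the corresponding cell line; they act as generator settings, and the
    tests check their recovery rather than the values themselves.
    """
    table = {
        "U87-MG": {"cytoplasm": (5.36, 0.44), "lipid_droplet": (5.39, 0.59),
                   "protein_glycogen": (5.38, 0.51)},
        "HT18136": {"cytoplasm": (5.37, 0.42), "lipid_droplet": (5.39, 0.45),
                    "protein_glycogen": (5.39, 0.47)},
        "HT18584": {"cytoplasm": (5.36, 0.41), "lipid_droplet": (5.38, 0.44)},
    }
    if cell_line not in table:
        raise ValueError(f"unknown cell line {cell_line!r}")
    bands = {"cytoplasm": PROTEIN_BANDS,
             "lipid_droplet": LIPID_BANDS,
             "protein_glycogen": PROTEIN_BANDS + GLYCOGEN_BANDS}
    out = {name: TissueClassProfile(name, nu, ga, raman_bands=bands[name])
           for name, (nu, ga) in table[cell_line].items()}
    out["medium"] = TissueClassProfile("medium", 5.10, 0.25,
                                       nu_B_spread=0.02, gamma_B_spread=0.02)
    return out


def organoid_profiles() -> dict[str, TissueClassProfile]:
    """Class profiles for organoid phantoms (five tissue classes + medium)."""
    out = {
        "cytoplasm": TissueClassProfile(
            "cytoplasm", 5.37, 0.45, raman_bands=PROTEIN_BANDS),
        "lipid_droplet": TissueClassProfile(
            "lipid_droplet", 5.32, 0.46, raman_bands=LIPID_BANDS),
        "protein": TissueClassProfile(
            "protein", 5.24, 0.36, raman_bands=PROTEIN2_BANDS),
        "cholesterol_lipid": TissueClassProfile(
            "cholesterol_lipid", 5.40, 0.80, raman_bands=CHOLESTEROL_LIPID_BANDS),
        "intercellular": TissueClassProfile(
            "intercellular", 5.20, 0.32, raman_bands=INTERCELLULAR_BANDS),
        "medium": TissueClassProfile("medium", 5.10, 0.25,
                                     nu_B_spread=0.02, gamma_B_spread=0.02),
    }
    return out


@dataclass
class PhantomConfig:
    """Geometry, optics and noise settings of one phantom acquisition."""

    layout: str = "raster"            # "raster" | "line"
    n_rows: int = 50
    n_cols: int = 50
    step_um: float = 2.0
    class_profiles: dict = field(default_factory=spheroid_profiles)
    class_fractions: dict | None = None   # line layouts: tissue-class mix
    medium_fraction: float = 0.15         # line layouts: blank/medium points
    noise_level: str | float = "0.2s"
    rayleigh_fwhm: float = 0.40           # GHz; 0.40 spheroids, 0.33 organoids
    dispersion_true: float = 0.044        # GHz/pixel
    reference_shift: float = METHANOL_SHIFT_GHZ
    n_pixels: int = 512
    elastic_pixel: float = 255.5
    sample_amplitude: float = 1000.0
    reference_amplitude: float = 650.0
    reference_intrinsic_fwhm: float = 0.30
    wavenumber_lo: float = 600.0
    wavenumber_hi: float = 1800.0
    wavenumber_step: float = 2.0
    raman_noise_sd: float = RAMAN_NOISE_SD
    raman_baseline: tuple = (0.8, 0.6, -0.3)  # polynomial coefficients, a.u.
    seed: int = 0

    def __post_init__(self):
        if self.layout not in ("raster", "line"):
            raise ValueError("layout must be 'raster' or 'line'")
        if self.dispersion_true <= 0:
            raise ValueError("dispersion_true must be positive")
        if self.n_rows < 1 or self.n_cols < 1 or self.step_um <= 0:
            raise ValueError("invalid grid")

    def _noise_params(self) -> tuple[float, float]:
        lvl = self.noise_level
        if isinstance(lvl, str):
            if lvl not in NOISE_LEVELS:
                raise ValueError(f"unknown noise regime {lvl!r}")
            return NOISE_LEVELS[lvl]
        return float(lvl), 0.0

    @property
    def brillouin_noise_sd(self) -> float:
        """Absolute CCD noise SD in counts."""
        return self._noise_params()[0] * self.sample_amplitude

    @property
    def width_jitter_sd(self) -> float:
        """Per-spectrum SD of the instrumental-broadening jitter (GHz)."""
        return self._noise_params()[1]

    def wavenumber_axis(self) -> np.ndarray:
        return np.arange(self.wavenumber_lo,
                         self.wavenumber_hi + 0.5 * self.wavenumber_step,
                         self.wavenumber_step)


@dataclass(frozen=True)
class StudyDesign:
    """Bookkeeping of an acquisition campaign.

    ``acquisitions`` is a tuple of (n_maps, points_per_map) pairs; the total
    observation count is the exact product-sum.
    """

    acquisitions: tuple

    def __post_init__(self):
        for n_maps, pts in self.acquisitions:
            if int(n_maps) != n_maps or int(pts) != pts or n_maps < 0 or pts < 0:
                raise ValueError("acquisitions must be non-negative integers")


def count_observations(design: StudyDesign) -> int:
    """Total number of point observations: sum of maps x points (exact)."""
    return int(sum(int(n) * int(p) for n, p in design.acquisitions))


@dataclass
class SpectralMap:
    """One generated phantom map with per-point ground truth."""

    config: PhantomConfig
    x_um: np.ndarray
    y_um: np.ndarray
    labels: list                 # ground-truth class name per point
    nu_B_true: np.ndarray
    gamma_B_true: np.ndarray
    brillouin: list              # BrillouinRawSpectrum per point
    raman: list | None           # RamanSpectrum per point (line layouts)

    @property
    def n_points(self) -> int:
        return len(self.labels)


def generate_brillouin_spectrum(nu_B: float, gamma_B_intrinsic: float,
                                config: PhantomConfig,
                                rng: np.random.Generator) -> BrillouinRawSpectrum:
    """One CCD spectrum: sample and reference Stokes/anti-Stokes bands.

    Bands are Lorentzians placed symmetrically about the elastic-line pixel;
    each generated FWHM is the intrinsic linewidth plus the Rayleigh FWHM
    (Lorentzian convolution widths add).  Additive Gaussian noise is scaled
    by the configured acquisition regime.  Ground truth is stored in the
    metadata, including the reference- and sample-band pixel positions that
    the fitting stage may use as hints.
    """
    if nu_B <= 0 or gamma_B_intrinsic <= 0:
        raise ValueError("nu_B and gamma_B_intrinsic must be positive")
    disp = config.dispersion_true
    ep = config.elastic_pixel
    x = np.arange(config.n_pixels, dtype=float)

    # instrumental broadening with optional per-spectrum alignment jitter
    jitter_sd = config.width_jitter_sd
    instrumental = config.rayleigh_fwhm
    if jitter_sd > 0:
        instrumental = max(instrumental + rng.normal(0.0, jitter_sd),
                           0.05 * config.rayleigh_fwhm)
    fwhm_sample = gamma_B_intrinsic + instrumental
    fwhm_ref = config.reference_intrinsic_fwhm + instrumental
    off_s = nu_B / disp
    off_r = config.reference_shift / disp
    centers = np.array([ep - off_s, ep + off_s, ep - off_r, ep + off_r])
    widths_px = np.array([fwhm_sample, fwhm_sample, fwhm_ref, fwhm_ref]) / disp
    amps = np.array([config.sample_amplitude, config.sample_amplitude,
                     config.reference_amplitude, config.reference_amplitude])
    if np.any(centers - widths_px / 2 < 0) or \
       np.any(centers + widths_px / 2 > config.n_pixels - 1):
        raise ValueError("bands fall outside the pixel axis; reject config")

    y = np.zeros_like(x)
    for c, w, a in zip(centers, widths_px, amps):
        y += lorentzian(x, c, w, a)
    sd = config.brillouin_noise_sd
    if sd > 0:
        y = y + rng.normal(0.0, sd, size=x.size)

    overlap = abs(nu_B - config.reference_shift) < 0.5 * (fwhm_sample + fwhm_ref)
    meta = {
        "nu_B_true": nu_B,
        "gamma_B_true": gamma_B_intrinsic,
        "rayleigh_fwhm": config.rayleigh_fwhm,
        "dispersion_true": disp,
        "elastic_pixel_true": ep,
        "reference_pixels": (centers[2], centers[3]),
        "sample_pixels": (centers[0], centers[1]),
        "noise_sd": sd,
        "overlap_warning": bool(overlap),
    }
    return BrillouinRawSpectrum(pixel=x, intensity=y, metadata=meta)


def _raman_baseline(axis: np.ndarray, coeffs) -> np.ndarray:
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    return sum(c * t ** i for i, c in enumerate(coeffs))


def gaussian_band(x: np.ndarray, center: float, fwhm: float,
                  amplitude: float) -> np.ndarray:
    """Gaussian line shape parameterised by FWHM (used for Raman bands)."""
    return amplitude * np.exp(-4.0 * np.log(2.0) * (x - center) ** 2
                              / fwhm ** 2)


def generate_raman_spectrum(profile: TissueClassProfile,
                            config: PhantomConfig,
                            rng: np.random.Generator) -> RamanSpectrum:
    """Sum of the profile's bands (Gaussian line shapes) plus a smooth
    polynomial baseline and additive Gaussian noise; class label kept as
    ground truth."""
    axis = config.wavenumber_axis()
    if not profile.raman_bands and not profile.is_blank:
        raise ValueError("non-blank profile without bands")
    for c, _, _ in profile.raman_bands:
        if not (axis[0] <= c <= axis[-1]):
            raise ValueError(f"band center {c} outside wavenumber axis")
    y = _raman_baseline(axis, config.raman_baseline)
    for c, w, a in profile.raman_bands:
        y = y + gaussian_band(axis, c, w, a)
    if config.raman_noise_sd > 0:
        y = y + rng.normal(0.0, config.raman_noise_sd, size=axis.size)
    return RamanSpectrum(wavenumber=axis, intensity=y, state="raw",
                         label=profile.name)


def _assign_classes(config: PhantomConfig, rng: np.random.Generator):
    """Per-point ground-truth class labels.

    Raster layouts place a disc of tissue in medium, with seeded droplet /
    glycogen (or other minority-class) blobs inside the disc.  Line layouts
    put medium at the line ends and draw interior classes from the
    configured mix.
    """
    names = [n for n in config.class_profiles if n not in _BLANK_NAMES]
    has_medium = any(n in _BLANK_NAMES for n in config.class_profiles)
    nr, nc = config.n_rows, config.n_cols
    n = nr * nc

    if config.layout == "raster":
        rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
        radius = 0.42 * min(nr, nc)
        inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
        labels = np.full((nr, nc), "medium" if has_medium else names[0],
                         dtype=object)
        labels[inside] = names[0]
        # minority classes as small blobs inside the disc
        minority = names[1:]
        idx_inside = np.argwhere(inside)
        for mi, mname in enumerate(minority):
            n_blobs = max(1, int(0.01 * idx_inside.shape[0]))
            blob_r = 1.5
            for _ in range(n_blobs):
                center = idx_inside[rng.integers(idx_inside.shape[0])]
                d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
                labels[(d2 <= blob_r ** 2) & inside] = mname
        return list(labels.ravel())

    # line layout
    frac = config.class_fractions
    if frac is None:
        frac = {name: 1.0 / len(names) for name in names}
    tot = sum(frac.values())
    probs = np.array([frac.get(name, 0.0) / tot for name in names])
    n_medium = int(round(config.medium_fraction * n)) if has_medium else 0
    interior = rng.choice(len(names), size=n - n_medium, p=probs)
    labels = ["medium"] * (n_medium // 2)
    labels += [names[i] for i in interior]
    labels += ["medium"] * (n_medium - n_medium // 2)
    return labels


def generate_phantom_map(config: PhantomConfig) -> SpectralMap:
    """Generate a full phantom map; deterministic under a fixed seed.

    Raster layouts carry Brillouin spectra only; line layouts additionally
    carry a co-localized Raman spectrum per point.
    """
    rng = np.random.default_rng(config.seed)
    labels = _assign_classes(config, rng)
    nr, nc = config.n_rows, config.n_cols
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    x_um = cc.ravel() * config.step_um
    y_um = rr.ravel() * config.step_um

    nu_true = np.empty(len(labels))
    ga_true = np.empty(len(labels))
    brillouin = []
    raman = [] if config.layout == "line" else None
    for i, name in enumerate(labels):
        prof = config.class_profiles[name]
        nu = rng.normal(prof.nu_B_median, prof.nu_B_spread)
        ga = rng.normal(prof.gamma_B_median, prof.gamma_B_spread)
        ga = max(ga, 0.05)  # keep linewidths physical in the far tail
        nu_true[i] = nu
        ga_true[i] = ga
        spec = generate_brillouin_spectrum(nu, ga, config, rng)
        spec.metadata["position_um"] = (float(x_um[i]), float(y_um[i]))
        spec.metadata["class"] = name
        brillouin.append(spec)
        if raman is not None:
            raman.append(generate_raman_spectrum(prof, config, rng))
    return SpectralMap(config=config, x_um=x_um, y_um=y_um, labels=labels,
                       nu_B_true=nu_true, gamma_B_true=ga_true,
                       brillouin=brillouin, raman=raman)


# ---------------------------------------------------------------------------
# Ready-made study configurations


def u87_line_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Co-localized line map through a U87-MG-like spheroid: 1 x 50 points,
    1 um step, 45 s acquisition, three tissue classes plus medium."""
    kw = dict(layout="line", n_rows=1, n_cols=50, step_um=1.0,
              class_profiles=spheroid_profiles("U87-MG"),
              class_fractions={"cytoplasm": 0.55, "lipid_droplet": 0.20,
                               "protein_glycogen": 0.25},
              medium_fraction=0.0, noise_level="45s", rayleigh_fwhm=0.40,
              seed=seed)
    kw.update(overrides)
    return PhantomConfig(**kw)


def ht18584_line_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Line map through an HT18584-like spheroid: two tissue classes only."""
    kw = dict(layout="line", n_rows=1, n_cols=50, step_um=1.0,
              class_profiles=spheroid_profiles("HT18584"),
              class_fractions={"cytoplasm": 0.70, "lipid_droplet": 0.30},
              medium_fraction=0.0, noise_level="45s", rayleigh_fwhm=0.40,
              seed=seed)
    kw.update(overrides)
    return PhantomConfig(**kw)


def organoid_line_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Organoid-like combined line: 20 points, 5 um step, five tissue
    classes plus a medium/blank fraction, 330 MHz Rayleigh regime."""
    kw = dict(layout="line", n_rows=1, n_cols=20, step_um=5.0,
              class_profiles=organoid_profiles(),
              class_fractions={"cytoplasm": 0.30, "lipid_droplet": 0.18,
                               "protein": 0.22, "cholesterol_lipid": 0.12,
                               "intercellular": 0.18},
              medium_fraction=0.15, noise_level="150s", rayleigh_fwhm=0.33,
              seed=seed)
    kw.update(overrides)
    return PhantomConfig(**kw)


def spheroid_map_config(cell_line: str = "U87-MG", seed: int = 0,
                        **overrides) -> PhantomConfig:
    """Raster Brillouin map of a spheroid: 50 x 50 points, 2 um step, 0.2 s
    acquisition."""
    kw = dict(layout="raster", n_rows=50, n_cols=50, step_um=2.0,
              class_profiles=spheroid_profiles(cell_line),
              noise_level="0.2s", rayleigh_fwhm=0.40, seed=seed)
    kw.update(overrides)
    return PhantomConfig(**kw)
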