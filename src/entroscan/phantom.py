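"""Synthetic speckle phantoms with controlled envelope statistics.

The simulator implements the minimal point-scatterer convolution model that
produces the pre-Rayleigh → Rayleigh continuum entropy imaging exploits: a
random field of point scatterers (uniform positions, configurable number
density per resolution cell and amplitude distribution) convolved axially
with a Gaussian-modulated sinusoid whose −6 dB envelope length equals the
pulse length.  Dense constant-amplitude scatterers (≥ 10 per resolution
cell) give fully developed speckle with a Rayleigh envelope (envelope SNR
≈ 1.91); sparse fields give pre-Rayleigh statistics (SNR < 1.91).

The steatosis stand-in follows the standard acoustic picture of fatty
liver: normal parenchyma is a quasi-regular (phase-coherent) lattice of
effective scatterers — the lobules — plus weak diffuse scattering and
sparse bright structural echoes, all under depth attenuation and a smooth
echogenicity texture; steatosis adds randomly distributed sub-resolution
fat scatterers that raise the diffuse floor.  Grade-to-parameter mapping
uses the Brunt hepatocyte-percentage cutoffs (<5%, 5–33%, 33–66%, >66%) as
coverage fractions of the fat admixture — a mnemonic, not a claim of
acoustic realism.  Everything downstream of a fixed seed is
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io import AcquisitionMeta, RFFrame

__all__ = [
    "Region",
    "ScattererPopulation",
    "PhantomSpec",
    "Subject",
    "default_meta",
    "resolution_cell_samples",
    "simulate_rf",
    "envelope_snr",
    "grade_phantom_spec",
    "make_cohort",
    "make_continuous_cohort",
    "subject_seed",
    "GRADE_COVERAGE",
    "RAYLEIGH_ENVELOPE_SNR",
    "HFF_SPAN_PERCENT",
]

#: Envelope SNR (mean/std) of fully developed Rayleigh speckle, sqrt(pi/(4-pi)).
RAYLEIGH_ENVELOPE_SNR = float(np.sqrt(np.pi / (4.0 - np.pi)))

#: Fat-admixture coverage fraction per steatosis grade (Brunt-cutoff mnemonic).
GRADE_COVERAGE = {0: 0.0, 1: 0.05, 2: 0.33, 3: 0.66}

#: Continuous-severity span emulated by the cohort generator (percent).
HFF_SPAN_PERCENT = (0.25, 44.66)

_FAT_DENSITY_FULL = 12.0  # added fat scatterers/cell at 100% coverage
_FAT_MEAN_GAIN = 1.4
_FAT_LOGNORMAL_SIGMA = 0.3
_DIFFUSE_DENSITY = 10.0  # weak diffuse scattering of normal parenchyma
_DIFFUSE_GAIN = 0.5
_STRUCTURAL_DENSITY = 1.0  # sparse bright structural echoes (vessels, tracts)
_STRUCTURAL_GAIN = 2.5


def default_meta(**overrides) -> AcquisitionMeta:
    """3 MHz center frequency, 12 MHz sampling, 2.3 mm pulse length."""
    kwargs = dict(
        sampling_frequency=12e6,
        center_frequency=3e6,
        pulse_length=2.3,
        scanline_pitch=0.3,
        geometry="linear",
    )
    kwargs.update(overrides)
    return AcquisitionMeta(**kwargs)


@dataclass(frozen=True)
class Region:
    """Rectangle (half-open index bounds) or ellipse in frame index space."""

    kind: str = "rect"  # "rect" | "ellipse"
    axial: tuple[float, float] = (0.0, -1.0)  # (-1, -1) means full extent
    lateral: tuple[float, float] = (0.0, -1.0)

    def resolve(self, frame_shape: tuple[int, int]) -> "Region":
        a = (0.0, float(frame_shape[0])) if self.axial[1] < 0 else self.axial
        l = (0.0, float(frame_shape[1])) if self.lateral[1] < 0 else self.lateral
        if not (0 <= a[0] < a[1] <= frame_shape[0] and 0 <= l[0] < l[1] <= frame_shape[1]):
            raise ConfigurationError("region must lie within the frame")
        return Region(kind=self.kind, axial=a, lateral=l)

    def area_samples(self) -> float:
        da = self.axial[1] - self.axial[0]
        dl = self.lateral[1] - self.lateral[0]
        if self.kind == "ellipse":
            return np.pi * (da / 2.0) * (dl / 2.0)
        return da * dl

    def contains(self, ax: np.ndarray, lat: np.ndarray) -> np.ndarray:
        if self.kind != "ellipse":
            return np.ones(ax.shape, dtype=bool)
        ca = (self.axial[0] + self.axial[1]) / 2.0
        cl = (self.lateral[0] + self.lateral[1]) / 2.0
        ra = (self.axial[1] - self.axial[0]) / 2.0
        rl = (self.lateral[1] - self.lateral[0]) / 2.0
        return ((ax - ca) / ra) ** 2 + ((lat - cl) / rl) ** 2 <= 1.0


@dataclass(frozen=True)
class ScattererPopulation:
    """One scatterer population: where, how many, how strong.

    ``coverage`` < 1 makes the population patchy: the region is tiled into
    resolution-cell-sized tiles and each tile carries the population with
    probability ``coverage`` (the fat-droplet picture of steatosis —
    fat-bearing lobule patches, not a uniform density change); ``density``
    then counts scatterers per *occupied* cell.
    """

    density: float  # scatterers per resolution cell
    region: Region = field(default_factory=Region)
    amplitude_dist: str = "constant"  # constant | uniform | lognormal
    mean_gain: float = 1.0
    coverage: float = 1.0
    arrangement: str = "random"  # random | lattice (quasi-regular)
    jitter: float = 0.005  # lattice node jitter, fraction of spacing (sub-wavelength)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ConfigurationError("scatterer density must be > 0")
        if not 0.0 < self.coverage <= 1.0:
            raise ConfigurationError("coverage must lie in (0, 1]")
        if self.amplitude_dist not in ("constant", "uniform", "lognormal"):
            raise ConfigurationError(f"unknown amplitude_dist {self.amplitude_dist!r}")
        if self.arrangement not in ("random", "lattice"):
            raise ConfigurationError(f"unknown arrangement {self.arrangement!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic frame; same spec + seed => same frame."""

    frame_shape: tuple[int, int] = (1024, 64)
    meta: AcquisitionMeta = field(default_factory=default_meta)
    background_density: float = 6.0
    background_arrangement: str = "random"
    inclusions: tuple[ScattererPopulation, ...] = ()
    lateral_psf_scanlines: float = 0.0  # Gaussian sigma; 0 disables lateral PSF
    noise_std: float = 0.0
    attenuation_db_cm: float = 0.0  # round-trip amplitude decay at fc, dB/cm
    texture_sigma_ln: float = 0.0  # log-std of the echogenicity texture field
    texture_corr_mm: float = 6.0  # correlation length of the texture field
    gain: float = 1.0  # overall frame gain (scanner / coupling factor)
    rng_seed: int = 0


def resolution_cell_samples(meta: AcquisitionMeta) -> float:
    """Resolution-cell area used for density accounting: 1 PL axially ×
    2 scanlines laterally, in sample units."""
    return meta.pulse_length_samples * 2.0


def _axial_pulse_params(meta: AcquisitionMeta) -> tuple[float, float, int]:
    """(sigma_samples, cycles_per_sample, half_support) of the axial pulse."""
    width = meta.pulse_length_samples  # -6 dB full width of the envelope
    sigma = width / np.sqrt(8.0 * np.log(1.0 / 10 ** (-6.0 / 20.0)))
    f0 = meta.center_frequency / meta.sampling_frequency
    half = int(np.ceil(3.8 * sigma))
    return sigma, f0, half


def _draw_amplitudes(
    pop: ScattererPopulation, n: int, rng: np.random.Generator
) -> np.ndarray:
    if pop.amplitude_dist == "constant":
        return np.full(n, pop.mean_gain)
    if pop.amplitude_dist == "uniform":
        return rng.uniform(0.5, 1.5, n) * pop.mean_gain
    # lognormal parameterized so the mean equals mean_gain
    sigma = _FAT_LOGNORMAL_SIGMA
    mu = np.log(pop.mean_gain) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, n)


def _lattice_positions(
    pop: ScattererPopulation,
    region: Region,
    meta: AcquisitionMeta,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-regular scatterer positions: one node per lattice site (one site
    per scanline, axial spacing of one carrier wavelength) with Gaussian
    positional jitter — the regular-lobule picture of normal parenchyma.

    Wavelength spacing makes the regular component sum phase-coherently with
    negligible inter-node envelope ripple, giving the narrow Rician-like
    envelope of structured tissue rather than speckle.  The population's
    ``density`` is preserved as total scattering strength by rescaling the
    per-node amplitude in the simulator."""
    spacing = meta.sampling_frequency / meta.center_frequency  # 1 wavelength
    a_nodes = np.arange(region.axial[0] + spacing / 2.0, region.axial[1], spacing)
    l_nodes = np.arange(np.ceil(region.lateral[0]), region.lateral[1], 1.0)
    aa, ll = np.meshgrid(a_nodes, l_nodes, indexing="ij")
    # jitter axially only: lateral jitter has no meaning without a lateral PSF
    ax = aa.ravel() + rng.normal(0.0, pop.jitter * spacing, aa.size)
    lat = ll.ravel()
    keep = (ax >= region.axial[0]) & (ax < region.axial[1])
    return ax[keep], lat[keep]


def _patchy_positions(
    pop: ScattererPopulation,
    region: Region,
    meta: AcquisitionMeta,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatterer positions for a patchy population: resolution-cell tiles are
    occupied independently with probability ``coverage``; occupied tiles get
    Poisson(density) scatterers uniformly inside them."""
    ta = meta.pulse_length_samples  # tile size: 1 PL x 2 scanlines
    tl = 2.0
    a_edges = np.arange(region.axial[0], region.axial[1], ta)
    l_edges = np.arange(region.lateral[0], region.lateral[1], tl)
    axs, lats = [], []
    for a0 in a_edges:
        a1 = min(a0 + ta, region.axial[1])
        occupied = rng.random(l_edges.size) < pop.coverage
        counts = rng.poisson(pop.density * ((a1 - a0) / ta), l_edges.size)
        for l0, occ, cnt in zip(l_edges, occupied, counts):
            if not occ or cnt == 0:
                continue
            l1 = min(l0 + tl, region.lateral[1])
            axs.append(rng.uniform(a0, a1, cnt))
            lats.append(rng.uniform(l0, l1, cnt))
    if not axs:
        return np.empty(0), np.empty(0)
    return np.concatenate(axs), np.concatenate(lats)


def _texture_field(
    frame_shape: tuple[int, int],
    meta: AcquisitionMeta,
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian field with ~``corr_mm`` correlation length:
    independent N(0,1) node values on a grid spaced one correlation length
    apart, interpolated bilinearly to the sample grid."""
    from scipy.interpolate import RegularGridInterpolator

    na, nl = frame_shape
    step_ax = max(2.0, corr_mm / meta.depth_per_sample_mm)
    step_lat = max(2.0, corr_mm / meta.lateral_pitch_mm())
    ax_nodes = np.arange(-step_ax, na + 2 * step_ax, step_ax)
    lat_nodes = np.arange(-step_lat, nl + 2 * step_lat, step_lat)
    values = rng.normal(0.0, 1.0, (ax_nodes.size, lat_nodes.size))
    interp = RegularGridInterpolator((ax_nodes, lat_nodes), values, method="linear")
    rr, cc = np.meshgrid(np.arange(na), np.arange(nl), indexing="ij")
    return interp(np.stack([rr, cc], axis=-1))


def simulate_rf(spec: PhantomSpec) -> RFFrame:
    """Simulate one RF frame from the point-scatterer convolution model.

    Scatterer counts are Poisson with mean density × number of resolution
    cells in the region; positions are uniform (continuous axially, discrete
    per scanline unless a lateral PSF is enabled).  Each scatterer deposits an
    amplitude-scaled Gaussian-modulated cosine evaluated at its sub-sample
    axial position, which is what gives the envelope its continuous phase
    statistics.
    """
    rng = np.random.default_rng(spec.rng_seed)
    na, nl = spec.frame_shape
    meta = spec.meta
    cell = resolution_cell_samples(meta)
    sigma, f0, half = _axial_pulse_params(meta)
    rf = np.zeros((na, nl))

    populations = [
        ScattererPopulation(
            density=spec.background_density, arrangement=spec.background_arrangement
        )
    ] + list(spec.inclusions)

    lat_sigma = spec.lateral_psf_scanlines
    lat_half = int(np.ceil(3.0 * lat_sigma)) if lat_sigma > 0 else 0
    lat_offsets = np.arange(-lat_half, lat_half + 1)
    lat_weights = (
        np.exp(-0.5 * (lat_offsets / lat_sigma) ** 2) if lat_sigma > 0 else np.ones(1)
    )

    att = spec.attenuation_db_cm
    dps_mm = meta.depth_per_sample_mm

    # Slowly varying multiplicative echogenicity texture (log-normal field):
    # emulates parenchymal inhomogeneity on top of the speckle statistics.
    texture = None
    if spec.texture_sigma_ln > 0:
        texture = np.exp(
            spec.texture_sigma_ln
            * _texture_field(spec.frame_shape, meta, spec.texture_corr_mm, rng)
        )

    for pop in populations:
        region = pop.region.resolve(spec.frame_shape)
        if pop.arrangement == "lattice":
            ax, lat = _lattice_positions(pop, region, meta, rng)
        elif pop.coverage < 1.0:
            ax, lat = _patchy_positions(pop, region, meta, rng)
        else:
            mean_count = pop.density * region.area_samples() / cell
            count = int(rng.poisson(mean_count))
            ax = rng.uniform(region.axial[0], region.axial[1], count)
            lat = rng.uniform(region.lateral[0], region.lateral[1], count)
        if ax.size == 0:
            warnings.warn("scatterer population drew zero scatterers (sparse regime)")
            continue
        keep = region.contains(ax, lat)
        ax, lat = ax[keep], lat[keep]
        amp = _draw_amplitudes(pop, ax.size, rng)
        if pop.arrangement == "lattice":
            # keep total scattering strength = density x cells regardless of
            # the wavelength-locked node count
            amp = amp * (pop.density * region.area_samples() / cell) / ax.size
        if att > 0:
            amp = amp * 10.0 ** (-att * (ax * dps_mm / 10.0) / 20.0)
        if texture is not None:
            ai = np.clip(ax.astype(int), 0, na - 1)
            li = np.clip(lat.astype(int), 0, nl - 1)
            amp = amp * texture[ai, li]
        cols = np.minimum(lat.astype(int), nl - 1)
        for a, j, A in zip(ax, cols, amp):
            lo = max(0, int(np.ceil(a - half)))
            hi = min(na - 1, int(np.floor(a + half)))
            if hi < lo:
                continue
            t = np.arange(lo, hi + 1) - a
            wave = A * np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2.0 * np.pi * f0 * t)
            for k, w in zip(lat_offsets, lat_weights):
                jj = j + int(k)
                if 0 <= jj < nl:
                    rf[lo : hi + 1, jj] += w * wave

    if spec.noise_std > 0:
        rf += rng.normal(0.0, spec.noise_std, rf.shape)
    if spec.gain != 1.0:
        rf *= spec.gain
    return RFFrame(samples=rf, meta=meta)


def envelope_snr(amplitude: np.ndarray) -> float:
    """Envelope SNR mean/std; ≈ 1.91 for fully developed (Rayleigh) speckle."""
    vals = np.asarray(amplitude, dtype=np.float64).ravel()
    return float(np.mean(vals) / np.std(vals))


def grade_phantom_spec(
    grade: int,
    seed: int,
    frame_shape: tuple[int, int] = (1024, 64),
    meta: AcquisitionMeta | None = None,
    coverage: float | None = None,
    diffuse_gain: float = _DIFFUSE_GAIN,
    structural_density: float = _STRUCTURAL_DENSITY,
    gain: float = 1.0,
) -> PhantomSpec:
    """Phantom spec for one steatosis grade (or explicit coverage fraction).

    Normal parenchyma is modeled per the standard acoustic picture of liver:
    a quasi-regular, phase-coherent lattice of effective scatterers (the
    lobules; density 6 per resolution cell), a weak diffuse random population
    (10 per cell at gain 0.5), and sparse bright structural echoes (vessel
    walls and portal tracts; 1 per cell at gain 2.5), under 4 dB/cm
    round-trip attenuation (2 × 0.67 dB/cm/MHz at 3 MHz) and a log-normal
    parenchymal echogenicity texture (sigma 0.45, 4 mm correlation).

    Steatosis adds randomly distributed sub-resolution fat scatterers at
    density 12 × coverage per cell (gain 1.4): the diffuse component grows
    with grade, so envelope statistics move from coherent/Rician-like toward
    Rayleigh, backscattered power rises (brighter B-mode), and the fixed
    structural echoes lose prominence against the rising diffuse floor (the
    sonographic smoothing of fatty liver).  Both entropy estimators increase
    along this continuum.
    """
    if meta is None:
        meta = default_meta()
    if coverage is None:
        if grade not in GRADE_COVERAGE:
            raise ConfigurationError(f"grade must be one of {sorted(GRADE_COVERAGE)}")
        coverage = GRADE_COVERAGE[grade]
    inclusions = [
        ScattererPopulation(density=_DIFFUSE_DENSITY, mean_gain=diffuse_gain),
        ScattererPopulation(density=structural_density, mean_gain=_STRUCTURAL_GAIN),
    ]
    if coverage > 0:
        inclusions.append(
            ScattererPopulation(
                density=_FAT_DENSITY_FULL * coverage,
                amplitude_dist="constant",
                mean_gain=_FAT_MEAN_GAIN,
            )
        )
    return PhantomSpec(
        frame_shape=frame_shape, meta=meta, background_density=6.0,
        background_arrangement="lattice", inclusions=tuple(inclusions),
        attenuation_db_cm=4.0, texture_sigma_ln=0.45, texture_corr_mm=4.0,
        gain=gain, rng_seed=seed,
    )


def _subject_variability(
    cohort_seed: int, index: int
) -> dict[str, float]:
    """Per-subject biological / instrumental variability of the liver model:
    lognormal multipliers on overall gain (sigma 0.08, scanner and body-wall
    coupling), diffuse scattering gain (sigma 0.20) and structural-echo
    density (sigma 0.10)."""
    rng = np.random.default_rng(np.random.SeedSequence((cohort_seed, index, 1)))
    return {
        "gain": float(rng.lognormal(0.0, 0.08)),
        "diffuse_gain": _DIFFUSE_GAIN * float(rng.lognormal(0.0, 0.20)),
        "structural_density": _STRUCTURAL_DENSITY * float(rng.lognormal(0.0, 0.10)),
    }


@dataclass(frozen=True)
class Subject:
    """One synthetic subject: a phantom spec plus its diagnostic label."""

    subject_id: str
    spec: PhantomSpec
    grade: int | None = None
    severity: float | None = None


def subject_seed(cohort_seed: int, index: int) -> int:
    """Per-subject child seed: a documented counter scheme on top of
    ``numpy.random.SeedSequence`` so cohorts are reproducible under
    resumption.  Always < 2**31."""
    return int(np.random.SeedSequence((cohort_seed, index)).generate_state(1)[0] % 2**31)


def make_cohort(
    n_per_grade: tuple[int, int, int, int] = (80, 70, 36, 18),
    seed: int = 0,
    frame_shape: tuple[int, int] = (384, 32),
    meta: AcquisitionMeta | None = None,
    grade_coverage: dict[int, float] | None = None,
) -> list[Subject]:
    """Graded synthetic cohort (default class sizes 80/70/36/18 for G0–G3).

    The grade → scatterer-complexity mapping must be strictly increasing;
    non-monotone mappings are rejected.
    """
    cov = dict(GRADE_COVERAGE if grade_coverage is None else grade_coverage)
    grades = sorted(cov)
    if any(cov[a] >= cov[b] for a, b in zip(grades, grades[1:])):
        raise ConfigurationError("grade mapping must be strictly increasing in complexity")
    subjects: list[Subject] = []
    idx = 0
    for grade, n in zip(grades, n_per_grade):
        for _ in range(n):
            spec = grade_phantom_spec(
                grade, subject_seed(seed, idx), frame_shape, meta,
                coverage=cov[grade], **_subject_variability(seed, idx),
            )
            subjects.append(Subject(subject_id=f"S{idx:04d}", spec=spec, grade=grade))
            idx += 1
    return subjects


def make_continuous_cohort(
    n_subjects: int = 72,
    seed: int = 0,
    frame_shape: tuple[int, int] = (384, 32),
    meta: AcquisitionMeta | None = None,
    severity_span: tuple[float, float] = HFF_SPAN_PERCENT,
) -> list[Subject]:
    """Continuous-severity cohort (fat-fraction stand-in, percent).

    Severities are log-uniform over ``severity_span`` so log10(severity) is
    uniformly exercised; the fat-admixture coverage is severity / 100.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
    lo, hi = severity_span
    sev = np.exp(rng.uniform(np.log(lo), np.log(hi), n_subjects))
    subjects = []
    for i, s in enumerate(sev):
        spec = grade_phantom_spec(
            -1, subject_seed(seed, i), frame_shape, meta,
            coverage=float(s) / 100.0, **_subject_variability(seed, i),
        )
        subjects.append(Subject(subject_id=f"C{i:04d}", spec=spec, severity=float(s)))
    return subjects
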