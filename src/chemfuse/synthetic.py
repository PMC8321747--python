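"""Seeded generator of LC-like and FTIR-like fingerprint blocks.

The generator emulates the statistical structure a geographical-traceability
study assumes: several geographic origin classes, two complementary
instrument blocks (chromatograms over a 60-min run; ATR-FTIR spectra over
4000-650 cm**-1), class-discriminative Gaussian peaks partly disjoint
between blocks, per-sample retention-time shifts (LC only), low-order
baseline drift, additive noise, and two FTIR regions (4000-3700 and
2670-1750 cm**-1) that carry elevated noise and no class signal.

Because the informative variables, shifts and class centroids are known by
construction, every downstream stage (alignment, selection, fusion,
evaluation) can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import FingerprintBlock

#: FTIR intervals (cm**-1) that must hold only noise: chemically silent /
#: ATR-crystal-interference regions that the pretreatment later removes.
FTIR_NOISE_BANDS = ((1750.0, 2670.0), (3700.0, 4000.0))

BLOCK_KINDS = ("lc", "ftir")


@dataclass(frozen=True)
class Peak:
    """One Gaussian constituent band.

    ``class_heights`` gives the mean apex height per origin class;
    ``latent_loading`` couples the height to a per-sample latent factor
    shared between blocks (models a sample-level chemotype that moves
    related constituents in both fingerprints together).
    """

    name: str
    block: str
    center: float
    width: float
    class_heights: tuple[float, ...]
    latent_loading: float = 0.0


@dataclass
class GeneratorConfig:
    n_per_class: int = 12
    n_classes: int = 5
    lc_points: int = 7201
    lc_minutes: float = 60.0
    ftir_points: int = 1737
    ftir_range: tuple[float, float] = (650.0, 4000.0)
    peak_table: list[Peak] = field(default_factory=list)
    shift_sd: float = 3.0          # retention-time jitter, in grid points
    noise_sd: float = 0.02         # additive noise scale
    baseline_amp: float = 0.05     # sd of random polynomial drift coefficients
    height_jitter: float = 0.08    # relative sd of per-sample peak heights
    latent_sd: float = 0.15        # sd of the shared latent chemotype factor
    noise_band_factor: float = 3.0  # noise multiplier inside FTIR_NOISE_BANDS
    informative_threshold: float = 0.2  # fraction of max class-mean range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.shift_sd < 0 or self.noise_sd < 0:
            raise ValueError("shift_sd and noise_sd must be >= 0")
        for p in self.peak_table:
            if p.block not in BLOCK_KINDS:
                raise ValueError(f"peak {p.name!r}: unknown block {p.block!r}")
            if p.width <= 0:
                raise ValueError(f"peak {p.name!r}: width must be > 0")
            if len(p.class_heights) != self.n_classes:
                raise ValueError(
                    f"peak {p.name!r}: needs {self.n_classes} class heights, "
                    f"got {len(p.class_heights)}")

    @property
    def n_samples(self) -> int:
        return self.n_per_class * self.n_classes

    def class_labels(self) -> list[str]:
        return [f"Class{c + 1}" for c in range(self.n_classes)]


@dataclass
class GroundTruth:
    """What the generator knows that an analyst would have to estimate."""

    informative_lc: np.ndarray   # column indices on the generated LC grid
    informative_ftir: np.ndarray  # column indices on the generated FTIR grid
    true_shifts: np.ndarray      # per-sample shift in points for this block


def default_design(n_per_class: int = 12, lc_points: int = 721,
                   ftir_points: int = 433, seed: int = 0,
                   **overrides) -> GeneratorConfig:
    """The package's reference study design.

    Five origin classes measured by both instruments.  Classes 3-5 each
    carry a strong marker peak in both blocks; classes 1 and 2 share all
    markers and differ only through one complementary peak pair: an LC peak
    where class 1 runs higher and an FTIR band where class 2 runs higher,
    both loaded on a shared latent factor.  Within either single block the
    latent variation masks the small class-1/2 offset, while the
    *difference* of the two peaks cancels the latent factor and doubles the
    offset — so the two classes are confusable per block but well separated
    jointly, and multi-block fusion has something real to gain.

    The grid sizes default to a reduced scale (721 LC / 433 FTIR points)
    that preserves the peak-to-grid geometry of the full-size instruments.
    """
    h = lambda *v: tuple(float(x) for x in v)
    even = lambda v: h(*([v] * 5))
    peaks = [
        # LC: common constituents
        Peak("lc_c1", "lc", 5.0, 0.35, even(1.2)),
        Peak("lc_c2", "lc", 12.0, 0.40, even(0.9)),
        Peak("lc_c3", "lc", 20.0, 0.50, even(1.4)),
        Peak("lc_c4", "lc", 28.5, 0.45, even(0.8)),
        Peak("lc_c5", "lc", 40.0, 0.50, even(1.0)),
        Peak("lc_c6", "lc", 52.0, 0.60, even(0.7)),
        # LC: origin markers
        Peak("lc_m12", "lc", 24.0, 0.50, h(1.1, 1.1, 0.3, 0.3, 0.3)),
        Peak("lc_m3", "lc", 16.0, 0.45, h(0.3, 0.3, 1.0, 0.3, 0.3)),
        Peak("lc_m4", "lc", 33.0, 0.50, h(0.3, 0.3, 0.3, 1.0, 0.3)),
        Peak("lc_m5", "lc", 45.0, 0.50, h(0.2, 0.2, 0.2, 0.2, 0.95)),
        # LC half of the complementary class-1/2 pair
        Peak("lc_A", "lc", 36.5, 0.50, h(1.0, 0.8, 0.25, 0.25, 0.25),
             latent_loading=1.0),
        # FTIR: common bands (kept clear of the noise-only regions)
        Peak("ftir_c1", "ftir", 1050.0, 30.0, even(1.2)),
        Peak("ftir_c2", "ftir", 1160.0, 25.0, even(0.8)),
        Peak("ftir_c3", "ftir", 1640.0, 35.0, even(1.0)),
        Peak("ftir_c4", "ftir", 2950.0, 40.0, even(0.9)),
        Peak("ftir_c5", "ftir", 3400.0, 80.0, even(1.1)),
        # FTIR: origin markers
        Peak("ftir_m12", "ftir", 1100.0, 25.0, h(1.0, 1.0, 0.35, 0.35, 0.35)),
        Peak("ftir_m3", "ftir", 1270.0, 25.0, h(0.3, 0.3, 0.9, 0.3, 0.3)),
        Peak("ftir_m4", "ftir", 1450.0, 28.0, h(0.3, 0.3, 0.3, 0.9, 0.3)),
        Peak("ftir_m5", "ftir", 2850.0, 30.0, h(0.25, 0.25, 0.25, 0.25, 0.9)),
        # FTIR half of the complementary pair (heights swapped vs lc_A)
        Peak("ftir_B", "ftir", 1550.0, 28.0, h(0.8, 1.0, 0.3, 0.3, 0.3),
             latent_loading=1.0),
    ]
    kwargs = dict(n_per_class=n_per_class, lc_points=lc_points,
                  ftir_points=ftir_points, peak_table=peaks, seed=seed)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def _block_axis(config: GeneratorConfig, block_kind: str) -> np.ndarray:
    if block_kind == "lc":
        return np.linspace(0.0, config.lc_minutes, config.lc_points)
    lo, hi = config.ftir_range
    return np.linspace(lo, hi, config.ftir_points)


def _in_bands(axis: np.ndarray, bands) -> np.ndarray:
    mask = np.zeros(axis.size, dtype=bool)
    for lo, hi in bands:
        mask |= (axis >= lo) & (axis <= hi)
    return mask


def _block_peaks(config: GeneratorConfig, block_kind: str) -> list[Peak]:
    return [p for p in config.peak_table if p.block == block_kind]


def _validate_peaks(config: GeneratorConfig, block_kind: str,
                    axis: np.ndarray) -> None:
    for p in _block_peaks(config, block_kind):
        if not (axis.min() <= p.center <= axis.max()):
            raise ValueError(
                f"peak {p.name!r}: center {p.center} outside axis range "
                f"[{axis.min()}, {axis.max()}]")
        if block_kind == "ftir":
            for lo, hi in FTIR_NOISE_BANDS:
                if p.center + 2 * p.width > lo and p.center - 2 * p.width < hi:
                    raise ValueError(
                        f"peak {p.name!r}: overlaps the noise-only band "
                        f"[{lo}, {hi}] cm^-1")


def class_mean_profiles(config: GeneratorConfig, block_kind: str,
                        axis: np.ndarray | None = None) -> np.ndarray:
    """Noiseless class centroids (n_classes x n) on the given axis.

    These equal the expected fingerprints: height jitter, the latent
    factor, shifts, drift and noise are all mean-zero perturbations.
    """
    if block_kind not in BLOCK_KINDS:
        raise ValueError(f"unknown block_kind {block_kind!r}")
    if axis is None:
        axis = _block_axis(config, block_kind)
    _validate_peaks(config, block_kind, axis)
    out = np.zeros((config.n_classes, axis.size))
    for p in _block_peaks(config, block_kind):
        shape = np.exp(-0.5 * ((axis - p.center) / p.width) ** 2)
        out += np.asarray(p.class_heights)[:, None] * shape[None, :]
    return out


def informative_columns(means: np.ndarray, threshold: float) -> np.ndarray:
    """Columns whose between-class mean range is at least ``threshold``
    times the largest range — the variables an ideal selector should find."""
    rng = means.max(axis=0) - means.min(axis=0)
    top = rng.max()
    if top <= 0:
        return np.array([], dtype=int)
    return np.flatnonzero(rng >= threshold * top)


def generate_block(config: GeneratorConfig, block_kind: str
                   ) -> tuple[FingerprintBlock, GroundTruth]:
    """Generate one seeded fingerprint block plus its ground truth.

    Identical ``config.seed`` gives bitwise-identical output.  The latent
    chemotype factor and the per-sample shifts are drawn from streams
    shared between block kinds, so the LC and FTIR blocks of one config
    describe the same physical samples.
    """
    if block_kind not in BLOCK_KINDS:
        raise ValueError(f"unknown block_kind {block_kind!r}; "
                         f"expected one of {BLOCK_KINDS}")
    axis = _block_axis(config, block_kind)
    _validate_peaks(config, block_kind, axis)
    m = config.n_samples
    n = axis.size
    classes = np.repeat(np.arange(config.n_classes), config.n_per_class)

    # streams shared across blocks: same samples, same latent state/shift
    latent = np.random.default_rng([config.seed, 101]).normal(
        0.0, config.latent_sd, m)
    shifts = np.rint(np.random.default_rng([config.seed, 102]).normal(
        0.0, config.shift_sd, m)).astype(int)
    rng = np.random.default_rng([config.seed, BLOCK_KINDS.index(block_kind)])

    peaks = _block_peaks(config, block_kind)
    jitter = rng.normal(0.0, config.height_jitter, (m, max(len(peaks), 1)))
    coeffs = rng.normal(0.0, config.baseline_amp, (m, 3))
    noise = rng.normal(0.0, 1.0, (m, n)) * config.noise_sd

    dt = axis[1] - axis[0] if n > 1 else 1.0
    true_shifts = shifts if block_kind == "lc" else np.zeros(m, dtype=int)

    values = np.zeros((m, n))
    for k, p in enumerate(peaks):
        heights = (np.asarray(p.class_heights)[classes] * (1.0 + jitter[:, k])
                   + p.latent_loading * latent)
        centers = p.center + true_shifts * dt
        shape = np.exp(-0.5 * ((axis[None, :] - centers[:, None]) / p.width) ** 2)
        values += heights[:, None] * shape

    u = np.linspace(0.0, 1.0, n)
    values += coeffs[:, :1] + coeffs[:, 1:2] * u + coeffs[:, 2:3] * u ** 2
    if block_kind == "ftir":
        band = _in_bands(axis, FTIR_NOISE_BANDS)
        noise[:, band] *= config.noise_band_factor
    values += noise

    labels = [f"Class{c + 1}" for c in classes]
    ids = [f"S{i + 1:03d}" for i in range(m)]
    block = FingerprintBlock(
        values, axis,
        "retention_time" if block_kind == "lc" else "wavenumber",
        ids, labels)

    thr = config.informative_threshold
    truth = GroundTruth(
        informative_lc=informative_columns(
            class_mean_profiles(config, "lc"), thr),
        informative_ftir=informative_columns(
            class_mean_profiles(config, "ftir"), thr),
        true_shifts=true_shifts,
    )
    return block, truth


def generate_dataset(config: GeneratorConfig
                     ) -> dict[str, tuple[FingerprintBlock, GroundTruth]]:
    """Both blocks of the design, keyed by block kind."""
    return {kind: generate_block(config, kind) for kind in BLOCK_KINDS}
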