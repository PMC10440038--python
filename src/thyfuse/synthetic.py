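"""Synthetic paired ultrasound/thermography phantom corpus.

The real paired-modality cohort this package targets is private, so the
generator produces a stand-in corpus with the same bookkeeping (paired
512x512 ultrasound and 320x240 thermography frames per case, benign or
malignant label, 6:2:2 stratified splits) and a controllable class signal:

* the **ultrasound** channel carries morphology — an elliptical nodule on
  multiplicative speckle whose boundary irregularity and aspect ratio are
  higher, and echogenicity lower, for malignant cases;
* the **thermography** channel carries thermal function — a smooth,
  left-right symmetric neck temperature field on which malignant cases
  superimpose a hotter, laterally displaced hotspot (higher amplitude and
  asymmetry).

Each case lists which modalities are *informative*; a modality not listed
draws its parameters from the class-neutral mixture and therefore carries
no class signal.  No claim of acoustic or bio-heat realism is made: the
phantoms exist so that every architectural mechanism is exercisable and
the learning task is solvable at desk scale.

All sampling distributions are fixed named constants in
:class:`PhantomParams` so tests can reference them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateSplitError, EmptyRegistryError, SpecValidationError

__all__ = [
    "PhantomParams", "CaseSpec", "DatasetRegistry",
    "sample_case", "generate_dataset", "default_registry", "stratified_split",
    "synthesize_us_image", "synthesize_irt_image", "contour_radii",
    "us_intensity_statistic", "irt_peak_statistic", "pixel_statistic_scores",
]

US_SIZE = 512                 # ultrasound frames are 512x512
IRT_SHAPE = (240, 320)        # thermography frames are 320x240 (width x height)
TEMP_MIN, TEMP_MAX = 20.0, 40.0   # sensor range, degrees Celsius


@dataclass(frozen=True)
class PhantomParams:
    """All phantom distribution constants (units: pixels, intensity in
    [0,1], temperature in degrees Celsius).  Class contrast is moderate by
    design: distributions overlap rather than saturate."""

    # -- ultrasound background
    bg_intensity: float = 0.55
    speckle_shape: float = 4.0        # Gamma shape of multiplicative speckle
    speckle_smooth: float = 1.2       # correlation length (px)
    edge_width: float = 0.04          # soft nodule edge, in normalized radius

    # -- nodule geometry (shared)
    semi_axis_lo: float = 45.0
    semi_axis_hi: float = 85.0
    center_jitter: float = 30.0
    harmonics: tuple[int, ...] = (2, 3, 4, 5, 6)

    # -- class-conditional morphology
    irregularity_benign: tuple[float, float] = (0.02, 0.08)
    irregularity_malignant: tuple[float, float] = (0.12, 0.30)
    aspect_benign: tuple[float, float] = (0.70, 1.05)      # height/width
    aspect_malignant: tuple[float, float] = (1.05, 1.60)   # taller-than-wide
    echo_benign: tuple[float, float] = (0.60, 0.08)        # mean, sd
    echo_malignant: tuple[float, float] = (0.40, 0.08)
    # class-neutral (uninformative-channel) morphology: the ambiguous
    # mid-range between the two class distributions
    irregularity_neutral: tuple[float, float] = (0.06, 0.14)
    aspect_neutral: tuple[float, float] = (0.90, 1.20)
    echo_neutral: tuple[float, float] = (0.50, 0.06)

    # -- thermography field
    ambient_temp: tuple[float, float] = (31.5, 0.4)        # mean, sd
    neck_amplitude: tuple[float, float] = (1.0, 2.5)       # symmetric warm region
    neck_sigma: tuple[float, float] = (55.0, 95.0)
    thermal_noise_sd: float = 0.15

    # -- class-conditional thermal function
    hotspot_benign: tuple[float, float] = (0.3, 1.2)       # amplitude, deg C
    hotspot_malignant: tuple[float, float] = (2.0, 4.5)
    hotspot_width_benign: tuple[float, float] = (18.0, 30.0)
    hotspot_width_malignant: tuple[float, float] = (14.0, 26.0)
    asymmetry_benign: tuple[float, float] = (0.0, 0.08)
    asymmetry_malignant: tuple[float, float] = (0.25, 0.60)
    # class-neutral thermal function (uninformative channel)
    hotspot_neutral: tuple[float, float] = (1.0, 2.2)
    hotspot_width_neutral: tuple[float, float] = (16.0, 28.0)
    asymmetry_neutral: tuple[float, float] = (0.08, 0.25)


DEFAULT_PARAMS = PhantomParams()


@dataclass
class CaseSpec:
    """Full parametrization of one synthetic case."""

    case_id: str
    label: str                                # "benign" | "malignant"
    informative: tuple[str, ...]              # subset of ("US", "IRT"), nonempty
    # nodule geometry (US)
    center: tuple[float, float]               # (col, row) in the 512x512 frame
    semi_axes: tuple[float, float]            # (a=width, b=height) in px
    irregularity: float                       # radial perturbation amplitude
    echogenicity: float                       # nodule intensity in [0, 1]
    phases: tuple[float, ...]                 # harmonic phases of the contour
    amplitudes: tuple[float, ...]             # harmonic amplitudes (unit max)
    # thermal function (IRT)
    hotspot_amplitude: float                  # deg C above the base field
    hotspot_width: float                      # Gaussian sigma, px
    asymmetry: float                          # lateral displacement index
    asymmetry_side: int                       # -1 left, +1 right
    noise_seed: int                           # per-case rendering seed

    @property
    def aspect_ratio(self) -> float:
        return self.semi_axes[1] / self.semi_axes[0]

    def validate(self) -> None:
        if self.label not in ("benign", "malignant"):
            raise SpecValidationError(f"unknown label {self.label!r}")
        if not self.informative:
            raise SpecValidationError("informative modalities must be nonempty")
        if not set(self.informative) <= {"US", "IRT"}:
            raise SpecValidationError(f"unknown modality in {self.informative}")
        cx, cy = self.center
        a, b = self.semi_axes
        reach = 1.0 + abs(self.irregularity)
        if (cx - a * reach < 0 or cx + a * reach >= US_SIZE
                or cy - b * reach < 0 or cy + b * reach >= US_SIZE):
            raise SpecValidationError(
                f"nodule geometry exceeds the {US_SIZE}x{US_SIZE} frame: "
                f"center={self.center}, semi_axes={self.semi_axes}"
            )


@dataclass
class DatasetRegistry:
    """Ordered corpus of case specifications with optional partition tags."""

    cases: list[CaseSpec]
    seed: int
    partitions: dict[str, str] = field(default_factory=dict)   # case_id -> tag

    def __len__(self) -> int:
        return len(self.cases)

    def subset(self, tag: str) -> list[CaseSpec]:
        return [c for c in self.cases if self.partitions.get(c.case_id) == tag]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.cases:
            out[c.label] = out.get(c.label, 0) + 1
        return out


# ---------------------------------------------------------------- case sampling

def _uniform(rng, lohi):
    return float(rng.uniform(*lohi))


def _sample_us_params(rng, cls: str, p: PhantomParams):
    if cls == "neutral":
        irr = _uniform(rng, p.irregularity_neutral)
        aspect = _uniform(rng, p.aspect_neutral)
        mu, sd = p.echo_neutral
    else:
        irr = _uniform(rng, p.irregularity_benign if cls == "benign"
                       else p.irregularity_malignant)
        aspect = _uniform(rng, p.aspect_benign if cls == "benign"
                          else p.aspect_malignant)
        mu, sd = p.echo_benign if cls == "benign" else p.echo_malignant
    echo = float(np.clip(rng.normal(mu, sd), 0.05, 0.95))
    return irr, aspect, echo


def _sample_irt_params(rng, cls: str, p: PhantomParams):
    if cls == "neutral":
        amp = _uniform(rng, p.hotspot_neutral)
        width = _uniform(rng, p.hotspot_width_neutral)
        asym = _uniform(rng, p.asymmetry_neutral)
    else:
        amp = _uniform(rng, p.hotspot_benign if cls == "benign"
                       else p.hotspot_malignant)
        width = _uniform(rng, p.hotspot_width_benign if cls == "benign"
                         else p.hotspot_width_malignant)
        asym = _uniform(rng, p.asymmetry_benign if cls == "benign"
                        else p.asymmetry_malignant)
    return amp, width, asym


def sample_case(case_id: str, label: str, informative: tuple[str, ...],
                rng: np.random.Generator,
                params: PhantomParams = DEFAULT_PARAMS) -> CaseSpec:
    """Draw one case.

    An uninformative modality draws its parameters from the class-neutral
    distribution — the ambiguous mid-range between the two class
    distributions — so it carries no class signal yet remains plausible.
    """
    p = params
    us_cls = label if "US" in informative else "neutral"
    irt_cls = label if "IRT" in informative else "neutral"
    irr, aspect, echo = _sample_us_params(rng, us_cls, p)
    amp, width, asym = _sample_irt_params(rng, irt_cls, p)

    a = _uniform(rng, (p.semi_axis_lo, p.semi_axis_hi))
    b = a * aspect
    half = US_SIZE / 2.0
    cx = half + rng.uniform(-p.center_jitter, p.center_jitter)
    cy = half + rng.uniform(-p.center_jitter, p.center_jitter)

    k = len(p.harmonics)
    amps = rng.uniform(0.3, 1.0, k)
    amps = amps / np.abs(amps).sum()        # unit total amplitude -> |f| <= 1
    spec = CaseSpec(
        case_id=case_id, label=label, informative=tuple(informative),
        center=(cx, cy), semi_axes=(a, b), irregularity=irr, echogenicity=echo,
        phases=tuple(float(x) for x in rng.uniform(0, 2 * np.pi, k)),
        amplitudes=tuple(float(x) for x in amps),
        hotspot_amplitude=amp, hotspot_width=width, asymmetry=asym,
        asymmetry_side=int(rng.choice((-1, 1))),
        noise_seed=int(rng.integers(0, 2**31 - 1)),
    )
    spec.validate()
    return spec


def generate_dataset(n_benign: int, n_malignant: int,
                     modality_informativeness_probs: tuple[float, float, float]
                     = (0.0, 0.0, 1.0),
                     seed: int = 0,
                     params: PhantomParams = DEFAULT_PARAMS) -> DatasetRegistry:
    """Registry of ``n_benign + n_malignant`` cases, reproducible from seed.

    ``modality_informativeness_probs`` gives the probabilities of a case
    being US-only, IRT-only, or both-informative (must sum to 1).
    """
    if n_benign < 0 or n_malignant < 0:
        raise SpecValidationError("case counts must be non-negative")
    if n_benign + n_malignant == 0:
        raise EmptyRegistryError("an empty registry was requested")
    probs = np.asarray(modality_informativeness_probs, dtype=float)
    if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise SpecValidationError(
            "modality_informativeness_probs must be 3 non-negative values summing to 1"
        )
    rng = np.random.default_rng(seed)
    options = (("US",), ("IRT",), ("US", "IRT"))
    cases: list[CaseSpec] = []
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    for i, label in enumerate(labels):
        informative = options[int(rng.choice(3, p=probs))]
        cases.append(sample_case(f"case{i:05d}", label, informative, rng, params))
    return DatasetRegistry(cases=cases, seed=seed)


def default_registry(seed: int = 0) -> DatasetRegistry:
    """The default corpus mirroring the study cohort: 2864 cases,
    1536 benign and 1328 malignant, both modalities informative."""
    return generate_dataset(1536, 1328, (0.0, 0.0, 1.0), seed=seed)


def stratified_split(registry: DatasetRegistry,
                     ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> DatasetRegistry:
    """Per-class 6:2:2 split: floor the validation and test shares, assign
    the remainder to training; random assignment given the seed."""
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise SpecValidationError("ratios must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    partitions: dict[str, str] = {}
    by_class: dict[str, list[CaseSpec]] = {}
    for c in registry.cases:
        by_class.setdefault(c.label, []).append(c)
    for label in sorted(by_class):
        group = by_class[label]
        n = len(group)
        n_val = int(np.floor(ratios[1] * n))
        n_test = int(np.floor(ratios[2] * n))
        n_train = n - n_val - n_test
        if min(n_train, n_val, n_test) < 1:
            raise DegenerateSplitError(
                f"class {label!r} has {n} cases; all three partitions need at least one"
            )
        order = rng.permutation(n)
        for rank, idx in enumerate(order):
            if rank < n_train:
                tag = "train"
            elif rank < n_train + n_val:
                tag = "val"
            else:
                tag = "test"
            partitions[group[idx].case_id] = tag
    return DatasetRegistry(cases=list(registry.cases), seed=registry.seed,
                           partitions=partitions)


# ------------------------------------------------------------- image synthesis

def contour_radii(spec: CaseSpec, angles: np.ndarray,
                  params: PhantomParams = DEFAULT_PARAMS) -> np.ndarray:
    """Normalized nodule boundary radius at each polar angle (1 = the
    unperturbed ellipse)."""
    f = np.zeros_like(angles, dtype=float)
    for k, amp, phase in zip(params.harmonics, spec.amplitudes, spec.phases):
        f += amp * np.cos(k * angles + phase)
    return 1.0 + spec.irregularity * f


def synthesize_us_image(spec: CaseSpec, rng: np.random.Generator | None = None,
                        params: PhantomParams = DEFAULT_PARAMS) -> np.ndarray:
    """Render the 512x512 ultrasound phantom, values in [0, 1]."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.noise_seed)
    p = params
    yy, xx = np.mgrid[0:US_SIZE, 0:US_SIZE].astype(np.float32)
    dx = (xx - spec.center[0]) / spec.semi_axes[0]
    dy = (yy - spec.center[1]) / spec.semi_axes[1]
    r = np.sqrt(dx * dx + dy * dy)
    theta = np.arctan2(dy, dx)
    boundary = contour_radii(spec, theta, params).astype(np.float32)
    # smooth transition from background to nodule over `edge_width`
    t = np.clip((r - boundary) / p.edge_width + 0.5, 0.0, 1.0)
    base = spec.echogenicity + (p.bg_intensity - spec.echogenicity) * t
    speckle = rng.gamma(p.speckle_shape, 1.0 / p.speckle_shape,
                        size=base.shape).astype(np.float32)
    speckle = gaussian_filter(speckle, p.speckle_smooth)
    return np.clip(base * speckle, 0.0, 1.0).astype(np.float32)


def temperature_field(spec: CaseSpec, rng: np.random.Generator | None = None,
                      params: PhantomParams = DEFAULT_PARAMS,
                      noise: bool = True) -> np.ndarray:
    """The 240x320 temperature field (deg C) before color mapping.

    The base field is left-right symmetric by construction; asymmetry
    enters only through the lateral displacement of the hotspot."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.noise_seed + 1)
    p = params
    h, w = IRT_SHAPE
    ambient = rng.normal(*p.ambient_temp)
    neck_amp = rng.uniform(*p.neck_amplitude)
    sx = rng.uniform(*p.neck_sigma)
    sy = rng.uniform(*p.neck_sigma)
    cy = rng.uniform(0.40 * h, 0.60 * h)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    cx = (w - 1) / 2.0          # pixel-grid mirror axis
    field = ambient + neck_amp * np.exp(-(((xx - cx) / sx) ** 2
                                          + ((yy - cy) / sy) ** 2) / 2.0)
    # hotspot, displaced laterally by the asymmetry index (fraction of w/4)
    hx = cx + spec.asymmetry_side * spec.asymmetry * (w / 4.0)
    hy = cy + rng.uniform(-0.05 * h, 0.05 * h) * (1.0 if spec.asymmetry > 0 else 0.0)
    s = spec.hotspot_width
    field = field + spec.hotspot_amplitude * np.exp(
        -(((xx - hx) ** 2 + (yy - hy) ** 2) / (2.0 * s * s))
    )
    if noise:
        field = field + rng.normal(0.0, p.thermal_noise_sd, field.shape)
    return np.clip(field, TEMP_MIN, TEMP_MAX).astype(np.float32)


def temperature_to_rgb(field: np.ndarray) -> np.ndarray:
    """Fixed monotone-in-temperature pseudo-color map.

    t = (T - 20) / 20; R = t, G = t^2, B = (1 - t)^2.  The red channel is
    exactly the normalized temperature, so temperature ordering survives
    into pixel space."""
    t = (field - TEMP_MIN) / (TEMP_MAX - TEMP_MIN)
    return np.stack([t, t * t, (1.0 - t) ** 2], axis=-1).astype(np.float32)


def synthesize_irt_image(spec: CaseSpec, rng: np.random.Generator | None = None,
                         params: PhantomParams = DEFAULT_PARAMS) -> np.ndarray:
    """Render the 320x240 pseudo-color thermogram as a (240, 320, 3) array
    in [0, 1] (rows x cols x RGB)."""
    return temperature_to_rgb(temperature_field(spec, rng, params))


# -------------------------------------------------- trivial pixel statistics

def us_intensity_statistic(us_image: np.ndarray) -> float:
    """Mean intensity of the central crop (the nodule neighbourhood);
    lower for hypoechoic (malignant-pattern) nodules."""
    h, w = us_image.shape
    return float(us_image[h // 4: 3 * h // 4, w // 4: 3 * w // 4].mean())


def irt_peak_statistic(irt_image: np.ndarray) -> float:
    """Peak normalized temperature recovered from the red channel."""
    return float(irt_image[..., 0].max())


def pixel_statistic_scores(us_images, irt_images) -> np.ndarray:
    """Malignancy score of the trivial pixel-statistic classifier:
    peak temperature minus mean nodule intensity (both on [0, 1] scales);
    threshold at the pooled midpoint (the sample mean)."""
    us_stat = np.array([us_intensity_statistic(u) for u in us_images])
    irt_stat = np.array([irt_peak_statistic(i) for i in irt_images])
    return irt_stat - us_stat
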