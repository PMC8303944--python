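"""Seeded generators: phantom grids and fruit cohorts with known ground truth.

The generators render the diffusion-model forward profile through a simple
camera model — multiplicative log-normal noise (a shot/speckle proxy),
rounding to digital numbers, and clipping at the saturation ceiling so the
central region is clipped and a saturated-area radius (DIP) exists, as on the
real instrument.  Full 2-D frames are available via
:func:`render_backscatter_image`; the grid/cohort generators default to
rendering the radial profile directly (identical radiometry, far cheaper),
which is what the downstream profile analysis consumes anyway.

Everything is a pure function of its spec and seed: the same seed reproduces
the same images, profiles and cohorts bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import N_REL_PHANTOM, OpticalProperties, farrell_reflectance
from .errors import InvalidInputError
from .phantoms import PhantomSpec, mu_a_from_nbb, mu_s_from_intralipid
from .profiles import (
    DEFAULT_PIXEL_SIZE,
    AttenuationProfile,
    BackscatterImage,
    extract_lbi_parameters,
)
from .severity import SEVERITY_LEVELS, FruitRecord

#: Radius (cm) inside which the default amplitude drives the sensor into
#: saturation, producing a realistic clipped core.
DEFAULT_SATURATION_RADIUS_CM = 0.1


@dataclass(frozen=True)
class CameraModel:
    """Geometry and radiometry of the acquisition."""

    width: int = 1280
    height: int = 1024
    bit_depth: int = 8
    pixel_size: float = DEFAULT_PIXEL_SIZE  # cm
    saturation: int | None = None  # DN ceiling; defaults to 2^bit_depth - 1
    noise_sigma: float = 0.05  # multiplicative log-normal sigma
    n_frames: int = 10

    def __post_init__(self):
        if min(self.width, self.height, self.bit_depth, self.n_frames) <= 0:
            raise InvalidInputError("camera dimensions must be positive")
        if self.pixel_size <= 0 or self.noise_sigma < 0:
            raise InvalidInputError("pixel_size must be > 0 and noise_sigma >= 0")
        if self.saturation is None:
            object.__setattr__(self, "saturation", 2**self.bit_depth - 1)
        if self.saturation > 2**self.bit_depth - 1:
            raise InvalidInputError("saturation cannot exceed the bit-depth ceiling")

    @property
    def n_profile_bins(self) -> int:
        return min(self.width, self.height) // 2 - 1

    def profile_radii(self) -> np.ndarray:
        return (np.arange(self.n_profile_bins) + 0.5) * self.pixel_size


@dataclass(frozen=True)
class EffectModel:
    """Severity -> optical-property shift, multiplicative on the sound means.

    Defaults: severe injury raises absorption 1.3x and reduced scattering
    1.35x (pigment change plus granulation and water soaking); moderate
    raises scattering 1.2x only (granulation without water soaking).
    Biological scatter is a 10% coefficient of variation per fruit.
    Equatorial positions express a configurable fraction of the effect
    (default 0.5), the stylar end the full effect, reflecting where injury
    develops first.
    """

    sound_mu_a: float = 0.20
    sound_mu_s: float = 3.0
    mu_a_multipliers: dict = field(
        default_factory=lambda: {"sound": 1.0, "moderate": 1.0, "severe": 1.3}
    )
    mu_s_multipliers: dict = field(
        default_factory=lambda: {"sound": 1.0, "moderate": 1.2, "severe": 1.35}
    )
    cv: float = 0.10
    equatorial_fraction: float = 0.5


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes and effect model for a synthetic fruit population.

    Default class sizes mirror a heavily imbalanced commercial cohort
    (320 sound / 64 moderate / 12 severe).
    """

    n_sound: int = 320
    n_moderate: int = 64
    n_severe: int = 12
    effect: EffectModel = field(default_factory=EffectModel)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_sound, self.n_moderate, self.n_severe) < 0:
            raise InvalidInputError("class sizes must be >= 0")
        if self.effect.cv < 0:
            raise InvalidInputError("coefficient of variation must be >= 0")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def default_amplitude(props: OpticalProperties, camera: CameraModel,
                      n_rel: float = N_REL_PHANTOM) -> float:
    """Amplitude that saturates the sensor inside DEFAULT_SATURATION_RADIUS_CM."""
    return camera.saturation / farrell_reflectance(
        DEFAULT_SATURATION_RADIUS_CM, props, n_rel
    )


def _quantize(signal: np.ndarray, camera: CameraModel, rng) -> np.ndarray:
    if camera.noise_sigma > 0:
        signal = signal * rng.lognormal(
            mean=0.0, sigma=camera.noise_sigma, size=signal.shape
        )
    return np.clip(np.rint(signal), 0, camera.saturation)


def render_backscatter_image(
    props: OpticalProperties,
    camera: CameraModel,
    amplitude: float | None = None,
    seed: int = 0,
    n_rel: float = N_REL_PHANTOM,
) -> BackscatterImage:
    """Render one 2-D frame: DN = clip(round(amplitude * R(r) * noise))."""
    if amplitude is None:
        amplitude = default_amplitude(props, camera, n_rel)
    cy, cx = (camera.height - 1) / 2, (camera.width - 1) / 2
    rows = (np.arange(camera.height)[:, None] - cy) * camera.pixel_size
    cols = (np.arange(camera.width)[None, :] - cx) * camera.pixel_size
    r = np.sqrt(rows**2 + cols**2)
    signal = amplitude * farrell_reflectance(r, props, n_rel)
    rng = np.random.default_rng(seed)
    pixels = _quantize(signal, camera, rng)
    if pixels.max() < 1:
        warnings.warn("rendered image is blank (no pixel reaches 1 DN)")
    return BackscatterImage(pixels, bit_depth=camera.bit_depth, pixel_size=camera.pixel_size)


def render_profile(
    props: OpticalProperties,
    camera: CameraModel,
    amplitude: float | None = None,
    seed: int = 0,
    n_rel: float = N_REL_PHANTOM,
    rng=None,
) -> AttenuationProfile:
    """Radial profile as the camera would record it, averaged over n_frames.

    Each frame is noised, rounded and clipped independently before frame
    averaging — the same order of operations as on real acquisitions.
    """
    if amplitude is None:
        amplitude = default_amplitude(props, camera, n_rel)
    if rng is None:
        rng = np.random.default_rng(seed)
    radii = camera.profile_radii()
    signal = amplitude * farrell_reflectance(radii, props, n_rel)
    frames = [_quantize(signal.copy(), camera, rng) for _ in range(camera.n_frames)]
    return AttenuationProfile(radii=radii, intensities=np.mean(frames, axis=0))


# ---------------------------------------------------------------------------
# Phantom grids
# ---------------------------------------------------------------------------

def phantom_truth(spec: PhantomSpec) -> OpticalProperties:
    """Ground-truth coefficients of a synthetic phantom from its composition."""
    return OpticalProperties(
        mu_a=mu_a_from_nbb(spec.nbb_pct), mu_s_prime=mu_s_from_intralipid(spec.intralipid_pct)
    )


def design_amplitude(design: list[PhantomSpec], camera: CameraModel,
                     n_rel: float = N_REL_PHANTOM) -> float:
    """One fixed source amplitude for a whole acquisition run.

    The instrument's laser power is constant across samples, so the
    saturated-area radius varies with the sample and carries information; the
    amplitude is calibrated once, against the mean truth of the design.
    """
    truths = [phantom_truth(s) for s in design]
    ref = OpticalProperties(
        mu_a=float(np.mean([t.mu_a for t in truths])),
        mu_s_prime=float(np.mean([t.mu_s_prime for t in truths])),
    )
    return default_amplitude(ref, camera, n_rel)


def generate_phantom_profiles(
    design: list[PhantomSpec],
    camera: CameraModel,
    seed: int = 0,
    n_rel: float = N_REL_PHANTOM,
):
    """Rendered radial profiles plus a ground-truth table for a phantom design."""
    if not design:
        raise InvalidInputError("phantom design must be non-empty")
    rng = np.random.default_rng(seed)
    amplitude = design_amplitude(design, camera, n_rel)
    profiles, rows = [], []
    for i, spec in enumerate(design):
        props = phantom_truth(spec)
        profiles.append(
            render_profile(props, camera, amplitude=amplitude, n_rel=n_rel, rng=rng)
        )
        rows.append(
            {
                "phantom_id": i,
                "intralipid_pct": spec.intralipid_pct,
                "nbb_pct": spec.nbb_pct,
                "mu_a_star": props.mu_a,
                "mu_s_star": props.mu_s_prime,
            }
        )
    return profiles, pd.DataFrame(rows)


def generate_phantom_images(
    design: list[PhantomSpec],
    camera: CameraModel,
    seed: int = 0,
    n_rel: float = N_REL_PHANTOM,
):
    """Full frame stacks (n_frames each) plus ground truth for a phantom design."""
    if not design:
        raise InvalidInputError("phantom design must be non-empty")
    root = np.random.default_rng(seed)
    amplitude = design_amplitude(design, camera, n_rel)
    stacks, rows = [], []
    for i, spec in enumerate(design):
        props = phantom_truth(spec)
        frame_seeds = root.integers(0, 2**31 - 1, size=camera.n_frames)
        stacks.append(
            [
                render_backscatter_image(
                    props, camera, amplitude=amplitude, seed=int(s), n_rel=n_rel
                )
                for s in frame_seeds
            ]
        )
        rows.append(
            {
                "phantom_id": i,
                "intralipid_pct": spec.intralipid_pct,
                "nbb_pct": spec.nbb_pct,
                "mu_a_star": props.mu_a,
                "mu_s_star": props.mu_s_prime,
            }
        )
    return stacks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fruit cohorts
# ---------------------------------------------------------------------------

def generate_fruit_cohort(
    spec: CohortSpec,
    camera: CameraModel,
    n_rel: float = 1.35,
) -> list[FruitRecord]:
    """Synthetic fruit cohort with four acquisition positions per fruit.

    Per fruit, baseline coefficients are drawn around the sound means with the
    effect model's coefficient of variation; the severity multipliers are
    applied in full at the stylar-end positions (3, 4) and at
    ``equatorial_fraction`` strength at the equatorial positions (1, 2).
    Profiles are rendered through the camera model and reduced to the five
    profile descriptors.
    """
    rng = np.random.default_rng(spec.seed)
    eff = spec.effect
    amplitude = default_amplitude(
        OpticalProperties(eff.sound_mu_a, eff.sound_mu_s), camera, n_rel
    )
    records = []
    counts = {"sound": spec.n_sound, "moderate": spec.n_moderate, "severe": spec.n_severe}
    fruit_no = 0
    for severity in SEVERITY_LEVELS:
        m_a = eff.mu_a_multipliers[severity]
        m_s = eff.mu_s_multipliers[severity]
        for _ in range(counts[severity]):
            base_a = max(rng.normal(eff.sound_mu_a, eff.cv * eff.sound_mu_a), 1e-6)
            base_s = max(rng.normal(eff.sound_mu_s, eff.cv * eff.sound_mu_s), 1e-3)
            lbi = {}
            for pos in (1, 2, 3, 4):
                frac = 1.0 if pos in (3, 4) else eff.equatorial_fraction
                props = OpticalProperties(
                    mu_a=base_a * (1.0 + frac * (m_a - 1.0)),
                    mu_s_prime=base_s * (1.0 + frac * (m_s - 1.0)),
                )
                profile = render_profile(props, camera, amplitude=amplitude,
                                         n_rel=n_rel, rng=rng)
                lbi[pos] = extract_lbi_parameters(profile)
            records.append(
                FruitRecord(sample_id=f"fruit-{fruit_no:04d}", lbi=lbi, severity=severity)
            )
            fruit_no += 1
    return records
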