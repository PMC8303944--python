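"""Backscattering images to radial attenuation profiles and LBI parameters.

A backscattering image is a grayscale frame of diffusely reflected laser
light.  Its central region is saturated (clipped at the camera ceiling);
outward the intensity decays with the sample's optical properties.  The
pipeline is: average the acquisition frames, locate the incident point from
the saturated area, optionally scrub specular reflection spots, average
intensity over 1-pixel annuli to get the radial profile, then summarize the
profile by five descriptors:

DIP   radius of the saturated area (distance to incident point), cm
Q1R   radius where intensity first falls to 75% of the plateau, cm
FWHM  twice the radius at 50% of the plateau, cm
Q3R   radius at 25% of the plateau, cm
SLP   magnitude of the slope of ln(intensity) vs radius between Q1R and Q3R,
      cm^-1 (the asymptotic decay rate; tracks mu_eff)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ShapeError, TruncatedProfileError

#: Geometric calibration: side of one pixel in cm.
DEFAULT_PIXEL_SIZE = 0.01015625

#: A profile bin within this fraction of the plateau counts as saturated.
PLATEAU_TOL = 0.995


@dataclass
class BackscatterImage:
    """A grayscale backscattering frame (or frame average) with metadata."""

    pixels: np.ndarray  # 2-D, DN; float allowed (frame averages)
    bit_depth: int = 8
    pixel_size: float = DEFAULT_PIXEL_SIZE  # cm per pixel side

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidInputError("image must be 2-D grayscale")
        if self.pixel_size <= 0:
            raise InvalidInputError("pixel_size must be > 0")
        ceiling = 2**self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > ceiling:
            raise InvalidInputError(
                f"pixel values must lie in [0, {ceiling}] for {self.bit_depth}-bit data"
            )

    @property
    def saturation(self) -> int:
        return 2**self.bit_depth - 1

    @classmethod
    def from_file(cls, path, bit_depth: int | None = None,
                  pixel_size: float = DEFAULT_PIXEL_SIZE) -> "BackscatterImage":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # grayscale stored with redundant channels
            arr = arr[..., 0]
        if bit_depth is None:
            bit_depth = 16 if arr.dtype.itemsize > 1 else 8
        return cls(arr, bit_depth=bit_depth, pixel_size=pixel_size)

    def to_file(self, path) -> None:
        import imageio.v3 as iio

        dtype = np.uint8 if self.bit_depth <= 8 else np.uint16
        iio.imwrite(path, np.rint(self.pixels).astype(dtype))


@dataclass
class AttenuationProfile:
    """Azimuthally averaged intensity vs radial distance."""

    radii: np.ndarray  # cm, bin centers, strictly increasing
    intensities: np.ndarray  # mean DN per annulus
    plateau: float = None  # saturation/maximum DN of the profile

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.radii.shape != self.intensities.shape or self.radii.size == 0:
            raise InvalidInputError("radii and intensities must be equal, non-zero length")
        if np.any(np.diff(self.radii) <= 0):
            raise InvalidInputError("radii must be strictly increasing")
        if self.plateau is None:
            self.plateau = float(self.intensities.max())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"radius_cm": self.radii, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AttenuationProfile":
        df = pd.read_csv(path)
        return cls(df["radius_cm"].to_numpy(), df["intensity"].to_numpy())


@dataclass(frozen=True)
class LBIParameters:
    """The five radial-profile descriptors."""

    DIP: float  # cm
    Q1R: float  # cm
    FWHM: float  # cm
    Q3R: float  # cm
    SLP: float  # cm^-1

    FEATURE_NAMES = ("DIP", "Q1R", "FWHM", "Q3R", "SLP")

    def __post_init__(self):
        tol = 1e-9
        if not (self.DIP <= self.Q1R + tol
                and self.Q1R <= self.FWHM / 2 + tol
                and self.FWHM / 2 <= self.Q3R + tol):
            raise InvalidInputError(
                f"ordering DIP <= Q1R <= FWHM/2 <= Q3R violated: {self}"
            )
        if self.SLP < 0:
            raise InvalidInputError("SLP must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.DIP, self.Q1R, self.FWHM, self.Q3R, self.SLP])


def lbi_table(rows: Sequence[tuple[str, int, LBIParameters]]) -> pd.DataFrame:
    """Flat table with columns sample_id, position, DIP..SLP."""
    return pd.DataFrame(
        [
            {"sample_id": sid, "position": pos, **dict(zip(LBIParameters.FEATURE_NAMES,
                                                           p.as_array()))}
            for sid, pos, p in rows
        ]
    )


# ---------------------------------------------------------------------------
# Image operations
# ---------------------------------------------------------------------------

def average_images(stack: Sequence[BackscatterImage]) -> BackscatterImage:
    """Pixel-wise arithmetic mean of an acquisition stack."""
    if len(stack) == 0:
        raise InvalidInputError("empty image stack")
    first = stack[0]
    for img in stack[1:]:
        if img.pixels.shape != first.pixels.shape:
            raise ShapeError("images in a stack must share dimensions")
        if img.bit_depth != first.bit_depth:
            raise ShapeError("images in a stack must share bit depth")
    mean = np.mean([img.pixels for img in stack], axis=0)
    return BackscatterImage(mean, bit_depth=first.bit_depth, pixel_size=first.pixel_size)


def locate_incident_point(img: BackscatterImage, sat_threshold: float | None = None):
    """Centroid of the saturated area and its equal-area circle radius (cm).

    Falls back to the global maximum with ``dip_radius = 0`` when no pixel
    reaches the threshold (weak signal, no clipping).
    """
    if sat_threshold is None:
        sat_threshold = img.saturation
    mask = img.pixels >= sat_threshold
    count = int(mask.sum())
    if count == 0:
        idx = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        return (float(idx[0]), float(idx[1])), 0.0
    rows, cols = np.nonzero(mask)
    center = (float(rows.mean()), float(cols.mean()))
    dip_radius = float(np.sqrt(count / np.pi) * img.pixel_size)
    return center, dip_radius


def _radius_map(shape, center):
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return np.sqrt(rows**2 + cols**2)


def remove_reflection_spot(
    img: BackscatterImage,
    center,
    factor: float = 3.0,
    core_radius_cm: float | None = None,
) -> BackscatterImage:
    """Replace specular outliers by the azimuthal median at their radius.

    A pixel is an outlier when its DN exceeds ``factor`` times the median of
    its 1-pixel annulus.  Pixels inside the saturated core (within
    ``core_radius_cm``, or within any annulus whose median is at saturation
    when not given) are never touched.
    """
    d = _radius_map(img.pixels.shape, center)
    bins = d.astype(int)
    out = img.pixels.copy()
    n_bins = bins.max() + 1
    medians = np.full(n_bins, np.nan)
    for k in range(n_bins):
        sel = bins == k
        if sel.any():
            medians[k] = np.median(img.pixels[sel])
    if core_radius_cm is not None:
        core = d * img.pixel_size <= core_radius_cm
    else:
        sat_bins = np.flatnonzero(medians >= PLATEAU_TOL * img.saturation)
        # one extra bin so partially-saturated boundary annuli stay untouched
        core_edge = (sat_bins.max() + 1.0) if sat_bins.size else -1.0
        core = d <= core_edge
    outliers = (out > factor * medians[bins]) & ~core
    out[outliers] = medians[bins][outliers]
    return BackscatterImage(out, bit_depth=img.bit_depth, pixel_size=img.pixel_size)


def radial_attenuation_profile(img: BackscatterImage, center) -> AttenuationProfile:
    """Mean DN over 1-pixel-wide annuli around ``center``.

    The profile extends to the largest circle inscribed in the image around
    the center; bin k averages pixels with distance in [k, k+1) px and is
    reported at radius (k + 0.5) * pixel_size.
    """
    h, w = img.pixels.shape
    if not (0 <= center[0] <= h - 1 and 0 <= center[1] <= w - 1):
        raise InvalidInputError(f"center {center} outside image of shape {img.pixels.shape}")
    inscribed = min(center[0], center[1], h - 1 - center[0], w - 1 - center[1])
    n_bins = int(np.floor(inscribed))
    if n_bins < 1:
        raise InvalidInputError("center too close to the border for any annulus")
    d = _radius_map(img.pixels.shape, center)
    bins = d.astype(int).ravel()
    keep = bins < n_bins
    sums = np.bincount(bins[keep], weights=img.pixels.ravel()[keep], minlength=n_bins)
    counts = np.bincount(bins[keep], minlength=n_bins)
    intensities = sums / np.maximum(counts, 1)
    radii = (np.arange(n_bins) + 0.5) * img.pixel_size
    return AttenuationProfile(radii=radii, intensities=intensities)


# ---------------------------------------------------------------------------
# Parameter extraction
# ---------------------------------------------------------------------------

def _first_crossing(radii, intensities, start, level):
    """Radius of the first downward crossing of ``level`` at/after ``start``."""
    for i in range(start, len(intensities) - 1):
        if intensities[i] >= level > intensities[i + 1]:
            # linear interpolation between bin centers
            frac = (intensities[i] - level) / (intensities[i] - intensities[i + 1])
            return radii[i] + frac * (radii[i + 1] - radii[i])
    return None


def extract_lbi_parameters(
    profile: AttenuationProfile, dip_radius: float | None = None
) -> LBIParameters:
    """Extract (DIP, Q1R, FWHM, Q3R, SLP) from a radial profile.

    The plateau is the profile maximum (the saturation ceiling when the core
    is clipped); threshold radii use the first downward crossing after the
    plateau with linear interpolation between bins.  ``dip_radius`` may be
    supplied from :func:`locate_incident_point`; otherwise the saturated
    plateau extent of the profile itself is used.
    """
    r = profile.radii
    y = profile.intensities
    plateau = profile.plateau
    i_max = int(np.argmax(y))
    # plateau run: contiguous bins at the ceiling from the maximum outward
    j = i_max
    while j + 1 < len(y) and y[j + 1] >= PLATEAU_TOL * plateau:
        j += 1
    if dip_radius is None:
        dip_radius = float(r[j]) if j > i_max or y[i_max] >= PLATEAU_TOL * plateau else float(r[i_max])

    crossings = {}
    for name, frac in (("Q1R", 0.75), ("half_fwhm", 0.50), ("Q3R", 0.25)):
        c = _first_crossing(r, y, j, frac * plateau)
        if c is None:
            raise TruncatedProfileError(frac)
        crossings[name] = float(c)

    q1r, half, q3r = crossings["Q1R"], crossings["half_fwhm"], crossings["Q3R"]
    sel = (r >= q1r) & (r <= q3r) & (y > 0)
    if sel.sum() < 2:
        # interpolated window narrower than one bin: widen to the bracketing bins
        sel = (r >= q1r - (r[1] - r[0])) & (r <= q3r + (r[1] - r[0])) & (y > 0)
    slope = np.polyfit(r[sel], np.log(y[sel]), 1)[0]
    return LBIParameters(
        DIP=min(float(dip_radius), q1r),
        Q1R=q1r,
        FWHM=2.0 * half,
        Q3R=q3r,
        SLP=abs(float(slope)),
    )
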