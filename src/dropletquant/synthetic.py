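"""Synthetic two-channel condensate image generator.

Emulates dual-channel fluorescence acquisitions of protein droplets so
that every analysis stage can be validated against known ground truth:
fields of bright quasi-circular droplets on a dark background with a
log-normal size distribution, a composition label per droplet
(heterotypic droplets emit in both the eGFP and mCherry channels,
homotypic droplets in one), an optional planar misregistration applied
to the red channel, Gaussian PSF blur, Poisson shot noise, additive
Gaussian read noise, and 16-bit quantization with saturation clipping.

All physical coordinates are (x, y) in nanometres with
x = (column + 0.5) * pixel_size, y = (row + 0.5) * pixel_size and the
origin at the top-left pixel corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .registration import PlanarTransform
from .segmentation import Image2D

__all__ = [
    "HETEROTYPIC",
    "GREEN_ONLY",
    "RED_ONLY",
    "CompositionModel",
    "DropletTruth",
    "DropletFieldTruth",
    "ImagingConfig",
    "PlacementError",
    "sample_droplet_field",
    "render_channels",
    "render_bead_field",
    "make_condition_set",
    "apply_disassembly",
]

HETEROTYPIC = "heterotypic"
GREEN_ONLY = "greenOnly"
RED_ONLY = "redOnly"
_COMPOSITIONS = (HETEROTYPIC, GREEN_ONLY, RED_ONLY)


class PlacementError(RuntimeError):
    """Field too small to place the requested droplets at the required separation."""


@dataclass
class CompositionModel:
    """Population model for droplet composition and size.

    Default composition probabilities follow the measured partition of a
    mixed alpha-synuclein / S100A9 droplet population: 44.7% heterotypic,
    43.1% red-only (mCherry-S100A9), 12.2% green-only (eGFP-alpha-syn).
    Radii are log-normal; ``radius_log_median_nm`` is the distribution
    median and ``radius_log_sigma`` the sigma of log(radius).
    """

    p_heterotypic: float = 0.447
    p_green_only: float = 0.122
    p_red_only: float = 0.431
    radius_log_median_nm: float = 1500.0
    radius_log_sigma: float = 0.4

    def __post_init__(self) -> None:
        probs = (self.p_heterotypic, self.p_green_only, self.p_red_only)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("composition probabilities must be >= 0 and sum to 1")
        if self.radius_log_median_nm <= 0 or self.radius_log_sigma < 0:
            raise ValueError("invalid radius distribution parameters")

    @property
    def probabilities(self) -> tuple[float, float, float]:
        return (self.p_heterotypic, self.p_green_only, self.p_red_only)


@dataclass
class DropletTruth:
    """Ground truth for one droplet.

    Intensities are expected photons per pixel at the disk plateau;
    a channel the droplet does not contain has intensity exactly 0.
    """

    id: int
    center_nm: tuple[float, float]
    radius_nm: float
    composition: str
    intensity_green: float
    intensity_red: float

    def __post_init__(self) -> None:
        if self.composition not in _COMPOSITIONS:
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.radius_nm <= 0:
            raise ValueError("radius must be positive")
        if self.composition == GREEN_ONLY and self.intensity_red != 0:
            raise ValueError("greenOnly droplet must have zero red intensity")
        if self.composition == RED_ONLY and self.intensity_green != 0:
            raise ValueError("redOnly droplet must have zero green intensity")
        if self.composition == HETEROTYPIC and not (
            self.intensity_green > 0 and self.intensity_red > 0
        ):
            raise ValueError("heterotypic droplet needs positive intensity in both channels")


@dataclass
class DropletFieldTruth:
    """Ground-truth droplet list for one simulated field of view."""

    droplets: list[DropletTruth]
    field_size_nm: tuple[float, float]
    pixel_size_nm: float
    seed: int
    clipped_ids: list[int] = field(default_factory=list)

    def centers(self, composition: str | None = None) -> np.ndarray:
        sel = [
            d.center_nm
            for d in self.droplets
            if composition is None or d.composition == composition
        ]
        return np.asarray(sel).reshape(-1, 2)

    def composition_counts(self) -> dict[str, int]:
        out = {c: 0 for c in _COMPOSITIONS}
        for d in self.droplets:
            out[d.composition] += 1
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [d.id for d in self.droplets],
                "x_nm": [d.center_nm[0] for d in self.droplets],
                "y_nm": [d.center_nm[1] for d in self.droplets],
                "radius_nm": [d.radius_nm for d in self.droplets],
                "composition": [d.composition for d in self.droplets],
                "intensity_green": [d.intensity_green for d in self.droplets],
                "intensity_red": [d.intensity_red for d in self.droplets],
            }
        )


@dataclass
class ImagingConfig:
    """Forward-model parameters for rendering a field.

    ``pixel_size_nm`` defaults to 114.17 (dual-view TIRF mode); use 325
    for the wide-field statistics mode.  ``psf_sigma_nm`` is the sigma
    of the isotropic Gaussian PSF.  ``channel_transform`` maps red
    droplet centers into the red channel's (misaligned) frame before
    rendering; identity means perfectly co-registered channels.
    ``profile`` selects the radiance model: ``disk`` (uniform) or
    ``speckled`` (uniform disk times smoothed multiplicative speckle,
    emulating unevenly filled droplets).
    """

    pixel_size_nm: float = 114.17
    psf_sigma_nm: float = 150.0
    background: float = 20.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    channel_transform: PlanarTransform | None = None
    seed: int = 0
    profile: str = "disk"
    speckle_strength: float = 0.5
    speckle_scale_nm: float = 500.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        if self.psf_sigma_nm < 0 or self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("noise/blur parameters must be non-negative")
        if self.profile not in ("disk", "speckled"):
            raise ValueError(f"unknown radiance profile {self.profile!r}")


def sample_droplet_field(
    composition: CompositionModel,
    n_droplets: int,
    field_size_nm: tuple[float, float],
    pixel_size_nm: float,
    seed: int,
    min_separation_nm: float | None = None,
    intensity_median: float = 150.0,
    intensity_log_sigma: float = 0.25,
    max_attempts_per_droplet: int = 500,
) -> DropletFieldTruth:
    """Draw a ground-truth droplet field.

    Compositions are i.i.d. from ``composition``; radii log-normal;
    centers uniform over the field with every droplet fully inside the
    bounds, subject to a pairwise minimum center separation (default
    twice the largest sampled radius) enforced by rejection sampling so
    ground-truth identity stays unambiguous.

    Raises
    ------
    PlacementError
        If the field cannot hold ``n_droplets`` at the required
        separation; the message names the achieved count.
    """
    if n_droplets < 0:
        raise ValueError("n_droplets must be >= 0")
    rng = np.random.default_rng(seed)
    width, height = field_size_nm
    comps = rng.choice(3, size=n_droplets, p=composition.probabilities)
    radii = np.exp(
        rng.normal(np.log(composition.radius_log_median_nm), composition.radius_log_sigma, n_droplets)
    )
    if min_separation_nm is None:
        min_separation_nm = 2.0 * (radii.max() if n_droplets else 0.0)

    centers = np.empty((n_droplets, 2))
    droplets: list[DropletTruth] = []
    min_sep2 = min_separation_nm**2
    for i in range(n_droplets):
        r = float(radii[i])
        if 2 * r >= width or 2 * r >= height:
            raise PlacementError(
                f"droplet radius {r:.0f} nm does not fit the field; placed {len(droplets)}"
            )
        placed = False
        for _ in range(max_attempts_per_droplet):
            x = rng.uniform(r, width - r)
            y = rng.uniform(r, height - r)
            if i == 0 or (
                ((centers[:i, 0] - x) ** 2 + (centers[:i, 1] - y) ** 2).min() >= min_sep2
            ):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place droplet {i + 1} of {n_droplets} at separation "
                f"{min_separation_nm:.0f} nm; achieved {len(droplets)} droplets"
            )
        centers[i] = (x, y)
        comp = _COMPOSITIONS[comps[i]]
        lg = np.log(intensity_median)
        ig = float(np.exp(rng.normal(lg, intensity_log_sigma)))
        ir = float(np.exp(rng.normal(lg, intensity_log_sigma)))
        droplets.append(
            DropletTruth(
                id=i,
                center_nm=(x, y),
                radius_nm=r,
                composition=comp,
                intensity_green=ig if comp in (HETEROTYPIC, GREEN_ONLY) else 0.0,
                intensity_red=ir if comp in (HETEROTYPIC, RED_ONLY) else 0.0,
            )
        )
    return DropletFieldTruth(
        droplets=droplets,
        field_size_nm=(float(width), float(height)),
        pixel_size_nm=float(pixel_size_nm),
        seed=int(seed),
    )


def _add_disk(
    canvas: np.ndarray,
    cx_nm: float,
    cy_nm: float,
    radius_nm: float,
    amplitude: float,
    pixel_size_nm: float,
    supersample: int = 4,
    speckle: np.random.Generator | None = None,
    speckle_strength: float = 0.5,
    speckle_scale_px: float = 4.0,
) -> bool:
    """Accumulate one uniform disk into ``canvas``; returns True if clipped.

    Pixel coverage fractions come from ``supersample``² subpixel samples,
    so edge pixels carry partial intensity and the rendered centroid
    tracks the true center to well below a pixel.
    """
    nrow, ncol = canvas.shape
    px = pixel_size_nm
    c0 = int(np.floor((cx_nm - radius_nm) / px)) - 1
    c1 = int(np.ceil((cx_nm + radius_nm) / px)) + 1
    r0 = int(np.floor((cy_nm - radius_nm) / px)) - 1
    r1 = int(np.ceil((cy_nm + radius_nm) / px)) + 1
    clipped = c0 < 0 or r0 < 0 or c1 > ncol or r1 > nrow
    c0c, c1c = max(c0, 0), min(c1, ncol)
    r0c, r1c = max(r0, 0), min(r1, nrow)
    if c0c >= c1c or r0c >= r1c:
        return True
    ss = supersample
    xs = (np.arange(c0c * ss, c1c * ss) + 0.5) * (px / ss) - cx_nm
    ys = (np.arange(r0c * ss, r1c * ss) + 0.5) * (px / ss) - cy_nm
    inside = (ys[:, None] ** 2 + xs[None, :] ** 2) <= radius_nm**2
    h, w = r1c - r0c, c1c - c0c
    coverage = inside.reshape(h, ss, w, ss).mean(axis=(1, 3))
    patch = amplitude * coverage
    if speckle is not None:
        g = ndimage.gaussian_filter(speckle.standard_normal((h, w)), speckle_scale_px)
        sd = g.std()
        if sd > 0:
            g /= sd
        patch = patch * np.clip(1.0 + speckle_strength * g, 0.1, None)
    canvas[r0c:r1c, c0c:c1c] += patch
    return clipped


def _finalize(
    expected: np.ndarray, config: ImagingConfig, rng: np.random.Generator, channel: str
) -> Image2D:
    """Blur, add noise, quantize to 16-bit. Clipping fraction goes to meta."""
    sigma_px = config.psf_sigma_nm / config.pixel_size_nm
    img = ndimage.gaussian_filter(expected, sigma_px) if sigma_px > 0 else expected.copy()
    img += config.background
    if config.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if config.read_noise_sd > 0:
        img += rng.normal(0.0, config.read_noise_sd, img.shape)
    img = np.rint(img)
    clip_fraction = float(np.mean(img >= 65535))
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return Image2D(
        img,
        config.pixel_size_nm,
        channel=channel,
        meta={"clip_fraction": clip_fraction, "psf_sigma_nm": config.psf_sigma_nm},
    )


def render_channels(
    truth: DropletFieldTruth, config: ImagingConfig
) -> tuple[Image2D, Image2D]:
    """Render the green and red channel images of a droplet field.

    Each droplet is a uniform disk of its true radius at its per-channel
    plateau intensity, convolved with the Gaussian PSF, on a constant
    background.  Red-channel centers are first mapped through
    ``config.channel_transform`` (the simulated chromatic
    misregistration).  Poisson shot noise is applied to the expected
    photon image, then Gaussian read noise; output is rounded and
    clipped to the 16-bit range, with the clipping fraction recorded in
    each image's ``meta``.  Droplets that extend past the field after
    the transform are silently cropped but flagged in
    ``truth.clipped_ids``.
    """
    px = config.pixel_size_nm
    ncol = int(round(truth.field_size_nm[0] / px))
    nrow = int(round(truth.field_size_nm[1] / px))
    expected_g = np.zeros((nrow, ncol))
    expected_r = np.zeros((nrow, ncol))
    tf = config.channel_transform
    ss_rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, truth.seed & 0x7FFFFFFF, 7]))
    speckle_scale_px = config.speckle_scale_nm / px
    truth.clipped_ids = []
    for d in truth.droplets:
        clipped = False
        spk = ss_rng if config.profile == "speckled" else None
        if d.intensity_green > 0:
            clipped |= _add_disk(
                expected_g, *d.center_nm, d.radius_nm, d.intensity_green, px,
                speckle=spk, speckle_strength=config.speckle_strength,
                speckle_scale_px=speckle_scale_px,
            )
        if d.intensity_red > 0:
            cx, cy = d.center_nm
            if tf is not None:
                cx, cy = tf(np.array([cx, cy]))
            clipped |= _add_disk(
                expected_r, cx, cy, d.radius_nm, d.intensity_red, px,
                speckle=spk, speckle_strength=config.speckle_strength,
                speckle_scale_px=speckle_scale_px,
            )
        if clipped:
            truth.clipped_ids.append(d.id)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, truth.seed & 0x7FFFFFFF])
    )
    green = _finalize(expected_g, config, noise_rng, "green")
    red = _finalize(expected_r, config, noise_rng, "red")
    return green, red


def _add_gaussian_spot(
    canvas: np.ndarray,
    cx_nm: float,
    cy_nm: float,
    sigma_nm: float,
    amplitude: float,
    pixel_size_nm: float,
) -> None:
    px = pixel_size_nm
    half = 6.0 * sigma_nm
    nrow, ncol = canvas.shape
    c0 = max(int(np.floor((cx_nm - half) / px)), 0)
    c1 = min(int(np.ceil((cx_nm + half) / px)) + 1, ncol)
    r0 = max(int(np.floor((cy_nm - half) / px)), 0)
    r1 = min(int(np.ceil((cy_nm + half) / px)) + 1, nrow)
    if c0 >= c1 or r0 >= r1:
        return
    xs = (np.arange(c0, c1) + 0.5) * px - cx_nm
    ys = (np.arange(r0, r1) + 0.5) * px - cy_nm
    canvas[r0:r1, c0:c1] += amplitude * np.exp(
        -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma_nm**2)
    )


def render_bead_field(
    n_beads: int,
    true_transform: PlanarTransform,
    config: ImagingConfig,
    seed: int,
    field_size_px: tuple[int, int] = (512, 512),
    amplitude: float = 2000.0,
    min_separation_nm: float | None = None,
) -> tuple[Image2D, Image2D, np.ndarray]:
    """Render a calibration bead pair and return the true bead coordinates.

    The same diffraction-limited point emitters (Gaussian spots of the
    PSF sigma) appear in both channels; in the second channel their
    positions are mapped through ``true_transform``.  Returns
    ``(channel_a, channel_b, coords_nm)`` with ``coords_nm`` the (n, 2)
    channel-A ground-truth positions.
    """
    if n_beads < 3:
        raise ValueError("at least 3 beads are required for transform estimation")
    rng = np.random.default_rng(seed)
    px = config.pixel_size_nm
    width, height = field_size_px[0] * px, field_size_px[1] * px
    margin = 10 * px
    if min_separation_nm is None:
        min_separation_nm = 20 * px
    coords: list[tuple[float, float]] = []
    for _ in range(n_beads):
        for _ in range(1000):
            x = rng.uniform(margin, width - margin)
            y = rng.uniform(margin, height - margin)
            if all((x - a) ** 2 + (y - b) ** 2 >= min_separation_nm**2 for a, b in coords):
                coords.append((x, y))
                break
        else:
            raise PlacementError(f"placed only {len(coords)} of {n_beads} beads")
    coords_arr = np.asarray(coords)
    coords_b = true_transform(coords_arr)

    shape = (field_size_px[1], field_size_px[0])
    sigma = max(config.psf_sigma_nm, 1e-9)
    exp_a, exp_b = np.zeros(shape), np.zeros(shape)
    for (xa, ya), (xb, yb) in zip(coords_arr, coords_b):
        _add_gaussian_spot(exp_a, xa, ya, sigma, amplitude, px)
        _add_gaussian_spot(exp_b, xb, yb, sigma, amplitude, px)
    cfg = replace(config, psf_sigma_nm=0.0)  # spots already carry the PSF
    rng_a = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 1]))
    rng_b = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 2]))
    img_a = _finalize(exp_a, cfg, rng_a, "green")
    img_b = _finalize(exp_b, cfg, rng_b, "red")
    return img_a, img_b, coords_arr


def make_condition_set(
    n_images: int = 30,
    composition: CompositionModel | None = None,
    config: ImagingConfig | None = None,
    field_size_px: tuple[int, int] = (500, 500),
    mean_droplets_per_image: float = 60.0,
    seed: int = 0,
    **field_kwargs,
) -> list[tuple[tuple[Image2D, Image2D], DropletFieldTruth]]:
    """Generate one experimental condition: a set of independent fields.

    Defaults mirror the statistics acquisition design: thirty 500 x 500
    pixel images.  Per-image droplet counts are Poisson around
    ``mean_droplets_per_image`` and per-image seeds derive
    deterministically from the master ``seed``, so the whole set is a
    pure function of its arguments.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    composition = composition or CompositionModel()
    config = config or ImagingConfig(pixel_size_nm=325.0)
    px = config.pixel_size_nm
    field_nm = (field_size_px[0] * px, field_size_px[1] * px)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_images) % (2**31)
    out = []
    for i in range(n_images):
        n = int(np.random.default_rng(int(child_seeds[2 * i])).poisson(mean_droplets_per_image))
        truth = sample_droplet_field(
            composition, n, field_nm, px, seed=int(child_seeds[2 * i + 1]), **field_kwargs
        )
        images = render_channels(truth, replace(config, seed=int(child_seeds[2 * i + 1])))
        out.append((images, truth))
    return out


def apply_disassembly(
    truth: DropletFieldTruth,
    removal_fraction: float,
    size_selective: bool,
    seed: int,
) -> DropletFieldTruth:
    """Remove droplets from a field, modelling condensate disassembly.

    With ``size_selective=True`` the removed droplets are drawn
    preferentially from below the field's median radius (small droplets
    dissolve first), which lowers the count while *raising* the mean
    equivalent volume of the survivors; with ``False`` removal is
    uniform and the surviving size distribution is unchanged in
    expectation.
    """
    if not 0.0 <= removal_fraction <= 1.0:
        raise ValueError("removal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(truth.droplets)
    n_remove = int(round(removal_fraction * n))
    if n_remove == 0:
        survivors = list(truth.droplets)
    else:
        radii = np.array([d.radius_nm for d in truth.droplets])
        if size_selective:
            median = np.median(radii)
            # droplets below the median are 9x as likely to dissolve
            w = np.where(radii < median, 9.0, 1.0)
            w /= w.sum()
        else:
            w = np.full(n, 1.0 / n)
        removed = set(rng.choice(n, size=n_remove, replace=False, p=w).tolist())
        survivors = [d for i, d in enumerate(truth.droplets) if i not in removed]
    return DropletFieldTruth(
        droplets=survivors,
        field_size_nm=truth.field_size_nm,
        pixel_size_nm=truth.pixel_size_nm,
        seed=truth.seed,
        clipped_ids=[],
    )
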