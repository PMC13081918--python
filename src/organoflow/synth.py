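"""Synthetic imaging data with machine-readable ground truth.

These generators emulate the imaging side of the chip experiments so
every analysis stage can be scored without microscope data: rendered
time-lapse fluorescence stacks whose intensity is affine in the simulated
concentration field, uniform calibration aliquots at known levels,
two-domain (dorsal/ventral) organoid cross-section phantoms, and nuclei
images with marker-positive subsets.  Each generator takes an explicit
seed and is bit-reproducible; each returns the ground truth needed to
score the corresponding analysis stage (true gain/offset, analytic areas,
true spot centres and marker flags).

What is emulated: affine camera response, additive Gaussian or
Poisson-Gaussian shot/read noise, domain geometry, nuclear spot shape
(Gaussian with the nominal FWHM).  What is not: a realistic PSF, light
scattering through tissue, photobleaching, illumination flat-field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import PlacementError
from .quant import ImageStack
from .region import SpotSet
from .transport import ConcentrationHistory

__all__ = [
    "RenderParams",
    "PhantomSpec",
    "render_fluorescence",
    "make_calibration_series",
    "make_two_domain_image",
    "make_nuclei_image",
]


@dataclass(frozen=True)
class RenderParams:
    """Camera model for rendering concentration into intensity.

    ``I = gain * c + offset + noise``.  ``noise_model`` is one of
    ``none | gaussian | poisson-gaussian``; for the Gaussian model
    ``noise_scale`` is the additive sd in intensity units (the default is
    5% of the full-scale signal for a 50 nM range at unit gain), for the
    Poisson-Gaussian model it is the intensity quantum per photon (shot
    noise) and also sets the read-noise sd.
    """

    gain: float = 2.0
    offset: float = 10.0
    noise_model: str = "gaussian"
    noise_scale: float = 0.05 * 2.0 * 50.0  # 5% of full scale (gain * 50 nM)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson-gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _apply_noise(signal: np.ndarray, params: RenderParams,
                 rng: np.random.Generator) -> np.ndarray:
    if params.noise_model == "none" or params.noise_scale == 0.0:
        return signal
    if params.noise_model == "gaussian":
        return signal + rng.normal(0.0, params.noise_scale, signal.shape)
    q = params.noise_scale
    shot = q * rng.poisson(np.clip(signal, 0.0, None) / q)
    out = shot + rng.normal(0.0, q, signal.shape)
    return np.clip(out, 0.0, None)


def render_fluorescence(history: ConcentrationHistory, params: RenderParams,
                        pixel_size: float | None = None
                        ) -> tuple[ImageStack, dict]:
    """Render stored concentration fields as a fluorescence time-lapse.

    Pixel size defaults to the grid spacing (in um).  Returns the stack
    and a ground-truth dict with the true gain/offset and the rendered
    concentration fields.
    """
    if pixel_size is None:
        pixel_size = history.grid.hx * 1e6
    rng = np.random.default_rng(params.seed)
    # fields are (T, nx, ny); images are (T, row=y, col=x)
    conc = np.transpose(history.fields, (0, 2, 1))
    frames = _apply_noise(params.gain * conc + params.offset, params, rng)
    times = history.times
    if times[0] == times[-1] or not np.all(np.diff(times) > 0):
        times = np.arange(len(frames), dtype=float)
    stack = ImageStack(frames=frames, timestamps=times, pixel_size=pixel_size)
    truth = {"gain": params.gain, "offset": params.offset, "concentration": conc}
    return stack, truth


def make_calibration_series(levels, params: RenderParams,
                            shape: tuple[int, int] = (64, 64)
                            ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render uniform aliquot images at known levels; return mean intensities.

    Emulates the dye-aliquot calibration: one uniform frame per
    concentration level, averaged to a single mean intensity.  Returns
    ``(levels, mean_intensities, truth)`` with truth holding the true
    gain and offset.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 3:
        raise ValueError("need at least 3 calibration levels")
    rng = np.random.default_rng(params.seed)
    means = np.empty_like(levels)
    for k, level in enumerate(levels):
        img = _apply_noise(np.full(shape, params.gain * level + params.offset),
                           params, rng)
        means[k] = float(img.mean())
    return levels, means, {"gain": params.gain, "offset": params.offset}


@dataclass(frozen=True)
class PhantomSpec:
    """Two-domain organoid phantom: a disc with a ventral cap.

    The organoid is a disc of ``radius`` um (default matching a measured
    cross-section area of ~123,258 um^2); the ventral domain is the
    bottom circular segment holding ``ventral_fraction`` of the disc
    area, with a linear dorsal-to-ventral cross-fade over
    ``band_width`` um emulating the biological transition zone.
    """

    radius: float = 198.06           # um
    ventral_fraction: float = 0.4749
    band_width: float = 10.0         # um
    background: float = 0.05
    dorsal_level: float = 0.25       # ventral-channel intensity in the dorsal part
    ventral_level: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.ventral_fraction <= 1.0):
            raise ValueError("ventral_fraction must lie in [0, 1]")
        if self.band_width < 0:
            raise ValueError("band_width must be >= 0")


def _cap_cut(radius: float, fraction: float) -> float:
    """Signed chord position d with area{y <= d} = fraction * disc area."""
    if fraction <= 0.0:
        return -radius
    if fraction >= 1.0:
        return radius

    def area(d):
        return (d * math.sqrt(max(radius**2 - d**2, 0.0))
                + radius**2 * math.asin(d / radius)
                + radius**2 * math.pi / 2.0)

    target = fraction * math.pi * radius**2
    return brentq(lambda d: area(d) - target, -radius, radius, xtol=1e-12 * radius)


def make_two_domain_image(spec: PhantomSpec, pixel_size: float,
                          margin: float = 20.0) -> dict:
    """Render a two-channel dorsal/ventral phantom with analytic areas.

    Channel ``ventral`` is bright in the ventral cap (with the dorsal
    remainder at ``dorsal_level``); channel ``dorsal`` is the complement.
    Returns a dict with ``images`` (y, x arrays), ground-truth ``masks``,
    rasterized areas ``a1``/``a2`` and analytic areas
    ``a1_analytic``/``a2_analytic`` (um^2).
    """
    R = spec.radius
    half = R + margin
    n = int(math.ceil(2 * half / pixel_size))
    coord = (np.arange(n) + 0.5) * pixel_size - half
    xx, yy = np.meshgrid(coord, coord)  # (row=y, col=x)
    rng = np.random.default_rng(spec.seed)

    disc = xx**2 + yy**2 <= R**2
    d = _cap_cut(R, spec.ventral_fraction)
    if spec.band_width > 0:
        wgt = np.clip((d - yy) / spec.band_width + 0.5, 0.0, 1.0)
    else:
        wgt = (yy <= d).astype(float)
    wgt = np.where(disc, wgt, 0.0)

    ventral_img = np.full((n, n), spec.background)
    ventral_img[disc] = spec.dorsal_level
    ventral_img += (spec.ventral_level - spec.dorsal_level) * wgt
    dorsal_img = np.full((n, n), spec.background)
    dorsal_img[disc] = spec.ventral_level
    dorsal_img -= (spec.ventral_level - spec.dorsal_level) * wgt
    if spec.noise_sd > 0:
        ventral_img = np.clip(ventral_img + rng.normal(0, spec.noise_sd, (n, n)), 0, None)
        dorsal_img = np.clip(dorsal_img + rng.normal(0, spec.noise_sd, (n, n)), 0, None)

    ventral_mask = disc & (wgt >= 0.5)
    a1_analytic = math.pi * R**2
    a2_analytic = spec.ventral_fraction * a1_analytic
    return {
        "images": {"ventral": ventral_img, "dorsal": dorsal_img},
        "masks": {"organoid": disc, "ventral": ventral_mask},
        "a1": float(disc.sum()) * pixel_size**2,
        "a2": float(ventral_mask.sum()) * pixel_size**2,
        "a1_analytic": a1_analytic,
        "a2_analytic": a2_analytic,
        "pixel_size": pixel_size,
    }


def make_nuclei_image(n: int, diameter: float = 4.5,
                      marker_probability: dict[str, float] | None = None,
                      frame_size: float = 512.0, pixel_size: float = 1.0,
                      seed: int = 0, jitter: float = 0.0,
                      min_separation: float | None = None,
                      noise_sd: float = 0.02,
                      max_attempts_per_spot: int = 500) -> dict:
    """Nuclei (DAPI) image plus marker channels lighting Bernoulli subsets.

    ``n`` Gaussian spots (FWHM = ``diameter`` um) are placed by rejection
    sampling with a minimum centre separation (default twice the
    diameter); marker channels reuse the same centres for a Bernoulli
    subset, displaced by a random direction with magnitude uniform in
    ``[0, jitter]`` um.  Returns images, ground-truth :class:`SpotSet`s
    and the marker membership flags.
    """
    if marker_probability is None:
        marker_probability = {}
    if min_separation is None:
        min_separation = 2.0 * diameter
    rng = np.random.default_rng(seed)
    border = diameter
    lo, hi = border, frame_size - border
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        if attempts > max_attempts_per_spot * max(n, 1):
            raise PlacementError(
                f"could not place {n} spots at separation {min_separation} um"
            )
        attempts += 1
        cand = rng.uniform(lo, hi, 2)
        ok = all((cand[0] - x) ** 2 + (cand[1] - y) ** 2 >= min_separation**2
                 for x, y in centers)
        if ok:
            centers.append((float(cand[0]), float(cand[1])))
    centers_arr = np.asarray(centers, dtype=float).reshape(-1, 2)

    npx = int(round(frame_size / pixel_size))
    coord = (np.arange(npx) + 0.5) * pixel_size
    sigma = diameter / 2.355
    halfwin = int(math.ceil(5 * sigma / pixel_size))

    def _render(points: np.ndarray) -> np.ndarray:
        # splat each Gaussian into a +/-5 sigma window only
        img = np.zeros((npx, npx))
        for x, y in points:
            cx_px, cy_px = int(x / pixel_size), int(y / pixel_size)
            c0, c1 = max(0, cx_px - halfwin), min(npx, cx_px + halfwin + 1)
            r0, r1 = max(0, cy_px - halfwin), min(npx, cy_px + halfwin + 1)
            gx = np.exp(-((coord[c0:c1] - x) ** 2) / (2 * sigma**2))
            gy = np.exp(-((coord[r0:r1] - y) ** 2) / (2 * sigma**2))
            img[r0:r1, c0:c1] += gy[:, None] * gx[None, :]
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, None)
        return img

    images = {"dapi": _render(centers_arr)}
    truth: dict = {"dapi": SpotSet(centers_arr, diameter=diameter, channel="dapi")}
    flags: dict[str, np.ndarray] = {}
    for channel, prob in marker_probability.items():
        keep = rng.random(n) < prob
        pts = centers_arr[keep].copy()
        if jitter > 0 and len(pts):
            mag = rng.uniform(0.0, jitter, len(pts))
            ang = rng.uniform(0.0, 2 * math.pi, len(pts))
            pts[:, 0] += mag * np.cos(ang)
            pts[:, 1] += mag * np.sin(ang)
            pts = np.clip(pts, 0.0, frame_size)
        images[channel] = _render(pts)
        truth[channel] = SpotSet(pts, diameter=diameter, channel=channel)
        flags[channel] = keep
    return {"images": images, "truth": truth, "flags": flags,
            "pixel_size": pixel_size, "frame_size": frame_size}
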