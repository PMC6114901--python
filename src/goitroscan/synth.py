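"""Ground-truthed synthetic data for the screening pipeline.

Real screens image the thyroid gland of reporter-line zebrafish embryos:
each embryo yields a bright-field image, an autofocus fluorescence image
and a 9-plane Z-stack. This module emulates the fluorescence channel and
the downstream tabular data so that every pipeline stage can be tested
against known ground truth:

* a scene is a smooth background gradient plus a bright elliptical gland
  (flat top, 1-px cosine edge roll-off so the true pixel sum stays
  analytic), occasional small bright pigment-cell spots, and additive
  Gaussian noise, quantized to 8 bits;
* Z-stacks blur the scene symmetrically around a focal plane;
* concentration-response datasets draw per-embryo pixel sums from a Hill
  curve with lognormal embryo-to-embryo variability;
* mortality tables draw binomial deaths from a log-logistic survival
  curve.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .doseresponse import HillParameters, hill_curve, _loglogistic_cdf

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "ResponseSimSpec",
    "generate_embryo_image",
    "generate_zstack",
    "generate_response_dataset",
    "generate_mortality_dataset",
    "write_scene",
    "read_truth",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic embryo fluorescence scene.

    Intensities are on the 8-bit grey scale. ``background_plane`` is
    ``(offset, x_slope, y_slope)`` in grey levels (per pixel for the
    slopes), emulating uneven illumination. ``edge_width`` is the width
    in pixels of the cosine roll-off at the gland boundary.
    ``pigment_placement`` is ``"away"`` (spots at least one ball-radius
    worth of clearance from the gland is not guaranteed, but outside it)
    or ``"adjacent"`` (spots touching the gland boundary, the hard case
    for label cleanup).
    """

    image_size: tuple[int, int] = (128, 128)  # (height, width)
    gland_center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    gland_axes: tuple[float, float] = (18.0, 10.0)  # (row, col) half-axes
    gland_peak_intensity: float = 120.0
    n_pigment_spots: int = 0
    pigment_intensity: float = 180.0
    pigment_radius: float = 2.5
    background_plane: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    edge_width: float = 1.0
    pigment_placement: str = "away"
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        cy, cx = self.gland_center
        ay, ax = self.gland_axes
        if h < 8 or w < 8:
            raise ValueError("image too small")
        if ay <= 0 or ax <= 0:
            raise ValueError("gland axes must be positive")
        if not (cy - ay >= 0 and cy + ay <= h - 1 and cx - ax >= 0 and cx + ax <= w - 1):
            raise ValueError("gland ellipse extends outside image bounds")
        if self.gland_peak_intensity <= 0:
            raise ValueError("gland_peak_intensity must be positive")
        if self.noise_sd < 0 or self.pigment_radius <= 0:
            raise ValueError("noise_sd must be >= 0 and pigment_radius > 0")
        if self.pigment_placement not in ("away", "adjacent"):
            raise ValueError("pigment_placement must be 'away' or 'adjacent'")


@dataclass
class SceneTruth:
    """Exact ground truth for a generated scene.

    ``true_pixel_sum`` is the sum of the noiseless gland component over
    ``gland_mask`` — what a perfect background subtraction and
    segmentation would measure. It is independent of background, pigment
    and noise realizations.
    """

    gland_mask: np.ndarray
    true_pixel_sum: float
    pigment_mask: np.ndarray


def _gland_component(spec: SceneSpec) -> np.ndarray:
    """Noiseless gland intensity profile: flat-top ellipse, cosine edge."""
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = spec.gland_center
    ay, ax = spec.gland_axes
    r = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    # distance (px) inward from the ellipse boundary, using the short axis
    # as the local scale — conservative, keeps the edge at least edge_width
    d = (1.0 - r) * min(ay, ax)
    profile = np.zeros((h, w))
    if spec.edge_width > 0:
        edge = (d > 0) & (d < spec.edge_width)
        profile[edge] = 0.5 * (1.0 - np.cos(np.pi * d[edge] / spec.edge_width))
    profile[d >= spec.edge_width] = 1.0
    return spec.gland_peak_intensity * profile


def _place_pigment(spec: SceneSpec, rng: np.random.Generator,
                   gland: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = spec.gland_center
    ay, ax = spec.gland_axes
    comp = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    placed = 0
    attempts = 0
    while placed < spec.n_pigment_spots and attempts < 1000:
        attempts += 1
        if spec.pigment_placement == "adjacent":
            theta = rng.uniform(0, 2 * np.pi)
            scale = 1.0 + (spec.pigment_radius + 1.0) / min(ay, ax)
            py = cy + scale * ay * np.sin(theta)
            px = cx + scale * ax * np.cos(theta)
            if not (0 <= py < h and 0 <= px < w):
                continue
        else:
            py = rng.uniform(0, h - 1)
            px = rng.uniform(0, w - 1)
            # reject spots overlapping the gland
            r = np.sqrt(((py - cy) / ay) ** 2 + ((px - cx) / ax) ** 2)
            if r < 1.0 + (spec.pigment_radius + 1.0) / min(ay, ax):
                continue
        spot = (yy - py) ** 2 + (xx - px) ** 2 <= spec.pigment_radius**2
        if not spot.any() or (spot & (gland > 0)).any():
            continue
        comp[spot] = np.maximum(comp[spot], spec.pigment_intensity)
        mask |= spot
        placed += 1
    return comp, mask


def _compose(spec: SceneSpec, rng: np.random.Generator):
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    off, sx, sy = spec.background_plane
    background = off + sx * xx + sy * yy
    gland = _gland_component(spec)
    # noise is drawn before pigment placement so that scenes differing
    # only in pigment configuration share the same noise realization
    noise = rng.normal(0.0, spec.noise_sd, size=(h, w)) if spec.noise_sd > 0 else 0.0
    pigment, pigment_mask = _place_pigment(spec, rng, gland)
    scene = background + gland + pigment + noise
    truth = SceneTruth(
        gland_mask=gland > 0,
        true_pixel_sum=float(gland.sum()),
        pigment_mask=pigment_mask,
    )
    return scene, truth


def _quantize(scene: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(scene), 0, 255).astype(np.uint8)


def generate_embryo_image(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render one 8-bit fluorescence scene with its exact ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scene, truth = _compose(spec, rng)
    return _quantize(scene), truth


def generate_zstack(
    spec: SceneSpec,
    n_planes: int = 9,
    focus_index: int = 4,
    blur_step: float = 1.0,
    autofocus_index: int | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a Z-stack around one focal plane.

    Plane ``focus_index`` is the unblurred scene (identical to
    ``generate_embryo_image``); a plane at distance ``k`` from it is
    Gaussian-blurred with sigma ``blur_step * k``, emulating defocus.
    Returns a ``(n_planes, H, W)`` uint8 array; ``autofocus_index`` is
    carried by the caller (the stack itself is a plain array).
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    if not 0 <= focus_index < n_planes:
        raise ValueError("focus_index out of range")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scene, truth = _compose(spec, rng)
    planes = np.empty((n_planes, *spec.image_size), dtype=np.uint8)
    for k in range(n_planes):
        sigma = blur_step * abs(k - focus_index)
        planes[k] = _quantize(gaussian_filter(scene, sigma) if sigma > 0 else scene)
    return planes, truth


@dataclass
class ResponseSimSpec:
    """Design of one simulated exposure replicate.

    Per-embryo pixel sums are drawn as

        control_pixel_sum * hill(concentration) * LN(1, embryo_cv)

    where LN(1, cv) is a lognormal with mean 1 and coefficient of
    variation ``embryo_cv`` — fluorescence is positive and right-skewed,
    and the paper-style normalization divides it out at the control.
    ``concentrations`` must include 0 (the control group).
    """

    concentrations: tuple[float, ...]
    n_embryos_per_conc: int
    hill: HillParameters
    embryo_cv: float = 0.15
    control_pixel_sum: float = 2.0e5
    compound: str = "synthetic"
    replicate: int = 1
    seed: int = 0

    def validate(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if (c < 0).any():
            raise ValueError("concentrations must be non-negative")
        if 0.0 not in c:
            raise ValueError("concentrations must include 0 (control)")
        if self.n_embryos_per_conc < 1:
            raise ValueError("n_embryos_per_conc must be >= 1")
        if self.embryo_cv < 0:
            raise ValueError("embryo_cv must be >= 0")
        if self.control_pixel_sum <= 0:
            raise ValueError("control_pixel_sum must be positive")


def _lognormal_unit_mean(rng, cv, size):
    """Lognormal deviates with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_response_dataset(spec: ResponseSimSpec) -> pd.DataFrame:
    """Per-embryo pixel-sum table for one simulated replicate.

    Columns: compound, concentration_uM, replicate, embryo_id,
    pixel_sum. Ready for :func:`goitroscan.doseresponse.normalize_to_control`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h = spec.hill
    rows = []
    embryo = 0
    for conc in spec.concentrations:
        mean = spec.control_pixel_sum * hill_curve(conc, h.Min, h.Max, h.EC50, h.slope)
        noise = _lognormal_unit_mean(rng, spec.embryo_cv, spec.n_embryos_per_conc)
        for v in mean * noise:
            rows.append(
                {
                    "compound": spec.compound,
                    "concentration_uM": float(conc),
                    "replicate": spec.replicate,
                    "embryo_id": f"{spec.compound}_r{spec.replicate}_e{embryo:03d}",
                    "pixel_sum": float(v),
                }
            )
            embryo += 1
    return pd.DataFrame(rows)


def generate_mortality_dataset(
    lc50: float,
    slope: float,
    concentrations,
    n_per_conc: int = 25,
    seed: int = 0,
    compound: str = "synthetic",
) -> pd.DataFrame:
    """Binomial mortality counts from a log-logistic survival curve.

    Deaths at concentration ``c`` are Binomial(n, F(c)) with
    ``F(c) = 1 / (1 + (c/lc50)^(-slope))`` (0 at the control, 1/2 at the
    LC50). Columns: compound, concentration_uM, n_exposed, n_dead.
    """
    if lc50 <= 0 or slope <= 0:
        raise ValueError("lc50 and slope must be positive")
    c = np.asarray(concentrations, dtype=float)
    if (c < 0).any():
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    p = _loglogistic_cdf(c, lc50, slope)
    deaths = rng.binomial(n_per_conc, p)
    return pd.DataFrame(
        {
            "compound": compound,
            "concentration_uM": c,
            "n_exposed": n_per_conc,
            "n_dead": deaths,
        }
    )


# ---------------------------------------------------------------------------
# on-disk representation: single-channel TIFF + JSON sidecar with RLE masks

def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return []
    padded = np.concatenate([[False], flat, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[::2], changes[1::2]
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def _rle_decode(runs, shape) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat.reshape(shape)


def write_scene(path, image: np.ndarray, truth: SceneTruth) -> None:
    """Write a scene as TIFF plus a ``.truth.json`` sidecar.

    Multi-plane arrays are written as multi-page TIFFs. Masks are stored
    run-length encoded on the flattened row-major image.
    """
    path = Path(path)
    tifffile.imwrite(path, image, photometric="minisblack")
    shape = image.shape[-2:]
    sidecar = {
        "shape": list(shape),
        "true_pixel_sum": truth.true_pixel_sum,
        "gland_mask_rle": _rle_encode(truth.gland_mask),
        "pigment_mask_rle": _rle_encode(truth.pigment_mask),
    }
    path.with_suffix(".truth.json").write_text(json.dumps(sidecar))


def read_truth(path) -> SceneTruth:
    """Read a ``.truth.json`` sidecar written by :func:`write_scene`."""
    data = json.loads(Path(path).read_text())
    shape = tuple(data["shape"])
    return SceneTruth(
        gland_mask=_rle_decode(data["gland_mask_rle"], shape),
        true_pixel_sum=float(data["true_pixel_sum"]),
        pigment_mask=_rle_decode(data["pigment_mask_rle"], shape),
    )
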