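"""Synthetic spheroid data: density time series and brightfield-like images.

The density generator wraps the solver: a smooth compact initial core
(logistic step in radius) is evolved under a chosen model variant, and
additive Gaussian observation noise (default sigma 0.01, roughly 2-5% of
typical peak densities 0.2-0.5) is applied and clipped at zero.  The image
generator draws a dark, radially symmetric core-plus-halo object on a
light background (brightfield convention: ``1 - im`` is high on the
object), with optional noise and elongated dark distractor objects.

Every generator is deterministic per seed and returns its ground truth so
recovery can be asserted in tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import ModelParams, RadialGrid
from .series import RadialDensitySeries
from .solver import simulate

__all__ = [
    "NoiseSpec",
    "make_initial_profile",
    "generate_density_series",
    "SpheroidImageSpec",
    "generate_spheroid_image",
    "save_image",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model: none, or additive i.i.d. Gaussian."""

    kind: str = "additive_gaussian"
    sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def make_initial_profile(
    grid: RadialGrid,
    core_radius: float = 0.5,
    peak_density: float = 0.5,
    edge_width: float = 0.1,
) -> np.ndarray:
    """Smooth compact initial spheroid profile (logistic step in r).

    ``peak_density / (1 + exp((r - core_radius) / edge_width))``: close to
    ``peak_density`` well inside the core, close to 0 beyond
    ``core_radius + a few edge_widths``, monotone non-increasing.
    """
    if not 0 < core_radius < grid.L:
        raise ValueError(
            f"core_radius must lie in (0, L={grid.L}), got {core_radius}"
        )
    if edge_width <= 0:
        raise ValueError("edge_width must be > 0")
    from scipy.special import expit  # overflow-safe logistic

    return peak_density * expit((core_radius - grid.r) / edge_width)


def generate_density_series(
    params: ModelParams,
    times,
    grid: RadialGrid | None = None,
    *,
    core_radius: float = 0.5,
    peak_density: float = 0.5,
    edge_width: float = 0.1,
    noise: NoiseSpec = NoiseSpec(),
    geometry: str = "spherical",
    support_threshold: float = 1e-3,
) -> tuple[RadialDensitySeries, dict]:
    """Simulate a model and add observation noise.

    Returns the observed series (total density only; negative noisy values
    clipped at 0) and a ground-truth record with the generating
    parameters, profile settings and the noiseless simulation.

    Real processed profiles are exactly zero beyond the detected spheroid
    boundary (the background-subtraction step), so observation noise is
    only applied where the noiseless density exceeds
    ``support_threshold``; outside the support the observed density is
    exactly 0.  With ``kind="none"`` the output is bit-identical to the
    noiseless simulation.
    """
    if grid is None:
        grid = RadialGrid.uniform()
    u0 = make_initial_profile(grid, core_radius, peak_density, edge_width)
    clean = simulate(params, u0, grid, times, geometry=geometry)
    u = clean.u
    if noise.kind == "additive_gaussian" and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        noisy = np.clip(u + rng.normal(0.0, noise.sigma, size=u.shape), 0.0, None)
        u = np.where(clean.u >= support_threshold, noisy, 0.0)
    observed = RadialDensitySeries(clean.times, grid, u)
    truth = {
        "params": params.as_dict(),
        "profile": {
            "core_radius": core_radius,
            "peak_density": peak_density,
            "edge_width": edge_width,
        },
        "noise": asdict(noise),
        "geometry": geometry,
        "clean": clean,
    }
    return observed, truth


# ---------------------------------------------------------------------------
# synthetic brightfield-like images


@dataclass(frozen=True)
class SpheroidImageSpec:
    """Geometry and contrast of a synthetic spheroid image.

    Default frame: 1152 x 1536 px spanning 3.24 x 4.33 mm.  The object is
    a dark core of radius ``core_radius`` px with a logistic edge of width
    ``edge_width`` px plus an exponential halo of decay length
    ``halo_decay`` px and relative amplitude ``halo_amplitude``.
    """

    height: int = 1152
    width: int = 1536
    center: tuple[float, float] = (576.0, 768.0)
    core_radius: float = 100.0
    edge_width: float = 4.0
    halo_decay: float = 60.0
    halo_amplitude: float = 0.5
    core_intensity: float = 0.25
    background_intensity: float = 0.85
    noise_sigma: float = 0.0
    n_distractors: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.center[0] < self.height and 0 <= self.center[1] < self.width):
            raise ValueError("center must lie inside the image")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")
        for name in ("core_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def radial_shape(self, r: np.ndarray) -> np.ndarray:
        """Ground-truth inverted-intensity shape as a function of radius (px).

        Normalized to 1 at the core center; this is the oracle that
        annulus averages of ``1 - im`` are checked against.
        """
        core = 1.0 / (1.0 + np.exp((r - self.core_radius) / self.edge_width))
        halo = self.halo_amplitude * np.exp(
            -np.clip(r - self.core_radius, 0.0, None) / self.halo_decay
        )
        return np.clip(core + halo * (1.0 - core), 0.0, 1.0)


def generate_spheroid_image(spec: SpheroidImageSpec) -> np.ndarray:
    """Render the synthetic image as a float array in [0, 1]."""
    rows = np.arange(spec.height)[:, None] - spec.center[0]
    cols = np.arange(spec.width)[None, :] - spec.center[1]
    r = np.hypot(rows, cols)
    contrast = spec.background_intensity - spec.core_intensity
    im = spec.background_intensity - contrast * spec.radial_shape(r)
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_distractors):
        im = _stamp_distractor(im, spec, rng)
    if spec.noise_sigma > 0:
        im = im + rng.normal(0.0, spec.noise_sigma, size=im.shape)
    return np.clip(im, 0.0, 1.0)


def _stamp_distractor(im, spec, rng):
    """Add one elongated dark ellipse away from the spheroid."""
    h, w = spec.height, spec.width
    margin = 2.5 * spec.core_radius
    for _ in range(100):
        cy = rng.uniform(0.1 * h, 0.9 * h)
        cx = rng.uniform(0.1 * w, 0.9 * w)
        if np.hypot(cy - spec.center[0], cx - spec.center[1]) > margin:
            break
    a = rng.uniform(2.5, 4.0) * spec.core_radius * 0.5  # semi-major, px
    b = a / rng.uniform(3.0, 5.0)  # strongly elongated
    theta = rng.uniform(0, np.pi)
    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    xr = cols * np.cos(theta) + rows * np.sin(theta)
    yr = -cols * np.sin(theta) + rows * np.cos(theta)
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    dip = 0.6 * (spec.background_intensity - spec.core_intensity)
    out = im.copy()
    out[inside] -= dip
    return out


def save_image(path, im: np.ndarray, ground_truth: dict | None = None) -> None:
    """Write a PNG (8-bit) or TIFF (16-bit) plus optional JSON sidecar."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, (np.clip(im, 0, 1) * 65535).astype(np.uint16))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, (np.clip(im, 0, 1) * 255).astype(np.uint8))
    if ground_truth is not None:
        with open(path + ".json", "w") as fh:
            json.dump(ground_truth, fh, indent=2, default=float)
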