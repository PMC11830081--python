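"""Core containers: radial grids, model parameter vectors, parameter bounds.

Four model variants are supported, all radially symmetric:

``RD``
    Single-population reaction-diffusion (Fisher-KPP with logistic growth).
``ARD``
    Single population with an additional outward advection term.
``RD_RD``
    Two populations, each reaction-diffusion, competing for a shared
    carrying capacity through the total density.
``RD_ARD``
    Two populations where the second additionally advects outward; the
    most general variant, of which the other three are boundary
    restrictions.

Units throughout: radius in mm, time in weeks, densities in the arbitrary
intensity units of processed brightfield images (typically 0 to ~0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "MODEL_IDS",
    "MODEL_FREE_PARAMS",
    "RadialGrid",
    "ModelParams",
    "ParameterBounds",
    "DEFAULT_BOUNDS",
]

MODEL_IDS = ("RD", "ARD", "RD_RD", "RD_ARD")

#: Free (estimated) parameters per model variant.  The single-population
#: variants keep ``alpha`` fixed at 1; ``ARD`` stores its advection rate in
#: the ``A2`` slot for uniformity.
MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "RD": ("D1", "rho1", "K1"),
    "ARD": ("D1", "rho1", "K1", "A2"),
    "RD_RD": ("D1", "rho1", "K1", "D2", "rho2", "K2", "alpha"),
    "RD_ARD": ("D1", "rho1", "K1", "D2", "rho2", "K2", "A2", "alpha"),
}


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node-centered radial grid on ``[0, L]``.

    Parameters
    ----------
    r : ndarray
        Ascending, uniformly spaced radial coordinates in mm, with
        ``r[0] >= 0`` and ``r[-1] == L``.
    """

    r: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 1 or r.size < 16:
            raise ValueError("radial grid needs at least 16 nodes")
        if r[0] < 0:
            raise ValueError("radial coordinates must be non-negative")
        dr = np.diff(r)
        if np.any(dr <= 0):
            raise ValueError("radial coordinates must be strictly ascending")
        if not np.allclose(dr, dr[0], rtol=1e-9, atol=1e-12):
            raise ValueError("radial grid must be uniform")
        object.__setattr__(self, "r", r)

    @classmethod
    def uniform(cls, L: float = 5.0, n: int = 400) -> "RadialGrid":
        """Default simulation grid: ``n`` nodes on ``[0, L]`` mm."""
        return cls(np.linspace(0.0, float(L), int(n)))

    @property
    def L(self) -> float:
        return float(self.r[-1])

    @property
    def n(self) -> int:
        return self.r.size

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])


@dataclass
class ModelParams:
    """Parameter vector for one model variant.

    ``D`` entries are diffusion coefficients (mm^2/week), ``rho`` growth
    rates (1/week), ``K`` carrying capacities (density units), ``A2`` the
    outward advection rate (mm/week) and ``alpha`` the fraction of the
    initial total density assigned to population 1.
    """

    model_id: str
    D1: float = 0.0
    rho1: float = 0.0
    K1: float = 0.0
    D2: float = 0.0
    rho2: float = 0.0
    K2: float = 0.0
    A2: float = 0.0
    alpha: float = 1.0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )
        for f in fields(self):
            if f.name == "model_id":
                continue
            v = float(getattr(self, f.name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
            setattr(self, f.name, v)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.model_id in ("RD", "ARD"):
            # single-population variants: everything lives in compartment 1
            self.alpha = 1.0

    @property
    def free_names(self) -> tuple[str, ...]:
        return MODEL_FREE_PARAMS[self.model_id]

    @property
    def kappa(self) -> int:
        """Number of estimated parameters (3, 4, 7 or 8)."""
        return len(self.free_names)

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names], dtype=float)

    @classmethod
    def from_free(cls, model_id: str, values) -> "ModelParams":
        names = MODEL_FREE_PARAMS[model_id]
        values = np.asarray(values, dtype=float)
        if values.shape != (len(names),):
            raise ValueError(
                f"{model_id} expects {len(names)} free parameters {names}, "
                f"got shape {values.shape}"
            )
        return cls(model_id, **dict(zip(names, values)))

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return d


#: Admissible ranges for each parameter used by the global fitting stage.
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "D1": (0.0, 0.2),
    "D2": (0.0, 0.2),
    "rho1": (0.0, 15.0),
    "rho2": (0.0, 15.0),
    "K1": (0.0, 1.0),
    "K2": (0.0, 1.0),
    "A2": (0.0, 3.0),
    "alpha": (0.0, 1.0),
}


@dataclass
class ParameterBounds:
    """Box constraints for parameter estimation.

    Defaults are the admissible ranges used throughout: diffusion in
    [0, 0.2] mm^2/week, growth in [0, 15] 1/week, carrying capacity in
    [0, 1], advection in [0, 3] mm/week and alpha in [0, 1].
    """

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if name not in _DEFAULT_RANGES:
                raise ValueError(f"unknown parameter name {name!r}")
            if not lo <= hi:
                raise ValueError(f"bounds for {name} must satisfy lower <= upper")

    @classmethod
    def default(cls, **overrides) -> "ParameterBounds":
        ranges = dict(_DEFAULT_RANGES)
        for name, rng in overrides.items():
            ranges[name] = (float(rng[0]), float(rng[1]))
        return cls(ranges)

    def for_model(self, model_id: str) -> list[tuple[float, float]]:
        return [self.ranges[n] for n in MODEL_FREE_PARAMS[model_id]]

    def contains(self, params: ModelParams, atol: float = 1e-12) -> bool:
        for n in params.free_names:
            lo, hi = self.ranges[n]
            v = getattr(params, n)
            if v < lo - atol or v > hi + atol:
                return False
        return True


DEFAULT_BOUNDS = ParameterBounds()
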