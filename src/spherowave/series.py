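"""Radial density time series and their CSV serialization.

The canonical on-disk form is a long-format CSV with header
``time_weeks,radius_mm,density``; a wide writer (rows = times,
columns = radii) is provided for spreadsheet use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RadialGrid

__all__ = ["RadialDensitySeries", "read_series_csv"]

LONG_COLUMNS = ("time_weeks", "radius_mm", "density")


@dataclass
class RadialDensitySeries:
    """Total cell density on a (time x radius) grid.

    ``u`` has shape ``(n_times, grid.n)``.  Simulated series also carry the
    per-subpopulation densities ``u1`` and ``u2`` with ``u = u1 + u2``.
    Observed data may contain small negative values from noise; these are
    kept but flagged with a warning.
    """

    times: np.ndarray
    grid: RadialGrid
    u: np.ndarray
    u1: np.ndarray | None = None
    u2: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be 1-D and strictly ascending")
        if self.u.shape != (self.times.size, self.grid.n):
            raise ValueError(
                f"u has shape {self.u.shape}, expected "
                f"({self.times.size}, {self.grid.n})"
            )
        if np.min(self.u) < -1e-3:
            warnings.warn(
                "density series contains negative values below noise scale",
                stacklevel=2,
            )
        for name in ("u1", "u2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.u.shape:
                    raise ValueError(f"{name} must have the same shape as u")
                setattr(self, name, v)
        if self.u1 is not None and self.u2 is not None:
            if not np.allclose(self.u, self.u1 + self.u2, atol=1e-8):
                raise ValueError("u must equal u1 + u2")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_obs(self) -> int:
        """Total number of space-time observations (N_t * N_r)."""
        return self.u.size

    def to_long_frame(self) -> pd.DataFrame:
        t = np.repeat(self.times, self.grid.n)
        r = np.tile(self.grid.r, self.n_times)
        return pd.DataFrame(
            {"time_weeks": t, "radius_mm": r, "density": self.u.ravel()}
        )

    def to_csv(self, path) -> None:
        """Write the long-format CSV (round-trips exactly)."""
        # %.17g guarantees binary round-trip of float64
        self.to_long_frame().to_csv(path, index=False, float_format="%.17g")

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.u, index=self.times, columns=self.grid.r)
        df.index.name = "time_weeks"
        df.columns.name = "radius_mm"
        return df

    def to_wide_csv(self, path) -> None:
        self.to_wide_frame().to_csv(path)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "RadialDensitySeries":
        missing = set(LONG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"long-format series is missing columns {sorted(missing)}")
        piv = df.pivot_table(
            index="time_weeks", columns="radius_mm", values="density", sort=True
        )
        grid = RadialGrid(piv.columns.to_numpy(dtype=float))
        return cls(piv.index.to_numpy(dtype=float), grid, piv.to_numpy(dtype=float))


def read_series_csv(path) -> RadialDensitySeries:
    """Read a long-format ``time_weeks,radius_mm,density`` CSV."""
    return RadialDensitySeries.from_long_frame(
        pd.read_csv(path, float_precision="round_trip")
    )
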