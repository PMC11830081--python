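"""Cross-cell-line phenotyping: normalization, Go-or-Grow calls,
clustering, partial correlation.

Fitted two-population coefficients are made dimensionless by dividing by
population aggregates (the across-line mean of ``(D1+D2)/2`` for
diffusion, of ``(rho1+rho2)/2`` for growth, and of ``A2`` for advection).
A line is Go-or-Grow when one subpopulation's rescaled motility exceeds
the other's by a factor k while the rescaled proliferation relationship
is reversed (advection counts toward the motility of population 2):

    pop-1 migrates:  D1_n > k*(D2_n + A2_n)  and  rho2_n > k*rho1_n
    pop-2 migrates:  (D2_n + A2_n) > k*D1_n  and  rho1_n > k*rho2_n

with strict inequalities and k = 5 by default.  Both sides of each
condition scale identically under a common rescaling of the aggregates,
so the labels do not depend on whether sums or means define them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core import ModelParams

__all__ = [
    "GoGrowTable",
    "normalize_parameters",
    "classify_go_or_grow",
    "ClusterResult",
    "cluster_cell_lines",
    "partial_correlation",
    "LABEL_POP1",
    "LABEL_POP2",
    "LABEL_NONE",
]

LABEL_POP1 = "go_or_grow_pop1_migrates"
LABEL_POP2 = "go_or_grow_pop2_migrates"
LABEL_NONE = "not_go_or_grow"


@dataclass
class GoGrowTable:
    """Normalized coefficients per cell line plus aggregates and labels."""

    table: pd.DataFrame  # index: cell line; D1_n, D2_n, rho1_n, rho2_n, A2_n
    aggregates: dict  # D_bar, rho_bar, A_bar
    k: float | None = None  # set once classified


def _params_frame(fits) -> pd.DataFrame:
    if isinstance(fits, pd.DataFrame):
        return fits
    rows = {}
    for name, p in fits.items():
        if isinstance(p, ModelParams):
            rows[name] = p.as_dict()
        else:
            rows[name] = dict(p)
    return pd.DataFrame.from_dict(rows, orient="index")


def normalize_parameters(fits) -> GoGrowTable:
    """Population-normalize per-line coefficients (labels unset).

    ``fits`` is a mapping cell line -> ModelParams (two-population fits)
    or an equivalent DataFrame with columns D1, D2, rho1, rho2, A2.
    """
    df = _params_frame(fits)
    if len(df) < 2:
        raise ValueError("normalization needs at least 2 cell lines")
    D_bar = float(((df["D1"] + df["D2"]) / 2).mean())
    rho_bar = float(((df["rho1"] + df["rho2"]) / 2).mean())
    A_bar = float(df["A2"].mean())
    for name, v in (("diffusion", D_bar), ("growth", rho_bar), ("advection", A_bar)):
        if v == 0:
            raise ValueError(f"degenerate normalization: {name} aggregate is 0")
    out = pd.DataFrame(
        {
            "D1_n": df["D1"] / D_bar,
            "D2_n": df["D2"] / D_bar,
            "rho1_n": df["rho1"] / rho_bar,
            "rho2_n": df["rho2"] / rho_bar,
            "A2_n": df["A2"] / A_bar,
        },
        index=df.index,
    )
    return GoGrowTable(
        table=out, aggregates={"D_bar": D_bar, "rho_bar": rho_bar, "A_bar": A_bar}
    )


def classify_go_or_grow(table: GoGrowTable, k: float = 5.0) -> GoGrowTable:
    """Attach Go-or-Grow labels (strict inequalities, factor ``k``)."""
    t = table.table.copy()
    mig2 = t["D2_n"] + t["A2_n"]
    cond_pop1 = (t["D1_n"] > k * mig2) & (t["rho2_n"] > k * t["rho1_n"])
    cond_pop2 = (mig2 > k * t["D1_n"]) & (t["rho1_n"] > k * t["rho2_n"])
    t["label"] = np.select(
        [cond_pop1, cond_pop2], [LABEL_POP1, LABEL_POP2], default=LABEL_NONE
    )
    return GoGrowTable(table=t, aggregates=dict(table.aggregates), k=float(k))


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    labels: pd.Series  # flat cluster id per cell line
    features: list[str]
    standardization: pd.DataFrame  # per-feature mean and sd (ddof=1)


def cluster_cell_lines(params_table, n_clusters: int) -> ClusterResult:
    """Average-linkage hierarchical clustering on standardized features.

    Each feature is divided by its across-line sample standard deviation
    (standardized Euclidean distance); zero-variance features are dropped
    with a warning.  Flat labels come from cutting the tree at
    ``n_clusters``.
    """
    df = _params_frame(params_table).select_dtypes("number")
    if n_clusters < 1 or n_clusters > len(df):
        raise ValueError("n_clusters must lie in [1, n_lines]")
    sd = df.std(ddof=1)
    dead = sd[(sd == 0) | sd.isna()].index
    if len(dead):
        warnings.warn(
            f"dropping zero-variance features {list(dead)}", stacklevel=2
        )
        df = df.drop(columns=dead)
        sd = sd.drop(dead)
    if df.shape[1] == 0:
        raise ValueError("no informative features left to cluster on")
    X = (df / sd).to_numpy()
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        linkage=Z,
        labels=pd.Series(flat, index=df.index, name="cluster"),
        features=list(df.columns),
        standardization=pd.DataFrame({"mean": df.mean(), "sd": sd}),
    )


def partial_correlation(rho_ab: float, rho_ac: float, rho_bc: float) -> float:
    """Correlation of A and B controlling for C.

    ``(rho_AB - rho_AC*rho_BC) / (sqrt(1-rho_AC^2) * sqrt(1-rho_BC^2))``,
    clamped to [-1, 1] against rounding.
    """
    for name, v in (("rho_ab", rho_ab), ("rho_ac", rho_ac), ("rho_bc", rho_bc)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1]")
    if abs(rho_ac) == 1.0 or abs(rho_bc) == 1.0:
        raise ValueError("control variable perfectly correlated: zero denominator")
    num = rho_ab - rho_ac * rho_bc
    den = np.sqrt(1 - rho_ac**2) * np.sqrt(1 - rho_bc**2)
    return float(np.clip(num / den, -1.0, 1.0))
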