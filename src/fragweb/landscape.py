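"""Patch connectivity (incidence-function index) and design-variable checks.

The connectivity of a focal habitat patch i is the distance-decayed,
area-weighted sum over neighbouring patches within a search radius:

    S_i = sum_{j != i, d_ij <= radius} exp(-alpha * d_ij) * (scale * A_j)^beta

with centroid Euclidean distances d_ij in metres and patch areas A_j in
hectares.  ``area_scale`` sets the unit of area inside the kernel (1 keeps
hectares; 1e4 expresses areas in square metres, which under the default
alpha and beta yields indices on the 20-849 scale typical of 2-km
neighbourhoods of calcareous grassland).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Patch:
    id: str
    x_m: float
    y_m: float
    area_ha: float
    focal: bool = False


@dataclass
class ConnectivityParams:
    """Distance decay alpha (1/m), area exponent beta, search radius (m)."""

    alpha: float = 0.001
    beta: float = 0.5
    radius: float = 2000.0
    area_scale: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.radius <= 0 or self.area_scale <= 0:
            raise ValueError("alpha, radius and area_scale must be positive")


def load_patches(path) -> list[Patch]:
    df = pd.read_csv(path, dtype={"id": str})
    required = ["id", "x_m", "y_m", "area_ha", "focal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        Patch(
            id=row["id"],
            x_m=float(row["x_m"]),
            y_m=float(row["y_m"]),
            area_ha=float(row["area_ha"]),
            focal=str(row["focal"]).strip().casefold() in ("true", "1", "yes"),
        )
        for _, row in df.iterrows()
    ]


def connectivity(
    focal: Patch, patches: list[Patch], params: ConnectivityParams | None = None
) -> float:
    """Incidence-function connectivity of one focal patch (>= 0)."""
    params = params or ConnectivityParams()
    s = 0.0
    for patch in patches:
        if patch.id == focal.id:
            continue
        d = float(np.hypot(patch.x_m - focal.x_m, patch.y_m - focal.y_m))
        if d <= params.radius:
            s += np.exp(-params.alpha * d) * (params.area_scale * patch.area_ha) ** params.beta
    return float(s)


def connectivity_all(
    patches: list[Patch], params: ConnectivityParams | None = None
) -> dict[str, float]:
    """Connectivity for every focal patch in one pass."""
    return {p.id: connectivity(p, patches, params) for p in patches if p.focal}


def design_check(design: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among the three design variables.

    Size class is encoded 0/1 (small/large), connectivity is log10-
    transformed; ties are mid-ranked.  A constant variable yields NaN with a
    warning instead of an error.
    """
    if len(design) < 3:
        raise ValueError("design_check needs at least 3 fragments")
    size = (
        design["size_class"]
        .map(lambda v: 1.0 if str(v).strip().casefold() in ("large", "1", "true") else 0.0)
        .to_numpy()
    )
    variables = {
        "size_class": size,
        "log10_connectivity": np.log10(design["connectivity"].to_numpy(dtype=float)),
        "arable_pct": design["arable_pct"].to_numpy(dtype=float),
    }
    names = list(variables)
    rho = pd.DataFrame(np.eye(3), index=names, columns=names)
    for a in range(3):
        for b in range(a + 1, 3):
            xa, xb = variables[names[a]], variables[names[b]]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                warnings.warn(
                    f"Spearman rho undefined for constant variable in pair "
                    f"({names[a]}, {names[b]})"
                )
                value = np.nan
            else:
                value = stats.spearmanr(xa, xb).statistic
            rho.iloc[a, b] = rho.iloc[b, a] = value
    return rho
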