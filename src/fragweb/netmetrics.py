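"""Weighted food-web indices: interaction diversity, generality, vulnerability
and linkage density, as effective numbers from Shannon entropies.

With p_ij = b_ij / B the proportion of total interaction strength in cell
(i, j):

* interaction diversity  H  = -sum p_ij ln p_ij                (nats)
* generality             G  = sum_j (b_.j / B) exp(H_j)        (effective
  plant species per leafhopper, weighted by consumer marginal totals;
  H_j is the entropy of column j's proportions)
* vulnerability          V  = sum_i (b_i. / B) exp(H_i)        (row mirror)
* weighted linkage density LD = (G + V) / 2                    (effective
  links per species)

Effective numbers are base-invariant: natural logs with exp() equal base-2
entropies with 2**H.  Empty cells contribute nothing (0 ln 0 := 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import QuantitativeWeb
from .community import SPECIALIST, DietDatabase, classify
from .errors import EmptyWebError, StatisticalError


@dataclass
class WebMetrics:
    fragment_id: str
    interaction_diversity: float
    generality: float
    vulnerability: float
    linkage_density: float
    richness_covariate: int
    n_specialists: int
    n_generalists: int


def _check(web: QuantitativeWeb) -> np.ndarray:
    b = np.asarray(web.b, dtype=float)
    if b.size == 0 or b.sum() <= 0:
        raise EmptyWebError(f"fragment {web.fragment_id}: web has no interactions")
    return b


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def interaction_diversity(web: QuantitativeWeb) -> float:
    """Shannon diversity (nats) of the web's cell-proportion distribution."""
    b = _check(web)
    return _entropy(b.ravel() / b.sum())


def generality(web: QuantitativeWeb) -> float:
    """Marginal-weighted effective number of plant species per consumer."""
    b = _check(web)
    col = b.sum(axis=0)
    B = b.sum()
    g = 0.0
    for j in range(b.shape[1]):
        if col[j] > 0:
            g += (col[j] / B) * np.exp(_entropy(b[:, j] / col[j]))
    return float(g)


def vulnerability(web: QuantitativeWeb) -> float:
    """Marginal-weighted effective number of consumers per plant (row mirror)."""
    b = _check(web)
    row = b.sum(axis=1)
    B = b.sum()
    v = 0.0
    for i in range(b.shape[0]):
        if row[i] > 0:
            v += (row[i] / B) * np.exp(_entropy(b[i, :] / row[i]))
    return float(v)


def linkage_density(web: QuantitativeWeb) -> float:
    """Mean of weighted generality and vulnerability: effective links per species."""
    _check(web)
    return 0.5 * (generality(web) + vulnerability(web))


def web_covariates(
    web: QuantitativeWeb, diet_db: DietDatabase
) -> tuple[int, int, int]:
    """(plants-in-web + consumers-in-web, n specialist, n generalist consumers)."""
    b = _check(web)
    n_plants = int((b.sum(axis=1) > 0).sum())
    n_consumers = len(web.consumers)
    n_spec = 0
    for consumer in web.consumers:
        if consumer not in diet_db:
            raise StatisticalError(f"consumer {consumer!r} missing from diet table")
        if classify(diet_db[consumer]) == SPECIALIST:
            n_spec += 1
    return n_plants + n_consumers, n_spec, n_consumers - n_spec


def web_metrics(web: QuantitativeWeb, diet_db: DietDatabase) -> WebMetrics:
    richness, n_spec, n_gen = web_covariates(web, diet_db)
    return WebMetrics(
        fragment_id=web.fragment_id,
        interaction_diversity=interaction_diversity(web),
        generality=generality(web),
        vulnerability=vulnerability(web),
        linkage_density=linkage_density(web),
        richness_covariate=richness,
        n_specialists=n_spec,
        n_generalists=n_gen,
    )


def metrics_table(
    webs: dict[str, QuantitativeWeb], diet_db: DietDatabase
) -> pd.DataFrame:
    """Tidy per-fragment metrics table (one row per fragment)."""
    rows = []
    for fid in sorted(webs):
        m = web_metrics(webs[fid], diet_db)
        rows.append(
            {
                "fragment_id": m.fragment_id,
                "H": m.interaction_diversity,
                "G": m.generality,
                "V": m.vulnerability,
                "LD": m.linkage_density,
                "richness_covariate": m.richness_covariate,
                "n_specialists": m.n_specialists,
                "n_generalists": m.n_generalists,
            }
        )
    return pd.DataFrame(rows)
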