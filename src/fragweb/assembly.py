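"""Assembly of quantitative plant-leafhopper webs from abundance and diet data.

The web for a fragment is a plants x consumers matrix ``b`` whose cell b_ij
carries the abundance of leafhopper j allocated to plant i.  Consumers are
excluded in three steps before allocation:

1. taxa not identified to species level (global),
2. taxa whose food plants are unknown at species or genus rank (global),
3. taxa none of whose food plants were recorded on the fragment's transects
   (per fragment).

A surviving consumer's pooled abundance is placed entirely on its single
matched food plant, or split across several in proportion to their mean
relative covers (re-normalised over the matched plants only), so column sums
conserve the retained abundances exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import DietDatabase, FragmentCommunity, genus_of, normalize_name
from .errors import AllocationError, CrossReferenceError, EmptyWebError

RULE_UNIDENTIFIED = "unidentified"
RULE_DIET_UNKNOWN = "diet_unknown"
RULE_NO_FOOD_PLANT = "no_food_plant_here"


@dataclass
class Exclusion:
    taxon: str
    rule: str
    specimens: int


@dataclass
class QuantitativeWeb:
    """Quantitative bipartite web of one fragment.

    Rows are plants, columns are leafhopper consumers; ``b[i, j]`` is the
    abundance of consumer j allocated to plant i.  ``exclusion_log`` records
    every consumer dropped on the way, with the rule and specimen count.
    """

    fragment_id: str
    plants: list[str]
    consumers: list[str]
    b: np.ndarray
    exclusion_log: list[Exclusion] = field(default_factory=list)

    @property
    def B(self) -> float:
        """Total allocated abundance (sum of all cells)."""
        return float(self.b.sum())

    @property
    def excluded_specimens(self) -> int:
        return sum(e.specimens for e in self.exclusion_log)

    def column_sums(self) -> np.ndarray:
        return self.b.sum(axis=0)

    def row_sums(self) -> np.ndarray:
        return self.b.sum(axis=1)

    def to_edge_list(self) -> pd.DataFrame:
        """Long-format positive cells: fragment_id, plant, consumer, weight."""
        rows = []
        for i, plant in enumerate(self.plants):
            for j, consumer in enumerate(self.consumers):
                if self.b[i, j] > 0:
                    rows.append((self.fragment_id, plant, consumer, self.b[i, j]))
        return pd.DataFrame(rows, columns=["fragment_id", "plant", "consumer", "weight"])

    def to_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.b, index=self.plants, columns=self.consumers)

    @property
    def n_links(self) -> int:
        return int((self.b > 0).sum())

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame, fragment_id: str) -> "QuantitativeWeb":
        sub = edges[edges["fragment_id"] == fragment_id]
        plants = sorted(sub["plant"].unique())
        consumers = sorted(sub["consumer"].unique())
        b = np.zeros((len(plants), len(consumers)))
        pi = {p: i for i, p in enumerate(plants)}
        cj = {c: j for j, c in enumerate(consumers)}
        for _, row in sub.iterrows():
            b[pi[row["plant"]], cj[row["consumer"]]] += row["weight"]
        return cls(fragment_id, plants, consumers, b)


def match_food_plants(
    consumer: str, diet_db: DietDatabase, community: FragmentCommunity
) -> list[str]:
    """Plants of this fragment that the consumer's literature diet matches.

    Species-rank diet entries match the exact plant taxon; genus-rank entries
    match every recorded congeneric plant.  Only plants with positive mean
    relative cover in the fragment qualify.
    """
    entry = diet_db[consumer]
    present = {
        normalize_name(p): p
        for p, c in community.mean_relative_cover.items()
        if c > 0
    }
    matched: list[str] = []
    for food, rank in entry.food_taxa:
        if rank == "species":
            hit = present.get(normalize_name(food))
            if hit is not None and hit not in matched:
                matched.append(hit)
        else:  # genus
            target = normalize_name(food)
            for norm, plant in present.items():
                if genus_of(norm) == target and plant not in matched:
                    matched.append(plant)
    return matched


def apply_exclusions(
    community: FragmentCommunity, diet_db: DietDatabase
) -> tuple[dict[str, int], list[Exclusion]]:
    """Filter the fragment's pooled consumers through the three rules."""
    retained: dict[str, int] = {}
    log: list[Exclusion] = []
    for taxon, n in sorted(community.pooled_abundance.items()):
        if taxon not in diet_db:
            raise CrossReferenceError(
                f"fragment {community.fragment_id}: leafhopper {taxon!r} has no row "
                "in the diet table; add one (with diet_known implied false if empty)"
            )
        entry = diet_db[taxon]
        if not entry.identified_to_species:
            log.append(Exclusion(taxon, RULE_UNIDENTIFIED, n))
        elif not entry.diet_known:
            log.append(Exclusion(taxon, RULE_DIET_UNKNOWN, n))
        elif not match_food_plants(taxon, diet_db, community):
            log.append(Exclusion(taxon, RULE_NO_FOOD_PLANT, n))
        else:
            retained[taxon] = n
    return retained, log


def allocate(abundance: int, covers: dict[str, float]) -> dict[str, float]:
    """Split a consumer's abundance across its matched food plants.

    One plant gets the full abundance; several share it in proportion to
    their covers, re-normalised over the matched set.
    """
    if abundance <= 0:
        raise ValueError("abundance must be positive")
    if not covers:
        raise AllocationError("no food plants to allocate to")
    if len(covers) == 1:
        (plant,) = covers
        return {plant: float(abundance)}
    total = sum(covers.values())
    if total <= 0:
        raise AllocationError("all matched food-plant covers are zero")
    return {plant: abundance * c / total for plant, c in covers.items()}


def build_web(community: FragmentCommunity, diet_db: DietDatabase) -> QuantitativeWeb:
    """Assemble the fragment's quantitative web after exclusions."""
    retained, log = apply_exclusions(community, diet_db)
    if not retained:
        raise EmptyWebError(
            f"fragment {community.fragment_id}: no leafhopper species survives "
            "the exclusion rules"
        )
    allocations: dict[str, dict[str, float]] = {}
    plants: list[str] = []
    for consumer, n in retained.items():
        matched = match_food_plants(consumer, diet_db, community)
        covers = {p: community.mean_relative_cover[p] for p in matched}
        allocations[consumer] = allocate(n, covers)
        for plant in allocations[consumer]:
            if plant not in plants:
                plants.append(plant)
    plants.sort()
    consumers = sorted(retained)
    b = np.zeros((len(plants), len(consumers)))
    pi = {p: i for i, p in enumerate(plants)}
    for j, consumer in enumerate(consumers):
        for plant, amount in allocations[consumer].items():
            b[pi[plant], j] = amount
    return QuantitativeWeb(community.fragment_id, plants, consumers, b, log)


def build_webs(
    communities: dict[str, FragmentCommunity], diet_db: DietDatabase
) -> dict[str, QuantitativeWeb]:
    """One web per fragment; fragments whose web is empty are skipped with a log entry."""
    webs: dict[str, QuantitativeWeb] = {}
    for fid, community in sorted(communities.items()):
        webs[fid] = build_web(community, diet_db)
    return webs
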