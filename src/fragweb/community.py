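"""Survey tables, pooling, relative covers and specialist classification.

The field protocol behind these structures: each grassland fragment holds six
transects; vascular-plant cover (%), bare-ground cover and litter cover are
recorded once per transect in a 1 x 5 m botanical plot, and leafhoppers are
swept on three occasions per transect.  Everything downstream (web assembly,
network indices, regression covariates) consumes the per-fragment summaries
produced here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    CrossReferenceError,
    DegenerateTransectError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: taxon codes reserved for the two non-plant cover fractions in covers.csv
BARE_GROUND = "_bare_ground"
LITTER = "_litter"

SPECIALIST = "specialist"
GENERALIST = "generalist"


@dataclass
class TransectSurvey:
    """One transect of one fragment: botany plus swept leafhopper counts.

    ``plant_cover`` maps plant taxon -> percent cover in the botanical plot;
    ``leafhopper_counts`` maps sampling occasion -> taxon -> individuals.
    Plant covers carry no occasion (botany is recorded once per transect).
    """

    fragment_id: str
    transect_id: str
    plant_cover: dict[str, float]
    bare_ground: float = 0.0
    litter: float = 0.0
    leafhopper_counts: dict[int, dict[str, int]] = field(default_factory=dict)

    def total_count(self) -> int:
        return sum(n for occ in self.leafhopper_counts.values() for n in occ.values())


@dataclass
class FragmentCommunity:
    """Per-fragment community summary feeding the web assembler.

    ``mean_relative_cover`` is the arithmetic mean over the fragment's
    transects of per-transect relative covers (a transect where the species
    is absent contributes zero), so values sum to at most one — bare ground
    and litter absorb the remainder.
    """

    fragment_id: str
    mean_relative_cover: dict[str, float]
    plant_richness: int
    pooled_abundance: dict[str, int]


@dataclass
class DietEntry:
    """Literature-derived diet and habitat information for one leafhopper.

    ``food_taxa`` lists (taxon name, rank) pairs where rank is ``"species"``
    or ``"genus"``; an empty list means the diet is unknown at either rank.
    ``habitat_condition`` and ``diet_condition`` are the two specialist
    criteria: strict requirements for warm, dry, short-sward calcareous
    grassland, and a diet restricted to plants exclusive to it.
    """

    taxon: str
    food_taxa: list[tuple[str, str]] = field(default_factory=list)
    monophagous: bool = False
    habitat_condition: bool = False
    diet_condition: bool = False
    identified_to_species: bool = True

    @property
    def diet_known(self) -> bool:
        return len(self.food_taxa) > 0

    @property
    def specialist(self) -> bool:
        return self.habitat_condition or self.diet_condition


class DietDatabase:
    """Lookup of :class:`DietEntry` by (normalised) taxon name."""

    def __init__(self, entries: list[DietEntry]):
        self._entries = {normalize_name(e.taxon): e for e in entries}

    def __contains__(self, taxon: str) -> bool:
        return normalize_name(taxon) in self._entries

    def __getitem__(self, taxon: str) -> DietEntry:
        return self._entries[normalize_name(taxon)]

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)


def normalize_name(name: str) -> str:
    """Trim and case-fold a taxon name; matching is plain string equality."""
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


def genus_of(name: str) -> str:
    """First token of a binomial, normalised."""
    return normalize_name(name).split(" ")[0]


def classify(entry: DietEntry) -> str:
    """Habitat specialist if either specialist condition holds, else generalist."""
    return SPECIALIST if entry.specialist else GENERALIST


# ---------------------------------------------------------------------------
# species codes (two letters of genus + two of epithet, digit on collision)
# ---------------------------------------------------------------------------

def species_code(name: str) -> str:
    parts = normalize_name(name).split(" ")
    genus = parts[0][:2].capitalize()
    epithet = parts[1][:2] if len(parts) > 1 else ""
    return genus + epithet


def assign_codes(names: list[str]) -> dict[str, str]:
    """Unique short code per taxon; collisions get an appended digit."""
    codes: dict[str, str] = {}
    used: dict[str, int] = {}
    for name in names:
        base = species_code(name)
        if base not in used:
            used[base] = 0
            codes[name] = base
        else:
            used[base] += 1
            codes[name] = f"{base}{used[base]}"
    return codes


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

COVER_COLUMNS = ["fragment_id", "transect_id", "taxon", "cover_pct"]
COUNT_COLUMNS = ["fragment_id", "transect_id", "occasion", "taxon", "count"]
DIET_COLUMNS = [
    "taxon",
    "food_taxon",
    "food_rank",
    "monophagous",
    "habitat_condition",
    "diet_condition",
    "identified_to_species",
]

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def _as_bool(value, where: str) -> bool:
    text = str(value).strip().casefold()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"{where}: cannot interpret {value!r} as a boolean")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_surveys(cover_path, counts_path) -> list[TransectSurvey]:
    """Read covers.csv and counts.csv into one survey per (fragment, transect).

    All validation problems in the two files are collected and raised together
    as one :class:`ValidationError`; counts that name a fragment absent from
    the cover table raise :class:`CrossReferenceError`.
    """
    covers = pd.read_csv(cover_path, dtype={"fragment_id": str, "transect_id": str})
    counts = pd.read_csv(counts_path, dtype={"fragment_id": str, "transect_id": str})
    return surveys_from_frames(covers, counts, cover_path, counts_path)


def surveys_from_frames(
    covers: pd.DataFrame,
    counts: pd.DataFrame,
    cover_path="covers",
    counts_path="counts",
) -> list[TransectSurvey]:
    """Frame-based core of :func:`load_surveys` (same validation rules)."""
    covers = covers.astype({"fragment_id": str, "transect_id": str})
    counts = counts.astype({"fragment_id": str, "transect_id": str})
    _require_columns(covers, COVER_COLUMNS, cover_path)
    _require_columns(counts, COUNT_COLUMNS, counts_path)

    problems: list[str] = []
    surveys: dict[tuple[str, str], TransectSurvey] = {}

    for idx, row in covers.iterrows():
        key = (row["fragment_id"], row["transect_id"])
        survey = surveys.get(key)
        if survey is None:
            survey = surveys[key] = TransectSurvey(key[0], key[1], {})
        cover = float(row["cover_pct"])
        if not 0.0 <= cover <= 100.0:
            problems.append(
                f"{cover_path} row {idx}: cover_pct {cover} outside [0, 100] "
                f"for taxon {row['taxon']!r}"
            )
            continue
        taxon = str(row["taxon"]).strip()
        if taxon == BARE_GROUND:
            survey.bare_ground = cover
        elif taxon == LITTER:
            survey.litter = cover
        else:
            survey.plant_cover[taxon] = survey.plant_cover.get(taxon, 0.0) + cover

    known_fragments = {k[0] for k in surveys}
    for idx, row in counts.iterrows():
        if row["fragment_id"] not in known_fragments:
            raise CrossReferenceError(
                f"{counts_path} row {idx}: fragment_id {row['fragment_id']!r} "
                f"not present in {cover_path}"
            )
        key = (row["fragment_id"], row["transect_id"])
        survey = surveys.get(key)
        if survey is None:
            # a swept transect without botany still needs a record
            survey = surveys[key] = TransectSurvey(key[0], key[1], {})
        n = row["count"]
        if float(n) != int(n) or int(n) < 0:
            problems.append(
                f"{counts_path} row {idx}: count {n!r} is not a non-negative integer"
            )
            continue
        occasion = int(row["occasion"])
        occ = survey.leafhopper_counts.setdefault(occasion, {})
        taxon = str(row["taxon"]).strip()
        occ[taxon] = occ.get(taxon, 0) + int(n)

    if problems:
        raise ValidationError(problems)

    occasions = {
        occ for s in surveys.values() for occ in s.leafhopper_counts
    }
    for survey in surveys.values():
        missing = occasions - set(survey.leafhopper_counts)
        if missing and survey.leafhopper_counts:
            logger.warning(
                "fragment %s transect %s: no counts for occasion(s) %s; treated as zeros",
                survey.fragment_id, survey.transect_id, sorted(missing),
            )

    return [surveys[k] for k in sorted(surveys)]


def load_diet(diet_path) -> DietDatabase:
    """Read diet.csv (one row per taxon x food taxon) into a DietDatabase."""
    return diet_from_frame(pd.read_csv(diet_path, keep_default_na=False), diet_path)


def diet_from_frame(df: pd.DataFrame, diet_path="diet") -> DietDatabase:
    """Frame-based core of :func:`load_diet`."""
    _require_columns(df, DIET_COLUMNS, diet_path)
    entries: dict[str, DietEntry] = {}
    problems: list[str] = []
    for idx, row in df.iterrows():
        key = normalize_name(row["taxon"])
        entry = entries.get(key)
        if entry is None:
            entry = entries[key] = DietEntry(
                taxon=str(row["taxon"]).strip(),
                monophagous=_as_bool(row["monophagous"], f"row {idx} monophagous"),
                habitat_condition=_as_bool(row["habitat_condition"], f"row {idx}"),
                diet_condition=_as_bool(row["diet_condition"], f"row {idx}"),
                identified_to_species=_as_bool(row["identified_to_species"], f"row {idx}"),
            )
        food = str(row["food_taxon"]).strip()
        if food:
            rank = str(row["food_rank"]).strip().casefold()
            if rank not in ("species", "genus"):
                problems.append(f"{diet_path} row {idx}: food_rank {rank!r} not species/genus")
                continue
            entry.food_taxa.append((food, rank))
    if problems:
        raise ValidationError(problems)
    for entry in entries.values():
        if entry.monophagous and len(entry.food_taxa) != 1:
            raise ValidationError(
                f"{diet_path}: {entry.taxon} flagged monophagous but lists "
                f"{len(entry.food_taxa)} food taxa"
            )
    return DietDatabase(list(entries.values()))


def diet_summary(diet_db: DietDatabase) -> dict:
    """Monophagy shares by habitat class over usable (identified, diet-known) taxa."""
    usable = [e for e in diet_db if e.identified_to_species and e.diet_known]
    spec = [e for e in usable if e.specialist]
    gen = [e for e in usable if not e.specialist]
    def pct_mono(entries):
        return 100.0 * sum(e.monophagous for e in entries) / len(entries) if entries else float("nan")
    return {
        "n_specialist_species": len(spec),
        "n_generalist_species": len(gen),
        "pct_monophagous_specialist": pct_mono(spec),
        "pct_monophagous_generalist": pct_mono(gen),
    }


# ---------------------------------------------------------------------------
# pooling and relative cover
# ---------------------------------------------------------------------------

def pool_abundances(surveys: list[TransectSurvey]) -> dict[str, int]:
    """Sum each leafhopper species over all transects and occasions.

    Species whose total is zero are omitted.  All surveys must belong to one
    fragment.
    """
    fragments = {s.fragment_id for s in surveys}
    if len(fragments) > 1:
        raise ValueError(f"pool_abundances received multiple fragments: {sorted(fragments)}")
    totals: dict[str, int] = {}
    for survey in surveys:
        for occ in survey.leafhopper_counts.values():
            for taxon, n in occ.items():
                totals[taxon] = totals.get(taxon, 0) + n
    return {taxon: n for taxon, n in totals.items() if n > 0}


def relative_cover(survey: TransectSurvey) -> dict[str, float]:
    """Cover of each species divided by total plant + bare ground + litter cover."""
    denominator = sum(survey.plant_cover.values()) + survey.bare_ground + survey.litter
    if denominator <= 0:
        raise DegenerateTransectError(
            f"fragment {survey.fragment_id} transect {survey.transect_id}: "
            "zero total cover"
        )
    return {taxon: cover / denominator for taxon, cover in survey.plant_cover.items()}


def fragment_community(
    surveys: list[TransectSurvey], diet_db: DietDatabase | None = None
) -> FragmentCommunity:
    """Summarise one fragment: mean relative covers, richness, pooled counts.

    Relative cover is computed per transect and then averaged over the
    fragment's transects (mean of ratios); transects with zero total cover
    are degenerate and rejected only if no transect remains.
    """
    fragments = {s.fragment_id for s in surveys}
    if len(fragments) != 1:
        raise ValueError(f"fragment_community needs exactly one fragment, got {sorted(fragments)}")
    (fragment_id,) = fragments

    per_transect: list[dict[str, float]] = []
    for survey in surveys:
        try:
            per_transect.append(relative_cover(survey))
        except DegenerateTransectError:
            logger.warning(
                "fragment %s transect %s degenerate (zero cover); skipped",
                survey.fragment_id, survey.transect_id,
            )
    if not per_transect:
        raise DegenerateTransectError(f"fragment {fragment_id}: every transect has zero cover")

    taxa = sorted({t for rc in per_transect for t in rc})
    n = len(per_transect)
    mean_cover = {taxon: sum(rc.get(taxon, 0.0) for rc in per_transect) / n for taxon in taxa}
    richness = sum(
        1
        for taxon in taxa
        if any(s.plant_cover.get(taxon, 0.0) > 0 for s in surveys)
    )
    return FragmentCommunity(
        fragment_id=fragment_id,
        mean_relative_cover=mean_cover,
        plant_richness=richness,
        pooled_abundance=pool_abundances(surveys),
    )


def fragment_communities(
    surveys: list[TransectSurvey], diet_db: DietDatabase | None = None
) -> dict[str, FragmentCommunity]:
    """Group surveys by fragment and summarise each one."""
    by_fragment: dict[str, list[TransectSurvey]] = {}
    for survey in surveys:
        by_fragment.setdefault(survey.fragment_id, []).append(survey)
    return {
        fid: fragment_community(group, diet_db)
        for fid, group in sorted(by_fragment.items())
    }
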