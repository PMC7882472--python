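"""Synthetic study generator with known ground-truth effect structure.

Emulates a fragmented calcareous-grassland study: 28 focal fragments (14
small, 0.06-0.60 ha; 14 large, 1.24-8.76 ha) along two orthogonal gradients
(incidence-function connectivity spanning roughly 20-849 within 2 km, and
27-77% arable land within the matrix), a regional pool of 167 plant taxa
surveyed on six 1 x 5 m transects per fragment, and 76 leafhopper taxa swept
on three occasions, of which 67 are usable (29 habitat specialists, 38
generalists) and 9 exercise the three web-assembly exclusion rules.

The ground truth is a coefficient vector theta on the logit of the expected
specialist share of the community, expressed on the standardized covariate
scale used by the inference module (L = arable in [0,1], S = size class 0/1,
C = log10 connectivity in [0,1]).  Specialist and generalist occupancy
probabilities are tilted so the expected specialist richness share equals
logistic(theta . x), which is exactly the quantity the binomial
richness-ratio model estimates.  Everything is deterministic given
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import BARE_GROUND, LITTER, genus_of, normalize_name
from .inference import standardize01
from .landscape import ConnectivityParams, Patch, connectivity_all

# -- name pools -------------------------------------------------------------

PLANT_GENERA = [
    "Bromus", "Festuca", "Carex", "Brachypodium", "Koeleria", "Briza", "Poa",
    "Helictotrichon", "Salvia", "Thymus", "Sanguisorba", "Plantago", "Lotus",
    "Medicago", "Trifolium", "Hippocrepis", "Onobrychis", "Anthyllis",
    "Scabiosa", "Knautia", "Centaurea", "Cirsium", "Leontodon", "Hieracium",
    "Pimpinella", "Daucus", "Galium", "Asperula", "Euphorbia", "Linum",
    "Polygala", "Gentiana", "Teucrium", "Prunella", "Origanum", "Veronica",
    "Campanula", "Ranunculus", "Potentilla", "Viola", "Ononis", "Stachys",
]

EPITHETS = [
    "erecta", "ovina", "flacca", "caryophyllea", "pinnata", "macra", "media",
    "pratensis", "montana", "verna", "minor", "vulgaris", "officinalis",
    "perennis", "arvensis", "campestris", "glabra", "hirta", "mollis",
    "rupestris", "saxatilis", "alpina", "angustifolia", "latifolia", "pumila",
    "elatior", "nutans", "comosa", "cristata", "tenuifolia",
]

HOPPER_GENERA = [
    "Adarrus", "Turrutus", "Arthaldeus", "Psammotettix", "Euscelis",
    "Mocydia", "Eupteryx", "Zyginidia", "Doratura", "Anoscopus", "Aphrodes",
    "Deltocephalus", "Errastunus", "Jassargus", "Graphocraerus",
    "Rhopalopyx", "Elymana", "Cicadula", "Macrosteles", "Neophilaenus",
    "Philaenus", "Evacanthus", "Megophthalmus", "Agallia", "Batracomorphus",
    "Eupelix", "Dikraneura", "Emelyanoviana", "Forcipata", "Kybos",
    "Empoasca", "Eurhadina", "Fagocyba", "Zygina", "Arboridia", "Ribautodelphax",
]

HOPPER_EPITHETS = [
    "multinotatus", "socialis", "pascuellus", "confinis", "helvolus",
    "crocea", "notata", "pullula", "stylata", "serratulae", "albifrons",
    "striatus", "ocellaris", "flavovirens", "sexnotatus", "abdominalis",
    "variegatus", "lineatus", "viridis", "campestris", "exiguus",
    "brevipennis", "obscurus", "pallens", "distinguendus", "fasciatus",
]


def _binomial_names(genera, epithets, n):
    names = []
    i = 0
    while len(names) < n:
        name = f"{genera[i % len(genera)]} {epithets[i // len(genera) % len(epithets)]}"
        if name not in names:
            names.append(name)
        i += 1
    return names


# -- configuration ----------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study-design constants and ground-truth effect structure.

    Defaults reproduce the design of the emulated study; ``theta`` holds the
    logit-scale coefficients of the specialist-share model on standardized
    covariates (keys: intercept, L, S, C, and the two-way interactions).
    """

    n_small: int = 14
    n_large: int = 14
    small_area: tuple = (0.06, 0.60)  # ha
    large_area: tuple = (1.24, 8.76)  # ha
    arable_range: tuple = (27.0, 77.0)  # percent within 500 m
    connectivity_range: tuple = (20.0, 849.0)  # target span of the index
    n_plant_taxa: int = 167
    n_consumer_taxa: int = 67
    n_specialists: int = 29
    n_unidentified: int = 1   # excluded by rule 1
    n_diet_unknown: int = 4   # excluded by rule 2
    n_restricted: int = 4     # prone to rule 3 (food plants rarely recorded)
    monophagy_specialist: float = 0.66
    monophagy_generalist: float = 0.24
    genus_rank_share: float = 0.15
    mean_consumer_richness: float = 24.0
    mu_specialist: float = 15.0   # specimens per present species per fragment
    mu_generalist: float = 6.0
    mu_excluded: float = 9.0
    excluded_occupancy: float = 0.16
    nb_dispersion: float = 1.5    # negative-binomial size parameter
    theta: dict = field(
        default_factory=lambda: {
            "intercept": float(np.log(29 / 38)),
            "L": 0.026,
            "S": -1.017,
            "C": 0.100,
            "L:C": -0.050,
            "S:C": 1.134,
            "L:S": 0.003,
        }
    )
    max_design_attempts: int = 200
    design_rho_limit: float = 0.3

    @property
    def n_fragments(self) -> int:
        return self.n_small + self.n_large

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: kernel parameters used for synthetic landscapes (areas in m^2 inside the
#: kernel so the default alpha/beta give indices on the published 20-849 scale)
LANDSCAPE_PARAMS = ConnectivityParams(alpha=0.001, beta=0.5, radius=2000.0, area_scale=1e4)


@dataclass
class SyntheticStudy:
    """All tables of one synthetic study plus the generating truth."""

    design: pd.DataFrame
    patches: pd.DataFrame
    covers: pd.DataFrame
    counts: pd.DataFrame
    diet: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("design", self.design), ("patches", self.patches),
            ("covers", self.covers), ("counts", self.counts), ("diet", self.diet),
        ]:
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = str(path)
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=2, default=float))
        paths["truth"] = str(truth_path)
        return paths


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def specialist_share(theta: dict, L, S, C) -> np.ndarray:
    """Expected specialist richness share on the logit-linear truth model."""
    eta = (
        theta["intercept"]
        + theta.get("L", 0.0) * L
        + theta.get("S", 0.0) * S
        + theta.get("C", 0.0) * C
        + theta.get("L:C", 0.0) * L * C
        + theta.get("S:C", 0.0) * S * C
        + theta.get("L:S", 0.0) * L * S
    )
    return _logistic(np.asarray(eta, dtype=float))


# -- landscape --------------------------------------------------------------

def generate_landscape(config: SyntheticConfig, seed) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fragment design table and habitat-patch table.

    Each focal fragment sits on its own 6-km grid cell (so 2-km neighbour-
    hoods never overlap) surrounded by a private cluster of non-focal
    grassland patches whose areas are scaled so the computed incidence-
    function connectivity is stratified log-uniformly across the target
    span.  The three design variables are rejection-sampled until every
    pairwise |Spearman rho| is below ``design_rho_limit``.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    n = config.n_fragments
    lo, hi = config.connectivity_range

    for _attempt in range(config.max_design_attempts):
        size_class = np.array(["small"] * config.n_small + ["large"] * config.n_large)
        rng.shuffle(size_class)
        areas = np.where(
            size_class == "small",
            rng.uniform(*config.small_area, size=n),
            rng.uniform(*config.large_area, size=n),
        )
        arable = rng.uniform(*config.arable_range, size=n)
        # stratified log-uniform connectivity targets, shuffled across fragments
        q = (np.arange(n) + rng.uniform(0, 1, size=n)) / n
        targets = lo * (hi / lo) ** q
        rng.shuffle(targets)

        patches: list[Patch] = []
        grid = int(np.ceil(np.sqrt(n)))
        for i in range(n):
            fid = f"F{i + 1:02d}"
            cx = (i % grid) * 6000.0
            cy = (i // grid) * 6000.0
            patches.append(Patch(fid, cx, cy, float(areas[i]), focal=True))
            k = 2 + int(rng.poisson(3))
            d = rng.uniform(250.0, 1800.0, size=k)
            angle = rng.uniform(0, 2 * np.pi, size=k)
            a = rng.lognormal(mean=0.0, sigma=0.8, size=k)
            kernel = np.exp(-LANDSCAPE_PARAMS.alpha * d)
            raw = float((kernel * np.sqrt(LANDSCAPE_PARAMS.area_scale * a)).sum())
            a = np.clip(a * (targets[i] / raw) ** 2, 0.005, 80.0)
            for j in range(k):
                patches.append(
                    Patch(
                        f"{fid}_n{j + 1}",
                        cx + d[j] * np.cos(angle[j]),
                        cy + d[j] * np.sin(angle[j]),
                        float(a[j]),
                        focal=False,
                    )
                )
        conn = connectivity_all(patches, LANDSCAPE_PARAMS)
        s = np.array([conn[f"F{i + 1:02d}"] for i in range(n)])
        size01 = (size_class == "large").astype(float)
        rhos = [
            abs(sps.spearmanr(size01, np.log10(s)).statistic),
            abs(sps.spearmanr(size01, arable).statistic),
            abs(sps.spearmanr(np.log10(s), arable).statistic),
        ]
        if max(rhos) < config.design_rho_limit:
            design = pd.DataFrame(
                {
                    "fragment_id": [f"F{i + 1:02d}" for i in range(n)],
                    "size_class": size_class,
                    "area_ha": areas,
                    "arable_pct": arable,
                    "connectivity": s,
                }
            )
            patch_df = pd.DataFrame(
                [
                    {"id": p.id, "x_m": p.x_m, "y_m": p.y_m, "area_ha": p.area_ha, "focal": p.focal}
                    for p in patches
                ]
            )
            return design, patch_df
    raise RuntimeError(
        "could not satisfy the design-independence screen; loosen "
        "design_rho_limit or widen the gradients"
    )


# -- species pools ----------------------------------------------------------

@dataclass
class _Pools:
    plants: pd.DataFrame       # taxon, genus, prevalence, mean_cover, calcareous
    consumers: pd.DataFrame    # taxon, group, specialist, mu, diet flags
    diet: pd.DataFrame         # diet.csv rows
    matched_plants: dict       # consumer -> frozenset of plant taxa its diet matches


def _generate_pools(config: SyntheticConfig, rng: np.random.Generator) -> _Pools:
    plant_names = _binomial_names(PLANT_GENERA, EPITHETS, config.n_plant_taxa)
    prevalence = rng.beta(0.9, 2.4, size=config.n_plant_taxa)
    prevalence = np.clip(prevalence, 0.02, 0.95)
    mean_cover = np.clip(rng.lognormal(mean=0.6, sigma=1.0, size=config.n_plant_taxa), 0.1, 45.0)
    calcareous = rng.random(config.n_plant_taxa) < 0.35
    plants = pd.DataFrame(
        {
            "taxon": plant_names,
            "genus": [genus_of(p).capitalize() for p in plant_names],
            "prevalence": prevalence,
            "mean_cover": mean_cover,
            "calcareous": calcareous,
        }
    )

    n_gen = config.n_consumer_taxa - config.n_specialists
    n_total = config.n_consumer_taxa + config.n_unidentified + config.n_diet_unknown + config.n_restricted
    names = _binomial_names(HOPPER_GENERA, HOPPER_EPITHETS, n_total)
    groups = (
        ["specialist"] * config.n_specialists
        + ["generalist"] * n_gen
        + ["unidentified"] * config.n_unidentified
        + ["diet_unknown"] * config.n_diet_unknown
        + ["restricted"] * config.n_restricted
    )
    # unidentified taxa are known only to genus
    for i, g in enumerate(groups):
        if g == "unidentified":
            names[i] = names[i].split(" ")[0] + " sp."

    prevalence_vec = plants["prevalence"].to_numpy()
    calc_idx = np.flatnonzero(plants["calcareous"].to_numpy())
    all_idx = np.arange(len(plants))
    weights_all = prevalence_vec / prevalence_vec.sum()
    weights_calc = prevalence_vec[calc_idx] / prevalence_vec[calc_idx].sum()
    rare_idx = np.argsort(prevalence_vec)[:12]  # rarely-recorded hosts

    diet_rows = []
    consumer_rows = []
    matched: dict[str, frozenset] = {}
    genus_members: dict[str, list[str]] = {}
    for _, row in plants.iterrows():
        genus_members.setdefault(row["genus"], []).append(row["taxon"])

    for name, group in zip(names, groups):
        specialist = group == "specialist"
        identified = group != "unidentified"
        # diets are drawn prevalence-weighted within the class pool: widespread
        # plants host more herbivores, and monophages persist on common hosts
        if group == "specialist":
            mono = rng.random() < config.monophagy_specialist
            pool_idx, pool_w = calc_idx, weights_calc
        elif group == "generalist":
            mono = rng.random() < config.monophagy_generalist
            pool_idx, pool_w = all_idx, weights_all
        elif group == "restricted":
            mono = rng.random() < 0.5
            pool_idx, pool_w = rare_idx, None
        else:  # unidentified / diet_unknown: diets usable only if identified
            mono = False
            pool_idx = all_idx if group == "unidentified" else None
            pool_w = weights_all if group == "unidentified" else None

        food: list[tuple[str, str]] = []
        if pool_idx is not None:
            k = 1 if mono else int(rng.integers(2, 4 if specialist else 5))
            k = min(k, len(pool_idx))
            chosen = rng.choice(pool_idx, size=k, replace=False, p=pool_w)
            for idx in np.atleast_1d(chosen):
                plant = plants.iloc[int(idx)]
                if (not mono) and rng.random() < config.genus_rank_share:
                    food.append((plant["genus"], "genus"))
                else:
                    food.append((plant["taxon"], "species"))
            # de-duplicate while preserving order
            seen = set()
            food = [f for f in food if not (f in seen or seen.add(f))]
            mono = mono and len(food) == 1

        habitat_cond = specialist and rng.random() < 0.7
        diet_cond = specialist and not habitat_cond
        if specialist and rng.random() < 0.3:
            diet_cond = True  # both conditions may hold

        expanded = set()
        for taxon, rank in food:
            if rank == "species":
                expanded.add(taxon)
            else:
                expanded.update(genus_members.get(taxon, []))
        matched[name] = frozenset(expanded)

        mu = {
            "specialist": config.mu_specialist,
            "generalist": config.mu_generalist,
        }.get(group, config.mu_excluded)
        consumer_rows.append(
            {"taxon": name, "group": group, "specialist": specialist, "mu": mu}
        )
        if food:
            for taxon, rank in food:
                diet_rows.append(
                    {
                        "taxon": name, "food_taxon": taxon, "food_rank": rank,
                        "monophagous": mono, "habitat_condition": habitat_cond,
                        "diet_condition": diet_cond, "identified_to_species": identified,
                    }
                )
        else:
            diet_rows.append(
                {
                    "taxon": name, "food_taxon": "", "food_rank": "",
                    "monophagous": False, "habitat_condition": habitat_cond,
                    "diet_condition": diet_cond, "identified_to_species": identified,
                }
            )

    return _Pools(
        plants=plants,
        consumers=pd.DataFrame(consumer_rows),
        diet=pd.DataFrame(diet_rows),
        matched_plants=matched,
    )


def generate_diet(config: SyntheticConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Just the diet table of a synthetic study (cheap; used for calibration checks)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]).spawn(2)[0])
    return _generate_pools(config, rng).diet


# -- communities ------------------------------------------------------------

def _nb_draw(rng, mu, size_param):
    """Negative-binomial with mean mu and dispersion (size) k; at least 1."""
    p = size_param / (size_param + mu)
    return max(1, int(rng.negative_binomial(size_param, p)))


def generate_community(
    design_row, pools: _Pools, config: SyntheticConfig,
    rng: np.random.Generator, covariates: dict,
) -> tuple[list[dict], list[dict]]:
    """Transect cover rows and count rows for one fragment.

    ``covariates`` holds the fragment's standardized L, S, C used by the
    specialist-share truth model.
    """
    fid = design_row["fragment_id"]
    plants = pools.plants
    present_mask = rng.random(len(plants)) < plants["prevalence"].to_numpy()
    if not present_mask.any():
        present_mask[rng.integers(len(plants))] = True
    present_plants = set(plants["taxon"].to_numpy()[present_mask])

    cover_rows: list[dict] = []
    for t in range(1, 7):
        for idx in np.flatnonzero(present_mask):
            if rng.random() < 0.7:
                base = plants["mean_cover"].iloc[idx]
                cover = float(np.clip(base * rng.lognormal(0.0, 0.6), 0.1, 60.0))
                cover_rows.append(
                    {
                        "fragment_id": fid, "transect_id": str(t),
                        "taxon": plants["taxon"].iloc[idx],
                        "cover_pct": round(cover, 2),
                    }
                )
        cover_rows.append(
            {"fragment_id": fid, "transect_id": str(t), "taxon": BARE_GROUND,
             "cover_pct": round(float(rng.uniform(2, 15)), 2)}
        )
        cover_rows.append(
            {"fragment_id": fid, "transect_id": str(t), "taxon": LITTER,
             "cover_pct": round(float(rng.uniform(2, 20)), 2)}
        )
    # guarantee every present plant is recorded on at least one transect
    recorded = {r["taxon"] for r in cover_rows}
    for plant in sorted(present_plants - recorded):
        base = float(plants.loc[plants["taxon"] == plant, "mean_cover"].iloc[0])
        cover_rows.append(
            {"fragment_id": fid, "transect_id": str(int(rng.integers(1, 7))),
             "taxon": plant, "cover_pct": round(min(base, 60.0), 2)}
        )

    p_share = float(
        specialist_share(config.theta, covariates["L"], covariates["S"], covariates["C"])
    )
    # occupancy is tilted so the expected share of specialist species among the
    # fragment's available consumers equals the truth model's p, and the mean
    # realized consumer richness matches the configured target; normalising by
    # the number of consumers whose food plants grow here keeps both on target
    # despite the availability filter
    has_food = {
        row["taxon"]: bool(pools.matched_plants[row["taxon"]] & present_plants)
        for _, row in pools.consumers.iterrows()
    }
    groups = pools.consumers.set_index("taxon")["group"]
    n_spec_avail = sum(1 for t, ok in has_food.items() if ok and groups[t] == "specialist")
    n_gen_avail = sum(1 for t, ok in has_food.items() if ok and groups[t] == "generalist")
    m = config.mean_consumer_richness
    q_spec = float(np.clip(m * p_share / max(n_spec_avail, 1), 0.02, 0.95))
    q_gen = float(np.clip(m * (1 - p_share) / max(n_gen_avail, 1), 0.02, 0.95))

    count_rows: list[dict] = []
    for _, consumer in pools.consumers.iterrows():
        group = consumer["group"]
        if group in ("specialist", "generalist"):
            q = q_spec if group == "specialist" else q_gen
            present = has_food[consumer["taxon"]] and rng.random() < q
        else:
            present = rng.random() < config.excluded_occupancy
        if not present:
            continue
        total = _nb_draw(rng, consumer["mu"], config.nb_dispersion)
        # clumped split over 6 transects x 3 occasions
        w = rng.dirichlet(np.full(18, 0.5))
        cells = rng.multinomial(total, w)
        for cell, nn in enumerate(cells):
            if nn > 0:
                count_rows.append(
                    {
                        "fragment_id": fid, "transect_id": str(cell % 6 + 1),
                        "occasion": cell // 6 + 1,
                        "taxon": consumer["taxon"], "count": int(nn),
                    }
                )
    return cover_rows, count_rows


def generate_study(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Full synthetic study: landscape, communities, diet table, truth record."""
    config = config or SyntheticConfig()
    design, patches = generate_landscape(config, seed)
    root = np.random.SeedSequence([int(seed), 202])
    pool_rng, community_rng = (np.random.default_rng(s) for s in root.spawn(2))
    pools = _generate_pools(config, pool_rng)

    L = standardize01(design["arable_pct"])
    S = (design["size_class"] == "large").to_numpy(dtype=float)
    C = standardize01(np.log10(design["connectivity"].to_numpy(dtype=float)))

    cover_rows: list[dict] = []
    count_rows: list[dict] = []
    for i, (_, row) in enumerate(design.iterrows()):
        cov = {"L": float(L[i]), "S": float(S[i]), "C": float(C[i])}
        c_rows, n_rows = generate_community(row, pools, config, community_rng, cov)
        cover_rows.extend(c_rows)
        count_rows.extend(n_rows)

    truth = {
        "seed": int(seed),
        "config": config.to_dict(),
        "theta": config.theta,
        "connectivity_params": dataclasses.asdict(LANDSCAPE_PARAMS),
        "expected_specialist_share": [
            float(v) for v in specialist_share(config.theta, L, S, C)
        ],
    }
    return SyntheticStudy(
        design=design,
        patches=patches,
        covers=pd.DataFrame(cover_rows),
        counts=pd.DataFrame(count_rows),
        diet=pools.diet,
        truth=truth,
    )


# -- lightweight generator for the parameter-recovery study -----------------

def simulate_richness_ratio(
    theta: dict,
    n_fragments: int,
    rng: np.random.Generator,
    n_specialist_pool: int = 29,
    n_generalist_pool: int = 38,
    mean_richness: float = 24.0,
) -> pd.DataFrame:
    """Design + specialist/generalist richness counts from the truth model.

    Uses the same occupancy tilt as the community generator but skips plants
    and webs, so large replicate studies stay cheap.  Returns the covariate
    frame the inference module consumes (L, S, C standardized, R an
    independent control covariate) with ``n_specialists``/``n_generalists``.
    """
    S = rng.integers(0, 2, size=n_fragments).astype(float)
    C = standardize01(np.log10(np.exp(rng.uniform(np.log(20.0), np.log(849.0), size=n_fragments))))
    L = standardize01(rng.uniform(27.0, 77.0, size=n_fragments))
    R = rng.uniform(0.0, 1.0, size=n_fragments)
    p = specialist_share(theta, L, S, C)
    q_spec = np.clip(mean_richness * p / n_specialist_pool, 0.02, 0.95)
    q_gen = np.clip(mean_richness * (1 - p) / n_generalist_pool, 0.02, 0.95)
    s = rng.binomial(n_specialist_pool, q_spec)
    g = rng.binomial(n_generalist_pool, q_gen)
    # a fragment with no usable consumers carries no information; re-seat one
    empty = (s + g) == 0
    s[empty] = 1
    return pd.DataFrame(
        {
            "fragment_id": [f"R{i + 1:03d}" for i in range(n_fragments)],
            "L": L, "S": S, "C": C, "R": R,
            "n_specialists": s, "n_generalists": g,
        }
    )


# -- deterministic toy fixture ----------------------------------------------

def tiny_fixture() -> SyntheticStudy:
    """Hand-written 3-fragment, 6-transect study used by the unit tests.

    Synthetic throughout.  Contains one consumer per exclusion rule
    (unidentified, diet unknown, food plant never recorded), a monophage, a
    polyphage with species-rank diet and a genus-rank Carex feeder, so every
    assembler branch is exercised deterministically.
    """
    plants = ["Bromus erecta", "Carex flacca", "Carex caryophyllea",
              "Salvia pratensis", "Plantago media"]
    cover_rows = []
    base = {"Bromus erecta": 30.0, "Carex flacca": 12.0, "Carex caryophyllea": 6.0,
            "Salvia pratensis": 9.0, "Plantago media": 4.0}
    for f, fid in enumerate(["F1", "F2", "F3"]):
        for t in range(1, 7):
            for p_i, plant in enumerate(plants):
                # F3 lacks Salvia; deterministic variation across transects
                if fid == "F3" and plant == "Salvia pratensis":
                    continue
                cover_rows.append(
                    {"fragment_id": fid, "transect_id": str(t), "taxon": plant,
                     "cover_pct": round(base[plant] + ((t + p_i + f) % 3) - 1, 2)}
                )
            cover_rows.append({"fragment_id": fid, "transect_id": str(t),
                               "taxon": BARE_GROUND, "cover_pct": 8.0})
            cover_rows.append({"fragment_id": fid, "transect_id": str(t),
                               "taxon": LITTER, "cover_pct": 10.0})

    diet_rows = [
        # monophagous specialist on Bromus
        {"taxon": "Adarrus multinotatus", "food_taxon": "Bromus erecta",
         "food_rank": "species", "monophagous": True, "habitat_condition": True,
         "diet_condition": False, "identified_to_species": True},
        # polyphagous generalist, species-rank diet
        {"taxon": "Turrutus socialis", "food_taxon": "Bromus erecta",
         "food_rank": "species", "monophagous": False, "habitat_condition": False,
         "diet_condition": False, "identified_to_species": True},
        {"taxon": "Turrutus socialis", "food_taxon": "Salvia pratensis",
         "food_rank": "species", "monophagous": False, "habitat_condition": False,
         "diet_condition": False, "identified_to_species": True},
        # genus-rank Carex feeder, specialist by diet condition
        {"taxon": "Eupteryx notata", "food_taxon": "Carex",
         "food_rank": "genus", "monophagous": False, "habitat_condition": False,
         "diet_condition": True, "identified_to_species": True},
        # rule 1: never identified to species
        {"taxon": "Doratura sp.", "food_taxon": "Plantago media",
         "food_rank": "species", "monophagous": True, "habitat_condition": False,
         "diet_condition": False, "identified_to_species": False},
        # rule 2: diet unknown
        {"taxon": "Mocydia crocea", "food_taxon": "", "food_rank": "",
         "monophagous": False, "habitat_condition": False,
         "diet_condition": False, "identified_to_species": True},
        # rule 3: host never recorded on any transect
        {"taxon": "Zyginidia pullula", "food_taxon": "Festuca ovina",
         "food_rank": "species", "monophagous": True, "habitat_condition": True,
         "diet_condition": False, "identified_to_species": True},
    ]

    count_rows = []
    abundances = {
        "F1": {"Adarrus multinotatus": 12, "Turrutus socialis": 10,
               "Eupteryx notata": 6, "Doratura sp.": 3, "Mocydia crocea": 2,
               "Zyginidia pullula": 4},
        "F2": {"Adarrus multinotatus": 8, "Turrutus socialis": 5,
               "Eupteryx notata": 9},
        "F3": {"Adarrus multinotatus": 7, "Turrutus socialis": 6,
               "Eupteryx notata": 3},
    }
    for fid, taxa in abundances.items():
        for taxon, total in taxa.items():
            # spread deterministically over occasions 1..3 and transects 1..6
            for i in range(total):
                occ = i % 3 + 1
                transect = str(i % 6 + 1)
                count_rows.append(
                    {"fragment_id": fid, "transect_id": transect,
                     "occasion": occ, "taxon": taxon, "count": 1}
                )

    design = pd.DataFrame(
        {
            "fragment_id": ["F1", "F2", "F3"],
            "size_class": ["small", "large", "small"],
            "area_ha": [0.3, 4.2, 0.5],
            "arable_pct": [35.0, 60.0, 50.0],
            "connectivity": [50.0, 600.0, 180.0],
        }
    )
    return SyntheticStudy(
        design=design,
        patches=pd.DataFrame(columns=["id", "x_m", "y_m", "area_ha", "focal"]),
        covers=pd.DataFrame(cover_rows),
        counts=pd.DataFrame(count_rows),
        diet=pd.DataFrame(diet_rows),
        truth={"fixture": "tiny", "synthetic": True},
    )
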