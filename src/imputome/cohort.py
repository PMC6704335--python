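"""Seeded synthetic cohorts with known planted structure.

The generator emulates a two-gender, three-group gut-microbiome study
design: 63 female samples (29 Vata, 11 Pitta, 23 Kapha) and 50 male
samples (13 Vata, 18 Pitta, 19 Kapha), Firmicutes/Bacteroidetes-dominated
compositions, a taxon x gene-family copy matrix, a three-level pathway
hierarchy above the gene families, 16S copy numbers, organism-level trait
annotations, and sample metadata.

Counts follow a Dirichlet-multinomial: each sample's OTU proportions are
drawn from a Dirichlet whose mean encodes phylum-level structure and whose
concentration (``dispersion``) controls overdispersion, then reads are
drawn multinomially at the sample's sequencing depth.

Planted group effects are realized through dedicated low-abundance
"driver" OTUs that exclusively carry the effect's gene families; the
drivers' expected abundance is multiplied by the fold-change in the target
(group, gender) stratum, so the named functions are enriched there by
construction while the rest of the composition is barely perturbed.
Optional trait effects multiply the expected abundance of trait-bearing
OTUs in a stratum.  The realized function-level fold changes are echoed in
``SyntheticBundle.truth``.

Everything is drawn from a single generator stream, so a given
(config, seed) pair reproduces the bundle exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GENDERS, GROUPS, RANKS, TRAIT_VOCABULARY, UNCLASSIFIED

L1_CATEGORIES = (
    "Cellular Processes",
    "Environmental Information Processing",
    "Genetic Information Processing",
    "Metabolism",
    "Unclassified",
)

DEFAULT_GROUP_SIZES = {
    "F": {"Vata": 29, "Pitta": 11, "Kapha": 23},
    "M": {"Vata": 13, "Pitta": 18, "Kapha": 19},
}

DEFAULT_PHYLUM_MIX = {
    "Firmicutes": 0.55,
    "Bacteroidetes": 0.32,
    "Proteobacteria": 0.06,
    "Actinobacteria": 0.04,
    "Fusobacteria": 0.02,
    "Tenericutes": 0.01,
}

# per-phylum probabilities for (aerobic, anaerobic, facultative, unannotated)
_OXYGEN_PROBS = {
    "Firmicutes": (0.03, 0.85, 0.10, 0.02),
    "Bacteroidetes": (0.02, 0.90, 0.05, 0.03),
    "Proteobacteria": (0.30, 0.20, 0.45, 0.05),
    "Actinobacteria": (0.25, 0.45, 0.25, 0.05),
    "Fusobacteria": (0.02, 0.90, 0.05, 0.03),
    "Tenericutes": (0.05, 0.60, 0.25, 0.10),
}
# per-phylum probabilities for (gram_positive, gram_negative, unannotated)
_GRAM_PROBS = {
    "Firmicutes": (0.90, 0.05, 0.05),
    "Bacteroidetes": (0.02, 0.95, 0.03),
    "Proteobacteria": (0.02, 0.95, 0.03),
    "Actinobacteria": (0.90, 0.05, 0.05),
    "Fusobacteria": (0.02, 0.95, 0.03),
    "Tenericutes": (0.10, 0.10, 0.80),
}
# independent binary traits: per-phylum bernoulli probabilities
_BINARY_TRAIT_PROBS = {
    "potential_pathogen": {"Proteobacteria": 0.35, "Fusobacteria": 0.40,
                           "default": 0.08},
    "mobile_elements": {"default": 0.30},
    "biofilm_forming": {"Proteobacteria": 0.40, "default": 0.25},
    "stress_tolerant": {"Firmicutes": 0.35, "default": 0.25},
}


@dataclass(frozen=True)
class PlantedEffect:
    """A (group, gender)-specific fold-change on a set of gene families."""

    group: str
    gender: str
    functions: tuple[str, ...]
    fold: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS or self.gender not in GENDERS:
            raise ValueError(f"unknown stratum ({self.group}, {self.gender})")
        if self.fold <= 0:
            raise ValueError("fold-change must be > 0")


@dataclass(frozen=True)
class TraitEffect:
    """A (group, gender)-specific abundance boost of trait-bearing OTUs."""

    group: str
    gender: str
    trait: str
    fold: float

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_VOCABULARY:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.fold <= 0:
            raise ValueError("fold-change must be > 0")


def _default_planted() -> tuple[PlantedEffect, ...]:
    # three fold-8 effects per (group, gender) stratum, each a 5-function
    # block feeding one dedicated level-3 pathway.  Nine planted pathways
    # per gender out of 40 (~22%) matches the signature density the
    # emulated study reports at level 3.  Equal planted mass per stratum
    # keeps the compositional renormalization balanced across groups, so
    # non-planted functions stay exchangeable (null).
    effects = []
    i = 0
    for gender in ("F", "M"):
        for group in GROUPS:
            for _ in range(3):
                funcs = tuple(f"F{j:04d}" for j in range(i * 5 + 1, i * 5 + 6))
                effects.append(PlantedEffect(group, gender, funcs, 8.0))
                i += 1
    return tuple(effects)


def pathogenic_trait_effects(fold: float = 2.0) -> tuple[TraitEffect, ...]:
    """Trait effects emulating the reported pathogen/stress enrichment
    (Kapha in females, Pitta in males).  Opt-in: trait boosts shift the
    whole composition of the target stratum, so they deliberately break
    the null for non-planted functions."""
    return (
        TraitEffect("Kapha", "F", "potential_pathogen", fold),
        TraitEffect("Kapha", "F", "stress_tolerant", fold),
        TraitEffect("Pitta", "M", "potential_pathogen", fold),
        TraitEffect("Pitta", "M", "stress_tolerant", fold),
    )


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 113 samples in the stated
    gender x group strata, a Firmicutes/Bacteroidetes-dominated phylum mix,
    200 gene families under 40 level-3 and 12 level-2 pathways, fold-8
    planted functional effects, and fold-2 trait effects.  Depth and
    dispersion are chosen for test power (the emulated study reports
    neither).
    """

    group_sizes: dict = field(
        default_factory=lambda: {g: dict(v)
                                 for g, v in DEFAULT_GROUP_SIZES.items()})
    n_otus: int = 150
    phylum_mix: dict = field(default_factory=lambda: dict(DEFAULT_PHYLUM_MIX))
    n_functions: int = 200
    n_pathways_l3: int = 40
    n_pathways_l2: int = 12
    planted_effects: tuple = field(default_factory=_default_planted)
    trait_effects: tuple = ()
    sequencing_depth: int = 50_000
    dispersion: float = 200.0
    n_driver_otus: int = 3
    driver_base_share: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_otus", "n_functions", "n_pathways_l3",
                     "n_pathways_l2", "sequencing_depth", "n_driver_otus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if abs(sum(self.phylum_mix.values()) - 1.0) > 1e-9:
            raise ValueError("phylum_mix must sum to 1")
        for gender, sizes in self.group_sizes.items():
            if gender not in GENDERS:
                raise ValueError(f"unknown gender {gender!r}")
            for group, n in sizes.items():
                if group not in GROUPS:
                    raise ValueError(f"unknown group {group!r}")
                if n < 2:
                    raise ValueError(
                        f"group {group}/{gender} has {n} samples; "
                        "at least 2 are required")
        self.planted_effects = tuple(
            e if isinstance(e, PlantedEffect) else PlantedEffect(*e)
            for e in self.planted_effects)
        self.trait_effects = tuple(
            e if isinstance(e, TraitEffect) else TraitEffect(*e)
            for e in self.trait_effects)

    @property
    def n_samples(self) -> int:
        return sum(n for sizes in self.group_sizes.values()
                   for n in sizes.values())

    def null(self) -> "CohortConfig":
        """A copy with every planted fold-change set to 1 (pure null)."""
        return replace(
            self,
            planted_effects=tuple(replace(e, fold=1.0)
                                  for e in self.planted_effects),
            trait_effects=tuple(replace(e, fold=1.0)
                                for e in self.trait_effects))


@dataclass
class SyntheticBundle:
    """Everything downstream stages consume, plus the planted ground truth."""

    otu_table: pd.DataFrame        # samples x OTUs integer counts
    taxonomy: pd.DataFrame         # OTU x rank
    copy_numbers: pd.Series        # OTU -> 16S copies (int >= 1)
    gene_content: pd.DataFrame     # OTU x function copies
    hierarchy: pd.DataFrame        # function, level3, level2, level1
    traits: pd.DataFrame           # OTU x trait in {0, 1}
    metadata: pd.DataFrame         # sample -> group, gender
    truth: pd.DataFrame            # planted effects with realized folds
    config: CohortConfig


def _allocate(n: int, weights: dict) -> dict:
    """Split n items over keys proportionally (largest-remainder rule)."""
    keys = list(weights)
    raw = np.array([weights[k] for k in keys], dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return {k: int(b) for k, b in zip(keys, base)}


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> SyntheticBundle:
    """Generate a complete input bundle with known planted structure."""
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    # --- samples & metadata (fixed order: gender, then group, then index)
    meta_rows = []
    for gender in sorted(config.group_sizes):
        i = 0
        for group in GROUPS:
            for _ in range(config.group_sizes[gender].get(group, 0)):
                i += 1
                meta_rows.append(
                    {"sample_id": f"{gender}{i:03d}", "group": group,
                     "gender": gender})
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    # --- OTUs, phylum assignment, taxonomy
    otu_ids = [f"OTU_{i:04d}" for i in range(1, config.n_otus + 1)]
    per_phylum = _allocate(config.n_otus, config.phylum_mix)
    phylum_of = []
    for ph in config.phylum_mix:
        phylum_of += [ph] * per_phylum[ph]
    phylum_of = pd.Series(phylum_of[:config.n_otus], index=otu_ids)
    tax_rows = []
    for otu in otu_ids:
        ph = phylum_of[otu]
        cls = f"{ph}_cls{1 + rng.integers(2)}"
        genus = (f"{ph}_gen{1 + rng.integers(12)}"
                 if rng.random() < 0.7 else UNCLASSIFIED)
        tax_rows.append(("Bacteria", ph, cls, UNCLASSIFIED, UNCLASSIFIED,
                         genus, UNCLASSIFIED))
    taxonomy = pd.DataFrame(tax_rows, index=otu_ids, columns=list(RANKS))

    # --- base expected relative abundances (lognormal within phylum)
    base = np.zeros(config.n_otus)
    for ph, target in config.phylum_mix.items():
        mask = (phylum_of == ph).to_numpy()
        draw = rng.lognormal(mean=0.0, sigma=1.0, size=mask.sum())
        base[mask] = draw / draw.sum() * target

    # --- driver OTUs for planted effects (low-abundance, dedicated)
    function_ids = [f"F{i:04d}" for i in range(1, config.n_functions + 1)]
    reserved = [f for e in config.planted_effects for f in e.functions]
    if len(set(reserved)) != len(reserved):
        raise ValueError("planted effects must use disjoint function sets")
    unknown = set(reserved) - set(function_ids)
    if unknown:
        raise ValueError(f"planted functions outside the catalog: {sorted(unknown)}")
    n_drivers = config.n_driver_otus * len(config.planted_effects)
    if n_drivers >= config.n_otus:
        raise ValueError("too many driver OTUs for n_otus")
    driver_pool = list(rng.choice(config.n_otus, size=n_drivers, replace=False))
    drivers_of: dict[int, list[int]] = {}
    for ei in range(len(config.planted_effects)):
        drivers_of[ei] = [int(driver_pool.pop()) for _ in range(config.n_driver_otus)]
    # drivers are minor community members with a fixed, equal base share
    all_drivers = [o for ds in drivers_of.values() for o in ds]
    if all_drivers:
        base[all_drivers] = config.driver_base_share
        base = base / base.sum()

    # --- 16S copy numbers
    copy_numbers = pd.Series(1 + rng.poisson(2.0, size=config.n_otus),
                             index=otu_ids, name="16S_copies")
    # drivers share one copy number: unequal copies would give each
    # stratum's boosted drivers a different normalized mass, leaking a
    # systematic shift into every non-planted function's relative abundance
    if all_drivers:
        copy_numbers.iloc[all_drivers] = 2

    # --- gene content: sparse Poisson with phylum-specific rate profiles
    gc = np.zeros((config.n_otus, config.n_functions))
    reserved_idx = [function_ids.index(f) for f in reserved]
    open_idx = [j for j in range(config.n_functions) if j not in set(reserved_idx)]
    for ph in config.phylum_mix:
        mask = (phylum_of == ph).to_numpy()
        presence = rng.random((mask.sum(), len(open_idx))) < 0.4
        rates = rng.gamma(shape=1.0, scale=1.0, size=len(open_idx))
        copies = 1 + rng.poisson(np.broadcast_to(rates, presence.shape))
        gc[np.ix_(mask, open_idx)] = np.where(presence, copies, 0)
    # drivers exclusively carry their effect's gene families: their
    # background content is cleared so boosting a driver moves only the
    # planted functions (plus a uniform renormalization of everything else)
    for ei, effect in enumerate(config.planted_effects):
        cols = [function_ids.index(f) for f in effect.functions]
        for o in drivers_of[ei]:
            gc[o, :] = 0
            gc[o, cols] = 10
    # guarantee every open function is carried by at least one non-driver
    non_drivers = np.setdiff1d(np.arange(config.n_otus), all_drivers)
    empty = [j for j in open_idx if gc[:, j].sum() == 0]
    for j in empty:
        gc[int(rng.choice(non_drivers)), j] = 1
    gene_content = pd.DataFrame(gc, index=otu_ids, columns=function_ids)

    # --- hierarchy: reserved blocks get dedicated level-3 pathways
    l3_ids = [f"L3_{i:02d}" for i in range(1, config.n_pathways_l3 + 1)]
    l2_ids = [f"L2_{i:02d}" for i in range(1, config.n_pathways_l2 + 1)]
    n_reserved_l3 = len(config.planted_effects)
    if n_reserved_l3 >= config.n_pathways_l3:
        raise ValueError("n_pathways_l3 too small for the planted effects")
    open_l3 = l3_ids[n_reserved_l3:]
    h_rows = []
    for ei, effect in enumerate(config.planted_effects):
        for f in effect.functions:
            h_rows.append((f, l3_ids[ei]))
    planted_set = set(reserved)
    for f in function_ids:
        if f in planted_set:
            continue
        k = 2 if rng.random() < 0.15 else 1
        for l3 in rng.choice(open_l3, size=k, replace=False):
            h_rows.append((f, str(l3)))
    l3_to_l2 = {l3: l2_ids[i % len(l2_ids)] for i, l3 in enumerate(l3_ids)}
    l2_to_l1 = {l2: L1_CATEGORIES[i % len(L1_CATEGORIES)]
                for i, l2 in enumerate(l2_ids)}
    hierarchy = pd.DataFrame(
        [(f, l3, l3_to_l2[l3], l2_to_l1[l3_to_l2[l3]]) for f, l3 in h_rows],
        columns=["function", "level3", "level2", "level1"])

    # --- traits
    traits = pd.DataFrame(0.0, index=otu_ids, columns=list(TRAIT_VOCABULARY))
    oxygen_cols = ("aerobic", "anaerobic", "facultative_anaerobic")
    gram_cols = ("gram_positive", "gram_negative")
    for i, otu in enumerate(otu_ids):
        ph = phylum_of[otu]
        ox = rng.choice(4, p=_OXYGEN_PROBS.get(ph, (0.1, 0.6, 0.2, 0.1)))
        if ox < 3:
            traits.loc[otu, oxygen_cols[ox]] = 1.0
        gm = rng.choice(3, p=_GRAM_PROBS.get(ph, (0.3, 0.6, 0.1)))
        if gm < 2:
            traits.loc[otu, gram_cols[gm]] = 1.0
        for trait, probs in _BINARY_TRAIT_PROBS.items():
            if rng.random() < probs.get(ph, probs["default"]):
                traits.loc[otu, trait] = 1.0

    # --- per-stratum expected mean vectors (planted + trait effects)
    strata = sorted({(g, s) for s in config.group_sizes
                     for g in config.group_sizes[s]})
    mean_by_stratum: dict[tuple[str, str], np.ndarray] = {}
    for group, gender in strata:
        mean = base.copy()
        for ei, effect in enumerate(config.planted_effects):
            if effect.group == group and effect.gender == gender:
                mean[drivers_of[ei]] *= effect.fold
        for te in config.trait_effects:
            if te.group == group and te.gender == gender:
                bearing = traits[te.trait].to_numpy() > 0
                mean[bearing] *= te.fold
        mean_by_stratum[(group, gender)] = mean / mean.sum()

    # --- Dirichlet-multinomial counts
    counts = np.zeros((len(metadata), config.n_otus), dtype=np.int64)
    for si, (sample, row) in enumerate(metadata.iterrows()):
        mean = mean_by_stratum[(row["group"], row["gender"])]
        p = rng.dirichlet(config.dispersion * mean)
        depth = rng.poisson(config.sequencing_depth)
        counts[si] = rng.multinomial(depth, p)
    otu_table = pd.DataFrame(counts, index=metadata.index, columns=otu_ids)

    # --- realized function-level folds (from expected profiles)
    inv_copies = 1.0 / copy_numbers.to_numpy()
    truth_rows = []
    for ei, effect in enumerate(config.planted_effects):
        cols = [function_ids.index(f) for f in effect.functions]
        target = mean_by_stratum[(effect.group, effect.gender)]
        target_ab = ((target * inv_copies) @ gc[:, cols]).mean()
        others, weights = [], []
        for (group, gender), mean in mean_by_stratum.items():
            if gender != effect.gender or group == effect.group:
                continue
            others.append(((mean * inv_copies) @ gc[:, cols]).mean())
            weights.append(config.group_sizes[gender][group])
        baseline = float(np.average(others, weights=weights)) if others else np.nan
        truth_rows.append({
            "group": effect.group, "gender": effect.gender,
            "functions": ",".join(effect.functions),
            "level3": l3_ids[ei],
            "fold": effect.fold,
            "realized_fold": float(target_ab / baseline) if baseline else np.nan,
        })
    truth = pd.DataFrame(truth_rows, columns=[
        "group", "gender", "functions", "level3", "fold", "realized_fold"])

    return SyntheticBundle(
        otu_table=otu_table, taxonomy=taxonomy, copy_numbers=copy_numbers,
        gene_content=gene_content, hierarchy=hierarchy, traits=traits,
        metadata=metadata, truth=truth, config=config)
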