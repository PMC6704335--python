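"""PICRUSt-style metagenome imputation from 16S OTU tables.

The imputation pathway is: divide each OTU's counts by its 16S rRNA gene
copy number (so counts approximate cell abundance), multiply the normalized
abundances through a taxon x gene-family copy matrix to predict the
community gene-family profile, and collapse gene families up a three-level
pathway hierarchy.  A gene family that maps to several pathways contributes
its full abundance to each of them (no splitting), which matches the
standard categorize-by-function behaviour; pathway-level mass can therefore
exceed gene-level mass.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVELS = ("gene", "L3", "L2", "L1")


@dataclass
class FunctionProfile:
    """Samples x functions predicted copy abundances at a given level."""

    data: pd.DataFrame  # samples x functions, values >= 0
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        vals = self.data.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValueError("profile values must be finite and >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def function_ids(self) -> list[str]:
        return list(self.data.columns)


def normalize_copy_number(table: pd.DataFrame, copies,
                          default_missing: float = 1.0) -> pd.DataFrame:
    """Divide each OTU's counts by its 16S rRNA copy number.

    ``copies`` maps OTU id -> copy number (> 0).  OTUs absent from the map
    default to ``default_missing`` (1, the convention for unannotated tips)
    with a warning, so no sample mass is silently dropped.
    """
    copies = pd.Series(copies, dtype=float)
    if (copies <= 0).any():
        bad = copies.index[copies <= 0].tolist()
        raise ValueError(f"non-positive 16S copy number for {bad}")
    missing = [o for o in table.columns if o not in copies.index]
    if missing:
        warnings.warn(
            f"{len(missing)} OTU(s) without 16S copy number; defaulting to "
            f"{default_missing}", stacklevel=2)
    divisor = copies.reindex(table.columns).fillna(default_missing)
    return table / divisor


def predict_metagenome(norm: pd.DataFrame, gene_content: pd.DataFrame
                       ) -> FunctionProfile:
    """Predict the community gene-family profile.

    ``F[s, k] = sum_o norm[s, o] * gene_content[o, k]`` — linear in the
    normalized abundances.  Every OTU in ``norm`` must have a gene-content
    row; missing OTUs raise with the offending ids listed.
    """
    missing = [o for o in norm.columns if o not in gene_content.index]
    if missing:
        raise KeyError(f"OTUs missing from gene content: {missing}")
    gc = gene_content.loc[norm.columns]
    values = norm.to_numpy() @ gc.to_numpy()
    return FunctionProfile(
        pd.DataFrame(values, index=norm.index, columns=gc.columns), "gene")


def _gene_to_l3(hierarchy: pd.DataFrame) -> pd.DataFrame:
    return hierarchy[["function", "level3"]]


def collapse_to_level(profile: FunctionProfile, hierarchy: pd.DataFrame,
                      level: str) -> FunctionProfile:
    """Collapse a gene-level profile to pathway level L3, L2 or L1.

    Collapse is hierarchical: gene families are first summed into their
    level-3 pathways (a family mapping to m pathways contributes its full
    value to each of the m), then level-3 totals sum into level-2 parents,
    then level-2 into level-1 categories.  Gene families absent from the
    hierarchy are dropped with a logged count.
    """
    if profile.level != "gene":
        raise ValueError("collapse expects a gene-level profile")
    if level not in ("L3", "L2", "L1"):
        raise ValueError(f"cannot collapse to {level!r}")
    known = set(hierarchy["function"])
    dropped = [k for k in profile.data.columns if k not in known]
    if dropped:
        logger.warning("collapse_to_level: dropped %d unknown function id(s)",
                       len(dropped))
    kept = [k for k in profile.data.columns if k in known]
    if not kept:
        return FunctionProfile(
            pd.DataFrame(index=profile.data.index, dtype=float), level)

    h = hierarchy[hierarchy["function"].isin(kept)]
    # L3 collapse via a sparse-ish indicator built per pathway
    l3_ids = sorted(h["level3"].unique())
    data = profile.data[kept]
    by_l3 = {}
    for l3, sub in h.groupby("level3"):
        by_l3[l3] = data[sub["function"].unique()].sum(axis=1)
    out = pd.DataFrame(by_l3, index=profile.data.index)[l3_ids]
    if level == "L3":
        return FunctionProfile(out, "L3")
    l3_to_l2 = h.drop_duplicates("level3").set_index("level3")["level2"]
    out = out.T.groupby(l3_to_l2).sum().T.sort_index(axis=1)
    if level == "L2":
        return FunctionProfile(out, "L2")
    l2_to_l1 = h.drop_duplicates("level2").set_index("level2")["level1"]
    out = out.T.groupby(l2_to_l1).sum().T.sort_index(axis=1)
    return FunctionProfile(out, "L1")


def default_presence_rule(values: np.ndarray) -> bool:
    """A function is present in a group if any sample has a nonzero value."""
    return bool((values > 0).any())


def venn_functions(profiles: dict[str, FunctionProfile | pd.DataFrame],
                   presence_rule=default_presence_rule) -> dict[frozenset, int]:
    """Count functions in every intersection region of per-group presence sets.

    ``profiles`` maps a stratum label (group and/or gender) to its profile.
    A function is "present" in a stratum when ``presence_rule`` holds on its
    column there.  Returns a mapping from each non-empty label subset to the
    number of functions present in exactly those strata (exclusive regions,
    as a Venn diagram draws them).
    """
    if len(profiles) < 2:
        raise ValueError("venn analysis needs at least 2 strata")
    presence: dict[str, set[str]] = {}
    for label, prof in profiles.items():
        df = prof.data if isinstance(prof, FunctionProfile) else prof
        presence[label] = {
            f for f in df.columns if presence_rule(df[f].to_numpy())}
    labels = sorted(presence)
    regions: dict[frozenset, int] = {}
    universe = set().union(*presence.values())
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set(universe)
            for lab in combo:
                inside &= presence[lab]
            for lab in labels:
                if lab not in combo:
                    inside -= presence[lab]
            regions[frozenset(combo)] = len(inside)
    return regions
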