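"""Organism-level trait aggregation.

Phenotype annotations of taxa (oxygen tolerance, gram stain, potential
pathogenicity, mobile-element carriage, biofilm formation, stress
tolerance) are aggregated by copy-number-normalized relative abundance:
a sample's share for a trait is the abundance-weighted mean of the trait
membership over its OTUs.  Memberships may be binary or continuous in
[0, 1].  Shares are ratios, so rescaling a sample's counts leaves them
unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .io import UNCLASSIFIED


def aggregate_traits(norm: pd.DataFrame, traits: pd.DataFrame,
                     trait_names: list[str] | None = None) -> pd.DataFrame:
    """Per-sample relative abundance of trait-bearing organisms.

    ``profile[s, t] = sum_o norm[s, o] * traits[o, t] / sum_o norm[s, o]``.
    OTUs absent from the trait table count as unannotated (membership 0).
    Requested traits missing from the table are reported as 0 with a
    warning; zero-abundance samples are excluded with a warning.
    """
    if traits.shape[0] == 0:
        raise ValueError("trait table annotates no OTUs")
    cols = list(traits.columns) if trait_names is None else list(trait_names)
    missing = [t for t in cols if t not in traits.columns]
    if missing:
        warnings.warn(f"trait(s) absent from table, reported as 0: {missing}",
                      stacklevel=2)
    memb = pd.DataFrame(0.0, index=norm.columns, columns=cols)
    present = [t for t in cols if t in traits.columns]
    memb[present] = traits.reindex(norm.columns)[present].fillna(0.0)
    totals = norm.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-abundance sample(s) excluded",
            stacklevel=2)
    norm = norm.loc[keep]
    weighted = norm.to_numpy() @ memb.to_numpy()
    return pd.DataFrame(weighted / totals[keep].to_numpy()[:, None],
                        index=norm.index, columns=cols)


def trait_phylum_breakdown(norm: pd.DataFrame, traits: pd.DataFrame,
                           taxonomy: pd.DataFrame) -> xr.DataArray:
    """Partition each trait's trait-bearing mass by phylum, per sample.

    Shares sum to 1 over phyla for every (sample, trait) with positive
    trait-bearing mass; degenerate (zero-mass) cells are NaN.
    """
    phyla_labels = (taxonomy["phylum"].reindex(norm.columns)
                    .fillna(UNCLASSIFIED).replace("", UNCLASSIFIED))
    phyla = sorted(phyla_labels.unique())
    cols = list(traits.columns)
    memb = traits.reindex(norm.columns).fillna(0.0).to_numpy()
    mass = np.zeros((norm.shape[0], len(cols), len(phyla)))
    norm_vals = norm.to_numpy()
    for pi, ph in enumerate(phyla):
        mask = (phyla_labels == ph).to_numpy()
        mass[:, :, pi] = norm_vals[:, mask] @ memb[mask]
    totals = mass.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(totals > 0, mass / totals, np.nan)
    return xr.DataArray(
        shares,
        coords={"sample": list(norm.index), "trait": cols, "phylum": phyla},
        dims=("sample", "trait", "phylum"),
        name="trait_phylum_share")


def group_trait_summary(profile: pd.DataFrame,
                        metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of trait shares per (gender, group).

    Returns a long frame with columns gender, group, trait, mean, sd, n.
    The standard deviation is the population form over the stratum's
    samples (zero for a single sample or identical samples).
    """
    meta = metadata.loc[profile.index]
    rows = []
    for (gender, group), idx in meta.groupby(["gender", "group"]).groups.items():
        sub = profile.loc[idx]
        for trait in profile.columns:
            vals = sub[trait].to_numpy()
            rows.append({
                "gender": gender, "group": group, "trait": trait,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
                "n": len(vals),
            })
    return pd.DataFrame(rows)
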