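"""Taxon-level decomposition of the imputed functional profile.

Because the predicted metagenome is a linear map of OTU abundances, every
unit of predicted function mass can be attributed exactly to the OTU that
contributed it.  This module aggregates those contributions to a chosen
taxonomic rank (phylum or class) and to the five level-1 functional
categories, and summarizes them the way contribution tables are reported:

* AAF — "average attribution of function": for a taxon and category, the
  mean over samples of the taxon's percentage share of that category's mass.
* AAT — "average attribution of total": the mean over samples of the
  taxon's category mass as a percentage of the sample's grand total over
  all categories.
* TotalAA — a taxon's AAT summed over categories; TotalAA sums to 100
  over taxa, and AAF columns sum to 100 within each category.

Averages are unweighted over samples (each sample's proportion is computed
first, then averaged), which is the only convention under which the AAT
rows sum to the per-taxon totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .io import UNCLASSIFIED


@dataclass
class AttributionSummary:
    """Per-(taxon, category) AAF/AAT percentages and per-taxon totals."""

    aaf: pd.DataFrame        # taxon x category, columns sum to 100
    aat: pd.DataFrame        # taxon x category, grand sum 100
    total_aa: pd.Series      # taxon -> sum of AAT over categories

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (taxon, category) with totals."""
        rows = []
        for taxon in self.aaf.index:
            for cat in self.aaf.columns:
                rows.append({
                    "taxon": taxon, "category": cat,
                    "avg_attribution_of_function": self.aaf.loc[taxon, cat],
                    "avg_attribution_of_total": self.aat.loc[taxon, cat],
                    "total_avg_attribution": self.total_aa[taxon],
                })
        return pd.DataFrame(rows)


def _category_weights(hierarchy: pd.DataFrame) -> pd.DataFrame:
    """Function x level-1 category weight matrix.

    The weight counts (function -> level-3) mappings landing in each
    category, so the tensor marginal over taxa reproduces the hierarchical
    L1 collapse exactly (a family with two level-3 pathways under one
    category contributes twice there).
    """
    counts = (hierarchy.groupby(["function", "level1"]).size()
              .unstack(fill_value=0))
    return counts.astype(float)


def compute_contributions(norm: pd.DataFrame, gene_content: pd.DataFrame,
                          taxonomy: pd.DataFrame, hierarchy: pd.DataFrame,
                          rank: str = "phylum") -> xr.DataArray:
    """Attribute predicted category mass to taxa at ``rank``.

    ``contribution[t, c, s] = sum_{o in t} sum_{k in c} norm[s, o] gc[o, k]``.
    OTUs unresolved at the rank (missing from the taxonomy or annotated
    "unclassified") are pooled under the "unclassified" label.
    """
    if rank not in ("phylum", "class"):
        raise ValueError("rank must be 'phylum' or 'class'")
    missing = [o for o in norm.columns if o not in gene_content.index]
    if missing:
        raise KeyError(f"OTUs missing from gene content: {missing}")
    labels = (taxonomy[rank].reindex(norm.columns).fillna(UNCLASSIFIED)
              .replace("", UNCLASSIFIED))
    weights = _category_weights(hierarchy)
    gc = gene_content.loc[norm.columns]
    common = [k for k in gc.columns if k in weights.index]
    # OTU x category mass per unit abundance
    per_otu = gc[common].to_numpy() @ weights.loc[common].to_numpy()
    categories = list(weights.columns)
    taxa = sorted(labels.unique())
    tensor = np.zeros((len(taxa), len(categories), norm.shape[0]))
    norm_vals = norm.to_numpy()
    for ti, taxon in enumerate(taxa):
        mask = (labels == taxon).to_numpy()
        # samples x categories for this taxon's OTUs
        tensor[ti] = (norm_vals[:, mask] @ per_otu[mask]).T
    return xr.DataArray(
        tensor,
        coords={"taxon": taxa, "category": categories,
                "sample": list(norm.index)},
        dims=("taxon", "category", "sample"),
        name="contribution")


def summarize_attribution(tensor: xr.DataArray) -> AttributionSummary:
    """Compute AAF/AAT/TotalAA percentages from a contribution tensor.

    Samples with zero grand total are excluded with a warning; a category
    empty in some sample contributes no term to that category's AAF mean.
    """
    if tensor.size == 0:
        raise ValueError("empty contribution tensor")
    cat_totals = tensor.sum("taxon")            # category x sample
    grand = cat_totals.sum("category")          # sample
    keep = grand > 0
    if not bool(keep.all()):
        warnings.warn(
            f"{int((~keep).sum())} sample(s) with zero total mass excluded",
            stacklevel=2)
        tensor = tensor.sel(sample=keep)
        cat_totals = cat_totals.sel(sample=keep)
        grand = grand.sel(sample=keep)
    if tensor.sizes["sample"] == 0:
        raise ValueError("no samples with positive mass")
    with np.errstate(invalid="ignore", divide="ignore"):
        share_of_cat = (tensor / cat_totals) * 100.0
    aaf = share_of_cat.mean("sample", skipna=True).to_pandas()
    aat = ((tensor / grand) * 100.0).mean("sample").to_pandas()
    total = aat.sum(axis=1)
    return AttributionSummary(aaf=aaf.fillna(0.0), aat=aat, total_aa=total)


def dominant_taxa(summary: AttributionSummary, category: str) -> list[str]:
    """Taxa ranked by descending AAF within ``category``; ties lexicographic."""
    if category not in summary.aaf.columns:
        raise KeyError(f"unknown category {category!r}")
    col = summary.aaf[category]
    return sorted(col.index, key=lambda t: (-col[t], t))
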