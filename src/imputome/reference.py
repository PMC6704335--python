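"""Packaged reference tables from the emulated study.

Three published summary tables ship with the package as plain TSV:

* the level-3 pathway signatures called in the female cohort by the
  less-strict discriminant route, one row per (group, pathway);
* the phylum-level functional attribution table for the female cohort
  (AAF/AAT percentages per category and per-phylum totals);
* the per-stratum co-occurrence network property table (node/edge counts
  and topology metrics).

They serve as ground truth for internal-consistency checks — e.g. that
per-phylum attribution totals equal the sum of their category entries, and
that each stratum's printed density satisfies the ordered-pair density
identity ``density = edges / (nodes * (nodes - 1))``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .network import density


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("imputome.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_reference_signatures() -> pd.DataFrame:
    """Level-3 signatures of the female cohort: group, id, function."""
    return _load("reference_signatures_female_l3.tsv")


def load_reference_attribution() -> pd.DataFrame:
    """Phylum x category AAF/AAT percentages with per-phylum totals."""
    return _load("reference_attribution_female.tsv")


def load_reference_network_metrics() -> pd.DataFrame:
    """Per-stratum network property table (ordered-pair edge counts)."""
    return _load("reference_network_metrics.tsv")


def check_attribution_consistency(tol: float = 0.005) -> pd.DataFrame:
    """Verify the per-phylum totals against their category sums.

    For every phylum the "total average attribution" should equal the sum
    of its five per-category "average attribution of total" entries, up to
    rounding of the printed values.  Returns a frame with the recomputed
    sums and the printed totals.
    """
    ref = load_reference_attribution()
    sums = ref.groupby("taxon")["avg_attribution_of_total"].sum()
    printed = ref.groupby("taxon")["total_avg_attribution"].first()
    out = pd.DataFrame({"category_sum": sums, "printed_total": printed})
    out["consistent"] = (out["category_sum"] - out["printed_total"]).abs() <= \
        tol * 5 * 2  # five addends each rounded to 2 decimals
    return out


def check_density_identity() -> pd.DataFrame:
    """Recompute each stratum's density from its node/edge counts."""
    ref = load_reference_network_metrics()
    out = ref[["gender", "group", "nodes", "edges", "density"]].copy()
    out["computed_density"] = [
        density(int(n), int(e)) for n, e in zip(ref["nodes"], ref["edges"])]
    return out
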