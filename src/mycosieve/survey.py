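"""Bundled summary tables from a published survey of agave fungal communities.

Three fiber-producing agave cultivars (*Agave fourcroydes*, *A. sisalana*,
hybrid 11648) were assembled de novo and their fungal transcripts extracted
and classified with the pipeline implemented here.  The survey's printed
per-community tables — fungal-group counts, assembly descriptors,
*Talaromyces* genus assignments, and HSP-annotated fractions — ship with the
package as small TSVs so the headline community arithmetic (phylum shares,
genus and HSP percentages) can be recomputed and checked without the raw
sequencing libraries.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .community_profile import percentage

GROUP_COLUMNS = ["ascomycota", "basidiomycota", "asco_or_basidio", "other_fungi"]


def _load(name: str) -> pd.DataFrame:
    resource = files("mycosieve").joinpath("data", "agave_survey", name)
    with resource.open("r") as handle:
        return pd.read_csv(handle, sep="\t")


def load_fungal_groups() -> pd.DataFrame:
    """Per-cultivar transcript counts in the four fungal groups plus totals."""
    return _load("fungal_groups.tsv")


def load_assembly_stats() -> pd.DataFrame:
    """Per-cultivar assembly descriptors of the fungal transcript sets."""
    return _load("assembly_stats.tsv")


def load_genus_assignments() -> pd.DataFrame:
    """Per-cultivar counts of transcripts assigned to *Talaromyces*."""
    return _load("genus_assignments.tsv")


def load_hsp_fractions() -> pd.DataFrame:
    """Per-cultivar percentage of fungal transcripts annotated as HSPs."""
    return _load("hsp_fractions.tsv")


def pooled_phylum_shares() -> dict[str, float]:
    """Percentage of each fungal group pooled over the three communities."""
    groups = load_fungal_groups()
    total = groups["total"].sum()
    return {col: percentage(groups[col].sum(), total) for col in GROUP_COLUMNS}


def genus_share_percentages() -> pd.Series:
    """Genus share (%) of total fungal transcripts per cultivar."""
    counts = load_genus_assignments().set_index("cultivar")["talaromyces_assigned"]
    totals = load_fungal_groups().set_index("cultivar")["total"]
    return (100.0 * counts / totals).rename("talaromyces_pct")


def mean_hsp_share() -> float:
    """Mean of the per-cultivar HSP percentages."""
    return float(load_hsp_fractions()["hsp_pct_of_fungal"].mean())
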