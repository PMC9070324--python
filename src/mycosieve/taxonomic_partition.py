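"""Two-stage taxonomic classification of assembled transcripts.

Stage 1 — host-vs-fungus separation by *top-hit voting*: a transcript is
called fungal when at least a fixed fraction (default 70%) of its top-N
(default 10) significant homology hits carry a fungal lineage.

Stage 2 — phylum-level consensus among significant hits against a fungal
reference: unanimous Ascomycota evidence yields ``ASCOMYCOTA``, unanimous
Basidiomycota yields ``BASIDIOMYCOTA``, any mixture of the two main phyla is
``ASCO_OR_BASIDIO`` (the classifier declines to distinguish them), and hits
to fungi outside both main phyla yield ``OTHER_FUNGI``.

A third, simpler rule assigns transcripts to a reference taxon set (e.g. a
single genus) when any hit clears an E-value and query-coverage threshold.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    FUNGAL_GROUPS,
    HomologyHit,
    Origin,
    PhylumGroup,
    TaxonCall,
    TranscriptRecord,
    sort_hits,
)

logger = logging.getLogger(__name__)

MAIN_PHYLA = {"Ascomycota": "ASCO", "Basidiomycota": "BASIDIO"}


def _qualifying(
    hits: Sequence[HomologyHit], e_value_max: float, top_n: int
) -> list[HomologyHit]:
    """Significant hits, ranked, truncated to the top N voting slots."""
    kept = [h for h in sort_hits(hits) if h.e_value <= e_value_max]
    return kept[:top_n]


def vote_host_vs_fungus(
    hits: Sequence[HomologyHit],
    top_n: int = 10,
    fungal_fraction: float = 0.70,
    e_value_max: float = 1e-10,
    min_hits: int = 1,
) -> tuple[Origin, dict[str, int]]:
    """Fraction-of-top-hits vote between host and fungal origin.

    Hits above ``e_value_max`` are discarded, the remainder ranked and
    truncated to ``top_n``.  With fewer than ``min_hits`` voting hits the
    transcript is ``UNCLASSIFIED``; otherwise it is ``FUNGAL`` iff the
    fungal share of the voting hits is at least ``fungal_fraction`` (the
    vote is taken over however many qualifying hits are available).
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if not 0 < fungal_fraction <= 1:
        raise ValueError(f"fungal_fraction must be in (0,1], got {fungal_fraction}")
    if min_hits < 1:
        raise ValueError(f"min_hits must be >= 1, got {min_hits}")
    voting = _qualifying(hits, e_value_max, top_n)
    if len(voting) < min_hits:
        return Origin.UNCLASSIFIED, {"fungal": 0, "non_fungal": 0}
    fungal = sum(1 for h in voting if h.subject_lineage.is_fungal)
    evidence = {"fungal": fungal, "non_fungal": len(voting) - fungal}
    origin = Origin.FUNGAL if fungal / len(voting) >= fungal_fraction else Origin.HOST
    return origin, evidence


def _phylum_category(hit: HomologyHit) -> str:
    phylum = hit.subject_lineage.phylum()
    if phylum is None:
        logger.info("hit %s -> %s lacks a phylum label; counted as OTHER",
                    hit.query_id, hit.subject_id)
        return "OTHER"
    return MAIN_PHYLA.get(phylum, "OTHER")


def classify_phylum(
    hits: Sequence[HomologyHit],
    e_value_max: float = 1e-10,
    top_n: int = 10,
    rule: str = "unanimity",
    majority_fraction: float = 0.9,
) -> tuple[PhylumGroup, dict[str, int]]:
    """Phylum-level consensus over the top-N significant fungal hits.

    ``rule="unanimity"`` (default): any mixture of Ascomycota and
    Basidiomycota votes is ``ASCO_OR_BASIDIO``; hits to other fungi do not
    block a unanimous main-phylum call.  ``rule="majority"``: a main phylum
    is called when it holds at least ``majority_fraction`` of the
    main-phylum votes.  With no qualifying hits the group is
    ``NOT_APPLICABLE``.
    """
    if rule not in ("unanimity", "majority"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    voting = _qualifying(hits, e_value_max, top_n)
    tally = Counter(_phylum_category(h) for h in voting)
    evidence = {"ASCO": tally["ASCO"], "BASIDIO": tally["BASIDIO"], "OTHER": tally["OTHER"]}
    a, b, o = evidence["ASCO"], evidence["BASIDIO"], evidence["OTHER"]
    if a + b + o == 0:
        return PhylumGroup.NOT_APPLICABLE, evidence
    if a + b == 0:
        return PhylumGroup.OTHER_FUNGI, evidence
    if rule == "unanimity":
        if a > 0 and b == 0:
            return PhylumGroup.ASCOMYCOTA, evidence
        if b > 0 and a == 0:
            return PhylumGroup.BASIDIOMYCOTA, evidence
        return PhylumGroup.ASCO_OR_BASIDIO, evidence
    # majority rule over the main-phylum votes
    if a / (a + b) >= majority_fraction:
        return PhylumGroup.ASCOMYCOTA, evidence
    if b / (a + b) >= majority_fraction:
        return PhylumGroup.BASIDIOMYCOTA, evidence
    return PhylumGroup.ASCO_OR_BASIDIO, evidence


def assign_to_reference_set(
    hits: Sequence[HomologyHit],
    e_value_max: float = 1e-10,
    min_coverage: float = 0.70,
    strict_coverage: bool = True,
) -> tuple[bool, str | None]:
    """Assign a transcript to a reference taxon set (e.g. one genus).

    Assigned iff at least one hit has ``e_value < e_value_max`` and query
    coverage above ``min_coverage`` (strictly above by default).  Returns
    the assignment flag and the top-ranked qualifying subject id.
    """
    for hit in sort_hits(hits):
        if hit.e_value >= e_value_max:
            continue
        cov_ok = (
            hit.query_coverage > min_coverage
            if strict_coverage
            else hit.query_coverage >= min_coverage
        )
        if cov_ok:
            return True, hit.subject_id
    return False, None


@dataclass(frozen=True)
class PartitionParams:
    """Thresholds for the two-stage partition."""

    top_n: int = 10
    fungal_fraction: float = 0.70
    e_value_max: float = 1e-10
    min_hits: int = 1
    phylum_e_value_max: float = 1e-10
    phylum_top_n: int = 10
    rule: str = "unanimity"
    majority_fraction: float = 0.9


@dataclass
class PartitionReport:
    """All per-transcript calls plus the phylum-group count summary."""

    calls: list[TaxonCall] = field(default_factory=list)

    @property
    def total_fungal(self) -> int:
        return sum(1 for c in self.calls if c.origin is Origin.FUNGAL)

    @property
    def counts(self) -> dict[PhylumGroup, int]:
        """Fungal transcripts per phylum group (incl. NOT_APPLICABLE no-calls)."""
        tally = Counter(
            c.phylum_group for c in self.calls if c.origin is Origin.FUNGAL
        )
        return {g: tally.get(g, 0) for g in PhylumGroup}

    @property
    def group_counts(self) -> dict[PhylumGroup, int]:
        """Counts over the four real fungal groups (the report row)."""
        counts = self.counts
        return {g: counts[g] for g in FUNGAL_GROUPS}

    def call_for(self, transcript_id: str) -> TaxonCall:
        for c in self.calls:
            if c.transcript_id == transcript_id:
                return c
        raise KeyError(transcript_id)

    def phylum_by_transcript(self) -> dict[str, PhylumGroup]:
        return {c.transcript_id: c.phylum_group for c in self.calls}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            ev = dict(c.evidence)
            rows.append(
                {
                    "transcript_id": c.transcript_id,
                    "origin": c.origin.value,
                    "phylum_group": c.phylum_group.value,
                    "ev_fungal": ev.get("fungal", 0),
                    "ev_non_fungal": ev.get("non_fungal", 0),
                    "ev_asco": ev.get("ASCO", 0),
                    "ev_basidio": ev.get("BASIDIO", 0),
                    "ev_other": ev.get("OTHER", 0),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "transcript_id", "origin", "phylum_group",
                "ev_fungal", "ev_non_fungal", "ev_asco", "ev_basidio", "ev_other",
            ],
        )

    def summary_frame(self) -> pd.DataFrame:
        counts = self.group_counts
        row = {g.value.lower(): n for g, n in counts.items()}
        row["total_fungal"] = self.total_fungal
        return pd.DataFrame([row])


def partition_transcriptome(
    records: Sequence[TranscriptRecord],
    host_hits: Mapping[str, Sequence[HomologyHit]],
    fungal_hits: Mapping[str, Sequence[HomologyHit]],
    params: PartitionParams = PartitionParams(),
) -> PartitionReport:
    """Run both classifier stages over a transcript set.

    ``host_hits`` are hits against a mixed (host + fungus) reference and
    drive the origin vote; ``fungal_hits`` are hits against a fungal
    reference with phylum-labelled subjects and drive the phylum consensus.
    The same table may serve both roles when its lineages carry kingdom and
    phylum ranks.  Fungal transcripts with no qualifying fungal hits keep
    ``NOT_APPLICABLE`` and are logged.
    """
    calls: list[TaxonCall] = []
    for rec in records:
        origin, vote_ev = vote_host_vs_fungus(
            host_hits.get(rec.id, ()),
            top_n=params.top_n,
            fungal_fraction=params.fungal_fraction,
            e_value_max=params.e_value_max,
            min_hits=params.min_hits,
        )
        group = PhylumGroup.NOT_APPLICABLE
        evidence: dict[str, int] = dict(vote_ev)
        if origin is Origin.FUNGAL:
            group, phylum_ev = classify_phylum(
                fungal_hits.get(rec.id, ()),
                e_value_max=params.phylum_e_value_max,
                top_n=params.phylum_top_n,
                rule=params.rule,
                majority_fraction=params.majority_fraction,
            )
            if group is PhylumGroup.NOT_APPLICABLE:
                logger.info(
                    "fungal transcript %s has no qualifying fungal hits", rec.id
                )
            evidence.update(phylum_ev)
        calls.append(
            TaxonCall(
                transcript_id=rec.id,
                origin=origin,
                phylum_group=group,
                evidence=evidence,
            )
        )
    return PartitionReport(calls=calls)
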