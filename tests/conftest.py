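"""Shared fixtures and hit-construction helpers."""

from __future__ import annotations

import hypothesis

from mycosieve.model import HomologyHit, Lineage

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=100
)
hypothesis.settings.load_profile("suite")

PLANT_LINEAGE = Lineage(
    (("superkingdom", "Eukaryota"), ("kingdom", "Viridiplantae"), ("phylum", "Streptophyta"))
)


def fungal_lineage(phylum: str | None = "Ascomycota") -> Lineage:
    ranks = [("superkingdom", "Eukaryota"), ("kingdom", "Fungi")]
    if phylum is not None:
        ranks.append(("phylum", phylum))
    return Lineage(tuple(ranks))


def make_hit(
    query: str = "q1",
    subject: str = "s1",
    e_value: float = 1e-20,
    bit_score: float = 100.0,
    phylum: str | None = "Ascomycota",
    fungal: bool = True,
    query_length: int = 300,
    alignment_length: int = 210,
    percent_identity: float = 90.0,
) -> HomologyHit:
    lineage = fungal_lineage(phylum) if fungal else PLANT_LINEAGE
    return HomologyHit.build(
        query_id=query,
        subject_id=subject,
        percent_identity=percent_identity,
        alignment_length=alignment_length,
        e_value=e_value,
        bit_score=bit_score,
        query_length=query_length,
        subject_lineage=lineage,
    )
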