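"""Representative-isoform selection and assembly summary statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import ExpressionTable, TranscriptRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssemblySummary:
    """Descriptors of one transcript set (the usual assembly-report row)."""

    n_transcripts: int
    mean_length_bp: float
    n50_bp: int
    min_cds_bp: int
    max_cds_bp: int


def select_representative_isoforms(
    records: Sequence[TranscriptRecord],
    expr: ExpressionTable,
    tpm_min: float = 1.0,
    orf_min_nt: int = 255,
    orf_inclusive: bool = True,
) -> list[TranscriptRecord]:
    """Keep, per locus, the longest isoform passing the TPM and ORF gates.

    An isoform qualifies when its mean TPM across all samples is strictly
    greater than ``tpm_min`` and its ORF length is ``>= orf_min_nt``
    (``> orf_min_nt`` when ``orf_inclusive`` is False).  Loci with no
    qualifying isoform are dropped.  Transcripts missing from the
    expression table fail the TPM gate and are logged.  Length ties within
    a locus resolve to the lexicographically smallest id.
    """
    means = expr.mean_overall()
    best: dict[str, TranscriptRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.id not in means.index:
            logger.info("transcript %s absent from expression table; fails TPM gate", rec.id)
            continue
        if means[rec.id] <= tpm_min:
            continue
        orf_ok = rec.orf_length_nt >= orf_min_nt if orf_inclusive else rec.orf_length_nt > orf_min_nt
        if not orf_ok:
            continue
        locus = rec.locus_id
        incumbent = best.get(locus)
        if incumbent is None:
            best[locus] = rec
            order.append(locus)
        elif rec.length_nt > incumbent.length_nt or (
            rec.length_nt == incumbent.length_nt and rec.id < incumbent.id
        ):
            # longer wins; on equal length the smaller id wins
            best[locus] = rec
    return [best[locus] for locus in order]


def n50(lengths: Iterable[int]) -> int:
    """Largest length L with total bases in sequences of length >= L covering
    at least half of all bases."""
    values = sorted(lengths, reverse=True)
    if not values:
        raise ValueError("n50 of an empty length set is undefined")
    half = sum(values) / 2
    running = 0
    for v in values:
        running += v
        if running >= half:
            return v
    return values[-1]  # unreachable; guards float edge cases


def assembly_summary(records: Sequence[TranscriptRecord]) -> AssemblySummary:
    """Summary statistics: count, mean/N50 of transcript lengths, min/max ORF."""
    if not records:
        raise ValueError("cannot summarize an empty transcript set")
    lengths = [r.length_nt for r in records]
    orfs = [r.orf_length_nt for r in records]
    return AssemblySummary(
        n_transcripts=len(records),
        mean_length_bp=sum(lengths) / len(lengths),
        n50_bp=n50(lengths),
        min_cds_bp=min(orfs),
        max_cds_bp=max(orfs),
    )
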