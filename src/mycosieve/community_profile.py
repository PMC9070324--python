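"""Downstream statistics on the fungal partition.

Covers tissue specificity (SPM), hypergeometric term enrichment against the
all-fungal background, transporter and secreted-CAZyme threshold filters,
and the summary percentages reported for a community (phylum shares, genus
share, HSP share).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import (
    AnnotationSource,
    ExpressionTable,
    HomologyHit,
    Origin,
    PhylumGroup,
    TaxonCall,
    sort_hits,
    validate_annotation_frame,
)
from .taxonomic_partition import PartitionReport

logger = logging.getLogger(__name__)

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")
_CAZY_RE = re.compile(r"^(CBM|GH|GT|PL|CE|AA)\d*(_\d+)?$")


@dataclass(frozen=True)
class SpecificityResult:
    """SPM profile of one transcript plus its unique >threshold call, if any."""

    transcript_id: str
    spm: Mapping[str, float] | None
    specific_tissue: str | None


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's hypergeometric test against the background."""

    term: str
    k: int  # term count in group
    n: int  # group size
    K: int  # term count in background
    N: int  # background size
    p_value: float
    p_adjusted: float
    significant: bool


def mean_tissue_expression(expr: ExpressionTable) -> pd.DataFrame:
    """Replicate-mean TPM per tissue (transcript x tissue)."""
    return expr.mean_by_tissue()


def spm_profile(tissue_means: Mapping[str, float]) -> dict[str, float] | None:
    """SPM_t = x_t / ||x||_2 — cosine with the single-tissue unit vector.

    Returns None for the all-zero vector (no profile).  SPM is
    scale-invariant and its squares sum to one, so at most one tissue can
    exceed 1/sqrt(2) and a high-threshold call is unique.
    """
    values = dict(tissue_means)
    if any(v < 0 for v in values.values()):
        raise ValueError("negative expression value in SPM profile")
    norm = math.sqrt(sum(v * v for v in values.values()))
    if norm == 0:
        return None
    return {t: v / norm for t, v in values.items()}


def call_tissue_specific(
    profile: Mapping[str, float] | None, threshold: float = 0.95
) -> str | None:
    """The unique tissue with SPM strictly above the threshold, else None."""
    if profile is None:
        return None
    for tissue, value in profile.items():
        if value > threshold:
            return tissue
    return None


def tissue_specificity(
    expr: ExpressionTable,
    threshold: float = 0.95,
    transcripts: Iterable[str] | None = None,
) -> list[SpecificityResult]:
    """SPM profiles and tissue-specific calls for the table's transcripts."""
    means = mean_tissue_expression(expr)
    if means.shape[1] < 2:
        raise ValueError("SPM needs at least two tissues")
    ids = list(transcripts) if transcripts is not None else list(means.index)
    results = []
    for tid in ids:
        if tid not in means.index:
            results.append(SpecificityResult(tid, None, None))
            continue
        profile = spm_profile(means.loc[tid].to_dict())
        results.append(
            SpecificityResult(tid, profile, call_tissue_specific(profile, threshold))
        )
    return results


def hypergeometric_enrichment(
    group: Collection[str],
    background: Collection[str],
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
    source: AnnotationSource | str | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of terms in ``group``.

    For each term with K carriers among the N background transcripts and k
    carriers among the n group transcripts, p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  ``correction`` is ``"none"`` (raw p < alpha, the
    conventional choice here) or ``"bh"`` (Benjamini-Hochberg).  ``source``
    optionally restricts the annotation table to one source (e.g. KO).
    Results are sorted by (p, term).
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    group_set, background_set = set(group), set(background)
    if not group_set <= background_set:
        stray = sorted(group_set - background_set)[:5]
        raise ValueError(f"group is not a subset of the background, e.g. {stray}")
    frame = validate_annotation_frame(annotations)
    if source is not None:
        src = source.value if isinstance(source, AnnotationSource) else source
        frame = frame[frame["source"] == src]
    frame = frame[frame["transcript_id"].isin(background_set)]
    N, n = len(background_set), len(group_set)
    carriers = frame.groupby("term")["transcript_id"].agg(set)
    if carriers.empty:
        return []
    terms = sorted(carriers.index)
    ks, Ks, pvals = [], [], []
    for term in terms:
        ids = carriers[term]
        K = len(ids)
        k = len(ids & group_set)
        ks.append(k)
        Ks.append(K)
        pvals.append(float(hypergeom.sf(k - 1, N, K, n)))
    if correction == "bh":
        reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        p_adj = pvals
        reject = [p < alpha for p in pvals]
    results = [
        EnrichmentResult(
            term=term, k=k, n=n, K=K, N=N,
            p_value=p, p_adjusted=float(pa), significant=bool(sig),
        )
        for term, k, K, p, pa, sig in zip(terms, ks, Ks, pvals, p_adj, reject)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.term))


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p_value": r.p_value, "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["term", "k", "n", "K", "N", "p_value", "p_adjusted", "significant"],
    )


def filter_transporter_hits(
    hits_by_transcript: Mapping[str, Sequence[HomologyHit]],
    e_value_max: float = 1e-5,
    min_coverage: float = 0.70,
) -> list[tuple[str, str]]:
    """Transporter-family assignment from reference-database hits.

    A transcript is retained iff its best-ranked hit has
    ``e_value <= e_value_max`` and query coverage ``>= min_coverage`` (both
    inclusive); the family is that hit's subject id.  Sorted by transcript.
    """
    retained = []
    for transcript, hits in hits_by_transcript.items():
        ranked = sort_hits(hits)
        if not ranked:
            continue
        best = ranked[0]
        if best.e_value <= e_value_max and best.query_coverage >= min_coverage:
            retained.append((transcript, best.subject_id))
    return sorted(retained)


def cazy_class(family: str) -> str | None:
    """Class prefix (GH/GT/PL/CE/AA/CBM) of a CAZy family string, or None."""
    match = _CAZY_RE.match(family.strip())
    return match.group(1) if match else None


def _calls_mapping(
    partition: PartitionReport | Mapping[str, PhylumGroup] | Iterable[TaxonCall],
) -> dict[str, PhylumGroup]:
    if isinstance(partition, PartitionReport):
        return partition.phylum_by_transcript()
    if isinstance(partition, Mapping):
        return dict(partition)
    return {c.transcript_id: c.phylum_group for c in partition}


def summarize_secreted_cazymes(
    annotations: pd.DataFrame,
    partition: PartitionReport | Mapping[str, PhylumGroup] | Iterable[TaxonCall],
    sp_score_min: float = 0.5,
) -> dict[tuple[str, PhylumGroup], int]:
    """Count secreted CAZy families per (CAZy class, phylum group).

    A transcript contributes its CAZY annotations iff it also carries a
    signal-peptide score strictly above ``sp_score_min``.  Families whose
    class prefix cannot be parsed are logged and skipped.
    """
    frame = validate_annotation_frame(annotations)
    calls = _calls_mapping(partition)
    sp = frame[frame["source"] == AnnotationSource.SIGNALP.value]
    secreted = set(sp.loc[sp["score"] > sp_score_min, "transcript_id"])
    counts: dict[tuple[str, PhylumGroup], int] = {}
    cazy = frame[frame["source"] == AnnotationSource.CAZY.value]
    for row in cazy.itertuples(index=False):
        if row.transcript_id not in secreted:
            continue
        klass = cazy_class(row.term)
        if klass is None:
            logger.warning("unparseable CAZy family %r on %s; skipped",
                           row.term, row.transcript_id)
            continue
        group = calls.get(row.transcript_id, PhylumGroup.NOT_APPLICABLE)
        key = (klass, group)
        counts[key] = counts.get(key, 0) + 1
    return counts


def percentage(part: float, whole: float) -> float:
    if whole == 0:
        raise ValueError("percentage with a zero denominator")
    return 100.0 * part / whole


def community_summary(
    partition: PartitionReport,
    genus_assigned: Collection[str],
    annotations: pd.DataFrame | None = None,
    genus_denominator: str = "fungal",
) -> dict[str, object]:
    """Headline percentages for one fungal community.

    * phylum shares: 100 x group count / total fungal transcripts;
    * genus share: 100 x assigned / total fungal (or / Ascomycota count when
      ``genus_denominator="ascomycota"``);
    * HSP share: 100 x transcripts carrying >= 1 HSP annotation / total
      fungal (None when no annotation table is given).

    Full precision is kept; round only at presentation.
    """
    if genus_denominator not in ("fungal", "ascomycota"):
        raise ValueError(f"unknown genus denominator {genus_denominator!r}")
    total = partition.total_fungal
    if total < 1:
        raise ValueError("community summary needs at least one fungal transcript")
    group_counts = partition.group_counts
    fungal_ids = {
        c.transcript_id for c in partition.calls if c.origin is Origin.FUNGAL
    }
    denom = (
        total
        if genus_denominator == "fungal"
        else group_counts[PhylumGroup.ASCOMYCOTA]
    )
    genus_ids = set(genus_assigned) & fungal_ids
    hsp_pct = None
    if annotations is not None:
        frame = validate_annotation_frame(annotations)
        hsp_ids = set(
            frame.loc[frame["source"] == AnnotationSource.HSP.value, "transcript_id"]
        )
        hsp_pct = percentage(len(hsp_ids & fungal_ids), total)
    return {
        "total_fungal": total,
        "phylum_share_pct": {
            g.value: percentage(n, total) for g, n in group_counts.items()
        },
        "genus_share_pct": percentage(len(genus_ids), denom),
        "hsp_share_pct": hsp_pct,
    }
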