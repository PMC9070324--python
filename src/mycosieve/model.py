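"""Shared data model for the fungal-community extraction pipeline.

The pipeline operates on four kinds of input derived from a de novo plant
transcriptome assembly: transcript sequences (FASTA, Trinity-style ids),
ranked homology hits (BLAST tabular extended with query length and subject
lineage), a TPM expression matrix with a tissue/replicate sample sheet, and
per-transcript functional annotations.  The types here are the lingua franca
between the I/O layer (:mod:`mycosieve.core_io`) and the analysis modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

_ISOFORM_RE = re.compile(r"_i\d+$")


class Origin(str, Enum):
    """Host-vs-fungus verdict for one transcript."""

    HOST = "HOST"
    FUNGAL = "FUNGAL"
    UNCLASSIFIED = "UNCLASSIFIED"


class PhylumGroup(str, Enum):
    """Four-way phylum-level consensus group (plus the no-call sentinel)."""

    ASCOMYCOTA = "ASCOMYCOTA"
    BASIDIOMYCOTA = "BASIDIOMYCOTA"
    ASCO_OR_BASIDIO = "ASCO_OR_BASIDIO"
    OTHER_FUNGI = "OTHER_FUNGI"
    NOT_APPLICABLE = "NOT_APPLICABLE"


#: The four real groups a fungal transcript can land in (report columns).
FUNGAL_GROUPS = (
    PhylumGroup.ASCOMYCOTA,
    PhylumGroup.BASIDIOMYCOTA,
    PhylumGroup.ASCO_OR_BASIDIO,
    PhylumGroup.OTHER_FUNGI,
)


class AnnotationSource(str, Enum):
    """Provenance of a functional annotation term."""

    KO = "KO"
    CDD = "CDD"
    CAZY = "CAZY"
    TCDB = "TCDB"
    HSP = "HSP"
    SIGNALP = "SIGNALP"
    GENUS = "GENUS"


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript.

    ``id`` follows the Trinity dialect ``<prefix>_DN<d>_c<d>_g<d>[_i<d>]``;
    ``locus_id`` is the id with a trailing isoform suffix (``_i<d>``)
    stripped.  ``orf_length_nt`` is the length of the longest annotated ORF
    in nucleotides (0 when no ORF was predicted; ORF calling is upstream).
    """

    id: str
    sequence: str
    orf_length_nt: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if self.orf_length_nt < 0:
            raise ValueError(f"{self.id}: orf_length_nt must be >= 0")

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def locus_id(self) -> str:
        return _ISOFORM_RE.sub("", self.id)


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic lineage, most inclusive rank first.

    Serialized as semicolon-delimited ``rank:name`` pairs.  A lineage is
    *fungal* when any taxon name is exactly ``Fungi``.
    """

    ranks: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = [r for r, _ in self.ranks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate rank names in lineage: {names}")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        text = text.strip()
        if not text:
            return cls(())
        pairs = []
        for chunk in text.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if ":" not in chunk:
                raise ValueError(f"malformed lineage segment {chunk!r}")
            rank, name = chunk.split(":", 1)
            if not rank or not name:
                raise ValueError(f"malformed lineage segment {chunk!r}")
            pairs.append((rank, name))
        return cls(tuple(pairs))

    def to_string(self) -> str:
        return ";".join(f"{rank}:{name}" for rank, name in self.ranks)

    @property
    def is_fungal(self) -> bool:
        return any(name == "Fungi" for _, name in self.ranks)

    def phylum(self) -> str | None:
        for rank, name in self.ranks:
            if rank == "phylum":
                return name
        return None


@dataclass(frozen=True)
class HomologyHit:
    """One ranked similarity hit for a query transcript.

    ``query_coverage`` is the aligned fraction of the *query* (see
    :func:`HomologyHit.build` for the amino-acid unit conversion used for
    translated searches).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    query_length: int
    subject_lineage: Lineage
    query_coverage: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"{self.query_id}: e_value must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"{self.query_id}: percent identity out of [0,100]")
        if self.alignment_length < 1:
            raise ValueError(f"{self.query_id}: alignment_length must be >= 1")
        if self.query_length < 1:
            raise ValueError(f"{self.query_id}: query_length must be >= 1")
        if not 0 < self.query_coverage <= 1:
            raise ValueError(f"{self.query_id}: query_coverage out of (0,1]")

    @classmethod
    def build(
        cls,
        query_id: str,
        subject_id: str,
        percent_identity: float,
        alignment_length: int,
        e_value: float,
        bit_score: float,
        query_length: int,
        subject_lineage: Lineage,
        alignment_units: str = "nt",
    ) -> "HomologyHit":
        """Construct a hit, deriving query coverage.

        ``alignment_units`` is ``"nt"`` for nucleotide-level alignments or
        ``"aa"`` for translated (amino-acid) alignments, whose lengths are
        converted to nucleotide units (x3) before dividing by query length.
        """
        if alignment_units not in ("nt", "aa"):
            raise ValueError(f"alignment_units must be 'nt' or 'aa', got {alignment_units!r}")
        factor = 3 if alignment_units == "aa" else 1
        coverage = min(1.0, factor * alignment_length / query_length)
        return cls(
            query_id=query_id,
            subject_id=subject_id,
            percent_identity=percent_identity,
            alignment_length=alignment_length,
            e_value=e_value,
            bit_score=bit_score,
            query_length=query_length,
            subject_lineage=subject_lineage,
            query_coverage=coverage,
        )

    @property
    def rank_key(self) -> tuple[float, float, str]:
        """Deterministic total order: E-value asc, bit score desc, subject asc."""
        return (self.e_value, -self.bit_score, self.subject_id)


def sort_hits(hits: Iterable[HomologyHit]) -> list[HomologyHit]:
    """Return hits sorted by the deterministic rank key (best first)."""
    return sorted(hits, key=lambda h: h.rank_key)


@dataclass
class ExpressionTable:
    """TPM matrix (transcript x sample) plus (tissue, replicate) metadata.

    Transcripts absent from the matrix are simply absent — missing
    expression is never imputed as zero.
    """

    tpm: pd.DataFrame
    samples: pd.DataFrame  # columns: sample_id, tissue, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "tissue", "replicate"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        if self.samples["sample_id"].duplicated().any():
            dupes = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in sheet: {sorted(set(dupes))}")
        sheet = set(self.samples["sample_id"])
        matrix = set(self.tpm.columns)
        if sheet != matrix:
            missing = sorted(matrix - sheet)
            extra = sorted(sheet - matrix)
            raise ValueError(
                f"sample sheet / matrix mismatch: matrix-only={missing}, sheet-only={extra}"
            )
        if self.tpm.index.duplicated().any():
            raise ValueError("duplicate transcript ids in expression matrix")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("negative TPM value in expression matrix")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    def mean_by_tissue(self) -> pd.DataFrame:
        """Arithmetic replicate-mean TPM per tissue (transcript x tissue)."""
        tissue_of = self.samples.set_index("sample_id")["tissue"]
        return self.tpm.T.groupby(tissue_of).mean().T

    def mean_overall(self) -> pd.Series:
        """Mean TPM across all samples (used by the isoform-selection gate)."""
        return self.tpm.mean(axis=1)


@dataclass(frozen=True)
class AnnotationRecord:
    """One functional term assignment for one transcript."""

    transcript_id: str
    source: AnnotationSource
    term: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.source is AnnotationSource.SIGNALP:
            if self.score is None or not 0 <= self.score <= 1:
                raise ValueError(
                    f"{self.transcript_id}: SIGNALP records need a score in [0,1]"
                )


ANNOTATION_COLUMNS = ["transcript_id", "source", "term", "score"]


def annotations_to_frame(records: Iterable[AnnotationRecord]) -> pd.DataFrame:
    """Convert AnnotationRecord objects to the canonical annotation frame."""
    rows = [
        (r.transcript_id, r.source.value, r.term, r.score) for r in records
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def validate_annotation_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate the canonical annotation frame; returns it unchanged."""
    if list(frame.columns) != ANNOTATION_COLUMNS:
        raise ValueError(f"annotation table must have columns {ANNOTATION_COLUMNS}")
    valid = {s.value for s in AnnotationSource}
    bad = set(frame["source"]) - valid
    if bad:
        raise ValueError(f"unknown annotation sources: {sorted(bad)}")
    if frame.duplicated(subset=["transcript_id", "source", "term"]).any():
        dupes = frame[frame.duplicated(subset=["transcript_id", "source", "term"])]
        raise ValueError(
            f"duplicate (transcript, source, term) triples, e.g. {dupes.iloc[0].tolist()}"
        )
    sp = frame.loc[frame["source"] == AnnotationSource.SIGNALP.value, "score"]
    if sp.isna().any() or ((sp < 0) | (sp > 1)).any():
        raise ValueError("SIGNALP annotations must carry a score in [0,1]")
    return frame


@dataclass(frozen=True)
class TaxonCall:
    """Per-transcript verdict from the two-stage taxonomic classifier."""

    transcript_id: str
    origin: Origin
    phylum_group: PhylumGroup = PhylumGroup.NOT_APPLICABLE
    evidence: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.origin is not Origin.FUNGAL and self.phylum_group in FUNGAL_GROUPS:
            raise ValueError(
                f"{self.transcript_id}: phylum group requires a FUNGAL origin"
            )
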