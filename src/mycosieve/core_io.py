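"""Readers and writers for the pipeline's plain-text interchange formats.

Formats
-------
* FASTA — transcript sequences; the header token up to the first whitespace
  is the transcript id.
* Hit table — tab-separated, the 12 standard BLAST tabular (``outfmt 6``)
  columns extended with ``qlen`` and a semicolon-delimited ``rank:name``
  lineage column::

      qseqid sseqid pident length mismatch gapopen qstart qend
      sstart send evalue bitscore qlen lineage

* Expression matrix — TSV, header ``transcript_id`` + sample ids; sample
  sheet TSV with columns ``sample_id  tissue  replicate``.
* Annotation table — TSV ``transcript_id  source  term  score``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ANNOTATION_COLUMNS,
    ExpressionTable,
    HomologyHit,
    Lineage,
    TranscriptRecord,
    sort_hits,
    validate_annotation_frame,
)

logger = logging.getLogger(__name__)

HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qlen", "lineage",
]

FASTA_LINE_WIDTH = 60


def read_fasta(
    path: str | Path,
    orf_lengths: Mapping[str, int] | None = None,
) -> list[TranscriptRecord]:
    """Read transcripts from FASTA, preserving order and uppercasing sequences.

    ``orf_lengths`` optionally supplies per-transcript ORF lengths (nt);
    transcripts absent from the mapping get ``orf_length_nt = 0``.
    Duplicate ids raise ``ValueError``.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate transcript id in FASTA: {entry.id}")
        seen.add(entry.id)
        orf = orf_lengths.get(entry.id, 0) if orf_lengths else 0
        records.append(
            TranscriptRecord(id=entry.id, sequence=str(entry.seq).upper(), orf_length_nt=orf)
        )
    if not records:
        logger.warning("FASTA file %s contained no sequences", path)
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts as FASTA wrapped at a fixed width."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_LINE_WIDTH)
        writer.write_file(seqs)


def _parse_hit_line(line: str, lineno: int, alignment_units: str) -> HomologyHit:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != len(HIT_TABLE_COLUMNS):
        raise ValueError(
            f"line {lineno}: expected {len(HIT_TABLE_COLUMNS)} columns, got {len(fields)}"
        )
    try:
        pident = float(fields[2])
        length = int(fields[3])
        evalue = float(fields[10])
        bitscore = float(fields[11])
        qlen = int(fields[12])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric field ({exc})") from None
    try:
        lineage = Lineage.from_string(fields[13])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None
    return HomologyHit.build(
        query_id=fields[0],
        subject_id=fields[1],
        percent_identity=pident,
        alignment_length=length,
        e_value=evalue,
        bit_score=bitscore,
        query_length=qlen,
        subject_lineage=lineage,
        alignment_units=alignment_units,
    )


def read_hit_table(
    path: str | Path,
    alignment_units: str = "nt",
) -> dict[str, list[HomologyHit]]:
    """Read an extended BLAST tabular file, grouping and ranking hits per query.

    Each query's list is sorted by the deterministic rank key (ascending
    E-value, descending bit score, ascending subject id), so downstream
    voting is independent of the file's row order.
    """
    hits: dict[str, list[HomologyHit]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            hit = _parse_hit_line(line, lineno, alignment_units)
            hits.setdefault(hit.query_id, []).append(hit)
    return {query: sort_hits(rows) for query, rows in hits.items()}


def write_hit_table(
    hits: Mapping[str, Iterable[HomologyHit]] | Iterable[HomologyHit],
    path: str | Path,
) -> None:
    """Write hits in the extended tabular dialect (coverage is re-derived on read)."""
    if isinstance(hits, Mapping):
        rows: Iterable[HomologyHit] = (h for hs in hits.values() for h in hs)
    else:
        rows = hits
    with open(path, "w") as handle:
        for h in rows:
            # mismatch/gapopen/coordinates are not consumed downstream; emit
            # placeholders consistent with the alignment length.
            handle.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        "0",
                        "0",
                        "1",
                        str(h.alignment_length),
                        "1",
                        str(h.alignment_length),
                        f"{h.e_value:.3e}",
                        f"{h.bit_score:.1f}",
                        str(h.query_length),
                        h.subject_lineage.to_string(),
                    ]
                )
                + "\n"
            )


def read_expression_table(
    matrix_path: str | Path,
    samples_path: str | Path,
) -> ExpressionTable:
    """Read a TPM matrix plus sample sheet into an :class:`ExpressionTable`."""
    tpm = pd.read_csv(matrix_path, sep="\t", index_col="transcript_id")
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str, "tissue": str})
    return ExpressionTable(tpm=tpm.astype(float), samples=samples)


def write_expression_table(
    expr: ExpressionTable,
    matrix_path: str | Path,
    samples_path: str | Path,
) -> None:
    expr.tpm.to_csv(matrix_path, sep="\t", index_label="transcript_id", float_format="%.6g")
    expr.samples.to_csv(samples_path, sep="\t", index=False)


def read_orf_lengths(path: str | Path) -> dict[str, int]:
    """Read a ``transcript_id  orf_length_nt`` TSV (ORF calling is upstream)."""
    frame = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if (frame["orf_length_nt"] < 0).any():
        raise ValueError("negative ORF length")
    return dict(zip(frame["transcript_id"], frame["orf_length_nt"].astype(int)))


def write_orf_lengths(orf_lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(orf_lengths), "orf_length_nt": list(orf_lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a ``transcript_id  source  term  score`` annotation TSV."""
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"transcript_id": str, "source": str, "term": str},
    )
    if "score" not in frame.columns:
        frame["score"] = float("nan")
    frame = frame[ANNOTATION_COLUMNS]
    return validate_annotation_frame(frame)


def write_annotation_table(frame: pd.DataFrame, path: str | Path) -> None:
    validate_annotation_frame(frame).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
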