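"""Ground-truth generators for every input the pipeline consumes.

The generators emulate a plant transcriptome assembly that contains a hidden
fungal community: transcript sets with known host/fungal origin and phylum
labels, ranked homology-hit tables with controlled label noise, TPM
expression matrices with planted tissue specificity, and annotation tables
with planted term enrichment.  Everything is a pure function of
``(design, seed)``; a single root seed is split into fixed per-generator
streams so each table can be regenerated independently.

Label noise semantics
---------------------
``label_noise_eps`` is the per-hit probability that a hit's lineage is
swapped to a *wrong* category at the taxonomic level being voted on: for a
fungal query the two main phyla are swapped (Ascomycota <-> Basidiomycota;
an "other fungi" query flips to one of the two main phyla), while a host
query's flipped hit becomes a random fungal lineage.  Under the unanimity
consensus a correct main-phylum call therefore survives iff no voting hit
flipped, giving the closed form TPR = (1 - eps)^top_n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import LabeledPool
from .core_io import (
    write_annotation_table,
    write_expression_table,
    write_fasta,
    write_hit_table,
    write_orf_lengths,
)
from .model import (
    AnnotationSource,
    ExpressionTable,
    HomologyHit,
    Lineage,
    Origin,
    TranscriptRecord,
    sort_hits,
)

CATEGORIES = ("HOST", "ASCO", "BASIDIO", "OTHER")

_HOST_LINEAGE = Lineage(
    (("superkingdom", "Eukaryota"), ("kingdom", "Viridiplantae"), ("phylum", "Streptophyta"))
)
_ASCO_LINEAGE = Lineage(
    (("superkingdom", "Eukaryota"), ("kingdom", "Fungi"), ("phylum", "Ascomycota"))
)
_BASIDIO_LINEAGE = Lineage(
    (("superkingdom", "Eukaryota"), ("kingdom", "Fungi"), ("phylum", "Basidiomycota"))
)
_OTHER_PHYLA = ("Mucoromycota", "Chytridiomycota", "Glomeromycota")
_OTHER_LINEAGES = tuple(
    Lineage((("superkingdom", "Eukaryota"), ("kingdom", "Fungi"), ("phylum", p)))
    for p in _OTHER_PHYLA
)
_GENUS_LINEAGE = Lineage(
    (("kingdom", "Fungi"), ("phylum", "Ascomycota"), ("genus", "Talaromyces"))
)
_TCDB_FAMILIES = (
    "1.A.11.3.3", "2.A.1.9.2", "2.A.1.9.11", "3.A.1.205.1", "1.A.33.1.2",
    "2.A.29.1.1", "3.A.16.1.2", "1.A.33.1.6", "3.A.18.1.1",
)
_CAZY_FAMILIES = (
    "GH18", "GH16", "GH17", "GH43", "GH10", "GH11", "GH128", "GH76", "GH79",
    "GT2", "GT4", "CE1", "AA9", "AA3", "PL1", "CBM1",
)
_CAZY_WEIGHTS = (
    10, 8, 6, 5, 3, 3, 5, 4, 3,
    6, 4, 3, 6, 3, 1, 2,
)
_HSP_TERMS = ("sHSP-ACD", "Hsp70", "Hsp90", "Hsp100", "DnaJ")
_HSP_WEIGHTS = (5, 3, 1, 2, 2)

_STREAMS = {
    "sequences": 0,
    "pool": 1,
    "hits": 2,
    "expression": 3,
    "annotations": 4,
    "genus": 5,
    "tcdb": 6,
}


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for one simulated community.

    Defaults emulate one fiber-cultivar community: ~25,000 assembled
    transcripts of which ~12% are fungal, the fungal fraction split across
    Ascomycota/Basidiomycota/other phyla in the proportions observed in the
    field, nine expression libraries (leaf/stem/root x 3 replicates), most
    fungal transcripts root-specific, ~15% of Ascomycota transcripts from
    the dominant genus, and ~6% of fungal transcripts HSP-annotated.
    """

    # community composition
    n_host: int = 22000
    n_asco: int = 1927
    n_basidio: int = 797
    n_other: int = 253
    # labeled reference pool (benchmarking)
    pool_asco: int = 5000
    pool_basidio: int = 2000
    pool_other: int = 300
    # homology-hit simulation
    hits_per_query: int = 10
    label_noise_eps: float = 0.0
    decoy_fraction: float = 0.2
    # sequence lengths (log-normal, nt)
    length_log_mean: float = 6.2
    length_log_sigma: float = 0.35
    min_length_nt: int = 200
    # expression structure
    tissues: tuple[str, ...] = ("leaf", "stem", "root")
    replicates: int = 3
    fungal_root_specific: float = 0.9
    host_specific_per_tissue: float = 0.02
    specific_minor_ratio: float = 0.05
    replicate_sigma: float = 0.2
    base_tpm_log_mean: float = 1.6
    base_tpm_log_sigma: float = 1.0
    # annotations
    n_ko_terms: int = 150
    ko_freq_low: float = 0.001
    ko_freq_high: float = 0.02
    n_cdd_terms: int = 80
    cdd_freq_low: float = 0.001
    cdd_freq_high: float = 0.02
    enriched_terms: tuple[tuple[str, float], ...] = ()
    enriched_group: str = "ASCO"
    genus_fraction: float = 0.15
    hsp_fraction: float = 0.062
    cazy_fraction: float = 0.08
    tcdb_fraction: float = 0.05
    secreted_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise_eps < 1:
            raise ValueError(f"label_noise_eps out of [0,1): {self.label_noise_eps}")
        for name in (
            "decoy_fraction", "fungal_root_specific",
            "host_specific_per_tissue", "genus_fraction", "hsp_fraction",
            "cazy_fraction", "tcdb_fraction", "secreted_fraction",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} out of range: {value}")
        for name in ("n_host", "n_asco", "n_basidio", "n_other",
                     "pool_asco", "pool_basidio", "pool_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1 or len(self.tissues) < 2:
            raise ValueError("need >= 2 tissues and >= 1 replicate")
        if "root" not in self.tissues and self.fungal_root_specific > 0:
            raise ValueError("fungal_root_specific > 0 requires a 'root' tissue")

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=seed)


def stream_rng(design: SimulationDesign, stream: str) -> np.random.Generator:
    """Independent, reproducible random stream for one generator."""
    return np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class TruthRow:
    origin: Origin
    phylum_label: str | None  # ASCO / BASIDIO / OTHER for fungal transcripts
    genus_flag: bool = False
    specific_tissue: str | None = None
    transporter_flag: bool = False


@dataclass
class TruthTable:
    """Ground truth covering every generated transcript exactly once."""

    rows: dict[str, TruthRow] = field(default_factory=dict)

    def ids(self) -> list[str]:
        return list(self.rows)

    def fungal_ids(self) -> list[str]:
        return [i for i, r in self.rows.items() if r.origin is Origin.FUNGAL]

    def categories(self) -> dict[str, str]:
        """Transcript -> voting category (HOST or the true phylum label)."""
        return {
            i: (r.phylum_label if r.origin is Origin.FUNGAL else "HOST")
            for i, r in self.rows.items()
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": i,
                    "origin": r.origin.value,
                    "phylum_label": r.phylum_label or "",
                    "genus_flag": int(r.genus_flag),
                    "specific_tissue": r.specific_tissue or "",
                    "transporter_flag": int(r.transporter_flag),
                }
                for i, r in self.rows.items()
            ],
            columns=[
                "transcript_id", "origin", "phylum_label",
                "genus_flag", "specific_tissue", "transporter_flag",
            ],
        )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    total = int(lengths.sum())
    flat = _BASES[rng.integers(0, 4, size=total)].tobytes().decode("ascii")
    out, pos = [], 0
    for n in lengths:
        out.append(flat[pos : pos + int(n)])
        pos += int(n)
    return out


def _draw_lengths(rng: np.random.Generator, design: SimulationDesign, n: int) -> np.ndarray:
    lengths = rng.lognormal(design.length_log_mean, design.length_log_sigma, size=n)
    return np.maximum(lengths.astype(int), design.min_length_nt)


def generate_community(
    design: SimulationDesign,
) -> tuple[list[TranscriptRecord], TruthTable]:
    """Transcript records plus ground truth for one simulated community."""
    rng = stream_rng(design, "sequences")
    labels = (
        ["HOST"] * design.n_host
        + ["ASCO"] * design.n_asco
        + ["BASIDIO"] * design.n_basidio
        + ["OTHER"] * design.n_other
    )
    n = len(labels)
    lengths = _draw_lengths(rng, design, n)
    seqs = _random_sequences(rng, lengths)
    orf_fracs = rng.uniform(0.3, 0.9, size=n)
    genus_draw = rng.random(n)
    transporter_draw = rng.random(n)
    specific_draw = rng.random(n)
    tissues = list(design.tissues)
    records: list[TranscriptRecord] = []
    truth = TruthTable()
    for i, label in enumerate(labels):
        tid = f"SIM_DN{i + 1}_c0_g1_i1"
        fungal = label != "HOST"
        orf = int(orf_fracs[i] * lengths[i])
        records.append(TranscriptRecord(id=tid, sequence=seqs[i], orf_length_nt=orf))
        specific: str | None = None
        if fungal:
            if specific_draw[i] < design.fungal_root_specific:
                specific = "root"
        else:
            # cumulative bins: one small window per tissue
            u = specific_draw[i]
            for j, t in enumerate(tissues):
                low = j * design.host_specific_per_tissue
                if low <= u < low + design.host_specific_per_tissue:
                    specific = t
                    break
        truth.rows[tid] = TruthRow(
            origin=Origin.FUNGAL if fungal else Origin.HOST,
            phylum_label=label if fungal else None,
            genus_flag=fungal and label == "ASCO" and genus_draw[i] < design.genus_fraction,
            specific_tissue=specific,
            transporter_flag=fungal and transporter_draw[i] < design.tcdb_fraction,
        )
    return records, truth


def generate_reference_pool(
    design: SimulationDesign,
) -> tuple[LabeledPool, list[TranscriptRecord]]:
    """Labeled CDS pool standing in for a public fungal-genome collection."""
    rng = stream_rng(design, "pool")
    labels = (
        ["ASCO"] * design.pool_asco
        + ["BASIDIO"] * design.pool_basidio
        + ["OTHER"] * design.pool_other
    )
    lengths = _draw_lengths(rng, design, len(labels))
    seqs = _random_sequences(rng, lengths)
    entries = []
    records = []
    for i, label in enumerate(labels):
        sid = f"REF_{label}_{i + 1}"
        entries.append((sid, label))
        records.append(TranscriptRecord(id=sid, sequence=seqs[i]))
    return LabeledPool(tuple(entries)), records


def _lineage_for(category: str, rng: np.random.Generator) -> Lineage:
    if category == "HOST":
        return _HOST_LINEAGE
    if category == "ASCO":
        return _ASCO_LINEAGE
    if category == "BASIDIO":
        return _BASIDIO_LINEAGE
    return _OTHER_LINEAGES[int(rng.integers(len(_OTHER_LINEAGES)))]


def _flip(category: str, rng: np.random.Generator) -> str:
    if category == "ASCO":
        return "BASIDIO"
    if category == "BASIDIO":
        return "ASCO"
    if category == "OTHER":
        return "ASCO" if rng.random() < 0.5 else "BASIDIO"
    return ("ASCO", "BASIDIO", "OTHER")[int(rng.integers(3))]


def simulate_hit_table(
    categories: Mapping[str, str] | TruthTable,
    design: SimulationDesign,
    subject_pools: Mapping[str, Sequence[str]] | None = None,
    query_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[HomologyHit]]:
    """Ranked homology hits per query with controlled label noise.

    True hits draw E-values log-uniformly in [1e-180, 1e-12] (well inside
    the pipeline's significance cutoffs); with probability
    ``decoy_fraction`` a query also gains a decoy hit with E-value in
    [1e-8, 1e-1] that every stage filters out.  ``subject_pools`` optionally
    maps each category to real subject ids (e.g. a benchmark reference set),
    enforcing self-exclusion semantics.
    """
    if isinstance(categories, TruthTable):
        categories = categories.categories()
    rng = stream_rng(design, "hits")
    table: dict[str, list[HomologyHit]] = {}
    m = design.hits_per_query
    for query, category in categories.items():
        qlen = int(query_lengths[query]) if query_lengths else int(
            max(design.min_length_nt, rng.lognormal(design.length_log_mean, design.length_log_sigma))
        )
        flips = rng.random(m) < design.label_noise_eps
        exponents = rng.uniform(-180, -12, size=m)
        fracs = rng.uniform(0.5, 0.98, size=m)
        pidents = rng.uniform(55, 99, size=m)
        hits = []
        for j in range(m):
            cat = _flip(category, rng) if flips[j] else category
            lineage = _lineage_for(cat, rng)
            if subject_pools is not None:
                pool = subject_pools[cat]
                subject = pool[int(rng.integers(len(pool)))]
            else:
                subject = f"{cat.lower()}_subj_{int(rng.integers(10**6))}"
            e_value = float(10.0 ** exponents[j])
            hits.append(
                HomologyHit.build(
                    query_id=query,
                    subject_id=subject,
                    percent_identity=float(pidents[j]),
                    alignment_length=max(1, int(fracs[j] * qlen)),
                    e_value=e_value,
                    bit_score=float(40.0 - 2.0 * exponents[j] + rng.uniform(0, 5)),
                    query_length=qlen,
                    subject_lineage=lineage,
                )
            )
        if rng.random() < design.decoy_fraction:
            cat = ("HOST", "ASCO", "BASIDIO", "OTHER")[int(rng.integers(4))]
            exponent = rng.uniform(-8, -1)
            hits.append(
                HomologyHit.build(
                    query_id=query,
                    subject_id=f"decoy_{int(rng.integers(10**6))}",
                    percent_identity=float(rng.uniform(30, 60)),
                    alignment_length=max(1, int(rng.uniform(0.2, 0.5) * qlen)),
                    e_value=float(10.0 ** exponent),
                    bit_score=float(40.0 - 2.0 * exponent),
                    query_length=qlen,
                    subject_lineage=_lineage_for(cat, rng),
                )
            )
        table[query] = sort_hits(hits)
    return table


def simulate_reference_assignment_hits(
    truth: TruthTable,
    design: SimulationDesign,
    stream: str = "genus",
) -> dict[str, list[HomologyHit]]:
    """Hits of fungal transcripts against a genus reference set.

    Genus-flagged transcripts get a hit clearing the assignment thresholds
    (E < 1e-10, coverage > 0.70); a minority of unflagged transcripts get a
    disqualifying hit (weak E-value or low coverage), the rest none.
    """
    rng = stream_rng(design, stream)
    table: dict[str, list[HomologyHit]] = {}
    for tid, row in truth.rows.items():
        if row.origin is not Origin.FUNGAL:
            continue
        qlen = int(max(design.min_length_nt,
                       rng.lognormal(design.length_log_mean, design.length_log_sigma)))
        if row.genus_flag:
            exponent = rng.uniform(-60, -11)
            frac = rng.uniform(0.75, 0.98)
        elif rng.random() < 0.3:
            if rng.random() < 0.5:
                exponent = rng.uniform(-60, -11)
                frac = rng.uniform(0.2, 0.65)  # fails the coverage gate
            else:
                exponent = rng.uniform(-9, -2)  # fails the E-value gate
                frac = rng.uniform(0.75, 0.95)
        else:
            continue
        table[tid] = [
            HomologyHit.build(
                query_id=tid,
                subject_id=f"TALA_{int(rng.integers(10**5))}",
                percent_identity=float(rng.uniform(70, 99)),
                alignment_length=max(1, int(frac * qlen)),
                e_value=float(10.0 ** exponent),
                bit_score=float(40.0 - 2.0 * exponent),
                query_length=qlen,
                subject_lineage=_GENUS_LINEAGE,
            )
        ]
    return table


def simulate_transporter_hits(
    truth: TruthTable,
    design: SimulationDesign,
) -> dict[str, list[HomologyHit]]:
    """Hits against a transporter classification reference.

    Transporter-flagged transcripts clear the filter (E <= 1e-5, coverage
    >= 0.70); some unflagged transcripts carry a disqualifying hit.
    """
    rng = stream_rng(design, "tcdb")
    table: dict[str, list[HomologyHit]] = {}
    for tid, row in truth.rows.items():
        if row.origin is not Origin.FUNGAL:
            continue
        qlen = int(max(design.min_length_nt,
                       rng.lognormal(design.length_log_mean, design.length_log_sigma)))
        family = _TCDB_FAMILIES[int(rng.integers(len(_TCDB_FAMILIES)))]
        if row.transporter_flag:
            exponent = rng.uniform(-40, -6)
            frac = rng.uniform(0.72, 0.98)
        elif rng.random() < 0.2:
            if rng.random() < 0.5:
                exponent = rng.uniform(-40, -6)
                frac = rng.uniform(0.2, 0.65)
            else:
                exponent = rng.uniform(-4, -1)
                frac = rng.uniform(0.72, 0.95)
        else:
            continue
        table[tid] = [
            HomologyHit.build(
                query_id=tid,
                subject_id=family,
                percent_identity=float(rng.uniform(40, 95)),
                alignment_length=max(1, int(frac * qlen)),
                e_value=float(10.0 ** exponent),
                bit_score=float(40.0 - 2.0 * exponent),
                query_length=qlen,
                subject_lineage=Lineage(),
            )
        ]
    return table


def generate_expression_matrix(
    truth: TruthTable,
    design: SimulationDesign,
) -> ExpressionTable:
    """TPM matrix with planted tissue specificity.

    A transcript flagged specific to tissue t gets its mean concentrated
    there (off-tissue means are ``specific_minor_ratio`` of the major one,
    giving a noise-free SPM ~ 0.9975, comfortably above the 0.95 calling
    threshold); other transcripts have balanced means.  Replicate values are
    the tissue mean times multiplicative log-normal noise with
    ``replicate_sigma`` (0 = exact means).
    """
    rng = stream_rng(design, "expression")
    ids = truth.ids()
    tissues = list(design.tissues)
    n, nt = len(ids), len(tissues)
    base = rng.lognormal(design.base_tpm_log_mean, design.base_tpm_log_sigma, size=n)
    means = np.tile(base[:, None], (1, nt))
    for i, tid in enumerate(ids):
        specific = truth.rows[tid].specific_tissue
        if specific is not None:
            j = tissues.index(specific)
            means[i, :] = base[i] * design.specific_minor_ratio
            means[i, j] = base[i]
    sample_ids = [f"{t}_{r}" for t in tissues for r in range(1, design.replicates + 1)]
    cols = np.repeat(np.arange(nt), design.replicates)
    values = means[:, cols]
    if design.replicate_sigma > 0:
        values = values * rng.lognormal(0.0, design.replicate_sigma, size=values.shape)
    tpm = pd.DataFrame(values, index=pd.Index(ids, name="transcript_id"), columns=sample_ids)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": [t for t in tissues for _ in range(design.replicates)],
            "replicate": list(range(1, design.replicates + 1)) * nt,
        }
    )
    return ExpressionTable(tpm=tpm, samples=samples)


def _bernoulli_terms(
    rng: np.random.Generator,
    ids: list[str],
    in_group: np.ndarray,
    terms: list[str],
    freq_low: float,
    freq_high: float,
    enriched: Mapping[str, float],
    source: AnnotationSource,
) -> list[tuple[str, str, str, float | None]]:
    if not terms:
        return []
    probs = rng.uniform(freq_low, freq_high, size=len(terms))
    prob_matrix = np.tile(probs, (len(ids), 1))
    for j, term in enumerate(terms):
        mult = enriched.get(term)
        if mult is not None:
            odds = probs[j] / (1 - probs[j])
            boosted = odds * mult / (1 + odds * mult)
            prob_matrix[in_group, j] = boosted
    draws = rng.random(prob_matrix.shape) < prob_matrix
    rows = []
    carriers, term_idx = np.nonzero(draws)
    for i, j in zip(carriers.tolist(), term_idx.tolist()):
        rows.append((ids[i], source.value, terms[j], None))
    return rows


def generate_annotation_tables(
    truth: TruthTable,
    design: SimulationDesign,
) -> pd.DataFrame:
    """Annotation table (KO, CDD, CAZY, HSP, TCDB, SIGNALP) for fungal transcripts.

    Term-carrier probabilities are uniform per term in the design's
    frequency band; ``enriched_terms`` multiplies the carrier *odds* for
    transcripts whose true category is ``enriched_group``.  Signal-peptide
    scores follow a two-component Beta mixture: a secreted minority with
    scores mostly above 0.5 and the rest mostly below.
    """
    rng = stream_rng(design, "annotations")
    ids = truth.fungal_ids()
    if not ids:
        return pd.DataFrame(columns=["transcript_id", "source", "term", "score"])
    cats = truth.categories()
    in_group = np.array([cats[i] == design.enriched_group for i in ids])
    enriched = dict(design.enriched_terms)
    rows: list[tuple[str, str, str, float | None]] = []
    ko_terms = [f"K{i:05d}" for i in range(1, design.n_ko_terms + 1)]
    rows += _bernoulli_terms(
        rng, ids, in_group, ko_terms,
        design.ko_freq_low, design.ko_freq_high, enriched, AnnotationSource.KO,
    )
    cdd_terms = [f"CDD:{100000 + i}" for i in range(1, design.n_cdd_terms + 1)]
    rows += _bernoulli_terms(
        rng, ids, in_group, cdd_terms,
        design.cdd_freq_low, design.cdd_freq_high, enriched, AnnotationSource.CDD,
    )
    # CAZy families, HSP types, transporter families: at most one draw each
    cazy_p = np.asarray(_CAZY_WEIGHTS, dtype=float)
    cazy_p /= cazy_p.sum()
    hsp_p = np.asarray(_HSP_WEIGHTS, dtype=float)
    hsp_p /= hsp_p.sum()
    cazy_mask = rng.random(len(ids)) < design.cazy_fraction
    hsp_mask = rng.random(len(ids)) < design.hsp_fraction
    secreted_mask = rng.random(len(ids)) < design.secreted_fraction
    sp_hi = rng.beta(8, 2, size=len(ids))
    sp_lo = rng.beta(1.5, 8, size=len(ids))
    cazy_choice = rng.choice(len(_CAZY_FAMILIES), size=len(ids), p=cazy_p)
    hsp_choice = rng.choice(len(_HSP_TERMS), size=len(ids), p=hsp_p)
    tcdb_choice = rng.integers(len(_TCDB_FAMILIES), size=len(ids))
    for i, tid in enumerate(ids):
        if cazy_mask[i]:
            rows.append((tid, AnnotationSource.CAZY.value, _CAZY_FAMILIES[cazy_choice[i]], None))
        if hsp_mask[i]:
            rows.append((tid, AnnotationSource.HSP.value, _HSP_TERMS[hsp_choice[i]], None))
        if truth.rows[tid].transporter_flag:
            rows.append((tid, AnnotationSource.TCDB.value, _TCDB_FAMILIES[tcdb_choice[i]], None))
        score = float(sp_hi[i] if secreted_mask[i] else sp_lo[i])
        rows.append((tid, AnnotationSource.SIGNALP.value, "signal_peptide", score))
    frame = pd.DataFrame(rows, columns=["transcript_id", "source", "term", "score"])
    return frame.sort_values(
        ["transcript_id", "source", "term"], ignore_index=True
    )


@dataclass
class SimulatedStudy:
    """All inputs for one end-to-end run, with ground truth."""

    design: SimulationDesign
    records: list[TranscriptRecord]
    truth: TruthTable
    hits: dict[str, list[HomologyHit]]
    genus_hits: dict[str, list[HomologyHit]]
    transporter_hits: dict[str, list[HomologyHit]]
    expression: ExpressionTable
    annotations: pd.DataFrame


def simulate_study(design: SimulationDesign) -> SimulatedStudy:
    """Generate every pipeline input for one community."""
    records, truth = generate_community(design)
    lengths = {r.id: r.length_nt for r in records}
    hits = simulate_hit_table(truth, design, query_lengths=lengths)
    return SimulatedStudy(
        design=design,
        records=records,
        truth=truth,
        hits=hits,
        genus_hits=simulate_reference_assignment_hits(truth, design),
        transporter_hits=simulate_transporter_hits(truth, design),
        expression=generate_expression_matrix(truth, design),
        annotations=generate_annotation_tables(truth, design),
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "hits": outdir / "hits.tsv",
        "genus_hits": outdir / "genus_hits.tsv",
        "transporter_hits": outdir / "transporter_hits.tsv",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "annotations": outdir / "annotations.tsv",
        "orf_lengths": outdir / "orf_lengths.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(study.records, paths["fasta"])
    write_orf_lengths({r.id: r.orf_length_nt for r in study.records}, paths["orf_lengths"])
    write_hit_table(study.hits, paths["hits"])
    write_hit_table(study.genus_hits, paths["genus_hits"])
    write_hit_table(study.transporter_hits, paths["transporter_hits"])
    write_expression_table(study.expression, paths["expression"], paths["samples"])
    write_annotation_table(study.annotations, paths["annotations"])
    study.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def kmer_containment(query: str, reference: str, k: int = 11) -> float:
    """Fraction of the query's k-mers present in the reference.

    A deliberately simple sequence-similarity score used to smoke-test the
    FASTA -> hit-table path; it is a synthetic stand-in for a real local
    aligner, not a reimplementation of one.
    """
    if len(query) < k or len(reference) < k:
        return 0.0
    qmers = {query[i : i + k] for i in range(len(query) - k + 1)}
    rmers = {reference[i : i + k] for i in range(len(reference) - k + 1)}
    return len(qmers & rmers) / len(qmers)
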