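"""End-to-end orchestration: simulated inputs -> partition -> profiles -> summary.

Glue over the library modules; every report is written as a deterministic
TSV (sorted rows, fixed float format) so identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .community_profile import (
    community_summary,
    enrichment_frame,
    hypergeometric_enrichment,
    summarize_secreted_cazymes,
    tissue_specificity,
)
from .model import AnnotationSource, Origin, PhylumGroup
from .synthetic_data import SimulatedStudy, SimulationDesign, simulate_study, write_study
from .taxonomic_partition import (
    PartitionParams,
    PartitionReport,
    assign_to_reference_set,
    partition_transcriptome,
)

FLOAT_FORMAT = "%.10g"


def analyze_study(
    study: SimulatedStudy,
    params: PartitionParams = PartitionParams(),
    spm_threshold: float = 0.95,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis over one (simulated or real) input bundle.

    Returns deterministic frames: the per-transcript partition, the fungal
    tissue-specificity calls, KO-term enrichment of the Ascomycota group
    against the all-fungal background, the secreted-CAZyme class counts, and
    the community summary percentages.
    """
    partition = partition_transcriptome(study.records, study.hits, study.hits, params)
    fungal = [c.transcript_id for c in partition.calls if c.origin is Origin.FUNGAL]
    by_group = partition.phylum_by_transcript()

    spec = tissue_specificity(study.expression, threshold=spm_threshold, transcripts=fungal)
    spec_frame = pd.DataFrame(
        [
            {
                "transcript_id": s.transcript_id,
                "specific_tissue": s.specific_tissue or "",
                **{
                    f"spm_{t}": (s.spm or {}).get(t, float("nan"))
                    for t in study.expression.tissues
                },
            }
            for s in spec
        ]
    ).sort_values("transcript_id", ignore_index=True)

    asco = [t for t in fungal if by_group[t] is PhylumGroup.ASCOMYCOTA]
    enr = hypergeometric_enrichment(
        asco, fungal, study.annotations, alpha=alpha, source=AnnotationSource.KO
    )
    genus_assigned = sorted(
        t
        for t in fungal
        if assign_to_reference_set(study.genus_hits.get(t, ()))[0]
    )
    summary = community_summary(partition, genus_assigned, study.annotations)
    summary_frame = pd.DataFrame(
        [
            {
                "total_fungal": summary["total_fungal"],
                **{
                    f"pct_{g.lower()}": v
                    for g, v in summary["phylum_share_pct"].items()
                },
                "pct_genus": summary["genus_share_pct"],
                "pct_hsp": summary["hsp_share_pct"],
            }
        ]
    )
    cazy = summarize_secreted_cazymes(study.annotations, partition)
    cazy_frame = pd.DataFrame(
        [
            {"cazy_class": klass, "phylum_group": group.value, "count": count}
            for (klass, group), count in sorted(
                cazy.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            )
        ],
        columns=["cazy_class", "phylum_group", "count"],
    )
    return {
        "partition": partition.to_frame().sort_values("transcript_id", ignore_index=True),
        "partition_summary": partition.summary_frame(),
        "specificity": spec_frame,
        "enrichment": enrichment_frame(enr),
        "secreted_cazymes": cazy_frame,
        "community_summary": summary_frame,
    }


def run_study(
    design: SimulationDesign,
    outdir: str | Path,
    params: PartitionParams = PartitionParams(),
    write_inputs: bool = False,
) -> dict[str, Path]:
    """Simulate one community, analyze it, and write all reports to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(design)
    if write_inputs:
        write_study(study, outdir / "inputs")
    frames = analyze_study(study, params)
    paths = {}
    for name, frame in frames.items():
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        paths[name] = path
    return paths
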