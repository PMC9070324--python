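"""Classifier evaluation: labeled query sets, confusion matrices, grid sweeps.

The evaluation protocol mirrors how a rule-based phylum classifier is
benchmarked against a labeled CDS pool: sample a query set (without
replacement), exclude it from the reference so no sequence can identify
itself, classify every query, and report one-vs-rest TPR/FPR per class over
a grid of (E-value cutoff, top-N, consensus rule) settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import FUNGAL_GROUPS, HomologyHit, PhylumGroup
from .taxonomic_partition import classify_phylum

LABELS = ("ASCO", "BASIDIO", "OTHER")

#: Truth label -> the phylum group a perfect classifier would call.
LABEL_TO_GROUP = {
    "ASCO": PhylumGroup.ASCOMYCOTA,
    "BASIDIO": PhylumGroup.BASIDIOMYCOTA,
    "OTHER": PhylumGroup.OTHER_FUNGI,
}


@dataclass(frozen=True)
class LabeledPool:
    """Sequences with known phylum labels (ASCO / BASIDIO / OTHER)."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids in a labeled pool must be unique")
        bad = {lab for _, lab in self.entries} - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS}")

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    def label_of(self) -> dict[str, str]:
        return dict(self.entries)

    def count(self, label: str) -> int:
        return sum(1 for _, lab in self.entries if lab == label)


def build_benchmark_sets(
    pool: LabeledPool,
    n_asco: int = 2000,
    n_basidio: int = 700,
    seed: int = 0,
) -> tuple[LabeledPool, LabeledPool]:
    """Sample a labeled query set and self-exclude it from the reference.

    Draws ``n_asco`` ASCO and ``n_basidio`` BASIDIO entries without
    replacement (seeded); the reference set is the pool minus the query set,
    so the two are disjoint by construction.
    """
    rng = np.random.default_rng(seed)
    chosen: set[int] = set()
    for label, want in (("ASCO", n_asco), ("BASIDIO", n_basidio)):
        idx = [i for i, (_, lab) in enumerate(pool.entries) if lab == label]
        if len(idx) < want:
            raise ValueError(
                f"pool has {len(idx)} {label} entries, need {want} "
                f"(short by {want - len(idx)})"
            )
        chosen.update(rng.choice(idx, size=want, replace=False).tolist())
    query = LabeledPool(tuple(pool.entries[i] for i in sorted(chosen)))
    reference = LabeledPool(
        tuple(e for i, e in enumerate(pool.entries) if i not in chosen)
    )
    return query, reference


def evaluate_classifier(
    calls: Mapping[str, PhylumGroup],
    truth: LabeledPool,
) -> pd.DataFrame:
    """One-vs-rest confusion per phylum group.

    For class c: TP = truth c called c, FN = truth c called anything else,
    FP = truth != c called c, TN = the rest (including ASCO_OR_BASIDIO and
    NOT_APPLICABLE calls).  TPR/FPR are NaN when their denominator is zero.
    """
    label_of = truth.label_of()
    unknown = set(calls) - set(label_of)
    if unknown:
        raise ValueError(f"calls for queries outside the truth set: {sorted(unknown)[:5]}")
    missing = set(label_of) - set(calls)
    if missing:
        raise ValueError(f"missing calls for truth entries: {sorted(missing)[:5]}")
    rows = []
    total = len(truth)
    for group in FUNGAL_GROUPS:
        positives = {q for q, lab in label_of.items() if LABEL_TO_GROUP.get(lab) is group}
        called = {q for q, g in calls.items() if g is group}
        tp = len(positives & called)
        fn = len(positives - called)
        fp = len(called - positives)
        tn = total - tp - fn - fp
        tpr = tp / (tp + fn) if tp + fn > 0 else float("nan")
        fpr = fp / (fp + tn) if fp + tn > 0 else float("nan")
        rows.append(
            {
                "class": group.value,
                "TP": tp, "FP": fp, "FN": fn, "TN": tn,
                "TPR": tpr, "FPR": fpr,
            }
        )
    return pd.DataFrame(rows)


def sweep_parameters(
    query_hits: Mapping[str, Sequence[HomologyHit]],
    truth: LabeledPool,
    e_value_grid: Sequence[float] = (1e-10, 1e-20),
    top_n_grid: Sequence[int] = (1, 3, 5, 10),
    rules: Sequence[str] = ("unanimity",),
) -> pd.DataFrame:
    """TPR/FPR over the full (E-value x top-N x rule) grid.

    Queries with no hit rows are classified ``NOT_APPLICABLE``.  Rows are
    sorted by (e_value_max, top_n, rule, class) for reproducibility.
    """
    if not e_value_grid or not top_n_grid or not rules:
        raise ValueError("parameter grids must be non-empty")
    frames = []
    for e_value_max in e_value_grid:
        for top_n in top_n_grid:
            for rule in rules:
                calls = {
                    q: classify_phylum(
                        query_hits.get(q, ()),
                        e_value_max=e_value_max,
                        top_n=top_n,
                        rule=rule,
                    )[0]
                    for q in truth.ids()
                }
                frame = evaluate_classifier(calls, truth)
                frame.insert(0, "rule", rule)
                frame.insert(0, "top_n", top_n)
                frame.insert(0, "e_value_max", e_value_max)
                frames.append(frame)
    report = pd.concat(frames, ignore_index=True)
    return report.sort_values(
        ["e_value_max", "top_n", "rule", "class"], ignore_index=True
    )
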