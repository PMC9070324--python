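"""SPM specificity, hypergeometric enrichment, and threshold filters."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from conftest import make_hit
from mycosieve.community_profile import (
    call_tissue_specific,
    cazy_class,
    community_summary,
    filter_transporter_hits,
    hypergeometric_enrichment,
    spm_profile,
    summarize_secreted_cazymes,
    tissue_specificity,
)
from mycosieve.model import (
    ExpressionTable,
    Origin,
    PhylumGroup,
    TaxonCall,
)
from mycosieve.taxonomic_partition import PartitionReport

# ---------------------------------------------------------------- SPM


def test_spm_closed_forms():
    assert spm_profile({"leaf": 0, "stem": 0, "root": 10}) == pytest.approx(
        {"leaf": 0.0, "stem": 0.0, "root": 1.0}
    )
    uniform = spm_profile({"a": 1, "b": 1, "c": 1})
    assert all(v == pytest.approx(1 / math.sqrt(3)) for v in uniform.values())
    skewed = spm_profile({"leaf": 1, "stem": 0, "root": 10})
    assert skewed["root"] == pytest.approx(10 / math.sqrt(101))
    assert call_tissue_specific(skewed) == "root"


def test_spm_degenerate_inputs():
    assert spm_profile({"a": 0, "b": 0}) is None
    assert call_tissue_specific(None) is None
    with pytest.raises(ValueError):
        spm_profile({"a": -1, "b": 2})


def test_specific_call_threshold_is_strict():
    value = 0.95
    rest = math.sqrt(1 - value * value)
    assert call_tissue_specific({"a": value, "b": rest}, threshold=0.95) is None
    assert call_tissue_specific({"a": value + 1e-6, "b": rest}, threshold=0.95) == "a"


@given(
    st.lists(st.floats(0, 1000, allow_nan=False), min_size=2, max_size=6).filter(
        lambda v: sum(v) > 0
    ),
    st.floats(0.1, 100),
)
def test_spm_normalization_and_scale_invariance(values, scale):
    profile = spm_profile({f"t{i}": v for i, v in enumerate(values)})
    assert sum(v * v for v in profile.values()) == pytest.approx(1.0, abs=1e-12)
    scaled = spm_profile({f"t{i}": scale * v for i, v in enumerate(values)})
    for t in profile:
        assert scaled[t] == pytest.approx(profile[t], abs=1e-9)


def test_tissue_specificity_over_expression_table():
    tpm = pd.DataFrame(
        {
            "leaf_1": [0.0, 5.0], "leaf_2": [0.0, 5.0],
            "root_1": [10.0, 5.0], "root_2": [12.0, 5.0],
        },
        index=pd.Index(["spec", "flat"], name="transcript_id"),
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["leaf_1", "leaf_2", "root_1", "root_2"],
            "tissue": ["leaf", "leaf", "root", "root"],
            "replicate": [1, 2, 1, 2],
        }
    )
    results = {r.transcript_id: r for r in tissue_specificity(ExpressionTable(tpm, samples))}
    assert results["spec"].specific_tissue == "root"
    assert results["flat"].specific_tissue is None
    # transcripts absent from the table stay absent, not imputed zero
    missing = tissue_specificity(ExpressionTable(tpm, samples), transcripts=["ghost"])
    assert missing[0].spm is None and missing[0].specific_tissue is None


# ---------------------------------------------------------------- enrichment


def _annotations(assignments: dict[str, list[str]], source: str = "KO") -> pd.DataFrame:
    rows = [
        {"transcript_id": t, "source": source, "term": term, "score": None}
        for t, terms in assignments.items()
        for term in terms
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "source", "term", "score"])


def test_hypergeometric_worked_example():
    """N=10, K=4, n=5, k=4 -> p = C(4,4)*C(6,1)/C(10,5) = 6/252."""
    background = [f"t{i}" for i in range(10)]
    group = background[:5]
    carriers = background[:4]
    annotations = _annotations({t: ["T"] for t in carriers})
    (result,) = hypergeometric_enrichment(group, background, annotations)
    assert (result.k, result.n, result.K, result.N) == (4, 5, 4, 10)
    assert result.p_value == pytest.approx(6 / 252)
    assert result.significant


def test_hypergeometric_degenerate_tails():
    background = [f"t{i}" for i in range(8)]
    # k = 0: the whole upper tail, p = 1
    annotations = _annotations({t: ["T"] for t in background[4:]})
    (res,) = hypergeometric_enrichment(background[:4], background, annotations)
    assert res.k == 0 and res.p_value == pytest.approx(1.0)
    # k = K = n = N: single forced outcome, p = 1
    annotations = _annotations({t: ["T"] for t in background})
    (res,) = hypergeometric_enrichment(background, background, annotations)
    assert res.p_value == pytest.approx(1.0)


def test_hypergeometric_matches_enumeration_on_small_case():
    """Exhaustive enumeration over all C(N,n) draws, N=9."""
    N, K, n = 9, 4, 5
    background = [f"t{i}" for i in range(N)]
    carriers = set(background[:K])
    for k in range(0, min(n, K) + 1):
        group = background[:k] + background[K : K + (n - k)]
        assert len(group) == n
        tail = sum(
            1 for draw in combinations(range(N), n) if sum(1 for i in draw if i < K) >= k
        )
        expected = tail / math.comb(N, n)
        annotations = _annotations({t: ["T"] for t in carriers})
        (res,) = hypergeometric_enrichment(group, background, annotations)
        assert res.p_value == pytest.approx(expected)


def test_enrichment_group_must_be_subset():
    with pytest.raises(ValueError, match="subset"):
        hypergeometric_enrichment(["a"], ["b"], _annotations({"b": ["T"]}))


def test_enrichment_sorting_and_bh_correction():
    background = [f"t{i}" for i in range(40)]
    group = background[:20]
    assignments: dict[str, list[str]] = {t: [] for t in background}
    for t in background[:10]:
        assignments[t].append("enriched")  # all 10 carriers inside the group
    for i, t in enumerate(background):
        if i % 2 == 0:
            assignments[t].append("flat")
    annotations = _annotations({t: terms for t, terms in assignments.items() if terms})
    raw = hypergeometric_enrichment(group, background, annotations)
    assert [r.term for r in raw] == ["enriched", "flat"]
    assert raw[0].significant and not raw[1].significant
    bh = hypergeometric_enrichment(group, background, annotations, correction="bh")
    assert bh[0].p_adjusted >= bh[0].p_value
    assert bh[0].significant


def test_enrichment_p_nonincreasing_in_k():
    N, K, n = 30, 10, 12
    pvals = [float(hypergeom.sf(k - 1, N, K, n)) for k in range(0, min(K, n) + 1)]
    assert all(a >= b for a, b in zip(pvals, pvals[1:]))


# ---------------------------------------------------------------- filters


def test_transporter_filter_thresholds_inclusive():
    retained = filter_transporter_hits(
        {
            "keep": [make_hit(subject="2.A.1.9.2", e_value=1e-6,
                              query_length=100, alignment_length=72)],
            "low_cov": [make_hit(subject="2.A.1.9.2", e_value=1e-6,
                                 query_length=100, alignment_length=69)],
            "weak_e": [make_hit(subject="2.A.1.9.2", e_value=1e-4,
                                query_length=100, alignment_length=90)],
            "boundary": [make_hit(subject="1.A.11.3.3", e_value=1e-5,
                                  query_length=100, alignment_length=70)],
        }
    )
    assert retained == [("boundary", "1.A.11.3.3"), ("keep", "2.A.1.9.2")]


def test_transporter_filter_judges_the_best_ranked_hit():
    hits = [
        make_hit(subject="top_low_cov", e_value=1e-30, query_length=100, alignment_length=30),
        make_hit(subject="second_good", e_value=1e-20, query_length=100, alignment_length=90),
    ]
    assert filter_transporter_hits({"t": hits}) == []


def test_cazy_class_parsing():
    assert cazy_class("GH18") == "GH"
    assert cazy_class("AA9") == "AA"
    assert cazy_class("CBM1") == "CBM"
    assert cazy_class("CE1") == "CE"
    assert cazy_class("GH5_7") == "GH"
    assert cazy_class("weird") is None


def test_summarize_secreted_cazymes_rules():
    annotations = pd.DataFrame(
        [
            ("basidio_gh", "CAZY", "GH18", None),
            ("basidio_gh", "SIGNALP", "signal_peptide", 0.8),
            ("at_threshold", "CAZY", "AA9", None),
            ("at_threshold", "SIGNALP", "signal_peptide", 0.5),
            ("no_sp", "CAZY", "GH16", None),
            ("bad_family", "CAZY", "weird", None),
            ("bad_family", "SIGNALP", "signal_peptide", 0.9),
        ],
        columns=["transcript_id", "source", "term", "score"],
    )
    calls = {
        "basidio_gh": PhylumGroup.BASIDIOMYCOTA,
        "at_threshold": PhylumGroup.ASCOMYCOTA,
        "no_sp": PhylumGroup.ASCOMYCOTA,
        "bad_family": PhylumGroup.ASCOMYCOTA,
    }
    counts = summarize_secreted_cazymes(annotations, calls)
    assert counts == {("GH", PhylumGroup.BASIDIOMYCOTA): 1}


# ---------------------------------------------------------------- summary


def _partition(n_asco: int, n_basidio: int, n_aob: int, n_other: int) -> PartitionReport:
    calls = []
    spec = [
        (PhylumGroup.ASCOMYCOTA, n_asco),
        (PhylumGroup.BASIDIOMYCOTA, n_basidio),
        (PhylumGroup.ASCO_OR_BASIDIO, n_aob),
        (PhylumGroup.OTHER_FUNGI, n_other),
    ]
    i = 0
    for group, n in spec:
        for _ in range(n):
            calls.append(TaxonCall(f"f{i}", Origin.FUNGAL, group))
            i += 1
    return PartitionReport(calls=calls)


def test_community_summary_reproduces_headline_percentages():
    report = _partition(1927, 797, 19, 253)
    assert report.total_fungal == 2996
    genus = [f"f{i}" for i in range(291)]
    hsp = pd.DataFrame(
        [(f"f{i}", "HSP", "Hsp70", None) for i in range(186)],
        columns=["transcript_id", "source", "term", "score"],
    )
    summary = community_summary(report, genus, hsp)
    assert round(summary["genus_share_pct"], 1) == 9.7
    assert summary["hsp_share_pct"] == pytest.approx(100 * 186 / 2996)
    assert round(summary["phylum_share_pct"]["ASCOMYCOTA"]) == 64
    assert sum(
        summary["phylum_share_pct"][g.value]
        for g in (PhylumGroup.ASCOMYCOTA, PhylumGroup.BASIDIOMYCOTA,
                  PhylumGroup.ASCO_OR_BASIDIO, PhylumGroup.OTHER_FUNGI)
    ) == pytest.approx(100.0)


def test_community_summary_denominator_option_and_errors():
    report = _partition(100, 50, 0, 0)
    genus = [f"f{i}" for i in range(20)]
    by_fungal = community_summary(report, genus)
    by_asco = community_summary(report, genus, genus_denominator="ascomycota")
    assert by_fungal["genus_share_pct"] == pytest.approx(100 * 20 / 150)
    assert by_asco["genus_share_pct"] == pytest.approx(100 * 20 / 100)
    with pytest.raises(ValueError):
        community_summary(PartitionReport(calls=[]), [])
    # genus ids outside the fungal set do not inflate the share
    stray = community_summary(report, ["not_fungal"])
    assert stray["genus_share_pct"] == 0.0


def test_zero_assigned_gives_zero_percent():
    report = _partition(10, 0, 0, 0)
    assert community_summary(report, [])["genus_share_pct"] == 0.0
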