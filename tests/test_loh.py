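import math
import random

import pandas as pd
import pytest

from hlakit.loh import (
    ArmDefinition, CnvCategory, GeneAnnotation, PrevalencePolicy,
    SampleProfile, SegmentCall, SegmentError, amplification_threshold,
    classify_segment, gene_events, is_arm_level, load_genes, load_segments,
    loh_prevalence,
)

PROFILE = SampleProfile("S", cellularity=0.8, ploidy=2.0)


def seg(cnt, a=None, b=None, sample="S", chrom="6", start=1, end=100_000):
    return SegmentCall(sample=sample, chromosome=chrom, start=start, end=end,
                       cnt=cnt, a=a, b=b)


# ---------------------------------------------------------------------------
# Segment classification

@pytest.mark.parametrize(
    "cnt, a, b, ploidy, expected",
    [
        (1, 1, 0, 2.0, CnvCategory.LOH),
        (2, 2, 0, 2.0, CnvCategory.CN_LOH),
        (0, 0, 0, 2.0, CnvCategory.BIALLELIC_LOSS),
        (7, 7, 0, 2.0, CnvCategory.LOH_AMPLIFICATION),
        (6, 6, 0, 2.0, CnvCategory.LOH_GAIN),          # just under the bound
        (4, 4, 0, 3.0, CnvCategory.LOH_GAIN),          # 4 < 1 + 2*3
        (7, 7, 0, 3.0, CnvCategory.LOH_AMPLIFICATION), # 7 >= 1 + 2*3
        (3, 2, 1, 2.0, CnvCategory.NONE),              # minor allele retained
        (3, 3, 0, 2.0, CnvCategory.LOH_GAIN),
    ],
)
def test_classify_segment(cnt, a, b, ploidy, expected):
    profile = SampleProfile("S", cellularity=0.8, ploidy=ploidy)
    assert classify_segment(seg(cnt, a, b), profile) == expected


def test_classify_without_allele_specific_copy_numbers():
    assert classify_segment(seg(2), PROFILE) == CnvCategory.NONE
    # ...but a zero total is a biallelic loss regardless
    assert classify_segment(seg(0), PROFILE) == CnvCategory.BIALLELIC_LOSS


def test_inconsistent_allele_copy_numbers_rejected():
    with pytest.raises(SegmentError):
        seg(3, a=1, b=1)
    with pytest.raises(SegmentError):
        seg(2, a=0, b=2)  # A >= B violated


def test_ploidy_rounding_half_up():
    assert amplification_threshold(2.49) == 7
    assert amplification_threshold(2.5) == 1 + 2 * 3
    assert amplification_threshold(9.4) == 1 + 2 * 9
    assert amplification_threshold(9.5) is None
    assert amplification_threshold(1.4) is None


def brute_force_category(cnt, a, b, ploidy):
    """Independent rule transcription used as the truth-table oracle."""
    if cnt == 0:
        return CnvCategory.BIALLELIC_LOSS
    if b != 0:
        return CnvCategory.NONE
    if a == cnt == 1:
        return CnvCategory.LOH
    if a == cnt == 2:
        return CnvCategory.CN_LOH
    # a == cnt >= 3
    p = math.floor(ploidy + 0.5)
    if p == 2 and cnt >= 7:
        return CnvCategory.LOH_AMPLIFICATION
    if 3 <= p <= 9 and cnt >= 1 + 2 * p:
        return CnvCategory.LOH_AMPLIFICATION
    return CnvCategory.LOH_GAIN


def test_classification_truth_table():
    """Exhaustive agreement over all (A, B, CNt <= 12, ploidy 2-9)."""
    n = 0
    for cnt in range(0, 13):
        for b in range(0, cnt // 2 + 1):
            a = cnt - b
            for ploidy in range(2, 10):
                profile = SampleProfile("S", 0.8, float(ploidy))
                got = classify_segment(seg(cnt, a, b), profile)
                assert got == brute_force_category(cnt, a, b, float(ploidy))
                n += 1
    assert n > 300


# ---------------------------------------------------------------------------
# Loading and filtering

GENES = [
    GeneAnnotation("HLA-A", "6", 1_000_000, 1_003_000, "HLA-classI"),
    GeneAnnotation("B2M", "15", 44_711_477, 44_718_877, "B2M"),
]


def frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chromosome", "start.pos",
                                       "end.pos", "CNt", "A", "B"])


def test_load_segments_filters():
    profiles = {
        "ok": SampleProfile("ok", 0.8, 2.0),
        "low": SampleProfile("low", 0.19, 2.0),
    }
    rows = [
        ("ok", "6", 980_000, 1_029_999, 1, 1, 0),      # 50 kb, overlaps gene
        ("ok", "6", 980_000, 1_029_998, 1, 1, 0),      # 49,999 b -> size
        ("low", "6", 980_000, 1_100_000, 1, 1, 0),     # cellularity
        ("ok", "6", 5_000_000, 5_100_000, 1, 1, 0),    # no targeted gene
        ("missing", "6", 980_000, 1_100_000, 1, 1, 0), # no profile
    ]
    retained, rejected = load_segments(frame(rows), profiles, GENES)
    assert len(retained) == 1
    assert retained[0].size == 50_000
    reasons = [r for _, r in rejected]
    assert any("size" in r for r in reasons)
    assert any("cellularity" in r for r in reasons)
    assert any("gene" in r for r in reasons)
    assert any("profile" in r for r in reasons)


def test_load_segments_malformed_record_raises():
    profiles = {"ok": SampleProfile("ok", 0.8, 2.0)}
    rows = [("ok", "6", 1_100_000, 980_000, 1, 1, 0)]  # end < start
    with pytest.raises(SegmentError):
        load_segments(frame(rows), profiles, GENES)


def test_bundled_gene_fixture_loads():
    genes = load_genes()
    roles = {g.role for g in genes}
    assert {"HLA-classI", "HLA-classII", "APP", "B2M", "CIITA"} <= roles


# ---------------------------------------------------------------------------
# Gene attribution and arm level

def test_gene_events_overlap_and_precedence():
    segments = [
        (seg(1, 1, 0, start=999_000, end=1_050_000), CnvCategory.LOH),
        (seg(3, 2, 1, start=1_001_000, end=1_060_000), CnvCategory.NONE),
        (seg(1, 1, 0, chrom="15", start=1, end=60_000), CnvCategory.LOH),
    ]
    events = gene_events(segments, GENES)
    assert len(events) == 1                    # chr15 segment misses B2M
    (e,) = events
    assert e.gene == "HLA-A"
    assert e.category == CnvCategory.LOH       # any-overlap, most severe wins
    assert e.all_categories == (CnvCategory.LOH, CnvCategory.NONE)


def test_gene_events_invariant_to_segment_order():
    segments = [
        (seg(1, 1, 0, start=999_000, end=1_050_000), CnvCategory.LOH),
        (seg(2, 2, 0, start=999_500, end=1_050_500), CnvCategory.CN_LOH),
        (seg(0, 0, 0, start=1_000_500, end=1_051_000), CnvCategory.BIALLELIC_LOSS),
    ]
    forward = gene_events(segments, GENES)
    backward = gene_events(list(reversed(segments)), GENES)
    assert [(e.sample, e.gene, e.category) for e in forward] == \
           [(e.sample, e.gene, e.category) for e in backward]
    assert forward[0].category == CnvCategory.BIALLELIC_LOSS


def test_is_arm_level():
    arm = ArmDefinition("6p", "6", 1, 1_000_000)
    assert is_arm_level(seg(1, 1, 0, start=1, end=950_000), arm)          # 95%
    assert not is_arm_level(seg(1, 1, 0, start=1, end=899_000), arm)      # 89.9%
    assert is_arm_level(seg(1, 1, 0, start=1, end=1_000_000), arm)        # 100%
    assert not is_arm_level(seg(1, 1, 0, chrom="15", start=1, end=1_000_000), arm)


# ---------------------------------------------------------------------------
# Prevalence

from hlakit.loh import GeneEvent

PREV_GENES = [
    GeneAnnotation("HLA-A", "6", 1, 10, "HLA-classI"),
    GeneAnnotation("B2M", "15", 1, 10, "B2M"),
]


def test_prevalence_basic_and_homozygote_exclusion():
    samples = [f"T{i}" for i in range(10)]
    events = [
        GeneEvent("T0", "HLA-A", CnvCategory.LOH),
        GeneEvent("T1", "HLA-A", CnvCategory.CN_LOH),
    ]
    rows = {r.name: r for r in loh_prevalence(events, samples, PREV_GENES)}
    assert rows["HLA-A"].prevalence == pytest.approx(0.2)

    # two non-LOH germline homozygotes shrink the denominator to 8
    germline = {s: frozenset({"HLA-A"}) if s in ("T8", "T9") else frozenset()
                for s in samples}
    rows = {r.name: r for r in loh_prevalence(
        events, samples, PREV_GENES, germline_homozygous=germline)}
    assert rows["HLA-A"].n_denominator == 8
    assert rows["HLA-A"].prevalence == pytest.approx(2 / 8)


def test_prevalence_b2m_counting_policy():
    samples = ["T0", "T1", "T2"]
    events = [
        GeneEvent("T0", "B2M", CnvCategory.CN_LOH),          # not counted
        GeneEvent("T1", "B2M", CnvCategory.BIALLELIC_LOSS),  # counted
        GeneEvent("T2", "B2M", CnvCategory.LOH),             # counted
    ]
    rows = {r.name: r for r in loh_prevalence(events, samples, PREV_GENES)}
    assert rows["B2M"].n_events == 2


def test_prevalence_missing_germline_excludes_sample():
    events = [GeneEvent("T0", "HLA-A", CnvCategory.LOH)]
    germline = {"T0": frozenset()}          # T1 unknown at HLA genes
    rows = {r.name: r for r in loh_prevalence(
        events, ["T0", "T1"], PREV_GENES, germline_homozygous=germline)}
    assert rows["HLA-A"].n_denominator == 1
    # ...but B2M has no homozygosity concept, so both samples count
    assert rows["B2M"].n_denominator == 2


def test_prevalence_gene_sets_require_all_members():
    genes = PREV_GENES + [GeneAnnotation("HLA-B", "6", 20, 30, "HLA-classI")]
    events = [
        GeneEvent("T0", "HLA-A", CnvCategory.LOH),
        GeneEvent("T0", "HLA-B", CnvCategory.LOH),
        GeneEvent("T1", "HLA-A", CnvCategory.LOH),
    ]
    rows = {r.name: r for r in loh_prevalence(
        events, ["T0", "T1"], genes,
        gene_sets={"A+B": ("HLA-A", "HLA-B")})}
    assert rows["A+B"].n_events == 1
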