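"""Loss-of-heterozygosity classification from allele-specific copy number.

Allele-specific copy-number segments (total copy number CNt, major allele A,
minor allele B, Sequenza-style) are filtered on size, tumor cellularity and
targeted-gene content, classified into LOH categories, attributed to genes
and chromosome arms by interval overlap, and aggregated into per-gene LOH
prevalence.  All LOH categories require complete loss of the minor allele
(B = 0); "CNA" denotes the copy number of the retained (major) allele:

* biallelic loss:     CNt = 0
* LOH:                A = CNt = 1
* CN-LOH:             A = CNt = 2
* LOH + gain:         A = CNt >= 3 below the amplification threshold
* LOH + amplification: CNt >= 7 at ploidy 2, or CNt >= 1 + 2*ploidy at
  ploidy 3-9 (ploidy rounded half-up to the nearest integer)

Coordinates are 1-based inclusive internally (Sequenza convention); BED
inputs (0-based half-open) are converted on read.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

logger = logging.getLogger(__name__)


class CnvCategory:
    """Mutually exclusive per-segment CNV categories."""

    BIALLELIC_LOSS = "biallelic-loss"
    LOH = "LOH"
    CN_LOH = "CN-LOH"
    LOH_AMPLIFICATION = "LOH+amplification"
    LOH_GAIN = "LOH+gain"
    NONE = "none"


#: Most severe first; used when several segments overlap one gene.
CATEGORY_PRECEDENCE = (
    CnvCategory.BIALLELIC_LOSS,
    CnvCategory.LOH,
    CnvCategory.CN_LOH,
    CnvCategory.LOH_AMPLIFICATION,
    CnvCategory.LOH_GAIN,
    CnvCategory.NONE,
)

#: Categories counting toward LOH prevalence at HLA genes.
HLA_QUALIFYING = frozenset({
    CnvCategory.LOH,
    CnvCategory.CN_LOH,
    CnvCategory.LOH_GAIN,
    CnvCategory.LOH_AMPLIFICATION,
})

#: Restricted counting policy for B2M and CIITA.
B2M_CIITA_QUALIFYING = frozenset({
    CnvCategory.LOH,
    CnvCategory.BIALLELIC_LOSS,
})

#: Gene symbols subject to the restricted counting policy.
RESTRICTED_POLICY_GENES = frozenset({"B2M", "CIITA"})

#: Gene roles whose prevalence denominators exclude germline homozygotes.
HLA_ROLES = frozenset({"HLA-classI", "HLA-classII"})


class SegmentError(ValueError):
    """Malformed or internally inconsistent segment record."""


@dataclass(frozen=True)
class SegmentCall:
    """One allele-specific copy-number segment (1-based inclusive)."""

    sample: str
    chromosome: str
    start: int
    end: int
    cnt: int
    a: Optional[int] = None            # major-allele copy number
    b: Optional[int] = None            # minor-allele copy number

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise SegmentError(f"end {self.end} < start {self.start}")
        if self.cnt < 0:
            raise SegmentError(f"negative CNt: {self.cnt}")
        if self.a is not None and self.b is not None:
            if self.a < self.b or self.b < 0:
                raise SegmentError(f"require A >= B >= 0, got A={self.a} B={self.b}")
            if self.a + self.b != self.cnt:
                raise SegmentError(
                    f"A + B != CNt ({self.a} + {self.b} != {self.cnt})"
                )

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleProfile:
    """Sequenza-style sample context: tumor cellularity and ploidy."""

    sample: str
    cellularity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cellularity <= 1.0:
            raise ValueError(f"cellularity must be in [0, 1]: {self.cellularity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive: {self.ploidy}")


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    chromosome: str
    start: int
    end: int
    role: str = "other"                # HLA-classI | HLA-classII | APP | B2M | CIITA | other

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene}: end < start")


@dataclass(frozen=True)
class ArmDefinition:
    arm: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"arm {self.arm}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length of two 1-based inclusive intervals (0 when disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


# ---------------------------------------------------------------------------
# Fixture loaders

def load_genes(path: Union[str, Path, None] = None) -> List[GeneAnnotation]:
    """Targeted-gene annotations from a TSV (or BED with a role column).

    TSVs carry 1-based inclusive ``start``/``end``; files named ``*.bed``
    are treated as 0-based half-open and converted (logged).
    """
    if path is None:
        with resources.as_file(
            resources.files("hlakit.data").joinpath("target_genes.tsv")
        ) as p:
            return load_genes(p)
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    if is_bed:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chromosome", "start", "end", "gene", "role"],
        )
        df["start"] = df["start"] + 1  # 0-based half-open -> 1-based inclusive
        logger.info("converted BED coordinates of %s to 1-based inclusive", path)
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneAnnotation(
            gene=str(r.gene), chromosome=str(r.chromosome),
            start=int(r.start), end=int(r.end),
            role=str(getattr(r, "role", "other")),
        )
        for r in df.itertuples(index=False)
    ]


def load_arms(path: Union[str, Path, None] = None) -> List[ArmDefinition]:
    if path is None:
        with resources.as_file(
            resources.files("hlakit.data").joinpath("chromosome_arms.tsv")
        ) as p:
            return load_arms(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ArmDefinition(
            arm=str(r.arm), chromosome=str(r.chromosome),
            start=int(r.start), end=int(r.end),
        )
        for r in df.itertuples(index=False)
    ]


def load_profiles(path: Union[str, Path]) -> Dict[str, SampleProfile]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r.sample): SampleProfile(
            sample=str(r.sample),
            cellularity=float(r.cellularity),
            ploidy=float(r.ploidy),
        )
        for r in df.itertuples(index=False)
    }


# Sequenza "_segments.txt" column aliases.
_SEGMENT_ALIASES = {
    "chromosome": "chromosome", "chrom": "chromosome",
    "start.pos": "start", "start": "start",
    "end.pos": "end", "end": "end",
    "CNt": "cnt", "cnt": "cnt",
    "A": "a", "a": "a",
    "B": "b", "b": "b",
    "sample": "sample",
}


def load_segments(
    source: Union[str, Path, pd.DataFrame],
    profiles: Mapping[str, SampleProfile],
    genes: Sequence[GeneAnnotation],
    min_size: int = 50_000,
    min_cellularity: float = 0.2,
) -> Tuple[List[SegmentCall], List[Tuple[dict, str]]]:
    """Read and filter segments; returns (retained, rejection log).

    Retention requires segment size >= ``min_size`` (default 50 kb), sample
    cellularity >= ``min_cellularity`` (default 0.2) and overlap with at
    least one targeted gene.  Samples without a profile are rejected
    wholesale.  Every rejection is logged with its reason.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
    df = df.rename(columns={c: _SEGMENT_ALIASES.get(c, c) for c in df.columns})
    required = {"sample", "chromosome", "start", "end", "cnt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table is missing columns {sorted(missing)}")

    genes_by_chrom: Dict[str, List[GeneAnnotation]] = defaultdict(list)
    for g in genes:
        genes_by_chrom[g.chromosome].append(g)

    retained: List[SegmentCall] = []
    rejected: List[Tuple[dict, str]] = []
    for lineno, row in enumerate(df.to_dict("records"), start=1):
        def _reject(reason: str) -> None:
            logger.debug("segment line %d rejected: %s", lineno, reason)
            rejected.append((row, reason))

        try:
            seg = SegmentCall(
                sample=str(row["sample"]),
                chromosome=str(row["chromosome"]),
                start=int(row["start"]),
                end=int(row["end"]),
                cnt=int(row["cnt"]),
                a=None if pd.isna(row.get("a")) else int(row["a"]),
                b=None if pd.isna(row.get("b")) else int(row["b"]),
            )
        except (SegmentError, ValueError, TypeError) as exc:
            raise SegmentError(f"segment record {lineno}: {exc}") from exc

        profile = profiles.get(seg.sample)
        if profile is None:
            _reject("no sample profile")
            continue
        if profile.cellularity < min_cellularity:
            _reject(f"cellularity {profile.cellularity} < {min_cellularity}")
            continue
        if seg.size < min_size:
            _reject(f"size {seg.size} < {min_size}")
            continue
        if not any(
            _overlap(seg.start, seg.end, g.start, g.end) > 0
            for g in genes_by_chrom.get(seg.chromosome, ())
        ):
            _reject("no targeted gene overlap")
            continue
        retained.append(seg)
    logger.info(
        "segments: retained %d, rejected %d", len(retained), len(rejected)
    )
    return retained, rejected


# ---------------------------------------------------------------------------
# Classification

def amplification_threshold(ploidy: float) -> Optional[int]:
    """CNt threshold separating LOH+gain from LOH+amplification.

    7 at (rounded) ploidy 2; 1 + 2*ploidy at ploidy 3-9; undefined outside
    that range (such segments stay LOH+gain).  Fractional ploidy is rounded
    half-up first, since the rule is stated on integer ploidy.
    """
    p = math.floor(ploidy + 0.5)
    if p == 2:
        return 7
    if 3 <= p <= 9:
        return 1 + 2 * p
    return None


def classify_segment(seg: SegmentCall, profile: SampleProfile) -> str:
    """Classify one segment into a :class:`CnvCategory` value."""
    if seg.cnt == 0:
        return CnvCategory.BIALLELIC_LOSS
    if seg.a is None or seg.b is None:
        logger.debug(
            "segment %s:%d-%d lacks allele-specific copy numbers; unclassifiable",
            seg.chromosome, seg.start, seg.end,
        )
        return CnvCategory.NONE
    if seg.b >= 1:
        return CnvCategory.NONE
    # Minor allele lost from here on (B = 0, A = CNt >= 1).
    if seg.cnt == 1:
        return CnvCategory.LOH
    if seg.cnt == 2:
        return CnvCategory.CN_LOH
    threshold = amplification_threshold(profile.ploidy)
    if threshold is not None and seg.cnt >= threshold:
        return CnvCategory.LOH_AMPLIFICATION
    if threshold is None:
        logger.debug(
            "ploidy %.2f outside the 2-9 amplification rule; "
            "CNt=%d kept as LOH+gain", profile.ploidy, seg.cnt,
        )
    return CnvCategory.LOH_GAIN


@dataclass
class GeneEvent:
    """Most severe CNV category affecting one gene in one sample."""

    sample: str
    gene: str
    category: str
    all_categories: Tuple[str, ...] = ()   # audit trail over all overlapping segments


def gene_events(
    classified: Iterable[Tuple[SegmentCall, str]],
    genes: Sequence[GeneAnnotation],
) -> List[GeneEvent]:
    """Attribute segment categories to genes by any-base overlap.

    When several segments overlap one gene the most severe category wins
    (precedence: biallelic-loss > LOH > CN-LOH > LOH+amplification >
    LOH+gain > none); all overlapping categories are kept in the audit
    trail.  Invariant to segment ordering.
    """
    severity = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    hits: Dict[Tuple[str, str], List[str]] = defaultdict(list)
    for seg, category in classified:
        for g in genes:
            if g.chromosome != seg.chromosome:
                continue
            if _overlap(seg.start, seg.end, g.start, g.end) > 0:
                hits[(seg.sample, g.gene)].append(category)
    events = []
    for (sample, gene), cats in sorted(hits.items()):
        cats_sorted = tuple(sorted(cats, key=severity.__getitem__))
        events.append(
            GeneEvent(
                sample=sample, gene=gene,
                category=cats_sorted[0], all_categories=cats_sorted,
            )
        )
    return events


def is_arm_level(
    seg: SegmentCall, arm: ArmDefinition, min_fraction: float = 0.9
) -> bool:
    """True iff the segment covers >= ``min_fraction`` of the arm length."""
    if seg.chromosome != arm.chromosome:
        return False
    return _overlap(seg.start, seg.end, arm.start, arm.end) / arm.length >= min_fraction


# ---------------------------------------------------------------------------
# Prevalence

@dataclass(frozen=True)
class PrevalencePolicy:
    """Counting policy for per-gene LOH prevalence.

    HLA genes count any of {LOH, CN-LOH, LOH+gain, LOH+amplification} and
    exclude germline-homozygous patients from both numerator and
    denominator; B2M and CIITA count only {LOH, biallelic-loss}.
    """

    hla_categories: frozenset = HLA_QUALIFYING
    restricted_categories: frozenset = B2M_CIITA_QUALIFYING
    restricted_genes: frozenset = RESTRICTED_POLICY_GENES


@dataclass
class PrevalenceRow:
    name: str                           # gene or gene-set label
    n_events: int
    n_denominator: int

    @property
    def prevalence(self) -> float:
        return self.n_events / self.n_denominator if self.n_denominator else 0.0


def _qualifies(gene: str, role: str, category: str, policy: PrevalencePolicy) -> bool:
    if gene in policy.restricted_genes:
        return category in policy.restricted_categories
    return category in policy.hla_categories


def loh_prevalence(
    events: Iterable[GeneEvent],
    evaluable_samples: Sequence[str],
    genes: Sequence[GeneAnnotation],
    germline_homozygous: Optional[Mapping[str, frozenset]] = None,
    gene_sets: Optional[Mapping[str, Sequence[str]]] = None,
    policy: PrevalencePolicy = PrevalencePolicy(),
) -> List[PrevalenceRow]:
    """Per-gene (and per-gene-set) LOH prevalence over evaluable tumors.

    ``germline_homozygous`` maps each sample to the set of HLA gene symbols
    at which the patient is germline homozygous; those samples are excluded
    from that gene's denominator (LOH cannot be observed without two
    germline alleles).  Samples missing from the mapping while it is
    provided are treated as unknown at HLA genes and excluded (logged).
    Multi-gene sets count tumors with qualifying events at every listed
    gene; their denominator excludes samples homozygous (or unknown) at any
    HLA gene of the set.
    """
    events = list(events)
    by_sample_gene: Dict[Tuple[str, str], str] = {
        (e.sample, e.gene): e.category for e in events
    }
    role_of = {g.gene: g.role for g in genes}
    samples = list(evaluable_samples)

    def _excluded(sample: str, gene: str) -> bool:
        if role_of.get(gene, "other") not in HLA_ROLES:
            return False
        if germline_homozygous is None:
            return False
        if sample not in germline_homozygous:
            logger.debug(
                "sample %s lacks germline genotype for %s; excluded", sample, gene
            )
            return True
        return gene in germline_homozygous[sample]

    def _has_event(sample: str, gene: str) -> bool:
        category = by_sample_gene.get((sample, gene), CnvCategory.NONE)
        return _qualifies(gene, role_of.get(gene, "other"), category, policy)

    rows: List[PrevalenceRow] = []
    for g in genes:
        denom = [s for s in samples if not _excluded(s, g.gene)]
        n_events = sum(_has_event(s, g.gene) for s in denom)
        rows.append(PrevalenceRow(g.gene, n_events, len(denom)))

    for label, members in (gene_sets or {}).items():
        denom = [
            s for s in samples
            if not any(_excluded(s, gene) for gene in members)
        ]
        n_events = sum(
            all(_has_event(s, gene) for gene in members) for s in denom
        )
        rows.append(PrevalenceRow(label, n_events, len(denom)))
    return rows
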