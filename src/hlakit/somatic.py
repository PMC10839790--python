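"""Tumor/normal somatic variant filtering over antigen-presentation genes.

A variant passes when it is effectively absent from the matched normal
(fewer than 4 supporting reads AND variant allele fraction below 0.06) and
well supported in the tumor (more than 3 supporting reads AND VAF of at
least 0.15).  Passing variants are restricted to a configurable gene set —
by default the 78 antigen processing and presentation genes of KEGG pathway
hsa04612 — and summarized per tumor.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

logger = logging.getLogger(__name__)

CONSEQUENCE_CLASSES = (
    "missense", "nonsense", "frameshift", "splice-site", "silent", "other",
)

#: Consequences counted as non-silent (splice-site included).
NON_SILENT = frozenset({"missense", "nonsense", "frameshift", "splice-site", "other"})


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant with paired tumor/normal read support."""

    sample: str
    gene: str
    consequence: str
    normal_alt: Optional[int]
    normal_vaf: Optional[float]        # fraction of mutated reads in the normal
    tumor_alt: Optional[int]
    tumor_vaf: Optional[float]
    qual_pass: bool = True             # upstream caller quality flag

    def __post_init__(self) -> None:
        for name in ("normal_vaf", "tumor_vaf"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]: {v}")
        for name in ("normal_alt", "tumor_alt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0: {v}")


@dataclass(frozen=True)
class FilterThresholds:
    """Read-count and VAF thresholds; defaults mirror the standard rule.

    Normal: alt reads strictly below ``normal_max_alt`` and VAF strictly
    below ``normal_max_vaf``.  Tumor: alt reads strictly above
    ``tumor_min_alt`` and VAF at or above ``tumor_min_vaf`` (inclusive).
    """

    normal_max_alt: int = 4            # pass iff normal alt < 4
    normal_max_vaf: float = 0.06       # pass iff normal VAF < 0.06
    tumor_min_alt: int = 3             # pass iff tumor alt > 3
    tumor_min_vaf: float = 0.15        # pass iff tumor VAF >= 0.15


def variant_passes(
    rec: VariantRecord, thresholds: FilterThresholds = FilterThresholds()
) -> Tuple[bool, List[str]]:
    """Evaluate the four-condition filter; returns (passed, failed reasons).

    All four conditions are conjunctive.  Records failing the upstream
    quality flag or with missing counts fail with an explicit reason.
    """
    failed: List[str] = []
    if not rec.qual_pass:
        return False, ["upstream-quality"]
    if any(
        v is None
        for v in (rec.normal_alt, rec.normal_vaf, rec.tumor_alt, rec.tumor_vaf)
    ):
        return False, ["missing-data"]
    if not rec.normal_alt < thresholds.normal_max_alt:
        failed.append("normal-alt-reads")
    if not rec.normal_vaf < thresholds.normal_max_vaf:
        failed.append("normal-vaf")
    if not rec.tumor_alt > thresholds.tumor_min_alt:
        failed.append("tumor-alt-reads")
    if not rec.tumor_vaf >= thresholds.tumor_min_vaf:
        failed.append("tumor-vaf")
    return not failed, failed


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols with a provenance label."""

    genes: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be non-empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], label: str = "") -> "GeneSet":
        """Read a TSV with a ``gene`` column (extra columns ignored)."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        genes = [str(g) for g in df["gene"]]
        if len(genes) != len(set(genes)):
            raise ValueError("gene set contains duplicate symbols")
        return cls(genes=frozenset(genes), label=label or str(path))

    @classmethod
    def app_kegg(cls) -> "GeneSet":
        """The bundled antigen processing and presentation gene set
        (KEGG pathway hsa04612, 78 genes)."""
        with resources.as_file(
            resources.files("hlakit.data").joinpath("app_genes_kegg_hsa04612.tsv")
        ) as p:
            return cls.from_tsv(p, label="KEGG hsa04612")


@dataclass
class TumorSummary:
    """Per-tumor mutation burden over the gene set."""

    sample: str
    n_variants: int = 0
    genes: List[str] = field(default_factory=list)
    max_vaf: Optional[float] = None
    median_vaf: Optional[float] = None


def summarize_somatic(
    records: Iterable[VariantRecord],
    genes: Optional[GeneSet] = None,
    include_silent: bool = False,
    thresholds: FilterThresholds = FilterThresholds(),
) -> Dict[str, TumorSummary]:
    """Filter, restrict to the gene set, and summarize burden per tumor.

    Silent variants are excluded unless ``include_silent``.  Returns only
    tumors with at least one retained variant.
    """
    genes = genes or GeneSet.app_kegg()
    kept: Dict[str, List[VariantRecord]] = {}
    for rec in records:
        passed, _ = variant_passes(rec, thresholds)
        if not passed:
            continue
        if rec.gene not in genes:
            continue
        if not include_silent and rec.consequence not in NON_SILENT:
            continue
        kept.setdefault(rec.sample, []).append(rec)

    summaries: Dict[str, TumorSummary] = {}
    for sample, recs in sorted(kept.items()):
        vafs = [r.tumor_vaf for r in recs if r.tumor_vaf is not None]
        summaries[sample] = TumorSummary(
            sample=sample,
            n_variants=len(recs),
            genes=sorted({r.gene for r in recs}),
            max_vaf=max(vafs) if vafs else None,
            median_vaf=statistics.median(vafs) if vafs else None,
        )
    return summaries
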