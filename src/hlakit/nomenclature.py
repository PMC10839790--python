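"""HLA allele nomenclature at two-field ("4-digit") resolution.

HLA alleles are named ``LOCUS*field1:field2`` with optional higher-resolution
fields and an optional single-letter expression suffix (N null, L low,
S secreted, Q questionable).  All comparisons in this package happen at
two-field (protein-level) resolution; higher-resolution fields on input are
truncated.  G groups — sets of alleles sharing identical nucleotide sequence
across the exons encoding the peptide-binding domains, and therefore
indistinguishable to many typing methods — are supported through a
user-supplied table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Tuple, Union

logger = logging.getLogger(__name__)

#: Closed set of loci this package understands.
LOCI: Tuple[str, ...] = (
    "A", "B", "C",
    "DRB1", "DRB3", "DRB4", "DRB5",
    "DQA1", "DQB1", "DPA1", "DPB1",
    "E", "F", "G",
)

#: The eight classical loci for which consensus genotypes are established.
CLASSICAL_LOCI: Tuple[str, ...] = (
    "A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1",
)

#: Canonical locus ordering used when rendering multilocus haplotypes.
LOCUS_ORDER: Tuple[str, ...] = (
    "A", "B", "C",
    "DRB1", "DRB3", "DRB4", "DRB5",
    "DQA1", "DQB1", "DPA1", "DPB1",
    "E", "F", "G",
)

EXPRESSION_SUFFIXES = frozenset("NLSQ")

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>[A-Z]+[0-9]*)\*"
    r"(?P<f1>\d+):(?P<f2>\d+)"
    r"(?P<rest>(?::\d+)*)"
    r"(?P<suffix>[NLSQ]?)$"
)

AlleleKey = Tuple[str, int, int]


class AlleleParseError(ValueError):
    """Raised when an allele name cannot be parsed."""


@dataclass(frozen=True, order=True)
class Allele:
    """One HLA allele at two-field resolution.

    ``field1`` is the allele group, ``field2`` the protein number.  The
    expression ``suffix`` (e.g. the N of the null allele DRB4*01:03N) is
    preserved in storage but ignored by default in matching, because the
    typing tools the consensus rule integrates cannot discriminate it.
    """

    locus: str
    field1: int
    field2: int
    suffix: str = ""
    raw: str = field(default="", compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unknown HLA locus: {self.locus!r}")
        if self.field1 < 1 or self.field2 < 1:
            raise AlleleParseError(
                f"allele fields must be >= 1, got {self.field1}:{self.field2}"
            )
        if self.suffix and self.suffix not in EXPRESSION_SUFFIXES:
            raise AlleleParseError(f"unknown expression suffix: {self.suffix!r}")

    @property
    def name(self) -> str:
        """Normalized two-field name, e.g. ``A*02:01`` or ``DRB4*01:03N``."""
        return f"{self.locus}*{self.field1:02d}:{self.field2:02d}{self.suffix}"

    def key(self, ignore_suffix: bool = True) -> tuple:
        """Hashable comparison key at two-field resolution."""
        if ignore_suffix:
            return (self.locus, self.field1, self.field2)
        return (self.locus, self.field1, self.field2, self.suffix)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def parse_allele(text: str) -> Allele:
    """Parse an allele name into a normalized two-field :class:`Allele`.

    Accepts both ``HLA-A*02:01`` and ``A*02:01`` dialects.  Fields beyond the
    second (e.g. synonymous or intronic fields) are discarded with a log
    notice.

    Raises
    ------
    AlleleParseError
        If the text is malformed or names a locus outside the closed set.
    """
    if not isinstance(text, str):
        raise AlleleParseError(f"allele name must be a string, got {text!r}")
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise AlleleParseError(f"malformed HLA allele name: {text!r}")
    locus = m.group("locus")
    if locus not in LOCI:
        raise AlleleParseError(f"unknown HLA locus {locus!r} in {text!r}")
    if m.group("rest"):
        logger.debug(
            "truncating %r to 2-field resolution (discarded %r)",
            text, m.group("rest"),
        )
    return Allele(
        locus=locus,
        field1=int(m.group("f1")),
        field2=int(m.group("f2")),
        suffix=m.group("suffix"),
        raw=text,
    )


class GGroupTable:
    """Partition of two-field alleles into G groups.

    Alleles absent from the table form their own singleton group, so the
    mapping is always a partition of the allele universe.
    """

    def __init__(self, mapping: Mapping[AlleleKey, str] | None = None) -> None:
        self._groups: dict[AlleleKey, str] = dict(mapping or {})

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "GGroupTable":
        """Build from (locus, allele-name, g_group) triples."""
        mapping: dict[AlleleKey, str] = {}
        for locus, allele_text, group in records:
            allele = parse_allele(
                allele_text if "*" in allele_text else f"{locus}*{allele_text}"
            )
            if allele.locus != locus:
                raise ValueError(
                    f"locus column {locus!r} disagrees with allele {allele_text!r}"
                )
            mapping[allele.key()] = group
        return cls(mapping)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "GGroupTable":
        """Read a TSV with columns ``locus``, ``allele``, ``g_group``."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"locus", "allele", "g_group"}
        if not required.issubset(df.columns):
            raise ValueError(f"G-group table must have columns {sorted(required)}")
        return cls.from_records(
            df[["locus", "allele", "g_group"]].itertuples(index=False, name=None)
        )

    @classmethod
    def bundled(cls) -> "GGroupTable":
        """The small G-group fixture shipped with the package."""
        with resources.as_file(
            resources.files("hlakit.data").joinpath("g_groups.tsv")
        ) as p:
            return cls.from_tsv(p)

    def group_of(self, allele: Allele) -> str:
        """G-group identifier; singleton alleles map to their own name."""
        return self._groups.get(allele.key(), allele.key(True).__repr__())

    def same_group(self, a: Allele, b: Allele) -> bool:
        return self.group_of(a) == self.group_of(b)

    def __len__(self) -> int:
        return len(self._groups)


def alleles_equivalent(
    a: Allele,
    b: Allele,
    mode: str = "ignore-suffix",
    g: Optional[GGroupTable] = None,
) -> bool:
    """Compare two alleles of the same locus.

    Modes:

    ``exact``
        (field1, field2, suffix) must all agree.
    ``ignore-suffix``
        expression suffix dropped; the default, because e.g. DRB4*01:03N
        cannot be discriminated from DRB4*01:03 by the typing tools.
    ``g-group``
        true iff both alleles belong to the same G group (requires ``g``).
    """
    if a.locus != b.locus:
        raise ValueError(f"locus mismatch: {a.locus} vs {b.locus}")
    if mode == "exact":
        return a.key(ignore_suffix=False) == b.key(ignore_suffix=False)
    if mode == "ignore-suffix":
        return a.key() == b.key()
    if mode == "g-group":
        if g is None:
            raise ValueError("g-group mode requires a GGroupTable")
        return g.same_group(a, b)
    raise ValueError(f"unknown comparison mode: {mode!r}")


def locus_sort_key(locus: str) -> int:
    """Index of a locus in the canonical ordering."""
    return LOCUS_ORDER.index(locus)
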