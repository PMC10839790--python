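"""Multilocus haplotype inference and classification.

Unphased multilocus genotypes are compatible with several haplotype pairs
(diplotypes).  This module enumerates those pairs, estimates haplotype
frequencies from a cohort with the classic expectation-maximization (EM)
algorithm for phase-ambiguous genotypes, assigns each individual its most
likely diplotype against a reference haplotype-frequency table, classifies
assigned haplotypes as known / variant / unknown relative to the reference,
and resolves DRB1–DRB3/4/5 combinations from the strong linkage between
DRB1 allele groups and the secondary DRB loci.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .nomenclature import Allele, GGroupTable, locus_sort_key, parse_allele

logger = logging.getLogger(__name__)

# A multilocus genotype: locus -> 1 or 2 alleles (unordered).
Genotype = Mapping[str, Tuple[Allele, ...]]

HapKey = Tuple[tuple, ...]  # one allele key per locus


@dataclass(frozen=True, order=True)
class Haplotype:
    """Ordered tuple of alleles, one per locus of a named locus set."""

    alleles: Tuple[Allele, ...]
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        loci = [a.locus for a in self.alleles]
        if len(set(loci)) != len(loci):
            raise ValueError(f"haplotype has duplicate loci: {loci}")
        ordered = sorted(self.alleles, key=lambda a: locus_sort_key(a.locus))
        if tuple(ordered) != self.alleles:
            object.__setattr__(self, "alleles", tuple(ordered))

    @property
    def loci(self) -> Tuple[str, ...]:
        return tuple(a.locus for a in self.alleles)

    def key(self) -> HapKey:
        return tuple(a.key() for a in self.alleles)

    @property
    def name(self) -> str:
        return "~".join(a.name for a in self.alleles)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class Diplotype:
    """Unordered haplotype pair with its assignment weight."""

    h1: Haplotype
    h2: Haplotype
    weight: float = 1.0
    rank: int = 0

    def key(self) -> Tuple[HapKey, HapKey]:
        k1, k2 = sorted((self.h1.key(), self.h2.key()))
        return (k1, k2)


def canonical_loci(genotype: Genotype) -> Tuple[str, ...]:
    return tuple(sorted(genotype, key=locus_sort_key))


def enumerate_diplotypes(genotype: Genotype) -> List[Diplotype]:
    """All unordered haplotype pairs compatible with an unphased genotype.

    For H >= 1 heterozygous loci there are exactly 2**(H-1) unordered pairs
    (one phase bit per heterozygous locus, modulo swapping the pair); a fully
    homozygous genotype yields a single pair of identical haplotypes.
    """
    if not genotype:
        raise ValueError("empty genotype")
    loci = canonical_loci(genotype)
    per_locus: List[Tuple[Tuple[Allele, Allele], ...]] = []
    for locus in loci:
        alleles = tuple(genotype[locus])
        if not 1 <= len(alleles) <= 2:
            raise ValueError(f"locus {locus} must carry 1 or 2 alleles")
        if len(alleles) == 1 or alleles[0].key() == alleles[1].key():
            a = alleles[0]
            per_locus.append(((a, a),))
        else:
            a, b = alleles
            per_locus.append(((a, b), (b, a)))

    seen = set()
    out: List[Diplotype] = []
    for assignment in itertools.product(*per_locus):
        h1 = Haplotype(tuple(pair[0] for pair in assignment))
        h2 = Haplotype(tuple(pair[1] for pair in assignment))
        key = tuple(sorted((h1.key(), h2.key())))
        if key in seen:
            continue
        seen.add(key)
        out.append(Diplotype(h1, h2))
    weight = 1.0 / len(out)
    for d in out:
        d.weight = weight
    return out


class HaplotypeFrequencyTable:
    """Reference haplotypes with population frequencies.

    Frequencies are fractions of chromosomes; published tables are often
    truncated, so the total mass may be below 1 (logged on load).
    """

    def __init__(
        self,
        loci: Sequence[str],
        frequencies: Mapping[HapKey, float],
        haplotypes: Mapping[HapKey, Haplotype] | None = None,
        labels: Mapping[HapKey, str] | None = None,
        population: str = "",
    ) -> None:
        self.loci = tuple(loci)
        self.frequencies: Dict[HapKey, float] = dict(frequencies)
        self.haplotypes: Dict[HapKey, Haplotype] = dict(haplotypes or {})
        self.labels: Dict[HapKey, str] = dict(labels or {})
        self.population = population
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("haplotype frequencies must be >= 0")
        mass = self.total_mass()
        if mass > 1 + 1e-6:
            raise ValueError(f"haplotype frequencies sum to {mass:.6f} > 1")
        logger.debug("haplotype table covers %.4f of chromosome mass", mass)

    def total_mass(self) -> float:
        return float(sum(self.frequencies.values()))

    def get(self, h: Union[Haplotype, HapKey], default: float = 0.0) -> float:
        key = h.key() if isinstance(h, Haplotype) else h
        return self.frequencies.get(key, default)

    def __len__(self) -> int:
        return len(self.frequencies)

    def __iter__(self):
        return iter(self.frequencies.items())

    @classmethod
    def from_haplotypes(
        cls,
        pairs: Iterable[Tuple[Haplotype, float]],
        population: str = "",
    ) -> "HaplotypeFrequencyTable":
        haps = list(pairs)
        if not haps:
            raise ValueError("empty haplotype table")
        loci = haps[0][0].loci
        freqs, keep, labels = {}, {}, {}
        for rank, (h, f) in enumerate(haps, start=1):
            if h.loci != loci:
                raise ValueError("all haplotypes must share a locus set")
            freqs[h.key()] = f
            keep[h.key()] = h
            labels[h.key()] = h.label or str(rank)
        return cls(loci, freqs, keep, labels, population)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], population: str = "") -> "HaplotypeFrequencyTable":
        """Read a TSV with columns ``rank``, one column per locus, ``frequency``."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        locus_cols = [c for c in df.columns if c not in ("rank", "frequency")]
        pairs = []
        for _, row in df.iterrows():
            alleles = tuple(
                parse_allele(row[c] if "*" in str(row[c]) else f"{c}*{row[c]}")
                for c in locus_cols
            )
            pairs.append(
                (Haplotype(alleles, label=str(row.get("rank", ""))),
                 float(row["frequency"]))
            )
        return cls.from_haplotypes(pairs, population=population)

    def to_tsv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        rows = []
        for key, freq in sorted(
            self.frequencies.items(), key=lambda kv: -kv[1]
        ):
            hap = self.haplotypes.get(key)
            row = {"rank": self.labels.get(key, "")}
            if hap is not None:
                for a in hap.alleles:
                    row[a.locus] = a.name
            row["frequency"] = freq
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class EMResult:
    """Outcome of EM haplotype-frequency estimation."""

    table: HaplotypeFrequencyTable
    log_likelihood: float
    n_iterations: int
    converged: bool
    log_likelihood_trace: List[float] = field(default_factory=list)


def em_frequencies(
    genotypes: Sequence[Genotype],
    tol: float = 1e-8,
    max_iter: int = 10_000,
    prune: float = 1e-12,
) -> EMResult:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    E-step: each compatible pair (h1, h2) of individual i receives weight
    f(h1) f(h2) (times 2 when h1 != h2 for the two orderings), normalized per
    individual.  M-step: f(h) is the expected count of h over 2N chromosomes.
    Initialization is uniform over the haplotypes compatible with at least
    one individual (deterministic, no seed required).  The log-likelihood is
    checked to be non-decreasing at every iteration; convergence is declared
    when the max absolute frequency change drops below ``tol``.
    """
    if not genotypes:
        raise ValueError("em_frequencies requires at least one genotype")
    locus_sets = {canonical_loci(g) for g in genotypes}
    if len(locus_sets) != 1:
        raise ValueError(f"genotypes must share one locus set, got {locus_sets}")
    (loci,) = locus_sets

    # Pre-enumerate compatible pairs once; EM only reweights them.
    individuals: List[List[Tuple[HapKey, HapKey]]] = []
    hap_objects: Dict[HapKey, Haplotype] = {}
    for g in genotypes:
        pairs = []
        for d in enumerate_diplotypes(g):
            k1, k2 = d.h1.key(), d.h2.key()
            hap_objects.setdefault(k1, d.h1)
            hap_objects.setdefault(k2, d.h2)
            pairs.append((k1, k2))
        individuals.append(pairs)

    haps = sorted(hap_objects)
    freq: Dict[HapKey, float] = {h: 1.0 / len(haps) for h in haps}
    n_chrom = 2 * len(genotypes)

    trace: List[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        counts: Dict[HapKey, float] = {h: 0.0 for h in haps}
        loglik = 0.0
        for pairs in individuals:
            weights = [
                freq[k1] * freq[k2] * (2.0 if k1 != k2 else 1.0)
                for k1, k2 in pairs
            ]
            total = sum(weights)
            if total <= 0.0:
                # All compatible haplotypes pruned to zero; re-seed uniformly.
                weights = [1.0] * len(pairs)
                total = float(len(pairs))
            loglik += math.log(total)
            for (k1, k2), w in zip(pairs, weights):
                share = w / total
                counts[k1] += share
                counts[k2] += share
        if trace and loglik < trace[-1] - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased: {trace[-1]} -> {loglik}"
            )
        trace.append(loglik)
        new_freq = {h: counts[h] / n_chrom for h in haps}
        delta = max(abs(new_freq[h] - freq[h]) for h in haps)
        freq = new_freq
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)

    kept = {h: f for h, f in freq.items() if f >= prune}
    mass = sum(kept.values())
    kept = {h: f / mass for h, f in kept.items()}
    table = HaplotypeFrequencyTable(
        loci,
        kept,
        haplotypes={h: hap_objects[h] for h in kept},
        labels={h: str(i) for i, h in enumerate(
            sorted(kept, key=lambda k: -kept[k]), start=1)},
    )
    return EMResult(
        table=table,
        log_likelihood=trace[-1],
        n_iterations=n_iter,
        converged=converged,
        log_likelihood_trace=trace,
    )


@dataclass
class DiplotypeRanking:
    """Full ranking of compatible pairs for one genotype."""

    ranked: List[Diplotype]
    ambiguous: bool

    @property
    def best(self) -> Diplotype:
        return self.ranked[0]


def most_likely_diplotype(
    genotype: Genotype,
    ref: HaplotypeFrequencyTable,
    epsilon: float = 1e-9,
) -> DiplotypeRanking:
    """Rank compatible diplotypes by reference-frequency likelihood.

    Each pair scores f(h1) f(h2) (times 2 when heterozygous); haplotypes
    absent from the reference receive the pseudo-frequency ``epsilon`` so
    every pair remains scoreable.  Ties are flagged ambiguous and broken by
    lexicographic haplotype order for determinism.
    """
    diplotypes = enumerate_diplotypes(genotype)
    scored = []
    for d in diplotypes:
        f1 = ref.get(d.h1, epsilon)
        f2 = ref.get(d.h2, epsilon)
        score = f1 * f2 * (2.0 if d.h1.key() != d.h2.key() else 1.0)
        scored.append((score, d))
    scored.sort(key=lambda sd: (-sd[0], sd[1].key()))
    total = sum(s for s, _ in scored)
    ranked = []
    for rank, (score, d) in enumerate(scored, start=1):
        d.weight = score / total if total > 0 else 1.0 / len(scored)
        d.rank = rank
        ranked.append(d)
    ambiguous = len(ranked) > 1 and math.isclose(
        scored[0][0], scored[1][0], rel_tol=0.0, abs_tol=0.0
    )
    return DiplotypeRanking(ranked=ranked, ambiguous=ambiguous)


@dataclass
class HaplotypeClass:
    """Classification of a haplotype against the reference table."""

    kind: str                          # known | variant | unknown
    reference_label: str = ""
    divergent_locus: Optional[str] = None
    suffix: str = ""
    g_group: bool = False

    @property
    def label(self) -> str:
        return f"{self.reference_label}{self.suffix}"


class VariantRegistry:
    """Assigns variant suffix letters (b, c, d, ...) in discovery order.

    The reference haplotype itself is implicitly suffix "a"; the first
    variant discovered against a given reference gets "b", the next "c",
    and a re-seen variant keeps its letter.
    """

    def __init__(self) -> None:
        self._by_ref: Dict[str, List[HapKey]] = {}

    def suffix_for(self, reference_label: str, hap_key: HapKey) -> str:
        seen = self._by_ref.setdefault(reference_label, [])
        if hap_key not in seen:
            seen.append(hap_key)
        index = seen.index(hap_key)
        return chr(ord("b") + index)


def classify_haplotype(
    h: Haplotype,
    ref: HaplotypeFrequencyTable,
    g: Optional[GGroupTable] = None,
    registry: Optional[VariantRegistry] = None,
) -> HaplotypeClass:
    """Classify a haplotype as known, variant, or unknown.

    A haplotype identical to a reference entry at two-field resolution at
    every locus is known.  One diverging from its closest reference at
    exactly one locus is a variant, labeled with that reference's number
    plus the next free suffix letter; divergence only by G-group membership
    still counts as a variant (flagged).  At least two divergent loci from
    every reference → unknown.  Distance-1 ties among references are broken
    toward the highest-frequency reference.
    """
    if h.loci != ref.loci:
        raise ValueError(
            f"haplotype loci {h.loci} do not match reference loci {ref.loci}"
        )
    if len(ref) == 0:
        logger.warning("empty reference table: every haplotype is unknown")
        return HaplotypeClass(kind="unknown")

    key = h.key()
    if key in ref.frequencies:
        return HaplotypeClass(kind="known", reference_label=ref.labels.get(key, ""))

    best: Optional[Tuple[int, float, HapKey, int]] = None  # (dist, -freq, refkey, locus_idx)
    for ref_key, freq in ref.frequencies.items():
        divergent = [i for i, (a, b) in enumerate(zip(key, ref_key)) if a != b]
        cand = (len(divergent), -freq, ref_key, divergent[0] if divergent else -1)
        if best is None or cand[:2] < best[:2]:
            best = cand
    assert best is not None
    distance, _, ref_key, locus_idx = best
    if distance != 1:
        return HaplotypeClass(kind="unknown")

    locus = ref.loci[locus_idx]
    ref_label = ref.labels.get(ref_key, "")
    g_flag = False
    if g is not None:
        own = h.alleles[locus_idx]
        ref_hap = ref.haplotypes.get(ref_key)
        if ref_hap is not None:
            g_flag = g.same_group(own, ref_hap.alleles[locus_idx])
    registry = registry or VariantRegistry()
    return HaplotypeClass(
        kind="variant",
        reference_label=ref_label,
        divergent_locus=locus,
        suffix=registry.suffix_for(ref_label, key),
        g_group=g_flag,
    )


# ---------------------------------------------------------------------------
# DRB1–DRB3/4/5 linkage

#: Rendered label per DR haplotype group.
DR_GROUP_LABELS = {
    "DR1": "DRB1",
    "DR8": "DRB1",
    "DR51": "DRB1-DRB5",
    "DR52": "DRB1-DRB3",
    "DR53": "DRB1-DRB4",
}


class UnresolvedLinkageError(KeyError):
    """A DRB1 allele group has no entry in the linkage table."""


class Drb345LinkageTable:
    """Maps DRB1 allele groups (field1) to DR haplotype groups.

    DR1 and DR8 haplotypes carry DRB1 alone; DR51/DR52/DR53 haplotypes carry
    an additional DRB5, DRB3 or DRB4 gene respectively.
    """

    def __init__(self, mapping: Mapping[int, str]) -> None:
        unknown = set(mapping.values()) - set(DR_GROUP_LABELS)
        if unknown:
            raise ValueError(f"unknown DR haplotype groups: {sorted(unknown)}")
        self._mapping = dict(mapping)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "Drb345LinkageTable":
        """Read a TSV with columns ``drb1_group`` (field1 int) and ``dr_group``."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(dict(zip(df["drb1_group"].astype(int), df["dr_group"])))

    @classmethod
    def bundled(cls) -> "Drb345LinkageTable":
        with resources.as_file(
            resources.files("hlakit.data").joinpath("drb345_linkage.tsv")
        ) as p:
            return cls.from_tsv(p)

    def group_of(self, drb1_allele: Allele) -> str:
        if drb1_allele.locus != "DRB1":
            raise ValueError(f"expected a DRB1 allele, got {drb1_allele.name}")
        try:
            return self._mapping[drb1_allele.field1]
        except KeyError:
            raise UnresolvedLinkageError(
                f"no DR haplotype group for DRB1*{drb1_allele.field1:02d}"
            ) from None


def resolve_drb345(
    drb1_genotype: Tuple[Allele, Allele],
    table: Optional[Drb345LinkageTable] = None,
) -> str:
    """Render the DRB1–DRB3/4/5 combination label for a DRB1 genotype.

    e.g. DRB1*03:01 / DRB1*07:01 (DR52 + DR53) → ``DRB1-DRB3/DRB1-DRB4``.

    Raises :class:`UnresolvedLinkageError` when an allele group is missing
    from the table; callers flag the patient unresolved.
    """
    table = table or Drb345LinkageTable.bundled()
    labels = sorted(
        DR_GROUP_LABELS[table.group_of(a)] for a in drb1_genotype
    )
    return "/".join(labels)
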