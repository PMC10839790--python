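"""Cohort-level allele frequencies, homozygosity, screening and ancestry.

Allele frequencies are occurrence counts over chromosomes (2N); homozygosity
is judged on the two-field, suffix-insensitive consensus genotype (a single
detected allele counts as a putative homozygote).  The over/under-
representation screen compares patient frequencies against published
control frequencies with three criteria on the frequency ratio RA
(patients / controls).  Ancestry assignment applies a simple fraction
threshold over the five continental superpopulations.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from .nomenclature import Allele

logger = logging.getLogger(__name__)

SUPERPOPULATIONS = ("EUR", "AFR", "AMR", "EAS", "SAS")

# A per-locus cohort: patient -> unordered allele pair, or None when the
# consensus is unresolved (excluded from denominators, count logged).
LocusCohort = Mapping[str, Optional[Tuple[Allele, Allele]]]


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies: occurrences / chromosomes."""

    locus: str
    frequencies: Dict[tuple, float]    # allele key -> frequency
    counts: Dict[tuple, int] = field(default_factory=dict)
    n_chromosomes: int = 0
    n_excluded: int = 0
    cohort: str = ""
    names: Dict[tuple, str] = field(default_factory=dict)

    def get(self, allele: Allele, default: float = 0.0) -> float:
        return self.frequencies.get(allele.key(), default)


def allele_frequencies(
    cohort: LocusCohort, locus: str, label: str = ""
) -> AlleleFrequencyTable:
    """Count allele occurrences over 2N chromosomes of consensus genotypes.

    Homozygotes contribute 2 occurrences.  Individuals without a consensus
    genotype (None) are excluded and counted in ``n_excluded``.
    """
    counts: Counter = Counter()
    names: Dict[tuple, str] = {}
    n_included = 0
    n_excluded = 0
    for patient, genotype in cohort.items():
        if genotype is None:
            n_excluded += 1
            continue
        if len(genotype) != 2:
            raise ValueError(f"patient {patient}: genotype must be an allele pair")
        for a in genotype:
            if a.locus != locus:
                raise ValueError(
                    f"patient {patient}: allele {a.name} is not at locus {locus}"
                )
            counts[a.key()] += 1
            names.setdefault(a.key(), a.name)
        n_included += 1
    if n_excluded:
        logger.info("locus %s: excluded %d unresolved individuals", locus, n_excluded)
    n_chromosomes = 2 * n_included
    freqs = {
        k: c / n_chromosomes for k, c in counts.items()
    } if n_chromosomes else {}
    return AlleleFrequencyTable(
        locus=locus,
        frequencies=freqs,
        counts=dict(counts),
        n_chromosomes=n_chromosomes,
        n_excluded=n_excluded,
        cohort=label,
        names=names,
    )


def is_homozygous(genotype: Tuple[Allele, Allele]) -> bool:
    """Two-field, suffix-insensitive identity of the consensus pair."""
    a, b = genotype
    return a.key() == b.key()


@dataclass
class HomozygosityRates:
    """Per-locus and multi-locus homozygosity fractions."""

    per_locus: Dict[str, float]
    joint: Dict[Tuple[str, ...], float] = field(default_factory=dict)
    at_least: Dict[Tuple[Tuple[str, ...], int], float] = field(default_factory=dict)
    n_per_locus: Dict[str, int] = field(default_factory=dict)


def homozygosity_rates(
    cohort_by_locus: Mapping[str, LocusCohort],
    joint_sets: Sequence[Sequence[str]] = (),
    at_least: Sequence[Tuple[Sequence[str], int]] = (),
) -> HomozygosityRates:
    """Homozygosity fractions per locus and over locus sets.

    ``joint_sets`` are locus groups counted homozygous only when every locus
    of the group is homozygous (e.g. DQA1-DQB1 jointly).  ``at_least`` pairs
    a locus set with a minimum count k, giving the fraction of individuals
    homozygous at >= k loci of the set.  Individuals unresolved at any locus
    of a multi-locus set are excluded from that set's denominator.
    """
    def _hom_flags(loci: Sequence[str]) -> Dict[str, Optional[bool]]:
        patients = set().union(*(cohort_by_locus.get(l, {}) for l in loci)) \
            if loci else set()
        flags = {}
        for p in patients:
            per = []
            for l in loci:
                g = cohort_by_locus.get(l, {}).get(p)
                per.append(None if g is None else is_homozygous(g))
            flags[p] = per
        return flags

    per_locus: Dict[str, float] = {}
    n_per_locus: Dict[str, int] = {}
    for locus, cohort in cohort_by_locus.items():
        resolved = [g for g in cohort.values() if g is not None]
        n_per_locus[locus] = len(resolved)
        per_locus[locus] = (
            sum(is_homozygous(g) for g in resolved) / len(resolved)
            if resolved else 0.0
        )

    joint: Dict[Tuple[str, ...], float] = {}
    for loci in joint_sets:
        loci = tuple(loci)
        flags = _hom_flags(loci)
        evaluable = {p: f for p, f in flags.items() if None not in f}
        joint[loci] = (
            sum(all(f) for f in evaluable.values()) / len(evaluable)
            if evaluable else 0.0
        )

    at_least_rates: Dict[Tuple[Tuple[str, ...], int], float] = {}
    for loci, k in at_least:
        loci = tuple(loci)
        flags = _hom_flags(loci)
        evaluable = {p: f for p, f in flags.items() if None not in f}
        at_least_rates[(loci, k)] = (
            sum(sum(f) >= k for f in evaluable.values()) / len(evaluable)
            if evaluable else 0.0
        )

    return HomozygosityRates(
        per_locus=per_locus,
        joint=joint,
        at_least=at_least_rates,
        n_per_locus=n_per_locus,
    )


@dataclass(frozen=True)
class ScreeningCriteria:
    """The three over/under-representation criteria.

    i)   frequency >= ``freq_either`` in either group and RA <= ``ra_low_i``
         or >= ``ra_high_i``;
    ii)  frequency >= ``freq_both`` in both groups and RA <= ``ra_low_ii``
         or >= ``ra_high_ii``;
    iii) allele not detected in patients with control frequency >=
         ``absent_control_min``.
    """

    freq_either: float = 0.1
    ra_low_i: float = 0.5
    ra_high_i: float = 2.0
    freq_both: float = 0.1
    ra_low_ii: float = 0.67
    ra_high_ii: float = 1.5
    absent_control_min: float = 0.07


@dataclass
class ScreeningResult:
    allele: str
    patient_freq: float
    control_freq: float
    ratio: Optional[float]             # RA = patients / controls; None when undefined
    flag: str                          # underrepresented | overrepresented | not-detected | patient-only | none
    criterion: Optional[str] = None    # "i" | "ii" | "iii"


def screen_alleles(
    patients: AlleleFrequencyTable,
    controls: AlleleFrequencyTable,
    criteria: ScreeningCriteria = ScreeningCriteria(),
) -> list[ScreeningResult]:
    """Evaluate every allele in the union of both tables against the screen.

    Criteria are tested in order i → ii → iii and the first that fires is
    recorded.  Direction comes from RA (low bound → underrepresented, high
    bound → overrepresented).  An allele present in patients but absent from
    controls has an undefined RA and is flagged ``patient-only``.
    """
    if patients.locus != controls.locus:
        raise ValueError(
            f"tables are on different loci: {patients.locus} vs {controls.locus}"
        )
    keys = sorted(set(patients.frequencies) | set(controls.frequencies))
    results = []
    for key in keys:
        fp = patients.frequencies.get(key, 0.0)
        fc = controls.frequencies.get(key, 0.0)
        name = patients.names.get(key) or controls.names.get(key) or str(key)
        if fc == 0.0:
            if fp > 0.0:
                results.append(ScreeningResult(name, fp, fc, None, "patient-only"))
            continue
        ra = fp / fc
        flag, criterion = "none", None
        if (fp >= criteria.freq_either or fc >= criteria.freq_either) and (
            ra <= criteria.ra_low_i or ra >= criteria.ra_high_i
        ):
            criterion = "i"
            flag = "underrepresented" if ra <= criteria.ra_low_i else "overrepresented"
        elif (fp >= criteria.freq_both and fc >= criteria.freq_both) and (
            ra <= criteria.ra_low_ii or ra >= criteria.ra_high_ii
        ):
            criterion = "ii"
            flag = "underrepresented" if ra <= criteria.ra_low_ii else "overrepresented"
        elif fp == 0.0 and fc >= criteria.absent_control_min:
            criterion = "iii"
            flag = "not-detected"
        results.append(ScreeningResult(name, fp, fc, ra, flag, criterion))
    return results


def assign_ancestry(
    fractions: Mapping[str, float], threshold: float = 0.70
) -> str:
    """Superpopulation label from ancestry fractions, or ``admixed``.

    The label is the unique superpopulation whose fraction meets the
    (inclusive) threshold; with a threshold > 0.5 at most one can.
    """
    missing = [sp for sp in SUPERPOPULATIONS if sp not in fractions]
    if missing:
        raise ValueError(f"missing superpopulation fractions: {missing}")
    bad = {sp: f for sp, f in fractions.items() if not 0.0 <= f <= 1.0}
    if bad:
        raise ValueError(f"ancestry fractions outside [0, 1]: {bad}")
    total = sum(fractions[sp] for sp in SUPERPOPULATIONS)
    if total > 1.0 + 1e-6:
        raise ValueError(f"ancestry fractions sum to {total:.4f} > 1")
    winners = [sp for sp in SUPERPOPULATIONS if fractions[sp] >= threshold]
    if len(winners) > 1:
        raise ValueError(
            f"multiple superpopulations meet the threshold: {winners} "
            "(inconsistent input)"
        )
    return winners[0] if winners else "admixed"
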