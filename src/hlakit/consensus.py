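"""Two-stage consensus HLA genotyping from multi-algorithm, multi-sample calls.

Typing algorithms run on different sequencing materials (normal WES, tumor
WES, tumor RNA-seq) each report a genotype per locus.  A consensus genotype
is established when a candidate genotype is supported by calls spanning at
least two distinct algorithms AND at least two distinct samples.  Stage 1
restricts the supporting algorithms to the two primary callers; stage 2
opens the full algorithm set for loci stage 1 could not resolve.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .nomenclature import Allele, CLASSICAL_LOCI

logger = logging.getLogger(__name__)

#: Valid material labels for NGS samples.
MATERIALS = ("normal-WES", "tumor-WES", "tumor-RNA")

#: Materials derived from RNA (subject to transcript-silencing dropout).
RNA_MATERIALS = frozenset({"tumor-RNA"})

GenotypeKey = Tuple[tuple, tuple]  # sorted pair of allele keys


@dataclass(frozen=True)
class GenotypeCall:
    """One per-(patient, sample, algorithm, locus) genotype call.

    A tool reporting a single allele is stored as a putative homozygote pair
    with ``single_allele`` set; it supports a homozygous candidate only.
    """

    patient: str
    sample: str
    algorithm: str
    locus: str
    alleles: Tuple[Allele, ...]
    material: str = ""
    single_allele: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("a genotype call carries 1 or 2 alleles")
        if any(a.locus != self.locus for a in self.alleles):
            raise ValueError("all alleles of a call must share the call's locus")
        if len(self.alleles) == 1 and not self.single_allele:
            object.__setattr__(self, "single_allele", True)

    def genotype_key(self) -> GenotypeKey:
        """Unordered pair key at two-field resolution, suffix-insensitive.

        Single-allele calls key as the putative homozygote (a, a).
        """
        keys = [a.key() for a in self.alleles]
        if len(keys) == 1:
            keys = keys * 2
        k1, k2 = sorted(keys)
        return (k1, k2)


@dataclass(frozen=True)
class ConsensusPolicy:
    """Which algorithms participate in each consensus stage."""

    stage1_algorithms: Tuple[str, ...] = ("HLA-HD", "HLAProfiler")
    stage2_algorithms: Tuple[str, ...] = (
        "HLA-HD", "HLAProfiler", "Optitype", "xHLA", "HISAT-genotype",
    )
    min_algorithms: int = 2
    min_samples: int = 2


@dataclass
class ConsensusResult:
    """Per-(patient, locus) consensus outcome."""

    patient: str
    locus: str
    status: str                         # consensus | unresolved | no-data
    genotype: Optional[Tuple[Allele, Allele]] = None
    support: frozenset = frozenset()    # (algorithm, sample) pairs
    stage: Optional[int] = None
    candidates: list = field(default_factory=list)


def _qualifying_candidates(
    by_candidate: Mapping[GenotypeKey, set],
    algorithms: Sequence[str],
    policy: ConsensusPolicy,
) -> dict:
    """Candidates whose supporters span enough distinct algorithms/samples."""
    out = {}
    algset = set(algorithms)
    for key, supporters in by_candidate.items():
        sub = {(alg, smp) for alg, smp in supporters if alg in algset}
        n_alg = len({alg for alg, _ in sub})
        n_smp = len({smp for _, smp in sub})
        if n_alg >= policy.min_algorithms and n_smp >= policy.min_samples:
            out[key] = frozenset(sub)
    return out


def consensus_genotype(
    calls: Iterable[GenotypeCall],
    policy: ConsensusPolicy = ConsensusPolicy(),
) -> ConsensusResult:
    """Derive the consensus genotype for one patient-locus.

    Candidate genotypes are whole unordered allele pairs compared
    suffix-insensitively at two-field resolution.  A candidate wins a stage
    iff it is the unique genotype whose exact supporters span at least two
    distinct algorithms (from the stage's algorithm set) and two distinct
    samples.  Several qualifying candidates at a stage → unresolved with all
    of them reported.
    """
    calls = list(calls)
    if not calls:
        return ConsensusResult(patient="", locus="", status="no-data")
    patients = {c.patient for c in calls}
    loci = {c.locus for c in calls}
    if len(patients) > 1 or len(loci) > 1:
        raise ValueError(
            f"consensus_genotype expects one patient-locus, got "
            f"patients={sorted(patients)} loci={sorted(loci)}"
        )
    patient, locus = calls[0].patient, calls[0].locus

    by_candidate: dict[GenotypeKey, set] = defaultdict(set)
    representative: dict[GenotypeKey, Tuple[Allele, Allele]] = {}
    for c in calls:
        key = c.genotype_key()
        by_candidate[key].add((c.algorithm, c.sample))
        if key not in representative:
            alleles = c.alleles if len(c.alleles) == 2 else c.alleles * 2
            representative[key] = tuple(sorted(alleles))  # type: ignore[assignment]
        if c.material:
            logger.debug(
                "call %s/%s %s on %s (%s): %s", patient, locus,
                c.algorithm, c.sample, c.material,
                "/".join(a.name for a in c.alleles),
            )

    stages = (
        (1, policy.stage1_algorithms),
        (2, policy.stage2_algorithms),
    )
    for stage, algorithms in stages:
        qualifying = _qualifying_candidates(by_candidate, algorithms, policy)
        if len(qualifying) == 1:
            (key, supporters), = qualifying.items()
            return ConsensusResult(
                patient=patient, locus=locus, status="consensus",
                genotype=representative[key], support=supporters, stage=stage,
            )
        if len(qualifying) > 1:
            return ConsensusResult(
                patient=patient, locus=locus, status="unresolved", stage=stage,
                candidates=[representative[k] for k in sorted(qualifying)],
            )
    return ConsensusResult(
        patient=patient, locus=locus, status="unresolved", stage=2,
        candidates=[representative[k] for k in sorted(by_candidate)],
    )


@dataclass
class PatientConsensus:
    """All per-locus consensus results for one patient."""

    patient: str
    results: dict                      # locus -> ConsensusResult
    completeness: int                  # loci with consensus among the 8 classical
    n_classical: int = len(CLASSICAL_LOCI)


def patient_consensus(
    calls: Iterable[GenotypeCall],
    policy: ConsensusPolicy = ConsensusPolicy(),
) -> PatientConsensus:
    """Per-locus consensus for one patient plus 8-locus completeness."""
    calls = list(calls)
    patients = {c.patient for c in calls}
    if len(patients) > 1:
        raise ValueError(f"expected one patient, got {sorted(patients)}")
    patient = calls[0].patient if calls else ""

    by_locus: dict[str, list[GenotypeCall]] = defaultdict(list)
    for c in calls:
        by_locus[c.locus].append(c)

    results = {
        locus: consensus_genotype(locus_calls, policy)
        for locus, locus_calls in by_locus.items()
    }
    for locus in CLASSICAL_LOCI:
        if locus not in results:
            results[locus] = ConsensusResult(
                patient=patient, locus=locus, status="no-data"
            )
    completeness = sum(
        1 for locus in CLASSICAL_LOCI if results[locus].status == "consensus"
    )
    return PatientConsensus(
        patient=patient, results=results, completeness=completeness
    )
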