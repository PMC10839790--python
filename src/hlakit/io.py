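"""TSV dialects connecting the pipeline stages.

Every stage reads and writes flat tab-separated tables so intermediate
results stay inspectable and the command-line stages can be re-run or
audited independently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import pandas as pd

from .consensus import GenotypeCall, PatientConsensus
from .nomenclature import Allele, parse_allele
from .cohort import AlleleFrequencyTable, ScreeningResult

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Genotype calls

def calls_to_frame(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "patient": c.patient,
            "sample": c.sample,
            "material": c.material,
            "algorithm": c.algorithm,
            "locus": c.locus,
            "allele1": c.alleles[0].name,
            "allele2": c.alleles[1].name if len(c.alleles) == 2 else "",
        })
    return pd.DataFrame(
        rows,
        columns=["patient", "sample", "material", "algorithm",
                 "locus", "allele1", "allele2"],
    )


def calls_from_frame(df: pd.DataFrame) -> List[GenotypeCall]:
    calls = []
    for r in df.itertuples(index=False):
        alleles = [parse_allele(r.allele1)]
        second = getattr(r, "allele2", "")
        if isinstance(second, str) and second.strip():
            alleles.append(parse_allele(second))
        calls.append(
            GenotypeCall(
                patient=str(r.patient),
                sample=str(r.sample),
                algorithm=str(r.algorithm),
                locus=str(r.locus),
                alleles=tuple(alleles),
                material=str(getattr(r, "material", "") or ""),
            )
        )
    return calls


def write_calls(calls: Iterable[GenotypeCall], path: PathLike) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: PathLike) -> List[GenotypeCall]:
    return calls_from_frame(
        pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    )


# ---------------------------------------------------------------------------
# Consensus results

def consensus_to_frame(results: Iterable[PatientConsensus]) -> pd.DataFrame:
    rows = []
    for pc in results:
        for locus, res in sorted(pc.results.items()):
            rows.append({
                "patient": pc.patient,
                "locus": locus,
                "status": res.status,
                "allele1": res.genotype[0].name if res.genotype else "",
                "allele2": res.genotype[1].name if res.genotype else "",
                "stage": res.stage if res.stage is not None else "",
                "n_support": len(res.support),
            })
    return pd.DataFrame(
        rows,
        columns=["patient", "locus", "status", "allele1", "allele2",
                 "stage", "n_support"],
    )


def read_consensus_genotypes(
    path: PathLike,
) -> Dict[str, Dict[str, Optional[Tuple[Allele, Allele]]]]:
    """Load consensus TSV as locus -> patient -> pair (None if unresolved)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: Dict[str, Dict[str, Optional[Tuple[Allele, Allele]]]] = {}
    for r in df.itertuples(index=False):
        locus_map = out.setdefault(str(r.locus), {})
        if r.status == "consensus":
            locus_map[str(r.patient)] = (
                parse_allele(r.allele1), parse_allele(r.allele2)
            )
        else:
            locus_map[str(r.patient)] = None
    return out


# ---------------------------------------------------------------------------
# Frequency / screening tables

def read_control_frequencies(path: PathLike) -> Dict[str, AlleleFrequencyTable]:
    """Control TSV (locus, allele, frequency, source) -> tables per locus."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    tables: Dict[str, AlleleFrequencyTable] = {}
    for locus, grp in df.groupby("locus"):
        freqs, names = {}, {}
        for r in grp.itertuples(index=False):
            allele = parse_allele(
                r.allele if "*" in r.allele else f"{locus}*{r.allele}"
            )
            freqs[allele.key()] = float(r.frequency)
            names[allele.key()] = allele.name
        tables[str(locus)] = AlleleFrequencyTable(
            locus=str(locus), frequencies=freqs, names=names,
            cohort=str(grp.iloc[0].get("source", "controls")),
        )
    return tables


def screening_to_frame(results: Iterable[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "allele": r.allele,
            "patient_freq": r.patient_freq,
            "control_freq": r.control_freq,
            "ratio": "" if r.ratio is None else r.ratio,
            "flag": r.flag,
            "criterion": r.criterion or "",
        } for r in results],
        columns=["allele", "patient_freq", "control_freq",
                 "ratio", "flag", "criterion"],
    )


def read_ancestry(path: PathLike) -> Dict[str, Dict[str, float]]:
    """Ancestry TSV (patient + five superpopulation fraction columns)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.to_dict("records"):
        patient = str(r.pop("patient"))
        out[patient] = {k: float(v) for k, v in r.items()}
    return out


# ---------------------------------------------------------------------------
# Variants / expression

def read_variants(path: PathLike) -> List["VariantRecord"]:
    from .somatic import VariantRecord

    df = pd.read_csv(path, sep="\t")
    records = []
    for r in df.itertuples(index=False):
        records.append(
            VariantRecord(
                sample=str(r.sample),
                gene=str(r.gene),
                consequence=str(r.consequence),
                normal_alt=None if pd.isna(r.n_alt) else int(r.n_alt),
                normal_vaf=None if pd.isna(r.n_vaf) else float(r.n_vaf),
                tumor_alt=None if pd.isna(r.t_alt) else int(r.t_alt),
                tumor_vaf=None if pd.isna(r.t_vaf) else float(r.t_vaf),
                qual_pass=bool(getattr(r, "qual_pass", True)),
            )
        )
    return records


def write_variants(records, path: PathLike) -> None:
    pd.DataFrame(
        [{
            "sample": r.sample, "gene": r.gene, "consequence": r.consequence,
            "n_alt": r.normal_alt, "n_vaf": r.normal_vaf,
            "t_alt": r.tumor_alt, "t_vaf": r.tumor_vaf,
            "qual_pass": r.qual_pass,
        } for r in records]
    ).to_csv(path, sep="\t", index=False)


def read_ct_records(path: PathLike) -> List["CtRecord"]:
    """Ct TSV: sample, assay, ct_rep1, ct_rep2[, ...]."""
    from .qpcr import CtRecord

    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("ct_rep")]
    records = []
    for r in df.itertuples(index=False):
        reps = tuple(
            float(getattr(r, c)) for c in rep_cols
            if not pd.isna(getattr(r, c))
        )
        records.append(CtRecord(sample=str(r.sample), assay=str(r.assay),
                                replicates=reps))
    return records


def write_ct_records(rows: Iterable[dict], path: PathLike) -> None:
    """Write simulate_expression rows as the Ct TSV dialect."""
    out = []
    n_reps = 0
    rows = list(rows)
    for row in rows:
        n_reps = max(n_reps, len(row["replicates"]))
    for row in rows:
        rec = {"sample": row["sample"], "assay": row["assay"]}
        for i in range(n_reps):
            reps = row["replicates"]
            rec[f"ct_rep{i + 1}"] = reps[i] if i < len(reps) else ""
        out.append(rec)
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)
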