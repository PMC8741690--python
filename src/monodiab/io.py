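"""Reading and writing the pipeline's tabular formats.

Conventions: tab-separated for genetic tables (weights, genotypes),
comma-separated for clinical tables; ``.`` marks a missing value; booleans
are serialized as ``1``/``0``; extra-pancreatic feature sets are
semicolon-joined codes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import MonogenicDiagnosis, PanelGene, VariantCall
from .grs import GenotypeMatrix, GrsResult, WeightTable
from .triage import ChildRecord, TriageDecision

MISSING = "."

WEIGHT_COLUMNS = ["snp_id", "chrom", "pos", "risk_allele", "other_allele", "weight"]
PHENOTYPE_COLUMNS = [
    "child_id", "age_at_diagnosis", "antibody_status", "insulin_treated",
    "clinically_diagnosed_t1d", "parent_with_diabetes", "hba1c",
    "mody_probability", "parental_consanguinity", "extra_pancreatic_features",
]


# -- weight table -----------------------------------------------------------

def read_weight_table(path: str | Path) -> WeightTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight table {path} lacks columns {sorted(missing)}")
    return WeightTable(
        tuple(df.snp_id.astype(str)),
        tuple(df.chrom),
        tuple(int(p) for p in df.pos),
        tuple(df.risk_allele),
        tuple(df.other_allele),
        df.weight.to_numpy(float),
    )


def write_weight_table(weights: WeightTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "snp_id": weights.snp_ids,
            "chrom": weights.chroms,
            "pos": weights.positions,
            "risk_allele": weights.risk_alleles,
            "other_allele": weights.other_alleles,
            "weight": weights.weights,
        }
    ).to_csv(path, sep="\t", index=False)


# -- genotypes --------------------------------------------------------------

def read_genotypes(path: str | Path, weights: WeightTable | None = None) -> GenotypeMatrix:
    """TSV with rows = children (first column ``child_id``), one column per
    SNP, cells 0/1/2 or ``.``.  When a weight table is supplied, SNP columns
    not in it raise immediately (naming the offender)."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("child_id")
    if weights is not None:
        unknown = [s for s in df.columns if s not in weights.snp_ids]
        if unknown:
            raise KeyError(f"genotype file contains SNPs absent from the weight table: {unknown}")
    dosages = df.replace(MISSING, np.nan).to_numpy(dtype=float)
    return GenotypeMatrix(tuple(df.index.astype(str)), tuple(df.columns), dosages)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=list(genotypes.child_ids), columns=list(genotypes.snp_ids)
    )
    out = df.map(lambda v: MISSING if np.isnan(v) else str(int(v)))
    out.index.name = "child_id"
    out.to_csv(path, sep="\t")


def read_genotypes_vcf(path: str | Path, weights: WeightTable) -> GenotypeMatrix:
    """Convert VCF genotypes to risk-allele dosages using the weight table.

    Variants are matched by ID.  REF/ALT must equal the weight table's
    risk/other alleles (in either orientation); anything else — including a
    strand-flipped pair — is an error, never silently harmonised.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    child_ids = tuple(vcf.samples)
    rows: dict[str, np.ndarray] = {}
    for variant in vcf:
        sid = variant.ID
        if sid is None or sid not in weights.snp_ids:
            continue
        i = weights.index_of(sid)
        risk, other = weights.risk_alleles[i], weights.other_alleles[i]
        alt = variant.ALT[0] if variant.ALT else None
        if {variant.REF, alt} != {risk, other}:
            raise ValueError(
                f"{sid}: VCF alleles {variant.REF}/{alt} do not match weight-table "
                f"alleles {risk}/{other} (strand flips are not harmonised)"
            )
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = variant.gt_types.astype(float)
        alt_dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows[sid] = alt_dosage if alt == risk else 2.0 - alt_dosage
    if not rows:
        raise ValueError(f"no weight-table SNPs found in {path}")
    snp_ids = tuple(rows)
    dosages = np.column_stack([rows[s] for s in snp_ids])
    return GenotypeMatrix(child_ids, snp_ids, dosages)


# -- phenotypes -------------------------------------------------------------

def _parse_bool(value: str, *, optional: bool = False):
    if value == MISSING or value == "":
        if optional:
            return None
        raise ValueError("missing value for a required boolean column")
    return value in ("1", "true", "True")


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, frozenset):
        return ";".join(sorted(value)) if value else MISSING
    return str(value)


def read_phenotypes(path: str | Path) -> list[ChildRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file {path} lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples():
        features = frozenset(
            f for f in str(row.extra_pancreatic_features).split(";") if f and f != MISSING
        )
        records.append(
            ChildRecord(
                child_id=str(row.child_id),
                age_at_diagnosis=None if row.age_at_diagnosis == MISSING
                else float(row.age_at_diagnosis),
                antibody_status=row.antibody_status,
                insulin_treated=_parse_bool(row.insulin_treated),
                clinically_diagnosed_t1d=_parse_bool(row.clinically_diagnosed_t1d),
                parent_with_diabetes=_parse_bool(row.parent_with_diabetes),
                hba1c=None if row.hba1c == MISSING else float(row.hba1c),
                mody_probability=None if row.mody_probability == MISSING
                else float(row.mody_probability),
                parental_consanguinity=_parse_bool(row.parental_consanguinity, optional=True),
                extra_pancreatic_features=features,
            )
        )
    return records


def write_phenotypes(records: Iterable[ChildRecord], path: str | Path) -> None:
    rows = [
        {
            "child_id": r.child_id,
            "age_at_diagnosis": _fmt(r.age_at_diagnosis),
            "antibody_status": r.antibody_status,
            "insulin_treated": _fmt(r.insulin_treated),
            "clinically_diagnosed_t1d": _fmt(r.clinically_diagnosed_t1d),
            "parent_with_diabetes": _fmt(r.parent_with_diabetes),
            "hba1c": _fmt(r.hba1c),
            "mody_probability": _fmt(r.mody_probability),
            "parental_consanguinity": _fmt(r.parental_consanguinity),
            "extra_pancreatic_features": _fmt(r.extra_pancreatic_features),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS).to_csv(path, index=False)


# -- GRS results ------------------------------------------------------------

def write_grs_results(results: Iterable[GrsResult], path: str | Path) -> None:
    rows = [
        {
            "child_id": r.child_id,
            "score": MISSING if r.score is None else f"{r.score:.6f}",
            "n_missing": r.n_missing,
            "centile": MISSING if r.centile is None else f"{r.centile:.2f}",
            "category": r.category if r.category is not None else MISSING,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_grs_results(path: str | Path) -> list[GrsResult]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        GrsResult(
            row.child_id,
            None if row.score == MISSING else float(row.score),
            int(row.n_missing),
            None if row.centile == MISSING else float(row.centile),
            None if row.category == MISSING else row.category,
        )
        for row in df.itertuples()
    ]


# -- triage decisions -------------------------------------------------------

def write_decisions(decisions: Iterable[TriageDecision], path: str | Path) -> None:
    pd.DataFrame(
        [{"child_id": d.child_id, "tested": _fmt(d.tested), "reason": d.reason}
         for d in decisions]
    ).to_csv(path, index=False)


def read_decisions(path: str | Path) -> list[TriageDecision]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [TriageDecision(r.child_id, _parse_bool(r.tested), r.reason) for r in df.itertuples()]


# -- panel, variant calls, diagnoses ---------------------------------------

def read_panel(path: str | Path) -> list[PanelGene]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [PanelGene(r.gene_symbol, frozenset(r.modes.split(","))) for r in df.itertuples()]


def read_variant_calls(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        VariantCall(r.child_id, r.gene_symbol, r.zygosity, _parse_bool(r.pathogenic))
        for r in df.itertuples()
    ]


def write_variant_calls(calls: Iterable[VariantCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"child_id": c.child_id, "gene_symbol": c.gene_symbol,
             "zygosity": c.zygosity, "pathogenic": _fmt(c.pathogenic)}
            for c in calls
        ],
        columns=["child_id", "gene_symbol", "zygosity", "pathogenic"],
    ).to_csv(path, index=False)


def write_diagnoses(diagnoses: Sequence[MonogenicDiagnosis], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"child_id": d.child_id, "gene_symbol": d.gene_symbol, "inheritance": d.inheritance}
            for d in diagnoses
        ],
        columns=["child_id", "gene_symbol", "inheritance"],
    ).to_csv(path, index=False)


def read_diagnoses(path: str | Path) -> list[MonogenicDiagnosis]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [MonogenicDiagnosis(r.child_id, r.gene_symbol, r.inheritance) for r in df.itertuples()]
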