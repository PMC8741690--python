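"""Synthetic clinic-cohort generator.

Emulates a paediatric diabetes clinic population with the statistical
structure the screening analysis assumes: a large autoimmune (type 1
diabetes) majority whose genotypes are drawn from case-enriched risk-allele
frequencies, and a small monogenic minority (default prevalence 3.1%, of
which 41% recessive and 3% mitochondrial/other) whose genotypes come from
background-population frequencies, so that monogenic children concentrate in
the low/moderate genetic-risk categories the triage rule tests.

Binary clinical criteria are generated class-conditionally from baseline
(background) rates and per-class odds ratios via the odds transform

    p_case = OR * o0 / (1 + OR * o0),   o0 = p0 / (1 - p0)

which makes the population odds ratio of each criterion against the rest of
the cohort equal to the configured value by construction.  Criteria are
conditionally independent given the class — real comorbidity correlation is
not modelled.  Continuous HbA1c and MODY-probability values are drawn
consistently with their thresholded binary criteria.

Every draw flows from a single integer seed; identical parameters and seed
reproduce the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import VariantCall
from .grs import GenotypeMatrix, GrsResult, WeightTable
from .triage import ChildRecord

TRUE_CLASSES = (
    "definite_t1d",
    "ab_negative_nonmonogenic",
    "monogenic_AD",
    "monogenic_AR",
    "monogenic_other",
)

#: gene frequencies among dominant monogenic cases (MODY genes dominate)
AD_GENE_FREQS = (
    ("GCK", 0.38), ("HNF1A", 0.26), ("HNF4A", 0.10), ("HNF1B", 0.08),
    ("ABCC8", 0.07), ("INS", 0.06), ("KCNJ11", 0.05),
)
#: gene frequencies among recessive cases (WFS1 and SLC19A2 commonest)
AR_GENE_FREQS = (
    ("WFS1", 0.32), ("SLC19A2", 0.25), ("SLC29A3", 0.08), ("EIF2AK3", 0.08),
    ("NEUROG3", 0.06), ("GLIS3", 0.06), ("SLC2A2", 0.05), ("TRMT10A", 0.04),
    ("PTF1A", 0.03), ("IER3IP1", 0.03),
)

#: extra-pancreatic feature vocabulary weighted toward the syndromic triad
FEATURE_FREQS = (
    ("deafness", 0.28), ("anaemia", 0.22), ("developmental_delay", 0.20),
    ("optic_atrophy", 0.09), ("diabetes_insipidus", 0.06),
    ("liver_dysfunction", 0.05), ("skeletal_dysplasia", 0.04),
    ("microcephaly", 0.03), ("short_stature", 0.03),
)


def load_default_weights() -> WeightTable:
    """The bundled synthetic 30-SNP weight table (one dominant-effect
    HLA-like SNP plus 29 modest-effect SNPs)."""
    path = resources.files("monodiab.data") / "snp_weights.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return WeightTable(
        tuple(df.snp_id), tuple(df.chrom), tuple(int(p) for p in df.pos),
        tuple(df.risk_allele), tuple(df.other_allele), df.weight.to_numpy(float),
    )


def load_default_freqs() -> pd.DataFrame:
    """Per-SNP risk-allele frequencies for type 1 diabetes cases and the
    background population (columns: snp_id, case_freq, background_freq)."""
    path = resources.files("monodiab.data") / "snp_freqs.tsv"
    return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class GrsSimParams:
    """Genotype-simulation configuration: the weight table plus per-class
    risk-allele frequencies (aligned with the weight table order)."""

    weights: WeightTable
    case_freqs: np.ndarray
    background_freqs: np.ndarray

    @classmethod
    def default(cls) -> "GrsSimParams":
        wt = load_default_weights()
        fq = load_default_freqs().set_index("snp_id").loc[list(wt.snp_ids)]
        return cls(wt, fq.case_freq.to_numpy(float), fq.background_freq.to_numpy(float))

    def __post_init__(self) -> None:
        n = len(self.weights)
        for name in ("case_freqs", "background_freqs"):
            f = np.asarray(getattr(self, name), dtype=float)
            if f.shape != (n,) or not np.all((f >= 0) & (f <= 1)):
                raise ValueError(f"{name} must be probabilities aligned with the weight table")
            object.__setattr__(self, name, f)


def _default_criterion_odds() -> dict[str, tuple[float | None, float | None]]:
    # (odds ratio in dominant cases, odds ratio in recessive cases);
    # None = criterion occurs at the baseline rate in that class
    return {
        "non_insulin_treatment": (105.1, None),
        "parent_with_diabetes": (6.2, None),
        "hba1c_le_58": (10.3, None),
        "mody_probability_ge_10": (38.0, None),
        "extra_pancreatic_features": (None, 66.9),
        "parental_consanguinity": (None, 4.0),
    }


def _default_baseline_rates() -> dict[str, float]:
    # background (rest-of-cohort) rates; parental_consanguinity is the
    # population consanguinity rate, the others are plumbing defaults
    return {
        "non_insulin_treatment": 0.02,
        "parent_with_diabetes": 0.15,
        "hba1c_le_58": 0.08,
        "mody_probability_ge_10": 0.05,
        "extra_pancreatic_features": 0.02,
        "parental_consanguinity": 0.20,
    }


@dataclass(frozen=True)
class GeneratorParams:
    n_cohort: int = 1093
    n_reference: int = 1963
    monogenic_prevalence: float = 0.031
    recessive_fraction_of_monogenic: float = 0.41
    other_fraction_of_monogenic: float = 0.03
    antibody_positive_rate_t1d: float = 0.45
    antibody_missing_rate: float = 0.12
    antibody_positive_rate_monogenic: float = 0.02
    criterion_odds: dict = field(default_factory=_default_criterion_odds)
    baseline_rates: dict = field(default_factory=_default_baseline_rates)
    grs_params: GrsSimParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohort < 1:
            raise ValueError("n_cohort must be >= 1")
        for name in (
            "monogenic_prevalence", "recessive_fraction_of_monogenic",
            "other_fraction_of_monogenic", "antibody_positive_rate_t1d",
            "antibody_missing_rate", "antibody_positive_rate_monogenic",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.recessive_fraction_of_monogenic + self.other_fraction_of_monogenic > 1:
            raise ValueError("recessive + other fractions of monogenic exceed 1")
        for crit, p0 in self.baseline_rates.items():
            if not 0.0 <= p0 < 1.0:
                raise ValueError(f"baseline rate for {crit!r} must be in [0, 1)")
        for crit, (or_ad, or_ar) in self.criterion_odds.items():
            if crit not in self.baseline_rates:
                raise ValueError(f"criterion {crit!r} has odds but no baseline rate")
            for orv in (or_ad, or_ar):
                if orv is not None and not orv > 0:
                    raise ValueError(f"odds ratio for {crit!r} must be positive")

    def resolved_grs_params(self) -> GrsSimParams:
        return self.grs_params if self.grs_params is not None else GrsSimParams.default()

    def class_rate(self, criterion: str, true_class: str) -> float:
        """Class-conditional probability of a binary criterion."""
        p0 = self.baseline_rates[criterion]
        or_ad, or_ar = self.criterion_odds.get(criterion, (None, None))
        orv = {"monogenic_AD": or_ad, "monogenic_AR": or_ar}.get(true_class)
        if orv is None:
            return p0
        o0 = p0 / (1.0 - p0)
        p = orv * o0 / (1.0 + orv * o0)
        if not p < 1.0:
            raise ValueError(f"criterion {criterion!r}: class rate reaches 1 after odds transform")
        return p


@dataclass(frozen=True)
class SyntheticCohort:
    children: list[ChildRecord]
    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # child_id, true_class, gene_symbol, zygosity
    params: GeneratorParams

    def truth_calls(self) -> list[VariantCall]:
        """Ground-truth pathogenic variant calls for the monogenic children."""
        calls = []
        for row in self.truth.itertuples():
            if row.true_class == "monogenic_AD":
                calls.append(VariantCall(row.child_id, row.gene_symbol, "monoallelic", True))
            elif row.true_class == "monogenic_AR":
                calls.append(VariantCall(row.child_id, row.gene_symbol, "biallelic", True))
            elif row.true_class == "monogenic_other":
                calls.append(
                    VariantCall(row.child_id, row.gene_symbol, "mitochondrial_variant", True)
                )
        return calls


def _score(dosages: np.ndarray, weights: WeightTable) -> np.ndarray:
    from .grs import weighted_scores

    return weighted_scores(dosages, weights.weights)[0]


def generate_reference(params: GeneratorParams) -> np.ndarray:
    """Scores for a gold-standard type 1 diabetes reference cohort, by
    simulating genotypes from the case-enriched allele frequencies."""
    gp = params.resolved_grs_params()
    rng = np.random.default_rng(params.seed)
    if params.n_reference == 0:
        return np.empty(0)
    dosages = rng.binomial(2, gp.case_freqs, size=(params.n_reference, len(gp.weights)))
    return _score(dosages, gp.weights)


def generate_cohort(params: GeneratorParams) -> SyntheticCohort:
    """Draw a full synthetic clinic cohort with truth labels."""
    gp = params.resolved_grs_params()
    # independent stream from the reference generator (seed offset)
    rng = np.random.default_rng((params.seed, 1))
    n = params.n_cohort

    # (1) class labels
    p_mono = params.monogenic_prevalence
    p_ar = p_mono * params.recessive_fraction_of_monogenic
    p_other = p_mono * params.other_fraction_of_monogenic
    p_ad = p_mono - p_ar - p_other
    etiology = rng.choice(
        ["autoimmune", "monogenic_AD", "monogenic_AR", "monogenic_other"],
        size=n,
        p=[1.0 - p_mono, p_ad, p_ar, p_other],
    )

    # (3) antibody status (drawn early so truth classes are defined)
    ab = np.empty(n, dtype=object)
    u = rng.random(n)
    for i, cls in enumerate(etiology):
        if cls == "autoimmune":
            p_pos, p_miss = params.antibody_positive_rate_t1d, params.antibody_missing_rate
        else:
            p_pos, p_miss = params.antibody_positive_rate_monogenic, params.antibody_missing_rate
        ab[i] = "positive" if u[i] < p_pos else ("missing" if u[i] < p_pos + p_miss else "negative")

    true_class = np.where(
        etiology == "autoimmune",
        np.where(ab == "positive", "definite_t1d", "ab_negative_nonmonogenic"),
        etiology,
    )

    # (2) genotypes: case-enriched for autoimmune children, background for monogenic
    n_snps = len(gp.weights)
    freqs = np.where(
        (etiology == "autoimmune")[:, None],
        gp.case_freqs[None, :],
        gp.background_freqs[None, :],
    )
    dosages = rng.binomial(2, freqs, size=(n, n_snps)).astype(float)

    # (4) binary clinical criteria, class-conditional
    crit_draws = {}
    for crit in params.baseline_rates:
        rates = np.array([params.class_rate(crit, c) for c in true_class])
        crit_draws[crit] = rng.random(n) < rates

    # (5) continuous measures consistent with their thresholded criteria
    hba1c = np.where(
        crit_draws["hba1c_le_58"],
        np.clip(rng.normal(51.0, 4.0, n), 35.0, 58.0),
        np.clip(rng.normal(82.0, 13.0, n), 58.5, 130.0),
    )
    mody_p = np.where(
        crit_draws["mody_probability_ge_10"],
        rng.uniform(0.10, 0.75, n),
        rng.uniform(0.001, 0.0995, n),
    )
    ages = rng.uniform(0.5, 20.0, n)

    feature_names = [f for f, _ in FEATURE_FREQS]
    feature_probs = np.array([p for _, p in FEATURE_FREQS])
    feature_probs = feature_probs / feature_probs.sum()

    children: list[ChildRecord] = []
    truth_rows = []
    for i in range(n):
        child_id = f"S{i + 1:04d}"
        insulin = not crit_draws["non_insulin_treatment"][i]
        features: frozenset[str] = frozenset()
        if crit_draws["extra_pancreatic_features"][i]:
            k = 1 + rng.binomial(2, 0.3)
            features = frozenset(rng.choice(feature_names, size=k, replace=False, p=feature_probs))
        clinical_t1d = True if etiology[i] == "autoimmune" else insulin
        children.append(
            ChildRecord(
                child_id=child_id,
                age_at_diagnosis=float(ages[i]),
                antibody_status=str(ab[i]),
                insulin_treated=insulin,
                clinically_diagnosed_t1d=clinical_t1d,
                parent_with_diabetes=bool(crit_draws["parent_with_diabetes"][i]),
                hba1c=float(hba1c[i]),
                mody_probability=float(mody_p[i]),
                parental_consanguinity=bool(crit_draws["parental_consanguinity"][i]),
                extra_pancreatic_features=features,
            )
        )
        # (6) truth variant calls for monogenic children
        gene, zyg = "", ""
        if true_class[i] == "monogenic_AD":
            gene = _sample_gene(rng, AD_GENE_FREQS)
            zyg = "monoallelic"
        elif true_class[i] == "monogenic_AR":
            gene = _sample_gene(rng, AR_GENE_FREQS)
            zyg = "biallelic"
        elif true_class[i] == "monogenic_other":
            gene, zyg = "MT-TL1", "mitochondrial_variant"
        truth_rows.append(
            {"child_id": child_id, "true_class": true_class[i], "gene_symbol": gene,
             "zygosity": zyg}
        )

    genotypes = GenotypeMatrix(
        tuple(c.child_id for c in children), gp.weights.snp_ids, dosages
    )
    truth = pd.DataFrame(truth_rows, columns=["child_id", "true_class", "gene_symbol", "zygosity"])
    return SyntheticCohort(children, genotypes, truth, params)


def _sample_gene(rng: np.random.Generator, table: Sequence[tuple[str, float]]) -> str:
    names = [g for g, _ in table]
    probs = np.array([p for _, p in table])
    return str(rng.choice(names, p=probs / probs.sum()))


def printed_partition_fixture() -> list[ChildRecord]:
    """Deterministic 1093-child cohort reproducing the published triage
    partition: 111 low-GRS, 125 moderate/antibody-negative, 516 high-GRS,
    208 moderate/antibody-positive and 133 moderate/antibody-missing.

    GRS categories are attached directly (representative scores); all other
    fields take neutral defaults.  Low-GRS children cycle through all three
    antibody statuses because their selection must not depend on it.
    """
    blocks = [
        (111, "low", 0.210, ("positive", "negative", "missing")),
        (125, "moderate", 0.250, ("negative",)),
        (516, "high", 0.300, ("positive", "negative", "missing")),
        (208, "moderate", 0.250, ("positive",)),
        (133, "moderate", 0.250, ("missing",)),
    ]
    records: list[ChildRecord] = []
    i = 0
    for count, category, score, ab_cycle in blocks:
        for j in range(count):
            i += 1
            child_id = f"F{i:04d}"
            records.append(
                ChildRecord(
                    child_id=child_id,
                    age_at_diagnosis=10.0,
                    antibody_status=ab_cycle[j % len(ab_cycle)],
                    insulin_treated=True,
                    clinically_diagnosed_t1d=True,
                    parent_with_diabetes=False,
                    hba1c=80.0,
                    mody_probability=0.01,
                    parental_consanguinity=False,
                    grs=GrsResult(child_id, score, 0, None, category),
                )
            )
    return records


def printed_case_calls() -> list[VariantCall]:
    """Deterministic pathogenic calls matching the published case mix:
    34 diagnoses among the tested children of the printed-partition fixture
    (19 monoallelic, 14 biallelic, 1 mitochondrial).

    Calls are assigned to the first tested child ids of the fixture; gene
    labels follow the recessive gene mix dominated by WFS1 and SLC19A2.
    """
    biallelic = ["WFS1"] * 5 + ["SLC19A2"] * 4 + ["SLC29A3"] * 2 + [
        "EIF2AK3", "NEUROG3", "GLIS3"]
    monoallelic = ["GCK"] * 7 + ["HNF1A"] * 5 + ["HNF4A"] * 3 + ["HNF1B"] * 2 + [
        "ABCC8", "INS"]
    calls = []
    i = 0
    for gene in biallelic:
        i += 1
        calls.append(VariantCall(f"F{i:04d}", gene, "biallelic", True))
    for gene in monoallelic:
        i += 1
        calls.append(VariantCall(f"F{i:04d}", gene, "monoallelic", True))
    i += 1
    calls.append(VariantCall(f"F{i:04d}", "MT-TL1", "mitochondrial_variant", True))
    return calls


def with_seed(params: GeneratorParams, seed: int) -> GeneratorParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
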