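"""Inheritance-mode classification of confirmed monogenic diabetes cases.

The classification rule is purely zygosity-based: every monoallelic
pathogenic variant counts as autosomal dominant, every biallelic pathogenic
variant (homozygous or compound heterozygous — phasing is out of scope) as
autosomal recessive, and mitochondrial variants as "other".  The gene symbol
plays no role beyond panel membership.

Prevalence estimates carry exact binomial (Clopper-Pearson) confidence
intervals and are labelled *minimum* prevalence whenever part of the cohort
was never tested; a projection helper adds hypothetical extra cases to the
numerator to bound what testing the untested subgroups could reveal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from . import stats as exact_stats

INHERITANCE_MODES = ("autosomal_dominant", "autosomal_recessive", "mitochondrial", "x_linked")
ZYGOSITIES = ("monoallelic", "biallelic", "mitochondrial_variant")
INHERITANCE_CLASSES = ("autosomal_dominant", "autosomal_recessive", "other")

_ZYGOSITY_TO_CLASS = {
    "monoallelic": "autosomal_dominant",
    "biallelic": "autosomal_recessive",
    "mitochondrial_variant": "other",
}


@dataclass(frozen=True)
class PanelGene:
    gene_symbol: str
    modes: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.modes) - set(INHERITANCE_MODES)
        if bad:
            raise ValueError(f"{self.gene_symbol}: unknown inheritance modes {sorted(bad)}")


@dataclass(frozen=True)
class VariantCall:
    child_id: str
    gene_symbol: str
    zygosity: str
    pathogenic: bool

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"{self.child_id}: unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class MonogenicDiagnosis:
    child_id: str
    gene_symbol: str
    inheritance: str  # autosomal_dominant / autosomal_recessive / other


def load_default_panel() -> list[PanelGene]:
    """The bundled 50-gene dominant + recessive monogenic diabetes panel.

    The gene list is a synthetic stand-in assembled from well-known
    monogenic diabetes genes; it includes WFS1 and SLC19A2 (the two
    commonest recessive causes in high-consanguinity cohorts) but is not a
    transcription of any published panel.
    """
    path = resources.files("monodiab.data") / "gene_panel.tsv"
    df = pd.read_csv(path, sep="\t")
    return [
        PanelGene(row.gene_symbol, frozenset(row.modes.split(",")))
        for row in df.itertuples()
    ]


def classify_case(call: VariantCall, panel: Sequence[PanelGene]) -> MonogenicDiagnosis:
    """Classify one pathogenic call by zygosity (monoallelic -> dominant,
    biallelic -> recessive, mitochondrial -> other)."""
    if not call.pathogenic:
        raise ValueError(f"{call.child_id}: only pathogenic calls are classified")
    if call.gene_symbol not in {g.gene_symbol for g in panel}:
        raise KeyError(f"gene {call.gene_symbol!r} is not on the testing panel")
    return MonogenicDiagnosis(call.child_id, call.gene_symbol, _ZYGOSITY_TO_CLASS[call.zygosity])


def classify_all(
    calls: Iterable[VariantCall], panel: Sequence[PanelGene]
) -> list[MonogenicDiagnosis]:
    """Classify pathogenic calls into one diagnosis per child.

    A child carrying both a monoallelic and a biallelic pathogenic call is
    classified by the biallelic one (with a warning): the rule must be total
    and recessive findings take precedence in this screening context.
    Non-pathogenic calls are ignored.
    """
    per_child: dict[str, list[VariantCall]] = {}
    for call in calls:
        if call.pathogenic:
            per_child.setdefault(call.child_id, []).append(call)
    diagnoses = []
    rank = {"biallelic": 0, "mitochondrial_variant": 1, "monoallelic": 2}
    for child_id, child_calls in per_child.items():
        if len(child_calls) > 1:
            warnings.warn(
                f"{child_id}: {len(child_calls)} pathogenic calls; "
                "classifying by the biallelic/mitochondrial call",
                stacklevel=2,
            )
        chosen = min(child_calls, key=lambda c: rank[c.zygosity])
        diagnoses.append(classify_case(chosen, panel))
    return diagnoses


@dataclass(frozen=True)
class InheritanceSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    per_gene: pd.DataFrame  # columns: gene_symbol, inheritance, count

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def summarize_causes(diagnoses: Sequence[MonogenicDiagnosis]) -> InheritanceSummary:
    """Counts and percentages per inheritance class plus a per-gene table
    (bar-chart ready).  Percentages are 100 * class count / total diagnoses;
    an empty input gives an empty (all-zero) summary."""
    counts = Counter(d.inheritance for d in diagnoses)
    full = {cls: counts.get(cls, 0) for cls in INHERITANCE_CLASSES}
    total = len(diagnoses)
    pct = {cls: (100.0 * n / total if total else 0.0) for cls, n in full.items()}
    gene_counts = Counter((d.gene_symbol, d.inheritance) for d in diagnoses)
    per_gene = pd.DataFrame(
        [
            {"gene_symbol": g, "inheritance": inh, "count": n}
            for (g, inh), n in sorted(gene_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["gene_symbol", "inheritance", "count"],
    )
    return InheritanceSummary(full, pct, per_gene)


def prevalence(
    n_cases: int, n_cohort: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Point prevalence with an exact (Clopper-Pearson) binomial CI.

    Returns proportions on the 0-1 scale.
    """
    if n_cohort <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= n_cases <= n_cohort:
        raise ValueError("case count must lie in [0, cohort size]")
    low, high = exact_stats.clopper_pearson(n_cases, n_cohort, confidence)
    return n_cases / n_cohort, low, high


def project_prevalence(
    n_cases: int, n_cohort: int, extra_cases: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Projected prevalence if testing the untested subgroups found
    ``extra_cases`` further cases (added to the numerator only)."""
    if extra_cases < 0:
        raise ValueError("extra case count must be non-negative")
    return prevalence(n_cases + extra_cases, n_cohort, confidence)
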