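"""End-to-end orchestration: simulate/load -> score -> triage -> classify ->
analyze, producing a machine-readable results bundle.

The bundle mirrors the structure of a screening-study results section:
a (minimum) prevalence block with exact binomial CI and a projection for
untested subgroups, an inheritance-mode summary with a per-gene table, a
selection-criteria report (exact odds ratio, CI and Fisher p per criterion
and inheritance class), and comparisons against the printed UK literature
cohorts.
"""

from __future__ import annotations

import math
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

from . import classify as dx
from . import stats as exact_stats
from . import triage as tri
from .constants import UK_COMBINED, UK_SYSTEMATIC
from .grs import ReferenceDistribution, calibrate_thresholds, compute_scores
from .simulate import GeneratorParams, generate_cohort, generate_reference
from .triage import TriageDecision

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Either simulation parameters or input paths must be provided."""

    sim_params: GeneratorParams | None = None
    fixture: str | None = None  # "printed_partition" uses the bundled deterministic cohort
    phenotypes: str | None = None
    genotypes: str | None = None
    weights: str | None = None
    variant_calls: str | None = None
    panel: str | None = None
    threshold_low: float | None = None
    threshold_high: float | None = None
    confidence: float = 0.95
    projected_extra_cases: int = 2
    seed: int = 0
    calibrate_from_reference: bool = False

    def __post_init__(self) -> None:
        if self.fixture is not None:
            if self.fixture != "printed_partition":
                raise ValueError(f"unknown fixture {self.fixture!r}")
            return
        if self.sim_params is None and (self.phenotypes is None or self.genotypes is None):
            raise ValueError("provide either sim_params, a fixture, or phenotype+genotype paths")


@dataclass
class ResultsBundle:
    """JSON-serialisable results of one pipeline run (plain types only)."""

    schema_version: int
    seed: int
    thresholds: dict
    n_cohort: int
    n_eligible: int
    partition: dict
    prevalence: dict
    inheritance: dict
    criteria: list
    uk_comparison: dict
    grs_distribution: dict
    consistency_flags: list

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ResultsBundle":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ResultsBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def run_pipeline(config: RunConfig, calls=None) -> ResultsBundle:
    """Execute the full screening pipeline for one configuration.

    ``calls`` optionally supplies variant calls directly (a sequence of
    :class:`~monodiab.classify.VariantCall`), overriding any calls path or
    simulated truth calls.
    """
    calls_override = calls
    from . import io as mio
    from .simulate import load_default_weights, with_seed

    # --- stage 0: acquire cohort -----------------------------------------
    if config.fixture == "printed_partition":
        from .simulate import printed_partition_fixture

        children = printed_partition_fixture()
        genotypes = None
        weights = None
        calls = mio.read_variant_calls(config.variant_calls) if config.variant_calls else []
        reference_scores = None
    elif config.sim_params is not None:
        params = with_seed(config.sim_params, config.seed)
        cohort = generate_cohort(params)
        children = cohort.children
        genotypes = cohort.genotypes
        weights = params.resolved_grs_params().weights
        calls = cohort.truth_calls()
        reference_scores = generate_reference(params)
    else:
        children = mio.read_phenotypes(config.phenotypes)
        weights = (
            mio.read_weight_table(config.weights) if config.weights else load_default_weights()
        )
        genotypes = mio.read_genotypes(config.genotypes, weights)
        calls = mio.read_variant_calls(config.variant_calls) if config.variant_calls else []
        reference_scores = None
    if calls_override is not None:
        calls = list(calls_override)

    # --- stage 1: score ----------------------------------------------------
    if config.calibrate_from_reference and reference_scores is not None:
        reference = calibrate_thresholds(reference_scores)
    else:
        reference = ReferenceDistribution.published_defaults()
    if config.threshold_low is not None or config.threshold_high is not None:
        reference = ReferenceDistribution(
            None,
            config.threshold_low if config.threshold_low is not None else reference.threshold_low,
            config.threshold_high
            if config.threshold_high is not None
            else reference.threshold_high,
        )
    if genotypes is not None:
        results = compute_scores(genotypes, weights, reference)
        by_child = {r.child_id: r for r in results}
        for rec in children:
            rec.grs = by_child.get(rec.child_id, rec.grs)

    # --- stage 2: triage ----------------------------------------------------
    eligible, excluded = tri.filter_eligible(children)
    decisions = [tri.select_for_testing(rec) for rec in eligible]
    decisions += [TriageDecision(rec.child_id, False, "ineligible") for rec, _ in excluded]
    partition = tri.partition_summary(decisions)
    tested_ids = {d.child_id for d in decisions if d.tested}

    # --- stage 3: classify (tested children only: minimum prevalence) ------
    panel = mio.read_panel(config.panel) if config.panel else dx.load_default_panel()
    tested_calls = [c for c in calls if c.child_id in tested_ids]
    diagnoses = dx.classify_all(tested_calls, panel)
    summary = dx.summarize_causes(diagnoses)

    # --- stage 4: analyze ----------------------------------------------------
    n_eligible = len(eligible)
    n_cases = summary.total
    point, lo, hi = dx.prevalence(n_cases, n_eligible, config.confidence)
    proj_point, proj_lo, proj_hi = dx.project_prevalence(
        n_cases, n_eligible, config.projected_extra_cases, config.confidence
    )
    prevalence_block = {
        "n_cases": n_cases,
        "n_cohort": n_eligible,
        "proportion": point,
        "ci_low": lo,
        "ci_high": hi,
        "confidence": config.confidence,
        "is_minimum": partition.untested_total > 0,
        "projected_extra_cases": config.projected_extra_cases,
        "projected_proportion": proj_point,
        "projected_ci": [proj_lo, proj_hi],
    }

    criteria_rows, flags = _criteria_report(eligible, diagnoses, config.confidence)

    uk_block = _uk_comparison(n_cases, n_eligible, summary.counts["autosomal_recessive"])

    grs_block = _grs_distribution_block(eligible, reference_scores)

    return ResultsBundle(
        schema_version=SCHEMA_VERSION,
        seed=config.seed,
        thresholds={
            "low": reference.threshold_low,
            "high": reference.threshold_high,
        },
        n_cohort=len(children),
        n_eligible=n_eligible,
        partition={
            "counts": dict(partition.counts),
            "tested_total": partition.tested_total,
            "untested_total": partition.untested_total,
        },
        prevalence=prevalence_block,
        inheritance={
            "counts": dict(summary.counts),
            "percentages": dict(summary.percentages),
            "per_gene": summary.per_gene.to_dict(orient="records"),
        },
        criteria=criteria_rows,
        uk_comparison=uk_block,
        grs_distribution=grs_block,
        consistency_flags=flags,
    )


def _criteria_report(eligible, diagnoses, confidence) -> tuple[list, list]:
    rows, flags = [], []
    for target in ("autosomal_dominant", "autosomal_recessive"):
        for name in exact_stats.BUILTIN_CRITERIA:
            try:
                res = exact_stats.evaluate_criterion(
                    eligible, diagnoses, name, target, confidence
                )
            except ValueError:
                continue  # degenerate table (e.g. no cases of this class)
            rows.append(
                {
                    "criterion": res.criterion_name,
                    "target_group": res.target_group,
                    "table": [res.table.a, res.table.b, res.table.c, res.table.d],
                    "odds_ratio": _jsonify(res.odds_ratio),
                    "ci_low": _jsonify(res.ci_low),
                    "ci_high": _jsonify(res.ci_high),
                    "sample_odds_ratio": _jsonify(res.sample_odds_ratio),
                    "fisher_p": res.fisher_p,
                    "n_excluded_missing": res.n_excluded_missing,
                }
            )
            # exact-test consistency: p < alpha should track CI excluding 1
            significant = res.fisher_p < 1.0 - confidence
            excludes_one = res.ci_low > 1.0 or res.ci_high < 1.0
            if significant != excludes_one:
                flags.append(
                    {
                        "criterion": res.criterion_name,
                        "target_group": res.target_group,
                        "fisher_p": res.fisher_p,
                        "ci": [_jsonify(res.ci_low), _jsonify(res.ci_high)],
                        "note": "Fisher p and exact OR CI disagree about significance",
                    }
                )
    return rows, flags


def _uk_comparison(n_cases: int, n_cohort: int, n_recessive: int) -> dict:
    out: dict = {}
    z, p = exact_stats.two_sample_proportion(
        n_cases, n_cohort, UK_SYSTEMATIC.n_monogenic, UK_SYSTEMATIC.n_screened
    )
    uk_prev = dx.prevalence(UK_SYSTEMATIC.n_monogenic, UK_SYSTEMATIC.n_screened)
    out["prevalence_vs_uk_systematic"] = {
        "cohort": UK_SYSTEMATIC.name,
        "uk_proportion": uk_prev[0],
        "uk_ci": [uk_prev[1], uk_prev[2]],
        "z": z,
        "p": p,
    }
    out["recessive_fraction_vs_uk_combined"] = compare_cohorts(
        n_cases, n_cohort, n_recessive,
        UK_COMBINED.n_monogenic, None, UK_COMBINED.n_recessive,
    )["recessive_fraction"]
    return out


def _grs_distribution_block(eligible, reference_scores) -> dict:
    """Median/IQR of definite type 1 diabetes cases vs the reference, with
    Mann-Whitney and Kolmogorov-Smirnov comparisons when both exist."""
    from .grs import compare_distributions

    case_scores = [
        r.grs.score for r in eligible
        if tri.is_definite_t1d(r) and r.grs is not None and r.grs.score is not None
    ]
    block: dict = {"n_definite_t1d": len(case_scores)}
    if len(case_scores) >= 2 and reference_scores is not None and len(reference_scores) >= 2:
        comp = compare_distributions(case_scores, reference_scores)
        block.update(
            {
                "median_cases": comp.median_x,
                "iqr_cases": list(comp.iqr_x),
                "median_reference": comp.median_y,
                "iqr_reference": list(comp.iqr_y),
                "mann_whitney_p": comp.mw_p,
                "ks_p": comp.ks_p,
            }
        )
    return block


def compare_cohorts(
    cases1: int,
    n1: int | None,
    recessive1: int,
    cases2: int,
    n2: int | None,
    recessive2: int,
) -> dict:
    """Compare two screening cohorts: prevalence (two-sample proportion
    test, requires both denominators) and recessive fraction (Fisher's exact
    test on the case-level 2x2)."""
    for cases, n, rec in ((cases1, n1, recessive1), (cases2, n2, recessive2)):
        if rec > cases:
            raise ValueError("recessive count exceeds case count")
        if n is not None and cases > n:
            raise ValueError("case count exceeds cohort size")
    out: dict = {}
    if n1 is not None and n2 is not None:
        z, p = exact_stats.two_sample_proportion(cases1, n1, cases2, n2)
        out["prevalence"] = {
            "proportion1": cases1 / n1, "proportion2": cases2 / n2, "z": z, "p": p,
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-margin tables legitimately occur here
        fisher_p = exact_stats.fisher_exact(
            [[recessive1, cases1 - recessive1], [recessive2, cases2 - recessive2]]
        )
    out["recessive_fraction"] = {
        "fraction1": recessive1 / cases1 if cases1 else math.nan,
        "fraction2": recessive2 / cases2 if cases2 else math.nan,
        "fisher_p": fisher_p,
    }
    return out


def _jsonify(x: float) -> float | str:
    """Keep infinities JSON-representable."""
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return x
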