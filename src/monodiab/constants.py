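"""Published constants used as configuration and literature comparators.

The centile thresholds are the WTCCC-derived type 1 diabetes genetic risk
score cut-offs (5th and 50th centile of 1963 gold-standard European type 1
diabetes patients).  The UK cohort counts are literature constants from two
low-consanguinity comparison cohorts (a systematic paediatric-clinic study
and routine diagnostic referrals); they are printed results, not data
shipped with this package.
"""

from dataclasses import dataclass

#: 5th centile of the WTCCC type 1 diabetes reference distribution.
GRS_THRESHOLD_LOW: float = 0.234
#: 50th centile of the WTCCC type 1 diabetes reference distribution.
GRS_THRESHOLD_HIGH: float = 0.280

#: Eligibility window for age at diabetes onset (years, both ends inclusive).
AGE_MIN_YEARS: float = 0.5
AGE_MAX_YEARS: float = 20.0

#: Per-child genotype missingness ceiling above which no score is reported.
DEFAULT_MISSINGNESS_CEILING: float = 0.20


@dataclass(frozen=True)
class LiteratureCohort:
    """Printed counts for an external monogenic-diabetes cohort."""

    name: str
    n_monogenic: int
    n_screened: int | None  # None when only cases (not the clinic base) are known
    n_recessive: int


#: Systematic UK paediatric-clinic study: 20 monogenic cases among 808
#: screened children, none with a recessive cause.
UK_SYSTEMATIC = LiteratureCohort("UK systematic paediatric clinic", 20, 808, 0)

#: Routine UK diagnostic referrals diagnosed at 0.5-20 years: 102 monogenic
#: cases, 2 recessive; no clinic denominator exists for referrals.
UK_REFERRALS = LiteratureCohort("UK routine diagnostic referrals", 102, None, 2)

#: Both UK cohorts pooled (used for the recessive-fraction contrast).
UK_COMBINED = LiteratureCohort("UK combined monogenic cohort", 122, None, 2)
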