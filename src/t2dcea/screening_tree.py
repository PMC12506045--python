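"""Decision-tree screening cascade.

The short-term phase of the model: a closed cohort of adults aged 40 with no
prior diabetes diagnosis is offered community-based screening (random
capillary blood glucose plus anthropometric risk triage).  Attendance,
test accuracy, risk-based referral and adherence to the referral route the
cohort into seven clinical end groups, stratified by exposure to health
education.  The tree is evaluated in expectation (fractional persons), which
is the natural input representation for a Markov cohort model.

End groups
----------
PREDIABETES, NGT_LOW, NGT_MOD          — non-diabetic glucose tolerance tiers
NGT_HIGH_TREATED / NGT_HIGH_UNTREATED  — high-risk NGT, with/without enrolment
                                         in Prolanis risk management
T2D_DIAGNOSED_PHC                      — screen-detected diabetes managed at
                                         primary care
T2D_UNDIAGNOSED                        — diabetes missed (false negative),
                                         refused or never screened
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .params import ParameterSet

__all__ = [
    "Group",
    "Strategy",
    "RiskCategory",
    "RiskProfile",
    "TreeOutput",
    "classify_risk",
    "screen_cohort",
]


class Strategy(str, enum.Enum):
    REFERENCE = "reference"
    SCREENING = "screening"
    SCREENING_EDUCATION = "screening_education"


class Group(str, enum.Enum):
    PREDIABETES = "PREDIABETES"
    NGT_LOW = "NGT_LOW"
    NGT_MOD = "NGT_MOD"
    NGT_HIGH_TREATED = "NGT_HIGH_TREATED"
    NGT_HIGH_UNTREATED = "NGT_HIGH_UNTREATED"
    T2D_DIAGNOSED_PHC = "T2D_DIAGNOSED_PHC"
    T2D_UNDIAGNOSED = "T2D_UNDIAGNOSED"


STRATA = ("not_educated", "educated")


class RiskCategory(str, enum.Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


@dataclass(frozen=True)
class RiskProfile:
    """One attendee's screening measurements (random capillary glucose, mg/dL)."""

    bmi: float
    waist: float
    sex: str  # 'M' or 'F'
    sbp: float
    dbp: float
    glucose: float

    def __post_init__(self):
        for name in ("bmi", "waist", "sbp", "dbp", "glucose"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive; got {v}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F'; got {self.sex!r}")


_ORDER = {RiskCategory.GREEN: 0, RiskCategory.YELLOW: 1, RiskCategory.RED: 2}


def _bin_bmi(bmi: float) -> RiskCategory:
    if bmi >= 25.0:
        return RiskCategory.RED
    if bmi >= 23.0:
        return RiskCategory.YELLOW
    return RiskCategory.GREEN


def _bin_waist(waist: float, sex: str) -> RiskCategory:
    cut = 90.0 if sex == "M" else 80.0
    return RiskCategory.RED if waist > cut else RiskCategory.GREEN


def _bin_bp(sbp: float, dbp: float) -> RiskCategory:
    if sbp >= 140.0 or dbp >= 90.0:
        return RiskCategory.RED
    if sbp >= 130.0 or dbp >= 80.0:
        return RiskCategory.YELLOW
    return RiskCategory.GREEN


def _bin_glucose(glucose: float) -> RiskCategory:
    if glucose >= 200.0:
        return RiskCategory.RED
    if glucose >= 145.0:
        return RiskCategory.YELLOW
    return RiskCategory.GREEN


def classify_risk(profile: RiskProfile) -> RiskCategory:
    """Triage a profile with the community risk-classification cut-offs.

    Each indicator (BMI, waist circumference by sex, blood pressure, random
    capillary glucose) is binned green/yellow/red; the overall category is
    the worst indicator.  Glucose >= 200 mg/dL is always red, and red
    implies referral to primary care.
    """
    cats = [
        _bin_bmi(profile.bmi),
        _bin_waist(profile.waist, profile.sex),
        _bin_bp(profile.sbp, profile.dbp),
        _bin_glucose(profile.glucose),
    ]
    return max(cats, key=_ORDER.__getitem__)


@dataclass
class TreeOutput:
    """End-of-tree cohort allocation.

    ``occupancy[(group, stratum)]`` holds fractional persons; strata are
    ``'not_educated'`` and ``'educated'``.  ``flagged_false_negatives`` is
    the sub-mass of T2D_UNDIAGNOSED who attended screening but tested
    negative — under repeated-screening scenarios these persons are known to
    the programme as high risk and are rescreened annually.
    """

    occupancy: dict[tuple[Group, str], float]
    tree_cost: float
    screened_count: float
    strategy: Strategy
    flagged_false_negatives: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in STRATA}
    )

    @property
    def total(self) -> float:
        return sum(self.occupancy.values())

    def group_total(self, group: Group) -> float:
        return sum(v for (g, _s), v in self.occupancy.items() if g is group)

    def check_conservation(self, cohort_size: float, tol: float = 1e-6) -> None:
        if abs(self.total - cohort_size) > tol:
            raise AssertionError(
                f"tree occupancy {self.total} != cohort size {cohort_size}"
            )


def screen_cohort(ps: ParameterSet, strategy: Strategy | str) -> TreeOutput:
    """Route the cohort through the screening cascade in expectation.

    Cascade: a fraction ``uptake`` attends; attendees split by glycaemic
    prevalence.  Diabetic attendees test positive with probability Se;
    non-diabetic attendees with probability 1 − Sp.  High-risk (red) NGT
    attendees are referred regardless of the glucose result.  Referred
    persons follow up at primary care with probability ``referral_adherence``:
    adherent true positives are diagnosed and treated at primary care,
    adherent false positives are confirmed non-diabetic and return to their
    tier, adherent high-risk NGT enrol in Prolanis risk management.
    Everyone else — non-attendees, false negatives, non-adherent referrals —
    keeps their underlying state, with all unconfirmed diabetes remaining
    undiagnosed.  Under the education strategy every attendee additionally
    enters the educated stratum.

    Tree-phase cost = programme cost (training + first-year worker
    incentives) + glucose-kit cost per person screened (+ education-material
    development for the education strategy); the no-intervention reference
    costs nothing.
    """
    strategy = Strategy(strategy)
    n = ps["cohort_size"]
    prev = ps.prevalence
    occ: dict[tuple[Group, str], float] = {
        (g, s): 0.0 for g in Group for s in STRATA
    }
    flagged = {s: 0.0 for s in STRATA}

    def baseline_alloc(mass: float, stratum: str) -> None:
        """Allocation with no screening: states by prevalence, T2D undiagnosed."""
        occ[(Group.T2D_UNDIAGNOSED, stratum)] += mass * prev["prev_t2d_undiagnosed"]
        occ[(Group.PREDIABETES, stratum)] += mass * prev["prev_prediabetes"]
        occ[(Group.NGT_LOW, stratum)] += mass * prev["prev_ngt_low"]
        occ[(Group.NGT_MOD, stratum)] += mass * prev["prev_ngt_mod"]
        occ[(Group.NGT_HIGH_UNTREATED, stratum)] += mass * prev["prev_ngt_high"]

    if strategy is Strategy.REFERENCE:
        baseline_alloc(n, "not_educated")
        return TreeOutput(occ, tree_cost=0.0, screened_count=0.0, strategy=strategy)

    uptake = ps["uptake"]
    se = ps["rcbg_sensitivity"]
    sp = ps["rcbg_specificity"]
    adh = ps["referral_adherence"]
    stratum = "educated" if strategy is Strategy.SCREENING_EDUCATION else "not_educated"

    attendees = n * uptake
    baseline_alloc(n - attendees, "not_educated")

    # --- diabetic attendees -------------------------------------------------
    t2d = attendees * prev["prev_t2d_undiagnosed"]
    tp = t2d * se  # screen-positive diabetes
    occ[(Group.T2D_DIAGNOSED_PHC, stratum)] += tp * adh
    occ[(Group.T2D_UNDIAGNOSED, stratum)] += tp * (1.0 - adh)  # refused referral
    fn = t2d * (1.0 - se)
    occ[(Group.T2D_UNDIAGNOSED, stratum)] += fn
    flagged[stratum] += fn

    # --- non-diabetic attendees: prediabetes and low/moderate NGT -----------
    # False positives are referred, and (if adherent) confirmed non-diabetic
    # and sent back to their tier — referral changes nothing but the referral
    # itself, so the whole tier mass stays put.
    occ[(Group.PREDIABETES, stratum)] += attendees * prev["prev_prediabetes"]
    occ[(Group.NGT_LOW, stratum)] += attendees * prev["prev_ngt_low"]
    occ[(Group.NGT_MOD, stratum)] += attendees * prev["prev_ngt_mod"]

    # --- high-risk NGT attendees: referred regardless of the glucose test ---
    high = attendees * prev["prev_ngt_high"]
    occ[(Group.NGT_HIGH_TREATED, stratum)] += high * adh
    occ[(Group.NGT_HIGH_UNTREATED, stratum)] += high * (1.0 - adh)

    cost = 0.0
    if attendees > 0.0:
        cost = (
            ps["pc_chw_training"]
            + ps["pc_chw_incentives_yearly"]
            + ps["pc_rcbg_kit"] * attendees
        )
        if strategy is Strategy.SCREENING_EDUCATION:
            cost += ps["pc_education_materials"]

    out = TreeOutput(
        occ,
        tree_cost=cost,
        screened_count=attendees,
        strategy=strategy,
        flagged_false_negatives=flagged,
    )
    out.check_conservation(n)
    return out
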