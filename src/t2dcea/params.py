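"""Parameter registry, configuration I/O and validation.

Every quantity the model consumes lives in a :class:`ParameterSet`: a flat,
ordered registry of named :class:`Parameter` entries, each carrying a base
value, an uncertainty distribution (:class:`DistributionSpec`), one-way
sensitivity bounds and a provenance tag.  The registry is the single source
of truth for a run; downstream modules read values by name and never hold
private copies, which is what makes probabilistic and one-way sensitivity
analysis (pin/replace a value, re-run) safe.

Currency is held internally in 2022 international dollars (Int$); Indonesian
rupiah appear only at the I/O boundary via :func:`to_int_dollars`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "Family",
    "Provenance",
    "DistributionSpec",
    "Parameter",
    "ParameterSet",
    "LifeTable",
    "ValidationIssue",
    "ValidationReport",
    "load_parameters",
    "save_parameters",
    "validate_parameters",
    "to_int_dollars",
    "PREVALENCE_KEYS",
]


class Family(str, enum.Enum):
    """Distribution family attached to a parameter for probabilistic analysis."""

    FIXED = "fixed"
    BETA = "beta"
    GAMMA = "gamma"
    NORMAL = "normal"
    LOGNORMAL = "lognormal"


class Provenance(str, enum.Enum):
    """Where a base value came from.

    ``PAPER`` marks values printed in the source study's main text;
    ``SYNTHETIC`` marks plausible placeholders standing in for unpublished
    supplementary values; ``USER`` marks values supplied by the caller.
    """

    PAPER = "paper"
    SYNTHETIC = "synthetic"
    USER = "user"


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty description for one parameter.

    Parameters
    ----------
    family
        One of ``fixed``, ``beta``, ``gamma``, ``normal``, ``lognormal``.
    mean
        Base-case value (the distribution mean).
    se
        Standard error, used for method-of-moments fits (beta, gamma) and as
        the scale of the (truncated) normal.
    ci_low, ci_high
        95% confidence bounds; used for lognormal sigma and, when present,
        as the default one-way sensitivity bounds.
    bounds
        Explicit (low, high) truncation / sensitivity bounds.
    """

    family: Family = Family.FIXED
    mean: float = 0.0
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    bounds: tuple[float, float] | None = None

    def feasible(self) -> tuple[bool, str]:
        """Check moment feasibility for the declared family.

        Returns ``(ok, message)``; ``message`` names the violated rule when
        ``ok`` is False.
        """
        f, m, s = self.family, self.mean, self.se
        if f is Family.FIXED:
            return True, ""
        if f is Family.BETA:
            if not (0.0 < m < 1.0):
                return False, f"beta requires mean in (0,1); got {m}"
            if s is not None and s > 0 and s * s >= m * (1.0 - m):
                return False, (
                    f"beta moment infeasibility: se^2={s * s:.6g} must be "
                    f"< mean*(1-mean)={m * (1 - m):.6g}"
                )
        elif f in (Family.GAMMA, Family.LOGNORMAL):
            if not m > 0.0:
                return False, f"{f.value} requires mean > 0; got {m}"
        if s is not None and s < 0:
            return False, f"se must be >= 0; got {s}"
        if f is not Family.FIXED and s is None and self.ci_low is None and self.bounds is None:
            return False, f"{f.value} needs one of se, ci pair or explicit bounds"
        return True, ""


#: Parameter kinds drive validation ranges and default OWSA clipping.
KIND_RANGES: dict[str, tuple[float, float]] = {
    "probability": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "cost": (0.0, math.inf),
    "rate": (0.0, math.inf),
    "count": (0.0, math.inf),
    "ratio": (0.0, math.inf),
    "other": (-math.inf, math.inf),
}


@dataclass(frozen=True)
class Parameter:
    """One named model quantity with value, uncertainty and provenance."""

    name: str
    value: float
    kind: str = "other"
    dist: DistributionSpec = field(default_factory=DistributionSpec)
    provenance: Provenance = Provenance.USER
    owsa_low: float | None = None
    owsa_high: float | None = None
    description: str = ""

    def resolved_bounds(self, default_range: float = 0.30) -> tuple[float, float]:
        """One-way sensitivity bounds: explicit > CI > +/- default_range of base.

        Probabilities and utilities are clipped to [0, 1].
        """
        if self.owsa_low is not None and self.owsa_high is not None:
            lo, hi = self.owsa_low, self.owsa_high
        elif self.dist.bounds is not None:
            lo, hi = self.dist.bounds
        elif self.dist.ci_low is not None and self.dist.ci_high is not None:
            lo, hi = self.dist.ci_low, self.dist.ci_high
        else:
            lo = self.value * (1.0 - default_range)
            hi = self.value * (1.0 + default_range)
        kmin, kmax = KIND_RANGES.get(self.kind, KIND_RANGES["other"])
        return max(lo, kmin), min(hi, kmax)


PREVALENCE_KEYS = (
    "prev_t2d_undiagnosed",
    "prev_prediabetes",
    "prev_ngt_low",
    "prev_ngt_mod",
    "prev_ngt_high",
)

#: parameters that must be present in every ParameterSet
REQUIRED_KEYS = PREVALENCE_KEYS + (
    "cohort_size",
    "start_age",
    "cycle_length",
    "discount_rate",
    "uptake",
    "referral_adherence",
    "rescreen_adherence",
    "rcbg_sensitivity",
    "rcbg_specificity",
    "tp_ngt_low_to_mod",
    "tp_ngt_mod_to_high",
    "tp_ngt_low_to_pre",
    "tp_ngt_mod_to_pre",
    "tp_ngt_high_to_pre",
    "tp_pre_to_t2d",
    "tp_undiag_detection",
    "tp_t2d_to_cvd",
    "tp_cvd_case_fatality",
    "hr_cvd_undiagnosed",
    "rr_prolanis_management",
    "u_ngt",
    "u_prediabetes",
    "u_t2d_undiagnosed",
    "u_t2d_phc",
    "u_t2d_secondary",
    "u_cvd",
    "c_t2d_phc",
    "c_t2d_secondary",
    "c_cvd",
    "c_prolanis_highrisk",
    "pc_chw_training",
    "pc_chw_incentives_yearly",
    "pc_education_materials",
    "pc_rcbg_kit",
    "atet_knowledge",
    "beta_knowledge_to_lifestyle",
    "rr_lifestyle",
    "knowledge_scale_max_gain",
    "wtp_gdp_per_capita",
    "fx_idr_per_intd",
    "mcs_iterations",
    "owsa_default_range",
    "rescreen_window",
    "age_cap",
)


class ParameterSet:
    """Ordered registry of parameters plus the education linkage mode.

    Access values with ``ps["name"]`` (the float) or ``ps.param("name")``
    (the full :class:`Parameter`).  :meth:`with_values` returns a modified
    copy and is the workhorse of the sensitivity machinery.
    """

    def __init__(self, params: Iterable[Parameter], linkage_mode: str = "fractional"):
        self._params: dict[str, Parameter] = {}
        for p in params:
            if p.name in self._params:
                raise ValueError(f"duplicate parameter {p.name!r}")
            self._params[p.name] = p
        if linkage_mode not in ("fractional", "threshold"):
            raise ValueError(f"unknown linkage_mode {linkage_mode!r}")
        self.linkage_mode = linkage_mode

    # -- mapping-ish surface -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._params[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def names(self) -> list[str]:
        return list(self._params)

    def param(self, name: str) -> Parameter:
        return self._params[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return (
            self.linkage_mode == other.linkage_mode
            and self._params == other._params
        )

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with the given base values replaced (same specs)."""
        out = []
        for name, p in self._params.items():
            if name in updates:
                out.append(replace(p, value=float(updates[name])))
            else:
                out.append(p)
        unknown = set(updates) - set(self._params)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return ParameterSet(out, linkage_mode=self.linkage_mode)

    # -- convenience views ---------------------------------------------------
    @property
    def prevalence(self) -> dict[str, float]:
        return {k: self[k] for k in PREVALENCE_KEYS}

    @property
    def uncertain_names(self) -> list[str]:
        return [n for n, p in self._params.items() if p.dist.family is not Family.FIXED]

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"linkage_mode": self.linkage_mode, "parameters": {}}
        for name, p in self._params.items():
            e: dict = {
                "value": float(p.value),
                "kind": p.kind,
                "provenance": p.provenance.value,
                "family": p.dist.family.value,
            }
            if p.dist.se is not None:
                e["se"] = float(p.dist.se)
            if p.dist.ci_low is not None:
                e["ci_low"] = float(p.dist.ci_low)
            if p.dist.ci_high is not None:
                e["ci_high"] = float(p.dist.ci_high)
            if p.dist.bounds is not None:
                e["bounds"] = [float(p.dist.bounds[0]), float(p.dist.bounds[1])]
            if p.owsa_low is not None:
                e["owsa_low"] = float(p.owsa_low)
            if p.owsa_high is not None:
                e["owsa_high"] = float(p.owsa_high)
            if p.description:
                e["description"] = p.description
            d["parameters"][name] = e
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        if "parameters" not in d:
            raise KeyError("missing required key 'parameters'")
        params = []
        for name, e in d["parameters"].items():
            if "value" not in e:
                raise KeyError(f"parameter {name!r}: missing required key 'value'")
            bounds = e.get("bounds")
            dist = DistributionSpec(
                family=Family(e.get("family", "fixed")),
                mean=float(e["value"]),
                se=e.get("se"),
                ci_low=e.get("ci_low"),
                ci_high=e.get("ci_high"),
                bounds=tuple(bounds) if bounds is not None else None,
            )
            params.append(
                Parameter(
                    name=name,
                    value=float(e["value"]),
                    kind=e.get("kind", "other"),
                    dist=dist,
                    provenance=Provenance(e.get("provenance", "user")),
                    owsa_low=e.get("owsa_low"),
                    owsa_high=e.get("owsa_high"),
                    description=e.get("description", ""),
                )
            )
        missing = [k for k in REQUIRED_KEYS if k not in {p.name for p in params}]
        if missing:
            raise KeyError(f"missing required parameter(s): {missing}")
        return cls(params, linkage_mode=d.get("linkage_mode", "fractional"))


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Abridged all-cause mortality table: contiguous ages and annual qx."""

    ages: tuple[int, ...]
    qx: tuple[float, ...]

    def __post_init__(self):
        if len(self.ages) != len(self.qx):
            raise ValueError("ages and qx must have equal length")
        if len(self.ages) == 0:
            raise ValueError("empty life table")
        for a, b in zip(self.ages, self.ages[1:]):
            if b != a + 1:
                raise ValueError(f"ages must be contiguous; gap at {a} -> {b}")
        for q in self.qx:
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"qx out of [0,1]: {q}")
        if self.qx[-1] != 1.0:
            raise ValueError("terminal age must have qx == 1")

    def q(self, age: int) -> float:
        i = age - self.ages[0]
        if i < 0 or i >= len(self.ages):
            raise KeyError(f"age {age} outside life table [{self.ages[0]}, {self.ages[-1]}]")
        return self.qx[i]

    @classmethod
    def from_tsv(cls, path) -> "LifeTable":
        """Read a 2-column delimited text file (age, qx); '#' lines ignored."""
        ages, qx = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, q = line.replace(",", "\t").split()[:2]
                ages.append(int(a))
                qx.append(float(q))
        return cls(tuple(ages), tuple(qx))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# age\tqx\n")
            for a, q in zip(self.ages, self.qx):
                fh.write(f"{a}\t{float(q)!r}\n")


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

def load_parameters(config_path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML configuration file.

    Raises ``ValueError`` listing every violated invariant if the set is
    invalid, or ``KeyError`` naming the first missing required key.
    """
    with open(config_path) as fh:
        d = yaml.safe_load(fh)
    ps = ParameterSet.from_dict(d)
    report = validate_parameters(ps)
    if not report.ok:
        raise ValueError("invalid parameter set:\n" + report.summary())
    return ps


def save_parameters(ps: ParameterSet, config_path) -> None:
    with open(config_path, "w") as fh:
        yaml.safe_dump(ps.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class ValidationIssue:
    parameter: str
    rule: str
    ok: bool
    message: str = ""


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return all(i.ok for i in self.issues)

    def failures(self) -> list[ValidationIssue]:
        return [i for i in self.issues if not i.ok]

    def summary(self) -> str:
        return "\n".join(
            f"  {i.parameter}: {i.rule} — {i.message}" for i in self.failures()
        ) or "all checks passed"


def validate_parameters(ps: ParameterSet) -> ValidationReport:
    """Check every registry invariant; returns a per-rule report.

    Rules: kind ranges (probabilities and utilities in [0,1], costs >= 0),
    prevalence simplex (sum to 1 within 1e-9), distribution moment
    feasibility, hazard ratio positivity and a nonnegative discount rate.
    """
    issues: list[ValidationIssue] = []
    for name in ps.names():
        p = ps.param(name)
        lo, hi = KIND_RANGES.get(p.kind, KIND_RANGES["other"])
        in_range = lo <= p.value <= hi
        issues.append(
            ValidationIssue(
                name,
                f"{p.kind} in [{lo:g}, {hi:g}]",
                in_range,
                "" if in_range else f"value {p.value} out of range",
            )
        )
        ok, msg = p.dist.feasible()
        issues.append(ValidationIssue(name, "distribution feasible", ok, msg))

    total = sum(ps.prevalence.values())
    simplex_ok = abs(total - 1.0) <= 1e-9
    issues.append(
        ValidationIssue(
            "prevalence",
            "simplex sums to 1",
            simplex_ok,
            "" if simplex_ok else f"prevalence sums to {total:.12g}, not 1",
        )
    )
    hr_ok = ps["hr_cvd_undiagnosed"] > 0
    issues.append(
        ValidationIssue("hr_cvd_undiagnosed", "hazard ratio > 0", hr_ok,
                        "" if hr_ok else f"got {ps['hr_cvd_undiagnosed']}")
    )
    r_ok = ps["discount_rate"] >= 0
    issues.append(
        ValidationIssue("discount_rate", "discount rate >= 0", r_ok,
                        "" if r_ok else f"got {ps['discount_rate']}")
    )
    return ValidationReport(issues)


def to_int_dollars(amount_idr: float, fx: float) -> float:
    """Convert Indonesian rupiah to international dollars at ``fx`` IDR/Int$."""
    if fx <= 0:
        raise ValueError(f"exchange rate must be positive; got {fx}")
    return amount_idr / fx


def discount_factors(n_cycles: int, rate: float) -> np.ndarray:
    """Per-cycle discount factors 1/(1+r)^t for t = 0..n_cycles (t=0 undiscounted)."""
    t = np.arange(n_cycles + 1, dtype=float)
    return (1.0 + rate) ** (-t)
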