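"""Case/control labelling from ICD-10-style diagnosis code rules.

Matching is prefix-based on dotted code strings: a rule code "O24" matches a
sample code "O24.0" (and "O24" itself), while "Z37.0" matches only exactly.
Code ranges such as "O10-O16" expand to the inclusive list of 3-character
prefixes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .simulate import Cohort

__all__ = [
    "CodeRuleSet",
    "default_rules",
    "expand_code_range",
    "assign_case_control",
    "filter_bmi",
]


def expand_code_range(spec: str) -> list[str]:
    """Expand "O10-O16" into ["O10", ..., "O16"]."""
    m = re.fullmatch(r"([A-Z])(\d+)-([A-Z])(\d+)", spec.replace("–", "-"))
    if not m or m.group(1) != m.group(3):
        raise ValueError(f"unrecognized code range: {spec!r}")
    letter, lo, hi = m.group(1), int(m.group(2)), int(m.group(4))
    if hi < lo:
        raise ValueError(f"descending code range: {spec!r}")
    width = max(len(m.group(2)), len(m.group(4)))
    return [f"{letter}{i:0{width}d}" for i in range(lo, hi + 1)]


def _matches(sample_code: str, rule_code: str) -> bool:
    return sample_code == rule_code or sample_code.startswith(rule_code + ".")


def _carries_any(codes: frozenset[str], rule_codes: frozenset[str]) -> bool:
    return any(_matches(c, r) for c in codes for r in rule_codes)


@dataclass(frozen=True)
class CodeRuleSet:
    """Inclusion/exclusion code sets defining the case-control partition."""

    case_codes: frozenset[str]
    control_required_codes: frozenset[str]
    case_exclusions: frozenset[str] = frozenset()
    control_exclusions: frozenset[str] = frozenset()
    strict_preeclampsia: bool = False

    def __post_init__(self) -> None:
        if not self.case_codes or not self.control_required_codes:
            raise ValueError("case_codes and control_required_codes must be non-empty")
        overlap = self.case_codes & self.case_exclusions
        if overlap:
            raise ValueError(f"codes in both case_codes and case_exclusions: {sorted(overlap)}")


def default_rules(strict_preeclampsia: bool = False, general_controls: bool = False) -> CodeRuleSet:
    """Default rule set for gestational hypertensive disorders.

    Cases: pregnancy-induced hypertension with/without proteinuria (O13, O14),
    eclampsia (O15), or the self-reported flag (pseudo-code SR1073). Controls:
    live-birth/pregnancy codes, excluding hypertensive disorders of pregnancy
    (O10-O16) and diabetes in pregnancy (O24.x) unless ``general_controls``.
    """
    live_birth = set(expand_code_range("O02-O09")) | {
        "Z34.8", "Z37.0", "Z37.2", "Z37.3", "Z37.5", "Z37.6",
        "Z38.1", "Z38.3", "Z38.6", "Z39", "O80",
    }
    exclusions = set(expand_code_range("O10-O16")) | {
        "O24.0", "O24.1", "O24.2", "O24.3", "O24.9",
    }
    return CodeRuleSet(
        case_codes=frozenset({"O13", "O14", "O15", "SR1073"}),
        control_required_codes=frozenset(live_birth),
        control_exclusions=frozenset() if general_controls else frozenset(exclusions),
        strict_preeclampsia=strict_preeclampsia,
    )


@dataclass
class CaseControlReport:
    n_cases: int
    n_controls: int
    n_excluded: int

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls + self.n_excluded


def assign_case_control(cohort: Cohort, rules: CodeRuleSet) -> tuple[Cohort, CaseControlReport]:
    """Label every sample case / control / excluded by the code rules.

    A sample is a case iff it carries a case code and no case-exclusion code;
    under ``strict_preeclampsia`` a sample whose only case codes are O13
    (hypertension without proteinuria) is not a case. Non-cases are controls
    iff they carry a required live-birth code and no control-exclusion code;
    everything else is excluded.
    """
    if cohort.n_samples == 0:
        raise ValueError("empty cohort")
    non_o13_case_codes = frozenset(c for c in rules.case_codes if c != "O13")
    labels = np.empty(cohort.n_samples, dtype=object)
    for i, codes in enumerate(cohort.diagnosis_codes):
        if any(c == "" for c in codes):
            raise ValueError(f"empty diagnosis code for sample {cohort.sample_ids[i]}")
        is_case = _carries_any(codes, rules.case_codes) and not _carries_any(
            codes, rules.case_exclusions
        )
        if is_case and rules.strict_preeclampsia and not _carries_any(codes, non_o13_case_codes):
            is_case = False  # carries only O13 among the case codes
        if is_case:
            labels[i] = "case"
        elif _carries_any(codes, rules.control_required_codes) and not _carries_any(
            codes, rules.control_exclusions
        ):
            labels[i] = "control"
        else:
            labels[i] = "excluded"
    labelled = Cohort(
        sample_ids=cohort.sample_ids.copy(),
        status=labels,
        bmi=cohort.bmi.copy(),
        diagnosis_codes=list(cohort.diagnosis_codes),
        true_liability=None if cohort.true_liability is None else cohort.true_liability.copy(),
    )
    report = CaseControlReport(
        n_cases=int((labels == "case").sum()),
        n_controls=int((labels == "control").sum()),
        n_excluded=int((labels == "excluded").sum()),
    )
    return labelled, report


def filter_bmi(cohort: Cohort, min_bmi: float = 18.5) -> Cohort:
    """Drop samples with missing BMI or BMI below ``min_bmi``; order preserved."""
    if min_bmi <= 0:
        raise ValueError("min_bmi must be positive")
    keep = np.flatnonzero(~np.isnan(cohort.bmi) & (cohort.bmi >= min_bmi))
    return cohort.subset(keep)
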