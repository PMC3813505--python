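"""Named drug-likeness rule sets.

Shipped rule sets (all expressed as data — criterion label, descriptor,
comparator, threshold — and overridable from a YAML config):

* **ro5** — Lipinski's rule of five.  A violation is MW > 500 Da,
  log P > 5, HBA > 10 or HBD > 5; the often-quoted fifth criterion
  (NRB <= 5) is reported as advisory but never enters the violation
  count.  Thresholds are inclusive by default (a molecule exactly at
  MW 500 does not violate); a strict mode is exposed because published
  percentages rarely say which convention they used.
* **drug_like / lead_like / fragment_like** — the standard screening
  subsets, with each printed criterion applied literally
  (drug-like: MW < 500, log P < 5, HBD <= 5, HBA <= 10;
  lead-like: 150 <= MW <= 350, log P <= 4, HBD <= 3, HBA <= 6;
  fragment-like: MW <= 250, -2 <= log P <= 3, HBD < 3, HBA < 6, NRB < 3).
* **ro3** — Jorgensen's rule of three for oral availability:
  log S > -5.7, Caco-2 permeability > 22 nm/s (strict), predicted
  primary metabolites < 7 (strict).

A record with a missing required descriptor never silently passes: the
affected criterion is marked not-evaluable, the outcome is flagged, and
``apply_ruleset`` tallies such records separately.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .chemio import Library
from .vector import DescriptorVector

_OPS = {
    "<": operator.lt, "<=": operator.le,
    ">": operator.gt, ">=": operator.ge,
}


@dataclass(frozen=True)
class Criterion:
    """One pass-condition: ``descriptor <op> threshold``."""

    label: str
    descriptor: str
    op: str  # "<", "<=", ">", ">="
    threshold: float
    advisory: bool = False  # reported but excluded from the violation count

    def evaluate(self, dv: DescriptorVector) -> str:
        value = dv.get(self.descriptor)
        if value is None:
            return "not-evaluable"
        return "pass" if _OPS[self.op](value, self.threshold) else "fail"

    @property
    def threshold_text(self) -> str:
        return f"{self.descriptor} {self.op} {self.threshold:g}"


@dataclass
class RuleOutcome:
    """Per-record result of applying one rule set."""

    rule_set: str
    criteria: list[tuple[str, str, str]]  # (label, threshold text, status)
    violations: int
    evaluable: bool

    @property
    def passed(self) -> bool:
        return self.evaluable and self.violations == 0


@dataclass(frozen=True)
class SubsetFlags:
    drug_like: bool
    lead_like: bool
    fragment_like: bool
    not_evaluable: tuple[str, ...] = ()  # subset names that could not be judged


def _ro5_criteria(boundaries: str) -> list[Criterion]:
    op = "<=" if boundaries == "inclusive" else "<"
    return [
        Criterion("MW", "MW", op, 500),
        Criterion("logP", "logP", op, 5),
        Criterion("HBA", "HBA", op, 10),
        Criterion("HBD", "HBD", op, 5),
        Criterion("NRB (advisory)", "NRB", "<=", 5, advisory=True),
    ]


#: The four shipped rule sets as data.  ro3's solubility threshold follows
#: Jorgensen's published rule (log S > -5.7); it is config-overridable.
RULESETS: dict[str, list[Criterion]] = {
    "ro5": _ro5_criteria("inclusive"),
    "ro5_strict": _ro5_criteria("strict"),
    "drug_like": [
        Criterion("MW", "MW", "<", 500),
        Criterion("logP", "logP", "<", 5),
        Criterion("HBD", "HBD", "<=", 5),
        Criterion("HBA", "HBA", "<=", 10),
    ],
    "lead_like": [
        Criterion("MW lower", "MW", ">=", 150),
        Criterion("MW upper", "MW", "<=", 350),
        Criterion("logP", "logP", "<=", 4),
        Criterion("HBD", "HBD", "<=", 3),
        Criterion("HBA", "HBA", "<=", 6),
    ],
    "fragment_like": [
        Criterion("MW", "MW", "<=", 250),
        Criterion("logP lower", "logP", ">=", -2),
        Criterion("logP upper", "logP", "<=", 3),
        Criterion("HBD", "HBD", "<", 3),
        Criterion("HBA", "HBA", "<", 6),
        Criterion("NRB", "NRB", "<", 3),
    ],
    "ro3": [
        Criterion("logS", "logS_wat", ">", -5.7),
        Criterion("Caco-2", "BIP_caco2", ">", 22),
        Criterion("# metab", "n_metab", "<", 7),
    ],
}


def load_rulesets(path: str | Path) -> dict[str, list[Criterion]]:
    """Load rule sets from YAML: {name: [{label, descriptor, op, threshold,
    advisory?}, ...]}.  Entries replace same-named shipped sets."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out = dict(RULESETS)
    for name, crits in raw.items():
        out[name] = [
            Criterion(
                c.get("label", c["descriptor"]), c["descriptor"],
                c["op"], float(c["threshold"]), bool(c.get("advisory", False)),
            )
            for c in crits
        ]
    return out


def evaluate_ruleset(
    dv: DescriptorVector, criteria: list[Criterion], name: str
) -> RuleOutcome:
    rows, violations, evaluable = [], 0, True
    for crit in criteria:
        status = crit.evaluate(dv)
        rows.append((crit.label, crit.threshold_text, status))
        if not crit.advisory:
            if status == "fail":
                violations += 1
            elif status == "not-evaluable":
                evaluable = False
    return RuleOutcome(name, rows, violations, evaluable)


def lipinski_violations(
    dv: DescriptorVector, boundaries: str = "inclusive"
) -> RuleOutcome:
    """Count rule-of-five violations (0-4); NRB reported as advisory only."""
    if boundaries not in ("inclusive", "strict"):
        raise ValueError(f"boundaries must be inclusive or strict, got {boundaries!r}")
    name = "ro5" if boundaries == "inclusive" else "ro5_strict"
    return evaluate_ruleset(dv, RULESETS[name], name)


def ro3_compliant(
    dv: DescriptorVector, criteria: list[Criterion] | None = None
) -> RuleOutcome:
    """Jorgensen rule-of-three outcome on imported solubility/permeability."""
    return evaluate_ruleset(dv, criteria or RULESETS["ro3"], "ro3")


def classify_subsets(dv: DescriptorVector) -> SubsetFlags:
    """Drug-like / lead-like / fragment-like flags, criteria as printed.

    A subset whose required descriptors are missing is False and listed in
    ``not_evaluable``.
    """
    flags, not_ev = {}, []
    for name in ("drug_like", "lead_like", "fragment_like"):
        outcome = evaluate_ruleset(dv, RULESETS[name], name)
        flags[name] = outcome.passed
        if not outcome.evaluable:
            not_ev.append(name)
    return SubsetFlags(
        flags["drug_like"], flags["lead_like"], flags["fragment_like"],
        tuple(not_ev),
    )


def apply_ruleset(
    library: Library,
    descriptors: dict[str, DescriptorVector],
    rule: str,
    rulesets: dict[str, list[Criterion]] | None = None,
) -> tuple[Library, pd.DataFrame, dict[str, int]]:
    """Filter a library by a named rule set.

    Returns (members passing the rule, per-record outcome table, counts).
    Records whose required descriptors are missing are excluded from the
    subset and counted under ``not_evaluable``.
    """
    sets = rulesets or RULESETS
    if rule not in sets:
        raise KeyError(
            f"unknown rule {rule!r}; available: {', '.join(sorted(sets))}"
        )
    criteria = sets[rule]
    rows, kept = [], []
    counts = {"passed": 0, "failed": 0, "not_evaluable": 0}
    for rec in library.records:
        dv = descriptors.get(rec.record_id, DescriptorVector())
        outcome = evaluate_ruleset(dv, criteria, rule)
        if not outcome.evaluable:
            status = "not-evaluable"
            counts["not_evaluable"] += 1
        elif outcome.passed:
            status = "pass"
            counts["passed"] += 1
            kept.append(rec)
        else:
            status = "fail"
            counts["failed"] += 1
        rows.append(
            {
                "record_id": rec.record_id,
                "status": status,
                "violations": outcome.violations,
                **{label: st for label, _t, st in outcome.criteria},
            }
        )
    filtered = Library(
        records=kept, name=f"{library.name}:{rule}", tag_schema=library.tag_schema
    )
    return filtered, pd.DataFrame(rows), counts
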