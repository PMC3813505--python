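"""Out-of-range descriptor counting ("#stars").

Each descriptor is checked against the range that covers 95% of known
drugs; one star is awarded per descriptor falling outside its range, so
0 stars is full DMPK compliance.  The shipped table is the 19
descriptor ranges with published bounds (see ``default_range_table``);
the original #stars statistic draws on a 24-descriptor set whose
remaining ranges are not public, so native scores are a documented
approximation.

Bounds are closed: a value exactly equal to a bound is in range.
Missing descriptors are skipped and reported, never counted as stars.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import yaml

from .chemio import Library
from .registry import validate_descriptor_name
from .vector import DescriptorVector

INF = math.inf

#: the recommended MDCK band used for range-compliance summaries
#: (distinct from star counting, where only low permeability is a concern)
MDCK_BAND = (25.0, 500.0)


@dataclass(frozen=True)
class ComplianceRange:
    """Closed interval [lower, upper] a drug-like value should fall into."""

    descriptor: str
    lower: float  # -inf for one-sided
    upper: float  # +inf for one-sided
    note: str = ""

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError(
                f"{self.descriptor}: lower {self.lower} > upper {self.upper}"
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class StarScore:
    stars: int
    violated: tuple[str, ...]
    evaluated: tuple[str, ...]
    skipped_missing: tuple[str, ...]


def default_range_table(variant: str = "footnote") -> list[ComplianceRange]:
    """The shipped 95%-of-drugs compliance ranges.

    ``variant="footnote"`` uses the tabulated bounds (logBB upper 1.0,
    logKhsa upper 1.2); ``variant="prose"`` the slightly wider bounds some
    narrative sections quote (1.2 and 1.5).  The permeability surrogates
    are one-sided for star purposes: their published anchors ("<5 low" for
    Caco-2, "<25 poor, >500 great" for MDCK) make only *low* permeability
    a concern, so exceeding the upper anchor never costs a star.  The
    25-500 nm/s MDCK band still exists as :data:`MDCK_BAND` for
    range-compliance reporting.  logHERG is one-sided (concern below -5).
    """
    if variant not in ("footnote", "prose"):
        raise ValueError(f"unknown variant {variant!r}")
    logbb_hi = 1.0 if variant == "footnote" else 1.2
    khsa_hi = 1.2 if variant == "footnote" else 1.5
    return [
        ComplianceRange("MW", 130, 725, "95% of drugs: 130-725 Da"),
        ComplianceRange("logP", -2, 6, "95% of drugs: -2 to 6"),
        ComplianceRange("HBA", 2, 20, "95% of drugs: 2-20"),
        ComplianceRange("HBD", 0, 6, "95% of drugs: 0-6"),
        ComplianceRange("NRB", 0, 15, "95% of drugs: 0-15"),
        ComplianceRange("logBB", -3.0, logbb_hi, "95% of drugs"),
        ComplianceRange("BIP_caco2", 5, INF, "<5 low; no upper penalty"),
        ComplianceRange("SASA_total", 300, 1000, "95% of drugs: 300-1000 A^2"),
        ComplianceRange("FOSA", 0, 750, "95% of drugs: 0-750 A^2"),
        ComplianceRange("V_mol", 500, 2000, "95% of drugs: 500-2000 A^3"),
        ComplianceRange("logS_wat", -6.0, 0.5, "95% of drugs: -6.0 to 0.5"),
        ComplianceRange("logKhsa", -1.5, khsa_hi, "95% of drugs"),
        ComplianceRange("MDCK", 25, INF, "<25 poor, >500 great; no upper penalty"),
        ComplianceRange("Ind_coh", 0.0, 0.05, "95% of drugs: 0.0-0.05"),
        ComplianceRange("Glob", 0.75, 0.95, "95% of drugs: 0.75-0.95"),
        ComplianceRange("QP_polrz", 13.0, 70.0, "95% of drugs: 13.0-70.0 A^3"),
        ComplianceRange("logHERG", -5, INF, "concern below -5"),
        ComplianceRange("logKp", -8.0, -1.0, "95% of drugs: -8.0 to -1.0"),
        ComplianceRange("n_metab", 1, 8, "95% of drugs: 1-8 reactions"),
    ]


def load_range_table(path: str | Path) -> list[ComplianceRange]:
    """Range table from YAML: {descriptor: {lower, upper, note?}}; the
    strings ``-inf``/``inf`` (or null) denote one-sided ranges."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    table = []
    for name, spec in raw.items():
        validate_descriptor_name(name)
        lo = spec.get("lower")
        hi = spec.get("upper")
        table.append(
            ComplianceRange(
                name,
                -INF if lo is None else float(lo),
                INF if hi is None else float(hi),
                str(spec.get("note", "")),
            )
        )
    return table


def star_score(
    dv: DescriptorVector, table: list[ComplianceRange] | None = None
) -> StarScore:
    """Count descriptors outside their 95%-of-drugs ranges.

    Output lists follow the table's descriptor order, so repeated runs are
    byte-identical.
    """
    if table is None:
        table = default_range_table()
    if not table:
        raise ValueError("empty compliance-range table")
    violated, evaluated, skipped = [], [], []
    for cr in table:
        value = dv.get(cr.descriptor)
        if value is None:
            skipped.append(cr.descriptor)
            continue
        evaluated.append(cr.descriptor)
        if not cr.contains(value):
            violated.append(cr.descriptor)
    return StarScore(
        stars=len(violated),
        violated=tuple(violated),
        evaluated=tuple(evaluated),
        skipped_missing=tuple(skipped),
    )


def star_distribution(
    library: Library,
    descriptors: dict[str, DescriptorVector],
    table: list[ComplianceRange] | None = None,
) -> dict:
    """Integer-binned #stars counts and percentages over evaluable records.

    A record is evaluable when at least one tabulated descriptor is
    present.  Returns ``{"counts": {stars: n}, "percentages": {stars: pct},
    "n": evaluable, "n_not_evaluable": m, "per_record": {id: stars}}``.
    """
    if table is None:
        table = default_range_table()
    per_record: dict[str, int] = {}
    n_not_evaluable = 0
    for rec in library.records:
        dv = descriptors.get(rec.record_id, DescriptorVector())
        score = star_score(dv, table)
        if not score.evaluated:
            n_not_evaluable += 1
            continue
        per_record[rec.record_id] = score.stars
    counts = Counter(per_record.values())
    n = len(per_record)
    return {
        "counts": dict(sorted(counts.items())),
        "percentages": {
            k: 100.0 * v / n for k, v in sorted(counts.items())
        } if n else {},
        "n": n,
        "n_not_evaluable": n_not_evaluable,
        "per_record": per_record,
    }
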