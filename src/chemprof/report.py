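"""Histograms, library-vs-library enhancement, and summary profiling.

Binning convention: half-open bins ``[lower, lower + width)`` anchored at
a configurable origin, each bin labeled by its lower edge (so with width
100 the label 0 covers 0-100).  Values below the origin get extra bins
extending downward.  One convention is used for every descriptor; axes
that are conventionally printed "301-400" therefore appear here as
300-400, a one-unit cosmetic difference on integer-style scales.

``enhancement`` sums the percentage-point differences of two libraries'
histograms over a descriptor range — e.g. how many more percent of
library A than of library B sits in the 300-500 Da window.  A bin is in
the range when its center is.

``profile`` produces the standard four-row summary (Total / drug-like /
lead-like / fragment-like), each row re-profiled on its members: size,
zero-star percentage, and per-descriptor means over evaluable records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .chemio import Library
from .rules import apply_ruleset, lipinski_violations
from .starscore import ComplianceRange, star_distribution
from .vector import DescriptorVector

logger = logging.getLogger(__name__)

#: Table-style summary columns, in report order.
PROFILE_DESCRIPTORS = (
    "MW", "logP", "HBA", "HBD", "NRB", "logBB", "BIP_caco2",
    "SASA_total", "FOSA", "V_mol", "logS_wat", "logKhsa", "MDCK",
    "Ind_coh", "Glob", "QP_polrz", "logHERG", "logKp", "n_metab",
)


@dataclass
class Histogram:
    descriptor: str
    bin_width: float
    lower_edges: list[float]  # strictly increasing
    counts: list[int]
    percentages: list[float]
    label_convention: str = "lower-limit"

    @property
    def n(self) -> int:
        return sum(self.counts)

    def as_dict(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "bin_width": self.bin_width,
            "lower_edges": self.lower_edges,
            "counts": self.counts,
            "percentages": self.percentages,
            "label_convention": self.label_convention,
        }


def bin_histogram(
    values,
    width: float,
    origin: float = 0.0,
    descriptor: str = "",
    edges: list[float] | None = None,
) -> Histogram:
    """Bin values into half-open [lower, lower+width) bins anchored at
    ``origin``.

    ``edges`` forces an explicit shared edge list (for cross-library
    comparison); otherwise edges span the data.  An empty value list
    yields an empty histogram with a warning.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    values = [float(v) for v in values if v is not None and not math.isnan(v)]
    if not values:
        logger.warning("bin_histogram(%s): no values", descriptor or "?")
        return Histogram(descriptor, width, [], [], [])
    if edges is None:
        k_lo = math.floor((min(values) - origin) / width)
        k_hi = math.floor((max(values) - origin) / width)
        edges = [origin + k * width for k in range(k_lo, k_hi + 1)]
    counts = [0] * len(edges)
    for v in values:
        k = math.floor((v - origin) / width) - round((edges[0] - origin) / width)
        if 0 <= k < len(edges):
            counts[k] += 1
    n = sum(counts)
    pct = [100.0 * c / n for c in counts] if n else [0.0] * len(counts)
    return Histogram(descriptor, width, list(edges), counts, pct)


def aligned_histograms(
    values_a, values_b, width: float, origin: float = 0.0, descriptor: str = ""
) -> tuple[Histogram, Histogram]:
    """Histograms of two value sets on one shared edge list."""
    both = [v for v in list(values_a) + list(values_b)
            if v is not None and not math.isnan(float(v))]
    ref = bin_histogram(both, width, origin, descriptor)
    return (
        bin_histogram(values_a, width, origin, descriptor, edges=ref.lower_edges),
        bin_histogram(values_b, width, origin, descriptor, edges=ref.lower_edges),
    )


def enhancement(a: Histogram, b: Histogram, lo: float, hi: float) -> float:
    """Percentage-point enhancement of a over b within [lo, hi].

    Sum over bins whose center lies in [lo, hi] of (pct_a - pct_b).  Over
    the full range this is 0 by conservation (both sum to 100).
    """
    if a.bin_width != b.bin_width or a.lower_edges != b.lower_edges:
        raise ValueError("histograms have mismatched bin structure")
    total = 0.0
    for edge, pa, pb in zip(a.lower_edges, a.percentages, b.percentages):
        center = edge + a.bin_width / 2.0
        if lo <= center <= hi:
            total += pa - pb
    return total


# ---------------------------------------------------------------------------
# Table-style library profile


def _summary_stats(
    records, descriptors: dict[str, DescriptorVector], names
) -> dict[str, dict]:
    out = {}
    for name in names:
        vals = [
            descriptors[r.record_id][name]
            for r in records
            if r.record_id in descriptors and name in descriptors[r.record_id]
        ]
        if vals:
            arr = np.asarray(vals, dtype=float)
            out[name] = {
                "n": int(arr.size),
                "mean": float(arr.mean()),
                "min": float(arr.min()),
                "max": float(arr.max()),
            }
        else:
            out[name] = {"n": 0, "mean": None, "min": None, "max": None}
    return out


def profile(
    library: Library,
    descriptors: dict[str, DescriptorVector],
    panel=PROFILE_DESCRIPTORS,
    range_table: list[ComplianceRange] | None = None,
    boundaries: str = "inclusive",
) -> dict:
    """Full library profile.

    Contains the four-row subset summary (Total, Drug-like, Lead-like,
    Fragment-like) with per-descriptor means and zero-star percentages,
    rule-of-five violation counts with percentages over both the full
    library and the evaluable subset, and the ro3 compliance fraction.
    """
    ro5_name = "ro5" if boundaries == "inclusive" else "ro5_strict"
    subsets: dict[str, list] = {"Total": list(library.records)}
    for rule, row_name in (
        ("drug_like", "Drug-like"),
        ("lead_like", "Lead-like"),
        ("fragment_like", "Fragment-like"),
    ):
        filtered, _table, _counts = apply_ruleset(library, descriptors, rule)
        subsets[row_name] = list(filtered.records)

    rows = {}
    for row_name, records in subsets.items():
        sub_lib = Library(records=records, name=row_name,
                          tag_schema=library.tag_schema)
        stars = star_distribution(sub_lib, descriptors, range_table)
        zero = stars["counts"].get(0, 0)
        rows[row_name] = {
            "size": len(records),
            "pct_zero_stars": (100.0 * zero / stars["n"]) if stars["n"] else None,
            "descriptors": _summary_stats(records, descriptors, panel),
        }

    # rule-of-five violation distribution
    viol_counts: dict[int, int] = {}
    n_eval = 0
    for rec in library.records:
        dv = descriptors.get(rec.record_id, DescriptorVector())
        outcome = lipinski_violations(dv, boundaries=boundaries)
        if not outcome.evaluable:
            continue
        n_eval += 1
        viol_counts[outcome.violations] = viol_counts.get(outcome.violations, 0) + 1
    n_total = len(library.records)
    zero_v = viol_counts.get(0, 0)
    lt2 = viol_counts.get(0, 0) + viol_counts.get(1, 0)
    ro5 = {
        "boundaries": boundaries,
        "violation_counts": dict(sorted(viol_counts.items())),
        "n_evaluable": n_eval,
        "n_total": n_total,
        "pct_zero_of_evaluable": 100.0 * zero_v / n_eval if n_eval else None,
        "pct_zero_of_total": 100.0 * zero_v / n_total if n_total else None,
        "pct_lt2_of_evaluable": 100.0 * lt2 / n_eval if n_eval else None,
        "pct_lt2_of_total": 100.0 * lt2 / n_total if n_total else None,
    }

    _f, _t, ro3_counts = apply_ruleset(library, descriptors, "ro3")
    ro3_eval = ro3_counts["passed"] + ro3_counts["failed"]
    ro3 = {
        **ro3_counts,
        "pct_compliant_of_evaluable":
            100.0 * ro3_counts["passed"] / ro3_eval if ro3_eval else None,
        "pct_compliant_of_total":
            100.0 * ro3_counts["passed"] / n_total if n_total else None,
    }

    return {
        "library": library.name,
        "n_records": n_total,
        "rows": rows,
        "ro5": ro5,
        "ro3": ro3,
        "stars": {
            k: v for k, v in star_distribution(
                library, descriptors, range_table
            ).items() if k != "per_record"
        },
    }


def descriptor_histograms(
    library: Library,
    descriptors: dict[str, DescriptorVector],
    widths: dict[str, float] | None = None,
) -> dict[str, Histogram]:
    """Per-descriptor histograms with the conventional bin widths
    (MW 100 Da; counts and log-unit descriptors width 1)."""
    default_widths = {"MW": 100.0, "logP": 1.0, "HBA": 1.0, "HBD": 1.0,
                      "NRB": 1.0, "TPSA": 20.0}
    widths = {**default_widths, **(widths or {})}
    out = {}
    for name, width in widths.items():
        vals = [
            descriptors[r.record_id][name]
            for r in library.records
            if r.record_id in descriptors and name in descriptors[r.record_id]
        ]
        if vals:
            out[name] = bin_histogram(vals, width, 0.0, name)
    return out
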