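"""DMPK formulas and absorption threshold summaries.

Two closed-form corrections are implemented here:

* **similarity-adjusted solubility** — predicted properties are blended
  toward the experimental value of the most similar training-set
  analogue once the similarity ``s`` exceeds 0.9.  The blend is the
  unique affine interpolation satisfying both stated boundary
  conditions: below s = 0.9 the raw prediction is kept unchanged, and at
  s = 1 (the query *is* the analogue) the experimental value is returned
  exactly.  The interpolation weight is lambda = (s - 0.9)/0.1, clamped
  to [0, 1].
* **maximum transdermal transport rate** —
  ``Jm = C * 10^logKp * 10^logS * MW`` in ug cm^-2 hr^-1, with the unit
  constant C = 1000 fixed by dimensional analysis of
  cm/hr x mol/L x g/mol (1 L = 1000 cm^3, g -> ug cancels mol).  C is
  config-exposed.

``absorption_summary`` produces the report-level fractions (high oral
absorption, Jm above the 100 ug cm^-2 hr^-1 cutoff, CNS activity,
per-descriptor range compliance).
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemio import Library
from .starscore import MDCK_BAND, ComplianceRange, default_range_table
from .vector import DescriptorVector

DEFAULT_JM_CONSTANT = 1000.0  # unit constant C in Jm = C * Kp * S * MW
DEFAULT_JM_CUTOFF = 100.0  # ug cm^-2 hr^-1
SIMILARITY_KNEE = 0.9  # below this, predictions are used as-is


@dataclass(frozen=True)
class SolubilityAdjustmentInput:
    """Inputs to the similarity-based property adjustment."""

    p_qp_query: float  # predicted property of the query molecule
    p_qp_similar: float  # predicted property of its most similar analogue
    p_exp_similar: float  # experimental property of that analogue
    similarity: float  # s in [0, 1]


def adjust_solubility(inp: SolubilityAdjustmentInput) -> float:
    """Similarity-adjusted property value (continuous in s at 0.9).

    Raises ValueError when the similarity is outside [0, 1].
    """
    s = inp.similarity
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"similarity must be in [0, 1], got {s}")
    if s < SIMILARITY_KNEE:
        return inp.p_qp_query
    lam = min(1.0, max(0.0, (s - SIMILARITY_KNEE) / (1.0 - SIMILARITY_KNEE)))
    return inp.p_qp_query + lam * (inp.p_exp_similar - inp.p_qp_similar)


def transdermal_rate(
    log_kp: float | None,
    log_s: float | None,
    mw: float | None,
    constant: float = DEFAULT_JM_CONSTANT,
) -> float | None:
    """Maximum transdermal transport rate Jm (ug cm^-2 hr^-1).

    Missing inputs yield None; a molecule with no aqueous solubility
    (log S modeled as None with zero solubility) transports nothing.
    Monotone increasing in each of Kp, S and MW.
    """
    if log_kp is None or log_s is None or mw is None:
        return None
    return constant * (10.0 ** log_kp) * (10.0 ** log_s) * mw


def attach_jm(descriptors: dict[str, DescriptorVector],
              constant: float = DEFAULT_JM_CONSTANT) -> int:
    """Fill in Jm for every vector with logKp, logS_wat and MW present.

    Imported Jm tags are left alone.  Returns the number filled.
    """
    n = 0
    for dv in descriptors.values():
        if "Jm" in dv:
            continue
        jm = transdermal_rate(dv.get("logKp"), dv.get("logS_wat"), dv.get("MW"),
                              constant)
        if jm is not None:
            dv.set("Jm", jm, "native")
            n += 1
    return n


def _fraction(descriptors, predicate, needed) -> dict:
    n_eval = n_true = 0
    for dv in descriptors.values():
        if not dv.has_all(needed):
            continue
        n_eval += 1
        if predicate(dv):
            n_true += 1
    return {
        "n_evaluable": n_eval,
        "n_true": n_true,
        "percent": (100.0 * n_true / n_eval) if n_eval else None,
    }


def absorption_summary(
    library: Library,
    descriptors: dict[str, DescriptorVector],
    jm_cutoff: float = DEFAULT_JM_CUTOFF,
    pct_abs_cutoff: float = 90.0,
    cns_cutoff: float = 1.0,
    range_table: list[ComplianceRange] | None = None,
) -> dict:
    """Library-level absorption/distribution threshold fractions.

    Each row reports the fraction of evaluable records meeting one
    threshold: high qualitative oral absorption (= 3), complete (= 100%)
    and high (> cutoff) percent oral absorption, Jm above its cutoff, CNS
    score above its cutoff, and — per compliance range — the fraction of
    records inside that descriptor's 95%-of-drugs range.  Thresholds are
    echoed in the output so reports are self-describing.
    """
    if range_table is None:
        range_table = default_range_table()
    descriptors = {
        rec.record_id: descriptors.get(rec.record_id, DescriptorVector())
        for rec in library.records
    }
    summary: dict = {
        "thresholds": {
            "jm_cutoff": jm_cutoff,
            "pct_abs_cutoff": pct_abs_cutoff,
            "cns_cutoff": cns_cutoff,
        },
        "n_records": len(library.records),
        "rows": {},
    }
    rows = summary["rows"]
    rows["qual_oral_abs_high"] = _fraction(
        descriptors, lambda dv: dv["qual_oral_abs"] == 3, ["qual_oral_abs"]
    )
    rows["pct_oral_abs_complete"] = _fraction(
        descriptors, lambda dv: dv["pct_oral_abs"] >= 100.0, ["pct_oral_abs"]
    )
    rows["pct_oral_abs_high"] = _fraction(
        descriptors, lambda dv: dv["pct_oral_abs"] > pct_abs_cutoff,
        ["pct_oral_abs"],
    )
    rows["jm_high"] = _fraction(
        descriptors, lambda dv: dv["Jm"] > jm_cutoff, ["Jm"]
    )
    rows["cns_active"] = _fraction(
        descriptors, lambda dv: dv["CNS"] > cns_cutoff, ["CNS"]
    )
    for cr in range_table:
        rows[f"in_range_{cr.descriptor}"] = _fraction(
            descriptors, lambda dv, cr=cr: cr.contains(dv[cr.descriptor]),
            [cr.descriptor],
        )
    lo, hi = MDCK_BAND
    rows["in_band_MDCK"] = _fraction(
        descriptors, lambda dv: lo <= dv["MDCK"] <= hi, ["MDCK"]
    )
    return summary
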