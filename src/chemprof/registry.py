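"""Canonical descriptor registry.

Every descriptor handled anywhere in the package is declared here once,
with its unit and value kind.  Report columns, tag schemas and range
tables all refer to these canonical names.
"""

from __future__ import annotations

from typing import NamedTuple


class DescriptorInfo(NamedTuple):
    unit: str
    kind: str  # "real" | "count" | "text"
    label: str  # display label used in reports


#: Canonical descriptor set.  Counts are stored as floats because imported
#: library averages are legitimately fractional (e.g. a mean HBD of 1.67).
DESCRIPTORS: dict[str, DescriptorInfo] = {
    "MW": DescriptorInfo("Da", "real", "MW"),
    "logP": DescriptorInfo("log units", "real", "log P"),
    "HBA": DescriptorInfo("count", "count", "HBA"),
    "HBD": DescriptorInfo("count", "count", "HBD"),
    "NRB": DescriptorInfo("count", "count", "NRB"),
    "NR": DescriptorInfo("count", "count", "NR"),
    "NO": DescriptorInfo("count", "count", "NO"),
    "NCC": DescriptorInfo("count", "count", "NCC"),
    "TPSA": DescriptorInfo("A^2", "real", "TPSA"),
    "SASA_total": DescriptorInfo("A^2", "real", "S_mol"),
    "FOSA": DescriptorInfo("A^2", "real", "S_mol,hfob"),
    "V_mol": DescriptorInfo("A^3", "real", "V_mol"),
    "Ind_coh": DescriptorInfo("dimensionless", "real", "Ind_coh"),
    "Glob": DescriptorInfo("dimensionless", "real", "Glob"),
    "logS_wat": DescriptorInfo("log mol/L", "real", "log S_wat"),
    "CIlogS": DescriptorInfo("log mol/L", "real", "CI log S"),
    "logKhsa": DescriptorInfo("log units", "real", "log K_HSA"),
    "logBB": DescriptorInfo("log units", "real", "log B/B"),
    "BIP_caco2": DescriptorInfo("nm/s", "real", "BIP_caco-2"),
    "MDCK": DescriptorInfo("nm/s", "real", "MDCK"),
    "QP_polrz": DescriptorInfo("A^3", "real", "QP_polrz"),
    "logHERG": DescriptorInfo("log units", "real", "log HERG"),
    "logKp": DescriptorInfo("log cm/hr", "real", "log K_p"),
    "n_metab": DescriptorInfo("count", "count", "# metab"),
    "qual_oral_abs": DescriptorInfo("scale 1-3", "count", "qual. oral abs."),
    "pct_oral_abs": DescriptorInfo("%", "real", "% oral abs."),
    "CNS": DescriptorInfo("scale -2..+2", "real", "CNS"),
    "Jm": DescriptorInfo("ug/cm^2/hr", "real", "J_m"),
}

#: Descriptors that only make sense as non-negative integers when native.
COUNT_DESCRIPTORS = frozenset(
    n for n, info in DESCRIPTORS.items() if info.kind == "count"
)

PROVENANCE_NATIVE = "native"
PROVENANCE_IMPORTED = "imported"


def validate_descriptor_name(name: str) -> str:
    if name not in DESCRIPTORS:
        raise KeyError(
            f"unknown descriptor {name!r}; known: {', '.join(sorted(DESCRIPTORS))}"
        )
    return name
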