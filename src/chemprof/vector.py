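"""The :class:`DescriptorVector` container.

A DescriptorVector is a sparse mapping from canonical descriptor names to
numeric values, each entry carrying a provenance flag: ``native`` (computed
in this package from the structure) or ``imported`` (parsed from property
tags written by external prediction software).  Absent entries are
"missing"; the rule and scoring layers treat missing explicitly and never
let a record pass a filter silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator

from .registry import DESCRIPTORS, validate_descriptor_name

logger = logging.getLogger(__name__)

MISSING = "missing"


@dataclass
class DescriptorVector:
    """Named numeric descriptors with per-entry provenance."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value: float, provenance: str) -> None:
        validate_descriptor_name(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return
        self.values[name] = float(value)
        self.provenance[name] = provenance

    def get(self, name: str, default: float | None = None) -> float | None:
        return self.values.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def has_all(self, names) -> bool:
        return all(n in self.values for n in names)

    def missing(self, names) -> list[str]:
        return [n for n in names if n not in self.values]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    @classmethod
    def from_dict(
        cls, values: dict[str, float], provenance: str = "imported"
    ) -> "DescriptorVector":
        dv = cls()
        for name, value in values.items():
            dv.set(name, value, provenance)
        return dv


def merge_descriptors(
    native: DescriptorVector,
    imported: DescriptorVector,
    policy: str = "prefer_imported",
    conflict_rel_tol: float = 0.10,
) -> DescriptorVector:
    """Merge native and imported descriptor vectors under a preference policy.

    When both sources carry a descriptor and the values disagree by more
    than ``conflict_rel_tol`` (relative to the larger magnitude), a warning
    is logged; the policy winner is kept either way.
    """
    if policy not in ("prefer_imported", "prefer_native"):
        raise ValueError(f"unknown merge policy {policy!r}")
    merged = DescriptorVector()
    for name in DESCRIPTORS:
        in_native = name in native
        in_imported = name in imported
        if in_native and in_imported:
            nv, iv = native[name], imported[name]
            scale = max(abs(nv), abs(iv))
            if scale > 0 and abs(nv - iv) / scale > conflict_rel_tol:
                logger.warning(
                    "descriptor conflict for %s: native=%g imported=%g "
                    "(rel. diff > %.0f%%)",
                    name, nv, iv, 100 * conflict_rel_tol,
                )
            if policy == "prefer_imported":
                merged.set(name, iv, imported.provenance[name])
            else:
                merged.set(name, nv, native.provenance[name])
        elif in_native:
            merged.set(name, native[name], native.provenance[name])
        elif in_imported:
            merged.set(name, imported[name], imported.provenance[name])
    return merged
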