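"""Reading and writing compound libraries.

Supported formats:

``sdf``
    MDL SDF, V2000 connection tables only.  Property tags are preserved
    verbatim on each record; structures are parsed with RDKit.  V3000
    records are rejected with a clear error rather than mis-parsed.
``smiles``
    One SMILES per line, optionally followed by a tab and a record id.
``table``
    UTF-8 tab-separated descriptor table: a header row of canonical
    descriptor names (plus an optional ``record_id`` column), one row per
    record.  Records read this way carry no structure — they are pure
    descriptor vectors, which is how boundary fixtures exactly on rule
    thresholds are expressed.

Malformed records are skipped with a logged warning and counted; a file
that yields zero parseable records is a fatal error.  Record ids come from
the SDF title line (``mol<ordinal>`` when blank) and duplicates are
deterministically suffixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import yaml
from rdkit import Chem
from rdkit import RDLogger

from .registry import DESCRIPTORS, validate_descriptor_name
from .vector import DescriptorVector

logger = logging.getLogger(__name__)

# RDKit's C++-level parse chatter is redundant with our own warnings.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


class LibraryError(Exception):
    """Fatal library IO error (unreadable file, zero parseable records...)."""


class TagSpec(NamedTuple):
    descriptor: str  # canonical descriptor name (registry key)
    unit: str
    kind: str  # "real" | "count"


#: tag name -> TagSpec.  Default schema covers the property-tag names the
#: QikProp / Maestro toolchain writes into SDF exports.
TagSchema = dict[str, TagSpec]

DEFAULT_TAG_SCHEMA: TagSchema = {
    "mol_MW": TagSpec("MW", "Da", "real"),
    "QPlogPo/w": TagSpec("logP", "log units", "real"),
    "accptHB": TagSpec("HBA", "count", "count"),
    "donorHB": TagSpec("HBD", "count", "count"),
    "#rotor": TagSpec("NRB", "count", "count"),
    "#ringatoms": TagSpec("NR", "count", "count"),
    "SASA": TagSpec("SASA_total", "A^2", "real"),
    "FOSA": TagSpec("FOSA", "A^2", "real"),
    "volume": TagSpec("V_mol", "A^3", "real"),
    "glob": TagSpec("Glob", "dimensionless", "real"),
    "QPlogS": TagSpec("logS_wat", "log mol/L", "real"),
    "CIQPlogS": TagSpec("CIlogS", "log mol/L", "real"),
    "QPlogKhsa": TagSpec("logKhsa", "log units", "real"),
    "QPlogBB": TagSpec("logBB", "log units", "real"),
    "QPPCaco": TagSpec("BIP_caco2", "nm/s", "real"),
    "QPPMDCK": TagSpec("MDCK", "nm/s", "real"),
    "QPpolrz": TagSpec("QP_polrz", "A^3", "real"),
    "QPlogHERG": TagSpec("logHERG", "log units", "real"),
    "QPlogKp": TagSpec("logKp", "log cm/hr", "real"),
    "#metab": TagSpec("n_metab", "count", "count"),
    "HumanOralAbsorption": TagSpec("qual_oral_abs", "scale 1-3", "count"),
    "PercentHumanOralAbsorption": TagSpec("pct_oral_abs", "%", "real"),
    "CNS": TagSpec("CNS", "scale -2..+2", "real"),
    "Jm": TagSpec("Jm", "ug/cm^2/hr", "real"),
}

# Canonical descriptor names are always accepted as tag names too, so a
# library written by this package reads back without a custom schema.
for _name, _info in DESCRIPTORS.items():
    DEFAULT_TAG_SCHEMA.setdefault(_name, TagSpec(_name, _info.unit, _info.kind))


def load_tag_schema(path: str | Path) -> TagSchema:
    """Load a tag schema from a YAML file.

    Layout: ``{tag name: {descriptor: ..., unit: ..., kind: ...}}``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise LibraryError(f"tag schema {path}: expected a mapping")
    schema: TagSchema = {}
    for tag, spec in raw.items():
        desc = validate_descriptor_name(spec["descriptor"])
        schema[str(tag)] = TagSpec(
            desc, str(spec.get("unit", "")), str(spec.get("kind", "real"))
        )
    return schema


@dataclass
class MoleculeRecord:
    """One parsed library entry: structure (optional) + raw property tags."""

    record_id: str
    title: str = ""
    mol: Chem.Mol | None = None
    raw_tags: dict[str, str] = field(default_factory=dict)
    source_line: int = 0

    @property
    def has_structure(self) -> bool:
        return self.mol is not None

    @property
    def has_3d(self) -> bool:
        if self.mol is None or self.mol.GetNumConformers() == 0:
            return False
        return self.mol.GetConformer().Is3D()

    @property
    def atoms(self) -> list[tuple[str, int, tuple[float, float, float] | None]]:
        """(element symbol, formal charge, optional 3D coordinates in Angstrom)."""
        if self.mol is None:
            return []
        conf = self.mol.GetConformer() if self.has_3d else None
        out = []
        for atom in self.mol.GetAtoms():
            xyz = None
            if conf is not None:
                p = conf.GetAtomPosition(atom.GetIdx())
                xyz = (p.x, p.y, p.z)
            out.append((atom.GetSymbol(), atom.GetFormalCharge(), xyz))
        return out

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        if self.mol is None:
            return []
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]


@dataclass
class Library:
    """An ordered collection of MoleculeRecords plus its tag schema."""

    records: list[MoleculeRecord] = field(default_factory=list)
    name: str = ""
    tag_schema: TagSchema = field(default_factory=lambda: dict(DEFAULT_TAG_SCHEMA))
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]


# ---------------------------------------------------------------------------
# reading


def _dedupe_ids(records: list[MoleculeRecord]) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        count = seen.get(rec.record_id, 0)
        seen[rec.record_id] = count + 1
        if count:
            new_id = f"{rec.record_id}_{count + 1}"
            logger.warning(
                "duplicate record_id %r at line %d renamed to %r",
                rec.record_id, rec.source_line, new_id,
            )
            seen[new_id] = seen.get(new_id, 0) + 1
            rec.record_id = new_id


def _split_sdf(text: str) -> list[tuple[int, list[str]]]:
    """Split SDF text into (1-based start line, record lines) chunks."""
    chunks: list[tuple[int, list[str]]] = []
    current: list[str] = []
    start = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "$$$$":
            chunks.append((start, current))
            current = []
            start = lineno + 1
        else:
            current.append(line)
    if any(l.strip() for l in current):  # trailing record without $$$$
        chunks.append((start, current))
    return chunks


def _parse_sdf_tags(lines: list[str]) -> dict[str, str]:
    """Parse the data-item block that follows ``M  END``, tags verbatim."""
    tags: dict[str, str] = {}
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            lo = line.find("<")
            if lo >= 0:
                tag = line[lo + 1 :].split(">", 1)[0]
            else:
                tag = line[1:].strip()
            value_lines = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                value_lines.append(lines[i])
                i += 1
            tags[tag] = "\n".join(value_lines)
        i += 1
    return tags


def _read_sdf(path: Path) -> tuple[list[MoleculeRecord], int]:
    text = path.read_text(encoding="utf-8", errors="replace")
    records: list[MoleculeRecord] = []
    n_skipped = 0
    for ordinal, (start_line, lines) in enumerate(_split_sdf(text), start=1):
        if len(lines) >= 4 and "V3000" in lines[3]:
            raise LibraryError(
                f"{path}: record at line {start_line} is V3000; "
                "only V2000 connection tables are supported"
            )
        try:
            end = next(
                i for i, l in enumerate(lines) if l.startswith("M  END")
            )
        except StopIteration:
            logger.warning(
                "%s: record at line %d has no 'M  END'; skipped", path, start_line
            )
            n_skipped += 1
            continue
        molblock = "\n".join(lines[: end + 1]) + "\n"
        mol = Chem.MolFromMolBlock(molblock, sanitize=True, removeHs=False)
        if mol is None:
            logger.warning(
                "%s: unparseable record at line %d; skipped", path, start_line
            )
            n_skipped += 1
            continue
        title = lines[0].strip() if lines else ""
        record_id = title if title else f"mol{ordinal}"
        records.append(
            MoleculeRecord(
                record_id=record_id,
                title=title,
                mol=mol,
                raw_tags=_parse_sdf_tags(lines[end + 1 :]),
                source_line=start_line,
            )
        )
    return records, n_skipped


def _read_smiles(path: Path) -> tuple[list[MoleculeRecord], int]:
    records: list[MoleculeRecord] = []
    n_skipped = 0
    ordinal = 0
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        ordinal += 1
        parts = line.split("\t")
        smiles = parts[0].strip()
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            logger.warning("%s: bad SMILES at line %d; skipped", path, lineno)
            n_skipped += 1
            continue
        rid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"mol{ordinal}"
        records.append(
            MoleculeRecord(record_id=rid, title=rid, mol=mol, source_line=lineno)
        )
    return records, n_skipped


def _read_table(path: Path) -> tuple[list[MoleculeRecord], int]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] == 0:
        return [], 0
    id_col = "record_id" if "record_id" in df.columns else None
    records = []
    for ordinal, (lineno, row) in enumerate(df.iterrows(), start=1):
        rid = row[id_col] if id_col and row[id_col] else f"mol{ordinal}"
        tags = {
            c: row[c]
            for c in df.columns
            if c != id_col and row[c] != ""
        }
        records.append(
            MoleculeRecord(
                record_id=str(rid), title=str(rid), mol=None,
                raw_tags=tags, source_line=int(lineno) + 2,
            )
        )
    return records, 0


def read_library(
    path: str | Path,
    format: str | None = None,
    tag_schema: TagSchema | None = None,
    name: str | None = None,
) -> Library:
    """Read a compound library from ``path``.

    ``format`` is one of ``sdf``, ``smiles``, ``table``; when omitted it is
    inferred from the file suffix.  Raises :class:`LibraryError` for an
    unreadable file or one with zero parseable records.
    """
    path = Path(path)
    if not path.is_file():
        raise LibraryError(f"cannot read library: no such file {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".sdf": "sdf", ".sd": "sdf", ".mol": "sdf",
            ".smi": "smiles", ".smiles": "smiles",
            ".tsv": "table", ".txt": "table", ".tab": "table",
        }.get(suffix)
        if format is None:
            raise LibraryError(f"cannot infer format from suffix {suffix!r}")
    readers = {"sdf": _read_sdf, "smiles": _read_smiles, "table": _read_table}
    if format not in readers:
        raise LibraryError(f"unknown format {format!r}; expected sdf, smiles or table")
    try:
        records, n_skipped = readers[format](path)
    except OSError as exc:
        raise LibraryError(f"cannot read library {path}: {exc}") from exc
    if not records:
        raise LibraryError(f"{path}: zero parseable records")
    _dedupe_ids(records)
    if n_skipped:
        logger.warning("%s: skipped %d malformed record(s)", path, n_skipped)
    return Library(
        records=records,
        name=name if name is not None else path.stem,
        tag_schema=dict(tag_schema) if tag_schema else dict(DEFAULT_TAG_SCHEMA),
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# descriptor extraction from tags


def _parse_tag_value(text: str, kind: str, tag: str) -> float | None:
    text = text.strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        logger.warning("tag %r: unparseable value %r; treated as missing", tag, text)
        return None
    if kind == "count" and not value.is_integer():
        # Fractional counts occur legitimately in library-average rows.
        logger.debug("tag %r declared count but value %g is fractional", tag, value)
    return value


def extract_descriptors(
    record: MoleculeRecord, schema: TagSchema
) -> DescriptorVector:
    """Parse schema-matched property tags into an imported DescriptorVector.

    Unmatched tags are ignored; unparseable values degrade to missing with a
    warning — nothing here is fatal.
    """
    dv = DescriptorVector()
    for tag, raw in record.raw_tags.items():
        spec = schema.get(tag)
        if spec is None:
            continue
        value = _parse_tag_value(raw, spec.kind, tag)
        if value is not None:
            dv.set(spec.descriptor, value, "imported")
    return dv


# ---------------------------------------------------------------------------
# writing


def _record_to_sdf(record: MoleculeRecord) -> str:
    block = Chem.MolToMolBlock(record.mol, includeStereo=True)
    # put the record id on the title line for round-tripping
    lines = block.split("\n")
    lines[0] = record.record_id
    out = ["\n".join(lines).rstrip("\n")]
    for tag, value in record.raw_tags.items():
        out.append(f">  <{tag}>")
        out.append(value)
        out.append("")
    out.append("$$$$")
    return "\n".join(out) + "\n"


def write_library(library: Library, path: str | Path, format: str = "sdf") -> None:
    """Write ``library`` to ``path`` as ``sdf`` or as a descriptor ``table``.

    SDF writing preserves structures (coordinates to 4 decimals, the MDL
    convention), tag names and tag values so that a read-back reproduces
    the library.  Structure-less records cannot be written to SDF and are
    skipped with a warning.
    """
    path = Path(path)
    if not library.records:
        raise LibraryError("refusing to write an empty library")
    if format == "sdf":
        chunks = []
        for rec in library.records:
            if rec.mol is None:
                logger.warning(
                    "record %r has no structure; omitted from SDF output",
                    rec.record_id,
                )
                continue
            chunks.append(_record_to_sdf(rec))
        if not chunks:
            raise LibraryError("no records with structures to write as SDF")
        try:
            path.write_text("".join(chunks), encoding="utf-8")
        except OSError as exc:
            raise LibraryError(f"cannot write {path}: {exc}") from exc
    elif format == "table":
        import pandas as pd

        schema = library.tag_schema
        rows = []
        for rec in library.records:
            dv = extract_descriptors(rec, schema)
            row: dict[str, object] = {"record_id": rec.record_id}
            row.update(dv.as_dict())
            rows.append(row)
        df = pd.DataFrame(rows)
        cols = ["record_id"] + [c for c in DESCRIPTORS if c in df.columns]
        try:
            df.to_csv(path, sep="\t", index=False, columns=cols)
        except OSError as exc:
            raise LibraryError(f"cannot write {path}: {exc}") from exc
    else:
        raise LibraryError(f"unknown output format {format!r}; expected sdf or table")
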