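"""RECAP fragmentation and most-common-substructure frequency ranking.

Molecules are cut at the retrosynthetically tractable bond types of the
RECAP scheme — amide, ester, amine (acyclic and cyclic), urea (as a pair
of amide cuts), ether, olefin, quaternary nitrogen, aromatic N -
aliphatic C, lactam N - aliphatic C, aromatic C - aromatic C,
sulphonamide.  Ring bonds are never cleaved, so cyclic cores survive
intact.  Every matching bond is cut simultaneously in a single pass, so
the fragments partition the parent's atoms: non-attachment heavy atoms
always sum to the parent's heavy-atom count, and re-fragmenting a
fragment returns it unchanged.  (This differs from hierarchy-style
decompositions, which delete linker atoms such as the urea carbonyl or
the ether oxygen during cleavage; here linkers survive as small
fragments and are suppressed from rankings by the minimum-size filter.)

Attachment points are marked with a wildcard atom and fragments are
canonicalized, so chemically identical pieces from different parents
merge.  Ranking fragment keys by the number of distinct parent molecules
containing them gives the library's most common substructures; molecules
above a molar-weight cutoff (default 700 Da) are excluded first, since
substructure analysis of very large structures is dominated by one-off
scaffolds.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from rdkit import Chem

from .chemio import Library, MoleculeRecord
from .vector import DescriptorVector

logger = logging.getLogger(__name__)

DEFAULT_MW_CUTOFF = 700.0
DEFAULT_MIN_HEAVY = 4

#: Cleavable-bond patterns: each SMARTS names exactly two atoms; the bond
#: between them is cut.  Atoms already carrying an attachment point
#: (bonded to a dummy) are excluded everywhere, which is what makes
#: fragmentation idempotent.
_NOT_DUMMY = ";!$([*]~[#0])"
_BOND_SMARTS: list[tuple[str, str]] = [
    ("amide",
     f"[$([C;!R](=O)){_NOT_DUMMY}:1]-!@[$([N;+0;!D1]){_NOT_DUMMY}:2]"),
    ("ester",
     f"[$([C;!R](=O)){_NOT_DUMMY}:1]-!@[$([O;+0;D2]){_NOT_DUMMY}:2]"),
    ("amine",
     f"[$([N;+0;!D1;!R;!$(N-C=[#7,#8,#15,#16]);!$(N=*);!$(N-S=O)])"
     f"{_NOT_DUMMY}:1]-!@[$([#6;!$([#6]=[!#6])]){_NOT_DUMMY}:2]"),
    ("cyclic amine",
     f"[$([N;+0;R;D3;!$(N-C=[#7,#8,#15,#16])]){_NOT_DUMMY}:1]"
     f"-!@[$([#6]){_NOT_DUMMY}:2]"),
    ("lactam N - aliphatic C",
     f"[$([N;+0;R;$(N@-C=O)]){_NOT_DUMMY}:1]"
     f"-!@[$([C;!$(C=O)]){_NOT_DUMMY}:2]"),
    ("ether",
     f"[$([#6]){_NOT_DUMMY}:1]-!@"
     f"[$([O;+0;D2;$(O([#6])[#6]);!$(O[#6]=[O,S,N,P])]){_NOT_DUMMY}:2]"),
    ("olefin",
     f"[$([C;!$(C=[O,N,S])]){_NOT_DUMMY}:1]=!@"
     f"[$([C;!$(C=[O,N,S])]){_NOT_DUMMY}:2]"),
    ("quaternary N",
     f"[$([N;+1;D4]){_NOT_DUMMY}:1]-!@[$([#6]){_NOT_DUMMY}:2]"),
    ("aromatic N - aliphatic C",
     f"[$([n;+0]){_NOT_DUMMY}:1]-!@[$([C]){_NOT_DUMMY}:2]"),
    ("aromatic C - aromatic C",
     f"[$([c]){_NOT_DUMMY}:1]-!@[$([c]){_NOT_DUMMY}:2]"),
    ("sulphonamide",
     f"[$([N;+0;!D1]){_NOT_DUMMY}:1]-!@[$([S](=O)=O){_NOT_DUMMY}:2]"),
]
_COMPILED = [(name, Chem.MolFromSmarts(s)) for name, s in _BOND_SMARTS]


@dataclass(frozen=True)
class FragmentRecord:
    key: str  # canonical SMILES, attachment points as [*]
    frequency: int  # number of distinct parent molecules containing it
    heavy_atoms: int  # non-attachment heavy atoms
    example_parents: tuple[str, ...]  # up to 5 record ids


def fragment_heavy_atoms(key: str) -> int:
    """Non-attachment heavy atoms of a canonical fragment key."""
    mol = Chem.MolFromSmiles(key)
    if mol is None:
        return 0
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def cleavable_bonds(mol: Chem.Mol) -> set[int]:
    """Bond indices matching any of the RECAP cleavage patterns."""
    bonds: set[int] = set()
    for _name, patt in _COMPILED:
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[0], match[1])
            if bond is not None and not bond.IsInRing():
                bonds.add(bond.GetIdx())
    return bonds


def recap_fragments(record: MoleculeRecord) -> list[str]:
    """Fragments of one molecule under exhaustive RECAP cleavage.

    All cleavable bonds are cut simultaneously; each fragment is returned
    as a canonical SMILES with attachment points as the wildcard atom
    (sorted, with multiplicity).  A molecule with no cleavable bond
    yields itself as its only fragment; unparseable structures yield an
    empty list with a warning.  The non-attachment heavy atoms of the
    fragments always sum to the parent's heavy-atom count (cuts split
    bonds, never atoms).
    """
    if record.mol is None:
        logger.warning("record %r has no structure; no fragments",
                       record.record_id)
        return []
    try:
        mol = Chem.RemoveHs(Chem.Mol(record.mol))
        Chem.SanitizeMol(mol)
        bonds = cleavable_bonds(mol)
        if not bonds:
            return [Chem.MolToSmiles(mol)]
        cut = Chem.FragmentOnBonds(mol, sorted(bonds), addDummies=True)
        for atom in cut.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetIsotope(0)  # unlabeled attachment points merge
        pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=False)
        keys = []
        for piece in pieces:
            Chem.SanitizeMol(piece)
            keys.append(Chem.MolToSmiles(piece))
        return sorted(keys)
    except Exception:
        logger.warning("record %r: RECAP decomposition failed", record.record_id)
        return []


def fragment_frequency(
    library: Library,
    descriptors: dict[str, DescriptorVector],
    mw_cutoff: float = DEFAULT_MW_CUTOFF,
    min_heavy: int = DEFAULT_MIN_HEAVY,
) -> tuple[list[FragmentRecord], dict[str, int]]:
    """Rank RECAP fragments by parent frequency across a library.

    Molecules with MW above ``mw_cutoff`` are excluded and counted;
    fragments with fewer than ``min_heavy`` non-attachment heavy atoms are
    suppressed.  Ranking is by frequency, then heavy atoms, then key —
    fully deterministic.  Returns (ranked fragments, counts) where counts
    holds ``analyzed`` / ``excluded_mw`` / ``no_structure``.
    """
    parents: dict[str, set[str]] = defaultdict(set)
    counts = {"analyzed": 0, "excluded_mw": 0, "no_structure": 0}
    for rec in library.records:
        dv = descriptors.get(rec.record_id, DescriptorVector())
        mw = dv.get("MW")
        if mw is not None and mw > mw_cutoff:
            counts["excluded_mw"] += 1
            continue
        if rec.mol is None:
            counts["no_structure"] += 1
            continue
        counts["analyzed"] += 1
        for key in set(recap_fragments(rec)):
            parents[key].add(rec.record_id)
    records = []
    for key, parent_ids in parents.items():
        heavy = fragment_heavy_atoms(key)
        if heavy < min_heavy:
            continue
        records.append(
            FragmentRecord(
                key=key,
                frequency=len(parent_ids),
                heavy_atoms=heavy,
                example_parents=tuple(sorted(parent_ids)[:5]),
            )
        )
    records.sort(key=lambda fr: (-fr.frequency, -fr.heavy_atoms, fr.key))
    return records, counts


def export_fragments(records: list[FragmentRecord], path) -> None:
    """Ranked fragment table as tab-separated text."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "fragment": fr.key,
                "frequency": fr.frequency,
                "heavy_atoms": fr.heavy_atoms,
                "example_parents": ",".join(fr.example_parents),
            }
            for fr in records
        ]
    ).to_csv(path, sep="\t", index=False)
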