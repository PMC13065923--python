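"""Pharmacophore-aware primary-scaffold extraction and peripheral harvesting.

The primary scaffold of a docked virtual hit is defined as the smallest
fragment, over all partial BRICS decompositions of the molecule (retro-
synthetic intermediates included), that (a) carries at least one attachment
point, (b) contains at least one ring, and (c) covers, as an atom set of the
parent 3D pose, every atom realizing the hypothesis' key pharmacophore
points.  Extracted scaffolds are neutralized, canonicalized and
deduplicated into the crude scaffold set (1-3 ports); the material removed
when the scaffold is excised is harvested as monovalent peripheral
fragments, classified *left* (nearer the hydrophobic key point) or *right*
(nearer the polar key points).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .io_formats import DataError, FragmentRecord, Pose, Scaffold, scaffold_from_smiles
from .pharmacophore import (
    FeatureType,
    MatchReport,
    PharmacophoreHypothesis,
    match_hypothesis,
)

logger = logging.getLogger(__name__)

#: Cap on the number of simultaneous BRICS cuts when enumerating partial
#: decompositions; keeps the cut-subset enumeration tractable.
DEFAULT_MAX_CUTS = 6

_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


@dataclass(frozen=True)
class FragmentCandidate:
    """A connected product of a partial BRICS decomposition."""

    smiles: str
    atom_map: tuple[int, ...]  # parent-pose atom indices, fragment atom order
    n_heavy: int  # heavy atoms excluding attachment points
    n_ports: int
    has_ring: bool

    @property
    def atom_set(self) -> frozenset[int]:
        return frozenset(self.atom_map)


@dataclass
class CrudeScaffoldSet:
    """Deduplicated scaffolds plus per-scaffold provenance."""

    scaffolds: dict[str, Scaffold] = field(default_factory=dict)  # canonical smiles -> Scaffold
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scaffolds)

    def records(self) -> Iterable[tuple[Scaffold, str, str]]:
        for smi, scaffold in self.scaffolds.items():
            for mol_id, exp_id in self.provenance[smi]:
                yield scaffold, mol_id, exp_id


# ---------------------------------------------------------------------------
# Partial BRICS decomposition
# ---------------------------------------------------------------------------


def _brics_bond_indices(mol: Chem.Mol) -> list[int]:
    out = []
    for (i, j), _labels in BRICS.FindBRICSBonds(mol):
        bond = mol.GetBondBetweenAtoms(i, j)
        out.append(bond.GetIdx())
    return sorted(set(out))


def brics_fragments_with_intermediates(
    pose_or_mol: Pose | Chem.Mol, max_cuts: int = DEFAULT_MAX_CUTS
) -> list[FragmentCandidate]:
    """Enumerate every connected fragment reachable by ≤ ``max_cuts`` BRICS cuts.

    This is a superset of leaf-level BRICS decomposition: for every subset of
    at most ``max_cuts`` BRICS-cleavable bonds, every connected piece of the
    cut molecule is reported once (deduplicated by parent atom set), with
    attachment points at the cut positions and a mapping back to parent atom
    indices.  The uncut parent itself is the 0-cut intermediate; a molecule
    with no cleavable bond yields only that candidate (0 ports — cannot
    become a scaffold).
    """
    if max_cuts < 1:
        raise ValueError("max_cuts must be >= 1")
    mol = pose_or_mol.mol if isinstance(pose_or_mol, Pose) else pose_or_mol
    n_parent = mol.GetNumAtoms()
    bonds = _brics_bond_indices(mol)

    seen: set[frozenset[int]] = set()
    candidates: list[FragmentCandidate] = []

    def add_fragments(frag_mol: Chem.Mol) -> None:
        frags = Chem.GetMolFrags(frag_mol, asMols=False, sanitizeFrags=False)
        mols = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False)
        for atom_idxs, piece in zip(frags, mols):
            parent_atoms = tuple(i for i in atom_idxs if i < n_parent)
            key = frozenset(parent_atoms)
            if key in seen:
                continue
            seen.add(key)
            piece = Chem.Mol(piece)
            for a in piece.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetIsotope(0)
            try:
                Chem.SanitizeMol(piece)
            except Exception:  # pragma: no cover - BRICS pieces sanitize cleanly
                continue
            n_ports = sum(a.GetAtomicNum() == 0 for a in piece.GetAtoms())
            candidates.append(
                FragmentCandidate(
                    smiles=Chem.MolToSmiles(piece),
                    atom_map=parent_atoms,
                    n_heavy=len(parent_atoms),
                    n_ports=n_ports,
                    has_ring=piece.GetRingInfo().NumRings() > 0,
                )
            )

    add_fragments(mol)  # the 0-cut intermediate
    for r in range(1, min(max_cuts, len(bonds)) + 1):
        for subset in itertools.combinations(bonds, r):
            cut = Chem.FragmentOnBonds(mol, list(subset), addDummies=True)
            add_fragments(cut)
    return candidates


# ---------------------------------------------------------------------------
# Side classification
# ---------------------------------------------------------------------------


def classify_side(centroid: np.ndarray, hyp: PharmacophoreHypothesis) -> str:
    """Classify a peripheral centroid as left (hydrophobic) or right (polar).

    Left iff strictly nearer the nearest key HYD point than the nearest key
    polar (HBD/HBA) point; equidistant ties go right.  Raises if the
    hypothesis lacks either kind of key point.
    """
    hyd = [p for p in hyp.key_points if p.ptype is FeatureType.HYD]
    polar = [p for p in hyp.key_points if p.ptype in (FeatureType.HBD, FeatureType.HBA)]
    if not hyd or not polar:
        raise DataError(
            "left/right classification needs key HYD and key HBD/HBA points"
        )
    d_hyd = min(float(np.linalg.norm(centroid - p.center)) for p in hyd)
    d_polar = min(float(np.linalg.norm(centroid - p.center)) for p in polar)
    return "left" if d_hyd < d_polar else "right"


# ---------------------------------------------------------------------------
# Primary scaffold extraction
# ---------------------------------------------------------------------------


def _peripheral_component(mol: Chem.Mol, start: int, scaffold_atoms: frozenset[int]) -> set[int]:
    comp = {start}
    stack = [start]
    while stack:
        i = stack.pop()
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nb.GetIdx()
            if j not in scaffold_atoms and j not in comp:
                comp.add(j)
                stack.append(j)
    return comp


def _label_ports(
    pose: Pose,
    hyp: PharmacophoreHypothesis,
    scaffold_atoms: frozenset[int],
) -> dict[tuple[int, int], int]:
    """Assign port labels to the severed bonds of an extracted scaffold.

    Each severed bond (scaffold atom, outside atom) loses a peripheral piece;
    its centroid classifies the port: the first left port gets label 1, the
    first right port label 2, remaining ports take the unused labels in
    deterministic bond order.
    """
    mol = pose.mol
    coords = pose.coords
    severed: list[tuple[tuple[int, int], str]] = []
    for i in sorted(scaffold_atoms):
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nb.GetIdx()
            if j in scaffold_atoms:
                continue
            comp = _peripheral_component(mol, j, scaffold_atoms)
            side = classify_side(coords[sorted(comp)].mean(axis=0), hyp)
            severed.append(((i, j), side))
    labels: dict[tuple[int, int], int] = {}
    free = [1, 2, 3]
    for bond, side in severed:
        want = 1 if side == "left" else 2
        labels[bond] = want if want in free else -1
        if want in free:
            free.remove(want)
    for bond, label in labels.items():
        if label == -1:
            labels[bond] = free.pop(0)
    return labels


def extract_primary_scaffold(
    pose: Pose,
    hyp: PharmacophoreHypothesis,
    max_cuts: int = DEFAULT_MAX_CUTS,
    definitions=None,
    report: Optional[MatchReport] = None,
) -> Optional[Scaffold]:
    """Extract the primary scaffold of a docked pose, or None.

    Poses that do not match every key point yield None.  Among fragment
    candidates with ≥1 port and ≥1 ring whose parent-atom set covers the key
    atoms, the fewest-heavy-atom one wins (attachment points excluded from
    the count); ties break on lexicographically smallest canonical SMILES.
    Port labels are assigned from the left/right classification of the lost
    peripheral pieces.
    """
    if report is None:
        report = match_hypothesis(pose, hyp, definitions)
    if not report.all_key_matched:
        return None
    key_atoms = report.key_atoms
    candidates = brics_fragments_with_intermediates(pose, max_cuts)
    qualifying = [
        c
        for c in candidates
        if c.n_ports >= 1 and c.has_ring and key_atoms <= c.atom_set
    ]
    if not qualifying:
        logger.info("pose %s: no qualifying fragment", pose.structure_id)
        return None
    best = min(qualifying, key=lambda c: (c.n_heavy, c.smiles))
    if best.n_ports > 3:
        logger.info(
            "pose %s: minimal fragment has %d ports (>3), dropped",
            pose.structure_id, best.n_ports,
        )
        return None

    labels = _label_ports(pose, hyp, best.atom_set)
    # rebuild the fragment with labeled dummies, in parent atom order
    cut_bonds = [pose.mol.GetBondBetweenAtoms(i, j).GetIdx() for (i, j) in labels]
    frag_mol = Chem.FragmentOnBonds(pose.mol, cut_bonds, addDummies=True) if cut_bonds else Chem.Mol(pose.mol)
    pieces = Chem.GetMolFrags(frag_mol, asMols=False, sanitizeFrags=False)
    mols = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False)
    n_parent = pose.mol.GetNumAtoms()
    for atom_idxs, piece in zip(pieces, mols):
        parent_atoms = frozenset(i for i in atom_idxs if i < n_parent)
        if parent_atoms != best.atom_set:
            continue
        piece = Chem.Mol(piece)
        # FragmentOnBonds isotope-labels each dummy with the index of the
        # atom it replaces, i.e. the outside end of the severed bond
        for a in piece.GetAtoms():
            if a.GetAtomicNum() == 0:
                outside_idx = a.GetIsotope()
                scaffold_idx = atom_idxs[a.GetNeighbors()[0].GetIdx()]
                a.SetIsotope(labels[(scaffold_idx, outside_idx)])
        try:
            Chem.SanitizeMol(piece)
        except Exception:
            return None
        smiles = Chem.MolToSmiles(piece)
        scaffold = scaffold_from_smiles(smiles)
        return Scaffold(
            smiles=scaffold.smiles,
            ports=scaffold.ports,
            atom_map=tuple(sorted(best.atom_set)),
        )
    return None  # pragma: no cover


# ---------------------------------------------------------------------------
# Neutralization
# ---------------------------------------------------------------------------


def neutralize(smiles: str) -> tuple[str, list[int]]:
    """Set removable formal charges to zero, flagging unneutralizable atoms.

    Charges removable by hydrogen-count adjustment without valence violation
    (protonated amines, deprotonated acids, ...) are zeroed; atoms like
    quaternary nitrogen are left charged and their indices returned.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparseable SMILES: {smiles!r}")
    for idx in [m[0] for m in mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)]:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(h_count - charge)
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    flagged = [a.GetIdx() for a in mol.GetAtoms() if a.GetFormalCharge() != 0]
    return Chem.MolToSmiles(mol), flagged


# ---------------------------------------------------------------------------
# Crude scaffold aggregation
# ---------------------------------------------------------------------------


def collect_crude_scaffolds(
    records: Iterable[tuple[Scaffold, str, str]]
) -> CrudeScaffoldSet:
    """Neutralize, canonicalize and deduplicate scaffolds into the crude set.

    Members with more than 3 attachment points are dropped; provenance
    (molecule_id, experiment_id) is merged per canonical scaffold.
    """
    out = CrudeScaffoldSet()
    for scaffold, mol_id, exp_id in records:
        neutral, _flags = neutralize(scaffold.smiles)
        try:
            norm = scaffold_from_smiles(neutral)
        except DataError as exc:
            logger.warning("dropping scaffold %s: %s", scaffold.smiles, exc)
            continue
        if norm.n_ports > 3:  # pragma: no cover - guarded by scaffold_from_smiles
            continue
        key = norm.smiles
        if key not in out.scaffolds:
            out.scaffolds[key] = norm
            out.provenance[key] = []
        out.provenance[key].append((mol_id, exp_id))
    return out


# ---------------------------------------------------------------------------
# Peripheral fragments
# ---------------------------------------------------------------------------


def extract_peripheral_fragments(
    pose: Pose,
    scaffold: Scaffold,
    hyp: PharmacophoreHypothesis,
) -> list[FragmentRecord]:
    """Excise the scaffold from the pose and harvest the peripheral pieces.

    Each remaining connected piece severed from the scaffold by exactly one
    bond is capped with an attachment point and classified left/right by the
    geometry of its parent-pose centroid; pieces attached through two or more
    bonds (fused periphery) violate the one-port invariant and are excluded
    with a log message.  A pose identical to its scaffold yields [].
    """
    mol = pose.mol
    if scaffold.atom_map is not None:
        scaffold_atoms = frozenset(scaffold.atom_map)
    else:
        query = Chem.MolFromSmiles(scaffold.smiles)
        query = Chem.DeleteSubstructs(query, Chem.MolFromSmarts("[#0]"))
        match = mol.GetSubstructMatch(query)
        if not match:
            raise DataError("scaffold is not a substructure of the pose")
        scaffold_atoms = frozenset(match)
    if not scaffold_atoms <= set(range(mol.GetNumAtoms())):
        raise DataError("scaffold atom map exceeds pose atoms")

    coords = pose.coords
    outside = [i for i in range(mol.GetNumAtoms()) if i not in scaffold_atoms]
    records: list[FragmentRecord] = []
    seen: set[frozenset[int]] = set()
    for start in outside:
        comp = frozenset(_peripheral_component(mol, start, scaffold_atoms))
        if comp in seen:
            continue
        seen.add(comp)
        boundary = [
            mol.GetBondBetweenAtoms(i, j).GetIdx()
            for i in comp
            for j in (nb.GetIdx() for nb in mol.GetAtomWithIdx(i).GetNeighbors())
            if j in scaffold_atoms
        ]
        if len(boundary) != 1:
            logger.info(
                "pose %s: peripheral piece severed at %d bonds excluded",
                pose.structure_id, len(boundary),
            )
            continue
        cut = Chem.FragmentOnBonds(mol, boundary, addDummies=True)
        for atom_idxs, piece in zip(
            Chem.GetMolFrags(cut, asMols=False, sanitizeFrags=False),
            Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=False),
        ):
            parent = frozenset(i for i in atom_idxs if i < mol.GetNumAtoms())
            if parent != comp:
                continue
            piece = Chem.Mol(piece)
            for a in piece.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetIsotope(0)
            Chem.SanitizeMol(piece)
            side = classify_side(coords[sorted(comp)].mean(axis=0), hyp)
            records.append(
                FragmentRecord(
                    smiles=Chem.MolToSmiles(piece),
                    side=side,
                    source_id=pose.structure_id,
                )
            )
    return records
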