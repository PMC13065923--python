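"""Synthetic docked-pose libraries with planted ground truth.

Every pipeline stage is testable offline against libraries assembled from
known scaffolds and known left/right peripheral fragments.  A pose is the
chemical join scaffold + left + right, given synthetic 3D coordinates that
realize a toy 3-point hypothesis exactly at zero noise:

* the scaffold's aromatic ring is laid out as a regular polygon whose
  hydrophobic-member centroid sits on the HYD point,
* the scaffold's donor and acceptor atoms sit on the HBD and HBA points,
* the left fragment is displaced beyond the HYD point (hydrophobic
  subpocket side), the right fragment beyond the polar points,
* remaining atoms get a relaxed neighbor layout.

Coordinates are constructed geometrically, not physically embedded —
downstream logic consumes them only through distance tests.  Gaussian noise
of ``noise_sd`` Å degrades the match rate in a controlled way.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .enumerator import join
from .io_formats import FragmentRecord, Pose, Scaffold, scaffold_from_smiles
from .pharmacophore import (
    DEFAULT_FEATURE_SMARTS,
    FeatureType,
    PharmacophoreHypothesis,
    PharmacophorePoint,
)

logger = logging.getLogger(__name__)

#: Bivalent toy scaffolds: one aromatic ring, a donor (OH/NH2), an acceptor
#: (nitrile N, hydroxyl O or amine N), ports on aromatic carbons.  Chosen so
#: the scaffold itself contains no internal BRICS-cleavable bond.
DEFAULT_SCAFFOLD_POOL: tuple[str, ...] = (
    "[1*]c1cc(O)c(C#N)cc1[2*]",
    "[1*]c1cc(N)c(C#N)cc1[2*]",
    "[1*]c1cc(N)cc(O)c1[2*]",
    "[1*]c1cc(N)c(F)c(O)c1[2*]",
    "[1*]c1c(N)cc(O)cc1[2*]",
    "[1*]c1cc(O)cc(C#N)c1[2*]",
)

#: Hydrophobic (left) peripheral fragments; attach through an sp3 carbon so
#: the junction to an aromatic scaffold carbon is BRICS-cleavable.
DEFAULT_LEFT_POOL: tuple[str, ...] = (
    "*CCC", "*CCCC", "*CC(C)C", "*CC(C)(C)C",
    "*CCCCC", "*CC(C)CC", "*CCC(C)C", "*CC(F)(F)F",
)

#: Polar (right) peripheral fragments.
DEFAULT_RIGHT_POOL: tuple[str, ...] = (
    "*CCO", "*CCN", "*CCOC", "*CCC(N)=O",
    "*CCOCC", "*CC(C)O", "*CCNC", "*CCC#N",
)

_G1_LAYOUT = (
    (FeatureType.HYD, (0.0, 0.0, 0.0)),
    (FeatureType.HBA, (3.4, 1.5, 0.5)),
    (FeatureType.HBD, (3.1, -1.9, 0.3)),
)

_RING_RADIUS = 1.39  # aromatic ring circumradius, Å
_BOND = 1.45  # generic layout bond length, Å


def make_toy_hypothesis(
    style: str = "g1",
    radius: float = 1.5,
    points: Optional[Sequence[PharmacophorePoint]] = None,
    name: str = "toy",
) -> PharmacophoreHypothesis:
    """A toy hypothesis for fixture libraries.

    ``g1`` style emulates a three-point layout — one hydrophobic point and a
    spatially separated acceptor/donor pair — with all three points key and a
    common tolerance ``radius``.  ``custom`` style takes explicit points and
    refuses hypotheses without key points.
    """
    if style == "g1":
        pts = [
            PharmacophorePoint(ptype, np.array(center), radius, key=True)
            for ptype, center in _G1_LAYOUT
        ]
        return PharmacophoreHypothesis(name=name, points=pts)
    if style == "custom":
        if points is None:
            raise ValueError("custom style requires explicit points")
        return PharmacophoreHypothesis(name=name, points=list(points))
    raise ValueError(f"unknown hypothesis style {style!r}")


# ---------------------------------------------------------------------------
# Geometric pose construction
# ---------------------------------------------------------------------------


def _first_match(mol: Chem.Mol, smarts_list, within: set[int], exclude: set[int] = frozenset()) -> Optional[int]:
    hits: set[int] = set()
    for smarts in smarts_list:
        patt = Chem.MolFromSmarts(smarts)
        hits.update(m[0] for m in mol.GetSubstructMatches(patt))
    eligible = sorted(h for h in hits if h in within and h not in exclude)
    return eligible[0] if eligible else None


def _scaffold_anchors(mol: Chem.Mol, scaffold_atoms: set[int]):
    """Locate the aromatic ring, donor atom and acceptor atom of the scaffold
    within the joined molecule; None when the scaffold is infeasible."""
    ring = next(
        (
            r
            for r in mol.GetRingInfo().AtomRings()
            if set(r) <= scaffold_atoms
            and all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
        ),
        None,
    )
    if ring is None:
        return None
    donor = _first_match(mol, DEFAULT_FEATURE_SMARTS[FeatureType.HBD], scaffold_atoms)
    if donor is None:
        return None
    acceptor = _first_match(
        mol, DEFAULT_FEATURE_SMARTS[FeatureType.HBA], scaffold_atoms, exclude={donor}
    )
    if acceptor is None:
        return None
    hyd_smarts = DEFAULT_FEATURE_SMARTS[FeatureType.HYD]
    hyd_atoms: set[int] = set()
    for smarts in hyd_smarts:
        patt = Chem.MolFromSmarts(smarts)
        hyd_atoms.update(m[0] for m in mol.GetSubstructMatches(patt))
    hyd_ring = [i for i in ring if i in hyd_atoms]
    if not hyd_ring:
        return None
    return ring, donor, acceptor, hyd_ring


def _hyp_centers(hyp: PharmacophoreHypothesis):
    def center(ptype: FeatureType) -> np.ndarray:
        pts = [p for p in hyp.key_points if p.ptype is ptype]
        if not pts:
            raise ValueError(f"hypothesis lacks a key {ptype.name} point")
        return pts[0].center

    return center(FeatureType.HYD), center(FeatureType.HBA), center(FeatureType.HBD)


def _layout_pose(
    mol: Chem.Mol,
    scaffold_atoms: set[int],
    left_atoms: set[int],
    right_atoms: set[int],
    hyp: PharmacophoreHypothesis,
) -> Optional[np.ndarray]:
    """Deterministic coordinates realizing the hypothesis at zero noise."""
    anchors = _scaffold_anchors(mol, scaffold_atoms)
    if anchors is None:
        return None
    ring, donor, acceptor, hyd_ring = anchors
    hyd_c, hba_c, hbd_c = _hyp_centers(hyp)

    n = mol.GetNumAtoms()
    coords = np.full((n, 3), np.nan)

    # ring as a regular polygon in the z=0 plane, then shifted so that the
    # centroid of its hydrophobic members hits the HYD center exactly
    k = len(ring)
    for pos, idx in enumerate(ring):
        theta = 2.0 * np.pi * pos / k
        coords[idx] = (_RING_RADIUS * np.cos(theta), _RING_RADIUS * np.sin(theta), 0.0)
    shift = hyd_c - coords[hyd_ring].mean(axis=0)
    for idx in ring:
        coords[idx] += shift

    coords[donor] = hbd_c
    coords[acceptor] = hba_c

    polar_mid = 0.5 * (hba_c + hbd_c)
    d_left = hyd_c - polar_mid
    d_left = d_left / np.linalg.norm(d_left)
    d_right = -d_left

    def chain_layout(atoms: set[int], base: np.ndarray, direction: np.ndarray) -> None:
        for j, idx in enumerate(sorted(atoms)):
            off = np.array([0.0, 0.3 * (j % 3), 0.3 * (j % 2)])
            coords[idx] = base + direction * (_BOND * j) + off

    chain_layout(left_atoms, hyd_c + 2.0 * d_left, d_left)
    chain_layout(right_atoms, polar_mid + 2.0 * d_right, d_right)

    # relaxed neighbor layout for remaining scaffold atoms (substituent
    # atoms that are not anchors): step outward from a placed neighbor
    ring_center = coords[list(ring)].mean(axis=0)
    remaining = [i for i in range(n) if np.isnan(coords[i]).any()]
    guard = 0
    while remaining and guard < 4 * n:
        guard += 1
        for idx in list(remaining):
            nbs = [
                nb.GetIdx()
                for nb in mol.GetAtomWithIdx(idx).GetNeighbors()
                if not np.isnan(coords[nb.GetIdx()]).any()
            ]
            if not nbs:
                continue
            anchor = coords[nbs[0]]
            out = anchor - ring_center
            norm = np.linalg.norm(out)
            direction = out / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
            coords[idx] = anchor + _BOND * direction + np.array([0.05 * idx, 0.0, 0.1])
            remaining.remove(idx)
    if remaining:  # disconnected leftovers should not occur
        return None
    return coords


def _component_atoms(mol: Chem.Mol, scaffold_atoms: set[int]) -> list[set[int]]:
    comps: list[set[int]] = []
    seen: set[int] = set()
    for start in range(mol.GetNumAtoms()):
        if start in scaffold_atoms or start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j not in scaffold_atoms and j not in comp:
                    comp.add(j)
                    stack.append(j)
        seen |= comp
        comps.append(comp)
    return comps


def _capped_smiles(mol: Chem.Mol, comp: set[int], scaffold_atoms: set[int]) -> Optional[str]:
    boundary = [
        mol.GetBondBetweenAtoms(i, j).GetIdx()
        for i in comp
        for j in (nb.GetIdx() for nb in mol.GetAtomWithIdx(i).GetNeighbors())
        if j in scaffold_atoms
    ]
    if len(boundary) != 1:
        return None
    cut = Chem.FragmentOnBonds(mol, boundary, addDummies=True)
    for atom_idxs, piece in zip(
        Chem.GetMolFrags(cut, asMols=False, sanitizeFrags=False),
        Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=False),
    ):
        parent = {i for i in atom_idxs if i < mol.GetNumAtoms()}
        if parent != comp:
            continue
        piece = Chem.Mol(piece)
        for a in piece.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetIsotope(0)
        Chem.SanitizeMol(piece)
        return Chem.MolToSmiles(piece)
    return None


def make_toy_library(
    n: int,
    scaffold_pool: Sequence[str] = DEFAULT_SCAFFOLD_POOL,
    left_pool: Sequence[str] = DEFAULT_LEFT_POOL,
    right_pool: Sequence[str] = DEFAULT_RIGHT_POOL,
    hyp: Optional[PharmacophoreHypothesis] = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[list[Pose], list[dict]]:
    """Build ``n`` synthetic docked poses with planted ground truth.

    Each pose is join(scaffold, left, right) for pool members drawn by a
    seeded generator, with coordinates constructed so that at ``noise_sd`` =
    0 every key point of ``hyp`` is realized by scaffold atoms.  Returns the
    poses and a truth table of dicts (pose_id, scaffold, left, right).
    Scaffold pool members that cannot realize all key features are skipped
    with a warning.
    """
    if not scaffold_pool or not left_pool or not right_pool:
        raise ValueError("pools must be non-empty")
    hyp = hyp or make_toy_hypothesis()
    rng = np.random.default_rng(rng_seed)

    scaffolds = [scaffold_from_smiles(s) for s in scaffold_pool]
    lefts = [FragmentRecord(Chem.MolToSmiles(Chem.MolFromSmiles(s)), "left") for s in left_pool]
    rights = [FragmentRecord(Chem.MolToSmiles(Chem.MolFromSmiles(s)), "right") for s in right_pool]

    poses: list[Pose] = []
    truth: list[dict] = []
    usable = list(range(len(scaffolds)))
    i = 0
    attempts = 0
    while len(poses) < n and attempts < 10 * n:
        attempts += 1
        si = int(rng.integers(len(usable)))
        scaffold = scaffolds[usable[si]]
        left = lefts[int(rng.integers(len(lefts)))]
        right = rights[int(rng.integers(len(rights)))]

        product = join(scaffold, left, right)
        mol = Chem.MolFromSmiles(product)
        query = Chem.DeleteSubstructs(Chem.MolFromSmiles(scaffold.smiles), Chem.MolFromSmarts("[#0]"))
        match = mol.GetSubstructMatch(query)
        if not match:
            logger.warning("pool scaffold %s lost in join; skipping member", scaffold.smiles)
            usable.pop(si)
            if not usable:
                raise ValueError("no feasible scaffold pool members")
            continue
        scaffold_atoms = set(match)
        comps = _component_atoms(mol, scaffold_atoms)
        left_atoms: set[int] = set()
        right_atoms: set[int] = set()
        for comp in comps:
            capped = _capped_smiles(mol, comp, scaffold_atoms)
            if capped == left.smiles and not left_atoms:
                left_atoms = comp
            elif capped == right.smiles:
                right_atoms = comp
        if not left_atoms or not right_atoms:
            # identical left/right draw or ambiguous excision; redraw
            continue

        coords = _layout_pose(mol, scaffold_atoms, left_atoms, right_atoms, hyp)
        if coords is None:
            logger.warning("infeasible geometry for scaffold %s; skipping member", scaffold.smiles)
            usable.pop(si)
            if not usable:
                raise ValueError("no feasible scaffold pool members")
            continue
        if noise_sd > 0:
            coords = coords + rng.normal(0.0, noise_sd, coords.shape)

        conf = Chem.Conformer(mol.GetNumAtoms())
        for idx in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(idx, Point3D(*map(float, coords[idx])))
        conf.Set3D(True)
        mol = Chem.Mol(mol)
        mol.AddConformer(conf, assignId=True)

        pose_id = f"FIX{i:05d}"
        i += 1
        pose = Pose(
            structure_id=pose_id,
            mol=mol,
            properties={"Structure ID": pose_id, "exp_id": "toy"},
        )
        poses.append(pose)
        truth.append(
            {
                "pose_id": pose_id,
                "scaffold": scaffold.smiles,
                "left": left.smiles,
                "right": right.smiles,
            }
        )
    if len(poses) < n:
        raise ValueError("could not assemble the requested library size")
    return poses, truth
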