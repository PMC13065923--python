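"""Pharmacophore feature perception and geometric hypothesis matching.

A pose is screened against a hypothesis of typed 3D points (HBD, HBA, HYD,
AROM, POS, NEG), a subset of which is flagged *key*.  A point is matched when
some perceived feature of the same type has its centroid within the point's
tolerance radius (boundary inclusive).  The union of atoms realizing the key
points is what gates scaffold acceptance downstream.

Feature perception uses a small, documented SMARTS catalogue (overridable):

* HBD — N or O bearing at least one hydrogen; one feature per atom.
* HBA — any O, or N that is not an amide N, not an aromatic N-H and not
  positively charged; one feature per atom.
* HYD — hydrophobic atoms (sp3/sp2 carbon not doubly bonded to a heteroatom,
  aromatic carbon, divalent non-H sulfur, halogens), grouped into units:
  each ring contributes the unit of its hydrophobic members, acyclic
  hydrophobic atoms form connected-chain units.
* AROM — one feature per fully aromatic ring, centred on the ring centroid.
* POS / NEG — formally charged atoms; one feature per atom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from rdkit import Chem

if TYPE_CHECKING:  # avoid a circular import at runtime
    from .io_formats import Pose


class FeatureType(enum.Enum):
    HBD = "hydrogen-bond donor"
    HBA = "hydrogen-bond acceptor"
    HYD = "hydrophobic"
    AROM = "aromatic ring"
    POS = "positive ionizable"
    NEG = "negative ionizable"


#: Default atom-level SMARTS per feature type.  HYD lists the hydrophobic
#: *atom* definition; grouping into ring/chain units is structural and fixed.
#: AROM is perceived from ring aromaticity, not from SMARTS.
DEFAULT_FEATURE_SMARTS: dict[FeatureType, list[str]] = {
    FeatureType.HBD: ["[#7;!H0]", "[#8;!H0]"],
    FeatureType.HBA: [
        "[#8;!$([#8+])]",
        "[#7;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([nH]);!$([#7+])]",
    ],
    FeatureType.HYD: [
        "[CX4]",
        "[CX3;!$([CX3]=[O,N,S,P])]",
        "[c]",
        "[SX2;H0]",
        "[F,Cl,Br,I]",
    ],
    FeatureType.POS: ["[+1,+2,+3]"],
    FeatureType.NEG: ["[-1,-2,-3]"],
}


@dataclass(frozen=True)
class PharmacophorePoint:
    """A typed tolerance sphere in 3D space; ``key`` marks a mandatory point."""

    ptype: FeatureType
    center: np.ndarray  # shape (3,), Å
    radius: float  # Å
    key: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass
class PharmacophoreHypothesis:
    name: str
    points: list[PharmacophorePoint]

    def __post_init__(self) -> None:
        if not any(p.key for p in self.points):
            raise ValueError("hypothesis must have at least one key point")

    @property
    def key_points(self) -> list[PharmacophorePoint]:
        return [p for p in self.points if p.key]

    def translated(self, shift: np.ndarray) -> "PharmacophoreHypothesis":
        return PharmacophoreHypothesis(
            name=self.name,
            points=[
                PharmacophorePoint(p.ptype, p.center + shift, p.radius, p.key)
                for p in self.points
            ],
        )

    def transformed(self, rotation: np.ndarray, shift: np.ndarray) -> "PharmacophoreHypothesis":
        return PharmacophoreHypothesis(
            name=self.name,
            points=[
                PharmacophorePoint(p.ptype, rotation @ p.center + shift, p.radius, p.key)
                for p in self.points
            ],
        )


@dataclass(frozen=True)
class FeatureInstance:
    """A perceived feature: member atoms plus their unweighted centroid."""

    ptype: FeatureType
    atom_indices: frozenset[int]
    centroid: np.ndarray

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError("feature must have at least one atom")


@dataclass
class PointMatch:
    point: PharmacophorePoint
    matched: bool
    feature: Optional[FeatureInstance]
    distance: float


@dataclass
class MatchReport:
    matches: list[PointMatch]
    all_key_matched: bool
    key_atoms: frozenset[int]


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------


def _atom_matches(mol: Chem.Mol, smarts_list: Sequence[str]) -> set[int]:
    hits: set[int] = set()
    for smarts in smarts_list:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in feature definitions: {smarts!r}")
        hits.update(m[0] for m in mol.GetSubstructMatches(patt))
    return hits


def _hydrophobic_units(mol: Chem.Mol, hyd_atoms: set[int]) -> list[frozenset[int]]:
    """Group hydrophobic atoms into ring units and acyclic chain units."""
    units: list[frozenset[int]] = []
    ring_info = mol.GetRingInfo()
    in_ring: set[int] = set()
    for ring in ring_info.AtomRings():
        members = frozenset(i for i in ring if i in hyd_atoms)
        if members:
            units.append(members)
            in_ring.update(members)
    # connected components of acyclic hydrophobic atoms
    chain = {i for i in hyd_atoms if i not in in_ring}
    seen: set[int] = set()
    for start in sorted(chain):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in chain and j not in comp:
                    comp.add(j)
                    stack.append(j)
        seen |= comp
        units.append(frozenset(comp))
    # deduplicate (two fused rings can restrict to the same hydrophobic set)
    return sorted(set(units), key=lambda u: sorted(u))


def perceive_features(
    pose: "Pose",
    definitions: Optional[dict[FeatureType, list[str]]] = None,
) -> list[FeatureInstance]:
    """Perceive all feature instances of a 3D pose.

    ``definitions`` maps feature types to atom-level SMARTS and defaults to
    :data:`DEFAULT_FEATURE_SMARTS`; AROM is always perceived from ring
    aromaticity.  Raises on an empty definition set.
    """
    if definitions is None:
        definitions = DEFAULT_FEATURE_SMARTS
    if not definitions:
        raise ValueError("feature definition set is empty")
    mol = pose.mol
    coords = pose.coords
    features: list[FeatureInstance] = []

    def centroid(atoms: frozenset[int]) -> np.ndarray:
        return coords[sorted(atoms)].mean(axis=0)

    for ptype in (FeatureType.HBD, FeatureType.HBA, FeatureType.POS, FeatureType.NEG):
        for idx in sorted(_atom_matches(mol, definitions.get(ptype, []))):
            atoms = frozenset([idx])
            features.append(FeatureInstance(ptype, atoms, centroid(atoms)))

    hyd_atoms = _atom_matches(mol, definitions.get(FeatureType.HYD, []))
    for unit in _hydrophobic_units(mol, hyd_atoms):
        features.append(FeatureInstance(FeatureType.HYD, unit, centroid(unit)))

    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            atoms = frozenset(ring)
            features.append(FeatureInstance(FeatureType.AROM, atoms, centroid(atoms)))

    return features


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def point_matched(
    features: Sequence[FeatureInstance],
    point: PharmacophorePoint,
    any_atom: bool = False,
    coords: Optional[np.ndarray] = None,
) -> tuple[bool, Optional[FeatureInstance], float]:
    """Test a hypothesis point against perceived features.

    Matched iff some same-type feature lies within ``point.radius`` of
    ``point.center`` (inclusive); the best feature is the nearest one, ties
    broken by lowest atom index.  In ``any_atom`` mode the feature's distance
    is the minimum over member atoms (``coords`` required) instead of the
    centroid distance.
    """
    best: Optional[FeatureInstance] = None
    best_d = np.inf
    for feat in features:
        if feat.ptype is not point.ptype:
            continue
        if any_atom:
            if coords is None:
                raise ValueError("any_atom mode requires pose coordinates")
            d = float(
                np.linalg.norm(coords[sorted(feat.atom_indices)] - point.center, axis=1).min()
            )
        else:
            d = float(np.linalg.norm(feat.centroid - point.center))
        if d < best_d or (d == best_d and best is not None
                          and min(feat.atom_indices) < min(best.atom_indices)):
            best, best_d = feat, d
    if best is not None and best_d <= point.radius:
        return True, best, best_d
    return False, best, best_d


def match_hypothesis(
    pose: "Pose",
    hyp: PharmacophoreHypothesis,
    definitions: Optional[dict[FeatureType, list[str]]] = None,
    any_atom: bool = False,
) -> MatchReport:
    """Match every hypothesis point against the pose's perceived features.

    ``key_atoms`` is the union of the best-feature atom sets over matched key
    points — the atoms the primary scaffold must retain.
    """
    features = perceive_features(pose, definitions)
    coords = pose.coords if any_atom else None
    matches: list[PointMatch] = []
    key_atoms: set[int] = set()
    for point in hyp.points:
        ok, feat, d = point_matched(features, point, any_atom=any_atom, coords=coords)
        matches.append(PointMatch(point, ok, feat if ok else feat, d))
        if ok and point.key and feat is not None:
            key_atoms |= feat.atom_indices
    all_key = all(m.matched for m in matches if m.point.key)
    return MatchReport(matches=matches, all_key_matched=all_key, key_atoms=frozenset(key_atoms))
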