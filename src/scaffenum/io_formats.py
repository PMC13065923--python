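"""Readers and writers for the external formats the tool touches.

Poses travel as SDF (V2000/V3000) with per-record properties, scaffold and
fragment tables as CSV (optionally gzipped), SMILES libraries as single-column
CSV, and pharmacophore hypotheses as JSON.  Attachment points are dummy atoms;
port identity (1 = hydrophobic-side vector, 2 = polar-side vector,
3 = auxiliary) is encoded as the dummy atom's isotope label on write, e.g.
``[1*]c1ccccc1[2*]``.  Unlabeled input ports are assigned labels by canonical
atom order so that port identity is always stable.
"""

from __future__ import annotations

import csv
import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem

from .pharmacophore import (
    FeatureType,
    PharmacophoreHypothesis,
    PharmacophorePoint,
)

logger = logging.getLogger(__name__)

#: SDF property names accepted as the structure identifier, in priority order.
STRUCTURE_ID_ALIASES = ("Structure ID", "structure_id")

#: Property names accepted for the experiment identifier (aliases both seen in
#: screening exports).
EXPERIMENT_ID_ALIASES = ("exp_id", "Experiment_config", "experiment_id")


class DataError(Exception):
    """A fatal problem with input data (maps to CLI exit code 2)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Pose:
    """A molecule with explicit 3D coordinates plus screening-record properties."""

    structure_id: str
    mol: Chem.Mol  # carries a 3D conformer
    properties: dict[str, str] = field(default_factory=dict)

    @property
    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates in Å, shape (n_atoms, 3)."""
        conf = self.mol.GetConformer()
        return np.asarray(conf.GetPositions(), dtype=float)

    @property
    def experiment_id(self) -> Optional[str]:
        for k in EXPERIMENT_ID_ALIASES:
            if k in self.properties:
                return self.properties[k]
        return None


@dataclass(frozen=True)
class Scaffold:
    """A 2D structure with 1-3 labeled attachment points (ports).

    ``smiles`` is canonical and carries isotope-labeled dummy atoms; ``ports``
    is the ordered tuple of port labels present.
    """

    smiles: str
    ports: tuple[int, ...]
    # Parent-pose atom indices of the scaffold atoms, when the scaffold was
    # extracted from a pose (used for peripheral-fragment excision).
    atom_map: Optional[tuple[int, ...]] = None

    @property
    def n_ports(self) -> int:
        return len(self.ports)

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - guarded at construction
            raise DataError(f"scaffold SMILES no longer parses: {self.smiles}")
        return m


@dataclass(frozen=True)
class FragmentRecord:
    """A monovalent peripheral fragment with a side label and provenance."""

    smiles: str
    side: str  # "left" | "right"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise DataError(f"fragment SMILES does not parse: {self.smiles}")
        return m


@dataclass
class ReaderReport:
    """Counters for skipped/rejected records during a streaming read."""

    n_read: int = 0
    n_skipped: int = 0
    n_rejected: int = 0


# ---------------------------------------------------------------------------
# Scaffold SMILES normalisation
# ---------------------------------------------------------------------------


def _port_label(atom: Chem.Atom) -> int:
    """Port label of a dummy atom from isotope or atom-map annotation (0 = none)."""
    if atom.GetIsotope() in (1, 2, 3):
        return atom.GetIsotope()
    if atom.GetAtomMapNum() in (1, 2, 3):
        return atom.GetAtomMapNum()
    return 0


def scaffold_from_smiles(smiles: str, require_ring: bool = True) -> Scaffold:
    """Parse a scaffold SMILES, normalising port labels and canonical form.

    Port labels are read from isotope or atom-map annotations ([1*]/[2*]/[3*]);
    fully or partially unlabeled ports are assigned the free labels in
    canonical atom order.  Raises :class:`DataError` for unparseable SMILES,
    0 or >3 attachment points, or (by default) ring-free structures.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparseable scaffold SMILES: {smiles!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if not 1 <= len(dummies) <= 3:
        raise DataError(
            f"scaffold must have 1-3 attachment points, got {len(dummies)}: {smiles!r}"
        )
    if require_ring and mol.GetRingInfo().NumRings() == 0:
        raise DataError(f"scaffold must contain at least one ring: {smiles!r}")

    labels = [_port_label(a) for a in dummies]
    if len(set(l for l in labels if l)) != len([l for l in labels if l]):
        raise DataError(f"duplicate port labels in scaffold: {smiles!r}")
    free = [l for l in (1, 2, 3) if l not in labels]
    ranks = list(Chem.CanonicalRankAtoms(mol, includeIsotopes=False))
    order = sorted(range(len(dummies)), key=lambda i: ranks[dummies[i].GetIdx()])
    for i in order:
        if labels[i] == 0:
            labels[i] = free.pop(0)
    for a, label in zip(dummies, labels):
        a.SetIsotope(label)
        a.SetAtomMapNum(0)
    canonical = Chem.MolToSmiles(mol)
    return Scaffold(smiles=canonical, ports=tuple(sorted(labels)))


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# SDF poses
# ---------------------------------------------------------------------------


def _record_is_3d(mol: Chem.Mol) -> bool:
    if mol.GetNumConformers() == 0:
        return False
    conf = mol.GetConformer()
    if conf.Is3D():
        return True
    # 2D-flagged records (all z == 0) are not usable as poses
    return bool(np.any(np.abs(conf.GetPositions()[:, 2]) > 1e-6))


def read_sdf_poses(path: str | Path, report: Optional[ReaderReport] = None) -> list[Pose]:
    """Read an SDF file into Poses, preserving record properties verbatim.

    Unparsable or coordinate-free records are skipped with a logged warning
    and counted in ``report``.  Raises :class:`DataError` if the file is
    missing or yields zero parsable records.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"SDF file not found: {path}")
    report = report if report is not None else ReaderReport()
    poses: list[Pose] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparsable SDF record %d in %s", i, path)
            report.n_skipped += 1
            continue
        if not _record_is_3d(mol):
            logger.warning("skipping SDF record %d without 3D coordinates", i)
            report.n_skipped += 1
            continue
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        structure_id = next(
            (props[k] for k in STRUCTURE_ID_ALIASES if k in props), ""
        ) or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
        poses.append(Pose(structure_id=structure_id, mol=mol, properties=props))
        report.n_read += 1
    if not poses:
        raise DataError(f"no parsable 3D records in {path}")
    return poses


def write_sdf_poses(poses: Iterable[Pose], path: str | Path) -> int:
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    n = 0
    for pose in poses:
        mol = Chem.Mol(pose.mol)
        mol.SetProp("_Name", pose.structure_id)
        for k, v in pose.properties.items():
            mol.SetProp(k, v)
        writer.write(mol)
        n += 1
    writer.close()
    return n


# ---------------------------------------------------------------------------
# CSV tables (streaming, gzip autodetected by extension)
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8", newline="" if "w" in mode else None)


def read_scaffold_csv(
    path: str | Path,
    column: str = "scaffold",
    report: Optional[ReaderReport] = None,
) -> Iterator[tuple[Scaffold, dict[str, str]]]:
    """Stream (Scaffold, row) pairs from a CSV with a scaffold column.

    Rows whose SMILES has 0 or >3 attachment points, no ring, or does not
    parse are rejected and counted.
    """
    report = report if report is not None else ReaderReport()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or column not in reader.fieldnames:
            raise DataError(f"column {column!r} missing from {path}")
        for row in reader:
            try:
                scaffold = scaffold_from_smiles(row[column])
            except DataError as exc:
                logger.warning("rejecting scaffold row: %s", exc)
                report.n_rejected += 1
                continue
            report.n_read += 1
            yield scaffold, row


def write_scaffold_csv(
    records: Iterable[tuple[Scaffold, dict[str, str]]],
    path: str | Path,
    extra_columns: Sequence[str] = ("molecule_id", "smiles", "experiment_id"),
) -> int:
    """Write scaffold rows with provenance columns (molecule_id, smiles,
    scaffold, experiment_id)."""
    n = 0
    with _open_text(path, "wt") as fh:
        cols = [c for c in extra_columns if c != "scaffold"]
        writer = csv.DictWriter(fh, fieldnames=[*cols, "scaffold"], extrasaction="ignore")
        writer.writeheader()
        for scaffold, row in records:
            out = {c: row.get(c, "") for c in cols}
            out["scaffold"] = scaffold.smiles
            writer.writerow(out)
            n += 1
    return n


def read_smiles_csv(
    path: str | Path, column: str = "smiles"
) -> Iterator[str]:
    """Stream SMILES strings from a one-or-more-column CSV (constant memory)."""
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or column not in reader.fieldnames:
            raise DataError(f"column {column!r} missing from {path}")
        for row in reader:
            yield row[column]


def write_smiles_csv(
    smiles: Iterable[str], path: str | Path, column: str = "smiles"
) -> int:
    """Stream SMILES to a single-column CSV (gzip by extension); returns count."""
    n = 0
    with _open_text(path, "wt") as fh:
        writer = csv.writer(fh)
        writer.writerow([column])
        for s in smiles:
            writer.writerow([s])
            n += 1
    return n


def read_fragment_csv(
    path: str | Path, report: Optional[ReaderReport] = None
) -> Iterator[FragmentRecord]:
    """Stream FragmentRecords from a CSV with smiles, side, source_id columns."""
    report = report if report is not None else ReaderReport()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise DataError(f"column 'smiles' missing from {path}")
        for row in reader:
            smi = row["smiles"]
            mol = Chem.MolFromSmiles(smi)
            if mol is None or sum(a.GetAtomicNum() == 0 for a in mol.GetAtoms()) != 1:
                logger.warning("rejecting fragment row %r", smi)
                report.n_rejected += 1
                continue
            report.n_read += 1
            yield FragmentRecord(
                smiles=Chem.MolToSmiles(mol),
                side=row.get("side", "left"),
                source_id=row.get("source_id", ""),
            )


def write_fragment_csv(records: Iterable[FragmentRecord], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "side", "source_id"])
        for rec in records:
            writer.writerow([rec.smiles, rec.side, rec.source_id])
            n += 1
    return n


# ---------------------------------------------------------------------------
# Hypothesis JSON
# ---------------------------------------------------------------------------


def read_hypothesis(path: str | Path) -> PharmacophoreHypothesis:
    """Load a pharmacophore hypothesis from JSON.

    Schema::

        {"name": "G1",
         "points": [{"type": "HYD", "center": [x, y, z], "radius": 1.5,
                     "key": true}, ...]}

    Units are Å.  Unknown feature types, non-positive radii or hypotheses
    without key points are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"hypothesis file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    points = []
    for p in data.get("points", []):
        token = p.get("type", "")
        try:
            ptype = FeatureType[token]
        except KeyError:
            raise DataError(f"unknown feature type {token!r} in {path}") from None
        radius = float(p.get("radius", 0.0))
        if radius <= 0:
            raise DataError(f"non-positive radius {radius} in {path}")
        points.append(
            PharmacophorePoint(
                ptype=ptype,
                center=np.asarray(p["center"], dtype=float),
                radius=radius,
                key=bool(p.get("key", False)),
            )
        )
    if not points:
        raise DataError(f"hypothesis {path} has no points")
    if not any(p.key for p in points):
        raise DataError(f"hypothesis {path} has no key points")
    return PharmacophoreHypothesis(name=str(data.get("name", path.stem)), points=points)


def write_hypothesis(hyp: PharmacophoreHypothesis, path: str | Path) -> None:
    data = {
        "name": hyp.name,
        "points": [
            {
                "type": p.ptype.name,
                "center": [float(x) for x in p.center],
                "radius": float(p.radius),
                "key": bool(p.key),
            }
            for p in hyp.points
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2)
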