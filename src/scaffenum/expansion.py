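"""Trivalent-to-bivalent scaffold expansion.

2D generative engines handle fragments with at most two attachment points
well, so trivalent crude scaffolds are converted into bivalent ones by
combinatorial replacement of one attachment point with a small capping
fragment.  The replacement is only chemically sensible at ports sitting on
aromatic carbons; every such port is tried for every cap, and the results
are canonicalized and deduplicated.  The shipped default capping set
(hydrogen, methyl, fluoro, chloro, methoxy, cyano, trifluoromethyl) is
configuration, not a constant — typical aromatic substituents, editable per
project.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .io_formats import DataError, Scaffold, scaffold_from_smiles
from .scaffolding import CrudeScaffoldSet

logger = logging.getLogger(__name__)

#: Default monovalent caps; "*[H]" deletes the port (hydrogen cap).
DEFAULT_CAPPING_SET: tuple[str, ...] = (
    "*[H]",
    "*C",
    "*F",
    "*Cl",
    "*OC",
    "*C#N",
    "*C(F)(F)F",
)


def _validate_cap(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is not None:
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            mol = None
    if mol is None:
        raise DataError(f"capping fragment does not parse: {smiles!r}")
    if sum(a.GetAtomicNum() == 0 for a in mol.GetAtoms()) != 1:
        raise DataError(f"capping fragment must have exactly one attachment point: {smiles!r}")
    return mol


def _is_hydrogen_cap(cap_mol: Chem.Mol) -> bool:
    heavy = [a for a in cap_mol.GetAtoms() if a.GetAtomicNum() > 1]
    return not heavy or all(a.GetAtomicNum() == 0 for a in heavy)


def _cap_port(scaffold_mol: Chem.Mol, port_idx: int, cap_mol: Chem.Mol) -> Chem.Mol:
    """Replace the dummy at ``port_idx`` with the cap (dummy deleted for [H])."""
    if _is_hydrogen_cap(cap_mol):
        rw = Chem.RWMol(scaffold_mol)
        rw.RemoveAtom(port_idx)
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        return out
    scaffold_mol = Chem.Mol(scaffold_mol)
    dummy = scaffold_mol.GetAtomWithIdx(port_idx)
    dummy.SetIsotope(0)
    dummy.SetAtomMapNum(9)
    cap = Chem.Mol(cap_mol)
    for a in cap.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetIsotope(0)
            a.SetAtomMapNum(9)
    combined = Chem.CombineMols(scaffold_mol, cap)
    out = Chem.molzip(combined)
    Chem.SanitizeMol(out)
    return out


def expand_trivalent(
    scaffold: Scaffold, capping_set: Sequence[str] = DEFAULT_CAPPING_SET,
    single_port: bool = False,
) -> list[Scaffold]:
    """Expand a trivalent scaffold into bivalent ones by port capping.

    Mono- and bivalent scaffolds pass through unchanged.  For a trivalent
    scaffold every port attached to an aromatic carbon is replaced, one at a
    time, by each capping fragment (``single_port`` restricts to the first
    such port); if no port sits on an aromatic carbon the scaffold is not
    expandable and [] is returned.  Surviving ports are relabeled onto
    {1, 2} preserving their order.
    """
    if not capping_set:
        raise DataError("capping set is empty")
    caps = [_validate_cap(c) for c in capping_set]
    if scaffold.n_ports <= 2:
        return [scaffold]

    mol = scaffold.mol()
    aromatic_ports = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0
        and any(nb.GetIsAromatic() and nb.GetAtomicNum() == 6 for nb in a.GetNeighbors())
    ]
    if not aromatic_ports:
        logger.info("scaffold %s has no aromatic-carbon port; not expandable", scaffold.smiles)
        return []
    if single_port:
        aromatic_ports = aromatic_ports[:1]

    out: dict[str, Scaffold] = {}
    for port_idx in aromatic_ports:
        for cap in caps:
            try:
                capped = _cap_port(mol, port_idx, cap)
            except Exception:
                logger.info("cap failed on %s", scaffold.smiles)
                continue
            # relabel surviving ports onto {1, 2} preserving order
            survivors = sorted(
                a.GetIsotope() for a in capped.GetAtoms() if a.GetAtomicNum() == 0
            )
            relabel = {old: new for new, old in enumerate(survivors, start=1)}
            for a in capped.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetIsotope(relabel[a.GetIsotope()])
            result = scaffold_from_smiles(Chem.MolToSmiles(capped))
            out[result.smiles] = result
    return list(out.values())


def finalize_scaffold_set(
    crude: CrudeScaffoldSet,
    capping_set: Sequence[str] = DEFAULT_CAPPING_SET,
    single_port: bool = False,
) -> list[Scaffold]:
    """Build the final scaffold set: mono/bivalent members plus all expansions.

    Trivalent scaffolds are expanded (unexpandable ones are excluded); the
    union is canonical-deduplicated.  Per-source counts are logged.
    """
    final: dict[str, Scaffold] = {}
    n_passthrough = n_expanded = n_unexpandable = 0
    for scaffold in crude.scaffolds.values():
        expanded = expand_trivalent(scaffold, capping_set, single_port=single_port)
        if scaffold.n_ports <= 2:
            n_passthrough += 1
        elif expanded:
            n_expanded += 1
        else:
            n_unexpandable += 1
        for s in expanded:
            final.setdefault(s.smiles, s)
    logger.info(
        "finalized %d scaffolds (%d passed through, %d trivalent expanded, %d unexpandable)",
        len(final), n_passthrough, n_expanded, n_unexpandable,
    )
    return list(final.values())
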