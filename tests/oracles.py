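"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fragment machinery: connected
components are computed on plain adjacency lists after deleting cut bonds,
so they provide an implementation-independent reference for the partial
BRICS decomposition and for minimal-fragment selection.
"""

import itertools

from rdkit import Chem
from rdkit.Chem import BRICS


def brics_bond_pairs(mol):
    return sorted({tuple(sorted(p)) for (p, _labels) in BRICS.FindBRICSBonds(mol)})


def _components(n_atoms, edges):
    adj = {i: set() for i in range(n_atoms)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, comps = set(), []
    for start in range(n_atoms):
        if start in seen:
            continue
        comp, stack = {start}, [start]
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if j not in comp:
                    comp.add(j)
                    stack.append(j)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def oracle_fragment_sets(mol, max_cuts):
    """All connected fragments from cutting ≤ max_cuts BRICS bonds.

    Returns {atom_set: (n_ports, has_ring)} plus the total piece count
    before deduplication.
    """
    n = mol.GetNumAtoms()
    all_edges = [
        tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))) for b in mol.GetBonds()
    ]
    cuttable = brics_bond_pairs(mol)
    rings = [frozenset(r) for r in mol.GetRingInfo().AtomRings()]
    out = {}
    pieces_before_dedup = 0
    for r in range(0, min(max_cuts, len(cuttable)) + 1):
        for subset in itertools.combinations(cuttable, r):
            kept = [e for e in all_edges if e not in set(subset)]
            for comp in _components(n, kept):
                pieces_before_dedup += 1
                ports = sum((i in comp) != (j in comp) for i, j in subset)
                has_ring = any(ring <= comp for ring in rings)
                out.setdefault(comp, (ports, has_ring))
    return out, pieces_before_dedup


def oracle_minimal_qualifying(mol, key_atoms, max_cuts):
    """Atom sets of minimal size among ring-bearing, ported, key-covering
    fragments; [] when no fragment qualifies."""
    sets, _ = oracle_fragment_sets(mol, max_cuts)
    qualifying = [
        comp
        for comp, (ports, has_ring) in sets.items()
        if ports >= 1 and has_ring and set(key_atoms) <= comp
    ]
    if not qualifying:
        return []
    best = min(len(c) for c in qualifying)
    return [c for c in qualifying if len(c) == best]
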