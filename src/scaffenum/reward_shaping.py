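"""Reward shaping for scaffold-diverse generative loops: CRV and SPAG.

Generative engines driven by a raw reward tend to exploit the highest-
scoring cluster.  Two composable modifications counteract that:

* **CRV** (Constant Reward Value) — every structure that passes all filters
  receives the same constant reward, removing the gradient that pulls the
  generator back into already-discovered clusters.
* **SPAG** (Similarity Penalty to Already Generated) — the reward of a
  candidate is reduced in proportion to its maximum fingerprint similarity
  to the archive of previously accepted structures (linear penalty, clamped
  at zero; the functional form is a pluggable strategy, linear by default).
  SPAG applies to the CRV-capped value (CRV first, then SPAG).

A deliberately small mutation-based generator (``toy_generate``) and a
scaffold-diversity report demonstrate the effect at desk scale; production
generative models are out of scope.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .io_formats import Pose
from .pharmacophore import (
    DEFAULT_FEATURE_SMARTS,
    FeatureType,
    PharmacophoreHypothesis,
)
from .scaffolding import brics_fragments_with_intermediates, extract_primary_scaffold

logger = logging.getLogger(__name__)


@dataclass
class RewardConfig:
    mode: str = "default"  # "default" | "crv" | "crv+spag"
    constant_value: float = 1.0  # the CRV constant c
    penalty_weight: float = 1.0  # SPAG weight w
    fp_radius: int = 2
    fp_bits: int = 2048

    def __post_init__(self) -> None:
        if self.constant_value <= 0:
            raise ValueError("constant_value must be positive")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be >= 0")
        if self.mode not in ("default", "crv", "crv+spag"):
            raise ValueError(f"unknown reward mode {self.mode!r}")


class GenerationArchive:
    """Fingerprint index over previously accepted structures."""

    def __init__(self, radius: int = 2, n_bits: int = 2048):
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
        self._fps: list = []
        self.smiles: list[str] = []

    def __len__(self) -> int:
        return len(self._fps)

    def _fp(self, smiles: str):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return self._gen.GetFingerprint(mol)

    def add(self, smiles: str) -> None:
        self._fps.append(self._fp(smiles))
        self.smiles.append(smiles)

    def max_similarity(self, smiles: str) -> float:
        """Maximum Tanimoto similarity of a candidate to any archive member
        (0.0 for an empty archive)."""
        if not self._fps:
            return 0.0
        fp = self._fp(smiles)
        return float(max(DataStructs.BulkTanimotoSimilarity(fp, self._fps)))


def crv_reward(passed_all_filters: bool, config: RewardConfig) -> Optional[float]:
    """Equalized reward: exactly ``constant_value`` for every passing
    structure, rejection (None) otherwise."""
    return config.constant_value if passed_all_filters else None


def spag_penalty(
    candidate: str,
    archive: GenerationArchive,
    config: RewardConfig,
    base: Optional[float] = None,
) -> float:
    """Penalize a filter-passing candidate by archive similarity, then insert it.

    reward = max(0, base − w · s_max) with s_max the maximum Tanimoto
    similarity of the candidate to any archive member.
    """
    if base is None:
        base = config.constant_value
    s_max = archive.max_similarity(candidate)
    reward = max(0.0, base - config.penalty_weight * s_max)
    archive.add(candidate)
    return reward


def tanimoto_scorer(target_smiles: str, config: Optional[RewardConfig] = None) -> Callable[[str], float]:
    """A raw exploit-prone scorer: similarity to a fixed target structure."""
    config = config or RewardConfig()
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.fp_radius, fpSize=config.fp_bits
    )
    target = gen.GetFingerprint(Chem.MolFromSmiles(target_smiles))

    def score(smiles: str) -> float:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return 0.0
        return float(DataStructs.TanimotoSimilarity(gen.GetFingerprint(mol), target))

    return score


def make_reward_fn(
    config: RewardConfig,
    base_scorer: Optional[Callable[[str], float]] = None,
    filter_fn: Optional[Callable[[str], bool]] = None,
) -> Callable[[str], Optional[float]]:
    """Compose filters, CRV capping and SPAG into a single reward function.

    Returns a callable mapping SMILES to a reward, or None for rejection
    (filter failure).  ``default`` mode passes the raw base score through;
    ``crv`` caps it to the constant; ``crv+spag`` additionally penalizes by
    archive similarity (the archive lives in the closure and starts empty).
    """
    archive = GenerationArchive(config.fp_radius, config.fp_bits)

    def reward(smiles: str) -> Optional[float]:
        if filter_fn is not None and not filter_fn(smiles):
            return None
        if config.mode == "default":
            if base_scorer is None:
                raise ValueError("default mode requires a base scorer")
            return base_scorer(smiles)
        capped = crv_reward(True, config)
        assert capped is not None
        if config.mode == "crv":
            return capped
        return spag_penalty(smiles, archive, config, base=capped)

    return reward


# ---------------------------------------------------------------------------
# Toy mutation-based generator
# ---------------------------------------------------------------------------

_SUBSTITUENTS = ("C", "F", "O", "N", "OC", "C#N", "Cl")
_RING_POOL = ("c1ccccc1", "C1CCCCC1", "c1ccncc1")
_TOURNAMENT = 4


def _sanitized(mol: Chem.Mol) -> Optional[Chem.Mol]:
    if Chem.DetectChemistryProblems(mol):
        return None
    try:
        Chem.SanitizeMol(mol)
        return mol
    except Exception:  # pragma: no cover - pre-screened above
        return None


def _attach(mol: Chem.Mol, atom_idx: int, frag_smiles: str) -> Optional[Chem.Mol]:
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    rw = Chem.RWMol(Chem.CombineMols(mol, frag))
    rw.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    return _sanitized(rw.GetMol())


_MAX_VALENCE = {6: 4, 7: 3, 8: 2}


def _mutate(mol: Chem.Mol, rng: random.Random) -> Optional[Chem.Mol]:
    """One random structural edit: atom substitution, substituent add/remove,
    or ring attachment.  Returns None when the edit is chemically invalid."""
    op = rng.choice(("swap", "add", "remove", "ring"))
    mol = Chem.Mol(mol)
    if op == "swap":
        candidates = [
            a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (6, 7, 8)
            and not a.GetIsAromatic()
        ]
        if not candidates:
            return None
        idx = rng.choice(candidates)
        atom = mol.GetAtomWithIdx(idx)
        bonded = int(atom.GetTotalValence()) - atom.GetTotalNumHs()
        choices = [
            z for z in {6: (7, 8), 7: (6, 8), 8: (6, 7)}[atom.GetAtomicNum()]
            if bonded <= _MAX_VALENCE[z]
        ]
        if not choices:
            return None
        atom.SetAtomicNum(rng.choice(choices))
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
    elif op in ("add", "ring"):
        candidates = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
        if not candidates:
            return None
        idx = rng.choice(candidates)
        frag = rng.choice(_SUBSTITUENTS if op == "add" else _RING_POOL)
        return _attach(mol, idx, frag)
    else:  # remove a terminal heavy atom
        terminals = [a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() == 1]
        if not terminals or mol.GetNumAtoms() <= 2:
            return None
        rw = Chem.RWMol(mol)
        rw.RemoveAtom(rng.choice(terminals))
        mol = rw.GetMol()
    return _sanitized(mol)


def toy_generate(
    seeds: Sequence[str],
    reward_fn: Callable[[str], Optional[float]],
    n_iterations: int,
    rng_seed: int,
) -> list[str]:
    """Iterative mutate–score–select loop; returns accepted structures.

    Seeds are scored first; each iteration picks a parent by reward
    tournament (size 4, ties broken at random — under CRV all rewards tie,
    so selection degenerates to uniform), applies one random mutation and
    scores the child.  Children with nonzero reward join the accepted set.
    Deterministic under ``rng_seed``.
    """
    if not seeds:
        raise ValueError("seed set is empty")
    rng = random.Random(rng_seed)
    accepted: dict[str, float] = {}
    for smi in seeds:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable seed: {smi!r}")
        canon = Chem.MolToSmiles(mol)
        r = reward_fn(canon)
        if r is not None and r > 0 and canon not in accepted:
            accepted[canon] = r
    for _ in range(n_iterations):
        if not accepted:
            break
        pool = list(accepted.items())
        contenders = [pool[rng.randrange(len(pool))] for _ in range(_TOURNAMENT)]
        best_r = max(r for _, r in contenders)
        winners = [s for s, r in contenders if r == best_r]
        parent = winners[rng.randrange(len(winners))]
        child = _mutate(Chem.MolFromSmiles(parent), rng)
        if child is None:
            continue
        smi = Chem.MolToSmiles(child)
        if smi in accepted:
            continue
        r = reward_fn(smi)
        if r is not None and r > 0:
            accepted[smi] = r
    return list(accepted)


# ---------------------------------------------------------------------------
# Diversity reporting
# ---------------------------------------------------------------------------


def _topological_scaffold(
    smiles: str, hyp: PharmacophoreHypothesis, max_cuts: int = 4
) -> Optional[str]:
    """2D reduction of primary-scaffold extraction for coordinate-free input.

    The smallest ring-bearing ≥1-port partial-BRICS fragment whose atoms
    include at least one atom of each *key feature type* of the hypothesis
    (donor/acceptor/hydrophobe by the shared SMARTS definitions) stands in
    for the 3D geometric gate when no pose is available.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    key_types = {p.ptype for p in hyp.key_points}
    type_atoms: dict[FeatureType, set[int]] = {}
    for ptype in key_types:
        hits: set[int] = set()
        if ptype is FeatureType.AROM:
            hits = {a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()}
        else:
            for smarts in DEFAULT_FEATURE_SMARTS.get(ptype, []):
                patt = Chem.MolFromSmarts(smarts)
                hits.update(m[0] for m in mol.GetSubstructMatches(patt))
        if not hits:
            return None
        type_atoms[ptype] = hits
    candidates = [
        c
        for c in brics_fragments_with_intermediates(mol, max_cuts)
        if c.n_ports >= 1
        and c.has_ring
        and all(c.atom_set & atoms for atoms in type_atoms.values())
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda c: (c.n_heavy, c.smiles)).smiles


def diversity_report(
    molecules: Iterable[Union[str, Pose]],
    hyp: PharmacophoreHypothesis,
    max_cuts: int = 4,
) -> dict:
    """Scaffold-diversity summary of a molecule set.

    Poses go through full 3D pharmacophore-aware extraction; bare SMILES use
    the 2D topological reduction.  The generic ring-system framework
    (Bemis–Murcko) is reported alongside as a pharmacophore-ignorant
    baseline.  Input is deduplicated by canonical SMILES first, so repeated
    entries do not inflate the counts.
    """
    unique: dict[str, Union[str, Pose]] = {}
    for item in molecules:
        if isinstance(item, Pose):
            unique[Chem.MolToSmiles(item.mol)] = item
        else:
            mol = Chem.MolFromSmiles(item)
            if mol is None:
                continue
            unique.setdefault(Chem.MolToSmiles(mol), item)

    primary: dict[str, int] = {}
    murcko: dict[str, int] = {}
    for canon, item in unique.items():
        if isinstance(item, Pose):
            scaffold = extract_primary_scaffold(item, hyp, max_cuts=max_cuts)
            smi = scaffold.smiles if scaffold is not None else None
        else:
            smi = _topological_scaffold(canon, hyp, max_cuts=max_cuts)
        if smi is not None:
            primary[smi] = primary.get(smi, 0) + 1
        bm = MurckoScaffold.MurckoScaffoldSmiles(canon)
        if bm:
            murcko[bm] = murcko.get(bm, 0) + 1

    return {
        "n_molecules": len(unique),
        "n_unique_primary_scaffolds": len(primary),
        "n_unique_bemis_murcko": len(murcko),
        "primary_scaffold_counts": dict(
            sorted(primary.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
    }
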