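"""Implicit Cartesian-product chemical spaces: counting, streaming, sampling.

The combinatorial explosion engine treats (scaffold set) × (left fragment
set) × (right fragment set) as an implicit space: its size is computed with
exact integer arithmetic without enumeration, full enumeration streams
products in deterministic lexicographic order with constant memory, and
sub-sampling draws, per scaffold, a seeded uniform without-replacement
subset of each fragment side and emits the cross product.  Left fragments
always fuse at port 1 (the hydrophobic-side vector), right fragments at
port 2 (the polar-side vector).  Chemically impossible junctions are
skipped and counted, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem

from .io_formats import DataError, FragmentRecord, Scaffold

logger = logging.getLogger(__name__)


class JoinError(DataError):
    """A junction could not be formed (arity mismatch or valence failure)."""


@dataclass
class EnumerationSpec:
    """An implicit combinatorial space plus optional sampling parameters."""

    scaffolds: Sequence[Scaffold]
    left: Sequence[FragmentRecord]
    right: Sequence[FragmentRecord]
    k_left: Optional[int] = None
    k_right: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for k in (self.k_left, self.k_right):
            if k is not None and k < 1:
                raise ValueError("sample sizes must be >= 1 when set")
        for s in self.scaffolds:
            if s.n_ports > 2:
                raise ValueError(f"enumeration requires mono/bivalent scaffolds: {s.smiles}")

    @property
    def sampled(self) -> bool:
        return self.k_left is not None or self.k_right is not None


@dataclass
class SpaceCount:
    n_scaffolds: int
    n_left: int
    n_right: int
    total: int  # exact arbitrary-precision integer

    def __str__(self) -> str:
        return (
            f"{self.n_scaffolds} scaffolds x {self.n_left} left x "
            f"{self.n_right} right = {self.total} structures"
        )


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------


def _prepare_fragment(frag: FragmentRecord, port: int) -> Chem.Mol:
    mol = frag.mol()
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise JoinError(f"fragment must be monovalent: {frag.smiles}")
    dummies[0].SetIsotope(0)
    dummies[0].SetAtomMapNum(port)
    return mol


def join(
    scaffold: Scaffold,
    left: Optional[FragmentRecord] = None,
    right: Optional[FragmentRecord] = None,
) -> str:
    """Fuse fragments onto a scaffold's ports by single bonds.

    ``left`` must be supplied iff the scaffold has port 1, ``right`` iff
    port 2.  Dummy atoms are removed, the single bond formed between the two
    port-neighbor atoms, and the canonical product SMILES returned.  Raises
    :class:`JoinError` on arity mismatch or a chemically invalid junction.
    """
    has_left, has_right = 1 in scaffold.ports, 2 in scaffold.ports
    if has_left != (left is not None) or has_right != (right is not None):
        raise JoinError(
            f"port/fragment arity mismatch for scaffold {scaffold.smiles} "
            f"(ports {scaffold.ports}, left={left is not None}, right={right is not None})"
        )
    mol = scaffold.mol()
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(a.GetIsotope())
            a.SetIsotope(0)
    combined = mol
    if left is not None:
        combined = Chem.CombineMols(combined, _prepare_fragment(left, 1))
    if right is not None:
        combined = Chem.CombineMols(combined, _prepare_fragment(right, 2))
    try:
        product = Chem.molzip(combined)
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise JoinError(f"invalid junction: {exc}") from exc
    return Chem.MolToSmiles(product)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def count_space(spec: EnumerationSpec) -> SpaceCount:
    """Exact size of the implicit space — integer arithmetic, no enumeration.

    Per scaffold, the left (right) factor is the left (right) set size when
    the scaffold has port 1 (2), reduced to min(k, set size) under sampling,
    and 1 for an absent port.  Totals are Python integers and never overflow.
    """
    n_left, n_right = len(spec.left), len(spec.right)
    total = 0
    for scaffold in spec.scaffolds:
        l = n_left if 1 in scaffold.ports else 1
        r = n_right if 2 in scaffold.ports else 1
        if spec.k_left is not None and 1 in scaffold.ports:
            l = min(spec.k_left, n_left)
        if spec.k_right is not None and 2 in scaffold.ports:
            r = min(spec.k_right, n_right)
        total += l * r
    return SpaceCount(
        n_scaffolds=len(spec.scaffolds), n_left=n_left, n_right=n_right, total=total
    )


# ---------------------------------------------------------------------------
# Streaming enumeration
# ---------------------------------------------------------------------------


class EnumerationStream:
    """Deterministic lexicographic iterator over the full product space.

    Iterates (scaffold_index, left_index, right_index, smiles); invalid
    junctions are skipped and tallied in :attr:`skipped`.  Constant memory in
    the space size.
    """

    def __init__(self, spec: EnumerationSpec):
        if spec.sampled:
            raise DataError("spec has sampling parameters set; use sample_space")
        self.spec = spec
        self.skipped = 0

    def __iter__(self) -> Iterator[tuple[int, int, int, str]]:
        spec = self.spec
        for si, scaffold in enumerate(spec.scaffolds):
            lefts: Sequence[Optional[FragmentRecord]] = (
                spec.left if 1 in scaffold.ports else [None]
            )
            rights: Sequence[Optional[FragmentRecord]] = (
                spec.right if 2 in scaffold.ports else [None]
            )
            for li, lf in enumerate(lefts):
                for ri, rf in enumerate(rights):
                    try:
                        smiles = join(scaffold, lf, rf)
                    except JoinError:
                        self.skipped += 1
                        continue
                    yield si, li, ri, smiles


def enumerate_stream(spec: EnumerationSpec) -> EnumerationStream:
    return EnumerationStream(spec)


# ---------------------------------------------------------------------------
# Seeded sampling
# ---------------------------------------------------------------------------


class SampleStream:
    """Per-scaffold seeded uniform sub-sampling of the product space.

    For each scaffold an independent generator seeded by (seed,
    scaffold_index) draws min(k, set size) fragments per side uniformly
    without replacement; the full cross product of the draws is emitted.
    Reruns with the same seed are byte-identical, and scaffolds can be
    processed in parallel without changing the draws.
    """

    def __init__(self, spec: EnumerationSpec):
        if not spec.sampled:
            raise DataError("spec has no sampling parameters; use enumerate_stream")
        self.spec = spec
        self.skipped = 0

    def _draw(self, rng: np.random.Generator, n: int, k: Optional[int]) -> list[int]:
        if k is None or k >= n:
            return list(range(n))
        return [int(i) for i in rng.choice(n, size=k, replace=False)]

    def __iter__(self) -> Iterator[str]:
        spec = self.spec
        for si, scaffold in enumerate(spec.scaffolds):
            rng = np.random.default_rng([spec.seed, si])
            left_idx = (
                self._draw(rng, len(spec.left), spec.k_left)
                if 1 in scaffold.ports else [None]
            )
            right_idx = (
                self._draw(rng, len(spec.right), spec.k_right)
                if 2 in scaffold.ports else [None]
            )
            for li in left_idx:
                for ri in right_idx:
                    try:
                        yield join(
                            scaffold,
                            spec.left[li] if li is not None else None,
                            spec.right[ri] if ri is not None else None,
                        )
                    except JoinError:
                        self.skipped += 1


def sample_space(spec: EnumerationSpec) -> SampleStream:
    return SampleStream(spec)


def dedup_stream(smiles: Iterator[str] | Sequence[str]) -> Iterator[str]:
    """Optional post-pass deduplication (holds the seen set in memory)."""
    seen: set[str] = set()
    for s in smiles:
        if s not in seen:
            seen.add(s)
            yield s
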