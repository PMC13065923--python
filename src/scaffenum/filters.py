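"""Medicinal-chemistry structural-alert (MCF) filtering and descriptors.

Three tiers of substructure alerts are shipped — ``minimal`` (reactive and
assay-interfering groups), ``moderate`` (a superset adding softer alerts)
and ``covalent`` (electrophilic warheads, applied as a separate list) — as
editable tab-separated files (rule_id, SMARTS, description).  The shipped
contents are assembled from public structural-alert collections; the file
format is the stable contract, the rule lists are project configuration.
``minimal ⊆ moderate`` containment is enforced at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

from rdkit import Chem
from rdkit.Chem import Descriptors

from .io_formats import DataError
from .pharmacophore import DEFAULT_FEATURE_SMARTS, FeatureType

logger = logging.getLogger(__name__)

_BUILTIN = {"minimal", "moderate", "covalent"}


@dataclass(frozen=True)
class AlertRule:
    rule_id: str
    smarts: str
    description: str
    pattern: Chem.Mol


@dataclass
class AlertRuleSet:
    name: str
    rules: list[AlertRule]

    def rule_ids(self) -> set[str]:
        return {r.rule_id for r in self.rules}


@dataclass(frozen=True)
class FilterVerdict:
    smiles: str
    passed: bool
    hits: tuple[str, ...]


def _parse_rules(lines: Iterable[str], name: str) -> list[AlertRule]:
    rules: list[AlertRule] = []
    seen: set[str] = set()
    for ln, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise DataError(f"ruleset {name}: malformed line {ln}: {line!r}")
        rule_id, smarts = parts[0], parts[1]
        desc = parts[2] if len(parts) > 2 else ""
        if rule_id in seen:
            raise DataError(f"ruleset {name}: duplicate rule_id {rule_id!r}")
        seen.add(rule_id)
        pattern = Chem.MolFromSmarts(smarts)
        if pattern is None:
            raise DataError(f"ruleset {name}: invalid SMARTS for {rule_id!r}: {smarts!r}")
        rules.append(AlertRule(rule_id, smarts, desc, pattern))
    return rules


def load_ruleset(name_or_path: str) -> AlertRuleSet:
    """Load a built-in tier (minimal/moderate/covalent) or a custom rule file.

    Built-in tiers are checked for minimal ⊆ moderate rule containment so a
    molecule failing minimal necessarily fails moderate.
    """
    if name_or_path in _BUILTIN:
        text = (
            resources.files("scaffenum.data")
            .joinpath(f"mcf_{name_or_path}.tsv")
            .read_text(encoding="utf-8")
        )
        rules = _parse_rules(text.splitlines(), name_or_path)
        ruleset = AlertRuleSet(name=name_or_path, rules=rules)
        if name_or_path == "moderate":
            minimal = load_ruleset("minimal")
            missing = minimal.rule_ids() - ruleset.rule_ids()
            if missing:
                raise DataError(
                    f"moderate ruleset must contain the minimal rules; missing {sorted(missing)}"
                )
        return ruleset
    path = Path(name_or_path)
    if not path.exists():
        raise DataError(f"ruleset not found: {name_or_path}")
    with open(path, encoding="utf-8") as fh:
        return AlertRuleSet(name=path.stem, rules=_parse_rules(fh, path.stem))


def mcf_filter(smiles: str, ruleset: AlertRuleSet) -> FilterVerdict:
    """Screen one molecule against an alert rule set.

    Every matching rule is listed in ``hits`` (order-independent semantics;
    reported in rule-file order).  Unparseable SMILES fail with the sentinel
    hit ``UNPARSEABLE``.  Input is canonicalized before matching so verdicts
    do not depend on the kekulization variant.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return FilterVerdict(smiles=smiles, passed=False, hits=("UNPARSEABLE",))
    hits = tuple(
        rule.rule_id for rule in ruleset.rules if mol.HasSubstructMatch(rule.pattern)
    )
    return FilterVerdict(smiles=smiles, passed=not hits, hits=hits)


def filter_stream(
    smiles: Iterable[str], ruleset: AlertRuleSet, invert: bool = False
) -> Iterator[FilterVerdict]:
    """Lazily screen a SMILES stream; ``invert`` keeps alert-bearing molecules
    instead (useful when the covalent tier is used to *select* warheads)."""
    for s in smiles:
        verdict = mcf_filter(s, ruleset)
        if verdict.passed != invert:
            yield verdict


# ---------------------------------------------------------------------------
# Descriptor annotation
# ---------------------------------------------------------------------------

_EXTRA_DESCRIPTORS: dict[str, Callable[[Chem.Mol], float]] = {}


def register_descriptor(name: str, fn: Callable[[Chem.Mol], float]) -> None:
    """Plug-in hook: register an extra descriptor computed on an RDKit Mol."""
    _EXTRA_DESCRIPTORS[name] = fn


def _count_atoms(mol: Chem.Mol, smarts_list) -> int:
    hits: set[int] = set()
    for smarts in smarts_list:
        patt = Chem.MolFromSmarts(smarts)
        hits.update(m[0] for m in mol.GetSubstructMatches(patt))
    return len(hits)


def annotate_descriptors(smiles: str) -> dict[str, float]:
    """MW (average molecular weight, g/mol) plus HBD/HBA heavy-atom counts.

    Donor/acceptor definitions are the same SMARTS the pharmacophore module
    perceives features with, so 2D annotation and 3D matching agree on what
    counts as a donor or acceptor.  Registered plug-in descriptors are
    appended.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparseable SMILES: {smiles!r}")
    out: dict[str, float] = {
        "MW": float(Descriptors.MolWt(mol)),
        "HBD": float(_count_atoms(mol, DEFAULT_FEATURE_SMARTS[FeatureType.HBD])),
        "HBA": float(_count_atoms(mol, DEFAULT_FEATURE_SMARTS[FeatureType.HBA])),
    }
    for name, fn in _EXTRA_DESCRIPTORS.items():
        out[name] = float(fn(mol))
    return out
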