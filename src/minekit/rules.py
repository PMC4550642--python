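"""Generalized enzymatic reaction rules and their application to compounds.

A rule captures a reactive-site motif and its bond changes as a mapped
SMIRKS transform, organized by third-level EC class, with explicit cofactor
molecules listed separately so the combined reaction is element-balanced.
Applying a rule to a substrate enumerates every subgraph match of the site
pattern and executes the transform at each, yielding raw product structures
that are standardized downstream.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

from minekit.registry import mol_from_smiles

log = logging.getLogger(__name__)


class RuleError(ValueError):
    """A rule definition or rule file is invalid."""


@dataclass
class ReactionRule:
    """A generalized transformation operator at third-level EC generality.

    ``transform`` is a mapped single-substrate SMIRKS: unmapped atoms on the
    product side are supplied by ``cofactor_reactants`` (e.g. the water of a
    hydrolysis), and atoms deleted from the substrate end up in
    ``cofactor_products``; the combined reaction is element-balanced.
    """

    name: str
    ec_class: str
    transform: str
    cofactor_reactants: list[str] = field(default_factory=list)
    cofactor_products: list[str] = field(default_factory=list)
    bidirectional: bool = False
    _rxn: AllChem.ChemicalReaction | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._rxn = self._parse_transform()

    def _parse_transform(self) -> AllChem.ChemicalReaction:
        try:
            rxn = AllChem.ReactionFromSmarts(self.transform)
        except Exception as exc:
            raise RuleError(f"rule {self.name!r}: transform does not parse: {exc}") from exc
        if rxn.GetNumReactantTemplates() != 1:
            raise RuleError(f"rule {self.name!r}: exactly one reactant template required")
        left = Counter(
            a.GetAtomMapNum()
            for t in rxn.GetReactants()
            for a in t.GetAtoms()
            if a.GetAtomMapNum()
        )
        right = Counter(
            a.GetAtomMapNum()
            for t in rxn.GetProducts()
            for a in t.GetAtoms()
            if a.GetAtomMapNum()
        )
        missing = set(left) - set(right)
        if missing or any(n > 1 for n in left.values()) or any(n > 1 for n in right.values()):
            raise RuleError(
                f"rule {self.name!r}: mapped atoms must appear exactly once per side"
                f" (unbalanced maps: {sorted(missing) or sorted(left.keys())})"
            )
        for cof in self.cofactor_reactants + self.cofactor_products:
            if Chem.MolFromSmiles(cof) is None:
                raise RuleError(f"rule {self.name!r}: unparseable cofactor {cof!r}")
        rxn.Initialize()
        return rxn

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        if self._rxn is None:
            self._rxn = self._parse_transform()
        return self._rxn


@dataclass
class RuleApplication:
    """One execution of a rule at one matched site of one substrate."""

    rule_name: str
    substrate_smiles: str
    site: tuple[int, ...]
    products: list[str]  # raw canonical SMILES, pre-curation


_COLUMNS = ["name", "ec_class", "transform", "cofactor_reactants", "cofactor_products", "bidirectional"]


def parse_rule_file(path: str | Path) -> list[ReactionRule]:
    """Load reaction rules from a TSV file, validating every transform.

    Columns: ``name``, ``ec_class``, ``transform`` (SMIRKS),
    ``cofactor_reactants`` / ``cofactor_products`` (semicolon-joined SMILES,
    may be empty), ``bidirectional`` (0/1). Lines starting with '#' are
    comments. Malformed transforms and duplicate names are load errors.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames is None:
        return []
    missing = [c for c in _COLUMNS if c not in reader.fieldnames]
    if missing:
        raise RuleError(f"{path}: missing columns {missing}")
    rules: list[ReactionRule] = []
    seen: set[str] = set()
    for i, row in enumerate(reader, start=2):
        name = (row.get("name") or "").strip()
        if not name:
            continue
        if name in seen:
            raise RuleError(f"{path}: duplicate rule name {name!r} at row {i}")
        seen.add(name)
        try:
            rule = ReactionRule(
                name=name,
                ec_class=(row.get("ec_class") or "").strip(),
                transform=(row.get("transform") or "").strip(),
                cofactor_reactants=_split(row.get("cofactor_reactants")),
                cofactor_products=_split(row.get("cofactor_products")),
                bidirectional=(row.get("bidirectional") or "0").strip() in {"1", "true", "True"},
            )
        except RuleError as exc:
            raise RuleError(f"{path}: row {i}: {exc}") from exc
        rules.append(rule)
    return rules


def _split(cell: str | None) -> list[str]:
    cell = (cell or "").strip()
    return [s for s in cell.split(";") if s] if cell else []


def apply_rule(structure: str | Chem.Mol, rule: ReactionRule) -> list[RuleApplication]:
    """Execute a rule at every matched site of a substrate.

    Products are raw (standardization happens downstream); cofactors are
    carried on the rule, not embedded in the product structures. Sites whose
    transform execution fails chemically are skipped with a warning.
    Symmetry-equivalent sites yielding identical product sets are collapsed,
    keeping the lexicographically smallest site tuple; the output, as
    product SMILES sets, is independent of substrate atom ordering.
    """
    mol = mol_from_smiles(structure) if isinstance(structure, str) else structure
    substrate_smiles = Chem.MolToSmiles(mol)
    applications: list[RuleApplication] = []
    seen_products: dict[frozenset[str], int] = {}
    for product_set in rule.rxn.RunReactants((mol,)):
        site_atoms: set[int] = set()
        smiles_list: list[str] = []
        try:
            for product in product_set:
                for atom in product.GetAtoms():
                    if atom.HasProp("react_atom_idx"):
                        site_atoms.add(atom.GetIntProp("react_atom_idx"))
                Chem.SanitizeMol(product)
                smiles_list.append(Chem.MolToSmiles(product))
        except Exception as exc:
            log.warning(
                "rule %s on %s: site skipped (%s)", rule.name, substrate_smiles, exc
            )
            continue
        site = tuple(sorted(site_atoms))
        key = frozenset(smiles_list)
        if key in seen_products:
            prev = applications[seen_products[key]]
            if site < prev.site:
                prev.site = site
            continue
        seen_products[key] = len(applications)
        applications.append(
            RuleApplication(
                rule_name=rule.name,
                substrate_smiles=substrate_smiles,
                site=site,
                products=sorted(smiles_list),
            )
        )
    applications.sort(key=lambda a: (a.products, a.site))
    return applications


def match_sites(structure: str | Chem.Mol, rule: ReactionRule) -> list[tuple[int, ...]]:
    """Matched-site atom tuples for a rule, symmetry-collapsed.

    Two matches are collapsed when they produce identical product sets, so
    the site count equals the number of distinct outcomes.
    """
    return [app.site for app in apply_rule(structure, rule)]


def element_counts(smiles: str) -> Counter:
    """Element multiset of a structure, hydrogens included."""
    mol = mol_from_smiles(smiles)
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] += h
    return counts


def is_balanced(application: RuleApplication, rule: ReactionRule) -> bool:
    """Check element conservation of substrate+cofactors vs products+cofactors."""
    lhs: Counter = element_counts(application.substrate_smiles)
    for cof in rule.cofactor_reactants:
        lhs += element_counts(cof)
    rhs: Counter = Counter()
    for smi in application.products:
        rhs += element_counts(smi)
    for cof in rule.cofactor_products:
        rhs += element_counts(cof)
    return lhs == rhs
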