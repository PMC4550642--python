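"""Whole-database expansion: every rule applied to every eligible compound.

Seeds (generation 0) are curated, then each generation applies the full
rule set to the compounds newly added in the previous generation. Products
are standardized, deduplicated against the whole database by Standard
InChIKey, and registered together with an element-balanced Reaction record.
The procedure is fully deterministic: identical inputs give identical
compound and reaction identifier sets regardless of input order.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field

from minekit.curation import (
    CurationReport,
    StandardizationError,
    curate,
    is_generalized,
    is_inorganic,
    standardize,
)
from minekit.registry import Compound, ParseError, mol_from_smiles, register_compound
from minekit.rules import ReactionRule, RuleApplication, apply_rule, element_counts

log = logging.getLogger(__name__)


@dataclass
class Reaction:
    """Stoichiometric record of one predicted transformation.

    ``reactants`` and ``products`` are (coefficient, compound_id) tuples;
    ``operators`` lists every rule that predicted the reaction. The id is
    'R' + SHA1 of the canonical reaction string, so a reaction and its
    reverse share one id.
    """

    reaction_id: str
    reactants: list[tuple[int, str]]
    products: list[tuple[int, str]]
    operators: list[str] = field(default_factory=list)

    def to_doc(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "reactants": [[c, cid] for c, cid in self.reactants],
            "products": [[c, cid] for c, cid in self.products],
            "operators": list(self.operators),
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "Reaction":
        return cls(
            reaction_id=doc["reaction_id"],
            reactants=[(int(c), cid) for c, cid in doc["reactants"]],
            products=[(int(c), cid) for c, cid in doc["products"]],
            operators=list(doc.get("operators", [])),
        )


@dataclass
class ExpansionConfig:
    """Deterministic expansion settings; no randomness anywhere.

    Inorganic reaction products (orthophosphate from a phosphatase rule,
    say) are registered by default: dropping them would leave reaction
    records dangling. Seed curation always filters inorganics.
    """

    generations: int = 1
    max_generations: int = 5
    filter_inorganic_products: bool = False


def _side_string(side: list[tuple[int, str]]) -> str:
    tokens = sorted(side, key=lambda t: t[1])
    return " + ".join(f"({coef}) {cid}" for coef, cid in tokens)


def canonical_reaction_string(
    reactants: list[tuple[int, str]], products: list[tuple[int, str]]
) -> str:
    """Sorted textual form of a reaction, identical for a reaction and its reverse.

    "(coef) cid" tokens sort lexicographically by compound id within each
    side; the lexicographically smaller side string comes first, joined by
    " <=> ".
    """
    if not reactants or not products:
        raise ValueError("reaction must have a non-empty reactant and product side")
    left, right = _side_string(reactants), _side_string(products)
    if right < left:
        left, right = right, left
    return f"{left} <=> {right}"


def reaction_id(reactants: list[tuple[int, str]], products: list[tuple[int, str]]) -> str:
    """'R' + SHA1 hex of the canonical reaction string."""
    text = canonical_reaction_string(reactants, products)
    return "R" + hashlib.sha1(text.encode("utf-8")).hexdigest()


def _as_side(cids: list[str]) -> list[tuple[int, str]]:
    counts = Counter(cids)
    return sorted(((n, cid) for cid, n in counts.items()), key=lambda t: t[1])


def _cancel(
    reactants: list[tuple[int, str]], products: list[tuple[int, str]]
) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """Remove compounds occurring on both sides (min count) — no no-op records."""
    left = Counter({cid: n for n, cid in reactants})
    right = Counter({cid: n for n, cid in products})
    common = left & right
    left -= common
    right -= common
    return (
        sorted(((n, c) for c, n in left.items()), key=lambda t: t[1]),
        sorted(((n, c) for c, n in right.items()), key=lambda t: t[1]),
    )


class _Database:
    """In-build registry keyed by compound_id with InChIKey-level dedup."""

    def __init__(self) -> None:
        self.compounds: dict[str, Compound] = {}
        self._by_inchikey: dict[str, str] = {}
        self.reactions: dict[str, Reaction] = {}

    def add_compound(self, comp: Compound) -> tuple[Compound, bool]:
        """Register, or resolve to the existing record with the same InChIKey."""
        existing_cid = self._by_inchikey.get(comp.inchikey)
        if existing_cid is not None:
            existing = self.compounds[existing_cid]
            if comp.generation < existing.generation:
                existing.generation = comp.generation
            return existing, False
        self.compounds[comp.compound_id] = comp
        self._by_inchikey[comp.inchikey] = comp.compound_id
        return comp, True

    def add_reaction(
        self,
        reactants: list[tuple[int, str]],
        products: list[tuple[int, str]],
        operator: str,
    ) -> Reaction | None:
        reactants, products = _cancel(reactants, products)
        if not reactants or not products:
            return None
        rid = reaction_id(reactants, products)
        rxn = self.reactions.get(rid)
        if rxn is None:
            rxn = Reaction(reaction_id=rid, reactants=reactants, products=products)
            self.reactions[rid] = rxn
            for _, cid in reactants:
                self.compounds[cid].reactant_in.append(rid)
            for _, cid in products:
                self.compounds[cid].product_of.append(rid)
        if operator not in rxn.operators:
            rxn.operators.append(operator)
            rxn.operators.sort()
        return rxn


def expand(
    seeds: list[str],
    rules: list[ReactionRule],
    config: ExpansionConfig | None = None,
) -> tuple[dict[str, Compound], dict[str, Reaction], list[CurationReport]]:
    """Expand a seed set through one or more generations of rule application.

    Returns the compound collection, the reaction collection, and one
    CurationReport per pass (seed curation first). ``mine_number`` serials
    are assigned in ascending ``compound_id`` order at the end, so they are
    independent of discovery order.
    """
    config = config or ExpansionConfig()
    generations = config.generations
    if generations > config.max_generations:
        log.warning(
            "generations %d exceeds cap %d; truncating", generations, config.max_generations
        )
        generations = config.max_generations

    db = _Database()
    seed_compounds, seed_report = curate(seeds, generation=0)
    for comp in seed_compounds:
        db.add_compound(comp)
    reports = [seed_report]

    rules = sorted(rules, key=lambda r: r.name)
    frontier = sorted(db.compounds)
    for gen in range(1, generations + 1):
        report = CurationReport()
        new_cids: list[str] = []
        for cid in frontier:
            substrate = db.compounds[cid]
            for rule in rules:
                for app in apply_rule(substrate.smiles, rule):
                    new_cids += _register_application(
                        db, substrate, rule, app, gen, config, report
                    )
        report.check()
        reports.append(report)
        frontier = sorted(set(new_cids))
        if not frontier:
            break

    finalize(db.compounds)
    return db.compounds, db.reactions, reports


def _register_application(
    db: _Database,
    substrate: Compound,
    rule: ReactionRule,
    app: RuleApplication,
    generation: int,
    config: ExpansionConfig,
    report: CurationReport,
) -> list[str]:
    """Register the products and reaction of one rule application.

    The application is dropped whole if it is not element-balanced or any
    product fails curation — a partial record would dangle.
    """
    report.n_input += len(app.products)
    if not _application_balanced(substrate, rule, app):
        log.warning(
            "rule %s on %s: application dropped (element balance lost)",
            rule.name,
            substrate.smiles,
        )
        report.n_rejected_standardization += len(app.products)
        return []

    new_cids: list[str] = []
    product_cids: list[str] = []
    staged: list[Compound] = []
    for smi in app.products:
        try:
            mol = mol_from_smiles(smi)
            if is_generalized(mol):
                raise StandardizationError("generalized product")
            if config.filter_inorganic_products and is_inorganic(mol):
                raise StandardizationError("inorganic product")
            std = standardize(mol)
            staged.append(register_compound(std, generation=generation))
        except (ParseError, StandardizationError, ValueError) as exc:
            log.warning("rule %s on %s: product %r dropped (%s); application skipped",
                        rule.name, substrate.smiles, smi, exc)
            report.n_rejected_standardization += len(app.products)
            return []
    for comp in staged:
        registered, created = db.add_compound(comp)
        if created:
            new_cids.append(registered.compound_id)
            report.n_retained += 1
        else:
            report.n_duplicates_removed += 1
        product_cids.append(registered.compound_id)

    reactant_cids = [substrate.compound_id]
    for cof in rule.cofactor_reactants:
        reactant_cids.append(_register_cofactor(db, cof))
    for cof in rule.cofactor_products:
        product_cids.append(_register_cofactor(db, cof))
    db.add_reaction(_as_side(reactant_cids), _as_side(product_cids), rule.name)
    return new_cids


def _application_balanced(
    substrate: Compound, rule: ReactionRule, app: RuleApplication
) -> bool:
    lhs = element_counts(substrate.smiles)
    for cof in rule.cofactor_reactants:
        lhs += element_counts(cof)
    rhs: Counter = Counter()
    for smi in app.products:
        rhs += element_counts(smi)
    for cof in rule.cofactor_products:
        rhs += element_counts(cof)
    return lhs == rhs


def _register_cofactor(db: _Database, smiles: str) -> str:
    """Cofactors (water, O2, ATP...) are generation-0 entries, never filtered."""
    comp = register_compound(smiles, generation=0)
    registered, _ = db.add_compound(comp)
    return registered.compound_id


def finalize(compounds: dict[str, Compound]) -> None:
    """Assign sequential mine_number serials in ascending compound_id order."""
    for serial, cid in enumerate(sorted(compounds), start=1):
        compounds[cid].mine_number = serial
        compounds[cid].reactant_in = sorted(set(compounds[cid].reactant_in))
        compounds[cid].product_of = sorted(set(compounds[cid].product_of))


def db_stats(
    compounds: dict[str, Compound],
    external_xref_keys: set[str] | None = None,
) -> dict:
    """Summary statistics: seed count, final count, fold increase, % cross-referenced.

    ``external_xref_keys`` is a set of InChIKey connectivity blocks (first
    14 characters); the percentage of database compounds whose block occurs
    in it is reported to two decimals. Fold increase is final/seed rounded
    to the nearest integer.
    """
    n_seed = sum(1 for c in compounds.values() if c.generation == 0)
    n_final = len(compounds)
    fold = round(n_final / n_seed) if n_seed else 0
    pct = 0.0
    if external_xref_keys is not None and n_final:
        hits = sum(1 for c in compounds.values() if c.inchikey[:14] in external_xref_keys)
        pct = round(100.0 * hits / n_final, 2)
    return {
        "seed_compounds": n_seed,
        "final_compounds": n_final,
        "fold_increase": fold,
        "pct_in_external": pct,
    }
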