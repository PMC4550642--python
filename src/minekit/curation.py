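"""Structure filtering and standardization ahead of registration.

Seed sets and raw rule products are filtered (generalized R-group
structures, carbon-free inorganics, disconnected multi-fragment records are
removed), normalized to canonical valences and charge placement, and
deduplicated by full Standard InChIKey. Generalized structures cannot be
assigned an accurate mass, which is what the downstream search matches on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from minekit.registry import Compound, ParseError, mol_from_smiles, register_compound

log = logging.getLogger(__name__)


@dataclass
class CurationReport:
    """Bookkeeping of a curation pass; input count equals retained + removals."""

    n_input: int = 0
    n_unparseable_removed: int = 0
    n_generalized_removed: int = 0
    n_inorganic_removed: int = 0
    n_disconnected_removed: int = 0
    n_rejected_standardization: int = 0
    n_duplicates_removed: int = 0
    n_retained: int = 0

    def removals(self) -> int:
        return (
            self.n_unparseable_removed
            + self.n_generalized_removed
            + self.n_inorganic_removed
            + self.n_disconnected_removed
            + self.n_rejected_standardization
            + self.n_duplicates_removed
        )

    def check(self) -> None:
        assert self.n_input == self.n_retained + self.removals(), asdict(self)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def __add__(self, other: "CurationReport") -> "CurationReport":
        merged = CurationReport()
        for k, v in asdict(self).items():
            setattr(merged, k, v + getattr(other, k))
        return merged


def _as_mol(structure: str | Chem.Mol) -> Chem.Mol:
    return mol_from_smiles(structure) if isinstance(structure, str) else structure


def is_generalized(structure: str | Chem.Mol) -> bool:
    """True iff the structure contains a wildcard/R-group/query atom."""
    mol = _as_mol(structure)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 or atom.HasQuery():
            return True
    return False


def is_inorganic(structure: str | Chem.Mol) -> bool:
    """True iff the structure contains no carbon atom."""
    mol = _as_mol(structure)
    return not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def is_disconnected(structure: str | Chem.Mol) -> bool:
    """True iff the molecular graph has more than one connected component."""
    mol = _as_mol(structure)
    return len(Chem.GetMolFrags(mol)) > 1


class StandardizationError(ValueError):
    """Structure could not be repaired to a chemically valid form."""


_uncharger = rdMolStandardize.Uncharger()


def standardize(structure: str | Chem.Mol) -> str:
    """Normalize a structure: canonical valences and placement of charge.

    Applies the normalization table (nitro, N-oxide, azide and similar
    groups rewritten in canonical charge-separated form) and neutralizes the
    overall charge where adding or removing protons on standard ionizable
    groups achieves it. Tautomers are NOT canonicalized globally: aggressive
    tautomer merging would silently conflate distinct database entries.

    Returns canonical SMILES of the standardized structure; raises
    :class:`StandardizationError` for unrepairable valences.
    """
    if isinstance(structure, str):
        # parse without sanitization so repairable valence errors reach the
        # normalizer instead of failing at the door
        mol = Chem.MolFromSmiles(structure, sanitize=False)
        if mol is None:
            raise ParseError(structure)
    else:
        mol = Chem.Mol(structure)
    try:
        mol.UpdatePropertyCache(strict=False)
        mol = rdMolStandardize.Normalize(mol)
        mol = _uncharger.uncharge(mol)
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise StandardizationError(f"unrepairable structure: {exc}") from exc
    return Chem.MolToSmiles(mol)


def dedupe(compounds: list[Compound]) -> tuple[list[Compound], CurationReport]:
    """Keep at most one compound per full Standard InChIKey.

    The compound with the lexicographically lowest ``compound_id`` is
    retained for each key; output is sorted by ``compound_id`` so the result
    is independent of input order.
    """
    report = CurationReport(n_input=len(compounds))
    by_key: dict[str, Compound] = {}
    for comp in sorted(compounds, key=lambda c: c.compound_id):
        if comp.inchikey in by_key:
            report.n_duplicates_removed += 1
        else:
            by_key[comp.inchikey] = comp
    retained = sorted(by_key.values(), key=lambda c: c.compound_id)
    report.n_retained = len(retained)
    report.check()
    return retained, report


def curate(
    structures: list[str],
    generation: int = 0,
    filter_inorganic: bool = True,
) -> tuple[list[Compound], CurationReport]:
    """Full curation pass: filter, standardize, register, deduplicate.

    Structures failing any filter are dropped (with per-category counts in
    the report), never repaired. Idempotent: curating the retained SMILES
    again changes nothing.
    """
    report = CurationReport(n_input=len(structures))
    registered: list[Compound] = []
    for smi in structures:
        try:
            mol = mol_from_smiles(smi)
        except ParseError:
            report.n_unparseable_removed += 1
            log.warning("dropped unparseable structure %r", smi)
            continue
        if is_generalized(mol):
            report.n_generalized_removed += 1
            continue
        if filter_inorganic and is_inorganic(mol):
            report.n_inorganic_removed += 1
            continue
        if is_disconnected(mol):
            report.n_disconnected_removed += 1
            continue
        try:
            std = standardize(mol)
            registered.append(register_compound(std, generation=generation))
        except (StandardizationError, ValueError) as exc:
            report.n_rejected_standardization += 1
            log.warning("dropped %r at standardization: %s", smi, exc)
    deduped, dreport = dedupe(registered)
    report.n_duplicates_removed = dreport.n_duplicates_removed
    report.n_retained = len(deduped)
    report.check()
    return deduped, report
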