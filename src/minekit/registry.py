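"""Canonical molecule representation, identifiers and computed properties.

Every structure entering the database passes through this module: SMILES are
canonicalized with RDKit, the Standard InChIKey provides the deduplication
key, and each compound receives a deterministic hash identifier — ``'C'``
followed by the SHA1 of the UTF-8 canonical SMILES — plus a human-readable
serial number assigned at database finalization.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys
from rdkit.Chem.inchi import MolToInchiKey

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

# CODATA values in unified atomic mass units.
ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466621

_PATH_FP_BITS = 1024
_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{8}[SN][A-Z]-[A-Z]$")
_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ParseError(ValueError):
    """A structure string could not be interpreted."""

    def __init__(self, text: str, kind: str = "SMILES"):
        self.text = text
        super().__init__(f"unparseable {kind}: {text!r}")


class UnknownElementError(ValueError):
    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"element not in atomic mass table: {symbol!r}")


class InchiUnavailableError(ValueError):
    """Raised for structures the InChI algorithm cannot represent."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES into an RDKit Mol, raising :class:`ParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(smiles)
    return mol


def canonicalize(smiles: str) -> str:
    """Return the unique canonical (isomeric) SMILES for a structure.

    All SMILES writings of the same molecular graph map to one output, and
    the output re-canonicalizes to itself.
    """
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def make_inchikey(structure: str | Chem.Mol) -> str:
    """Standard 27-character InChIKey (14-8-1-1-1 hyphenated layout).

    The first 14 characters (connectivity block) are shared by stereoisomers
    and isotopologues of the same skeleton and drive cross-database matching.
    """
    mol = mol_from_smiles(structure) if isinstance(structure, str) else structure
    key = MolToInchiKey(mol)
    if not key or not _INCHIKEY_RE.match(key):
        raise InchiUnavailableError(
            f"InChI cannot represent structure {Chem.MolToSmiles(mol)!r}"
        )
    return key


def connectivity_block(inchikey: str) -> str:
    """First 14 characters of a Standard InChIKey (skeleton layer)."""
    return inchikey[:14]


def molecular_formula(structure: str | Chem.Mol) -> str:
    """Hill-order molecular formula (C first, H second, rest alphabetical).

    Charge designators are excluded from the formula text.
    """
    mol = mol_from_smiles(structure) if isinstance(structure, str) else structure
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    parts = []
    carbon = "C" in counts
    order = [s for s in ("C", "H") if carbon and s in counts]
    order += sorted(s for s in counts if s not in ({"C", "H"} if carbon else set()))
    if not carbon:
        order = sorted(counts)
    for sym in order:
        n = counts[sym]
        parts.append(sym + (str(n) if n > 1 else ""))
    return "".join(parts)


@dataclass(frozen=True)
class AtomicMassTable:
    """Monoisotopic masses (most abundant isotope) plus particle constants.

    Element masses are drawn from RDKit's periodic table; the proton and
    electron masses are CODATA constants, needed for adduct arithmetic and
    charged-species mass correction.
    """

    proton: float = PROTON_MASS
    electron: float = ELECTRON_MASS

    def mass(self, symbol: str) -> float:
        pt = Chem.GetPeriodicTable()
        try:
            m = pt.GetMostCommonIsotopeMass(symbol)
        except Exception:
            raise UnknownElementError(symbol) from None
        if m <= 0:
            raise UnknownElementError(symbol)
        return m

    def __getitem__(self, symbol: str) -> float:
        return self.mass(symbol)

    def __contains__(self, symbol: str) -> bool:
        try:
            self.mass(symbol)
            return True
        except UnknownElementError:
            return False


MASS_TABLE = AtomicMassTable()


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill formula string into element counts."""
    if not formula or not formula.strip():
        raise ParseError(formula, kind="formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN_RE.finditer(formula):
        if m.start() != pos:
            raise ParseError(formula, kind="formula")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ParseError(formula, kind="formula")
    return counts


def exact_mass(structure: str | Chem.Mol) -> float:
    """Monoisotopic mass in Da of a formula, SMILES string, or Mol.

    The sum of most-abundant-isotope atomic masses; for charged species the
    electron mass is subtracted per positive charge (added per negative).
    """
    if isinstance(structure, Chem.Mol):
        return _mass_of_mol(structure)
    text = structure.strip() if isinstance(structure, str) else ""
    if not text:
        raise ParseError(structure, kind="formula or SMILES")
    # SMILES interpretation wins for ambiguous strings like "CO"; Hill
    # formulas ("H2O", "C6H12O6") are not valid SMILES and fall through.
    mol = Chem.MolFromSmiles(text)
    if mol is not None:
        return _mass_of_mol(mol)
    return formula_mass(text)


def formula_mass(formula: str) -> float:
    """Monoisotopic mass in Da of a Hill formula string."""
    counts = parse_formula(formula)
    return sum(MASS_TABLE[el] * n for el, n in counts.items())


def _mass_of_mol(mol: Chem.Mol) -> float:
    total = 0.0
    charge = 0
    for atom in mol.GetAtoms():
        total += MASS_TABLE[atom.GetSymbol()]
        total += atom.GetTotalNumHs() * MASS_TABLE["H"]
        charge += atom.GetFormalCharge()
    return total - charge * ELECTRON_MASS


def fingerprints(structure: str | Chem.Mol) -> tuple[int, int]:
    """(path fingerprint, key fingerprint) as bit integers.

    The path fingerprint hashes linear fragments up to 7 bonds into 1024
    bits; the key fingerprint is the fixed MACCS substructure-key dictionary
    (167 bits). Both are deterministic functions of the molecular graph.
    """
    mol = mol_from_smiles(structure) if isinstance(structure, str) else structure
    path_fp = Chem.RDKFingerprint(mol, minPath=1, maxPath=7, fpSize=_PATH_FP_BITS)
    key_fp = MACCSkeys.GenMACCSKeys(mol)
    return _bv_to_int(path_fp), _bv_to_int(key_fp)


def _bv_to_int(bv) -> int:
    out = 0
    for bit in bv.GetOnBits():
        out |= 1 << bit
    return out


def tanimoto(a: int, b: int) -> float:
    union = (a | b).bit_count()
    if union == 0:
        return 1.0
    return (a & b).bit_count() / union


def compound_id(canonical_smiles: str) -> str:
    """'C' + lowercase hex SHA1 of the UTF-8 canonical SMILES bytes."""
    return "C" + hashlib.sha1(canonical_smiles.encode("utf-8")).hexdigest()


@dataclass
class Compound:
    """A registered molecule with identifiers, properties and provenance."""

    compound_id: str
    smiles: str
    inchikey: str
    formula: str
    exact_mass: float
    path_fingerprint: int
    key_fingerprint: int
    generation: int = 0
    mine_number: int = -1  # assigned at database finalization
    xrefs: list[tuple[str, str]] = field(default_factory=list)
    reactant_in: list[str] = field(default_factory=list)
    product_of: list[str] = field(default_factory=list)
    properties: dict[str, float] = field(default_factory=dict)

    def to_doc(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "mine_number": self.mine_number,
            "smiles": self.smiles,
            "inchikey": self.inchikey,
            "formula": self.formula,
            "exact_mass": round(self.exact_mass, 6),
            "path_fingerprint": format(self.path_fingerprint, "x"),
            "key_fingerprint": format(self.key_fingerprint, "x"),
            "generation": self.generation,
            "xrefs": [list(x) for x in self.xrefs],
            "reactant_in": list(self.reactant_in),
            "product_of": list(self.product_of),
            "properties": dict(self.properties),
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "Compound":
        return cls(
            compound_id=doc["compound_id"],
            mine_number=doc.get("mine_number", -1),
            smiles=doc["smiles"],
            inchikey=doc["inchikey"],
            formula=doc["formula"],
            exact_mass=float(doc["exact_mass"]),
            path_fingerprint=int(doc["path_fingerprint"], 16),
            key_fingerprint=int(doc["key_fingerprint"], 16),
            generation=int(doc.get("generation", 0)),
            xrefs=[tuple(x) for x in doc.get("xrefs", [])],
            reactant_in=list(doc.get("reactant_in", [])),
            product_of=list(doc.get("product_of", [])),
            properties=dict(doc.get("properties", {})),
        )


def register_compound(smiles: str, generation: int = 0) -> Compound:
    """Canonicalize a structure and build its full Compound record.

    The record is a deterministic function of the molecular graph (except
    ``mine_number``, assigned once at finalization).
    """
    canonical = canonicalize(smiles)
    mol = mol_from_smiles(canonical)
    path_fp, key_fp = fingerprints(mol)
    return Compound(
        compound_id=compound_id(canonical),
        smiles=canonical,
        inchikey=make_inchikey(mol),
        formula=molecular_formula(mol),
        exact_mass=_mass_of_mol(mol),
        path_fingerprint=path_fp,
        key_fingerprint=key_fp,
        generation=generation,
    )
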