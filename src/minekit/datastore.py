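"""Persistence and structure-based queries over an expanded database.

The default backend is an embedded single-directory store: JSON-lines
collections for compounds and reactions plus a metadata header. SDF (V2000)
export carries the registry fields as data items so a database can be
exchanged with any chemistry toolkit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from minekit.expansion import Reaction
from minekit.registry import Compound, mol_from_smiles, tanimoto

log = logging.getLogger(__name__)

FORMAT_VERSION = "1"

SDF_FIELDS = ("MINE_ID", "COMPOUND_ID", "FORMULA", "EXACT_MASS", "INCHIKEY", "GENERATION")


class IntegrityError(ValueError):
    """A stored bundle is unreadable, inconsistent, or version-mismatched."""


@dataclass
class DatabaseBundle:
    """Compound and reaction collections plus build metadata."""

    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Assert referential integrity in both directions."""
        for rid, rxn in self.reactions.items():
            for _, cid in rxn.reactants:
                if cid not in self.compounds:
                    raise IntegrityError(f"reaction {rid} references missing compound {cid}")
                if rid not in self.compounds[cid].reactant_in:
                    raise IntegrityError(f"compound {cid} missing reactant_in link to {rid}")
            for _, cid in rxn.products:
                if cid not in self.compounds:
                    raise IntegrityError(f"reaction {rid} references missing compound {cid}")
                if rid not in self.compounds[cid].product_of:
                    raise IntegrityError(f"compound {cid} missing product_of link to {rid}")
        for cid, comp in self.compounds.items():
            for rid in comp.reactant_in + comp.product_of:
                if rid not in self.reactions:
                    raise IntegrityError(f"compound {cid} references missing reaction {rid}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatabaseBundle):
            return NotImplemented
        return (
            {k: v.to_doc() for k, v in self.compounds.items()}
            == {k: v.to_doc() for k, v in other.compounds.items()}
            and {k: v.to_doc() for k, v in self.reactions.items()}
            == {k: v.to_doc() for k, v in other.reactions.items()}
            and self.metadata == other.metadata
        )


def save(bundle: DatabaseBundle, path: str | Path) -> None:
    """Write a bundle to a directory: compounds.jsonl, reactions.jsonl, metadata.json.

    Records are written in ascending id order, so two identical bundles
    serialize byte-identically.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(bundle.metadata)
    meta["format_version"] = FORMAT_VERSION
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    with (path / "compounds.jsonl").open("w") as fh:
        for cid in sorted(bundle.compounds):
            fh.write(json.dumps(bundle.compounds[cid].to_doc(), sort_keys=True) + "\n")
    with (path / "reactions.jsonl").open("w") as fh:
        for rid in sorted(bundle.reactions):
            fh.write(json.dumps(bundle.reactions[rid].to_doc(), sort_keys=True) + "\n")


def load(path: str | Path) -> DatabaseBundle:
    """Read a bundle back; any corruption yields IntegrityError, never a partial bundle."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"no database bundle at {path}")
    try:
        meta = json.loads((path / "metadata.json").read_text())
    except FileNotFoundError:
        raise
    except (json.JSONDecodeError, OSError) as exc:
        raise IntegrityError(f"unreadable metadata in {path}: {exc}") from exc
    version = meta.pop("format_version", None)
    if version != FORMAT_VERSION:
        raise IntegrityError(
            f"format version mismatch: file has {version!r}, reader expects {FORMAT_VERSION!r}"
        )
    bundle = DatabaseBundle(metadata=meta)
    try:
        with (path / "compounds.jsonl").open() as fh:
            for line in fh:
                comp = Compound.from_doc(json.loads(line))
                bundle.compounds[comp.compound_id] = comp
        with (path / "reactions.jsonl").open() as fh:
            for line in fh:
                rxn = Reaction.from_doc(json.loads(line))
                bundle.reactions[rxn.reaction_id] = rxn
    except (json.JSONDecodeError, KeyError, ValueError, OSError) as exc:
        raise IntegrityError(f"corrupted bundle at {path}: {exc}") from exc
    bundle.validate()
    return bundle


def substructure_search(bundle: DatabaseBundle, query: str) -> list[str]:
    """Compound ids whose structure contains the SMARTS (or SMILES) query subgraph."""
    pattern = Chem.MolFromSmarts(query)
    if pattern is None or pattern.GetNumAtoms() == 0:
        raise ValueError(f"invalid substructure query: {query!r}")
    hits = []
    for cid in sorted(bundle.compounds):
        mol = Chem.MolFromSmiles(bundle.compounds[cid].smiles)
        if mol is not None and mol.HasSubstructMatch(pattern):
            hits.append(cid)
    return hits


def similarity_search(
    bundle: DatabaseBundle, query: str, threshold: float
) -> list[tuple[str, float]]:
    """Tanimoto similarity on path fingerprints, descending, ties by compound_id."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    from minekit.registry import fingerprints

    query_fp, _ = fingerprints(mol_from_smiles(query))
    scored = []
    for cid in sorted(bundle.compounds):
        score = tanimoto(query_fp, bundle.compounds[cid].path_fingerprint)
        if score >= threshold:
            scored.append((cid, score))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def export_sdf(bundle: DatabaseBundle, path: str | Path) -> None:
    """One V2000 SDF record per compound with the registry data fields."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for cid in sorted(bundle.compounds):
            comp = bundle.compounds[cid]
            mol = Chem.MolFromSmiles(comp.smiles)
            if mol is None:  # pragma: no cover - registered SMILES always parse
                log.warning("skipping unwritable compound %s", cid)
                continue
            mol.SetProp("_Name", comp.compound_id)
            mol.SetProp("MINE_ID", str(comp.mine_number))
            mol.SetProp("COMPOUND_ID", comp.compound_id)
            mol.SetProp("FORMULA", comp.formula)
            mol.SetProp("EXACT_MASS", f"{comp.exact_mass:.4f}")
            mol.SetProp("INCHIKEY", comp.inchikey)
            mol.SetProp("GENERATION", str(comp.generation))
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[str]:
    """SMILES list from an SDF file (seed-input reader)."""
    supplier = Chem.SDMolSupplier(str(path))
    out = []
    for mol in supplier:
        if mol is not None:
            out.append(Chem.MolToSmiles(mol))
    return out


def export_json(bundle: DatabaseBundle, path: str | Path) -> None:
    """Single-file JSON dump mirroring the document schema verbatim."""
    doc = {
        "metadata": {**bundle.metadata, "format_version": FORMAT_VERSION},
        "compounds": [bundle.compounds[c].to_doc() for c in sorted(bundle.compounds)],
        "reactions": [bundle.reactions[r].to_doc() for r in sorted(bundle.reactions)],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
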