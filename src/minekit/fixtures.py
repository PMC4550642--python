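"""Self-contained demo inputs: seed metabolites, demo rules, peak lists.

Everything any workflow needs can be generated here with no downloads and
no randomness: a seed set of ~30 common metabolites (sugars, amino acids,
organic acids, one phosphoethanolamine lipid, pentane-2,4-dione), a demo
rule set of 12 generalized transformations spanning oxidoreductase,
transferase, hydrolase and lyase chemistry, and a peak list whose m/z
values are theoretical adduct masses of expansion products perturbed by
fixed offsets of at most 1 mDa. Regeneration is byte-identical.
"""

from __future__ import annotations

import csv
from pathlib import Path

from minekit.datastore import DatabaseBundle
from minekit.expansion import ExpansionConfig, expand, finalize
from minekit.masssearch import adduct_table
from minekit.registry import register_compound

# PE(16:0/16:1): 1-palmitoyl-2-palmitoleoyl-glycero-3-phosphoethanolamine,
# C37H72NO8P — the worked annotation example.
PE_16_0_16_1 = (
    "CCCCCCCCCCCCCCCC(=O)OC[C@H](COP(=O)(O)OCCN)OC(=O)CCCCCCC/C=C\\CCCCCC"
)

DEMO_SEEDS: list[tuple[str, str]] = [
    ("OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O", "D-glucose"),
    ("OCC(=O)[C@@H](O)[C@H](O)[C@H](O)CO", "D-fructose_open"),
    ("OC[C@H]1OC(O)[C@H](O)[C@H](O)[C@H]1O", "D-galactose"),
    ("OC[C@H]1OC(O)[C@H](O)[C@@H]1O", "D-ribose"),
    ("NCC(=O)O", "glycine"),
    ("C[C@H](N)C(=O)O", "L-alanine"),
    ("OC[C@H](N)C(=O)O", "L-serine"),
    ("N[C@@H](CC(=O)O)C(=O)O", "L-aspartate"),
    ("N[C@@H](CCC(=O)O)C(=O)O", "L-glutamate"),
    ("N[C@@H](Cc1ccccc1)C(=O)O", "L-phenylalanine"),
    ("N[C@@H](Cc1ccc(O)cc1)C(=O)O", "L-tyrosine"),
    ("N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O", "L-tryptophan"),
    ("CC(C)C[C@H](N)C(=O)O", "L-leucine"),
    ("NCCCC[C@H](N)C(=O)O", "L-lysine"),
    ("CSCC[C@H](N)C(=O)O", "L-methionine"),
    ("CC(=O)C(=O)O", "pyruvate"),
    ("CC(O)C(=O)O", "lactate"),
    ("OC(=O)CC(O)(CC(=O)O)C(=O)O", "citrate"),
    ("OC(=O)CCC(=O)O", "succinate"),
    ("OC(=O)/C=C/C(=O)O", "fumarate"),
    ("OC(=O)CC(O)C(=O)O", "malate"),
    ("CC(=O)O", "acetate"),
    ("CCO", "ethanol"),
    ("OCC(O)CO", "glycerol"),
    ("NCCO", "ethanolamine"),
    ("NCCc1ccc(O)c(O)c1", "dopamine"),
    ("Oc1ccccc1C(=O)O", "salicylate"),
    ("CCOC(C)=O", "ethyl_acetate"),
    ("C=CC(=O)O", "acrylate"),
    ("CC(O)CC=O", "3-hydroxybutanal"),
    ("CC(=O)NC", "N-methylacetamide"),
    (PE_16_0_16_1, "PE(16:0/16:1)"),
    ("CC(=O)CC(C)=O", "pentane-2,4-dione"),
]

_ATP = "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O"
_ADP = "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)O)C(O)C1O"
# name, ec_class, transform (SMIRKS), cofactor_reactants, cofactor_products, bidirectional
DEMO_RULES: list[tuple[str, str, str, list[str], list[str], int]] = [
    (
        "alcohol_oxidation", "1.1.3",
        "[CX4H2:1][OX2H1:2]>>[CX3H1:1]=[OX1:2]",
        ["O=O"], ["OO"], 0,
    ),
    (
        "aldehyde_oxidation", "1.2.3",
        "[CX3H1:1]=[OX1:2]>>[CX3H0:1](=[OX1:2])[OX2H1]",
        ["O=O", "O"], ["OO"], 0,
    ),
    (
        "phenol_methylation", "2.1.1",
        "[c:1][OX2H1:2]>>[c:1][OX2H0:2][CH3]",
        ["CSC"], ["CS"], 0,
    ),
    (
        "transamination", "2.6.1",
        "[CX3:1](=[OX1])[CX3:2](=[OX1:3])[OX2H1:4]"
        ">>[CX4H1:1]([NX3H2])[CX3:2](=[OX1:3])[OX2H1:4]",
        ["NC(CCC(=O)O)C(=O)O"], ["O=C(CCC(=O)O)C(=O)O"], 1,
    ),
    (
        "alcohol_phosphorylation", "2.7.1",
        "[CX4H2:1][OX2H1:2]>>[CX4H2:1][OX2H0:2]P(=O)(O)O",
        [_ATP], [_ADP], 0,
    ),
    (
        "ester_hydrolysis", "3.1.1",
        "[CX3:1](=[OX1:2])[OX2:3][#6:4]>>[CX3:1](=[OX1:2])[OX2H1].[OX2H1:3][#6:4]",
        ["O"], [], 0,
    ),
    (
        "phosphoester_hydrolysis", "3.1.3",
        "[PX4:1](=[OX1:2])([OX2:5])([OX2:6])[OX2:3][#6:4]"
        ">>[PX4:1](=[OX1:2])([OX2:5])([OX2:6])[OX2H1].[OX2H1:3][#6:4]",
        ["O"], [], 0,
    ),
    (
        "amide_hydrolysis", "3.5.1",
        "[CX3:1](=[OX1:2])[NX3H1:3]>>[CX3:1](=[OX1:2])[OX2H1].[NX3H2:3]",
        ["O"], [], 0,
    ),
    (
        "diketone_hydrolysis", "3.7.1",
        "[CX3:1](=[OX1:2])[CX4H2:3][CX3:4](=[OX1:5])"
        ">>[CX3:1](=[OX1:2])[OX2H1].[CX4H3:3][CX3:4]=[OX1:5]",
        ["O"], [], 0,
    ),
    (
        "decarboxylation", "4.1.1",
        "[#6:1][CX3](=[OX1])[OX2H1]>>[#6:1]",
        [], ["O=C=O"], 0,
    ),
    (
        "retro_aldol", "4.1.2",
        "[CX4:1]([OX2H1:2])[CX4H2:3][CX3H1:4]=[OX1:5]"
        ">>[CX3:1]=[OX2:2].[CX4H3:3][CX3H1:4]=[OX1:5]",
        [], [], 1,
    ),
    (
        "alkene_hydration", "4.2.1",
        "[CX3H2:1]=[CX3H1:2]>>[CX4H3:1][CX4H1:2][OX2H1]",
        ["O"], [], 1,
    ),
]

# Fixed, cycling mass perturbations in Da (all at most 1 mDa) standing in
# for instrument error; deliberately constants, not samples.
_PEAK_OFFSETS = [0.0003, -0.0006, 0.0009, -0.0002, 0.0007, -0.0009, 0.0001, -0.0004]

# Observed precursor m/z of the PE(16:0/16:1) [M+H]+ ion in the worked
# annotation example; about 3 mDa above the theoretical value.
PE_OBSERVED_MZ = 690.5099


def write_rule_file(path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("# demo generalized reaction rules, third-level EC generality\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["name", "ec_class", "transform", "cofactor_reactants", "cofactor_products", "bidirectional"]
        )
        for name, ec, transform, cr, cp, bidir in DEMO_RULES:
            writer.writerow([name, ec, transform, ";".join(cr), ";".join(cp), bidir])


def write_seed_file(path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for smiles, name in DEMO_SEEDS:
            fh.write(f"{smiles}\t{name}\n")


def fixture_bundle(generations: int = 1) -> DatabaseBundle:
    """Expand the demo seeds with the demo rules into a DatabaseBundle."""
    from minekit.rules import ReactionRule

    rules = [
        ReactionRule(name, ec, transform, list(cr), list(cp), bool(bidir))
        for name, ec, transform, cr, cp, bidir in DEMO_RULES
    ]
    compounds, reactions, _ = expand(
        [s for s, _ in DEMO_SEEDS], rules, ExpansionConfig(generations=generations)
    )
    return DatabaseBundle(
        compounds=compounds,
        reactions=reactions,
        metadata={"seed_source": "demo_seeds", "rule_set": "demo_rules",
                  "generations": generations},
    )


def make_peaklist(bundle: DatabaseBundle, n_peaks: int = 20) -> list[tuple[str, float, str]]:
    """(peak_id, mz, polarity) rows built from known expansion products.

    Each row is the theoretical adduct m/z of a generation-1 compound
    shifted by a fixed sub-mDa offset, so every peak has a known true
    annotation. The final row is the observed PE(16:0/16:1) precursor ion.
    """
    adducts = adduct_table()
    products = sorted(
        cid for cid, c in bundle.compounds.items() if c.generation >= 1
    )[:n_peaks]
    rows = []
    for i, cid in enumerate(products):
        comp = bundle.compounds[cid]
        adduct = adducts[i % len(adducts)]
        mz = adduct.mz(comp.exact_mass) + _PEAK_OFFSETS[i % len(_PEAK_OFFSETS)]
        rows.append((f"peak{i + 1:03d}", round(mz, 4), adduct.polarity))
    rows.append(("pe_precursor", PE_OBSERVED_MZ, "+"))
    return rows


def make_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the full demo input set: seeds, rules, peaks, organism list.

    Fully deterministic — regenerating produces byte-identical files.
    Returns the path of each written file by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "seeds": outdir / "seeds.smi",
        "rules": outdir / "rules.tsv",
        "peaks": outdir / "peaks.csv",
        "organism": outdir / "organism_compounds.txt",
    }
    write_seed_file(paths["seeds"])
    write_rule_file(paths["rules"])

    bundle = fixture_bundle(generations=1)
    with paths["peaks"].open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["peak_id", "mz", "polarity"])
        for row in make_peaklist(bundle):
            writer.writerow(row)

    # organism subset: every third seed compound, as an id list
    seed_cids = sorted(c.compound_id for c in bundle.compounds.values() if c.generation == 0)
    with paths["organism"].open("w") as fh:
        for cid in seed_cids[::3]:
            fh.write(cid + "\n")
    return paths


_SERIES_GROUPS = ["O", "N", "C(=O)O", "S", "OC", "C#N", "Cl", "Br", "C(N)=O", "OP(=O)(O)O"]


def synthetic_bundle(n_compounds: int) -> DatabaseBundle:
    """A bundle of ``n_compounds`` distinct homologous-series molecules.

    Alkyl chains of increasing length crossed with ten terminal functional
    groups — synthetic scale-test data for search benchmarks, not real
    metabolites.
    """
    compounds = {}
    k = 1
    while len(compounds) < n_compounds:
        for group in _SERIES_GROUPS:
            if len(compounds) >= n_compounds:
                break
            comp = register_compound("C" * k + group)
            compounds[comp.compound_id] = comp
        k += 1
    finalize(compounds)
    return DatabaseBundle(compounds=compounds, metadata={"seed_source": "synthetic_series"})
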