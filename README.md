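# minekit

In silico metabolic network expansion and accurate-mass annotation for
untargeted metabolomics.

Untargeted LC–MS experiments routinely detect thousands of features that no
curated metabolite database can explain, because many cellular metabolites
arise from undocumented promiscuous side-activities of known enzymes.
`minekit` addresses this by *expanding* a seed set of known metabolites:
generalized reaction rules — reactive-site motifs with their bond changes,
curated at third-level EC generality — are applied to every seed compound,
and the predicted products are registered as a searchable compound database
alongside stoichiometric, element-balanced reaction records. Accurate-mass
peak lists are then annotated against this expanded database by adduct-aware
tolerance search.

## What it does

1. **Curation** — seed structures are filtered (R-group/wildcard structures,
   carbon-free inorganics and disconnected fragments are removed, duplicates
   collapsed by Standard InChIKey) and normalized to canonical valences and
   charge placement.
2. **Expansion** — every rule is applied to every eligible compound for one
   or more generations. A rule is a mapped SMIRKS transform plus explicit
   cofactor molecules; each application is checked for element conservation.
   Compounds get deterministic ids (`'C'` + SHA1 of the canonical SMILES),
   reactions get `'R'` + SHA1 of the sorted reaction string, so a reaction
   and its reverse share one id and two runs of the same inputs are
   byte-identical.
3. **Annotation** — a peak's observed m/z is matched to every (compound,
   adduct) pair of the right polarity within a tolerance (mDa or ppm),
   using the standard adduct set [M+H]+, [M+Na]+, [M+]+, [M−H]−,
   [M+CH3COO]−. For a neutral monoisotopic mass *M* and adduct shift
   *δ* (electron-mass corrected), the theoretical m/z of a singly charged
   ion is *m/z = M + δ*; a hit requires |observed − theoretical| ≤ tol.
   Candidates can be filtered by logP / Kováts retention-index annotations
   and flagged against an organism-specific compound list.

## Worked example

Everything runs from generated demo inputs — no downloads:

```bash
minekit fixtures --out fx
minekit expand --seeds fx/seeds.smi --rules fx/rules.tsv --generations 1 --out db
minekit annotate --db db --peaks fx/peaks.csv --tolerance-mda 2 \
    --organism-list fx/organism_compounds.txt --out results.csv
minekit stats --db db
```

which logs

```
INFO minekit: expanded to 92 compounds, 57 reactions -> db
INFO minekit: annotated 20/21 peaks (37 candidate hits) -> results.csv
{
  "seed_compounds": 43,
  "final_compounds": 92,
  "fold_increase": 2,
  "pct_in_external": 0.0
}
```

The 33 demo seeds (plus auto-registered cofactors such as water and O2 —
43 generation-0 entries) expand to 92 compounds and 57 element-balanced
reactions under the 12 demo rules. 20 of the 21 peaks are annotated at
2 mDa; the remaining one is an *observed* lipid precursor ion at
m/z 690.5099 (+). Its annotation is the package's worked example: the
phosphoethanolamine lipid PE(16:0/16:1), C37H72NO8P, has theoretical
[M+H]+ m/z 690.5068, i.e. 3.07 mDa below the observed value — found as a
candidate when searching at 5 mDa:

```bash
minekit annotate --db db --peaks fx/peaks.csv --tolerance-mda 5 --out results5.csv
# INFO minekit: annotated 21/21 peaks (38 candidate hits) -> results5.csv
```

In Python, the same pipeline is three calls:

```python
from minekit import expand, parse_rule_file, search_peaks, SearchConfig, Peak
from minekit.datastore import DatabaseBundle

compounds, reactions, reports = expand(seed_smiles, parse_rule_file("rules.tsv"))
bundle = DatabaseBundle(compounds=compounds, reactions=reactions)
hits = search_peaks(bundle, [Peak("p1", 690.5099, "+")], SearchConfig(tolerance_mda=5.0))
```

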