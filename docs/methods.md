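# Methods

## The model

`minekit` treats enzyme promiscuity as a graph-rewriting process on
molecular structures. A *reaction rule* is a generalized operator: a
substructure pattern identifying the reactive-site motif, a mapped
product template encoding which bonds break and form, and an explicit list
of cofactor molecules consumed and produced. Rules are organized at
third-level EC generality (e.g. 3.7.1, hydrolases acting on C–C bonds),
the level at which one operator covers a family of related enzymatic
transformations rather than a single documented reaction.

Expansion applies every rule to every eligible compound. Generation 0 is
the curated seed set; generation *g* compounds are the curated, novel
products of applying all rules to the compounds first registered in
generation *g − 1*. The default is a single generation, the regime in
which false-positive structures stay closest to documented metabolism;
deeper expansions are supported up to a configurable cap (default 5) since
the product set grows combinatorially. No likeliness, thermodynamic or
kinetic scoring is applied: the expansion is purely constitutive, and
ranking is left to downstream annotation context.

### Assumptions

- Substrates are small neutral organic molecules; the curation stage
  guarantees this for everything a rule sees.
- A rule application is legitimate only if element-balanced: the element
  multiset of substrate + cofactor reactants must equal that of products +
  cofactor products. Applications violating this (e.g. through a pattern
  matching an unanticipated environment) are dropped and logged, never
  silently stored.
- Stereocenters at reacting atoms are emitted without stereo designation;
  untouched stereocenters are preserved.
- One substrate per rule application. Condensations are encoded in the
  retro direction or with the partner as a cofactor.

## Identity and determinism

Compound identity is the Standard InChIKey (full 27 characters) for
deduplication and the SHA1 hash of the RDKit canonical isomeric SMILES
(prefixed `C`) as the primary key. The human-readable serial
(`mine_number`) is assigned at finalization in ascending compound-id
order, making it independent of discovery order. Reactions are written as
`"(coef) cid"` tokens sorted by compound id within each side, the two side
strings ordered lexicographically and joined by `" <=> "`; the id is `R` +
SHA1 of that string, so a reaction and its reverse — as produced by a
bidirectional rule — collapse to one record. Compounds appearing on both
sides of a candidate reaction are cancelled at min count; reactions with
an empty side after cancellation are not stored.

These choices make the whole pipeline a pure function of its inputs: the
test suite asserts byte-identical database exports across runs and
invariance of the id sets under seed-order permutation.

## Curation policy

- *Generalized* = any wildcard/query atom (`*`, R-group placeholder). Such
  structures cannot be assigned an accurate mass and are removed.
- *Inorganic* = carbon-free. CO2, carbonate and cyanide are retained.
- *Disconnected* = more than one connected component; removed rather than
  salt-stripped. Filters are applied in that order, so a carbon-free salt
  counts as inorganic, not disconnected.
- Standardization applies RDKit's normalization table (nitro, N-oxide,
  azide and similar groups rewritten in canonical charge-separated form)
  followed by proton-based neutralization of standard ionizable groups.
  Tautomers are *not* canonicalized globally: aggressive tautomer merging
  would conflate distinct database entries; only the local normalization
  table is applied, and distinct tautomers keep distinct records.
- Deduplication keeps, per full InChIKey, the compound with the lowest
  compound id — an arbitrary but deterministic tie-break.
- Inorganic *reaction products* (e.g. orthophosphate released by a
  phosphatase rule) are registered rather than filtered, as are cofactors
  (generation-0 entries): dropping either would leave reaction records
  referencing missing compounds. A config toggle restores strict filtering.

## Masses, adducts and search

Monoisotopic masses are sums of most-abundant-isotope atomic masses
(RDKit's periodic table) with an electron-mass correction of
±0.00054858 Da per unit of net charge. The adduct table carries signed,
electron-corrected shifts:

| adduct | shift (Da) |
|---|---|
| [M+H]+ | +1.007276 |
| [M+Na]+ | +22.989218 |
| [M+]+ | −0.000549 |
| [M−H]− | −1.007276 |
| [M+CH3COO]− | +59.013853 |

The radical cation [M+]+ is treated as M minus one electron (not M
exactly); all table adducts are singly charged with multiplicity 1, so
m/z = M + shift.

Search tolerance is expressed in mDa (matching accurate-mass instrument
conventions; 2 mDa is a typical high-resolution window, 5 mDa a permissive
one) or alternatively in ppm — exactly one of the two. Candidates are
found by binary search over a mass-sorted compound array, one window per
adduct; a brute-force (compound × adduct) scan serves as the independent
oracle in the tests. Hits are ordered by |error| rounded to 10⁻⁶ mDa,
ties broken by compound id — the rounding makes exact-mass isomers true
ties instead of leaving their order to floating-point summation noise.

Optional per-compound annotations (`logp`, `kovats_ri` in
`Compound.properties`) support range filters; these values come from
pluggable property providers, since no general-purpose estimator ships
with the package. Compounds lacking an annotation pass range filters by
default (configurable) to avoid silently discarding candidates. Organism
highlighting consumes a plain compound-id list.

## The demo rule set and fixture generator

The 198-rule operator library such an expansion would use in production is
not distributable, so the package bundles 12 demonstration rules spanning
oxidoreductase (alcohol and aldehyde oxidation with an O2/H2O2 couple),
transferase (phenol methylation, transamination against the
glutamate/2-oxoglutarate pair, alcohol phosphorylation against ATP/ADP),
hydrolase (ester, phosphoester, amide and 1,3-diketone hydrolysis) and
lyase (decarboxylation, retro-aldol cleavage, alkene hydration) chemistry.
The methyl-donor couple for phenol methylation is written as dimethyl
sulfide/methanethiol — a minimal neutral pair carrying one CH2 — to keep
the demo reaction element-balanced without the charge bookkeeping of the
physiological sulfonium donor. Every rule is validated at load time
(pattern parses; mapped atoms conserved) and every application is checked
for element balance at run time; the TSV rule format accepts user rule
sets of any size.

The fixture generator emulates a metabolomics study at desk scale: 33
seed metabolites (sugars, amino acids, organic acids, amines, one
phosphoethanolamine lipid, pentane-2,4-dione), and a peak list whose m/z
values are theoretical adduct masses of expansion products shifted by
fixed offsets of at most 1 mDa — deliberately constants, not samples, so
regeneration is byte-identical. One additional peak is an observed lipid
precursor ion (m/z 690.5099, positive mode) lying ~3 mDa from its
theoretical [M+H]+ value, which is why the demo annotates 20/21 peaks at
2 mDa and 21/21 at 5 mDa. What the fixtures do **not** emulate: real
instrument noise distributions, isotopic envelopes, in-source fragments,
retention behavior, or the scale (10⁵–10⁶ compounds) of a production
expansion — passing tests demonstrate correctness of the machinery, not
annotation accuracy on real data.

The scale tests use a separate synthetic bundle of 1,000
homologous-series molecules (alkyl chains × ten terminal groups), chosen
because the series contains many exact-mass isomers and adjacent masses —
the hard cases for windowed search.

## Numerical choices

- Mass arithmetic in float64; formula/structure mass consistency asserted
  to 1e-4 Da; adduct shifts validated to 1e-5 Da.
- Path fingerprints: RDKit linear-path hashing, paths of 1–7 bonds, 1024
  bits. Key fingerprints: the fixed 167-key MACCS dictionary. Tanimoto
  similarity on the path fingerprint drives similarity search.
- SDF export writes V2000 with data fields MINE_ID, COMPOUND_ID, FORMULA,
  EXACT_MASS (4 decimals), INCHIKEY, GENERATION.
- Degenerate inputs: empty seed sets, empty rule files, header-only TSVs,
  empty bundles and zero-generation expansions are all defined no-ops.

## Known limitations

- Rule applications fire independently at overlapping sites; no site
  exclusion or kinetic preference is modelled.
- Single-substrate operators only; true bimolecular condensations between
  two database compounds are out of scope.
- The embedded JSON-lines store loads the full database into memory;
  production-scale deployments would put a server-backed document store
  behind the same `save`/`load` interface.
- No MS/MS spectral matching, isotopic-pattern scoring or retention-index
  prediction; these are annotation layers the search results feed into.
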