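# Packaged data

- `reference_pharmacology.csv` — literature-reported pharmacology for eleven
  melatonin-receptor screening hits plus melatonin itself: pKi, pEC50, EC50
  (nM), Emax (% of melatonin), ligand efficiency (kcal/mol per heavy atom),
  MT2/MT1 selectivity fold and Tanimoto novelty distance, per receptor
  subtype. Censored entries are kept verbatim as strings (`ND`, `>30000`,
  `>1000.0`). This table is input data for the summary/metrics stages and the
  regression tests; nothing in it is produced by this package.
- `library_templates.csv` — synthetic template molecules with hand-annotated
  filter outcomes (`expect_pass`, `fail_reason`), used by the library
  generator and as filter-funnel ground truth. Annotations were computed with
  this package's own property/filter routines and are frozen here.
- `reactive_patterns.smarts` — the package's declared reactive-group SMARTS
  list used by library preparation (see file header).
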