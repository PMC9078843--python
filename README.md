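# deltascan

Discovery, annotation and cohort statistics for residue-localized
delta-mass variants from open-search (wildcard) proteomics.

Open searches report, for each peptide-spectrum match (PSM), a *delta
mass*: the difference between the observed precursor mass and the coding
peptide. `deltascan` turns tables of such PSMs into annotated variant
peaks and cohort-level statistics:

1. **filter** — keep confident PSMs (Score ≥ 300, Delta Mod Score ≥ 10,
   2D FDR ≤ 0.01 by default), restricted to a target residue (default
   tryptophan) and a delta range (default −150 to 500 Da, zero excluded).
2. **cluster** — partition delta masses into 1-Da windows, fit Gaussian
   mixtures per window with BIC model selection, keep components with
   enough support, a tight spread, and a good histogram fit (R²), and
   re-unify peaks split by window boundaries.
3. **annotate** — match each peak center against a curated database of
   preknown variants (error < 10 mDa), then explain the rest as cascade
   reactions (base entry + secondary Unimod-style modification), rank
   candidates by combined mass error, and classify every peak into
   Reactive species / AA substitution / Chemical derivative / Artefact /
   Unknown.
4. **summarize / diff / survive** — per-class frequency accounting,
   site-level spectral-count aggregation, paired tumor-vs-NAT
   differential levels (Wilcoxon + Benjamini–Hochberg), Spearman
   correlation between modification profiles, and optimal-cutpoint
   log-rank survival analysis (with a permutation-adjusted p that
   accounts for cutpoint selection).

A `synthetic` module generates PSM tables with planted delta-mass peaks,
uniform background, paired cohort designs and survival metadata, so the
whole pipeline is testable without any external data.

## Command line

```sh
deltascan simulate sim.yaml                 # synthetic PSM/clinical tables
deltascan filter psms.tsv -o kept.tsv
deltascan cluster kept.tsv -o clusters.tsv --members-out members.tsv
deltascan annotate clusters.tsv -o annotated.tsv --report report.json
deltascan summarize annotated.tsv -o summary.tsv
deltascan diff members.tsv -o diff.tsv
deltascan survive clinical.tsv --permutations 200 --seed 1
```

An example simulate config:

```yaml
peaks:
  - {true_delta: 15.9949, n_psms: 400, mass_sd: 0.002}
cohort: {n_pairs: 3, seed: 5, noise_fraction: 0.1}
psm_out: psms.tsv
```

## File formats

All tables are UTF-8 TSV with a header row.

* **PSM table**: `spectrum_id peptide protein site residue delta_mass
  score delta_mod_score fdr_2d sample_id group` (group is `tumor`/`NAT`;
  site is 1-based over the full UniProt sequence, initiator Met
  included).
* **Modification DB**: `name composition class plausible source`;
  compositions use a Unimod-like signed dialect (`O`, `O(2)`,
  `C(-1)O`, `H(11)C(6)NO(3)S(2)`).
* **Clinical table**: `patient_id time event marker`.

Two databases ship with the package (`src/deltascan/data/`): a 62-entry
curated list of preknown tryptophan variants and a larger Unimod-like
table of secondary modifications, plus a 25-peak published summary table
used by the acceptance report.

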