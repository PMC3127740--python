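# mirasym

Analysis toolkit for miRNA/miRNA* strand-asymmetry informatics on small-RNA
sequencing libraries:

* **annotation_io** — pre-miRNA hairpin FASTA + mature-arm coordinates
  (miRBase-dialect GFF3 or 6-column TSV) and tag-count libraries
  (2-column TSV or FASTA with `_xN` header suffixes); library pooling.
* **quantify** — exact-substring isoform profiling onto hairpin arms,
  miRNA/miRNA* strand designation by pooled abundance (5p tie-break,
  annotation override available), the ≥100-read expression filter and
  asymmetry binning (highly ≥10, moderately [2, 10), quasisymmetric [1, 2)).
* **composition** — abundance-weighted 5′-nucleotide frequencies with a
  resampling null (100 random sets drawn from nt 1–18, one draw per
  hairpin-strand per set), empirical and Gaussian-tail P values, and the
  flanking-U profile (offsets −10..+10 around miRNA nt 1 with an empirical
  95% background interval).
* **duplex_structure** — exact inside–outside partition function over all
  non-crossing intermolecular pairings (Watson–Crick + G:U) under a
  documented additive score, per-nucleotide pairing probabilities, and
  binary paired/unpaired calls at the strict >0.5 threshold.  An external
  engine (ViennaRNA bindings or an `(i, j, p)` probability TSV) plugs into
  the same matrix contract, with fallback to the builtin engine.
* **covariation** — the 144-feature duplex representation (2 strands × 2
  anchors × 18 positions × {nucleotide identity, pairing status}) and a
  per-feature Fisher's exact test against miRNA nt-1 identity (exact 2×2,
  exact r×c enumeration below a configurable table-space cap, Patefield
  margin-preserving Monte Carlo above it).
* **synthetic_data** — cohort generator with controllable 5′-nt
  distributions, asymmetry and depth laws, isoform jitter and an injectable
  nt1→feature dependency; emits the exact formats `annotation_io` reads
  plus a truth ledger, bit-reproducibly per seed.
* **cli/pipeline** — subcommands `simulate`, `quantify`, `composition`,
  `structure`, `covariation`, `all` sharing one flat YAML config; TSV
  reports, a JSON run manifest, and optional PNG plots.

## Quick start

Everything runs offline from simulated data:

```sh
mirasym simulate --n-hairpins 100 --seed 1 --mirna-u-prob 0.79 --outdir sim
mirasym all \
    --hairpin-fasta sim/hairpins.fa \
    --mature-coords sim/arms.tsv \
    --tag-counts sim/reads.tsv \
    --outdir out --seed 1 --plot
```

`out/` then contains `duplexes.tsv`, `composition.tsv`, `structure.tsv`,
`covariation.tsv` (144 rows, ordered for plotting), `flanking.tsv` and
`manifest.json`.  Reruns with the same config and seed are byte-identical.

A YAML config may replace or complement the flags (flags win):

```yaml
min_reads: 100
n_sets: 100
window_start: 1
window_end: 18
pairing_threshold: 0.5
seed: 1
```

Real libraries are supplied the same way: hairpin FASTA, mature coordinates
(GFF3 with `miRNA` rows carrying `ID`/`Derives_from`, or TSV), and one
`--tag-counts` file per library (they are pooled tag-wise).

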