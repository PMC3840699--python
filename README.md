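# trflpkit

In-silico T-RFLP community fingerprinting and transect community analysis:
a reusable pipeline for studying how prokaryotic community composition is
structured by water masses along a deep-ocean transect, and whether it
changes gradually along a water mass's flow path.

The package covers:

- **`trflpkit.simulate`** — a synthetic transect generator: depth-stratified
  communities tied to water-mass groups, per-layer environmental envelopes,
  configurable fractions of ubiquitous / group-unique OTUs, and a controlled
  along-path community turnover confined to one water mass. OTU reference
  sequences are generated primer-flanked with distinct, resolvable forward
  terminal-restriction fragments.
- **`trflpkit.trflp`** — in-silico PCR (exact IUPAC primer matching) and
  restriction digestion (HhaI `GCG^C` by default), electropherogram peak
  profiles with co-migration and multiplicative noise, and binning /
  standardization into a fingerprint matrix (rows sum to 1).
- **`trflpkit.diversity`** — p-distance, OTU clustering at a fractional
  identity cutoff (default 0.02, average linkage), Shannon / Margalef /
  bias-corrected Chao1, analytic hypergeometric rarefaction, rank-abundance,
  and incidence summaries (ubiquitous / unique OTUs across groups).
- **`trflpkit.structure`** — Bray–Curtis resemblance (percent similarity),
  normalized Euclidean environmental distances, deterministic UPGMA
  clustering with Newick export, and a Mantel-type rank correlation between
  resemblance matrices with a label-permutation null.
- **`trflpkit.succession`** — similarity-to-reference series per water mass,
  OLS distance-decay regression, a stations-bootstrap percentile test of the
  slope, and an ANCOVA homogeneity-of-slopes comparison against a
  permutation null ensemble.
- **`trflpkit.io` / `trflpkit.config` / `trflpkit.pipeline` /
  `trflpkit.cli`** — plain-text readers/writers (FASTA, CSV, Newick),
  strict YAML run configuration, and the end-to-end pipeline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the acceptance criteria, including two
Monte-Carlo calibration studies (marked `slow`, a few minutes total).

## Command line

All stages are exposed as subcommands of one entry point:

```sh
trflpkit simulate --seed 3 --out runs/sim          # synthetic scenario
trflpkit digest --fasta runs/sim/otus.fasta --out frags.csv
trflpkit fingerprint --peaks peaks.csv --out fp.csv \
    --bin-width 1 --size-min 34 --size-max 966
trflpkit otu --fasta aligned.fasta --cutoff 0.02 --linkage average --out otus.csv
trflpkit diversity --counts counts.csv --out div.csv
trflpkit rarefy --counts counts.csv --sample S1 --out rare.csv
trflpkit incidence --matrix fp.csv --metadata meta.csv
trflpkit resemble --matrix fp.csv --out bc.csv
trflpkit cluster --resemblance bc.csv --out dendro.nwk
trflpkit relate --matrix-a bc.csv --matrix-b env.csv --permutations 9999 --seed 1
trflpkit succession --fingerprints fp.csv --metadata meta.csv \
    --water-mass NADW --n-boot 10000 --n-null 1000 --seed 7 --out succ.csv
trflpkit run --config config.yaml --seed 1 --out runs/full   # whole chain
```

`trflpkit run` executes simulate → digest → fingerprint → resemble →
cluster → relate → diversity → succession into one run directory with
stage-named subfolders, sidecar parameter records, and a `summary.json`.
Two runs with the same config are byte-identical.

## Notes on conventions

- Similarity matrices are stored as percent (0–100); distances are derived
  as `100 − S` for clustering only.
- Shannon index uses natural log; Chao1 is the bias-corrected form;
  Margalef and Chao1 are only reported for integer count data.
- The OTU clustering cutoff is inclusive (merge while distance ≤ cutoff).
- The reference station's self-similarity point (100% at 0 km) is excluded
  from distance-decay regressions by default (`include_reference=True` to
  keep it).
- The bootstrap resamples stations, not pairwise values, because every
  point in a series shares the single reference sample.
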