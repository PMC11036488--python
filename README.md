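# loxkit

A genotyping toolkit for recombinase-scrambled synthetic chromosomes.
Cre acting on chromosomes carrying symmetric 34 bp recombination sites
(loxPsym by default) stochastically deletes, inverts, duplicates and
translocates the inter-site segments ("loxP units", LUs). `loxkit` covers the
in-silico arm of screening such populations:

* **`genome_model`** — motif scanning, LU segmentation, signed LU
  arrangements, sequence rendering, and deterministic synthetic-chromosome
  fixtures (linear or circular).
* **`tag_design`** — one diagnostic qPCR primer pair per motif junction,
  chosen by exhaustive, deterministic penalty minimization
  (nearest-neighbor Tm, GC, length, mask constraints), with a multi-motif
  spanning fallback for LUs too short to host a primer, plus a brute-force
  both-strand off-target screen with Hamming-mismatch tolerance. A
  `within_unit` mode emulates classic within-segment assays for comparison.
* **`insilico_pcr`** — mismatch-tolerant end-point PCR prediction
  (default: amplicons ≤ 1000 bp, ≤ 2 mismatches per primer) reducing to a
  binary sample × junction genotype matrix, with TSV and heatmap output.
* **`scramble_sim`** — a rearrangement simulator on LU arrangements with a
  configurable event mix (default 63% deletion / 23% inversion / 7%
  duplication / 7% translocation), protected-LU viability, and JSON truth
  logs that replay exactly.
* **`genotype_interpret`** — turns presence/absence rows into candidate
  event calls (runs of ≥ 2 missing junctions → deletion; two distant
  singletons → inversion-or-translocation, explicitly ambiguous;
  duplications are a structural blind spot), annotates events in known
  signed arrangements, scores diversity, and greedily selects maximally
  diverse candidates.
* **`io_cli`** — FASTA/BED/CSV/TSV/YAML/JSON formats and the `loxkit`
  command line.

All coordinates are **0-based, half-open**, everywhere.

## Command line

Each subcommand writes its outputs plus a `manifest.json` (inputs, effective
config, seed, version) into `--outdir`. Exit codes: 0 success, 1 validation
error, 2 I/O error.

```bash
# 12-LU synthetic chromosome fixture (FASTA + BED)
loxkit --seed 7 fixture --n-lus 12 --lu-min 1500 --lu-max 2500 -o fx/

# motif scan (BED), junction panel design (CSV), off-target screen
loxkit scan fx/fixture.fasta -o scan/
loxkit design fx/fixture.fasta -o design/
loxkit offtarget design/panel.csv fx/fixture.fasta -o ot/

# simulate a scrambled population, genotype it, interpret the patterns
loxkit --seed 1 simulate fx/fixture.fasta --n 12 -o sim/
loxkit insilico sim/population.fasta design/panel.csv -o pcr/
loxkit classify pcr/matrix.tsv -o calls/
loxkit compare fx/fixture.fasta sim/truth_logs.json -o events/
loxkit select pcr/matrix.tsv -k 4 -o picks/
```

Design and simulation parameters can be overridden with a YAML file passed
via `loxkit --config params.yaml <subcommand> …`.

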