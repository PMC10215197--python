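# mitoredox

Simulation and analysis toolkit for cysteine redox proteomics. It models two
complementary quantification platforms end to end:

* **Competitive reactivity profiling** — reactive cysteines are labeled with a
  light (control) or heavy (oxidant-treated) isotopic probe; oxidation shows
  up as loss of heavy labeling, i.e. a light:heavy ratio above 1. A peroxide
  dose series (1, 2.5, 5, 10 mM) ranks sites by redox sensitivity.
* **Differential-alkylation percent oxidation** — free thiols take the light
  label, reversibly oxidized thiols are reduced and take the heavy label, so
  the heavy share of the signal directly measures the reversibly oxidized
  fraction.

A synthetic-data generator drives both platforms from a shared per-site ground
truth (Hill dose response, reversible/irreversible split, per-platform
detectability), so every analysis stage is verifiable by parameter recovery.

## Layout

| Module | Role |
| --- | --- |
| `mitoredox.synthetic_data` | tryptic digestion, peptide masses, ground-truth sampling, observation and chromatogram simulators |
| `mitoredox.quantify` | EIC integration, co-elution QC, capped light:heavy ratios |
| `mitoredox.isotop` | replicate aggregation, fold/CV filtering, sensitivity classification, implied oxidation, dose medians |
| `mitoredox.oxicat` | ratio → percent-oxidation conversion, dispersion filter, condition comparison |
| `mitoredox.annotate` | mitochondrial filtering, 12-way pathway binning, hypergeometric overrepresentation (BH-adjusted) |
| `mitoredox.pipeline` / `mitoredox.cli` | orchestration, config, manifests, CLI |

All tables are TSV with a versioned comment header (`# mitoredox.tsv.v1
kind=...`); sequences are FASTA. No binary formats are read or written.

## CLI

```bash
# full pipeline: simulate -> aggregate -> classify -> annotate -> report
mitoredox run-all --seed 1 --outdir out/

# stage by stage (identical outputs for the same config + seed)
mitoredox simulate --seed 1 --outdir out/ --chromatograms
mitoredox quantify --chromatograms out/chromatograms.tsv --out out/requant.tsv
mitoredox isotop   --seed 1 --outdir out/ --presence 2/2 --fold 2 --cv 0.5
mitoredox oxicat   --seed 1 --outdir out/ --presence 2/3 --sd-threshold 30
mitoredox report   --seed 1 --outdir out/
```

A YAML config (`--config run.yaml`) can set any `RunConfig` field — seed,
doses, replicate counts, noise CV, thresholds, presence rules, an input FASTA
and annotation table; CLI flags win over the file. `run-all` writes a
`manifest.json` echoing every threshold applied, and identical config + seed
gives byte-identical outputs.

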