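# ciliascreen

Analysis pipeline for arrayed RNAi ciliation screens: count-level
quantification of percent ciliation, normalization to same-experiment
scrambled controls, negative-control-based threshold calibration with a
positive-control anchor, a two-round duplex/gene hit-calling automaton with
knockdown concordance, cilium-length two-sample statistics for the
gain-of-ciliation arm, and a seeded synthetic-screen generator with a
Monte-Carlo design evaluator.

## Layout

| module | role |
| --- | --- |
| `ciliascreen.screen_model` | domain types, invariants, delimited-text/JSON readers and writers |
| `ciliascreen.quantification` | percent ciliation, control normalization, ddCt / percent-remaining knockdown |
| `ciliascreen.calibration` | loss/gain thresholds from negative-control dispersion + anchor validation |
| `ciliascreen.hit_calling` | duplex classification and the two-round gene decision automaton |
| `ciliascreen.length_analysis` | pooled-variance (or Welch) two-tailed t-tests on cilium lengths |
| `ciliascreen.synthetic_data` | hierarchical binomial screen simulator and operating-characteristics harness |
| `ciliascreen.cli_report` | `ciliascreen` CLI, YAML config, results tree and QC log |
| `ciliascreen.fixtures` | packaged 41-gene qualitative outcome fixture and its deterministic expansion |

## Input formats

UTF-8 comma-delimited tables with headers:

- `counts.csv`: `experiment_id,reagent_id,ciliated_count,total_count`
- `layout.csv`: `reagent_id,gene,reagent_class,round,category`
  (`reagent_class` in `SIRNA|MIRNA_MIMIC|SCRAMBLED_CONTROL|POSITIVE_CONTROL`)
- `qpcr.csv`: `reagent_id,mode,replicate,value,reference_value,control_link`
  (`mode` in `CT|PERCENT_REMAINING`; percent values on the 0–100 scale)
- `lengths.csv`: `reagent_id,length_um`

## CLI

```sh
# full pipeline: quantify -> calibrate -> call hits -> length report
ciliascreen call --counts counts.csv --layout layout.csv --qpcr qpcr.csv \
    --lengths lengths.csv --anchor siPCM1-1 --out results/

# synthetic screen (seed-deterministic, writes ground_truth.csv alongside)
ciliascreen simulate --out sim/ --seed 7

# Monte-Carlo operating characteristics of the design
ciliascreen evaluate --replicates 200 --seed 7 --out oc.tsv

# stand-alone cilium-length comparisons
ciliascreen lengths --lengths lengths.csv --control scr-1
```

`call` writes `results.json` (effects, thresholds, decisions, tallies),
`summary.tsv`, `tallies.tsv`, `lengths_report.tsv` and `qc.log`.  All
parameters (`k_sd`, anchor reagent, knockdown cutoff, minimum cells, alpha)
can come from a YAML config file; explicit flags win.

## Python API

```python
from ciliascreen import read_screen, call_screen, HitStatus

screen = read_screen("counts.csv", "layout.csv", qpcr="qpcr.csv")
result = call_screen(screen, anchor_reagent_id="siPCM1-1")
print(result.tallies)
print(result.decisions["SYNE1"])   # GeneDecision with rationale trace
```

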