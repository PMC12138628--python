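# biolube

Statistical optimization toolkit for enzymatic biolubricant (ester)
synthesis experiments. It implements the complete desk workflow around a
Taguchi L9(3⁴) screening design for esterification conversion:

- **design** — canonical L9(3⁴) orthogonal array, balance/orthogonality
  validation, mapping between 1-based level indices and physical factor
  values (molar ratio, biocatalyst load, oil blend, reaction time);
- **titration** — acidity index (mg NaOH/g) from titration records,
  fatty-acid conversion from the initial/final acidity drop, replicate
  aggregation (mean, sample sd);
- **sn_analysis** — larger-is-better signal-to-noise ratios
  (−10·log₁₀(mean 1/y²), dB), per-factor response tables with delta
  ranking, optimum selection (argmax or explicit levels), additive
  predicted-optimum S/N and its back-transform to a conversion;
- **variance_model** — pooled Taguchi ANOVA (smallest-SS factor pooled
  into the error row, F/p/contribution per factor), OLS conversion model
  in physical units, contour grids and parity data;
- **synthetic_data** — seeded generators for synthetic L9 experiments
  (additive linear response + Gaussian run/replicate noise) and titration
  series, plus a parameter-recovery study harness;
- **cli_io** — CSV/JSON readers and writers, the consolidated analysis
  report, and the `biolube` command-line interface.

All computation keeps full precision; 2-decimal truncating and half-up
display formatters are provided separately because published S/N tables
commonly mix both conventions.

## CLI

```sh
# full analysis -> JSON report
biolube analyze --design design.csv --factors factors.csv \
    --results results.csv --out report.json \
    --explicit-levels 2,2,1,1 --contour BLxCat --fixed MR=5,t=48

# orthogonality/balance check of a design file
biolube validate-design --design design.csv --factors factors.csv

# raw titration file -> per-run conversion results
biolube titrate --in titration.csv --out results.csv

# synthetic experiment (results, titration records, ground truth)
biolube simulate --config gen.json --seed 42 --out-dir sim/
```

File schemas (comma-separated, UTF-8, header row mandatory; the `1:n`
molar-ratio notation is accepted and normalized to the numeric ratio):

- factors: `factor,unit,level1,level2,level3`
- design (physical units): `run,MR,Cat,BL,t`
- results: `run,replicate,conversion_pct` or `run,conversion_mean,conversion_sd`
- titration: `run,replicate,mw_naoh,molarity,f,v_naoh_ml,m_g,stage`
  with `stage` ∈ {initial, final}

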