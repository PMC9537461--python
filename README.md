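# ipm — integrated process modelling for specification-driven acceptance criteria

`ipm` derives **intermediate acceptance criteria (iACs)** for critical quality
attributes (CQAs) at each unit operation (UO) of a multi-step purification
process, such that staying within an iAC guarantees a pre-defined
out-of-specification (OOS) probability at drug substance (DS), accounting for
process-parameter variability and model uncertainty.

## How it works

1. **Unit-operation models** (`ipm.unit_models`) — each UO×CQA pair is
   described on the natural-log scale of its performance indicator (specific
   clearance for impurities, yield for purities) by one of:
   - *DoE model*: OLS on [-1, 1]-coded process parameters, selected by
     exhaustive best-subset search (partial-t p < 0.1, strong heredity);
   - *SC model*: log-log OLS on the specific load concentration, with a
     no-extrapolation clamp at the observed load range;
   - *Manufacturing SC*: a lognormal fit to manufacturing runs;
   - *Combined*: DoE model times a deterministic load-correction factor
     anchored at the DoE starting-material concentration.
2. **Monte-Carlo chain** (`ipm.ipm_engine`) — process parameters are sampled
   from their normal operating range (Normal around the set-point, 3% CV by
   default), a performance value is drawn from each model's predictive
   distribution, and each UO's pool becomes the next UO's load; 800 runs per
   simulation by default.
3. **OOS probability** (`ipm.oos_stats`) — a normal distribution with the
   arithmetic mean and the upper 80% confidence bound of the standard
   deviation is fitted to the DS sample; OOS is the tail area beyond the DS
   specification limit. Includes the plausibility check against
   manufacturing runs and the conventional ±3 SD baseline.
4. **Sensitivity inversion** (`ipm.iac_psa`) — the pool value at a UO is
   imposed on a 15-point grid spanning ±10 SD of the manufacturing pools,
   the downstream chain is simulated per grid point (common random numbers),
   and the iAC is the pool value where an isotonic fit of the OOS curve
   crosses the threshold (default 5%). UOs without usable data (e.g. all
   values at the limit of quantification) fall back to the DS limit.
5. **Synthetic ground truth** (`ipm.synthetic_data`) — a fully specified
   9-UO, 3-CQA process with known generating models, dataset generators for
   manufacturing runs and designed experiments (OFAT, face-centered CCD,
   5×3 grid), and closed-form oracles for lognormal-clearance chains.

## CLI

```bash
ipm synth --seed 1 --out data/                  # synthetic config + datasets
ipm fit --config data/process.yaml --out fitted.json --diagnostics
ipm simulate --model fitted.json --seed 1 --n-runs 800 --out sim/
ipm validate --model fitted.json --manufacturing data/manufacturing.csv \
    --seed 1 --out report.json                  # plausibility check
ipm psa --model fitted.json --uo 4 --cqa HCP --seed 1 --out curve.csv
ipm iac-table --model fitted.json --seed 1 --threshold 0.05 --out iac.csv
ipm compare-3sd --iac-table iac.csv --out cmp.csv
```

Every command writes a JSON run manifest (seed, input digests, timings,
warnings) next to its outputs; identical seeds give byte-identical results.

## File formats

- **Process config** (YAML): UO list in order with process-parameter
  set-points / CVs / design ranges, CQA definitions with DS limits, per-UO
  model assignments, modelled sub-ranges, dataset paths.
- **Manufacturing CSV**: `batch_id, uo_id, cqa, load_value, pool_value,
  scale`; limit-of-quantification values as `<LOQ:x` markers (all-LOQ cells
  trigger the DS-limit fallback; mixed cells substitute LOQ/2 with a
  warning).
- **DoE CSV**: `#design`/`#uo`/`#range`/`#slc`/`#response_kind` header
  records, then `run_id`, native-unit factor columns and one
  `response_<cqa>` column per CQA.

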