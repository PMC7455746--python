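# vesiquant

Quantification pipeline for **DNA-programmed phospholipid synthesis inside
liposomes**: single-vesicle fluorescence image analysis plus targeted
mass-spectrometry bookkeeping, with a ground-truth-annotated synthetic-data
generator so that every stage is testable without any experimental download.

## Who this is for

Experiments that express lipid-synthesis enzymes (the *E. coli* Kennedy
pathway: PlsB → PlsC → CdsA branching to PssA/Psd for PE and PgsA/PgpA for
PG) inside giant unilamellar vesicles produce two kinds of data:

1. **Two-channel confocal images** — a membrane dye (e.g. Texas Red) showing
   each vesicle as a bright equatorial ring, and a reporter channel (e.g. the
   PS-specific probe LactC2-eGFP, or NBD-labelled acyl chains) whose
   membrane-localised intensity reports successful lipid synthesis in that
   vesicle.
2. **Targeted MRM peak tables** — integrated counts per (sample, transition,
   injection), with dilution series of lipid standards bracketing each run,
   and heavy-isotope product channels that separate de novo lipids from the
   pre-existing membrane.

vesiquant turns these into per-vesicle and per-sample numbers:

- **Segmentation** — binarize the membrane channel, flood-fill the dark
  background inward from the border, and keep the enclosed dark regions as
  vesicle lumina; per vesicle: centroid, radius, Crofton perimeter,
  circularity `4πA/P²`, and the perimeter-based *apparent radius* `P/2π`
  under a perfect-circle assumption.
- **Membrane profiling** — 63 radial rays from the centroid to 1.5× the
  radius, bilinear sampling at 0.5 px steps; the per-ray maximum is the
  membrane crossing and their mean is the vesicle's membrane reporter
  intensity. A manual mode accepts straight cross-sections only when they
  show exactly two membrane peaks.
- **Enrichment statistics** — a vesicle is *enriched* when its intensity
  exceeds `mean + 2·SD` of a negative-control population (≈2.3% false
  positives under a Gaussian null); plus coefficient of variation, Welch's
  *t*-test, Tukey box statistics, Pearson correlation.
- **Kinetics** — per-liposome logistic fits
  `I(t) = b + A/(1 + e^{−k(t−t₀)})`; maximum recruitment rate `A·k/4`
  (a.u./min) and plateau time `t₀ + ln(19)/k` (time to 95% of amplitude, h);
  apparent-radius-change histograms with 0.25 µm bins.
- **MS quantification** — duplicate-injection averaging, pooled pre/post
  linear calibration `counts = a·c + b`, inversion to µM, reference-peptide
  normalization, isotope-shift bookkeeping (+3 Da per ¹³C₃-G3P moiety, so
  +6 Da for PG which carries two), acyl-chain composition fractions with the
  random-incorporation null `DP = p², DO = (1−p)², PO = 2p(1−p)`, and the
  acyl-CoA conversion yield `100·Σ cᵢ·nchainsᵢ / [acyl-CoA]₀`.

## Worked example

Run the demo pipeline end to end on synthetic data (synthesis → segmentation
→ profiling → enrichment → kinetics → MS quantification):

```bash
vesiquant run --seed 1 --out demo/
```

which prints (abridged):

```json
{
  "enrichment": {
    "threshold": 119.51,
    "n_total": 10,
    "n_enriched": 8,
    "percent_enriched": 80.0,
    "welch_p": 0.0343
  },
  "kinetics": {
    "n_traces": 50,
    "n_responders": 27,
    "median_max_rate_au_per_min": 4.04,
    "median_plateau_time_h": 4.79
  },
  "msquant": {
    "conversion_yield_percent": 41.56,
    "chain_fractions_null": {"DP": 0.25, "DO": 0.25, "PO": 0.5}
  }
}
```

Reading this: of the 10 segmented vesicles, 8 exceeded the `mean + 2·SD`
threshold set by the enrichment-free control image (the generator seeded
roughly half the test vesicles as enriched, and dim enriched vesicles near
the control background can fall either side of the threshold at this small
n). Of 50 synthetic kinetic traces, 27 were responders (the generator's
non-responder fraction is 0.5), with a median maximum recruitment rate of
4.0 a.u./min and a median plateau time of 4.8 h. The MS stage back-calculated
20.8 µM of diacyl end products from noisy peak tables (truth: 20 µM),
i.e. a 41.6% acyl-CoA conversion yield, and reports the 50% mixed-chain
random-incorporation null alongside the observed fractions. Per-vesicle and
per-trace tables are written as CSV next to `summary.json`, and every
discarded vesicle or profile is logged with a reason in `run_log.json`.

Each stage is also available separately (`vesiquant synth|segment|profile|
enrich|kinetics|msquant`, see `--help`) and as plain library functions.

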