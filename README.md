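# comutpath

Pathway-comutation biomarkers for immunotherapy outcome.

Tumour mutational burden (TMB) and neoantigen load (NAL) predict benefit
from immune checkpoint blockade, but both lack portable cut-offs across
panels and cancer types. A pathway-level alternative: call a tumour
**comut+** when it carries non-silent mutations in *both* members of a
designated pair of signaling pathways. `comutpath` implements the full
workflow around that idea, for statistical bioinformaticians working with
MAF-style mutation calls, GMT gene sets, clinical tables and expression
matrices:

- **discovery** — build the non-silent gene×sample binary matrix (1%
  frequency filter), collapse to pathway mutation status, screen pathways
  against overall survival with covariate-adjusted Cox models and BH-FDR,
  regress TMB/NAL on the retained pathways, and select the optimal
  comutated pair by pairwise Wilcoxon contest; choose the comutation-count
  cut-off by the Youden index (J = sensitivity + specificity − 1) against
  top-quartile TMB/NAL;
- **classification** — comut+/comut− labels and comutation counts per
  patient;
- **immune profiling** — CYT, MHC-I and ssGSEA GEP scores, 47-gene immune
  panel differential testing, preranked GSEA;
- **validation** — Fisher's exact response analysis, Kaplan–Meier/log-rank
  survival stratification (including two-biomarker strata such as
  comut × PD-L1 ≥ 50%), confusion statistics vs MSI-H, C-index/AUROC
  biomarker comparison;
- **meta-analysis** — DerSimonian–Laird random-effects pooling of hazard
  or risk ratios with Q, τ², I² and a consistency rule
  (P_het > 0.1 and I² < 50%);
- **simulation** — a synthetic multi-cohort generator with a planted
  comutated pair (elevated TMB/NAL, hazard ratio < 1, higher response
  rate, upregulated immune genes) so the whole chain is testable without
  any data download.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

`examples/01_simulate_and_discover.py` plants the pair (PW01, PW02) in a
1000-patient cohort (carrier hazard ratio 0.6, +3 mutations/Mb) and
rediscovers it:

```
retained at FDR<0.05: ['PW01', 'PW02', 'PW09']
candidates with positive beta for both TMB and NAL: ['PW01', 'PW02', 'PW09']
selected comutated pair: ('PW01', 'PW02')
planted pair:            ('PW01', 'PW02')
```

The screen retains the two planted pathways (plus an occasional false
positive, here PW09); the regression filter and the pairwise rank-sum
contest then pick the planted pair. `examples/02_classify_and_validate.py`
validates such a classification clinically:

```
ORR comut+ 57.7% vs comut- 25.5%, Fisher p = 0.0000
median survival comut+ 31.809 vs comut- 20.755 months, log-rank p = 1.70e-05
comut+ as an MSI-H predictor: sensitivity 84.3% (91/108), specificity 78.7% (702/892)
```

i.e. comut+ patients respond more than twice as often, live ~11 months
longer at the median, and the label recovers most MSI-high tumours. The
other examples cover immune profiling and forest-plot pooling; each prints
a line explaining what the numbers mean.

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
comutpath simulate --seed 7 --outdir run/sim
comutpath discover --maf run/sim/synthetic.maf.tsv \
    --gmt run/sim/synthetic.pathways.gmt \
    --clinical run/sim/synthetic.clinical.tsv --outdir run/disc
comutpath classify ... | comutpath immune ... | comutpath validate ...
comutpath meta --effects effects.tsv --outdir run/meta
```

Every run writes a `manifest.json` (config hash, seed, input checksums);
identical config + seed reproduces byte-identical outputs.

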