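# tracemfa

Steady-state ¹³C metabolic flux analysis (MFA) for ex vivo tissue cultures:
from integrated mass-isotopomer (MI) peak areas and spent-medium
concentrations to fitted intracellular fluxes with profile-likelihood
confidence intervals and a carbon-flow decomposition.

## What it does

- **Model I/O** (`tracemfa.model_io`) — parse/serialize atom-mapped network
  models in an OpenFLUX-style sheet dialect, with carbon-balance validation,
  stoichiometric matrices, and a free-flux parameterization of the
  steady-state flux space.
- **EMU simulation** (`tracemfa.emu`) — elementary-metabolite-unit
  decomposition and level-wise linear solves for steady-state MIDs, with
  compartment/medium mixtures and reversible-flux expansion. A brute-force
  full-isotopomer simulator (`tracemfa.isotopomer`) serves as an independent
  cross-check oracle.
- **MID processing** (`tracemfa.labeling`) — peak areas → MI fractions,
  collision filtering against unlabeled controls (excess over the natural
  ¹³C binomial > 0.05), natural-abundance correction by inverting the
  binomial convolution, enrichment `e = Σ i·xᵢ / n`, replicate aggregation.
- **Exchange rates** (`tracemfa.exchange`) — uptake/release in
  µmol·g⁻¹·day⁻¹ (release positive) from fold changes, isotope-dilution
  quantification against a ¹²C standard, or direct assays.
- **Flux fitting** (`tracemfa.mfa`) — multistart weighted least squares over
  free fluxes, exchange fluxes, and mixture coefficients; χ² goodness of fit
  (sd floor 0.03 on MI fractions); residual-influence ranking;
  profile-likelihood CIs; substrate→product carbon-flow matrices with
  exchange discounting; label-free FVA for comparison.
- **Synthetic data** (`tracemfa.synth`) — bundled toy networks (including a
  liver-like model with a futile glucose cycle, glycogenolysis, TCA and
  urea-cycle fragments, and protein turnover) plus noisy replicate dataset
  generation with hidden ground truth and recovery scoring.
- **GSM scoring** (`tracemfa.gsm`) — pooled reaction z-scores from SBML
  gene–reaction associations (sum over genes, z > 3 significant,
  deduplicated gene sets).

## CLI

```sh
tracemfa synth --out bundle --seed 0           # synthetic input bundle
tracemfa fit --model bundle/model.csv \
    --measurements bundle/measurements.tsv \
    --labeling bundle/labeling.yaml --out fit  # flux estimates + fit report
tracemfa ci --model bundle/model.csv --measurements bundle/measurements.tsv \
    --labeling bundle/labeling.yaml --reactions gk,glycogen --out ci.tsv
tracemfa fva --model bundle/model.csv \
    --measurements bundle/measurements.tsv --out fva.tsv
tracemfa process --areas areas.tsv --out proc  # MID + enrichment tables
tracemfa gsm --sbml model.xml --genes genes.csv --out scores.tsv
```

All commands are deterministic for a fixed `--seed`, and every output embeds
a digest of the configuration that produced it.

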