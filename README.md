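# thermosol

Cross-species analysis of the thermal stress response in budding yeasts:
how growth, the transcriptional heat-shock response, and proteome-wide
biomolecular condensation are tuned to a species' thermal niche.

`thermosol` is written for groups doing sedimentation-fractionation
quantitative proteomics (Total / Supernatant / Pellet fractions before and
after heat shock), growth assays across temperature, flow-cytometry reporter
assays of the heat-shock response, dynamic light scattering (DLS) of
purified condensing proteins, and hydrogen-deuterium exchange mass
spectrometry (HDX-MS) of monomers versus condensates. Every analysis stage
has a synthetic-data generator with known ground truth, so the whole
pipeline is testable without any external download.

## The core model

After ultracentrifugation, each fraction of a lysate is processed and
measured separately, so measured peak areas violate conservation of mass.
For protein *i* with measured Total *Tᵢ*, Supernatant *Sᵢ* and Pellet *Pᵢ*,
per-experiment **mixing ratios** α_S and α_P absorb the differential
processing:

```
log(Tᵢ) ~ Normal( log(α_S·Sᵢ + α_P·Pᵢ), σ )
α_S, α_P ~ Gamma(1, 1)        σ ~ half-Cauchy(0, 3)
```

The posterior mixing ratios give each protein's **proportion in
supernatant**,

```
pSupᵢ = α_S·Sᵢ / (α_S·Sᵢ + α_P·Pᵢ),
```

with per-draw credible intervals. A drop in pSup during heat shock is read
as condensation. Only proteins with Total intensity > 1 enter the
mixing-ratio fit; pSup is reported for every protein with Sᵢ + Pᵢ > 0.

Around this sit the thermal phenotype fits:

* **CTMI** — the cardinal temperature model with inflection
  μ(T; T_min, T_opt, T_max, μ_opt), fitted by nonlinear least squares to
  per-temperature maximum specific growth rates (slope of the best linear
  window of ln OD₆₀₀ vs time);
* **skew-normal HSR fit** — reporter fold change vs temperature, whose
  numeric mode is the temperature of maximum heat-shock response;
* **T_condense** — onset of condensation in a DLS temperature ramp, as a
  sustained departure of R_h from the monomer baseline (mean R_h below
  35 °C);
* **HDX-MS comparison** — peptide %D normalized between undeuterated and
  saturated controls, aggregated to per-residue profiles, differenced
  between condensate and monomer (Δ%D), and correlated across orthologs
  over a global sequence alignment against shuffled-site nulls;
* **cross-species aggregation** — ortholog joins, protein-class means ± SE,
  species × condition R² matrices, temperature tuning curves, TPM, and
  regulon-level fold-change medians with cross-species Spearman ρ.

## Worked example

```python
import numpy as np
from thermosol import simulate as sim
from thermosol.psup import MixingRatioModel

# one simulated heat-shock fractionation experiment, known ground truth
scenario = sim.default_scenario(n_proteins=1000)
quant, truth = sim.simulate_fractionation(
    scenario, alpha_s=0.8, alpha_p=1.2, sigma=0.1, seed=42, condition="shocked"
)

model = MixingRatioModel(quant, intensity_threshold=1.0)
results = model.fit(seed=0)          # adaptive random-walk Metropolis
print(results.summary().round(4))
```

```
             mean      sd  hdi_2.5%  hdi_97.5%   r_hat   ess_bulk
parameter
alpha_s    0.8064  0.0035    0.7996     0.8133  1.0050  1339.8753
alpha_p    1.1981  0.0079    1.1834     1.2137  1.0038  1446.9855
sigma      0.1021  0.0024    0.0976     0.1067  1.0024  1421.9148
```

Both mixing ratios are recovered within 1% of the values used to generate
the data (0.8 and 1.2), with split-R-hat < 1.01 and effective sample sizes
above 1300, so `results.converged` is `True`. Plugging the posterior into
the pSup formula:

```python
est = results.compute_psup()
print(est.head(3).round(3)[["protein_id", "psup", "ci_low", "ci_high"]])
rmse = np.sqrt(np.nanmean((est["psup"] - truth.true_psup) ** 2))
print(f"pSup RMSE vs truth: {rmse:.4f}")
```

```
  protein_id   psup  ci_low  ci_high
0  prot00000  0.083   0.082    0.085
1  prot00001  0.086   0.085    0.088
2  prot00002  0.135   0.133    0.137
pSup RMSE vs truth: 0.0009
```

The low pSups are condensed proteins in the shocked condition; each carries
a 95% credible interval from the per-draw pSup. The per-protein estimates
land within 0.001 of the latent truth on average.

The thermal fits follow the same pattern
(`CTMIModel(...).fit()`, `SkewNormalHSRModel(...).fit()`,
`compute_tcondense(ramp)`), and every fit object exposes `summary()` and a
diagnostic `plot()`.

## Command line

```bash
thermosol simulate --seed 1 --n-proteins 500 --out run/
thermosol psup estimate run/fractionation.tsv --seed 1 --out run/psup.tsv
thermosol growth fit growth.tsv --out ctmi.json
thermosol dls tcondense ramps.tsv --out tcondense.json
thermosol run --config pipeline.yaml        # simulate -> psup -> compare
```

All tables are TSV with validated schemas (see `thermosol.io.SCHEMAS`);
sequences are FASTA; fits are written as JSON with seeds and convergence
flags.

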