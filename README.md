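# edna-occupancy

Multi-scale Bayesian occupancy modelling of environmental-DNA (eDNA)
surveys quantified by droplet digital PCR (ddPCR).

Surveys of cryptic aquatic species — the motivating case is invasive
Burmese pythons at wading-bird breeding islands in the Everglades — collect
water samples at paired colony/control sites, split each sample into PCR
replicates, and observe only *detections*, never presence itself. This
package implements the full inferential chain for such designs:

1. **Quantification** (`edna_occupancy.ddpcr`): Poisson-partition
   concentration estimates from droplet counts, `λ̂ = −ln(1 − m₁/m)/v`
   copies/μL with delta-method SEs and log-scale Wald CIs; best-run
   selection across inhibitor-removal re-runs; limit-of-blank (LOB)
   screening against negative controls; internal-positive-control
   inhibition scores.
2. **Occupancy model** (`edna_occupancy.occupancy`): the three-level
   hierarchy

       z_i ~ Bern(ψ_i), a_ij | z_i=1 ~ Bern(θ_ij), y_ijk | a_ij=1 ~ Bern(p_ijk)

   with logit-linear covariates at each level (site occupancy ψ, sample
   occurrence θ, replicate detection p), fitted by a Gibbs sampler with
   exact Pólya-Gamma augmentation for the coefficient blocks.
3. **Model selection** (`edna_occupancy.waic`): WAIC on the site-level
   marginal likelihood, reported as lack-of-fit plus predictive-variance
   penalty (the sum is exact by construction).
4. **Field statistics** (`edna_occupancy.field`): temperature imputation,
   time–temperature correlation, the 8 °C pair-exclusion screen, naive
   count summaries, and the paired colony-vs-control concentration test.
5. **Synthetic surveys** (`edna_occupancy.synthetic`): a generator with
   known truth down to droplet counts, plus a deterministic fixture
   reproducing the count-level summaries of the published Everglades
   survey.

## Worked example

Fit the best-ranked model (occupancy by island type, detection declining
with time of day) to the bundled deterministic survey:

```python
from edna_occupancy import everglades_fixture, run_mcmc, summarize_posterior

ds = everglades_fixture()          # 30 sites, 265 samples, 1325 ddPCR wells
draws = run_mcmc(ds, n_iter=20_000, burn_in=2_000, seed=1)
print(summarize_posterior(draws).table.round(2).to_string(index=False))
```

```
        parameter  median  cri_low  cri_high
 beta_type_colony    1.94     0.22      4.79
beta_type_control   -0.39    -1.79      1.50
  alpha_intercept   -1.77    -2.29     -1.26
  delta_intercept    4.38     2.86      6.51
       delta_time   -2.23    -6.43      0.84
       psi_colony    0.87     0.55      0.99
      psi_control    0.40     0.14      0.82
        theta_bar    0.15     0.09      0.22
            p_bar    0.92     0.70      1.00
```

Read: colony islands are occupied with posterior median probability 0.87
against 0.40 at the matched controls, while eDNA occurs in only ~15% of
samples from an occupied island — presence is real but spatially patchy.
The site and sample levels are driven by the detection *pattern*, which the
fixture reproduces from the published counts; replicate-level detection
(p̄ = 0.92 here) is higher than in the real survey because the fixture
gives every positive sample a full set of positive wells.

The same pipeline runs from the shell:

```bash
edna-occupancy simulate --fixture --out data/
edna-occupancy all --sites data/sites.csv --samples data/samples.csv \
    --replicates data/replicates.csv --neg-controls data/neg_controls.csv \
    --out results/ --n-iter 20000 --burn-in 2000 --seed 1
```

which writes `quantification.csv`, `detections.csv`, `table2_naive.csv`,
`pair_comparison.csv`, `design_counts.csv`, per-model posterior summaries
and diagnostics, `waic_ranking.csv`, and a `manifest.json` with checksums.

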