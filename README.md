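# cdompae

Optical water-quality analysis for lake surveys: excitation–emission matrix
(EEM) fluorescence of chromophoric dissolved organic matter (CDOM), and the
question of whether its integrated fluorescence components can stand in for
chemical measurements of phthalate ester (PAE) contamination — with a USEPA
drinking-water risk assessment on top.

The package is written for environmental scientists working with
fluorometer + UV-Vis surveys of inland waters. It covers, end to end:

1. **EEM preprocessing** — blank subtraction, inner-filter correction
   `I·10^((A(λex)+A(λem))/2)`, and Rayleigh scatter excision
   (`|λem−λex| ≤ w₁`, `|λem−2λex| ≤ w₂`) with interpolation.
2. **Fluorescence regional integration (FRI)** — the five-region scheme
   (R1 tyrosine-like, R2 tryptophan-like, R3 fulvic-like, R4 microbial
   protein-like, R5 humic-like), integrating the Riemann volume
   `Φᵢ = Σ_ex Σ_em I(λex,λem)·Δλex·Δλem` per region, with shares
   `Pᵢ = Φᵢ/Φ_T` and the allochthonous (R3+R5) vs autochthonous (R1+R2+R4)
   split. Half-open region bounds make the five regions a true partition.
3. **CDOM absorption** — Napierian coefficients `a(λ) = 2.303·OD(λ)/γ`,
   spectral slope S275–295 (log-linear OLS), E250:365 = a(250)/a(365),
   SUVA254 = a(254)/DOC, slope ratio S_R, and the source indices
   FI370 = I(370,450)/I(370,500) and FI310 = I(310,380)/I(310,430).
4. **PAE composition & risk** — congener composition statistics for
   DMP/DEP/DBP and the USEPA ingestion model
   `ADD = C·DR·EF·ED/(BW·AT)`, `HQ = ADD/RfD`, `HI = ΣHQ`
   (plus `CR = ADD·CSF`, `RI = ΣCR` when slope factors are configured).
5. **Association** — pairwise-complete Pearson matrices, simple OLS
   regression (DEP on Φ₃ etc.), one-way ANOVA for seasonal contrasts.
6. **Synthetic survey generator** — a seeded two-season, 45-sample cohort
   (25 June + 20 October) with latent terrestrial/autochthonous factors,
   five Gaussian fluorophores, exponential CDOM absorption and PAE
   concentrations, so every stage is testable without field data.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic survey (seed 42) and write their tables under `results/`:

```sh
python analysis/01_simulate_survey.py
python analysis/02_cdom_optics.py
python analysis/03_pae_risk.py
python analysis/04_fri_pae_association.py
```

`02_cdom_optics.py` prints the seasonal optical summary:

```
        fi370  fi310  s275_295   a350    a254  e250_365  suva254
season
JUN     1.392  0.386     0.021  2.302  16.942    10.873    0.643
OCT     1.146  0.353     0.017  4.829  24.018     6.840    1.009
```

October shows the terrestrial signature — FI370 below 1.4 (terrestrially
derived fulvic material), roughly doubled a(350) and higher SUVA254 —
while June reflects summer algal production.

`04_fri_pae_association.py` evaluates the FRI components as optical
proxies for DEP:

```
  phi3: r2 = 0.819 (p = 1.52e-17)
  phi4: r2 = 0.818 (p = 1.63e-17)
  phi5: r2 = 0.715 (p = 2.68e-13)
allochthonous share P(3+5): JUN 0.805 -> OCT 0.867
```

The fulvic-like volume Φ₃ is the strongest single predictor of DEP: both
trace the same terrestrial inputs. `03_pae_risk.py` closes the loop with
exposure: the maximum hazard index over all 45 site/season combinations is
1.49e-02 — two orders of magnitude below the HI = 1 non-cancer threshold,
i.e. no human health risk from the three congeners at these levels.

The same stages are scriptable from the shell:

```sh
cdompae synth --seed 1 --out survey/          # generate a bundle
cdompae run --config survey/pipeline.yaml --out survey/results
cdompae fri survey/eems/JUN_01.csv --force    # one-off integration
cdompae risk --samples survey/samples.csv
```

## Layout

```
src/cdompae/     library: dataio, preprocess, fri, absorption, risk,
                 association, synthetic, pipeline, cli
analysis/        numbered narrative drivers over the library
tests/           pytest suite (unit, property and end-to-end)
docs/methods.md  model, assumptions, parameter choices, limitations
```
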