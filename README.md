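# desiram

Bayesian decipherment of chemical stimuli from the flagellar-rotation
responses of *Escherichia coli*.

*E. coli* senses attractants through a handful of receptors feeding one
signalling pathway that sets the switching of its flagellar motors between
clockwise (CW) and counterclockwise (CCW) rotation. A single cell's
response is far too noisy to tell chemicals apart — but the
ensemble-averaged CW-bias time course of a hundred tethered cells is
characteristic of the stimulating species. `desiram` implements the full
statistical pipeline that exploits this:

1. **traces** — per-cell rotation records (10-ms frames, labelled CW/CCW or
   NONE below a 7.5°/frame threshold) are pooled into a 1-s-binned ensemble
   CW-bias trace.
2. **template fit** — each trace is reduced to a six-line geometric template
   (baseline L1, excitation plateau L2, three-phase recovery L3–L5, adapted
   level L6) and a 15-index characteristic vector {y₁…y₁₅} of durations,
   amplitudes, slopes and levels.
3. **dose–response models** — for every chemical *s* and index *i*, training
   data teach a model function *f(x|s,i)* of concentration *x* (OLS on
   log₁₀ x) with residual scale σ\_{s,i}.
4. **Bayesian classification** — the posterior over the chemical identity of
   a blind vector marginalises the unknown concentration:

       p(s | {yᵢ}) ∝ ∫ ∏ᵢ A(s,i) · exp( −(yᵢ − f(x|s,i))² / 2σ²_{s,i} ) dx

   with A(s,i) = 1/(√(2π)·σ\_{s,i}), evaluated in the log domain by
   trapezoidal quadrature over log₁₀ x.
5. **evaluation** — leave-one-out accuracy, the random-selection (RS)
   baseline 1/N_A with its Monte-Carlo SD and exact-rational binomial tail
   probabilities, the decrease in self-information
   DSI = log₂(acc) − log₂(acc_RS), and accuracy spectra over all k-subsets
   of a chemical panel.

Because no per-cell recordings of the original assay are publicly
deposited, the package ships a **synthetic tethered-cell simulator**
(two-state telegraph switching, concentration-dependent exclusive-CCW
excitation, piecewise-linear adaptation, strong cell-to-cell variability)
that generates study-condition data for every stage; see
`docs/methods.md` for the model and its limits.

## Worked example

Train on two amino-acid attractants and decipher a blind trace:

```python
import desiram as ds

profiles = ds.default_profiles()
pair = [profiles["L-Glu"], profiles["L-Asn"]]
cfg = ds.SimulationConfig(n_cells=50, seed=7)
concs = {p.name: ds.log_spaced_concentrations(p, 4) for p in pair}
training = ds.simulate_training_set(pair, concs, 4, cfg,
                                    ds.TemplateFitConfig(grid_step=10.0))

results = ds.ChemicalDeciphermentModel(training).fit()

# A blind sample: L-Asn at 3 mM, simulated with an unrelated seed.
blind = ds.simulate_ensemble(profiles["L-Asn"], 3.0,
                             ds.SimulationConfig(n_cells=50, seed=99))
vec = ds.SixLineTemplateModel(blind, ds.TemplateFitConfig(grid_step=10.0)).fit().vector()
post = results.posterior(vec)
print("y1 =", round(vec.y[0], 1), " y4 =", round(vec.y[3], 1))
for s, p in zip(post.chemicals, post.probabilities):
    print(f"p({s}) = {p:.4f}")
print("decision:", post.decision,
      " MAP conc:", round(post.map_concentration[post.decision], 2), "mM")

rep = results.loo_accuracy()
print(f"LOO accuracy {rep.accuracy:.3f} vs RS {rep.rs_rate:.2f} "
      f"(+/- {rep.rs_sd:.3f}); tail p {rep.rs_tail_prob:.2e}; DSI {rep.dsi:.2f} bits")
```

prints

```
y1 = 156.0  y4 = 106.5
p(L-Glu) = 0.0004
p(L-Asn) = 0.9996
decision: L-Asn  MAP conc: 7.81 mM
LOO accuracy 0.688 vs RS 0.50 (+/- 0.088); tail p 2.51e-02; DSI 0.46 bits
```

The blind vector's excitation duration (y₁ = 156 s) and first recovery
phase (y₄ = 106 s) sit on L-Asn's dose–response curves at a single
consistent concentration, while explaining them under L-Glu would require
inconsistent concentrations — so nearly all posterior mass lands on L-Asn,
with a maximum-a-posteriori concentration of the right order of magnitude.
The leave-one-out accuracy of 0.688 over 32 training traces beats uniform
guessing (0.50 ± 0.088): random selection would reach it with probability
only 2.5 × 10⁻², a gain of 0.46 bits of self-information. (This preset pair
is deliberately similar; well-separated pairs such as L-Glu/L-Ser exceed
0.9.)

The same pipeline is scriptable from the shell:

```
desiram simulate --profile L-Glu --conc 1.0 --seed 7 --out trace.csv
desiram extract  --trace trace.csv --label L-Glu --conc 1.0 --out vec.csv
desiram train    --vectors train.csv --out models.json
desiram classify --models models.json --vectors blind.csv --out posterior.csv
desiram evaluate --vectors train.csv --group L-Glu,L-Asn --out report.json
desiram spectrum --vectors train.csv --k 2 --out-prefix spectrum
```

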