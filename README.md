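# solmap

Atom-level solubility fingerprints, Mulliken charge maps, and ROESY contact
localization for micellar solubilization studies.

## The problem

Where does a hydrophobic drug sit inside a surfactant micelle — buried in the
hydrophobic core, at the palisade interface, or near the headgroup surface?
The question matters for drug delivery: the solubilization locus controls
stability and release. `solmap` implements three complementary computable
views of a guest molecule such as medroxyprogesterone (MP) in gemini
surfactant (14-6-14,2Br⁻) micelles:

1. **Structural fingerprint.** Circular (ECFP4-style) fingerprints are
   computed for a training table of molecules with known aqueous solubility
   (logS = log₁₀ S / mol L⁻¹) and regressed with a Bayesian ridge model

   *y* = *b* + Φ**m** + ε, ε ~ N(0, β⁻¹), *m*ⱼ ~ N(0, α⁻¹),

   with (α, β) set by evidence maximization. Each fingerprint bit's
   coefficient *m*ⱼ is mapped back onto the atoms whose environments set the
   bit, giving a signed per-atom solubility contribution that is rendered as
   a red (solubilizing) / blue (desolubilizing) molecule map.
2. **Charge map.** Mulliken partial charges
   *q*_A = *Z*_A − Σ_{μ∈A} (**PS**)_{μμ} from user-supplied density and
   overlap matrices, rendered with the same diverging colormap.
3. **ROE contact localization.** ROESY cross-peak tables (solute proton ×
   surfactant proton) are reduced per solute proton to a score
   (n_core − n_surface)/(n_core + n_surface) ∈ [−1, +1] over the
   surfactant's chain/spacer/headgroup regions, formalizing the
   core-vs-surface reading of the spectra.

A seeded synthetic-data generator produces molecule/logS tables whose logS
is an exactly additive function of functional-group counts, so weight signs,
noise levels and attribution conservation can be tested against known truth.

## Worked example

Simulate a 500-molecule training table, fit the model, and map the
solubility contributions of medroxyprogesterone:

```bash
solmap pipeline --n 500 --seed 7 --outdir demo
```

prints

```
Bayesian ridge regression (evidence maximization)
====================================================
observations                 500
fingerprint bits            2048
active bits                 1435
alpha (prior prec.)       26.591
beta (noise prec.)        9.4634
noise sd (1/sqrt b)       0.3251
intercept                -2.1812
iterations                    16  converged=True
train RMSE                0.2099
train R^2                 0.9737
predicted logS for query = -3.1998
```

The generator draws noise with SD 0.3; the model's noise estimate
1/√β = 0.325 recovers it, and R² ≈ 0.97 reflects the additive ground truth.
`demo/query_map.svg` is the colored depiction and `demo/query_atoms.csv`
the per-atom weights — in this run the most positive atom is the 17α-hydroxy
oxygen (+0.146 logS units) and the most negative a steroid-skeleton carbon
(−0.405), i.e. the hydroxyl pulls toward water while the hydrocarbon frame
pushes MP into the micellar core. The atom weights always sum to
(prediction − intercept).

The same workflow runs on real data: any CSV with `smiles` and `logS`
columns can be passed to `solmap train --input table.csv --out model.json`.

Library use mirrors the CLI:

```python
import solmap as sm

table, truth = sm.generate_solubility_dataset(sm.SyntheticSolubilitySpec(seed=7))
results = sm.BayesianRidge.from_dataframe(table).fit()
print(results.summary())
print(results.predict_smiles(sm.MP_SMILES))
```

Other subcommands: `simulate`, `train`, `predict`, `map`, `mulliken`
(charges from `P.txt`/`S.txt`/`header.json`), `roe-summary` (localization
report for a contact CSV). Every artifact gets a JSON provenance sidecar
with input hashes, configuration and versions.

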