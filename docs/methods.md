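# Methods

## Fingerprints

Molecules are parsed from SMILES with RDKit; fingerprints are Morgan
(extended-connectivity) fingerprints of radius 2 (ECFP4) folded to 2048
binary bits, RDKit's standard invariants (atomic number, heavy degree,
attached H count, formal charge, ring membership). Both radius and width
are configurable; 2048 bits is the de-facto ECFP4 default, and chirality is
ignored by default (exposed as a flag). Environments covering identical
atom sets are deduplicated keeping the smaller radius, and every surviving
`(center atom, radius)` environment is recorded per bit
(`FingerprintResult.bit_info`), which is what makes coefficient-to-atom
attribution possible. Bits are presence/absence, not counts — see
*Limitations*.

## Bayesian ridge regression

The solubility model is linear-Gaussian: logS = b + Φm + ε with an
isotropic Gaussian prior m ~ N(0, α⁻¹I) and noise ε ~ N(0, β⁻¹). The
posterior-mean weights for fixed hyperparameters are the ridge solution on
column- and target-centered data (the intercept is unpenalized, recovered as
b = ȳ − m·Φ̄). Hyperparameters are set by type-II maximum likelihood with
MacKay fixed-point updates:

    γ  = Σⱼ λⱼ/(α + λⱼ),  λⱼ = eigenvalues of β Φcᵀ Φc
    α ← γ / mᵀm
    β ← (N − γ) / ‖yc − Φc m‖²

Evidence maximization replaces opaque hyperparameter search: it is
deterministic, needs no validation split, and stays in the same model
family. Implementation detail: one thin SVD of Φc is taken up front, so
each update costs O(min(n, p)) and columns that are constant in the
training data get exactly zero weight. Iteration stops when both α and β
change by < 1e-4 relative (default; `fit(tol=..., max_iter=...)`), default
cap 300 iterations; a fit that exhausts the cap is returned flagged
`converged=False` with a warning logged. The log marginal likelihood is
tracked per iteration and is non-decreasing in practice (asserted to 1e-8
in tests). α is initialized at 1 and β at the reciprocal target variance;
the fixed point is insensitive to these starting values in all tested
problems. 1/√β is the model's residual-noise SD estimate. Training RMSE
and R² are reported; an optional k-fold cross-validation flag
(`train --cv k`) adds out-of-sample values, since training-set metrics
flatter any model fitted on all data.

The closed-form solver is verified against dense normal equations to 1e-10
and the full evidence loop against an independent reference implementation
(scikit-learn's, with its gamma hyperpriors zeroed) to 1e-8 — both are
cross-checks only; the implementation is self-contained.

## Attribution

A query molecule's on bit j contributes its coefficient mⱼ (binary
features). Each bit's contribution is split equally across the center atoms
of the environments that set it — the similarity-map convention. An
alternative `spread="environment"` mode distributes each share uniformly
over all atoms of the environment, for sensitivity analysis; both conserve
the total exactly: Σ atom weights = prediction − intercept (tested at
1e-10). Colors come from a diverging map (`RdBu_r`) normalized by the
molecule's maximum absolute weight, symmetric about zero, so hue encodes
sign and intensity encodes relative magnitude within the molecule; atoms
with |weight| < 1e-12 are left uncolored. Weights live on heavy atoms;
protons are read through their attached heavy atom (e.g. the C6-methyl
protons of MP through the methyl carbon). Rendering is deterministic:
identical inputs give byte-identical SVG.

## Mulliken population analysis

Given a density matrix P and overlap matrix S in an atom-centered basis,
gross orbital populations are diag(PS) (for symmetric P and S this equals
the symmetrized ½·diag(PS + SP), asserted in tests) and atomic charges are
q_A = Z_A − Σ_{μ∈A}(PS)_{μμ}. Inputs are validated before computing:
unit overlap diagonal (1e-8), and trace(PS) equal to the electron count
implied by Z and the total charge (1e-6) — inconsistent inputs are refused
rather than silently renormalized. Charge conservation Σq_A = total charge
then holds by construction. The quantum-chemistry calculation that produces
P is out of scope by design: reimplementing an integrals/SCF engine is a
different project, and the analysis step proper is the population formula
and the map. Matrices arrive as whitespace-delimited text plus a JSON
header (basis→atom map, nuclear charges, total charge). For the charge
map the default orientation is red = negative charge (high electron
density), the usual electron-density convention; it is configurable because
red/blue assignment is a presentation choice, not physics.

## ROE contact localization

Contact tables are CSVs of (solute proton, surfactant proton, optional
intensity) with labels validated against the declared sets (H1–H22 for the
steroid, Ha–Hf for the gemini surfactant); duplicates are errors.
Intensities default to presence/absence because ROESY correlations from
these systems are reported qualitatively; intensity-weighted scoring is
available but off by default, and no distance estimation is attempted (ROE
intensity → distance requires mixing-time physics outside this scope).

The default region map assigns Ha/Hb/Hc to the hydrophobic chains, Hd to
the spacer, He/Hf to the headgroups. Chain and terminal-methyl regions
count as *core*, spacer and headgroup as *surface*; per solute proton,
score = (n_core − n_surface)/(n_core + n_surface), labelled core above
+1/3, surface below −1/3, interface between. The ±1/3 cut points are
conventions chosen to trisect the score range, not physical thresholds.
The region map is configuration, not a constant: mid-chain protons such as
Hc sit near the palisade layer and are legitimately describable as chain or
spacer — under the default map the acetyl proton H22 scores +1 ("core") at
both 2 mM and 5 mM surfactant while H20 (the C6-methyl protons) scores −1
("surface") at 5 mM; reassigning Hc to the spacer region flips H4 and H22
toward the surface, which is exactly the sensitivity the swappable map is
meant to expose.

## Synthetic data

The generator emulates a small-molecule solubility training set with fully
known structure: a random linear/branched alkane backbone (3–12 carbons)
decorated with functional groups from a six-fragment vocabulary (methyl,
hydroxyl, amino, carbonyl, carboxyl, phenyl), with logS = intercept +
Σ count_f · contribution_f + N(0, noise_sd²). Defaults: 500 molecules,
intercept −2.0, noise SD 0.3, contributions methyl −0.5, hydroxyl +1.0,
amino +0.8, carbonyl −0.5, carboxyl +1.2, phenyl −1.5 — hydrogen-bonding
groups raise aqueous solubility, added hydrophobic carbon lowers it, with
magnitudes in the range of classical group-contribution logS schemes. The
vocabulary spans both signs and 1–6-atom fragments so that sign recovery
and attribution dilution are both exercised.

Each fragment type appears at most once per molecule (independent inclusion
with probability 0.4). This is deliberate: binary fingerprints cannot
distinguish one occurrence of an environment from two identical ones, so
repeated identical fragments would make the additive ground truth
unrepresentable by the feature family and the generator would no longer
test recovery, only misfit. With distinct-context fragments the residual
representation floor is ≈ 0.16 logS RMSE at zero noise, small against the
0.3 noise SD. Ground truth (fragment counts, noiseless logS, per-atom
fragment membership in the emitted SMILES atom order) is emitted alongside
the table and re-derivable to 1e-12.

What the generator does *not* emulate: real logS distributions and
chemistry coverage (no rings beyond phenyl, no stereochemistry, no
duplicates or measurement-protocol heterogeneity), conformers, or
count-dependent effects. Passing recovery tests therefore demonstrates the
estimator and attribution machinery are correct, not that fingerprint
ridge regression is accurate on real solubility data — on real data,
expect RMSE on the order of 1 logS unit, not 0.2.

Mulliken fixtures: `orthonormal_neutral` (S = I, per-atom populations equal
to Z), `h2_symmetric` (2 basis functions, off-diagonal overlap 0.659 — a
representative H–H minimal-basis value; any s ∈ (0,1) yields the same zero
charges since diag(PS) = 1 per atom), `asymmetric_ionic` (S = I,
P = diag(1.8, 0.2) → charges ∓0.8). Random valid inputs are constructed by
normalizing a random PD matrix to unit diagonal (S) and rescaling a random
PSD matrix so trace(PS) matches the implied electron count (P).

## Problem sizes and determinism

Tests and the acceptance script run at n = 100–1000 molecules and 2048
bits, sizes at which every stage completes in seconds while leaving the
recovery signals (sign, noise SD) well resolved. All randomness flows from
explicit seeds; generation, fitting and rendering are bit-reproducible
across runs on the same software versions.

## Known limitations

- Binary bits cannot count: a symmetric diol contributes like a single
  hydroxyl. Count fingerprints would lift this but are deliberately out of
  scope for v1 (the binary-bit-array convention is kept).
- Bit folding can merge unrelated environments (2048 → occasional
  collisions); attribution then blends their contributions.
- Attribution spreads a fragment's effect over every environment that
  correlates with it, so per-atom means dilute multi-atom fragments;
  per-instance summed weights are the faithful recovery statistic.
- Evidence maximization assumes homoscedastic Gaussian noise; heavy-tailed
  or structured residuals will bias β.
- The localization score treats contacts as independent counts; it encodes
  no geometry beyond the core/surface dichotomy.
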