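"""Map fingerprint-bit coefficients back onto atoms and draw the result.

The model assigns one coefficient per fingerprint bit.  Each on bit of a
query molecule was set by one or more atom environments, so a bit's
contribution is divided equally among the *center atoms* of its generating
environments (the similarity-map convention).  Summing over bits gives a
signed per-atom solubility contribution; by construction these sum to the
model's prediction minus its intercept.

An alternative ``spread="environment"`` mode divides each environment's
share further over all atoms of the environment, for sensitivity analysis.

Rendering produces a 2-D depiction with atoms colored by a diverging map
(RdBu by default) normalized symmetrically about zero, mirroring the usual
red = solubilizing / blue = desolubilizing convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D

from .bayes_ridge import BayesianRidgeResults
from .fingerprint import FingerprintResult, environment_atoms

__all__ = ["AtomAttribution", "bit_contributions", "atom_weights", "render_molecule_map"]

ZERO_TOL = 1e-12


def bit_contributions(results: BayesianRidgeResults, fp: FingerprintResult) -> dict:
    """Per-on-bit contribution to the prediction: ``{bit: weight}``.

    For binary features the contribution of an on bit is simply its model
    coefficient; off bits contribute nothing and are absent from the map.
    """
    if fp.nbits != results.weights.shape[0]:
        raise ValueError("fingerprint length does not match model")
    return {j: float(results.weights[j]) for j in sorted(fp.on_bits)}


@dataclass
class AtomAttribution:
    """Signed per-atom solubility contributions (logS units).

    ``normalization`` is the maximum absolute weight, used for symmetric
    diverging-color scaling; it is 0 only when every weight is 0.
    """

    weights: np.ndarray
    normalization: float

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def atom_weights(
    mol: Chem.Mol,
    fp: FingerprintResult,
    contributions: dict,
    spread: str = "center",
) -> AtomAttribution:
    """Distribute bit contributions onto atoms.

    Each contributing bit with ``k`` environments in this molecule gives
    ``contribution / k`` to each environment's center atom (``spread=
    "center"``), or spreads that share uniformly over the environment's
    atoms (``spread="environment"``).  The atom weights always sum to the
    sum of the bit contributions.
    """
    if spread not in ("center", "environment"):
        raise ValueError(f"unknown spread mode {spread!r}")
    w = np.zeros(mol.GetNumAtoms(), dtype=float)
    for bit, contrib in contributions.items():
        envs = fp.bit_info.get(bit)
        if not envs:
            raise ValueError(f"bit {bit} has no recorded environments")
        share = contrib / len(envs)
        for center, radius in envs:
            if spread == "center":
                w[center] += share
            else:
                atoms = environment_atoms(mol, center, radius)
                w[list(atoms)] += share / len(atoms)
    norm = float(np.max(np.abs(w))) if w.size else 0.0
    return AtomAttribution(weights=w, normalization=norm)


def render_molecule_map(
    mol: Chem.Mol,
    weights: np.ndarray,
    colormap: str = "RdBu_r",
    size: tuple = (450, 400),
) -> str:
    """Render a 2-D depiction with per-atom diverging colors; returns SVG text.

    Colors are taken from ``colormap`` at ``0.5 * (1 + w / max|w|)`` so the
    scale is symmetric about zero; atoms with negligible weight are left
    uncolored.  ``RdBu_r`` puts positive weights in red, negative in blue.
    Output is deterministic for identical inputs.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != mol.GetNumAtoms():
        raise ValueError("need exactly one weight per atom")
    cmap = colormaps[colormap]
    norm = float(np.max(np.abs(weights))) if weights.size else 0.0
    colors = {}
    for i, w in enumerate(weights):
        if norm > 0 and abs(w) >= ZERO_TOL:
            r, g, b, _ = cmap(0.5 * (1.0 + w / norm))
            colors[i] = (r, g, b, 0.85)
    draw_mol = Chem.Mol(mol)
    rdDepictor.SetPreferCoordGen(True)
    rdDepictor.Compute2DCoords(draw_mol)
    drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        draw_mol,
        highlightAtoms=sorted(colors),
        highlightAtomColors=colors,
        highlightBonds=[],
    )
    drawer.FinishDrawing()
    return drawer.GetDrawingText()


def attribute_molecule(
    results: BayesianRidgeResults, mol: Chem.Mol, fp: FingerprintResult, spread: str = "center"
) -> AtomAttribution:
    """Convenience: bit contributions + atom weights in one call."""
    return atom_weights(mol, fp, bit_contributions(results, fp), spread=spread)
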