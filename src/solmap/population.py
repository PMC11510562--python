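"""Mulliken population analysis from precomputed density and overlap matrices.

Given a one-particle density matrix ``P`` and basis overlap matrix ``S`` in
an atom-centered basis, the Mulliken gross population of basis function mu
is ``(P S)_{mu mu}`` and the partial charge of atom A is

    q_A = Z_A - sum_{mu in A} (P S)_{mu mu}

Charges conserve the total molecular charge by construction, because
``trace(P S)`` equals the electron count.  The SCF calculation that produces
``P`` is deliberately outside this module: inputs arrive as plain-text
matrices plus a JSON header (see :func:`read_population_input`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .attribution import render_molecule_map

__all__ = [
    "PopulationInput",
    "ChargeResult",
    "mulliken_charges",
    "charge_map",
    "read_population_input",
    "write_population_input",
]

_DIAG_TOL = 1e-8
_ELECTRON_TOL = 1e-6


class PopulationValidationError(ValueError):
    """Raised when density/overlap inputs are inconsistent."""


@dataclass
class PopulationInput:
    """Matrices and bookkeeping for a Mulliken analysis.

    Attributes
    ----------
    P : (nbf, nbf) array
        Symmetric one-particle density matrix.
    S : (nbf, nbf) array
        Symmetric overlap matrix with unit diagonal.
    basis_map : (nbf,) int array
        Owning atom index of each basis function.
    Z : (natom,) array
        Nuclear charges.
    total_charge : int
        Net molecular charge.
    """

    P: np.ndarray
    S: np.ndarray
    basis_map: np.ndarray
    Z: np.ndarray
    total_charge: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.basis_map = np.asarray(self.basis_map, dtype=int)
        self.Z = np.asarray(self.Z, dtype=float)
        nbf = self.P.shape[0]
        if self.P.shape != (nbf, nbf) or self.S.shape != (nbf, nbf):
            raise PopulationValidationError("P and S must be square with equal dimension")
        if self.basis_map.shape != (nbf,):
            raise PopulationValidationError("basis_map length must equal basis dimension")
        if self.basis_map.min() < 0 or self.basis_map.max() >= self.Z.shape[0]:
            raise PopulationValidationError("basis_map refers to atoms outside Z")
        if np.max(np.abs(np.diag(self.S) - 1.0)) > _DIAG_TOL:
            raise PopulationValidationError("overlap diagonal must be 1 (normalized basis)")
        n_elec = float(self.Z.sum()) - float(self.total_charge)
        tr = float(np.trace(self.P @ self.S))
        if abs(tr - n_elec) > _ELECTRON_TOL:
            raise PopulationValidationError(
                f"trace(P S) = {tr:.8f} but Z and total charge imply {n_elec:.8f} electrons"
            )

    @property
    def n_atoms(self) -> int:
        return self.Z.shape[0]


@dataclass
class ChargeResult:
    """Atomic partial charges (elementary charge units) and gross populations."""

    q: np.ndarray
    gross_orbital_populations: np.ndarray


def mulliken_charges(inp: PopulationInput) -> ChargeResult:
    """Compute Mulliken atomic charges: ``q_A = Z_A - sum_{mu in A} (P S)_{mu mu}``."""
    gop = np.diag(inp.P @ inp.S).copy()
    pops = np.zeros(inp.n_atoms)
    np.add.at(pops, inp.basis_map, gop)
    return ChargeResult(q=inp.Z - pops, gross_orbital_populations=gop)


def charge_map(
    mol: Chem.Mol,
    charges: ChargeResult,
    red_negative: bool = True,
    colormap: str = "RdBu_r",
) -> str:
    """Render an atomic-charge-colored depiction as SVG.

    By default negative charge (high electron density) is drawn red, the
    usual electron-density convention; pass ``red_negative=False`` to flip.
    """
    q = np.asarray(charges.q, dtype=float)
    if q.shape[0] != mol.GetNumAtoms():
        raise ValueError(
            f"{q.shape[0]} charges for a molecule with {mol.GetNumAtoms()} atoms"
        )
    weights = -q if red_negative else q
    return render_molecule_map(mol, weights, colormap=colormap)


# -- plain-text I/O ---------------------------------------------------------


def write_population_input(inp: PopulationInput, directory) -> Path:
    """Write P.txt, S.txt and header.json into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "P.txt", inp.P, fmt="%.12g")
    np.savetxt(d / "S.txt", inp.S, fmt="%.12g")
    header = {
        "basis_map": inp.basis_map.tolist(),
        "Z": inp.Z.tolist(),
        "total_charge": int(inp.total_charge),
    }
    (d / "header.json").write_text(json.dumps(header, indent=1) + "\n")
    return d


def read_population_input(directory) -> PopulationInput:
    """Read the matrix-file format written by :func:`write_population_input`."""
    d = Path(directory)
    header = json.loads((d / "header.json").read_text())
    return PopulationInput(
        P=np.atleast_2d(np.loadtxt(d / "P.txt")),
        S=np.atleast_2d(np.loadtxt(d / "S.txt")),
        basis_map=np.asarray(header["basis_map"], dtype=int),
        Z=np.asarray(header["Z"], dtype=float),
        total_charge=int(header["total_charge"]),
    )
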