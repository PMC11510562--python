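"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators live here:

* a molecule/logS table generator producing random branched alkanes
  decorated with functional-group fragments, whose logS is an exactly
  additive function of fragment counts plus Gaussian noise — so weight,
  sign and noise-level recovery can be tested against known truth;
* analytic Mulliken fixtures (density/overlap matrices with hand-computable
  charges) plus a random-valid-input generator for conservation tests;
* transcribed ROESY contact fixtures for the medroxyprogesterone /
  14-6-14,2Br- system at 2 mM and 5 mM surfactant.

Everything is driven by explicit seeds and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .population import PopulationInput
from .roe import ContactTable

__all__ = [
    "SyntheticSolubilitySpec",
    "GroundTruth",
    "FRAGMENTS",
    "DEFAULT_CONTRIBUTIONS",
    "generate_solubility_dataset",
    "make_mulliken_fixture",
    "random_population_input",
    "MULLIKEN_CASES",
    "make_contact_fixture",
]


class ConfigurationError(ValueError):
    pass


# -- fragment grammar -------------------------------------------------------

# name -> (free valences consumed on the host carbon, builder)
# Builders append atoms/bonds to an RWMol and return the new atom indices
# that belong to the fragment.
def _add_methyl(rw: Chem.RWMol, host: int) -> list:
    i = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(host, i, Chem.BondType.SINGLE)
    return [i]


def _add_hydroxyl(rw: Chem.RWMol, host: int) -> list:
    i = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(host, i, Chem.BondType.SINGLE)
    return [i]


def _add_amino(rw: Chem.RWMol, host: int) -> list:
    i = rw.AddAtom(Chem.Atom(7))
    rw.AddBond(host, i, Chem.BondType.SINGLE)
    return [i]


def _add_carbonyl(rw: Chem.RWMol, host: int) -> list:
    # turns the host carbon into a ketone/aldehyde carbon; the host belongs
    # to the fragment too (its chemistry changes), handled by the caller
    i = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(host, i, Chem.BondType.DOUBLE)
    return [i]


def _add_carboxyl(rw: Chem.RWMol, host: int) -> list:
    c = rw.AddAtom(Chem.Atom(6))
    o1 = rw.AddAtom(Chem.Atom(8))
    o2 = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(host, c, Chem.BondType.SINGLE)
    rw.AddBond(c, o1, Chem.BondType.DOUBLE)
    rw.AddBond(c, o2, Chem.BondType.SINGLE)
    return [c, o1, o2]


def _add_phenyl(rw: Chem.RWMol, host: int) -> list:
    idx = []
    for _ in range(6):
        a = Chem.Atom(6)
        a.SetIsAromatic(True)
        idx.append(rw.AddAtom(a))
    for k in range(6):
        b = rw.AddBond(idx[k], idx[(k + 1) % 6], Chem.BondType.AROMATIC)
        rw.GetBondWithIdx(b - 1).SetIsAromatic(True)
    rw.AddBond(host, idx[0], Chem.BondType.SINGLE)
    return idx


FRAGMENTS = {
    "methyl": (1, _add_methyl, False),
    "hydroxyl": (1, _add_hydroxyl, False),
    "amino": (1, _add_amino, False),
    "carbonyl": (2, _add_carbonyl, True),  # host carbon is part of the fragment
    "carboxyl": (1, _add_carboxyl, False),
    "phenyl": (1, _add_phenyl, False),
}

#: Default logS increments (log10 mol/L) per fragment: polar hydrogen-bonding
#: groups raise aqueous solubility, added hydrophobic carbon lowers it.
DEFAULT_CONTRIBUTIONS = {
    "methyl": -0.5,
    "hydroxyl": 1.0,
    "amino": 0.8,
    "carbonyl": -0.5,
    "carboxyl": 1.2,
    "phenyl": -1.5,
}


@dataclass
class SyntheticSolubilitySpec:
    """Recipe for a synthetic molecule/logS table.

    ``true_contribution`` maps each fragment to its additive logS increment;
    ``noise_sd`` is the SD of homoscedastic Gaussian noise on logS.
    """

    n_molecules: int = 500
    fragment_vocab: tuple = tuple(DEFAULT_CONTRIBUTIONS)
    true_contribution: dict = field(default_factory=lambda: dict(DEFAULT_CONTRIBUTIONS))
    intercept_true: float = -2.0
    noise_sd: float = 0.3
    seed: int = 0
    min_backbone: int = 3
    max_backbone: int = 12
    decoration_prob: float = 0.4

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for f in self.fragment_vocab:
            if f not in FRAGMENTS:
                raise ConfigurationError(
                    f"unknown fragment {f!r}; known fragments: {sorted(FRAGMENTS)}"
                )
        missing = [f for f in self.fragment_vocab if f not in self.true_contribution]
        if missing:
            raise ConfigurationError(f"no true_contribution for fragment(s): {missing}")


@dataclass
class GroundTruth:
    """Exact generating quantities for a synthetic table.

    ``fragment_counts`` is one row per molecule (columns = vocabulary);
    ``noiseless_logS[i] = intercept + counts_i . contributions`` holds
    exactly; ``atom_membership[i][fragment]`` lists the atom indices (in the
    emitted SMILES atom order) that belong to each fragment instance.
    """

    fragment_counts: pd.DataFrame
    noiseless_logS: np.ndarray
    atom_membership: list
    intercept_true: float
    true_contribution: dict

    def to_json(self, path) -> None:
        payload = {
            "fragment_counts": self.fragment_counts.to_dict(orient="list"),
            "noiseless_logS": list(self.noiseless_logS),
            "atom_membership": self.atom_membership,
            "intercept_true": self.intercept_true,
            "true_contribution": self.true_contribution,
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def _random_molecule(rng: np.random.Generator, spec: SyntheticSolubilitySpec):
    """Build one decorated alkane; returns (canonical smiles, counts, membership)."""
    rw = Chem.RWMol()
    n_bb = int(rng.integers(spec.min_backbone, spec.max_backbone + 1))
    free = {}  # atom index -> remaining valence for decoration
    first = rw.AddAtom(Chem.Atom(6))
    free[first] = 4
    for _ in range(n_bb - 1):
        hosts = [a for a, v in free.items() if v >= 1]
        host = int(rng.choice(hosts))
        new = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(host, new, Chem.BondType.SINGLE)
        free[host] -= 1
        free[new] = 3
    counts = {f: 0 for f in spec.fragment_vocab}
    membership = {f: [] for f in spec.fragment_vocab}
    # Each fragment type appears at most once per molecule, so each instance
    # occupies a distinct circular environment and the additive ground truth
    # stays representable by binary (presence/absence) fingerprint features.
    include = rng.random(len(spec.fragment_vocab)) < spec.decoration_prob
    for frag, keep in zip(spec.fragment_vocab, include):
        if not keep:
            continue
        need, builder, host_in_frag = FRAGMENTS[frag]
        hosts = [a for a, v in free.items() if v >= need]
        if not hosts:
            continue
        host = int(rng.choice(hosts))
        new_atoms = builder(rw, host)
        free[host] -= need
        counts[frag] += 1
        atoms = ([host] if host_in_frag else []) + new_atoms
        membership[frag].extend(atoms)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    smiles = Chem.MolToSmiles(mol)
    # remap membership into the atom order of the emitted SMILES
    order = list(
        map(
            int,
            mol.GetPropsAsDict(includePrivate=True, includeComputed=True)[
                "_smilesAtomOutputOrder"
            ],
        )
    )
    pos = {orig: k for k, orig in enumerate(order)}
    membership = {f: sorted(pos[a] for a in atoms) for f, atoms in membership.items()}
    return smiles, counts, membership


def generate_solubility_dataset(
    spec: SyntheticSolubilitySpec,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a molecule/logS table plus its exact generating ground truth.

    Returns a DataFrame with columns ``id, smiles, logS`` and a
    :class:`GroundTruth`.  Identical specs (including seed) give identical
    outputs.
    """
    rng = np.random.default_rng(spec.seed)
    smiles_list, count_rows, memberships = [], [], []
    for _ in range(spec.n_molecules):
        smi, counts, membership = _random_molecule(rng, spec)
        smiles_list.append(smi)
        count_rows.append(counts)
        memberships.append(membership)
    counts_df = pd.DataFrame(count_rows, columns=list(spec.fragment_vocab))
    contrib = np.array([spec.true_contribution[f] for f in spec.fragment_vocab])
    noiseless = spec.intercept_true + counts_df.to_numpy() @ contrib
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_molecules) if spec.noise_sd > 0 else 0.0
    table = pd.DataFrame(
        {
            "id": [f"mol{i:05d}" for i in range(spec.n_molecules)],
            "smiles": smiles_list,
            "logS": noiseless + noise,
        }
    )
    truth = GroundTruth(
        fragment_counts=counts_df,
        noiseless_logS=noiseless,
        atom_membership=memberships,
        intercept_true=spec.intercept_true,
        true_contribution=dict(spec.true_contribution),
    )
    return table, truth


# -- Mulliken fixtures ------------------------------------------------------

_H2_OVERLAP = 0.659  # representative H-H minimal-basis overlap; any s in (0,1) works


def _case_orthonormal_neutral():
    # two atoms (He, H), orthonormal basis, per-atom populations equal to Z
    P = np.diag([1.0, 1.0, 1.0])
    S = np.eye(3)
    inp = PopulationInput(
        P=P, S=S, basis_map=np.array([0, 0, 1]), Z=np.array([2.0, 1.0]), total_charge=0
    )
    return inp, np.array([0.0, 0.0])


def _case_h2_symmetric():
    s = _H2_OVERLAP
    P = np.full((2, 2), 1.0 / (1.0 + s))
    S = np.array([[1.0, s], [s, 1.0]])
    inp = PopulationInput(
        P=P, S=S, basis_map=np.array([0, 1]), Z=np.array([1.0, 1.0]), total_charge=0
    )
    return inp, np.array([0.0, 0.0])


def _case_asymmetric_ionic():
    inp = PopulationInput(
        P=np.diag([1.8, 0.2]),
        S=np.eye(2),
        basis_map=np.array([0, 1]),
        Z=np.array([1.0, 1.0]),
        total_charge=0,
    )
    return inp, np.array([-0.8, 0.8])


MULLIKEN_CASES = {
    "orthonormal_neutral": _case_orthonormal_neutral,
    "h2_symmetric": _case_h2_symmetric,
    "asymmetric_ionic": _case_asymmetric_ionic,
}


def make_mulliken_fixture(case_name: str) -> tuple[PopulationInput, np.ndarray]:
    """Return an analytic population-analysis fixture and its expected charges."""
    try:
        factory = MULLIKEN_CASES[case_name]
    except KeyError:
        raise ConfigurationError(
            f"unknown Mulliken case {case_name!r}; available: {sorted(MULLIKEN_CASES)}"
        ) from None
    return factory()


def random_population_input(
    rng: np.random.Generator, max_atoms: int = 5, max_bf_per_atom: int = 3
) -> PopulationInput:
    """Random *valid* population input: S symmetric PD with unit diagonal,
    P symmetric PSD, trace(P S) matching the implied electron count."""
    natom = int(rng.integers(2, max_atoms + 1))
    bf_per_atom = rng.integers(1, max_bf_per_atom + 1, size=natom)
    basis_map = np.repeat(np.arange(natom), bf_per_atom)
    nbf = basis_map.shape[0]
    B = rng.normal(size=(nbf, nbf))
    M = B @ B.T + nbf * np.eye(nbf)
    d = 1.0 / np.sqrt(np.diag(M))
    S = d[:, None] * M * d[None, :]
    A = rng.normal(size=(nbf, nbf))
    P0 = A @ A.T
    Z = rng.integers(1, 9, size=natom).astype(float)
    total_charge = int(rng.integers(-1, 2))
    n_elec = float(Z.sum()) - total_charge
    P = P0 * (n_elec / float(np.trace(P0 @ S)))
    return PopulationInput(P=P, S=S, basis_map=basis_map, Z=Z, total_charge=total_charge)


# -- ROE contact fixtures ---------------------------------------------------

#: Key ROESY cross-peaks between medroxyprogesterone and 14-6-14,2Br-
#: protons, transcribed from the 2D spectra: at 2 mM surfactant only
#: Hc-H4 and Hc-H22; at 5 mM additionally He-H20.
_CONTACT_FIXTURES = {
    "2mM": {"pairs": [("H4", "Hc"), ("H22", "Hc")], "concentration_mM": 2.0},
    "5mM": {
        "pairs": [("H4", "Hc"), ("H20", "He"), ("H22", "Hc")],
        "concentration_mM": 5.0,
    },
}


def make_contact_fixture(concentration_label: str) -> ContactTable:
    """ROESY contact table for the MP / 14-6-14,2Br- system ("2mM" or "5mM")."""
    try:
        fx = _CONTACT_FIXTURES[concentration_label]
    except KeyError:
        raise ConfigurationError(
            f"unknown concentration {concentration_label!r}; "
            f"available: {sorted(_CONTACT_FIXTURES)}"
        ) from None
    df = pd.DataFrame(fx["pairs"], columns=["solute_proton", "surfactant_proton"])
    df["intensity"] = 1.0
    return ContactTable(
        entries=df,
        condition={"concentration_mM": fx["concentration_mM"], "temperature_K": 298.2},
    )
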