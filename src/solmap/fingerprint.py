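"""Circular (ECFP-style) fingerprints with full bit -> atom-environment provenance.

Extended-connectivity fingerprints encode each atom's neighborhood out to a
fixed radius as hashed integer identifiers folded into a fixed-length bit
vector.  Downstream attribution needs to know *which* atom environments set
*which* bits, so every fingerprint computed here carries a ``bit_info`` map
from bit index to the list of ``(center_atom, radius)`` environments that
produced it.

Molecules are carried as :class:`rdkit.Chem.Mol` objects; :func:`parse_smiles`
is the single entry point that turns SMILES text into one, with explicit
errors for syntax and valence problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, rdmolops

__all__ = [
    "SmilesParseError",
    "FingerprintResult",
    "parse_smiles",
    "atom_table",
    "compute_circular_fingerprint",
    "environment_atoms",
    "featurize_table",
]

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a valid molecule."""


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule.

    Parameters
    ----------
    smiles : str
        Non-empty SMILES text.

    Returns
    -------
    rdkit.Chem.Mol
        Sanitized molecule (aromaticity perceived, valences checked).

    Raises
    ------
    SmilesParseError
        If the string is empty, syntactically invalid, or chemically
        impossible (valence violation).
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"syntactically invalid SMILES: {smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types here
        raise SmilesParseError(f"chemistry error in SMILES {smiles!r}: {exc}") from exc
    return mol


def atom_table(mol: Chem.Mol) -> pd.DataFrame:
    """Per-atom view of the molecular graph.

    Columns: ``element``, ``formal_charge``, ``n_h`` (attached hydrogens),
    ``in_ring``, ``aromatic`` — one row per heavy atom, indexed by atom index.
    """
    rows = [
        {
            "element": a.GetSymbol(),
            "formal_charge": a.GetFormalCharge(),
            "n_h": a.GetTotalNumHs(),
            "in_ring": a.IsInRing(),
            "aromatic": a.GetIsAromatic(),
        }
        for a in mol.GetAtoms()
    ]
    return pd.DataFrame(rows)


@dataclass
class FingerprintResult:
    """A folded binary circular fingerprint plus environment provenance.

    Attributes
    ----------
    nbits : int
        Fingerprint length after folding.
    radius : int
        Maximum neighborhood radius (ECFP4 <-> radius 2).
    on_bits : frozenset[int]
        Indices of bits set to 1.
    bit_info : dict[int, list[tuple[int, int]]]
        For every on bit, the ``(center_atom_index, radius)`` environments
        that set it.  Environments covering identical atom sets are
        deduplicated (keeping the smallest radius) by the generator.
    """

    nbits: int
    radius: int
    on_bits: frozenset = field(default_factory=frozenset)
    bit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.bit_info) != set(self.on_bits):
            raise ValueError("bit_info keys must equal on_bits")
        for bit, envs in self.bit_info.items():
            if not envs:
                raise ValueError(f"bit {bit} has no generating environment")

    def dense(self) -> np.ndarray:
        """Return the fingerprint as a dense 0/1 integer vector."""
        v = np.zeros(self.nbits, dtype=np.int64)
        v[list(self.on_bits)] = 1
        return v


def compute_circular_fingerprint(
    mol: Chem.Mol,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
    use_chirality: bool = False,
) -> FingerprintResult:
    """Compute a folded circular fingerprint with bit provenance.

    The Morgan algorithm hashes initial atom invariants (atomic number,
    degree, attached H count, formal charge, ring membership) and iteratively
    extends them over bond neighborhoods for ``r = 1..radius``; surviving
    identifiers are folded to ``id mod nbits``.  Chirality is ignored by
    default.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if nbits < 16:
        raise ValueError(f"nbits must be >= 16, got {nbits}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=nbits, includeChirality=use_chirality
    )
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    fp = gen.GetFingerprint(mol, additionalOutput=out)
    bit_info = {int(b): [tuple(e) for e in envs] for b, envs in out.GetBitInfoMap().items()}
    on_bits = frozenset(int(b) for b in fp.GetOnBits())
    return FingerprintResult(nbits=nbits, radius=radius, on_bits=on_bits, bit_info=bit_info)


def environment_atoms(mol: Chem.Mol, center: int, radius: int) -> frozenset:
    """Atoms within graph distance ``radius`` of ``center`` (inclusive)."""
    if not 0 <= center < mol.GetNumAtoms():
        raise ValueError(f"center atom index {center} out of range")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    dists = rdmolops.GetDistanceMatrix(mol)[center]
    return frozenset(int(i) for i in np.flatnonzero(dists <= radius))


def featurize_table(
    table: pd.DataFrame,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
    smiles_col: str = "smiles",
) -> np.ndarray:
    """Build the binary design matrix Phi (rows = molecules, columns = bits).

    Every SMILES must parse; offending row ids are collected and reported in
    a single error rather than silently dropped.
    """
    bad: list = []
    rows = []
    for idx, smi in table[smiles_col].items():
        try:
            mol = parse_smiles(smi)
        except SmilesParseError:
            bad.append(idx)
            continue
        rows.append(compute_circular_fingerprint(mol, radius=radius, nbits=nbits).dense())
    if bad:
        raise SmilesParseError(f"unparseable SMILES at rows: {bad}")
    if not rows:
        return np.zeros((0, nbits), dtype=np.int64)
    return np.vstack(rows)
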