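"""ROESY cross-peak contact tables and micellar localization scoring.

A ROESY cross-peak between a solute proton and a surfactant proton means the
two are spatially close (under roughly 5 angstrom), so the pattern of
contacts over the surfactant's chain, spacer and headgroup protons places
each solute proton radially within the micelle.  This module parses
transcribed contact tables, tabulates contacts by surfactant region, and
reduces each solute proton's contacts to a core-vs-surface localization
score

    score = (n_core - n_surface) / (n_core + n_surface)    in [-1, +1]

where core regions are the hydrophobic chain and terminal methyls and
surface regions are the spacer and headgroups.  Scores above +1/3 are
labelled "core", below -1/3 "surface", in between "interface"; the +-1/3
cut points are conventional, not physical.

The default region map covers the gemini surfactant 14-6-14,2Br- (protons
Ha-Hf): Ha/Hb/Hc on the tetradecyl chains, Hd on the hexanediyl spacer,
He/Hf at the quaternary-ammonium headgroups.  Region maps are configuration,
not constants — assignments of mid-chain protons near the palisade layer
are genuinely ambiguous and worth varying.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ContactTable",
    "RegionMap",
    "DEFAULT_REGIONS",
    "CORE_REGIONS",
    "SURFACE_REGIONS",
    "parse_contact_table",
    "region_summary",
    "localization_index",
]

REGIONS = ("chain", "terminal_methyl", "spacer", "headgroup")
CORE_REGIONS = frozenset({"chain", "terminal_methyl"})
SURFACE_REGIONS = frozenset({"spacer", "headgroup"})

SOLUTE_LABELS = frozenset(f"H{i}" for i in range(1, 23))
SURFACTANT_LABELS = frozenset("H" + c for c in "abcdef")


class ContactTableError(ValueError):
    """Raised for malformed contact tables or region maps."""


@dataclass
class RegionMap:
    """Map surfactant proton label -> micellar region."""

    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, region in self.regions.items():
            if region not in REGIONS:
                raise ContactTableError(
                    f"unknown region {region!r} for {label}; expected one of {REGIONS}"
                )

    def __getitem__(self, label: str) -> str:
        return self.regions[label]

    def swapped(self) -> "RegionMap":
        """Core <-> surface swapped variant (chain<->spacer etc.), for
        sensitivity checks."""
        flip = {
            "chain": "headgroup",
            "terminal_methyl": "spacer",
            "spacer": "terminal_methyl",
            "headgroup": "chain",
        }
        return RegionMap({k: flip[v] for k, v in self.regions.items()})

    @classmethod
    def from_json(cls, path) -> "RegionMap":
        return cls(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.regions, indent=1) + "\n")


#: 14-6-14,2Br- assignment: Ha/Hb/Hc on the hydrophobic tetradecyl chains,
#: Hd on the hexanediyl spacer, He/Hf adjacent to the ammonium headgroups.
DEFAULT_REGIONS = RegionMap(
    {
        "Ha": "chain",
        "Hb": "chain",
        "Hc": "chain",
        "Hd": "spacer",
        "He": "headgroup",
        "Hf": "headgroup",
    }
)


@dataclass
class ContactTable:
    """Validated solute-proton x surfactant-proton ROE contacts.

    ``entries`` is a DataFrame with columns ``solute_proton``,
    ``surfactant_proton`` and ``intensity`` (defaults to 1; the source
    spectra report correlations qualitatively).  ``condition`` carries
    metadata such as surfactant concentration (mM) and temperature (K).
    """

    entries: pd.DataFrame
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.entries
        required = {"solute_proton", "surfactant_proton"}
        if not required.issubset(df.columns):
            raise ContactTableError(f"contact table needs columns {sorted(required)}")
        if "intensity" not in df.columns:
            df = df.assign(intensity=1.0)
        df = df.reset_index(drop=True)
        for col, allowed in (
            ("solute_proton", SOLUTE_LABELS),
            ("surfactant_proton", SURFACTANT_LABELS),
        ):
            bad = sorted(set(df[col]) - allowed)
            if bad:
                raise ContactTableError(f"unknown {col} label(s): {bad}")
        if (df["intensity"] < 0).any():
            raise ContactTableError("intensities must be >= 0")
        dup = df.duplicated(subset=["solute_proton", "surfactant_proton"])
        if dup.any():
            pairs = df.loc[dup, ["solute_proton", "surfactant_proton"]].values.tolist()
            raise ContactTableError(f"duplicate contact pair(s): {pairs}")
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> set:
        return set(
            zip(self.entries["solute_proton"], self.entries["surfactant_proton"])
        )

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def parse_contact_table(path, condition: dict | None = None) -> ContactTable:
    """Read a contact-table CSV (``solute_proton,surfactant_proton[,intensity]``)."""
    df = pd.read_csv(path)
    return ContactTable(entries=df, condition=condition or {})


def region_summary(table: ContactTable, regions: RegionMap = DEFAULT_REGIONS) -> pd.DataFrame:
    """Contingency counts of contacts per solute proton by surfactant region.

    Returns a DataFrame indexed by solute proton with one column per region;
    the grand total equals the number of table entries.
    """
    uncovered = sorted(set(table.entries["surfactant_proton"]) - set(regions.regions))
    if uncovered:
        raise ContactTableError(f"region map does not cover surfactant proton(s): {uncovered}")
    df = table.entries.assign(
        region=table.entries["surfactant_proton"].map(regions.regions)
    )
    counts = (
        df.groupby(["solute_proton", "region"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return counts.reindex(columns=list(REGIONS), fill_value=0)


def localization_index(
    summary: pd.DataFrame,
    weighted: bool = False,
    table: ContactTable | None = None,
    regions: RegionMap = DEFAULT_REGIONS,
) -> pd.DataFrame:
    """Core-vs-surface localization score and label per solute proton.

    ``score = (n_core - n_surface) / (n_core + n_surface)``; labels are
    "core" (> +1/3), "surface" (< -1/3), "interface" otherwise, and
    "unobserved" for protons without any contact.  With ``weighted=True``
    (and the originating ``table``) region counts are replaced by summed
    intensities.
    """
    if weighted:
        if table is None:
            raise ValueError("weighted scoring needs the originating contact table")
        df = table.entries.assign(
            region=table.entries["surfactant_proton"].map(regions.regions)
        )
        summary = (
            df.groupby(["solute_proton", "region"], observed=True)["intensity"]
            .sum()
            .unstack(fill_value=0.0)
            .reindex(columns=list(REGIONS), fill_value=0.0)
        )
    n_core = summary[list(CORE_REGIONS)].sum(axis=1)
    n_surface = summary[list(SURFACE_REGIONS)].sum(axis=1)
    total = n_core + n_surface
    out = pd.DataFrame(index=summary.index)
    out["score"] = 0.0
    observed = total > 0
    out.loc[observed, "score"] = (n_core - n_surface)[observed] / total[observed]
    out["label"] = "unobserved"
    out.loc[observed & (out["score"] > 1 / 3), "label"] = "core"
    out.loc[observed & (out["score"] < -1 / 3), "label"] = "surface"
    out.loc[observed & (out["score"].abs() <= 1 / 3), "label"] = "interface"
    return out
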