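"""Per-bead-type parameter tables.

Every bead type (20 amino acid residues plus the two DNA bead roles DB and
DN) carries a mass (g/mol), a charge (e), a pair-size parameter sigma
(Angstrom) and a unitless hydropathy lambda in [0, 1.5].  The packaged
default follows the Urry-scale parameterization of the hydropathy-scale (HPS)
family of coarse-grained models, with histidine neutral; alternative tables
can be loaded from TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

PROTEIN_BEADS = tuple("ARNDCQEGHILKMFPSTWYV")
DNA_BEADS = ("DB", "DN")
REQUIRED_BEADS = PROTEIN_BEADS + DNA_BEADS

LAMBDA_MIN, LAMBDA_MAX = 0.0, 1.5


class ParameterError(ValueError):
    """Missing bead type or out-of-range parameter value."""


@dataclass(frozen=True)
class ParameterTable:
    """Validated per-bead parameter table.

    Attributes
    ----------
    table : pandas.DataFrame
        Indexed by bead type with columns ``mass``, ``charge``, ``sigma``,
        ``lambda``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [b for b in REQUIRED_BEADS if b not in self.table.index]
        if missing:
            raise ParameterError(f"parameter table missing bead types: {missing}")
        for col in ("mass", "charge", "sigma", "lambda"):
            if col not in self.table.columns:
                raise ParameterError(f"parameter table missing column {col!r}")
        if (self.table["sigma"] <= 0).any():
            bad = self.table.index[self.table["sigma"] <= 0].tolist()
            raise ParameterError(f"non-positive sigma for bead types {bad}")
        if (self.table["mass"] <= 0).any():
            bad = self.table.index[self.table["mass"] <= 0].tolist()
            raise ParameterError(f"non-positive mass for bead types {bad}")
        lam = self.table["lambda"]
        if ((lam < LAMBDA_MIN) | (lam > LAMBDA_MAX)).any():
            bad = self.table.index[(lam < LAMBDA_MIN) | (lam > LAMBDA_MAX)].tolist()
            raise ParameterError(
                f"lambda outside [{LAMBDA_MIN}, {LAMBDA_MAX}] for bead types {bad}"
            )

    def __len__(self) -> int:
        return len(self.table)

    def mass(self, bead: str) -> float:
        return float(self.table.at[bead, "mass"])

    def charge(self, bead: str) -> float:
        return float(self.table.at[bead, "charge"])

    def sigma(self, bead: str) -> float:
        return float(self.table.at[bead, "sigma"])

    def lam(self, bead: str) -> float:
        return float(self.table.at[bead, "lambda"])

    def arrays_for(self, beads) -> dict:
        """Vectorized lookup: per-bead mass/charge/sigma/lambda arrays."""
        sub = self.table.reindex(beads)
        if sub["mass"].isna().any():
            unknown = sorted(set(b for b in beads if b not in self.table.index))
            raise ParameterError(f"unknown bead types: {unknown}")
        return {
            "mass": sub["mass"].to_numpy(float),
            "charge": sub["charge"].to_numpy(float),
            "sigma": sub["sigma"].to_numpy(float),
            "lambda": sub["lambda"].to_numpy(float),
        }


def load_parameter_table(source=None) -> ParameterTable:
    """Load a parameter table from TSV, or the packaged default.

    The TSV must have columns bead/mass/charge/sigma/lambda; ``#`` starts a
    comment line.
    """
    if source is None:
        ref = resources.files("cgslab").joinpath("data/hps_urry.tsv")
        with resources.as_file(ref) as path:
            return load_parameter_table(path)
    df = pd.read_csv(Path(source), sep="\t", comment="#", dtype={"bead": str})
    if "bead" not in df.columns:
        raise ParameterError("parameter TSV must have a 'bead' column")
    df = df.set_index("bead")
    df.columns = [c.strip() for c in df.columns]
    return ParameterTable(table=df[["mass", "charge", "sigma", "lambda"]].astype(float))


_default_table = None


def default_table() -> ParameterTable:
    """Cached packaged default table."""
    global _default_table
    if _default_table is None:
        _default_table = load_parameter_table(None)
    return _default_table
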