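"""Feature encoders for lysine-centered peptide windows.

The central idea is a *positional influence vector*: a vector of 2n+1
weights, one per window offset k in -n..+n, drawn from one of three even
polynomial families

    constant    y = c1
    square root y = a1 |k|^(1/2) + b1
    quadratic   y = a2 k^2 + b2

Even families are used because upstream and downstream flanks are assumed
to contribute symmetrically around the modified lysine.  A window is encoded
by multiplying, position by position, the influence weight with the
physico-chemical property value of the residue at that position, one block
per property (length P x (2n+1)).  Under a constant influence of 1 this
reduces exactly to the raw per-position property profile.

Also provides the conventional baselines: one-hot (binary) encoding,
(grouped) amino-acid composition, and per-property means.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .peptides import AMINO_ACIDS, PeptideWindow

__all__ = [
    "InfluenceSpec",
    "influence_vector",
    "PropertyTable",
    "encode_window",
    "encode_dataset",
    "encode_binary",
    "encode_aac",
    "encode_physchem_mean",
    "FAMILIES",
    "DEFAULT_COEFFICIENTS",
]

FAMILIES = ("constant", "sqrt", "quadratic")

#: Published reference coefficients for the three families
#: (c = 57.6, a1 = 4.1, b1 = 27.1, a2 = -2.7, b2 = 67.1).
DEFAULT_COEFFICIENTS = {
    "constant": {"c1": 57.6},
    "sqrt": {"a1": 4.1, "b1": 27.1},
    "quadratic": {"a2": -2.7, "b2": 67.1},
}

#: Default coefficient search ranges: slopes in [-10, 10], intercepts/constant
#: in [-100, 100].
COEFFICIENT_RANGES = {
    "c1": (-100.0, 100.0),
    "a1": (-10.0, 10.0),
    "b1": (-100.0, 100.0),
    "a2": (-10.0, 10.0),
    "b2": (-100.0, 100.0),
}


@dataclass(frozen=True)
class InfluenceSpec:
    """One polynomial family with exactly its own coefficients."""

    family: str
    c1: float | None = None
    a1: float | None = None
    b1: float | None = None
    a2: float | None = None
    b2: float | None = None

    _REQUIRED = {"constant": ("c1",), "sqrt": ("a1", "b1"), "quadratic": ("a2", "b2")}

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown influence family {self.family!r}; choose from {FAMILIES}")
        required = self._REQUIRED[self.family]
        for name in required:
            if getattr(self, name) is None:
                raise ValueError(f"family {self.family!r} requires coefficient {name!r}")
        for name in ("c1", "a1", "b1", "a2", "b2"):
            if name not in required and getattr(self, name) is not None:
                raise ValueError(f"coefficient {name!r} does not belong to family {self.family!r}")

    @classmethod
    def default(cls, family: str) -> "InfluenceSpec":
        return cls(family=family, **DEFAULT_COEFFICIENTS[family])

    def coefficients(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._REQUIRED[self.family]}


def influence_vector(spec: InfluenceSpec, n: int) -> np.ndarray:
    """Realize the 2n+1 positional weights of a family at offsets -n..+n.

    The square-root family is evaluated on |k| so that it is a well-defined
    even function on the signed offsets.
    """
    if n < 1:
        raise ValueError("window half-width n must be >= 1")
    k = np.arange(-n, n + 1, dtype=float)
    if spec.family == "constant":
        return np.full(2 * n + 1, float(spec.c1))
    if spec.family == "sqrt":
        return spec.a1 * np.sqrt(np.abs(k)) + spec.b1
    return spec.a2 * k**2 + spec.b2


class PropertyTable:
    """Per-residue values for P physico-chemical properties.

    Rows are property identifiers (AAIndex accessions for the bundled
    default), columns the 20 standard residues.  When ``standardized`` each
    property row is z-scored across the 20 residues so no single property
    dominates by scale.  The unknown residue 'X' always contributes 0.
    """

    def __init__(self, values: pd.DataFrame, standardized: bool = True):
        missing = set(AMINO_ACIDS) - set(values.columns)
        if missing:
            raise ValueError(f"property table lacks residues: {sorted(missing)}")
        values = values[list(AMINO_ACIDS)].astype(float)
        if values.isna().any().any():
            raise ValueError("property table contains missing values")
        if standardized:
            mean = values.mean(axis=1)
            std = values.std(axis=1, ddof=0)
            if (std == 0).any():
                bad = values.index[std == 0].tolist()
                raise ValueError(f"constant property rows cannot be standardized: {bad}")
            values = values.sub(mean, axis=0).div(std, axis=0)
        self.values = values
        self.standardized = standardized
        # 21-column lookup: residue index 20 is 'X' -> 0
        self._matrix = np.column_stack([values.to_numpy(), np.zeros(len(values))])
        self._residue_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        self._residue_index["X"] = 20

    @property
    def property_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_properties(self) -> int:
        return len(self.values)

    @classmethod
    def from_file(cls, path: str | Path, standardized: bool = True) -> "PropertyTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"property table not found: {path}")
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df, standardized=standardized)

    @classmethod
    def default(cls, standardized: bool = True) -> "PropertyTable":
        """The bundled 13-property AAIndex selection."""
        ref = importlib.resources.files("laipt.data") / "aaindex_table10.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path, standardized=standardized)

    def profile(self, residues: str) -> np.ndarray:
        """P x L matrix of property values along a residue string."""
        try:
            idx = [self._residue_index[ch] for ch in residues]
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]!r} missing from property table") from None
        return self._matrix[:, idx]

    def value(self, property_id: str, residue: str) -> float:
        if residue == "X":
            return 0.0
        return float(self.values.at[property_id, residue])


def encode_window(
    window: PeptideWindow,
    table: PropertyTable,
    influence: np.ndarray,
    reduce: str = "none",
) -> np.ndarray:
    """Influence-weighted property profile of one window.

    Element (p, k) is ``influence[k] * table[p, residue_k]``, flattened
    property-major to length P x (2n+1).  ``reduce="sum"`` instead sums the
    weighted values over positions, yielding one value per property.
    """
    influence = np.asarray(influence, dtype=float)
    if influence.size != len(window.residues):
        raise ValueError(
            f"influence length {influence.size} != window length {len(window.residues)}"
        )
    weighted = table.profile(window.residues) * influence[np.newaxis, :]
    if reduce == "sum":
        return weighted.sum(axis=1)
    if reduce != "none":
        raise ValueError(f"unknown reduction {reduce!r}")
    return weighted.ravel()


def encode_dataset(
    dataset,
    table: PropertyTable,
    influence: np.ndarray,
    reduce: str = "none",
) -> np.ndarray:
    """Stack encode_window over a LabeledDataset into a sample x feature matrix."""
    return np.array(
        [encode_window(w, table, influence, reduce=reduce) for w in dataset.windows]
    )


def encode_binary(window: PeptideWindow) -> np.ndarray:
    """One-hot encoding: a 20-bit block per position; 'X' is all-zero."""
    L = len(window.residues)
    out = np.zeros(20 * L)
    for pos, ch in enumerate(window.residues):
        if ch != "X":
            out[20 * pos + AMINO_ACIDS.index(ch)] = 1.0
    return out


#: Default residue grouping for the grouped-composition baseline.
RESIDUE_GROUPS = {
    "hydrophobic": "AVLIMFWP",
    "polar": "GSTCYNQ",
    "charged": "DEKRH",
}


def encode_aac(window: PeptideWindow, grouped: bool = False) -> np.ndarray:
    """Amino-acid (or residue-group) composition over non-'X' positions."""
    counted = [ch for ch in window.residues if ch != "X"]
    if not counted:
        raise ValueError("cannot compute composition of an all-'X' window")
    if grouped:
        groups = list(RESIDUE_GROUPS.values())
        counts = np.array([sum(ch in g for ch in counted) for g in groups], dtype=float)
    else:
        counts = np.array([counted.count(aa) for aa in AMINO_ACIDS], dtype=float)
    return counts / len(counted)


def encode_physchem_mean(window: PeptideWindow, table: PropertyTable) -> np.ndarray:
    """Per-property mean over the non-'X' positions of a window."""
    mask = np.array([ch != "X" for ch in window.residues])
    if not mask.any():
        raise ValueError("cannot average properties of an all-'X' window")
    return table.profile(window.residues)[:, mask].mean(axis=1)
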