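"""Mixed-variable Gower dissimilarity between species.

For species i, j the dissimilarity is the weighted mean of per-trait
contributions d_ijk: |x_ik - x_jk| / range_k for continuous traits (range
taken over the species pool in the table) and an unequal-level indicator
for nominal traits. Distances are bounded in [0, 1]. A continuous trait
with zero range contributes 0 (with a warning); missing values are
rejected — species with incomplete traits are dropped upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ecofilter.data_model import SchemaError, TraitTable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with zero diagonal."""

    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.species_ids = [str(s) for s in self.species_ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if v.shape != (n, n):
            raise SchemaError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise SchemaError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise SchemaError("distance matrix diagonal is not zero")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise SchemaError("distances must lie in [0, 1]")
        self.values = v

    def loc(self, a: str, b: str) -> float:
        ia = self.species_ids.index(a)
        ib = self.species_ids.index(b)
        return float(self.values[ia, ib])

    def subset(self, species: list[str]) -> "DistanceMatrix":
        idx = [self.species_ids.index(s) for s in species]
        return DistanceMatrix(list(species), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids,
                            columns=self.species_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


def _trait_contributions(traits: TraitTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-trait stacked contribution matrices and weights.

    Returns (D, w) where D has shape (n_traits, n, n).
    """
    n = len(traits.species_ids)
    names = traits.trait_names
    if n < 2:
        raise SchemaError("need at least 2 species for pairwise distances")
    if traits.traits[names].isna().any().any():
        bad = traits.traits[names].isna().any()
        raise SchemaError(
            f"missing trait values in {list(bad[bad].index)}; drop those "
            "species before computing distances"
        )
    parts = np.zeros((len(names), n, n))
    weights = np.array([float(traits.variable_spec[t]["weight"]) for t in names])
    for k, name in enumerate(names):
        col = traits.traits[name]
        if traits.variable_spec[name]["kind"] == "continuous":
            x = pd.to_numeric(col).to_numpy(dtype=float)
            rng = np.ptp(x)
            if rng == 0:
                warnings.warn(
                    f"continuous trait {name!r} has zero range; it "
                    "contributes 0 to all distances",
                    stacklevel=3,
                )
                continue
            parts[k] = np.abs(x[:, None] - x[None, :]) / rng
        else:
            x = col.astype(str).to_numpy()
            parts[k] = (x[:, None] != x[None, :]).astype(float)
    return parts, weights


def gower_matrix(traits: TraitTable) -> DistanceMatrix:
    """Gower dissimilarity matrix over all species in the trait table."""
    parts, weights = _trait_contributions(traits)
    if weights.sum() <= 0:
        raise SchemaError("trait weights sum to zero")
    d = np.tensordot(weights, parts, axes=(0, 0)) / weights.sum()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 1.0)
    if d.size and d.max() == 0.0:
        warnings.warn("all species identical on every trait; zero matrix",
                      stacklevel=2)
    return DistanceMatrix(traits.species_ids, d)


def gower_pair(species_a: str, species_b: str, traits: TraitTable) -> float:
    """Dissimilarity between two named species (matches the matrix cell).

    Independent scalar entry point: contributions are accumulated trait by
    trait rather than sliced from the matrix.
    """
    for sp in (species_a, species_b):
        if sp not in traits.species_ids:
            raise KeyError(f"unknown species id {sp!r}")
    if species_a == species_b:
        return 0.0
    num = 0.0
    den = 0.0
    for name in traits.trait_names:
        w = float(traits.variable_spec[name]["weight"])
        a = traits.traits.loc[species_a, name]
        b = traits.traits.loc[species_b, name]
        if pd.isna(a) or pd.isna(b):
            raise SchemaError(f"missing value for trait {name!r}")
        if traits.variable_spec[name]["kind"] == "continuous":
            col = pd.to_numeric(traits.traits[name]).to_numpy(dtype=float)
            rng = np.ptp(col)
            contrib = 0.0 if rng == 0 else abs(float(a) - float(b)) / rng
        else:
            contrib = 0.0 if str(a) == str(b) else 1.0
        num += w * contrib
        den += w
    return num / den
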