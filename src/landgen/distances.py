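"""Labeled symmetric pairwise distance matrices — the lingua franca of the
pipeline (genetic, geographic, resistance, and barrier-indicator distances)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Symmetric real matrix over labeled sites with a zero diagonal.

    ``kind`` tags provenance: genetic | geographic | resistance | indicator.
    Infinite entries are allowed only for resistance matrices (disconnected
    site pairs).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.labels = tuple(str(l) for l in self.labels)
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix not symmetric within 1e-12")
        if not np.all(np.diag(v) == 0):
            raise ValueError("diagonal must be exactly zero")
        if self.kind != "resistance" and not np.all(np.isfinite(v)):
            raise ValueError("non-finite entries")
        self.values = 0.5 * (v + v.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(str(l)) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(float), kind)

    @classmethod
    def from_condensed(cls, labels: Sequence[str], condensed: np.ndarray,
                       kind: str = "generic") -> "DistanceMatrix":
        n = len(labels)
        v = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        v[iu] = condensed
        v += v.T
        return cls(tuple(labels), v, kind)
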