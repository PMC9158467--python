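"""Core data containers shared by every pipeline stage.

All expression values are assumed to be on a log2-like scale (normalized
abundance); every statistic downstream is rank- or correlation-based, so the
exact normalization endpoint does not matter as long as it is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "GeneSetCollection",
    "CohortTruth",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are feature (gene) identifiers, columns are sample identifiers.
    space : str
        Feature-space tag, ``"mRNA"`` or ``"lncRNA"``.
    """

    values: pd.DataFrame
    space: str = "mRNA"

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            raise ValueError("duplicated feature identifiers")
        if cols.has_duplicates:
            raise ValueError("duplicated sample identifiers")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.space not in ("mRNA", "lncRNA"):
            raise ValueError(f"unknown feature space {self.space!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.space)


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes, one row per sample.

    ``data`` must carry a unique sample index plus ``time`` (>0, months) and
    ``event`` (1 = event observed, 0 = censored) columns; any further columns
    are treated as clinical covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicated sample identifiers")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col!r}")
        t = self.data["time"].to_numpy(float)
        e = self.data["event"].to_numpy()
        if not np.all(t > 0):
            raise ValueError("survival times must be positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def subset(self, samples) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)])


class GeneSetCollection(dict):
    """Mapping of gene-set name to an ordered list of gene identifiers.

    Behaves like a plain dict; construction validates that no set is empty
    and that member identifiers are strings. A set may reference genes absent
    from a given expression matrix — they are dropped at use time.
    """

    def __init__(self, sets) -> None:
        super().__init__()
        for name, genes in dict(sets).items():
            genes = list(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if not all(isinstance(g, str) for g in genes):
                raise ValueError(f"gene set {name!r} has non-string members")
            self[str(name)] = genes

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.values():
            out.update(genes)
        return out


@dataclass
class CohortTruth:
    """Planted ground truth of a synthetic cohort, for recovery tests."""

    subtype_of_sample: dict[str, str]
    modulator_pairs: set[tuple[str, str]] = field(default_factory=set)
    prognostic_lnc: dict[str, float] = field(default_factory=dict)
    purity: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(s in ("S1", "S2") for s in self.subtype_of_sample.values()):
            raise ValueError("subtypes must be 'S1' or 'S2'")
        if not all(np.isfinite(b) for b in self.prognostic_lnc.values()):
            raise ValueError("planted log-hazard coefficients must be finite")
        if not all(0 < p <= 1 for p in self.purity.values()):
            raise ValueError("purity values must lie in (0, 1]")

    def subtype_vector(self, sample_ids) -> np.ndarray:
        return np.array([self.subtype_of_sample[s] for s in sample_ids])
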