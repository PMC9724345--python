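"""Cluster-level survey data: the unit of geostatistical inference.

Each record is one survey cluster: a displaced coordinate, the number of
women interviewed, the number reporting four or more antenatal-care visits
with a qualified provider (ANC4+), a survey weight, equity-stratum labels
and cluster-level covariate values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: closed label vocabularies for the three equity stratifiers
STRATA_LEVELS = {
    "wealth": ("poor", "non-poor"),
    "education": ("none", "some"),
    "access": ("within_1h", "beyond_1h"),
}

RESERVED_COLUMNS = {
    "cluster_id", "x", "y", "true_x", "true_y", "urban",
    "n_women", "n_anc4", "weight", "district_id",
    "wealth", "education", "access",
}


@dataclass
class SurveyDataset:
    """Cluster records plus the list of columns that are model covariates."""

    df: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.df
        required = {"cluster_id", "x", "y", "n_women", "n_anc4"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"survey table missing columns: {sorted(missing)}")
        if (df["n_women"] < 1).any():
            raise ValueError("every cluster needs at least one interviewed woman")
        if ((df["n_anc4"] < 0) | (df["n_anc4"] > df["n_women"])).any():
            raise ValueError("need 0 <= n_anc4 <= n_women in every cluster")
        if "weight" in df.columns and (df["weight"] <= 0).any():
            raise ValueError("survey weights must be positive")
        for name, levels in STRATA_LEVELS.items():
            if name in df.columns:
                bad = set(df[name].dropna().unique()) - set(levels)
                if bad:
                    raise ValueError(f"unknown {name} labels: {sorted(bad)}")
        for c in self.covariates:
            if c not in df.columns:
                raise ValueError(f"covariate column {c!r} not in table")

    # ------------------------------------------------------------- accessors
    @property
    def n_clusters(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        """(m, 2) array of analysis (displaced) coordinates in km."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.df["n_women"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["n_anc4"].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray:
        if "weight" in self.df.columns:
            return self.df["weight"].to_numpy(dtype=float)
        return np.ones(len(self.df))

    def design_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Intercept-plus-covariates matrix for the given covariate names."""
        names = self.covariates if names is None else list(names)
        cols = [np.ones(len(self.df))]
        cols += [self.df[c].to_numpy(dtype=float) for c in names]
        return np.column_stack(cols)

    # ------------------------------------------------------------- selection
    def subset(self, mask: np.ndarray) -> "SurveyDataset":
        return SurveyDataset(self.df.loc[np.asarray(mask)].reset_index(drop=True),
                             list(self.covariates))

    def filter_stratum(self, stratifier: str, level: str) -> "SurveyDataset":
        if stratifier not in STRATA_LEVELS:
            raise ValueError(f"unknown stratifier {stratifier!r}")
        if level not in STRATA_LEVELS[stratifier]:
            raise ValueError(f"unknown level {level!r} for {stratifier!r}")
        return self.subset((self.df[stratifier] == level).to_numpy())

    def drop_missing(self, columns: list[str]) -> tuple["SurveyDataset", float]:
        """Drop records missing any of `columns`; return (kept, dropped fraction)."""
        ok = self.df[columns].notna().all(axis=1).to_numpy()
        return self.subset(ok), 1.0 - ok.mean()

    # --------------------------------------------------------------------- IO
    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.attrs = {}
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 covariates: list[str] | None = None) -> "SurveyDataset":
        df = pd.read_csv(path)
        if covariates is None:
            covariates = [c for c in df.columns if c not in RESERVED_COLUMNS]
        return cls(df, list(covariates))
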