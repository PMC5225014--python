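"""Core in-memory containers shared across pipeline stages.

Tabular payloads are plain pandas objects; the dataclasses here only bundle
them with the metadata the stages need (taxonomy, sample annotations, size
standards) and enforce the structural invariants each stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "FingerprintProfile",
    "PeakSet",
    "DiversityIndices",
    "DistanceMatrix",
    "AnosimResult",
    "QpcrRun",
    "StandardCurve",
    "CohortPhenotypes",
    "GroundTruth",
]


@dataclass
class OTUTable:
    """OTU count matrix (rows = OTUs, columns = samples) with annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, index = OTU ids, columns = sample ids.
    taxonomy
        Lineage string per OTU (semicolon-separated ranks).
    sample_meta
        One row per sample with at least ``pig``, ``group`` (H/D or NA) and
        ``day`` columns.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ValueError("OTU counts must be integral")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        self.taxonomy = self.taxonomy.reindex(self.counts.index)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def groups(self) -> pd.Series:
        """H/D label per sample, aligned to count columns."""
        return self.sample_meta.loc[self.counts.columns, "group"]


@dataclass
class FingerprintProfile:
    """A single electrophoresis trace.

    ``positions`` are scan units on a raw trace and size-standard-calibrated
    units after preprocessing. ``standard_peaks`` holds the internal size
    standard as (observed position, nominal size) pairs.
    """

    sample_id: str
    positions: np.ndarray
    intensities: np.ndarray
    standard_peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class PeakSet:
    """Detected peaks of one profile: (position, area fraction, height)."""

    sample_id: str
    positions: np.ndarray
    areas: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if np.any(self.areas < 0):
            raise ValueError("peak areas must be non-negative")

    @property
    def n_peaks(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class DiversityIndices:
    """Alpha-diversity summary of one fingerprint."""

    simpson: float
    shannon: float
    richness: int
    evenness: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(labels=list(df.index), values=df.values)


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int


@dataclass
class QpcrRun:
    """Standards and unknowns of one qPCR assay.

    ``standards``: columns (copies, cq); ``samples``: columns
    (sample, target, cq, dna_mass_ug).
    """

    standards: pd.DataFrame
    samples: pd.DataFrame
    target: str = ""

    def __post_init__(self) -> None:
        if (self.standards["copies"] <= 0).any():
            raise ValueError("standard copy numbers must be positive")
        if (self.standards["cq"] <= 0).any():
            raise ValueError("Cq values must be positive")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of Cq on log10(copies)."""

    slope: float
    intercept: float
    r_squared: float
    cq_min: float
    cq_max: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class CohortPhenotypes:
    """Per-pig phenotype records.

    ``pigs``: one row per pig (pig, litter, sex, group, muc13_len1,
    muc13_len2, colostrum intake and component concentrations).
    ``dm``: long table (pig, day, dm_pct).
    ``weights``: long table (pig, day, weight_kg), optional.
    """

    pigs: pd.DataFrame
    dm: pd.DataFrame = field(default_factory=pd.DataFrame)
    weights: pd.DataFrame = field(default_factory=pd.DataFrame)

    def dm_series(self, pig: str) -> pd.Series:
        sub = self.dm[self.dm["pig"] == pig].sort_values("day")
        return pd.Series(sub["dm_pct"].values, index=sub["day"].values)


@dataclass
class GroundTruth:
    """What the synthetic generator planted, for downstream verification."""

    group_labels: dict[str, str]
    true_effects: dict[str, float]
    true_copies: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        bad = {p: g for p, g in self.group_labels.items() if g not in ("H", "D")}
        if bad:
            raise ValueError(f"labels must be H or D: {bad}")
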