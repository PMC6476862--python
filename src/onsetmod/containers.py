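"""Core in-memory containers shared across the analysis modules.

Genotypes are held as a dense samples x markers matrix of minor-allele
dosages (0/1/2, NaN for missing).  Relatedness is a symmetric matrix
aligned to the sample list.  Phenotypes travel as a pandas DataFrame
with a fixed schema (see :func:`check_phenotypes`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

EDU_LEVELS = ["none", "elementary", "highschool", "tertiary"]

PHENOTYPE_COLUMNS = ["sample_id", "adaoo", "sex", "edu_years", "edu_group"]


class EmptyPanelError(ValueError):
    """Raised when an operation is asked to run on a zero-marker panel."""


@dataclass
class MarkerInfo:
    """Metadata for one SNP.

    ``counted_allele`` names the allele the dosage column counts (the
    in-sample minor allele after orientation); ``flipped`` records
    whether orientation inverted the source file's ALT dosage.
    ``n_alleles`` is the number of alleles declared by the source
    record, used by QC criterion "exactly two alleles".
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str | None = None
    n_alleles: int = 2
    counted_allele: str | None = None
    flipped: bool = False

    def __post_init__(self):
        if self.pos <= 0:
            raise ValueError(f"marker {self.id}: pos must be positive (1-based)")
        if self.counted_allele is None:
            self.counted_allele = self.alt_allele


@dataclass
class GenotypeMatrix:
    dosage: np.ndarray  # (n_samples, n_markers) float; values {0,1,2,NaN}
    markers: list[MarkerInfo]
    samples: list[str]

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x markers)")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError("sample list does not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker list does not match dosage columns")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        ids = [mk.id for mk in self.markers]
        if len(set(ids)) != m:
            raise ValueError("duplicate marker ids")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    def column(self, marker_id: str) -> np.ndarray:
        return self.dosage[:, self.marker_index(marker_id)]

    def subset_markers(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosage=self.dosage[:, keep],
            markers=[self.markers[i] for i in keep],
            samples=list(self.samples),
        )

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosage=self.dosage[keep, :],
            markers=[replace(m) for m in self.markers],
            samples=[self.samples[i] for i in keep],
        )


@dataclass
class KinshipMatrix:
    """Symmetric pairwise-relatedness matrix used as the polygenic covariance.

    Diagonal entries exceed 1 for inbred individuals, so no
    diagonal-dominance constraint is imposed.
    """

    values: np.ndarray
    samples: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.samples)

    def align(self, sample_order: Sequence[str]) -> "KinshipMatrix":
        """Reorder/subset to ``sample_order``; raises on unknown ids."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_order if s not in pos]
        if missing:
            raise KeyError(f"samples absent from kinship matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in sample_order])
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(sample_order))

    def subset(self, keep: np.ndarray) -> "KinshipMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return KinshipMatrix(
            self.values[np.ix_(keep, keep)], [self.samples[i] for i in keep]
        )


def check_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the phenotype schema and return a normalized copy.

    Requires columns sample_id, adaoo, sex, edu_years, edu_group with
    adaoo > 0, sex in {F, M} and edu_group one of the four ordered
    education levels.
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    out = df[PHENOTYPE_COLUMNS].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["adaoo"] = out["adaoo"].astype(float)
    if (out["adaoo"] <= 0).any():
        raise ValueError("adaoo must be positive (years)")
    if not out["sex"].isin(["F", "M"]).all():
        raise ValueError("sex must be coded F/M")
    if not out["edu_group"].isin(EDU_LEVELS).all():
        raise ValueError(f"edu_group must be one of {EDU_LEVELS}")
    out["edu_group"] = pd.Categorical(out["edu_group"], categories=EDU_LEVELS, ordered=True)
    if out["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    return out.reset_index(drop=True)
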