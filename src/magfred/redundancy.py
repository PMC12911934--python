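"""Functional diversity and redundancy of a community.

Given a MAG x trait table and per-sample relative abundances, a community's
functional redundancy is

    FRed = 1 - U,    U = Q / D,

with Q = sum_ij p_i p_j d_ij (Rao's quadratic entropy, the community's
functional diversity), D = 1 - sum_i p_i^2 (Gini-Simpson diversity) and
d_ij the pairwise Euclidean trait dissimilarity scaled so the maximum
observed distance is 1.  FRed is 1 when all members carry identical traits
and 0 when all members are maximally functionally distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from magfred.exceptions import CommunityUndefinedError, UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["sample_id", "subset_name", "mode", "N", "D", "Q", "U", "FRed"]


@dataclass(frozen=True)
class TraitDistanceMatrix:
    """Symmetric pairwise functional dissimilarities in [0, 1], zero diagonal."""

    mag_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.mag_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} does not match {n} ids")
        if len(set(self.mag_ids)) != n:
            raise ValidationError("duplicated MAG ids in distance matrix")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if d.min() < -1e-12 or d.max() > 1.0 + 1e-9:
            raise ValidationError("distances must lie in [0, 1] after scaling")
        object.__setattr__(self, "values", d)
        object.__setattr__(self, "mag_ids", tuple(self.mag_ids))

    def subset(self, mag_ids: Sequence[str]) -> "TraitDistanceMatrix":
        """Restrict to ``mag_ids`` (order preserved); unknown ids raise."""
        index = {m: i for i, m in enumerate(self.mag_ids)}
        missing = [m for m in mag_ids if m not in index]
        if missing:
            raise ValidationError(f"MAGs missing from distance matrix: {missing}")
        idx = np.array([index[m] for m in mag_ids], dtype=int)
        return TraitDistanceMatrix(tuple(mag_ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.mag_ids), columns=list(self.mag_ids))


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative abundances of the retained MAGs of one community (sum to 1)."""

    mag_ids: tuple[str, ...]
    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or len(p) != len(self.mag_ids):
            raise ValidationError("profile length does not match ids")
        if np.any(p <= 0):
            raise ValidationError("relative abundances must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(f"relative abundances sum to {p.sum():.15f}, not 1")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "mag_ids", tuple(self.mag_ids))


@dataclass(frozen=True)
class FRedResult:
    sample_id: str
    subset_name: str
    mode: str  # "potential" | "expressed"
    N: int
    D: float
    Q: float
    U: float
    FRed: float


def _raw_euclidean(table: pd.DataFrame) -> np.ndarray:
    if table.shape[0] < 2:
        raise ValidationError("trait distance requires at least 2 MAGs")
    if table.isna().any().any():
        raise ValidationError("trait table contains missing values")
    return squareform(pdist(table.to_numpy(dtype=float), metric="euclidean"))


def _max_scale(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    return d / dmax if dmax > 0 else d


def trait_distance(table: pd.DataFrame) -> TraitDistanceMatrix:
    """Pairwise Euclidean distance between MAG trait rows, max-scaled to [0, 1].

    Distances are divided by the maximum observed pairwise distance so
    ``max d_ij = 1`` (uniqueness Q/D is only bounded by 1 for unit-bounded
    dissimilarities).  If all pairwise distances are zero the matrix is
    all-zero.  Requires >= 2 MAG rows and no missing values.
    """
    d = _max_scale(_raw_euclidean(table))
    return TraitDistanceMatrix(tuple(str(m) for m in table.index), d)


def relative_abundance(row: pd.Series | Mapping[str, float],
                       min_abundance: float = 0.0) -> AbundanceProfile:
    """Drop MAGs at or below ``min_abundance`` and renormalize to sum 1.

    Raises :class:`CommunityUndefinedError` when fewer than 2 MAGs remain
    (pairwise redundancy needs at least one pair).
    """
    series = pd.Series(row, dtype=float)
    if (series < 0).any():
        bad = series.index[series < 0].tolist()
        raise ValidationError(f"negative abundance for {bad}")
    kept = series[series > min_abundance]
    if len(kept) < 2:
        raise CommunityUndefinedError(
            f"community has {len(kept)} MAG(s) above threshold {min_abundance}; need >= 2")
    p = kept.to_numpy() / kept.to_numpy().sum()
    # exact renormalization guard against accumulated rounding
    p = p / p.sum()
    return AbundanceProfile(tuple(str(m) for m in kept.index), p)


def gini_simpson(profile: AbundanceProfile) -> float:
    """Gini-Simpson diversity D = 1 - sum p_i^2."""
    return float(1.0 - np.dot(profile.p, profile.p))


def rao_q(profile: AbundanceProfile, dist: TraitDistanceMatrix) -> float:
    """Rao's quadratic entropy Q = sum_i sum_j p_i p_j d_ij."""
    sub = dist.subset(profile.mag_ids)
    return float(profile.p @ sub.values @ profile.p)


def fred(profile: AbundanceProfile, dist: TraitDistanceMatrix,
         sample_id: str = "", subset_name: str = "all",
         mode: str = "potential") -> FRedResult:
    """Functional redundancy FRed = 1 - Q/D for one community.

    Raises :class:`UndefinedStatisticError` when D = 0 (a single effective
    species, so uniqueness is 0/0).
    """
    # deterministic summation order for bitwise reproducibility
    order = np.argsort(np.asarray(profile.mag_ids))
    profile = AbundanceProfile(tuple(np.asarray(profile.mag_ids)[order]), profile.p[order])
    d = gini_simpson(profile)
    if d <= 0:
        raise UndefinedStatisticError("Gini-Simpson diversity is 0; uniqueness undefined")
    q = rao_q(profile, dist)
    u = q / d
    u = min(max(u, 0.0), 1.0)
    return FRedResult(sample_id=sample_id, subset_name=subset_name, mode=mode,
                      N=len(profile.mag_ids), D=d, Q=q, U=u, FRed=1.0 - u)


def community_fred(table: pd.DataFrame, abundance: pd.DataFrame,
                   subsets: Mapping[str, Iterable[str]] | None = None,
                   min_abundance: float = 0.0,
                   scale_per_sample: bool = False,
                   mode: str = "potential") -> pd.DataFrame:
    """FRed per (sample, trait subset) from one trait table and an abundance matrix.

    Parameters
    ----------
    table
        MAG x trait matrix (raw hit counts or completeness-normalized values).
    abundance
        sample x MAG abundance matrix; rows are samples.
    subsets
        Mapping subset_name -> trait ids.  ``None`` computes the full trait
        universe under subset name ``"all"``.
    min_abundance
        MAGs at or below this abundance are dropped before normalization.
    scale_per_sample
        Rescale distances within each sample's community instead of once over
        the full MAG set.  The default (global scaling per subset) keeps FRed
        comparable across samples.

    Undefined communities (fewer than 2 MAGs, or D = 0) yield rows with NaN
    diversity fields rather than aborting the run.
    """
    from magfred.traits import subset_traits  # local import avoids a cycle

    table = table.copy()
    table.index = table.index.astype(str)
    abundance = abundance.copy()
    abundance.index = abundance.index.astype(str)
    abundance.columns = abundance.columns.astype(str)
    common = [m for m in table.index if m in set(abundance.columns)]
    if len(common) < 2:
        raise ValidationError("fewer than 2 MAGs shared between trait table and abundance matrix")
    dropped = set(table.index) - set(common)
    if dropped:
        logger.warning("%d MAGs in trait table missing from abundance matrix; dropped", len(dropped))
    table = table.loc[sorted(common)]
    abundance = abundance[table.index.tolist()]

    if subsets is None:
        subsets = {"all": list(table.columns)}

    rows = []
    for subset_name in sorted(subsets):
        sub_table = subset_traits(table, subsets[subset_name], subset_name=subset_name)
        raw = _raw_euclidean(sub_table)
        if not scale_per_sample:
            raw = _max_scale(raw)
        mag_index = {m: i for i, m in enumerate(sub_table.index)}
        for sample_id in abundance.index:
            try:
                profile = relative_abundance(abundance.loc[sample_id], min_abundance)
                idx = np.array([mag_index[m] for m in profile.mag_ids], dtype=int)
                block = raw[np.ix_(idx, idx)]
                if scale_per_sample:
                    block = _max_scale(block)
                d = TraitDistanceMatrix(profile.mag_ids, block)
                result = fred(profile, d, sample_id=str(sample_id),
                              subset_name=subset_name, mode=mode)
                rows.append(result.__dict__)
            except (CommunityUndefinedError, UndefinedStatisticError) as exc:
                logger.warning("sample %s / subset %s undefined: %s", sample_id, subset_name, exc)
                n = int((abundance.loc[sample_id] > min_abundance).sum())
                rows.append({"sample_id": str(sample_id), "subset_name": subset_name,
                             "mode": mode, "N": n, "D": np.nan, "Q": np.nan,
                             "U": np.nan, "FRed": np.nan})
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return out.sort_values(["sample_id", "subset_name"], kind="mergesort").reset_index(drop=True)
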