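"""Expressed trait tables from transcript counts, and expressed FRed.

Per-sample gene read counts are length-normalized to transcripts per
million (TPM = rate / sum(rates) * 1e6 with rate = count / (length/1000)),
summed per (MAG, trait) into an expressed trait table, and fed through the
same redundancy machinery as the genomic (potential) traits.  Expressed
distances are max-scaled per sample because each sample has its own
expressed trait table.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from magfred.exceptions import CommunityUndefinedError, UndefinedStatisticError, ValidationError
from magfred.redundancy import (
    RESULT_COLUMNS,
    AbundanceProfile,
    TraitDistanceMatrix,
    _max_scale,
    _raw_euclidean,
    fred,
    relative_abundance,
)
from magfred.traits import subset_traits

logger = logging.getLogger(__name__)

MILLION = 1e6


def tpm_normalize(counts: pd.DataFrame, sample_id: str) -> pd.Series:
    """Per-gene TPM values for one sample.

    rate_g = read_count_g / (gene_length_g / 1000); TPM_g = rate_g /
    sum(rates) * 1e6, so TPM sums to 1e6.  Raises on a sample with no reads.
    """
    sub = counts[counts["sample_id"] == sample_id]
    if sub.empty:
        raise ValidationError(f"sample '{sample_id}' not present in transcript counts")
    rates = sub["read_count"].to_numpy(dtype=float) / (sub["gene_length"].to_numpy(dtype=float) / 1000.0)
    total = rates.sum()
    if total <= 0:
        raise ValidationError(f"sample '{sample_id}' has no mapped reads; TPM undefined")
    return pd.Series(rates / total * MILLION, index=sub["gene_id"].to_numpy())


def aggregate_expressed_traits(tpm: pd.Series, mapping: pd.DataFrame) -> pd.DataFrame:
    """Sum gene TPM into a MAG x trait expressed trait table.

    ``mapping`` has columns gene_id, mag_id, trait_id; a gene annotated to
    several traits contributes its full TPM to each.  Genes with positive
    TPM but no mapping are dropped with a warning.
    """
    for col in ("gene_id", "mag_id", "trait_id"):
        if col not in mapping.columns:
            raise ValidationError(f"mapping needs column '{col}'")
    mapped = mapping[mapping["gene_id"].isin(tpm.index)].copy()
    unmapped = set(tpm.index[tpm > 0]) - set(mapping["gene_id"])
    if unmapped:
        logger.warning("%d expressed gene(s) without (mag, trait) mapping dropped", len(unmapped))
    mapped["tpm"] = tpm.loc[mapped["gene_id"]].to_numpy()
    table = (mapped.groupby(["mag_id", "trait_id"], sort=True)["tpm"].sum()
             .unstack(fill_value=0.0))
    table.index.name = "mag_id"
    table.columns.name = "trait_id"
    return table


def build_expressed_tables(counts: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """One expressed trait table per sample from a long transcript-count table."""
    mapping = counts[["gene_id", "mag_id", "trait_id"]].drop_duplicates()
    tables = {}
    for sample_id in sorted(counts["sample_id"].unique()):
        try:
            tpm = tpm_normalize(counts, sample_id)
        except ValidationError as exc:
            logger.warning("skipping sample %s: %s", sample_id, exc)
            continue
        tables[str(sample_id)] = aggregate_expressed_traits(tpm, mapping)
    return tables


def expressed_fred(expressed: Mapping[str, pd.DataFrame], abundance: pd.DataFrame,
                   subsets: Mapping[str, Iterable[str]] | None = None,
                   min_abundance: float = 0.0,
                   weight: str = "abundance",
                   log1p: bool = False,
                   min_expressed_genes: int = 0) -> pd.DataFrame:
    """Expressed FRed per (sample, subset).

    For each sample: restrict to MAGs with both metagenomic abundance above
    threshold and at least one expressed trait in the subset, build Euclidean
    distances on the expressed TPM table (max-scaled per sample), and weight
    by the sample's metagenomic relative abundances (``weight="tpm"``
    switches to transcript-sum weights for sensitivity analysis).  Samples
    with fewer than 2 expressing MAGs give flagged NaN rows.  Communities
    whose subset has fewer than ``min_expressed_genes`` expressed (MAG,
    trait) cells with positive TPM are computed but logged as low-support.
    """
    if weight not in ("abundance", "tpm"):
        raise ValidationError(f"unknown weight mode '{weight}'")
    abundance = abundance.copy()
    abundance.index = abundance.index.astype(str)
    abundance.columns = abundance.columns.astype(str)

    rows = []
    sample_ids = sorted(set(map(str, abundance.index)))
    for sample_id in sample_ids:
        table = expressed.get(sample_id)
        for subset_name in sorted(subsets) if subsets is not None else ["all"]:
            try:
                if table is None or table.empty:
                    raise CommunityUndefinedError("no expressed traits in sample")
                sub = (subset_traits(table, subsets[subset_name], subset_name=subset_name)
                       if subsets is not None else table)
                expressing = sub.index[(sub > 0).any(axis=1)].astype(str)
                known = [m for m in expressing if m in abundance.columns]
                ab = abundance.loc[sample_id, known]
                candidates = ab[ab > min_abundance]
                if len(candidates) < 2:
                    raise CommunityUndefinedError(
                        f"{len(candidates)} MAG(s) with abundance and expression; need >= 2")
                sub = sub.loc[candidates.index.tolist()]
                n_cells = int((sub.to_numpy() > 0).sum())
                if n_cells < min_expressed_genes:
                    logger.warning("sample %s / subset %s: only %d expressed cells (low support)",
                                   sample_id, subset_name, n_cells)
                values = np.log1p(sub) if log1p else sub
                d = TraitDistanceMatrix(tuple(map(str, sub.index)),
                                        _max_scale(_raw_euclidean(values)))
                if weight == "abundance":
                    profile = relative_abundance(candidates, 0.0)
                else:
                    profile = relative_abundance(sub.sum(axis=1), 0.0)
                result = fred(profile, d, sample_id=sample_id,
                              subset_name=subset_name, mode="expressed")
                rows.append(result.__dict__)
            except (CommunityUndefinedError, UndefinedStatisticError, ValidationError) as exc:
                logger.warning("expressed sample %s / subset %s undefined: %s",
                               sample_id, subset_name, exc)
                rows.append({"sample_id": sample_id, "subset_name": subset_name,
                             "mode": "expressed", "N": 0, "D": np.nan, "Q": np.nan,
                             "U": np.nan, "FRed": np.nan})
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return out.sort_values(["sample_id", "subset_name"], kind="mergesort").reset_index(drop=True)
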