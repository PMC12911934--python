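"""Build and manipulate MAG x trait tables.

Raw annotation hit counts are corrected for genome incompleteness: each
MAG's gene copy number is converted to a percentage of its total genes and
divided by the mean completeness (as a fraction) of quality-filtered MAGs
from the same taxonomic order.  Subsetting restricts the table to a trait
category (energy, substrate, CO/H2/N/S modules, CAZymes, ...).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from magfred.exceptions import ValidationError

logger = logging.getLogger(__name__)

LOG2FC_EPSILON = 1e-8


def order_mean_completeness(meta: pd.DataFrame) -> pd.Series:
    """Mean completeness (%) per taxonomic order over the supplied (filtered) MAGs.

    For a single-MAG order the mean equals that MAG's completeness.
    """
    if "order" not in meta.columns or "completeness" not in meta.columns:
        raise ValidationError("MAG metadata needs 'order' and 'completeness' columns")
    means = meta.groupby("order")["completeness"].mean()
    if ((means <= 0) | (means > 100)).any():
        raise ValidationError("order mean completeness outside (0, 100]")
    return means


def normalize_by_completeness(hits: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Completeness-normalized trait table.

    value(m, t) = 100 * hit(m, t) / total_genes(m) / (mean_completeness(order(m)) / 100)

    where the order mean is computed over the quality-filtered MAGs in
    ``meta`` sharing the MAG's order.  Completeness enters as a fraction, so
    incomplete genomes are corrected upward.

    Parameters
    ----------
    hits
        MAG x trait matrix of non-negative hit counts.
    meta
        MAG metadata indexed by mag_id with ``total_genes``, ``completeness``
        and ``order`` columns; assumed already quality-filtered.
    """
    missing = [m for m in hits.index if m not in meta.index]
    if missing:
        raise ValidationError(f"MAGs without metadata: {missing[:5]}"
                              + ("..." if len(missing) > 5 else ""))
    if (meta.loc[hits.index, "total_genes"] < 1).any():
        raise ValidationError("total_genes must be >= 1 for every MAG")

    means = order_mean_completeness(meta)
    orders = meta.loc[hits.index, "order"]
    unknown_orders = sorted(set(orders) - set(means.index))
    if unknown_orders:
        raise ValidationError(f"orders with no MAGs after filtering: {unknown_orders}")

    total = meta.loc[hits.index, "total_genes"].to_numpy(dtype=float)
    frac = means.loc[orders].to_numpy(dtype=float) / 100.0
    values = 100.0 * hits.to_numpy(dtype=float) / total[:, None] / frac[:, None]
    out = pd.DataFrame(values, index=hits.index, columns=hits.columns)
    # canonical ordering so the result is invariant to input row/column order
    return out.sort_index(axis=0).sort_index(axis=1)


def subset_traits(table: pd.DataFrame, trait_ids: Iterable[str],
                  subset_name: str = "subset") -> pd.DataFrame:
    """Column-filter a trait table to one subset, preserving MAG order.

    Trait ids absent from the table produce a warning (packaged subset lists
    are supersets of any given annotation run); an empty intersection is an
    error.  MAGs whose rows become all-zero are retained — they may still
    carry abundance.
    """
    wanted = list(dict.fromkeys(trait_ids))
    if not wanted:
        raise ValidationError(f"subset '{subset_name}' has no trait ids")
    present = [t for t in wanted if t in table.columns]
    unknown = [t for t in wanted if t not in table.columns]
    if unknown:
        logger.warning("subset '%s': %d trait id(s) absent from the table (e.g. %s)",
                       subset_name, len(unknown), unknown[:3])
    if not present:
        raise ValidationError(f"subset '{subset_name}' shares no traits with the table")
    return table[present]


def _gene_community_abundance(table: pd.DataFrame, abundance: pd.DataFrame,
                              trait: str) -> pd.Series:
    """Per-sample abundance of all MAGs encoding ``trait``.

    Abundance-weighted sum over MAGs with a positive trait value:
    sum_m [value(m, trait) > 0] * abundance(s, m) * value(m, trait).
    """
    if trait not in table.columns:
        raise ValidationError(f"trait '{trait}' not in table")
    values = table[trait]
    carriers = values[values > 0]
    common = [m for m in carriers.index if m in abundance.columns]
    if not common:
        return pd.Series(0.0, index=abundance.index)
    return abundance[common].mul(carriers.loc[common], axis=1).sum(axis=1)


def seasonal_log2fc(table: pd.DataFrame, abundance: pd.DataFrame,
                    samples: pd.DataFrame, trait: str,
                    by_bay: bool = False,
                    transform: str = "log2_ratio",
                    epsilon: float = LOG2FC_EPSILON) -> pd.DataFrame:
    """Spring-vs-summer contrast of one gene's community-level abundance.

    Positive values indicate higher abundance in spring.  ``transform``
    selects ``"log2_ratio"`` (log2 of the ratio of season means, with an
    ``epsilon`` pseudocount) or ``"log10_diff"`` (difference of mean log10
    abundances).  Significance is a two-sided Wilcoxon rank-sum test on the
    per-sample values.  With ``by_bay=True`` the contrast is computed
    separately within each bay.
    """
    from magfred.stats import wilcoxon_rank_sum

    if transform not in ("log2_ratio", "log10_diff"):
        raise ValidationError(f"unknown transform '{transform}'")
    gene_ab = _gene_community_abundance(table, abundance, trait)
    meta = samples.loc[gene_ab.index]

    groups = [(bay, meta[meta["bay"] == bay]) for bay in sorted(meta["bay"].unique())] \
        if by_bay else [("all", meta)]
    rows = []
    for label, sub in groups:
        spring = gene_ab.loc[sub.index[sub["season"] == "spring"]]
        summer = gene_ab.loc[sub.index[sub["season"] == "summer"]]
        for name, vals in (("spring", spring), ("summer", summer)):
            if len(vals) == 0:
                raise ValidationError(f"no {name} samples in group '{label}'")
        if transform == "log2_ratio":
            stat_fc = math.log2((spring.mean() + epsilon) / (summer.mean() + epsilon))
        else:
            stat_fc = float(np.mean(np.log10(spring + epsilon)) - np.mean(np.log10(summer + epsilon)))
        if spring.nunique() == 1 and summer.nunique() == 1 and spring.iloc[0] == summer.iloc[0]:
            p = 1.0  # degenerate constant gene
        else:
            _, p = wilcoxon_rank_sum(spring.to_numpy(), summer.to_numpy())
        rows.append({"trait_id": trait, "group": label, "log2fc": stat_fc, "p": p,
                     "n_spring": len(spring), "n_summer": len(summer)})
    return pd.DataFrame(rows)


def seasonal_log2fc_all(table: pd.DataFrame, abundance: pd.DataFrame,
                        samples: pd.DataFrame, by_bay: bool = False,
                        transform: str = "log2_ratio") -> pd.DataFrame:
    """Seasonal contrasts for every trait, with Benjamini-Hochberg adjusted p."""
    frames = [seasonal_log2fc(table, abundance, samples, t, by_bay=by_bay,
                              transform=transform) for t in table.columns]
    out = pd.concat(frames, ignore_index=True)
    for label, sub in out.groupby("group"):
        out.loc[sub.index, "p_bh"] = _benjamini_hochberg(sub["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out
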