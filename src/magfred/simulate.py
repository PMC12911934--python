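"""Seeded synthetic communities with controlled redundancy structure.

MAGs are organized into g guilds of m members.  Guild centroids are
mutually equidistant one-hot trait blocks, so with zero within-guild noise
and guild-uniform abundances the community FRed has the closed form
(m - 1) / (g m - 1).  Abundances follow a log-linear model of sample
covariates (temperature, season, salinity) with per-guild slopes, and
transcripts are a partially silenced, noisy multinomial read-out of the
encoded traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from magfred.exceptions import ValidationError

# child-seed offsets so stages are independently reproducible
_TRAIT_SEED = 11
_ABUNDANCE_SEED = 23
_TRANSCRIPT_SEED = 37

_SEASON_TEMP = {"spring": 12.0, "summer": 25.0}
_SALINITY_PSU = {"low": 4.0, "medium": 15.0, "high": 28.0}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_guilds: int = 8
    members_per_guild: int = 5
    n_traits: int = 60
    within_guild_noise: float = 0.0  # sd of additive trait noise (counts rounded >= 0)
    centroid_amplitude: int = 6  # hit count at a guild's marker traits
    markers_per_guild: int = 3
    completeness_range: tuple[float, float] = (75.0, 99.0)
    n_samples_per_cell: int = 2  # per (bay x season x salinity_class) cell
    guild_intercepts: tuple[float, ...] | None = None  # per guild, baseline log-abundance
    temperature_slopes: tuple[float, ...] | None = None  # per guild, on z-scored temperature
    season_slopes: tuple[float, ...] | None = None  # per guild, on the summer indicator
    salinity_slopes: tuple[float, ...] | None = None  # per guild, on z-scored salinity
    abundance_noise: float = 0.3  # sd of per-MAG lognormal abundance noise
    expression_probability: float = 0.9  # pi: chance an encoded trait is expressed at all
    activity_mu: float = 0.0
    activity_sigma: float = 0.5  # lognormal activity of expressed genes
    reads_per_sample: int = 200_000
    gene_length_range: tuple[int, int] = (500, 2000)

    def __post_init__(self) -> None:
        if self.n_guilds < 1 or self.members_per_guild < 1:
            raise ValidationError("need n_guilds >= 1 and members_per_guild >= 1")
        if self.n_guilds * self.members_per_guild < 2:
            raise ValidationError("need at least 2 MAGs (g*m >= 2)")
        if self.n_traits < self.n_guilds * self.markers_per_guild:
            raise ValidationError("n_traits too small for one marker block per guild")
        lo, hi = self.completeness_range
        if not (70.0 < lo <= hi <= 100.0):
            raise ValidationError("completeness_range must lie in (70, 100]")
        if not 0.0 <= self.expression_probability <= 1.0:
            raise ValidationError("expression_probability must be in [0, 1]")
        if self.within_guild_noise < 0 or self.abundance_noise < 0 or self.activity_sigma < 0:
            raise ValidationError("noise parameters must be >= 0")
        for name in ("guild_intercepts", "temperature_slopes", "season_slopes", "salinity_slopes"):
            slopes = getattr(self, name)
            if slopes is not None and len(slopes) != self.n_guilds:
                raise ValidationError(f"{name} must have one slope per guild")

    def slopes(self, name: str) -> np.ndarray:
        values = getattr(self, name)
        return np.zeros(self.n_guilds) if values is None else np.asarray(values, dtype=float)


@dataclass(frozen=True)
class SyntheticTruth:
    guild_of: dict[str, int]
    expected_fred: float  # (m-1)/(gm-1), exact when noise = 0 and abundances guild-uniform
    temperature_slopes: tuple[float, ...]
    season_slopes: tuple[float, ...]
    salinity_slopes: tuple[float, ...]


def _mag_ids(config: SimulationConfig) -> list[str]:
    return [f"mag_g{g:02d}_m{m:02d}" for g in range(config.n_guilds)
            for m in range(config.members_per_guild)]


def simulate_trait_table(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Guild-structured MAG x trait hit table plus metadata and ground truth.

    Each guild owns a disjoint block of marker traits set to
    ``centroid_amplitude``; members add rounded, clipped Gaussian noise.
    All between-guild centroid distances are equal, hence 1 after
    max-scaling; within-guild distances are 0 at zero noise.
    """
    rng = np.random.default_rng(config.seed + _TRAIT_SEED)
    g, m, k = config.n_guilds, config.members_per_guild, config.markers_per_guild
    mags = _mag_ids(config)
    traits = [f"gene{t:03d}" for t in range(config.n_traits)]

    centroids = np.zeros((g, config.n_traits))
    for guild in range(g):
        centroids[guild, guild * k:(guild + 1) * k] = config.centroid_amplitude

    values = np.repeat(centroids, m, axis=0)
    if config.within_guild_noise > 0:
        noise = rng.normal(0.0, config.within_guild_noise, size=values.shape)
        values = np.clip(np.rint(values + noise), 0, None)
    table = pd.DataFrame(values, index=mags, columns=traits)
    table.index.name = "mag_id"
    table.columns.name = "trait_id"

    lo, hi = config.completeness_range
    meta = pd.DataFrame({
        "total_genes": rng.integers(1500, 3500, size=len(mags)),
        "completeness": rng.uniform(lo, hi, size=len(mags)),
        "contamination": rng.uniform(0.0, 4.0, size=len(mags)),
        "order": [f"Order_g{i // m:02d}" for i in range(len(mags))],
        "fraction": ["PA" if i % 2 == 0 else "FL" for i in range(len(mags))],
    }, index=pd.Index(mags, name="mag_id"))

    truth = SyntheticTruth(
        guild_of={mag: i // m for i, mag in enumerate(mags)},
        expected_fred=(m - 1) / (g * m - 1),
        temperature_slopes=tuple(config.slopes("temperature_slopes")),
        season_slopes=tuple(config.slopes("season_slopes")),
        salinity_slopes=tuple(config.slopes("salinity_slopes")),
    )
    return table, meta, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_abundances(config: SimulationConfig,
                        truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x MAG relative abundance matrix driven by sample covariates.

    log-abundance(i, s) = sum of per-guild slopes times (z-scored
    temperature, summer indicator, z-scored salinity) plus Gaussian noise,
    then a per-sample softmax.  The design crosses bay x season x
    salinity_class with ``n_samples_per_cell`` replicates per cell.
    """
    rng = np.random.default_rng(config.seed + _ABUNDANCE_SEED)
    mags = list(truth.guild_of)
    guilds = np.array([truth.guild_of[m] for m in mags])

    records = []
    idx = 0
    for bay in ("Chesapeake", "Delaware"):
        for season in ("spring", "summer"):
            for sal_class in ("low", "medium", "high"):
                for rep in range(config.n_samples_per_cell):
                    temp = _SEASON_TEMP[season] + rng.uniform(-4.0, 4.0)
                    sal = max(_SALINITY_PSU[sal_class] + rng.uniform(-2.0, 2.0), 0.1)
                    records.append({
                        "sample_id": f"S{idx:03d}_{bay[:2]}_{season[:3]}_{sal_class}",
                        "bay": bay, "season": season, "salinity_class": sal_class,
                        "fraction": "PA" if rep % 2 == 0 else "FL",
                        "temperature": temp, "salinity": sal,
                        "nitrate": float(rng.lognormal(0.5, 0.6)),
                        "phosphate": float(rng.lognormal(-1.0, 0.5)),
                        "silicate": float(rng.lognormal(1.0, 0.6)),
                        "ammonium": float(rng.lognormal(-0.5, 0.5)),
                        "chlorophyll_a": float(rng.lognormal(1.2, 0.7)),
                        "cell_count": float(rng.lognormal(13.0, 0.4)),
                    })
                    idx += 1
    samples = pd.DataFrame(records).set_index("sample_id")

    z_temp = _zscore(samples["temperature"].to_numpy())
    z_sal = _zscore(samples["salinity"].to_numpy())
    summer = (samples["season"] == "summer").to_numpy(dtype=float)

    beta_t = config.slopes("temperature_slopes")[guilds]
    beta_s = config.slopes("season_slopes")[guilds]
    beta_z = config.slopes("salinity_slopes")[guilds]
    intercept = config.slopes("guild_intercepts")[guilds]
    log_ab = (intercept[None, :] + np.outer(z_temp, beta_t)
              + np.outer(summer, beta_s) + np.outer(z_sal, beta_z))
    if config.abundance_noise > 0:
        log_ab = log_ab + rng.normal(0.0, config.abundance_noise, size=log_ab.shape)
    log_ab = log_ab - log_ab.max(axis=1, keepdims=True)
    weights = np.exp(log_ab)
    abundance = pd.DataFrame(weights / weights.sum(axis=1, keepdims=True),
                             index=samples.index, columns=mags)
    abundance.columns.name = "mag_id"
    return abundance, samples


def simulate_transcripts(config: SimulationConfig, table: pd.DataFrame,
                         abundance: pd.DataFrame) -> pd.DataFrame:
    """Transcript counts: silenced Bernoulli(pi) genes, lognormal activity,
    multinomial reads at the configured depth.

    One gene variant per encoded (MAG, trait) cell; expression status,
    activity, and gene length are drawn once per gene; per-sample expected
    rates are abundance(sample, MAG) * encoded value * activity.  Every
    sample with a positive total rate receives exactly ``reads_per_sample``
    reads.
    """
    rng = np.random.default_rng(config.seed + _TRANSCRIPT_SEED)
    lo, hi = config.gene_length_range
    genes = []
    for mag in table.index:
        for trait in table.columns:
            encoded = table.loc[mag, trait]
            if encoded <= 0:
                continue
            genes.append({
                "gene_id": f"{mag}|{trait}",
                "mag_id": mag, "trait_id": trait,
                "encoded": float(encoded),
                "gene_length": int(rng.integers(lo, hi + 1)),
                "expressed": bool(rng.random() < config.expression_probability),
                "activity": float(rng.lognormal(config.activity_mu, config.activity_sigma)),
            })
    gene_df = pd.DataFrame(genes)
    expressed = gene_df[gene_df["expressed"]].reset_index(drop=True)
    rows = []
    for sample_id in abundance.index:
        if expressed.empty:
            continue
        ab = abundance.loc[sample_id, expressed["mag_id"]].to_numpy(dtype=float)
        rates = ab * expressed["encoded"].to_numpy() * expressed["activity"].to_numpy()
        total = rates.sum()
        counts = (rng.multinomial(config.reads_per_sample, rates / total)
                  if total > 0 else np.zeros(len(rates), dtype=int))
        for gene, length, trait, mag, c in zip(expressed["gene_id"], expressed["gene_length"],
                                               expressed["trait_id"], expressed["mag_id"], counts):
            rows.append({"sample_id": sample_id, "gene_id": gene, "mag_id": mag,
                         "trait_id": trait, "gene_length": int(length),
                         "read_count": int(c)})
    columns = ["sample_id", "gene_id", "mag_id", "trait_id", "gene_length", "read_count"]
    return pd.DataFrame(rows, columns=columns)


def simulate_all(config: SimulationConfig) -> dict:
    """Run all three stages; returns dict with table, meta, truth, abundance, samples, transcripts."""
    table, meta, truth = simulate_trait_table(config)
    abundance, samples = simulate_abundances(config, truth)
    transcripts = simulate_transcripts(config, table, abundance)
    return {"table": table, "meta": meta, "truth": truth,
            "abundance": abundance, "samples": samples, "transcripts": transcripts}
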