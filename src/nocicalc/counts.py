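"""Synthetic gene-level count matrices with planted differential expression.

Emulates a targeted-sequencing maturation time course: negative-binomial
counts for ``n_genes`` genes across ``n_timepoints`` time points with
``n_replicates`` independent differentiations each.  A configurable fraction
of genes is planted as differentially expressed relative to the first time
point, with signed log2 fold changes drawn uniformly from a range.  The truth
table records every planted effect so that the differential-expression filter
and the gene-set activation scores can be tested against known answers.

Counts are gamma-Poisson (negative-binomial) with a single shared dispersion;
in the dispersion → 0 limit the simulator reduces to Poisson sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["SimCountsConfig", "simulate_counts"]


@dataclass(frozen=True)
class SimCountsConfig:
    """Configuration of a simulated count matrix.

    ``effect_profile`` chooses how a planted log2FC unfolds over time:
    ``"constant"`` applies the full effect at every non-baseline time point;
    ``"ramp"`` grows it linearly from 0 at baseline to the full value at the
    last time point, emulating a maturation gradient.
    """

    n_genes: int = 2000
    n_timepoints: int = 7
    n_replicates: int = 3
    library_size_mean: float = 1_000_000.0
    library_size_cv: float = 0.05  # relative spread of per-sample sequencing depth
    dispersion: float = 0.1
    deg_fraction: float = 0.05
    effect_log2fc_range: tuple[float, float] = (1.0, 3.0)
    effect_profile: str = "constant"
    geneset_definitions: Mapping[str, Sequence[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_timepoints < 1 or self.n_replicates < 1:
            raise ConfigError("n_genes, n_timepoints and n_replicates must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive (use a tiny value for ~Poisson)")
        if self.library_size_cv < 0:
            raise ConfigError("library_size_cv must be non-negative")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ConfigError("deg_fraction must lie in [0, 1]")
        lo, hi = self.effect_log2fc_range
        if lo > hi:
            raise ConfigError("effect_log2fc_range must satisfy lo <= hi")
        if self.effect_profile not in ("constant", "ramp"):
            raise ConfigError(f"unknown effect_profile {self.effect_profile!r}")
        gene_ids = {f"g{i:05d}" for i in range(self.n_genes)}
        for set_name, members in self.geneset_definitions.items():
            unknown = set(members) - gene_ids
            if unknown:
                raise ConfigError(
                    f"gene set {set_name!r} references unknown gene ids: {sorted(unknown)[:5]}"
                )

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


def simulate_counts(
    cfg: SimCountsConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate counts and return ``(counts, sample_meta, truth)``.

    Returns
    -------
    counts
        genes × samples integer DataFrame; sample ids ``tp{t}_rep{r}``.
    sample_meta
        One row per sample with ``sample``, ``timepoint`` (0-based index) and
        ``replicate`` columns.
    truth
        One row per planted DEG: ``gene`` and the signed final ``log2fc``
        relative to the first time point. Empty when ``deg_fraction`` is 0.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids()

    # per-gene relative abundance on a realistic lognormal scale
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.n_genes)
    base_prop = weights / weights.sum()

    n_deg = int(round(cfg.deg_fraction * cfg.n_genes))
    deg_idx = rng.choice(cfg.n_genes, size=n_deg, replace=False)
    lo, hi = cfg.effect_log2fc_range
    magnitudes = rng.uniform(lo, hi, size=n_deg)
    signs = rng.choice((-1.0, 1.0), size=n_deg)
    planted_lfc = np.zeros(cfg.n_genes)
    planted_lfc[deg_idx] = signs * magnitudes

    columns: list[str] = []
    meta_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    for t in range(cfg.n_timepoints):
        if t == 0:
            factor = 0.0
        elif cfg.effect_profile == "constant":
            factor = 1.0
        else:
            factor = t / (cfg.n_timepoints - 1) if cfg.n_timepoints > 1 else 1.0
        prop_t = base_prop * np.power(2.0, planted_lfc * factor)
        prop_t = prop_t / prop_t.sum()
        for r in range(cfg.n_replicates):
            if cfg.library_size_cv > 0:
                lib = rng.lognormal(np.log(cfg.library_size_mean), cfg.library_size_cv)
            else:
                lib = cfg.library_size_mean
            mu = prop_t * lib
            if cfg.dispersion > 1e-8:
                lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
            else:
                lam = mu
            blocks.append(rng.poisson(lam))
            sample = f"tp{t}_rep{r}"
            columns.append(sample)
            meta_rows.append({"sample": sample, "timepoint": t, "replicate": r})

    counts = pd.DataFrame(np.column_stack(blocks), index=genes, columns=columns)
    counts.index.name = "gene"
    sample_meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        {"gene": [genes[i] for i in deg_idx], "log2fc": planted_lfc[deg_idx]}
    ).sort_values("gene", ignore_index=True)
    return counts, sample_meta, truth
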