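"""CPM, differential expression, gene-set over-representation and activation scores.

This chain summarises a maturation time-course transcriptome (gene-level
counts across time points with independent differentiations as replicates):

1. counts → CPM (counts per million reads of the sample);
2. per time point vs a baseline time point: log2 fold change of mean CPM
   (with pseudocount), a per-gene two-sample test on log2(CPM + 1), BH
   adjustment across genes, and the DEG filter
   (adjusted p < 0.05 AND linear fold change ≥ 2, i.e. |log2FC| ≥ 1);
3. hypergeometric over-representation of gene sets among the DEGs, BH across
   sets ("oGO" = over-represented set at adjusted p < 0.05);
4. per-set activation score = (% of measured set members that are DEGs) ×
   (mean |log2FC| of those DEG members);
5. superordinate-group trajectories: mean ± SEM of member-set scores per time
   point, tested against a reference time point by paired t-test over sets.

The differential-expression step is a deliberately simple stand-in for a
negative-binomial GLM framework: a Welch t-test on log2(CPM + 1).  It is
adequate for planted-effect recovery and keeps the filter semantics exact;
externally computed p-values can be supplied to bypass it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, StatisticsError

__all__ = [
    "GeneSet",
    "GeneSetScore",
    "compute_cpm",
    "bh_adjust",
    "differential_expression",
    "over_representation",
    "find_overrepresented",
    "activation_score",
    "score_matrix",
    "group_trajectories",
    "top_variable_pca",
    "read_gmt",
    "write_gmt",
]

SUPERORDINATE_GROUPS = (
    "Synapse signaling",
    "Neurotransmitter",
    "Receptors Channels Transporters",
    "Morphogenesis",
    "other",
)


@dataclass(frozen=True)
class GeneSet:
    """A gene-ontology-style set with an optional superordinate group."""

    set_id: str
    name: str
    members: tuple[str, ...]
    group: str = "other"

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.set_id!r} has no members")

    def measured(self, measured_genes: Sequence[str]) -> tuple[str, ...]:
        measured_set = set(measured_genes)
        return tuple(g for g in self.members if g in measured_set)


@dataclass(frozen=True)
class GeneSetScore:
    """Activation score of one gene set at one time point.

    ``score = pct_significant × mean_fold_change`` where ``pct_significant``
    is the percentage of measured members that are DEGs and
    ``mean_fold_change`` the mean |log2FC| over those DEG members.
    """

    set_id: str
    timepoint: object
    score: float
    pct_significant: float
    mean_fold_change: float


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count / sample total × 1e6, per sample (column)."""
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise InputError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InputError(f"sample(s) with zero total reads: {bad}")
    return counts.div(totals, axis=1) * 1e6


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _moderated_t_test(x: np.ndarray, y: np.ndarray, prior_df: float) -> np.ndarray:
    """Per-row moderated t-test of x vs y (rows = genes, columns = replicates).

    Pools the within-group variance per gene, shrinks it toward the mean
    pooled variance over all genes with ``prior_df`` prior observations, and
    refers the statistic to a t distribution with residual + prior df.
    """
    n1, n2 = x.shape[1], y.shape[1]
    d = n1 + n2 - 2
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    s2_prior = float(np.mean(s2))
    s2_mod = (prior_df * s2_prior + d * s2) / (prior_df + d)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(axis=1) - y.mean(axis=1)) / se
    p = 2.0 * stats.t.sf(np.abs(t), df=d + prior_df)
    return np.where(np.isnan(p), 1.0, p)


def differential_expression(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    baseline: object | None = None,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    p_values: pd.DataFrame | None = None,
    moderation_df: float | None = 10.0,
) -> pd.DataFrame:
    """Per-gene expression statistics for every time point vs a baseline.

    Parameters
    ----------
    counts
        genes × samples count matrix.
    sample_meta
        Columns ``sample``, ``timepoint`` (and optionally ``replicate``).
    baseline
        Baseline time point; defaults to the smallest/earliest label.
    pseudocount
        Added to CPM before log2, for both fold changes and tests.
    p_values
        Optional genes × timepoints table of externally computed p-values
        (e.g. from a negative-binomial model) that replaces the built-in
        two-sample test.
    alpha, min_abs_log2fc
        The DEG filter: adjusted p < ``alpha`` AND |log2FC| ≥ ``min_abs_log2fc``
        (the default corresponds to a linear fold change of 2).
    moderation_df
        Prior degrees of freedom for empirical-Bayes variance moderation: each
        gene's pooled variance is shrunk toward the genome-wide mean variance
        with this weight, and the t-test gains the prior df.  Small replicate
        numbers (2–3 differentiations) make an unmoderated per-gene test
        hopelessly underpowered after multiplicity adjustment.  ``None``
        switches to a plain Welch t-test.

    Returns
    -------
    Tidy DataFrame with one row per (gene, non-baseline timepoint):
    ``gene, timepoint, cpm, log2fc, fc, p_value, p_adjusted, is_deg``.
    BH adjustment is applied across genes within each time point.
    """
    meta = sample_meta.set_index("sample")
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise InputError(f"samples missing from metadata: {missing[:5]}")
    timepoints = sorted(meta.loc[list(counts.columns), "timepoint"].unique().tolist())
    if baseline is None:
        baseline = timepoints[0]
    if baseline not in timepoints:
        raise InputError(f"baseline time point {baseline!r} not present in the data")

    cpm = compute_cpm(counts)
    log_cpm = np.log2(cpm + pseudocount)
    samples_at = {
        t: [s for s in counts.columns if meta.at[s, "timepoint"] == t] for t in timepoints
    }
    if len(samples_at[baseline]) < 2:
        raise InputError("baseline needs >= 2 replicates")

    base_mean_cpm = cpm[samples_at[baseline]].mean(axis=1)
    base_log = log_cpm[samples_at[baseline]]
    frames = []
    for t in timepoints:
        if t == baseline:
            continue
        cols = samples_at[t]
        if len(cols) < 2:
            raise InputError(f"time point {t!r} needs >= 2 replicates")
        mean_cpm = cpm[cols].mean(axis=1)
        log2fc = np.log2((mean_cpm + pseudocount) / (base_mean_cpm + pseudocount))
        if p_values is not None:
            p = p_values.loc[counts.index, t].to_numpy(dtype=float)
        elif moderation_df is not None:
            p = _moderated_t_test(log_cpm[cols].to_numpy(), base_log.to_numpy(),
                                  prior_df=moderation_df)
        else:
            with np.errstate(invalid="ignore"):
                res = stats.ttest_ind(
                    log_cpm[cols].to_numpy(), base_log.to_numpy(), axis=1, equal_var=False
                )
            p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        p_adj = bh_adjust(p)
        frames.append(
            pd.DataFrame(
                {
                    "gene": counts.index,
                    "timepoint": t,
                    "cpm": mean_cpm.to_numpy(),
                    "log2fc": log2fc.to_numpy(),
                    "fc": np.power(2.0, log2fc.to_numpy()),
                    "p_value": p,
                    "p_adjusted": p_adj,
                }
            )
        )
    stats_df = pd.concat(frames, ignore_index=True)
    stats_df["is_deg"] = (stats_df["p_adjusted"] < alpha) & (
        stats_df["log2fc"].abs() >= min_abs_log2fc
    )
    return stats_df


def over_representation(deg_set: set[str], gene_set: Sequence[str], universe: Sequence[str]) -> float:
    """One-sided hypergeometric tail P(X ≥ k) for gene-set enrichment in the DEGs.

    ``k`` is the observed overlap between the DEGs and the set, drawing
    ``len(deg_set ∩ universe)`` genes from a universe containing
    ``len(set ∩ universe)`` set members.
    """
    universe_set = set(universe)
    if not universe_set:
        raise InputError("empty gene universe")
    degs = set(deg_set) & universe_set
    members = set(gene_set) & universe_set
    k = len(degs & members)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, len(universe_set), len(members), len(degs)))


def find_overrepresented(
    deg_set: set[str],
    gene_sets: Sequence[GeneSet],
    universe: Sequence[str],
    alpha: float = 0.05,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Enrichment of every set among the DEGs, BH-adjusted across sets.

    Sets with adjusted p < ``alpha`` are flagged over-represented (``is_ogo``);
    with ``top_n`` the flagged sets are additionally restricted to the ``n``
    lowest-p sets (rank-and-take, mirroring a "Top50" style selection).
    """
    rows = []
    for gs in gene_sets:
        p = over_representation(deg_set, gs.members, universe)
        overlap = len(set(deg_set) & set(gs.members) & set(universe))
        rows.append({"set_id": gs.set_id, "name": gs.name, "group": gs.group,
                     "n_members": len(gs.measured(universe)), "n_deg_members": overlap,
                     "p_value": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(p_adjusted=[], is_ogo=[])
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    df["is_ogo"] = df["p_adjusted"] < alpha
    if top_n is not None:
        ranked = df.sort_values("p_value").index[:top_n]
        df["is_ogo"] = df["is_ogo"] & df.index.isin(ranked)
    return df.sort_values("p_value", ignore_index=True)


def activation_score(
    gene_set: GeneSet,
    stats_at_timepoint: pd.DataFrame,
    fc_mode: str = "abs_log2",
) -> GeneSetScore:
    """Activation score of one set at one time point.

    ``stats_at_timepoint`` holds the per-gene statistics of a single time
    point (columns ``gene``, ``is_deg``, ``log2fc``, ``fc``).  The percentage
    denominator is the set members *measured* in the table; the fold-change
    factor averages, over the DEG members only, |log2FC| (default), the signed
    log2FC (``"signed_log2"``) or the linear FC (``"linear"``).  A set with no
    measured members has no defined score and raises :class:`InputError`.
    """
    if fc_mode not in ("abs_log2", "signed_log2", "linear"):
        raise InputError(f"unknown fc_mode {fc_mode!r}")
    table = stats_at_timepoint.set_index("gene")
    measured = gene_set.measured(table.index)
    if not measured:
        raise InputError(f"gene set {gene_set.set_id!r} has no measured members")
    sub = table.loc[list(measured)]
    deg = sub[sub["is_deg"].astype(bool)]
    pct = 100.0 * len(deg) / len(measured)
    if len(deg) == 0:
        mean_fc = 0.0
    elif fc_mode == "abs_log2":
        mean_fc = float(deg["log2fc"].abs().mean())
    elif fc_mode == "signed_log2":
        mean_fc = float(deg["log2fc"].mean())
    else:
        mean_fc = float(deg["fc"].mean())
    tp = stats_at_timepoint["timepoint"].iloc[0] if "timepoint" in stats_at_timepoint else None
    return GeneSetScore(
        set_id=gene_set.set_id,
        timepoint=tp,
        score=pct * mean_fc,
        pct_significant=pct,
        mean_fold_change=mean_fc,
    )


def score_matrix(
    gene_sets: Sequence[GeneSet],
    stats_df: pd.DataFrame,
    fc_mode: str = "abs_log2",
) -> pd.DataFrame:
    """Activation scores for every (set, time point): sets × time points."""
    timepoints = sorted(stats_df["timepoint"].unique().tolist())
    data = {
        t: [
            activation_score(gs, stats_df[stats_df["timepoint"] == t], fc_mode=fc_mode).score
            for gs in gene_sets
        ]
        for t in timepoints
    }
    return pd.DataFrame(data, index=[gs.set_id for gs in gene_sets]).rename_axis("set_id")


def group_trajectories(
    scores: pd.DataFrame,
    group_map: Mapping[str, str],
    reference_timepoint: object,
) -> pd.DataFrame:
    """Superordinate-group score trajectories with testing vs a reference time point.

    ``scores`` is a sets × time points matrix; ``group_map`` maps set id →
    group.  Per group and time point the mean and SEM over member-set scores
    are reported, plus the p-value of a paired t-test (pairing by set) of that
    time point's member scores against the reference time point.  Groups with
    a single member have undefined SEM (NaN); the reference time point itself
    gets p = NaN.
    """
    if reference_timepoint not in scores.columns:
        raise StatisticsError(f"reference time point {reference_timepoint!r} not in scores")
    rows = []
    for group in sorted(set(group_map.values())):
        members = [s for s in scores.index if group_map.get(s) == group]
        if not members:
            continue
        sub = scores.loc[members]
        ref = sub[reference_timepoint].to_numpy()
        for t in scores.columns:
            vals = sub[t].to_numpy()
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            if t == reference_timepoint or len(vals) < 2:
                p = float("nan")
            else:
                diff = vals - ref
                if np.allclose(diff, diff[0]):
                    # zero-variance differences: identical scores → null; constant
                    # nonzero shift → unambiguous difference
                    p = 1.0 if abs(diff[0]) < 1e-12 else 0.0
                else:
                    p = float(stats.ttest_rel(vals, ref).pvalue)
            rows.append({"group": group, "timepoint": t, "mean_score": mean,
                         "sem": sem, "n_sets": len(vals), "p_vs_reference": p})
    return pd.DataFrame(rows)


def top_variable_pca(cpm: pd.DataFrame, n: int = 500) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the ``n`` most variable genes of log2(CPM + 1).

    Genes are ranked by variance across samples; the selected block is
    gene-centred and decomposed by SVD.  Returns the sample coordinates on the
    first two components and the explained-variance fractions of all
    components.  ``n`` larger than the gene count is clamped with a warning.
    """
    if cpm.shape[1] < 3:
        raise InputError("PCA needs at least 3 samples")
    if n > cpm.shape[0]:
        warnings.warn(
            f"requested {n} genes but only {cpm.shape[0]} available; clamping",
            stacklevel=2,
        )
        n = cpm.shape[0]
    log_cpm = np.log2(cpm.astype(float) + 1.0)
    variances = log_cpm.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False).index[:n]
    block = log_cpm.loc[top].to_numpy().T  # samples × genes
    centered = block - block.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    coords = centered @ vt[:2].T
    total_var = (s**2).sum()
    explained = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    out = pd.DataFrame(coords, index=cpm.columns, columns=["PC1", "PC2"])
    return out, explained


def read_gmt(path: str | Path, group_map: Mapping[str, str] | None = None) -> list[GeneSet]:
    """Read gene sets from a GMT file (set id, description, members...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"malformed GMT line: {line[:60]!r}")
        set_id, name, *members = parts
        group = group_map.get(set_id, "other") if group_map else "other"
        sets.append(GeneSet(set_id=set_id, name=name, members=tuple(members), group=group))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.set_id, gs.name, *gs.members]) for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
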