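"""The binary reactivity endpoint: noise thresholds, calls, fractions, overlap.

The primary functional endpoint of the assay is the *fraction of reactive
cells* in a stimulated well.  A cell is called reactive when its stimulus-
evoked fluorescence change ΔF strictly exceeds a well-specific threshold

    T = min(mean(ΔF_control) + 3 · SD(ΔF_control), cap)        (cap = 18)

where ΔF_control is the fluorescence change evoked by negative-control
(HBSS) stimulation — either the HBSS pre-stimulus of the same well or, when
absent, pooled matched control wells.  The cap keeps wells with pathologically
noisy (or genuinely responsive) controls from silencing real responses.
Ties at the threshold are non-reactive (strict inequality).

Downstream summaries follow the experimental hierarchy: technical replicates
(wells) are averaged within a biological replicate (independent cell
preparation) before cross-replicate means, SEMs and significance tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    EmptyWellError,
    InsufficientControlError,
    PairingError,
    StatisticsError,
)

__all__ = [
    "DEFAULT_CAP",
    "ReactivityThreshold",
    "WellSummary",
    "ReplicateSummary",
    "OverlapSummary",
    "compute_threshold",
    "classify",
    "fraction_reactive",
    "summarize_replicates",
    "double_stim_overlap",
    "compare_conditions",
    "well_thresholds",
]

#: Upper limit on the noise-based threshold, in raw ΔF intensity units.
DEFAULT_CAP = 18.0


@dataclass(frozen=True)
class ReactivityThreshold:
    """Well-specific reactivity threshold with its provenance."""

    well_id: str
    value: float
    control_mean: float
    control_sd: float
    cap: float = DEFAULT_CAP
    capped: bool = False


@dataclass(frozen=True)
class WellSummary:
    """Reactive-cell count and fraction for one (well, stimulus)."""

    well_id: str
    stimulus: str
    n_cells: int
    n_reactive: int

    @property
    def fraction_reactive(self) -> float:
        return self.n_reactive / self.n_cells


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean ± SEM of per-biological-replicate reactive fractions for one condition."""

    condition: str
    fractions: tuple[float, ...]
    mean: float
    sem: float  # NaN when only one biological replicate is available

    @property
    def n_replicates(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class OverlapSummary:
    """Cross-tabulated double-stimulation outcome, as fractions of all cells."""

    fraction_both: float
    fraction_A_only: float
    fraction_B_only: float
    fraction_neither: float
    n_cells: int

    def as_dict(self) -> dict[str, float]:
        return {
            "both": self.fraction_both,
            "A_only": self.fraction_A_only,
            "B_only": self.fraction_B_only,
            "neither": self.fraction_neither,
        }


def compute_threshold(
    control_delta_f: Sequence[float],
    cap: float = DEFAULT_CAP,
    well_id: str = "",
) -> ReactivityThreshold:
    """Noise-based threshold: min(mean + 3·SD, cap) over control-stimulation ΔF.

    The SD is the sample standard deviation (n − 1 denominator).  At least two
    control values are required; a negative cap is a configuration error.
    """
    if cap < 0:
        raise ConfigError("threshold cap must be non-negative")
    values = np.asarray(control_delta_f, dtype=float)
    if values.size < 2:
        raise InsufficientControlError(
            f"need >= 2 control ΔF values to estimate noise, got {values.size}"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    naive = mean + 3.0 * sd
    capped = naive > cap
    return ReactivityThreshold(
        well_id=well_id,
        value=min(naive, cap),
        control_mean=mean,
        control_sd=sd,
        cap=cap,
        capped=capped,
    )


def well_thresholds(
    delta_f: pd.DataFrame,
    well_metadata: pd.DataFrame,
    control_stimulus: str = "HBSS",
    cap: float = DEFAULT_CAP,
) -> dict[str, ReactivityThreshold]:
    """One threshold per well, preferring the same-well control stimulus.

    ``delta_f`` is a tidy table with columns ``well_id``, ``cell_id``,
    ``stimulus``, ``delta_f``; ``well_metadata`` has ``well_id``, ``plate`` and
    boolean ``is_control``.  A well containing the control stimulus uses its
    own control ΔF sample; otherwise the ΔF values of the control wells of the
    same plate are pooled.  Wells with neither source raise
    :class:`PairingError`.
    """
    required = {"well_id", "stimulus", "delta_f"}
    if not required <= set(delta_f.columns):
        raise PairingError(f"delta_f table must have columns {sorted(required)}")
    meta = well_metadata.set_index("well_id")
    out: dict[str, ReactivityThreshold] = {}
    for well, sub in delta_f.groupby("well_id"):
        own = sub.loc[sub["stimulus"] == control_stimulus, "delta_f"]
        if len(own) >= 2:
            out[str(well)] = compute_threshold(own.to_numpy(), cap=cap, well_id=str(well))
            continue
        if well not in meta.index:
            raise PairingError(f"well {well!r} missing from metadata and has no control stimulus")
        plate = meta.at[well, "plate"]
        control_wells = meta.index[(meta["plate"] == plate) & meta["is_control"].astype(bool)]
        pooled = delta_f.loc[delta_f["well_id"].isin(control_wells), "delta_f"]
        if len(pooled) < 2:
            raise PairingError(
                f"no same-well control stimulus and no matched control wells for well {well!r}"
            )
        out[str(well)] = compute_threshold(pooled.to_numpy(), cap=cap, well_id=str(well))
    return out


def classify(delta_f: pd.DataFrame, threshold: ReactivityThreshold) -> pd.DataFrame:
    """Binary reactive/non-reactive calls: reactive ⇔ ΔF > threshold (strict).

    Accepts a tidy ΔF table (columns ``cell_id``, ``stimulus``, ``delta_f``)
    and returns it with a boolean ``reactive`` column appended.
    """
    if "delta_f" not in delta_f.columns:
        raise PairingError("delta_f table must have a 'delta_f' column")
    calls = delta_f.copy()
    calls["reactive"] = calls["delta_f"].to_numpy() > threshold.value
    return calls


def fraction_reactive(calls: pd.DataFrame, well_id: str = "", stimulus: str | None = None) -> WellSummary:
    """Exact reactive-cell fraction of one well (optionally one stimulus)."""
    sub = calls if stimulus is None else calls[calls["stimulus"] == stimulus]
    n = len(sub)
    if n == 0:
        raise EmptyWellError("cannot summarise a well with no calls")
    n_reactive = int(sub["reactive"].sum())
    label = stimulus if stimulus is not None else (
        sub["stimulus"].iloc[0] if sub["stimulus"].nunique() == 1 else "all"
    )
    return WellSummary(well_id=well_id, stimulus=str(label), n_cells=n, n_reactive=n_reactive)


def summarize_replicates(
    well_fractions: pd.DataFrame,
    condition: str | None = None,
) -> ReplicateSummary:
    """Condition mean ± SEM over biological replicates.

    ``well_fractions`` is tidy with columns ``condition``, ``replicate``
    (biological replicate id) and ``fraction_reactive``; technical replicates
    (multiple wells per biological replicate) are averaged first.  SEM is
    sd/√n over biological replicates and NaN when n = 1.
    """
    df = well_fractions
    if condition is not None:
        df = df[df["condition"] == condition]
    if df.empty:
        raise StatisticsError(f"no wells for condition {condition!r}")
    label = condition if condition is not None else str(df["condition"].iloc[0])
    per_bio = df.groupby("replicate")["fraction_reactive"].mean()
    fractions = tuple(float(v) for v in per_bio)
    mean = float(per_bio.mean())
    sem = float(per_bio.std(ddof=1) / math.sqrt(len(per_bio))) if len(per_bio) > 1 else float("nan")
    return ReplicateSummary(condition=label, fractions=fractions, mean=mean, sem=sem)


def double_stim_overlap(calls_A: pd.DataFrame, calls_B: pd.DataFrame) -> OverlapSummary:
    """Overlap of responders to two sequential stimuli on the same cells.

    Cross-tabulates the two binary calls per cell and normalises by the number
    of cells; the four fractions sum to 1.
    """
    a = calls_A.set_index("cell_id")["reactive"]
    b = calls_B.set_index("cell_id")["reactive"]
    if set(a.index) != set(b.index) or len(a) != len(b):
        raise PairingError("double stimulation requires the same cell set for both calls")
    if a.index.has_duplicates or b.index.has_duplicates:
        raise PairingError("duplicate cell ids in call table")
    b = b.reindex(a.index)
    n = len(a)
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = n - both - a_only - b_only
    return OverlapSummary(
        fraction_both=both / n,
        fraction_A_only=a_only / n,
        fraction_B_only=b_only / n,
        fraction_neither=neither / n,
        n_cells=n,
    )


def compare_conditions(
    fractions_by_condition: Mapping[str, Sequence[float]],
    reference: str,
    design: str = "unpaired",
    posthoc: str = "dunnett",
) -> pd.DataFrame:
    """Significance of each condition against a reference condition.

    Two conditions → two-sample t-test (paired when ``design="paired"``).
    Three or more → one-way ANOVA followed by Dunnett-style many-to-one
    comparison against ``reference`` (or all-pairs Tukey HSD, reported only
    for the reference contrasts, when ``posthoc="tukey"``).

    Returns a DataFrame with one row per non-reference condition and columns
    ``condition``, ``p_value``, ``significant`` (α = 0.05).
    """
    if reference not in fractions_by_condition:
        raise StatisticsError(f"reference condition {reference!r} not present")
    groups = {k: np.asarray(v, dtype=float) for k, v in fractions_by_condition.items()}
    for name, vals in groups.items():
        if vals.size < 2:
            raise StatisticsError(f"condition {name!r} has fewer than 2 replicates")
    others = [k for k in groups if k != reference]
    if not others:
        raise StatisticsError("need at least two conditions to compare")
    ref = groups[reference]

    def _clean(p: float, a: np.ndarray, b: np.ndarray) -> float:
        if math.isnan(p):  # zero variance in both groups
            return 1.0 if math.isclose(a.mean(), b.mean(), abs_tol=1e-12) else 0.0
        return float(p)

    if len(others) == 1:
        other = groups[others[0]]
        if design == "paired":
            if other.size != ref.size:
                raise StatisticsError("paired design requires equal replicate counts")
            res = stats.ttest_rel(other, ref)
        else:
            res = stats.ttest_ind(other, ref)
        pvals = [_clean(res.pvalue, other, ref)]
    elif posthoc == "tukey":
        names = [reference] + others
        res = stats.tukey_hsd(*(groups[n] for n in names))
        pvals = [_clean(float(res.pvalue[0, i + 1]), groups[o], ref) for i, o in enumerate(others)]
    else:
        res = stats.dunnett(*(groups[o] for o in others), control=ref)
        pvals = [_clean(float(p), groups[o], ref) for p, o in zip(res.pvalue, others)]

    return pd.DataFrame(
        {
            "condition": others,
            "p_value": pvals,
            "significant": [p < 0.05 for p in pvals],
        }
    )
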