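"""Seeded synthetic Ca²⁺-imaging wells with known ground truth.

The generator emulates the structure of a high-content Ca²⁺-imaging experiment
on nociceptor-enriched cultures: a 45-s recording at a fixed frame rate, a
10-s baseline, then automated stimulus addition.  A well holds a mixture of

* non-responders,
* cells responding only to the first stimulus (e.g. the P2X3 agonist
  α,β-meATP — fast-inactivating transients),
* cells responding only to the second stimulus (e.g. the TRPV1 agonist
  capsaicin — sustained plateaus), and
* cells responding to both,

drawn from configurable class probabilities.  Each responding cell adds a
kinetic template scaled by a per-cell amplitude on top of a slowly bleaching
baseline, plus Gaussian read noise.  A negative-control (HBSS) stimulus is a
zero-amplitude stimulus by default; its evoked amplitude can be raised to
model mechanical-allodynia-like hypersensitivity after drug pre-treatment.

Every output is a pure function of its configuration, including the seed, so
ground truth can be used for parameter-recovery tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError
from .extraction import ImageStack, TraceMatrix

__all__ = [
    "KineticTemplate",
    "P2X3_LIKE",
    "TRPV1_LIKE",
    "RESPONDER_CLASSES",
    "CellGroundTruth",
    "SimWellConfig",
    "make_trace",
    "simulate_well",
    "render_image_stack",
    "truths_to_dataframe",
]

RESPONDER_CLASSES = ("none", "A_only", "B_only", "both")


@dataclass(frozen=True)
class KineticTemplate:
    """Unit-peak response shape: linear rise, exponential decay to a plateau.

    The template is 0 before the stimulus, rises linearly to 1 over
    ``rise_time`` (after ``onset_delay``), then decays exponentially with time
    constant ``decay_time`` toward ``plateau_fraction`` of the peak.  A
    fast-inactivating channel (P2X3-like) has plateau_fraction ≈ 0; a sustained
    one (TRPV1-like) has plateau_fraction ≈ 1.
    """

    name: str
    onset_delay: float = 0.0
    rise_time: float = 1.0
    decay_time: float = 5.0
    plateau_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.onset_delay, self.rise_time, self.decay_time) < 0:
            raise ConfigError("template times must be non-negative")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ConfigError("plateau_fraction must lie in [0, 1]")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the unit-peak template at times ``t`` relative to stimulus addition."""
        t = np.asarray(t, dtype=float)
        rel = t - self.onset_delay
        out = np.zeros_like(rel)
        if self.rise_time > 0:
            rising = (rel >= 0) & (rel < self.rise_time)
            out[rising] = rel[rising] / self.rise_time
        after = rel >= self.rise_time
        tail = rel[after] - self.rise_time
        if self.decay_time > 0:
            out[after] = self.plateau_fraction + (1.0 - self.plateau_fraction) * np.exp(
                -tail / self.decay_time
            )
        else:
            # instantaneous decay: unit peak only exactly at the end of the rise
            out[after] = np.where(tail == 0, 1.0, self.plateau_fraction)
        return np.clip(out, 0.0, 1.0)


#: Fast-inactivating transient typical of P2X3 (purinergic) responses.
P2X3_LIKE = KineticTemplate(name="fast_inactivating", rise_time=0.5, decay_time=2.0,
                            plateau_fraction=0.0)
#: Sustained response typical of TRPV1 (capsaicin) activation.
TRPV1_LIKE = KineticTemplate(name="sustained", rise_time=2.0, decay_time=10.0,
                             plateau_fraction=1.0)


@dataclass(frozen=True)
class CellGroundTruth:
    """Planted parameters of one simulated cell."""

    cell_id: str
    responder_class: str
    amplitude_A: float
    amplitude_B: float
    baseline_level: float
    position: tuple[float, float] = (0.0, 0.0)  # (x, y) pixels
    amplitude_control: float = 0.0

    def __post_init__(self) -> None:
        if self.responder_class not in RESPONDER_CLASSES:
            raise ConfigError(f"unknown responder class {self.responder_class!r}")
        if self.baseline_level <= 0:
            raise ConfigError("baseline_level must be positive")
        if self.responder_class in ("none", "B_only") and self.amplitude_A != 0:
            raise ConfigError("amplitude_A must be 0 for cells not responding to A")
        if self.responder_class in ("none", "A_only") and self.amplitude_B != 0:
            raise ConfigError("amplitude_B must be 0 for cells not responding to B")


@dataclass(frozen=True)
class SimWellConfig:
    """Configuration of one simulated well.

    ``stimulus_times`` maps stimulus label → addition time (seconds); the first
    two non-control labels play the roles of stimulus A and B for the responder
    classes.  The ``control_label`` stimulus (HBSS by default) evokes, in every
    cell, an amplitude drawn from the control-amplitude distribution — 0 by
    default, positive to emulate mechanical hypersensitivity.
    """

    n_cells: int = 100
    class_probabilities: tuple[float, float, float, float] = (0.25, 0.40, 0.10, 0.25)
    amplitude_mean: float = 30.0
    amplitude_sd: float = 5.0
    noise_sd: float = 1.0
    bleach_rate: float = 0.002
    frame_rate: float = 2.0
    duration: float = 45.0
    baseline_duration: float = 10.0
    stimulus_times: Mapping[str, float] = field(
        default_factory=lambda: {"alpha_beta_meATP": 10.0}
    )
    control_label: str = "HBSS"
    control_amplitude_mean: float = 0.0
    control_amplitude_sd: float = 0.0
    baseline_mean: float = 100.0
    baseline_sd: float = 5.0
    frame_shape: tuple[int, int] = (128, 128)
    spot_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probabilities, dtype=float)
        if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ConfigError("class_probabilities must be 4 non-negative values summing to 1")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ConfigError("frame_rate and duration must be positive")
        if self.duration < self.baseline_duration:
            raise ConfigError("duration must cover the baseline")
        for label, t in self.stimulus_times.items():
            if not self.baseline_duration <= t <= self.duration:
                raise ConfigError(
                    f"stimulus {label!r} at {t} s lies outside "
                    f"[{self.baseline_duration}, {self.duration}]"
                )
        if self.n_cells < 0:
            raise ConfigError("n_cells must be non-negative")
        if min(self.noise_sd, self.amplitude_sd, self.control_amplitude_sd,
               self.baseline_sd, self.bleach_rate) < 0:
            raise ConfigError("spreads and rates must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def stimulus_labels(self) -> list[str]:
        return list(self.stimulus_times)

    def role_labels(self) -> tuple[str | None, str | None]:
        """Labels playing the A and B responder roles (non-control stimuli, in order)."""
        non_control = [s for s in self.stimulus_times if s != self.control_label]
        a = non_control[0] if non_control else None
        b = non_control[1] if len(non_control) > 1 else None
        return a, b


def make_trace(
    template: KineticTemplate,
    truth: CellGroundTruth,
    cfg: SimWellConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one cell's trace for the first stimulus of the protocol.

    The trace is ``baseline_level · exp(−bleach_rate·t) + amplitude_A ·
    template(t − t_stim) + N(0, noise_sd)``, sampled at the configured frame
    rate; reproducible for a fixed config seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = cfg.frame_times
    t_stim = next(iter(cfg.stimulus_times.values()))
    trace = truth.baseline_level * np.exp(-cfg.bleach_rate * t)
    trace = trace + truth.amplitude_A * template(t - t_stim)
    if cfg.noise_sd > 0:
        trace = trace + rng.normal(0.0, cfg.noise_sd, size=t.size)
    return trace


def _positions_on_grid(n: int, frame_shape: tuple[int, int], spot_sigma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Jittered grid positions with pairwise separation ≥ 4·spot_sigma.

    The grid expands beyond ``frame_shape`` when the configured frame cannot
    hold ``n`` well-separated cells; rendering such a well then requires a
    correspondingly larger frame (checked by :func:`render_image_stack`).
    """
    if n == 0:
        return np.empty((0, 2))
    height, width = frame_shape
    margin = 4.0 * spot_sigma
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    min_sep = 4.0 * spot_sigma
    dx = max((width - 2 * margin) / cols, 1.5 * min_sep)
    dy = max((height - 2 * margin) / rows, 1.5 * min_sep)
    # adjacent centres are dx apart: jitter ≤ (dx − min_sep)/2 preserves separation
    jitter = 0.9 * (min(dx, dy) - min_sep) / 2.0
    pts = []
    for i in range(n):
        r, c = divmod(i, cols)
        x = margin + (c + 0.5) * dx + rng.uniform(-jitter, jitter)
        y = margin + (r + 0.5) * dy + rng.uniform(-jitter, jitter)
        pts.append((x, y))
    return np.asarray(pts)


def simulate_well(
    cfg: SimWellConfig,
    templates: Mapping[str, KineticTemplate] | None = None,
) -> tuple[TraceMatrix, list[CellGroundTruth]]:
    """Simulate all traces of one well plus the planted ground truth.

    ``templates`` maps each stimulus label in ``cfg.stimulus_times`` to its
    kinetic template; a missing entry is a configuration error.  When omitted,
    the A-role stimulus defaults to the fast-inactivating template, the B-role
    to the sustained one, and the control to the fast-inactivating shape.
    """
    label_a, label_b = cfg.role_labels()
    if templates is None:
        templates = {}
        for label in cfg.stimulus_times:
            if label == label_b:
                templates[label] = TRPV1_LIKE
            else:
                templates[label] = P2X3_LIKE
    missing = [s for s in cfg.stimulus_times if s not in templates]
    if missing:
        raise ConfigError(f"missing kinetic template(s) for stimuli: {missing}")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    classes = rng.choice(4, size=n, p=np.asarray(cfg.class_probabilities, dtype=float))
    responds_a = np.isin(classes, (1, 3))
    responds_b = np.isin(classes, (2, 3))
    amp_a = np.where(responds_a, np.clip(rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, n),
                                         0.0, None), 0.0)
    amp_b = np.where(responds_b, np.clip(rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, n),
                                         0.0, None), 0.0)
    has_control = cfg.control_label in cfg.stimulus_times
    if has_control:
        amp_c = np.clip(rng.normal(cfg.control_amplitude_mean, cfg.control_amplitude_sd, n),
                        0.0, None)
    else:
        amp_c = np.zeros(n)
    baselines = np.clip(rng.normal(cfg.baseline_mean, cfg.baseline_sd, n), 1e-6, None)
    positions = _positions_on_grid(n, cfg.frame_shape, cfg.spot_sigma, rng)

    t = cfg.frame_times
    values = baselines[:, None] * np.exp(-cfg.bleach_rate * t)[None, :]
    for label, t_add in cfg.stimulus_times.items():
        shape = templates[label](t - t_add)
        if label == cfg.control_label:
            amp = amp_c
        elif label == label_a:
            amp = amp_a
        elif label == label_b:
            amp = amp_b
        else:
            amp = np.zeros(n)
        values = values + amp[:, None] * shape[None, :]
    if cfg.noise_sd > 0 and n > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)

    cell_ids = [f"cell_{i:04d}" for i in range(n)]
    truths = [
        CellGroundTruth(
            cell_id=cell_ids[i],
            responder_class=RESPONDER_CLASSES[classes[i]],
            amplitude_A=float(amp_a[i]),
            amplitude_B=float(amp_b[i]),
            baseline_level=float(baselines[i]),
            position=(float(positions[i, 0]), float(positions[i, 1])),
            amplitude_control=float(amp_c[i]),
        )
        for i in range(n)
    ]
    traces = TraceMatrix(cell_ids=cell_ids, frame_times=t, values=values)
    return traces, truths


def render_image_stack(
    traces: TraceMatrix,
    truths: Sequence[CellGroundTruth],
    frame_shape: tuple[int, int] | None = None,
    spot_sigma: float = 2.0,
    background: float = 50.0,
) -> ImageStack:
    """Render traces as a 16-bit image stack of Gaussian spots on a flat background.

    Each cell is an isotropic 2-D Gaussian at its ground-truth position whose
    integrated intensity is proportional to the cell's trace value in that
    frame (the spot peak equals the trace value).  Spots must sit fully inside
    the frame and be pairwise separated by at least twice the spot radius
    (radius = 2·spot_sigma); violations raise :class:`PlacementError`.
    """
    if len(truths) != traces.n_cells:
        raise PlacementError("one ground-truth record per trace is required")
    radius = 2.0 * spot_sigma
    pos = np.array([t.position for t in truths], dtype=float).reshape(-1, 2)
    if frame_shape is None:
        if len(pos):
            side_x = int(np.ceil(pos[:, 0].max() + radius + 1))
            side_y = int(np.ceil(pos[:, 1].max() + radius + 1))
            frame_shape = (max(side_y, 32), max(side_x, 32))
        else:
            frame_shape = (32, 32)
    height, width = frame_shape
    for x, y in pos:
        if not (radius <= x <= width - 1 - radius and radius <= y <= height - 1 - radius):
            raise PlacementError(f"cell position ({x:.1f}, {y:.1f}) too close to frame edge")
    if len(pos) > 1:
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < (2 * radius) ** 2:
            raise PlacementError("cell spots closer than twice the spot radius")

    n_frames = traces.frame_times.size
    frames = np.full((n_frames, height, width), background, dtype=float)
    half = int(np.ceil(4 * spot_sigma))
    for i, (x0, y0) in enumerate(pos):
        xi, yi = int(round(x0)), int(round(y0))
        ys = slice(max(0, yi - half), min(height, yi + half + 1))
        xs = slice(max(0, xi - half), min(width, xi + half + 1))
        yy, xx = np.mgrid[ys, xs]
        footprint = np.exp(-(((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * spot_sigma**2)))
        frames[:, ys, xs] += traces.values[i][:, None, None] * footprint[None, :, :]
    frames = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return ImageStack(frames=frames, frame_times=traces.frame_times.copy())


def truths_to_dataframe(truths: Sequence[CellGroundTruth]) -> pd.DataFrame:
    """Tidy ground-truth table (one row per cell), suitable for CSV export."""
    return pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in truths],
            "responder_class": [t.responder_class for t in truths],
            "amplitude_A": [t.amplitude_A for t in truths],
            "amplitude_B": [t.amplitude_B for t in truths],
            "amplitude_control": [t.amplitude_control for t in truths],
            "baseline_level": [t.baseline_level for t in truths],
            "x": [t.position[0] for t in truths],
            "y": [t.position[1] for t in truths],
        }
    )
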