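"""Image stacks, ROI detection, trace extraction and per-stimulus ΔF computation.

The analysis converts a fluorescence image stack (time × y × x) into per-cell
intensity traces and then, given a stimulation protocol, into one ΔF value per
(cell, stimulus) pair:

    ΔF = max over the response window − mean over the pre-stimulus baseline

in raw intensity units.  ΔF is deliberately *not* normalised to baseline
(no ΔF/F): the downstream reactivity threshold carries an absolute cap, which
only has meaning on the un-normalised scale.  For the second and later stimuli
of a multi-stimulus protocol the baseline is re-anchored to the seconds
immediately preceding that stimulus, so a sustained plateau evoked by an
earlier stimulus does not leak into the later ΔF.

Segmentation here is a simple, deterministic stand-in for dedicated
high-content Ca²⁺-imaging software: temporal-maximum projection, Gaussian
smoothing, background subtraction and local-maximum detection with a
minimum-separation constraint, yielding fixed-radius circular ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.feature import peak_local_max

from .errors import InputError, ProtocolError

__all__ = [
    "ImageStack",
    "ROI",
    "StimulationProtocol",
    "TraceMatrix",
    "detect_cells",
    "extract_traces",
    "compute_delta_f",
]


@dataclass
class ImageStack:
    """A fluorescence recording: frames (time × y × x) plus per-frame times in seconds."""

    frames: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise InputError("frames must be a 3-D array (time, y, x)")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise InputError("one frame time per frame is required")
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise InputError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def to_tiff(self, path: str | Path) -> None:
        """Write the stack as a multi-frame 16-bit grayscale TIFF."""
        data = np.clip(np.round(self.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(str(path), data)

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        frame_rate: float | None = None,
        frame_times: Sequence[float] | None = None,
    ) -> "ImageStack":
        """Read a multi-frame TIFF; timing comes from ``frame_rate`` or explicit times."""
        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None, :, :]
        if frame_times is not None:
            times = np.asarray(frame_times, dtype=float)
        elif frame_rate is not None and frame_rate > 0:
            times = np.arange(frames.shape[0]) / float(frame_rate)
        else:
            raise InputError("either frame_rate or frame_times must be given")
        return cls(frames=frames, frame_times=times)


@dataclass(frozen=True)
class ROI:
    """A circular region of interest around one cell body."""

    cell_id: str
    center: tuple[float, float]  # (x, y) in pixels, 0-based
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InputError("ROI radius must be positive")


@dataclass(frozen=True)
class StimulationProtocol:
    """Stimulus identities/times and the analysis windows of a recording.

    ``stimuli`` is an ordered list of (label, addition_time) pairs. The first
    stimulus uses ``baseline_window`` as its baseline; later stimuli re-anchor
    their baseline to the ``rebaseline_length`` seconds immediately preceding
    their own addition. All windows are half-open [start, end) and a frame
    belongs to a window by its timestamp.
    """

    stimuli: tuple[tuple[str, float], ...]
    baseline_window: tuple[float, float] = (0.0, 10.0)
    response_window_length: float = 30.0
    rebaseline_length: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimuli", tuple((str(s), float(t)) for s, t in self.stimuli))
        if not self.stimuli:
            raise ProtocolError("protocol must contain at least one stimulus")
        labels = [s for s, _ in self.stimuli]
        if len(set(labels)) != len(labels):
            raise ProtocolError("stimulus labels must be unique")
        times = [t for _, t in self.stimuli]
        if any(b > a for a, b in zip(times[1:], times[:-1])):
            raise ProtocolError("stimuli must be ordered by addition time")
        b0, b1 = self.baseline_window
        if b1 <= b0:
            raise ProtocolError("baseline window must have positive length")
        if b1 > times[0]:
            raise ProtocolError("baseline window must end at or before the first stimulus")
        if self.response_window_length <= 0:
            raise ProtocolError("response_window_length must be positive")
        if self.rebaseline_length <= 0:
            raise ProtocolError("rebaseline_length must be positive")

    def response_window(self, k: int) -> tuple[float, float]:
        """Half-open response window of stimulus ``k``, truncated at the next stimulus."""
        t_add = self.stimuli[k][1]
        end = t_add + self.response_window_length
        if k + 1 < len(self.stimuli):
            end = min(end, self.stimuli[k + 1][1])
        return t_add, end

    def baseline_for(self, k: int) -> tuple[float, float]:
        if k == 0:
            return self.baseline_window
        t_add = self.stimuli[k][1]
        return t_add - self.rebaseline_length, t_add

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "stimuli": [{"label": s, "time": t} for s, t in self.stimuli],
            "baseline_window": list(self.baseline_window),
            "response_window_length": self.response_window_length,
            "rebaseline_length": self.rebaseline_length,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StimulationProtocol":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            stimuli=tuple((d["label"], float(d["time"])) for d in payload["stimuli"]),
            baseline_window=tuple(payload.get("baseline_window", (0.0, 10.0))),
            response_window_length=float(payload.get("response_window_length", 30.0)),
            rebaseline_length=float(payload.get("rebaseline_length", 5.0)),
        )


@dataclass
class TraceMatrix:
    """Per-cell fluorescence traces: cells × frames with a shared time axis."""

    cell_ids: list[str]
    frame_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.cell_ids), -1)
        if self.values.shape != (len(self.cell_ids), self.frame_times.size):
            raise InputError("trace matrix must be rectangular: n_cells × n_frames")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.frame_times)

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: rows = cells, columns = frame times in seconds."""
        df = self.to_dataframe()
        df.index.name = "cell_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraceMatrix":
        df = pd.read_csv(path, index_col=0)
        times = np.array([float(c) for c in df.columns])
        return cls(cell_ids=list(df.index.astype(str)), frame_times=times, values=df.to_numpy())


def detect_cells(
    stack: ImageStack,
    smoothing_sigma: float = 2.0,
    min_separation: int = 6,
    roi_radius: float = 4.0,
    threshold_factor: float = 5.0,
) -> list[ROI]:
    """Detect cell bodies on the temporal-maximum projection of a stack.

    The projection is Gaussian-smoothed, the median background is subtracted,
    and local maxima exceeding ``threshold_factor`` robust noise SDs (MAD-based)
    are kept, subject to a minimum pairwise separation.  Two cells closer than
    ``min_separation`` pixels merge into a single ROI (the brighter peak wins).
    Deterministic for fixed parameters.
    """
    if stack.n_frames == 0 or stack.frames.size == 0:
        raise InputError("cannot detect cells on an empty stack")
    proj = stack.frames.max(axis=0).astype(float)
    smooth = ndimage.gaussian_filter(proj, sigma=smoothing_sigma)
    resid = smooth - np.median(smooth)
    mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
    threshold = max(threshold_factor * mad, 1e-6)
    border = int(np.ceil(roi_radius))
    peaks = peak_local_max(
        resid,
        min_distance=int(min_separation),
        threshold_abs=threshold,
        exclude_border=border,
    )
    # sort by (row, col) for a stable cell ordering
    order = np.lexsort((peaks[:, 1], peaks[:, 0])) if peaks.size else []
    rois = []
    for i, idx in enumerate(order):
        y, x = peaks[idx]
        rois.append(ROI(cell_id=f"cell_{i:04d}", center=(float(x), float(y)), radius=roi_radius))
    return rois


def _disk_indices(roi: ROI, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    x0, y0 = roi.center
    r = roi.radius
    if x0 - r < -0.5 or y0 - r < -0.5 or x0 + r > shape[1] - 0.5 or y0 + r > shape[0] - 0.5:
        raise InputError(f"ROI {roi.cell_id} extends outside the frame bounds")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= r**2
    return np.nonzero(mask)


def extract_traces(stack: ImageStack, rois: Sequence[ROI]) -> TraceMatrix:
    """Mean pixel intensity inside each ROI disk, per frame."""
    values = np.empty((len(rois), stack.n_frames), dtype=float)
    for i, roi in enumerate(rois):
        ys, xs = _disk_indices(roi, stack.frame_shape)
        if ys.size == 0:
            raise InputError(f"ROI {roi.cell_id} covers no pixels")
        values[i] = stack.frames[:, ys, xs].mean(axis=1)
    return TraceMatrix(
        cell_ids=[r.cell_id for r in rois],
        frame_times=stack.frame_times,
        values=values,
    )


def compute_delta_f(
    traces: TraceMatrix,
    protocol: StimulationProtocol,
    baseline_stat: str = "mean",
    response_stat: str = "max",
) -> pd.DataFrame:
    """Per-(cell, stimulus) ΔF: response-window peak minus baseline level.

    Parameters
    ----------
    traces
        Trace matrix covering all protocol windows.
    protocol
        Stimulus labels/times and analysis windows.
    baseline_stat
        ``"mean"`` (default) or ``"median"`` over the baseline window.
    response_stat
        ``"max"`` (default, the peak) or ``"mean"`` over the response window.

    Returns
    -------
    DataFrame with columns ``cell_id``, ``stimulus``, ``delta_f`` in the raw
    intensity units of the traces; exactly n_cells × n_stimuli rows.
    """
    if baseline_stat not in ("mean", "median"):
        raise ProtocolError(f"unknown baseline_stat {baseline_stat!r}")
    if response_stat not in ("max", "mean"):
        raise ProtocolError(f"unknown response_stat {response_stat!r}")
    times = traces.frame_times
    if times.size == 0:
        raise ProtocolError("trace matrix has no frames")
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    records: list[dict] = []
    for k, (label, _t_add) in enumerate(protocol.stimuli):
        b0, b1 = protocol.baseline_for(k)
        r0, r1 = protocol.response_window(k)
        if r1 > times[-1] + dt + 1e-9:
            raise ProtocolError(
                f"response window of stimulus {label!r} extends past the recording end"
            )
        bmask = (times >= b0) & (times < b1)
        rmask = (times >= r0) & (times < r1)
        if not bmask.any():
            raise ProtocolError(f"baseline window of stimulus {label!r} contains no frames")
        if not rmask.any():
            raise ProtocolError(f"response window of stimulus {label!r} contains no frames")
        if baseline_stat == "mean":
            baseline = traces.values[:, bmask].mean(axis=1)
        else:
            baseline = np.median(traces.values[:, bmask], axis=1)
        if response_stat == "max":
            response = traces.values[:, rmask].max(axis=1)
        else:
            response = traces.values[:, rmask].mean(axis=1)
        delta = response - baseline
        records.extend(
            {"cell_id": cid, "stimulus": label, "delta_f": float(d)}
            for cid, d in zip(traces.cell_ids, delta)
        )
    return pd.DataFrame.from_records(records, columns=["cell_id", "stimulus", "delta_f"])
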