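"""Per-ROI, per-stimulus response scores from calcium traces.

For each ROI and each stimulus regressor, the fluorescence trace is
regressed on the regressor (ordinary least squares with intercept) over
that stimulus class's time window — from the first onset of the class to
the last offset plus a decay pad of ``window_pad`` kernel time constants.
The response score is the regression slope (equivalent to dF/F against a
unit-max regressor) times the coefficient of determination R^2. Negative
slopes are kept: suppression scores negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import RegressorMatrix, StimulusProtocol, STIM_CLASSES


@dataclass
class TraceMatrix:
    """ROI x time fluorescence matrix (arbitrary units)."""

    values: np.ndarray
    frame_rate: float
    roi_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace matrix must be 2-D (ROI x time)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.roi_ids is None:
            self.roi_ids = np.arange(self.values.shape[0])

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ResponseScoreMatrix:
    scores: np.ndarray  # ROI x 8, slope * R^2
    roi_ids: np.ndarray
    stim_classes: tuple[str, ...] = STIM_CLASSES
    scaled_scores: np.ndarray | None = None

    def to_dataframe(self, responder_mask: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=[f"score_{c}" for c in self.stim_classes])
        df.insert(0, "roi_id", self.roi_ids)
        if self.scaled_scores is not None:
            for i, c in enumerate(self.stim_classes):
                df[f"scaled_{c}"] = self.scaled_scores[:, i]
        if responder_mask is not None:
            df["responder"] = responder_mask
        return df


def stimulus_windows(
    protocol: StimulusProtocol,
    frame_rate: float,
    n_frames: int,
    tau: float,
    window_pad: float = 3.0,
) -> dict[str, slice]:
    """Per-class fitting window: first onset to last offset + window_pad*tau."""
    windows: dict[str, slice] = {}
    for stim_class in STIM_CLASSES:
        events = protocol.events_of(stim_class)
        if not events:
            raise ValueError(f"no events of class {stim_class!r}")
        start = int(round(min(e.onset for e in events) * frame_rate))
        stop = int(round((max(e.offset for e in events) + window_pad * tau) * frame_rate))
        windows[stim_class] = slice(max(start, 0), min(stop, n_frames))
    return windows


def fit_response_scores(
    traces: TraceMatrix,
    regressors: RegressorMatrix,
    protocol: StimulusProtocol,
    window_pad: float = 3.0,
) -> ResponseScoreMatrix:
    """OLS slope x R^2 per ROI and stimulus, on the stimulus time window."""
    if traces.n_frames != regressors.n_frames:
        raise ValueError(
            f"traces have {traces.n_frames} frames but regressors have "
            f"{regressors.n_frames}"
        )
    if traces.frame_rate != regressors.frame_rate:
        raise ValueError("traces and regressors must share a frame rate")

    windows = stimulus_windows(
        protocol, traces.frame_rate, traces.n_frames, regressors.tau, window_pad
    )
    n_rois = traces.n_rois
    scores = np.zeros((n_rois, len(STIM_CLASSES)))
    for j, stim_class in enumerate(regressors.stim_classes):
        w = windows[stim_class]
        x = regressors.values[w, j]
        var_x = x.var()
        if var_x == 0:
            raise ValueError(
                f"regressor {stim_class!r} has zero variance on its window"
            )
        y = traces.values[:, w]
        # vectorized simple OLS with intercept:
        #   slope = cov(x, y) / var(x); R^2 = corr(x, y)^2
        xc = x - x.mean()
        yc = y - y.mean(axis=1, keepdims=True)
        cov_xy = yc @ xc / x.size
        var_y = (yc**2).mean(axis=1)
        slope = cov_xy / var_x
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(var_y > 0, cov_xy**2 / (var_x * var_y), 0.0)
        scores[:, j] = slope * r2
    return ResponseScoreMatrix(scores=scores, roi_ids=traces.roi_ids)


def select_responders(
    scores: ResponseScoreMatrix,
    percentile: float = 95.0,
    pooled: bool = False,
) -> np.ndarray:
    """Flag ROIs scoring above the population percentile for any stimulus.

    The threshold is computed per stimulus column by default (``pooled=True``
    uses one threshold over all scores). An ROI is a responder if it
    *strictly* exceeds the threshold for at least one stimulus, so a fully
    degenerate population (all scores identical) has no responders.
    """
    s = scores.scores
    if s.shape[0] < 20:
        raise ValueError("need at least 20 ROIs for a meaningful percentile")
    if pooled:
        thresh = np.percentile(s, percentile)
        return (s > thresh).any(axis=1)
    thresh = np.percentile(s, percentile, axis=0)
    return (s > thresh[None, :]).any(axis=1)


def scale_scores(scores: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Z-score each stimulus column against a reference population.

    The reference is the full recorded population (not only responders or
    labelled ROIs); scaling a labelled subset against the population keeps
    its scores on the population scale.
    """
    scores = np.asarray(scores, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mean = reference.mean(axis=0)
    sd = reference.std(axis=0)
    if np.any(sd == 0):
        bad = [STIM_CLASSES[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"reference has zero variance for stimuli {bad}")
    return (scores - mean) / sd
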