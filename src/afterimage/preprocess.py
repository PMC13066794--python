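"""Binning, dF/F conversion, baseline handling and trial averaging.

Everything downstream (correlation matrices, angles, decoders) consumes the
``BinnedResponse`` produced here: a time-bin x unit activity matrix for one
odor/window, either per trial or trial-averaged.  Responses entering angle
and correlation computations are baseline-subtracted per unit (mean activity
in a pre-odor window) so that odor-evoked suppression shows up as negative
components -- the substrate of ON/OFF anticorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import medfilt

from .session import (
    RecordingSession,
    SessionValidationError,
    TrialRecord,
    WindowSpec,
)

__all__ = [
    "BinnedResponse",
    "bin_spikes",
    "resample_traces",
    "compute_dff",
    "dff_session",
    "trial_average",
    "baseline_stats",
    "baseline_subtract",
    "time_average",
    "response_matrix",
    "DEFAULT_BASELINE_WINDOW",
]

#: default pre-odor baseline: the 2 s immediately before odor onset
DEFAULT_BASELINE_WINDOW = WindowSpec("BASELINE", -2.0, 0.0, "odor_onset")


@dataclass
class BinnedResponse:
    """Time-bin x unit activity matrix for one condition/window.

    ``bin_edges_s`` are relative to the window's anchoring event (odor onset
    or offset); bins are half-open ``[edge_i, edge_{i+1})`` of constant width.
    """

    values: np.ndarray  # (n_timebins, n_units)
    bin_edges_s: np.ndarray  # (n_timebins + 1,)
    units: list[str]
    odor: str
    window: str
    trial_id: str  # a trial id or "trial-averaged"
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_edges_s = np.asarray(self.bin_edges_s, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time bins x units)")
        if self.bin_edges_s.size != self.values.shape[0] + 1:
            raise ValueError("bin_edges_s must have n_timebins + 1 entries")
        widths = np.diff(self.bin_edges_s)
        if widths.size and not np.allclose(widths, widths[0]):
            raise ValueError("bin widths must be constant within a matrix")
        if self.values.shape[1] != len(self.units):
            raise ValueError("values column count must match unit count")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


def _check_window_bounds(trial: TrialRecord, start: float, end: float) -> None:
    if start < trial.t_start_s - 1e-9 or end > trial.t_end_s + 1e-9:
        raise SessionValidationError(
            f"trial {trial.trial_id}: window [{start:.3f}, {end:.3f}) extends "
            f"beyond the recorded trial [{trial.t_start_s:.3f}, {trial.t_end_s:.3f}]"
        )


def bin_spikes(
    trial: TrialRecord,
    bin_width_s: float,
    window: WindowSpec,
    units: Sequence[str],
) -> BinnedResponse:
    """Count spikes of each unit in non-overlapping bins tiling a window.

    A window whose length is not a multiple of ``bin_width_s`` is truncated
    to the last full bin (never padded).  Bins are half-open: a spike at
    exactly the right edge belongs to the next bin.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    start, end = window.resolve(trial)
    n_bins = int(np.floor((end - start) / bin_width_s + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    end = start + n_bins * bin_width_s
    _check_window_bounds(trial, start, end)
    edges_abs = start + bin_width_s * np.arange(n_bins + 1)
    values = np.zeros((n_bins, len(units)))
    for j, uid in enumerate(units):
        st = trial.activity.get(uid)
        if st is None or st.size == 0:
            continue
        # right edge excluded: np.histogram includes it, so clip explicitly
        sel = st[(st >= start) & (st < end)]
        values[:, j] = np.histogram(sel, bins=edges_abs)[0]
    rel0 = window.start_s
    edges_rel = rel0 + bin_width_s * np.arange(n_bins + 1)
    return BinnedResponse(values, edges_rel, list(units), trial.odor,
                          window.name, trial.trial_id)


def resample_traces(
    trial: TrialRecord,
    frames_per_bin: int,
    window: WindowSpec,
    units: Sequence[str],
    sample_rate_hz: float,
) -> BinnedResponse:
    """Average trace frames within a window in non-overlapping blocks.

    The trailing partial block is dropped so bin widths stay constant.
    ``frames_per_bin = 1`` is the identity on the window.
    """
    if frames_per_bin < 1:
        raise ValueError("frames_per_bin must be >= 1")
    start, end = window.resolve(trial)
    _check_window_bounds(trial, start, end)
    n_frames_total = len(next(iter(trial.activity.values())))
    tt = trial.t_start_s + np.arange(n_frames_total) / sample_rate_hz
    idx = np.nonzero((tt >= start) & (tt < end))[0]
    n_bins = len(idx) // frames_per_bin
    if n_bins < 1:
        raise ValueError("window contains fewer frames than one bin")
    idx = idx[: n_bins * frames_per_bin]
    values = np.zeros((n_bins, len(units)))
    for j, uid in enumerate(units):
        seg = np.asarray(trial.activity[uid], float)[idx]
        values[:, j] = seg.reshape(n_bins, frames_per_bin).mean(axis=1)
    width = frames_per_bin / sample_rate_hz
    rel0 = tt[idx[0]] - (start - window.start_s)
    edges_rel = rel0 + width * np.arange(n_bins + 1)
    return BinnedResponse(values, edges_rel, list(units), trial.odor,
                          window.name, trial.trial_id)


def compute_dff(
    raw_trace: np.ndarray,
    baseline_frames: np.ndarray | slice,
    median_filter_len: int = 5,
    roi: str = "",
) -> np.ndarray:
    """dF/F = (F - F0)/F0 with F0 the mean over the baseline frames, then an
    odd-length running median filter to remove single-frame artifacts."""
    raw = np.asarray(raw_trace, dtype=float)
    f0 = float(np.mean(raw[baseline_frames]))
    if f0 <= 0:
        raise FloatingPointError(
            f"non-positive baseline fluorescence F0={f0:.4g}"
            + (f" for ROI {roi}" if roi else "")
        )
    dff = (raw - f0) / f0
    if median_filter_len > 1:
        if median_filter_len % 2 == 0:
            raise ValueError("median_filter_len must be odd")
        dff = medfilt(dff, kernel_size=median_filter_len)
    return dff


def dff_session(
    session: RecordingSession,
    baseline_window: WindowSpec = DEFAULT_BASELINE_WINDOW,
    median_filter_len: int = 5,
) -> RecordingSession:
    """Convert a raw-fluorescence trace session to dF/F, per trial and ROI."""
    if session.modality != "traces":
        raise SessionValidationError("dff_session requires a trace session")
    rate = session.sample_rate_hz
    new_trials = []
    for trial in session.trials:
        start, end = baseline_window.resolve(trial)
        n_frames = len(next(iter(trial.activity.values())))
        tt = trial.t_start_s + np.arange(n_frames) / rate
        base = (tt >= start) & (tt < end)
        if not base.any():
            raise SessionValidationError(
                f"trial {trial.trial_id}: no frames in baseline window"
            )
        activity = {
            uid: compute_dff(arr, base, median_filter_len, roi=uid)
            for uid, arr in trial.activity.items()
        }
        new_trials.append(replace(trial, activity=activity))
    out = replace(session, trials=new_trials)
    out.meta = dict(session.meta, dff="true")
    return out


def trial_average(responses: Sequence[BinnedResponse]) -> BinnedResponse:
    """Element-wise mean over per-trial matrices with identical layout."""
    if not responses:
        raise ValueError("no responses to average")
    ref = responses[0]
    for r in responses[1:]:
        if r.values.shape != ref.values.shape or r.units != ref.units:
            raise ValueError("mismatched shapes or unit order in trial_average")
        if not np.allclose(r.bin_edges_s, ref.bin_edges_s):
            raise ValueError("mismatched bin edges in trial_average")
        if r.baseline_subtracted != ref.baseline_subtracted:
            raise ValueError("mixed baseline_subtracted flags in trial_average")
    mean = np.mean([r.values for r in responses], axis=0)
    return BinnedResponse(mean, ref.bin_edges_s.copy(), list(ref.units),
                          ref.odor, ref.window, "trial-averaged",
                          ref.baseline_subtracted)


def baseline_stats(
    session: RecordingSession,
    trials: Sequence[TrialRecord],
    baseline_window: WindowSpec,
    bin_width_s: float | None = None,
    frames_per_bin: int | None = None,
) -> np.ndarray:
    """Per-unit mean activity per bin in a pre-odor window, pooled over trials.

    For spike sessions the result is an expected spike count per bin of the
    analysis bin width, so subtracting it converts counts to counts above
    baseline (suppression to ~0 spikes maps to a negative value).
    """
    mats = []
    for trial in trials:
        if session.modality == "spikes":
            br = bin_spikes(trial, bin_width_s, baseline_window, session.units)
        else:
            br = resample_traces(trial, frames_per_bin, baseline_window,
                                 session.units, session.sample_rate_hz)
        mats.append(br.values.mean(axis=0))
    return np.mean(mats, axis=0)


def baseline_subtract(binned: BinnedResponse,
                      baseline_mean: np.ndarray) -> BinnedResponse:
    """Subtract a per-unit baseline; refuses to run twice on the same matrix."""
    if binned.baseline_subtracted:
        raise ValueError("response is already baseline-subtracted")
    baseline_mean = np.asarray(baseline_mean, dtype=float)
    if baseline_mean.shape != (len(binned.units),):
        raise ValueError("baseline_mean length must match unit count")
    return BinnedResponse(binned.values - baseline_mean[None, :],
                          binned.bin_edges_s.copy(), list(binned.units),
                          binned.odor, binned.window, binned.trial_id,
                          baseline_subtracted=True)


def time_average(binned: BinnedResponse, mode: str = "mean") -> np.ndarray:
    """Collapse a matrix to one population vector (mean or summed over bins)."""
    if binned.n_bins == 0:
        raise ValueError("empty matrix")
    if mode == "mean":
        return binned.values.mean(axis=0)
    if mode == "sum":
        return binned.values.sum(axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def response_matrix(
    session: RecordingSession,
    odor: str,
    window: WindowSpec,
    bin_width_s: float | None = None,
    frames_per_bin: int | None = None,
    baseline_window: WindowSpec | None = DEFAULT_BASELINE_WINDOW,
    trials: Sequence[TrialRecord] | None = None,
) -> BinnedResponse:
    """Trial-averaged, optionally baseline-subtracted matrix for one odor.

    The standard entry point used by the geometry and sequential analyses:
    bin (or block-average) every trial of ``odor`` over ``window``, average
    across trials, and subtract the per-unit pre-odor baseline.
    """
    if trials is None:
        trials = session.trials_for(odor)
    if not trials:
        raise SessionValidationError(f"no trials for odor {odor!r}")
    per_trial = []
    for trial in trials:
        if session.modality == "spikes":
            per_trial.append(bin_spikes(trial, bin_width_s, window, session.units))
        else:
            per_trial.append(resample_traces(trial, frames_per_bin, window,
                                             session.units, session.sample_rate_hz))
    avg = trial_average(per_trial)
    if baseline_window is not None:
        base = baseline_stats(session, trials, baseline_window,
                              bin_width_s=bin_width_s,
                              frames_per_bin=frames_per_bin)
        avg = baseline_subtract(avg, base)
    return avg
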