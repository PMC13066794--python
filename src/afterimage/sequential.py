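"""History-dependent contrast enhancement between sequential odors.

Compares the correlation between a reference odor's population ON response
and each context odor's ON response in two conditions: both odors presented
alone ("solitary"), versus the reference presented immediately after the
context odor ("sequential"), so that the context odor's OFF response
overlaps the reference's ON response.  The lingering inverted OFF pattern
suppresses shared ensembles, so sequential correlations are expected to be
systematically lower -- contrast enhancement by the odor afterimage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import pearson
from .preprocess import (
    DEFAULT_BASELINE_WINDOW,
    WindowSpec,
    response_matrix,
    time_average,
)
from .session import RecordingSession
from .stats import TestResult, paired_t

__all__ = ["SequentialComparison", "sequential_contrast"]


@dataclass
class SequentialComparison:
    """Per-context-odor solitary vs sequential correlations and their test."""

    reference_odor: str
    pairs: list[tuple[str, float, float]]  # (context, corr_solitary, corr_sequential)
    delta: np.ndarray  # corr_sequential - corr_solitary per pair
    test: TestResult | None

    def context_odors(self) -> list[str]:
        return [c for c, _, _ in self.pairs]


def sequential_contrast(
    session: RecordingSession,
    reference_odor: str,
    on_window: WindowSpec | None = None,
    bin_width_s: float = 0.05,
    frames_per_bin: int = 4,
    baseline_window: WindowSpec = DEFAULT_BASELINE_WINDOW,
    sidedness: str = "one",
    average_mode: str = "mean",
) -> SequentialComparison:
    """Quantify contrast enhancement for one reference odor.

    For every context odor ``c`` with both a solitary block and a
    sequential (c -> reference) block in the session:

    * ``corr_solitary``  = Pearson(solitary reference ON vector,
      solitary ``c`` ON vector);
    * ``corr_sequential`` = Pearson(reference-after-``c`` ON vector,
      solitary ``c`` ON vector).

    ON vectors are trial-averaged, time-averaged and baseline-subtracted
    (pre-trial baseline).  The second odor's ON window starts at its own
    onset with the same duration as the solitary ON window.  A paired t-test
    (one-sided by default: solitary > sequential) is run over context odors.
    """
    solitary = [t for t in session.trials if len(t.odor_sequence) == 1]
    sequential = [t for t in session.trials
                  if len(t.odor_sequence) == 2
                  and t.odor_sequence[1][0] == reference_odor]
    sol_odors = {t.odor for t in solitary}
    if reference_odor not in sol_odors:
        raise ValueError(f"no solitary block for reference {reference_odor!r}")

    on_s = next(t for t in solitary if t.odor == reference_odor)
    if on_window is None:
        dur = on_s.offset_s - on_s.onset_s
        on_window = WindowSpec("ON", 0.0, dur, "odor_onset")
    kw = dict(bin_width_s=bin_width_s, frames_per_bin=frames_per_bin,
              baseline_window=baseline_window)

    v_ref = time_average(
        response_matrix(session, reference_odor, on_window,
                        trials=[t for t in solitary
                                if t.odor == reference_odor], **kw),
        mode=average_mode)

    seq_by_ctx: dict[str, list] = {}
    for t in sequential:
        seq_by_ctx.setdefault(t.odor_sequence[0][0], []).append(t)

    pairs: list[tuple[str, float, float]] = []
    contexts = sorted(sol_odors - {reference_odor})
    # second odor's ON window anchored at its own onset; pre-trial baseline
    # anchored at the first odor of the pair
    seq_window = WindowSpec("ON", on_window.start_s, on_window.end_s,
                            "odor_onset", odor_index=1)
    seq_baseline = None if baseline_window is None else WindowSpec(
        "BASELINE", baseline_window.start_s, baseline_window.end_s,
        "odor_onset", odor_index=0)
    for ctx in contexts:
        if ctx not in seq_by_ctx:
            warnings.warn(f"no sequential ({ctx}){reference_odor} block; skipped")
            continue
        v_ctx = time_average(
            response_matrix(session, ctx, on_window,
                            trials=[t for t in solitary if t.odor == ctx], **kw),
            mode=average_mode)
        v_seq = time_average(
            response_matrix(session, reference_odor, seq_window,
                            trials=seq_by_ctx[ctx], bin_width_s=bin_width_s,
                            frames_per_bin=frames_per_bin,
                            baseline_window=seq_baseline),
            mode=average_mode)
        pairs.append((ctx, pearson(v_ref, v_ctx), pearson(v_seq, v_ctx)))

    delta = np.array([seq - sol for _, sol, seq in pairs])
    test = None
    if len(pairs) >= 2:
        test = paired_t([sol for _, sol, _ in pairs],
                        [seq for _, _, seq in pairs], sidedness=sidedness)
    else:
        warnings.warn("fewer than 2 context pairs; paired test not run")
    return SequentialComparison(reference_odor, pairs, delta, test)
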