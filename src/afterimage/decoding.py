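"""k-NN odor decoding with leave-one-trial-out validation.

Time-bin-by-time-bin decoding pools every (trial, time-bin) population
vector in the analysis window across all odors and trials; ITI decoding uses
one time-averaged vector per trial.  For each query vector the k nearest
neighbors are drawn only from *other* trials (leave-one-trial-out), the
predicted odor is the majority label among them, and significance against
chance is assessed with a trial-level label-permutation null corrected by
Benjamini-Hochberg FDR across time bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowSpec, bin_spikes, resample_traces
from .session import RecordingSession
from .stats import FdrResult, bh_fdr, permutation_pvalue

__all__ = [
    "DecodingResult",
    "knn_predict_loto",
    "timecourse_decoding",
    "iti_decoding",
    "decoding_significance",
    "session_accuracy_vs_chance",
]

UNCLASSIFIABLE = ""


@dataclass
class DecodingResult:
    """Predictions and accuracy traces from a leave-one-trial-out k-NN run."""

    predictions: np.ndarray  # predicted label per vector
    labels: np.ndarray  # true label per vector
    trial_ids: np.ndarray  # trial id per vector
    bin_index: np.ndarray  # time-bin index per vector (0 for ITI-averaged)
    bin_centers_s: np.ndarray
    odors: list[str]
    accuracy_by_odor: np.ndarray  # (n_odors, n_bins)
    overall_accuracy: np.ndarray  # (n_bins,)
    chance: float
    params: dict
    null_mean: np.ndarray | None = None
    null_band: np.ndarray | None = None  # (2, n_bins) 2.5/97.5 percentiles
    p_values: np.ndarray | None = None
    significant_bins: np.ndarray | None = None
    _neighbors: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_vectors(self) -> int:
        return len(self.labels)


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise correlation distance (1 - Pearson) or angular distance (deg).

    Rows whose distance is undefined (zero variance under correlation, zero
    norm under angular) get NaN rows/columns.
    """
    X = np.asarray(X, float)
    if metric == "correlation":
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = (Xc @ Xc.T) / np.outer(norms, norms)
        D = 1.0 - np.clip(C, -1.0, 1.0)
        D[norms == 0, :] = np.nan
        D[:, norms == 0] = np.nan
        return D
    if metric == "angular":
        norms = np.linalg.norm(X, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            G = (X @ X.T) / np.outer(norms, norms)
        D = np.degrees(np.arccos(np.clip(G, -1.0, 1.0)))
        D[norms == 0, :] = np.nan
        D[:, norms == 0] = np.nan
        return D
    raise ValueError(f"unknown metric {metric!r}; use correlation or angular")


def _neighbor_table(X: np.ndarray, trial_ids: np.ndarray, k: int,
                    metric: str) -> np.ndarray:
    """(n, k) indices of each query's k nearest neighbors from other trials.

    -1 marks missing neighbors (unclassifiable query or pool too small).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    D = _distance_matrix(X, metric)
    same_trial = trial_ids[:, None] == trial_ids[None, :]
    D = np.where(same_trial, np.inf, D)
    eligible = (~same_trial).sum(axis=1).min()
    if k > eligible:
        raise ValueError(f"k={k} exceeds the {eligible} eligible neighbors")
    D = np.where(np.isnan(D), np.inf, D)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    dist_ok = np.take_along_axis(D, order, axis=1) < np.inf
    return np.where(dist_ok, order, -1).astype(np.int64)


def _vote(neighbors: np.ndarray, codes: np.ndarray, n_classes: int) -> np.ndarray:
    """Majority vote per query; ties broken by the tied label holding the
    single nearest neighbor.  Returns -1 for unclassifiable queries."""
    n, k = neighbors.shape
    valid = neighbors >= 0
    neigh_codes = np.where(valid, codes[np.clip(neighbors, 0, None)], -1)
    best = np.full(n, -1, dtype=np.int64)
    best_score = np.full(n, -1, dtype=np.int64)
    for c in range(n_classes):
        mask = neigh_codes == c
        count = mask.sum(axis=1)
        first = np.where(mask.any(axis=1), mask.argmax(axis=1), k)
        score = count * (k + 1) + (k - first)
        better = (count > 0) & (score > best_score)
        best[better] = c
        best_score[better] = score[better]
    return best


def knn_predict_loto(X: np.ndarray, trial_ids, labels, k: int = 10,
                     metric: str = "correlation") -> np.ndarray:
    """Leave-one-trial-out k-NN prediction for every vector in the pool.

    Neighbors never come from the query's own trial.  Queries with no
    defined distance (e.g. zero variance under correlation distance) are
    returned as the empty string and count as errors in accuracy.
    """
    trial_ids = np.asarray(trial_ids)
    labels = np.asarray(labels)
    odors = sorted(set(labels.tolist()))
    codes = np.array([odors.index(l) for l in labels])
    neigh = _neighbor_table(np.asarray(X, float), trial_ids, k, metric)
    pred_codes = _vote(neigh, codes, len(odors))
    return np.array([odors[c] if c >= 0 else UNCLASSIFIABLE for c in pred_codes])


def _accuracy_tables(pred_codes: np.ndarray, codes: np.ndarray,
                     bin_index: np.ndarray, n_odors: int,
                     n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    correct = pred_codes == codes
    overall = np.zeros(n_bins)
    by_odor = np.full((n_odors, n_bins), np.nan)
    for b in range(n_bins):
        sel = bin_index == b
        overall[b] = correct[sel].mean() if sel.any() else np.nan
        for c in range(n_odors):
            s = sel & (codes == c)
            if s.any():
                by_odor[c, b] = correct[s].mean()
    return by_odor, overall


def _pool_vectors(session: RecordingSession, window: WindowSpec,
                  bin_width_s: float | None, frames_per_bin: int | None,
                  average: bool):
    """Stack (trial, bin) population vectors over a window for all trials."""
    X, labels, trial_ids, bin_index = [], [], [], []
    centers = None
    for trial in session.trials:
        if session.modality == "spikes":
            br = bin_spikes(trial, bin_width_s, window, session.units)
        else:
            br = resample_traces(trial, frames_per_bin, window, session.units,
                                 session.sample_rate_hz)
        if average:
            X.append(br.values.mean(axis=0))
            labels.append(trial.odor)
            trial_ids.append(trial.trial_id)
            bin_index.append(0)
            centers = np.array([br.bin_centers_s().mean()])
        else:
            X.extend(br.values)
            labels.extend([trial.odor] * br.n_bins)
            trial_ids.extend([trial.trial_id] * br.n_bins)
            bin_index.extend(range(br.n_bins))
            centers = br.bin_centers_s()
    return (np.asarray(X), np.asarray(labels), np.asarray(trial_ids),
            np.asarray(bin_index), centers)


def _run(X, labels, trial_ids, bin_index, centers, k, metric, params):
    odors = sorted(set(labels.tolist()))
    codes = np.array([odors.index(l) for l in labels])
    neigh = _neighbor_table(X, trial_ids, k, metric)
    pred_codes = _vote(neigh, codes, len(odors))
    n_bins = int(bin_index.max()) + 1
    by_odor, overall = _accuracy_tables(pred_codes, codes, bin_index,
                                        len(odors), n_bins)
    preds = np.array([odors[c] if c >= 0 else UNCLASSIFIABLE
                      for c in pred_codes])
    return DecodingResult(
        predictions=preds, labels=labels, trial_ids=trial_ids,
        bin_index=bin_index, bin_centers_s=centers, odors=odors,
        accuracy_by_odor=by_odor, overall_accuracy=overall,
        chance=1.0 / len(odors), params=dict(params, k=k, metric=metric),
        _neighbors=neigh)


def timecourse_decoding(
    session: RecordingSession,
    window: WindowSpec,
    bin_width_s: float | None = 0.2,
    frames_per_bin: int | None = 4,
    k: int = 10,
    metric: str = "correlation",
) -> DecodingResult:
    """Time-bin-by-time-bin odor decoding over one analysis window.

    Every (trial, bin) vector in the window, concatenated across odors and
    trials, forms the classification pool (a locust-style 21 s ITI at 200 ms
    bins over 7 odors x 10 trials gives 7350 vectors); accuracy is reported
    per time bin, per odor and overall.
    """
    if len(session.odors) < 2:
        raise ValueError("need at least 2 odors to decode")
    X, labels, trial_ids, bin_index, centers = _pool_vectors(
        session, window, bin_width_s, frames_per_bin, average=False)
    return _run(X, labels, trial_ids, bin_index, centers, k, metric,
                {"window": window.name, "mode": "timecourse"})


def iti_decoding(
    session: RecordingSession,
    iti_window: WindowSpec,
    k: int = 10,
    metric: str = "angular",
    bin_width_s: float | None = 0.05,
    frames_per_bin: int | None = 4,
) -> DecodingResult:
    """Decode odor identity from one time-averaged vector per trial ITI."""
    X, labels, trial_ids, bin_index, centers = _pool_vectors(
        session, iti_window, bin_width_s, frames_per_bin, average=True)
    return _run(X, labels, trial_ids, bin_index, centers, k, metric,
                {"window": iti_window.name, "mode": "iti_averaged"})


def decoding_significance(
    result: DecodingResult,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> DecodingResult:
    """Permutation null (odor labels shuffled at the trial level; all bins of
    a trial move together) + BH-FDR over time bins.

    Fills null_mean, null_band (2.5/97.5 percentiles), p_values and
    significant_bins on a copy of the result.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives no usable null")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100: permutation p-values will be coarse")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    odors = result.odors
    codes = np.array([odors.index(l) for l in result.labels])
    n_bins = len(result.overall_accuracy)
    uniq, inv = np.unique(result.trial_ids, return_inverse=True)
    trial_codes = np.zeros(len(uniq), dtype=np.int64)
    trial_codes[inv] = codes  # label of each trial
    neigh = result._neighbors
    null = np.empty((n_perm, n_bins))
    for p in range(n_perm):
        perm_trial_codes = trial_codes[rng.permutation(len(uniq))]
        perm_codes = perm_trial_codes[inv]
        pred = _vote(neigh, perm_codes, len(odors))
        _, overall = _accuracy_tables(pred, perm_codes, result.bin_index,
                                      len(odors), n_bins)
        null[p] = overall
    pvals = np.array([
        permutation_pvalue(result.overall_accuracy[b], null[:, b])
        for b in range(n_bins)
    ])
    fdr = bh_fdr(pvals, q=q)
    from dataclasses import replace

    return replace(
        result,
        null_mean=null.mean(axis=0),
        null_band=np.percentile(null, [2.5, 97.5], axis=0),
        p_values=pvals,
        significant_bins=fdr.significant,
        params=dict(result.params, n_perm=n_perm, q=q),
    )


def session_accuracy_vs_chance(
    accuracy_traces: np.ndarray,
    chance: float,
    bin_group: int = 5,
    q: float = 0.05,
) -> FdrResult:
    """Across-session test of decoding accuracy against chance over time.

    Per-session accuracy traces are averaged in non-overlapping groups of
    ``bin_group`` consecutive time points; each group is tested with a
    one-sided one-sample t-test against chance and BH-FDR corrected.
    """
    import scipy.stats

    A = np.asarray(accuracy_traces, float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need accuracy traces from >= 2 sessions")
    n_groups = A.shape[1] // bin_group
    G = A[:, : n_groups * bin_group].reshape(A.shape[0], n_groups, bin_group)
    G = G.mean(axis=2)
    pvals = np.empty(n_groups)
    for g in range(n_groups):
        col = G[:, g]
        if np.allclose(col, col[0]):
            pvals[g] = 1.0 if col[0] <= chance else np.finfo(float).tiny
        else:
            pvals[g] = scipy.stats.ttest_1samp(
                col, chance, alternative="greater").pvalue
    return bh_fdr(np.clip(pvals, np.finfo(float).tiny, 1.0), q=q)
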