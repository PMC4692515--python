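"""Temporal filtering, run-wise standardisation, trial feature extraction.

Pipeline order is filter -> z-score -> extract.  The high-pass filter is
a GLM projection onto a Fourier basis (intercept, linear trend, sine and
cosine at 1..n cycles per run); z-scoring uses the population (N)
standard deviation per voxel per run; features are per-trial averages of
the volumes acquired 4-10 s after trial onset (3 volumes at TR = 2 s).
"""

from __future__ import annotations

import numpy as np

from .containers import BOLDDataset, EventTable, TrialFeatureMatrix, VolumeMask

__all__ = [
    "highpass_fourier",
    "zscore_runs",
    "extract_trial_features",
    "preprocess_and_extract",
]


def _fourier_basis(n_volumes: int, n_cycles: int) -> np.ndarray:
    """Columns: intercept, linear trend, sin & cos at 1..n_cycles cycles/run."""
    t = np.arange(n_volumes, dtype=float)
    cols = [np.ones(n_volumes), t - t.mean()]
    for k in range(1, n_cycles + 1):
        cols.append(np.sin(2 * np.pi * k * t / n_volumes))
        cols.append(np.cos(2 * np.pi * k * t / n_volumes))
    return np.column_stack(cols)


def highpass_fourier(dataset: BOLDDataset, n_cycles: int = 2) -> BOLDDataset:
    """High-pass filter each run by OLS removal of a Fourier basis.

    Per voxel and run, the time course is regressed on [intercept, linear
    trend, sin/cos at 1..n_cycles cycles per run]; the residuals plus the
    run mean are returned, so slow drifts and offsets-within-basis vanish
    while the mean level is preserved.
    """
    out = np.empty_like(dataset.data)
    for run in range(1, dataset.n_runs + 1):
        sl = dataset.run_slice(run)
        nv = sl.stop - sl.start
        if nv < 2 * (2 * n_cycles + 2):
            raise ValueError(
                f"run {run} has {nv} volumes; need >= {2 * (2 * n_cycles + 2)} "
                f"for a {n_cycles}-cycle basis"
            )
        X = _fourier_basis(nv, n_cycles)
        Y = dataset.data[..., sl].reshape(-1, nv).T  # (t, voxels)
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        filtered = resid + Y.mean(axis=0, keepdims=True)
        out[..., sl] = filtered.T.reshape(dataset.shape + (nv,))
    return BOLDDataset(
        out, tr_s=dataset.tr_s, voxel_size_mm=dataset.voxel_size_mm,
        run_volumes=dataset.run_volumes,
    )


def zscore_runs(dataset: BOLDDataset) -> tuple[BOLDDataset, np.ndarray]:
    """Z-score each voxel within each run (population SD).

    Removes signal offsets and variance differences between runs.
    Constant voxels map to all-zeros; the returned 3D boolean array flags
    voxels that were constant in at least one run.
    """
    out = np.empty_like(dataset.data)
    flagged = np.zeros(dataset.shape, dtype=bool)
    for run in range(1, dataset.n_runs + 1):
        sl = dataset.run_slice(run)
        if sl.stop - sl.start < 2:
            raise ValueError(f"run {run} has fewer than 2 volumes")
        block = dataset.data[..., sl]
        mean = block.mean(axis=3, keepdims=True)
        sd = block.std(axis=3, keepdims=True)  # population (N) SD
        const = sd[..., 0] == 0
        flagged |= const
        sd_safe = np.where(sd == 0, 1.0, sd)
        out[..., sl] = np.where(const[..., None], 0.0, (block - mean) / sd_safe)
    z = BOLDDataset(
        out, tr_s=dataset.tr_s, voxel_size_mm=dataset.voxel_size_mm,
        run_volumes=dataset.run_volumes,
    )
    return z, flagged


def extract_trial_features(
    dataset: BOLDDataset,
    events: EventTable,
    mask: VolumeMask | None = None,
    window_s: tuple[float, float] = (4.0, 10.0),
) -> TrialFeatureMatrix:
    """Average, per trial and voxel, the volumes in the post-onset window.

    A volume acquired at run time ``v * tr`` enters trial ``i`` when its
    onset-relative time lies in the half-open window [4, 10) s — at
    TR = 2 s exactly the 3 volumes at 4, 6 and 8 s after onset.  Labels
    and run ids are carried through in event order (no hidden sorting).
    """
    lo, hi = window_s
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    if mask is not None:
        if mask.grid.shape != dataset.shape:
            raise ValueError("mask shape does not match the dataset grid")
        if mask.n_voxels == 0:
            raise ValueError("selection mask is empty")
        grid = mask.grid
    else:
        grid = np.ones(dataset.shape, dtype=bool)
    voxel_index = np.argwhere(grid)
    flat = dataset.data[grid]  # (voxels, t)

    tr = dataset.tr_s
    run_order = {int(r): i for i, r in enumerate(np.sort(events.runs))}
    starts = np.concatenate([[0], np.cumsum(dataset.run_volumes)])

    values = np.empty((events.n_trials, len(voxel_index)))
    labels = np.empty(events.n_trials, dtype=int)
    runs = np.empty(events.n_trials, dtype=int)
    for i, (_, row) in enumerate(events.frame.iterrows()):
        r = int(row["run"])
        nv = dataset.run_volumes[run_order[r]]
        onset = float(row["onset"])
        # onsets off the volume grid are rounded to the nearest volume
        onset = round(onset / tr) * tr
        local = np.arange(nv) * tr - onset
        vols = np.flatnonzero((local >= lo) & (local < hi))
        if len(vols) == 0 or vols[-1] >= nv or onset + hi > nv * tr:
            raise ValueError(
                f"trial {i + 1} (run {r}, onset {row['onset']} s): feature "
                f"window [{lo}, {hi}) s exceeds the run"
            )
        sel = starts[run_order[r]] + vols
        values[i] = flat[:, sel].mean(axis=1)
        labels[i] = int(row["condition"])
        runs[i] = r
    return TrialFeatureMatrix(values, labels, runs, voxel_index)


def preprocess_and_extract(
    dataset: BOLDDataset,
    events: EventTable,
    mask: VolumeMask | None = None,
    n_cycles: int = 2,
    window_s: tuple[float, float] = (4.0, 10.0),
) -> TrialFeatureMatrix:
    """The canonical chain: high-pass filter, z-score runs, extract features."""
    filtered = highpass_fourier(dataset, n_cycles=n_cycles)
    z, _ = zscore_runs(filtered)
    return extract_trial_features(z, events, mask=mask, window_s=window_s)
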