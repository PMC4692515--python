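"""Ground-truth-labelled synthetic data for every pipeline stage.

The forward model mirrors the analysis GLM: direction-selective voxels
respond to each trial with a condition-specific amplitude, the boxcar of
responses is convolved with the canonical two-gamma HRF, and a slow
cosine drift (one cycle per run) plus iid Gaussian noise are added on
top of a constant baseline.  Non-informative voxels carry baseline,
drift and noise only.  Gaze traces emulate fixation jitter with optional
direction-locked saccades and blinks; the injected events are returned
as a ground-truth log so detector tests have an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from ._seeds import substream
from .containers import BOLDDataset, EventTable, GazeRecording, VolumeMask
from .paradigm import ParadigmSpec
from .univariate import two_gamma_hrf

__all__ = [
    "GroundTruth",
    "generate_bold",
    "dilate_mask",
    "generate_gaze",
]


@dataclass
class GroundTruth:
    """Hidden state of one synthetic BOLD dataset.

    ``informative_voxels`` is an (n, 3) array of grid indices;
    ``amplitude_matrix`` is (n_conditions, n_informative) in the order of
    the paradigm's conditions, in signal units.  ``noise_sd`` is the SD
    of the iid Gaussian noise; ``drift_amplitude`` scales one cosine
    cycle per run; ``baseline`` is the constant raw-signal level.
    """

    informative_voxels: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=int)
    )
    amplitude_matrix: np.ndarray = field(
        default_factory=lambda: np.empty((4, 0))
    )
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.informative_voxels = np.asarray(self.informative_voxels, dtype=int)
        if self.informative_voxels.size == 0:
            self.informative_voxels = self.informative_voxels.reshape(0, 3)
        if self.informative_voxels.ndim != 2 or self.informative_voxels.shape[1] != 3:
            raise ValueError("informative_voxels must be an (n, 3) index array")
        self.amplitude_matrix = np.atleast_2d(np.asarray(self.amplitude_matrix, float))
        if self.amplitude_matrix.shape[1] != len(self.informative_voxels):
            raise ValueError(
                "amplitude_matrix must have one column per informative voxel"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_bold(
    events: EventTable,
    truth: GroundTruth,
    shape: tuple[int, int, int],
    spec: ParadigmSpec,
) -> BOLDDataset:
    """Simulate a 4D BOLD dataset from events and a ground truth.

    signal = baseline
           + sum_c amplitude(c, voxel) * (condition-c boxcar * HRF)
           + drift_amplitude * cos(one cycle over the run)
           + N(0, noise_sd)

    Convolution restarts at run boundaries.  Deterministic for a fixed
    ``truth.seed``.
    """
    if events.n_trials == 0:
        raise ValueError("event table is empty")
    if truth.amplitude_matrix.shape[0] != len(spec.conditions):
        raise ValueError("amplitude_matrix rows must match the paradigm conditions")
    run_volumes = events.run_volumes
    if run_volumes is None:
        raise ValueError("events must carry run_volumes (use generate_events)")
    shape = tuple(int(s) for s in shape)
    if len(truth.informative_voxels) and (
        np.any(truth.informative_voxels < 0)
        or np.any(truth.informative_voxels >= np.asarray(shape))
    ):
        raise ValueError("informative voxels must lie inside the grid shape")

    tr = spec.tr_s
    n_t = int(sum(run_volumes))
    hrf = two_gamma_hrf(np.arange(0.0, 32.0 + tr, tr))
    data = np.full(shape + (n_t,), float(truth.baseline))

    offset = 0
    for idx, run in enumerate(np.sort(events.runs)):
        nv = int(run_volumes[idx])
        sl = slice(offset, offset + nv)
        # condition regressors for this run
        regs = {}
        g = events.for_run(run)
        for ci, cond in enumerate(spec.conditions):
            box = np.zeros(nv)
            for _, row in g[g["condition"] == cond].iterrows():
                v0 = int(round(row["onset"] / tr))
                v1 = int(round((row["onset"] + row["duration"]) / tr))
                if v1 > nv:
                    raise ValueError(f"trial at {row['onset']} s exceeds run {run}")
                box[v0:v1] = 1.0
            regs[ci] = np.convolve(box, hrf)[:nv]
        if truth.drift_amplitude:
            drift = truth.drift_amplitude * np.cos(2 * np.pi * np.arange(nv) / nv)
            data[..., sl] += drift
        for v, (i, j, k) in enumerate(truth.informative_voxels):
            course = np.zeros(nv)
            for ci in range(len(spec.conditions)):
                amp = truth.amplitude_matrix[ci, v]
                if amp:
                    course += amp * regs[ci]
            data[i, j, k, sl] += course
        offset += nv

    if truth.noise_sd > 0:
        rng = substream(truth.seed, "bold-noise")
        data += rng.normal(0.0, truth.noise_sd, size=data.shape)
    return BOLDDataset(data, tr_s=tr, voxel_size_mm=1.1, run_volumes=tuple(run_volumes))


# 6-connected (face adjacency) structuring element.
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def dilate_mask(mask: VolumeMask, n_fold: int) -> VolumeMask:
    """Volumetric n-fold dilation: add face-adjacent neighbours n times.

    The volumetric analog of adding boundary vertices to a surface patch.
    Clipped at grid borders; ``n_fold=0`` returns a copy of the input.
    """
    if n_fold < 0:
        raise ValueError("n_fold must be >= 0")
    if mask.n_voxels == 0:
        raise ValueError("cannot dilate an empty mask")
    grid = mask.grid.copy()
    if n_fold > 0:
        grid = ndimage.binary_dilation(
            grid, structure=_FACE_STRUCTURE, iterations=n_fold
        )
    return VolumeMask(f"{mask.name}_dilated{n_fold}", grid, voxel_size_mm=mask.voxel_size_mm)


def generate_gaze(
    events: EventTable,
    spec: ParadigmSpec,
    direction_lock: dict[int, float] | None = None,
    blink_rate_hz: float = 0.0,
    sampling_rate_hz: float = 60.0,
    seed: int = 0,
    fixation_noise_deg: float = 0.02,
    saccades_per_trial: int = 2,
    saccade_amplitude_deg: float = 1.0,
    saccade_duration_s: float = 0.05,
    direction_kappa: float = 100.0,
    blink_duration_s: float = 0.2,
    par_baseline: float = 1.0,
    par_noise: float = 0.01,
) -> GazeRecording:
    """Simulate a session-long gaze recording.

    Fixation is Gaussian jitter around (0, 0).  If ``direction_lock``
    maps conditions to angles (degrees), ``saccades_per_trial`` smooth
    sigmoidal position steps are injected per trial of those conditions,
    with direction = locked angle + von Mises noise (concentration
    ``direction_kappa``).  Blinks arrive at ``blink_rate_hz`` as pupil
    aspect-ratio drops with gaze dropout to (0, 0)-anchored noise.

    The injected saccades and blinks are attached to the returned
    recording as ground-truth logs (``injected_saccades``,
    ``injected_blinks``).
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    if blink_rate_hz < 0:
        raise ValueError("blink_rate_hz must be >= 0")
    run_volumes = events.run_volumes
    if run_volumes is None:
        raise ValueError("events must carry run_volumes (use generate_events)")
    rng = substream(seed, "gaze")

    total_s = float(sum(run_volumes)) * spec.tr_s
    dt = 1.0 / sampling_rate_hz
    n = int(round(total_s * sampling_rate_hz))
    time_s = np.arange(n) * dt

    x = rng.normal(0.0, fixation_noise_deg, n)
    y = rng.normal(0.0, fixation_noise_deg, n)
    par = par_baseline + rng.normal(0.0, par_noise, n)
    trial_id = np.zeros(n, dtype=int)
    condition = np.zeros(n, dtype=int)

    # run start offsets in session time
    run_starts = {
        int(run): float(sum(run_volumes[:i])) * spec.tr_s
        for i, run in enumerate(np.sort(events.runs))
    }

    sacc_rows = []
    for tnum, (_, row) in enumerate(events.frame.iterrows(), start=1):
        t0 = run_starts[int(row["run"])] + row["onset"]
        t1 = t0 + row["duration"]
        sel = (time_s >= t0) & (time_s < t1)
        trial_id[sel] = tnum
        condition[sel] = int(row["condition"])
        if direction_lock and int(row["condition"]) in direction_lock:
            locked = np.deg2rad(direction_lock[int(row["condition"])])
            margin = 2.0 * saccade_duration_s
            for _ in range(saccades_per_trial):
                tc = rng.uniform(t0 + margin, t1 - margin)
                ang = rng.vonmises(locked, direction_kappa)
                # smooth sigmoidal step of the full amplitude around tc
                step = saccade_amplitude_deg * expit(
                    (time_s - tc) / (saccade_duration_s / 8.0)
                )
                x += np.cos(ang) * step
                y += np.sin(ang) * step
                sacc_rows.append(
                    {
                        "trial": tnum,
                        "condition": int(row["condition"]),
                        "time_s": tc,
                        "direction_deg": float(np.rad2deg(ang) % 360.0),
                        "amplitude_deg": saccade_amplitude_deg,
                    }
                )

    blink_rows = []
    if blink_rate_hz > 0:
        n_blinks = rng.poisson(blink_rate_hz * total_s)
        for tb in np.sort(rng.uniform(0.0, total_s, n_blinks)):
            sel = (time_s >= tb) & (time_s < tb + blink_duration_s)
            par[sel] = 0.2 + rng.normal(0.0, par_noise, sel.sum())
            x[sel] = rng.normal(0.0, 5 * fixation_noise_deg, sel.sum())
            y[sel] = rng.normal(0.0, 5 * fixation_noise_deg, sel.sum())
            blink_rows.append({"time_s": float(tb), "duration_s": blink_duration_s})

    sacc_log = pd.DataFrame(
        sacc_rows,
        columns=["trial", "condition", "time_s", "direction_deg", "amplitude_deg"],
    )
    blink_log = pd.DataFrame(blink_rows, columns=["time_s", "duration_s"])
    return GazeRecording(
        time_s=time_s,
        x_deg=x,
        y_deg=y,
        pupil_aspect_ratio=par,
        trial=trial_id,
        condition=condition,
        sampling_rate_hz=sampling_rate_hz,
        injected_saccades=sacc_log,
        injected_blinks=blink_log,
    )
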