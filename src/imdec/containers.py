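"""In-memory carriers for the decoding pipeline.

The containers mirror the on-disk formats of the field: event tables are
BIDS-style TSV (``run onset duration condition``), volumes are NIfTI-1
with a diagonal affine at the nominal voxel size, gaze recordings are flat
CSV.  Grid indices are 0-based throughout; run indices are 1-based as in
the event files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "BOLDDataset",
    "VolumeMask",
    "TrialFeatureMatrix",
    "GazeRecording",
    "StatMap",
]

EVENT_COLUMNS = ["run", "onset", "duration", "condition"]


class EventTable:
    """Per-trial records of (run, onset, duration, condition).

    Onsets are in seconds from the start of the trial's run.  Conditions
    are the integer direction labels (1-4 by default).  ``run_volumes``
    optionally records how many volumes each run spans, which the
    simulator fills in and file readers may supply or infer.
    """

    def __init__(self, frame: pd.DataFrame, run_volumes: tuple[int, ...] | None = None):
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        self.frame = frame.reset_index(drop=True).astype(
            {"run": int, "onset": float, "duration": float, "condition": int}
        )
        self.run_volumes = tuple(run_volumes) if run_volumes is not None else None
        self._validate()

    def _validate(self) -> None:
        f = self.frame
        if len(f) == 0:
            raise ValueError("event table is empty")
        for run, g in f.groupby("run"):
            g = g.sort_values("onset")
            ends = (g["onset"] + g["duration"]).to_numpy()
            starts = g["onset"].to_numpy()
            if np.any(starts[1:] < ends[:-1] - 1e-9):
                raise ValueError(f"overlapping trials in run {run}")

    # -- conveniences -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.frame)

    @property
    def runs(self) -> np.ndarray:
        return np.sort(self.frame["run"].unique())

    @property
    def conditions(self) -> np.ndarray:
        return np.sort(self.frame["condition"].unique())

    def for_run(self, run: int) -> pd.DataFrame:
        return self.frame[self.frame["run"] == run]

    def condition_counts(self) -> pd.Series:
        return self.frame["condition"].value_counts().sort_index()

    # -- I/O ----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, run_volumes: Sequence[int] | None = None) -> "EventTable":
        frame = pd.read_csv(path, sep="\t")
        rv = tuple(run_volumes) if run_volumes is not None else None
        return cls(frame, run_volumes=rv)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EventTable({self.n_trials} trials, runs={list(self.runs)})"


@dataclass
class BOLDDataset:
    """A 4D (i, j, k, t) voxel grid with runs concatenated along time.

    ``run_volumes`` gives the per-run volume counts; their sum must equal
    the time dimension.  Volume ``v`` of a run is acquired at ``v * tr_s``
    seconds from that run's start.
    """

    data: np.ndarray
    tr_s: float = 2.0
    voxel_size_mm: float = 1.1
    run_volumes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (i, j, k, t)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        self.run_volumes = tuple(int(v) for v in self.run_volumes)
        if not self.run_volumes:
            self.run_volumes = (self.data.shape[3],)
        if sum(self.run_volumes) != self.data.shape[3]:
            raise ValueError(
                f"run_volumes {self.run_volumes} do not sum to the time "
                f"dimension {self.data.shape[3]}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_runs(self) -> int:
        return len(self.run_volumes)

    def run_slice(self, run: int) -> slice:
        """Time slice of 1-based run ``run``."""
        starts = np.concatenate([[0], np.cumsum(self.run_volumes)])
        return slice(int(starts[run - 1]), int(starts[run]))

    def run_data(self, run: int) -> np.ndarray:
        return self.data[..., self.run_slice(run)]

    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    # -- I/O: one NIfTI per run so run boundaries survive round trips --
    def to_nifti_runs(self, directory: str | Path, stem: str = "bold") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for r in range(1, self.n_runs + 1):
            img = nib.Nifti1Image(self.run_data(r), self.affine())
            img.header.set_zooms((self.voxel_size_mm,) * 3 + (self.tr_s,))
            p = directory / f"{stem}_run-{r:02d}.nii"
            nib.save(img, str(p))
            paths.append(p)
        return paths

    @classmethod
    def from_nifti_runs(
        cls, paths: Iterable[str | Path], tr_s: float = 2.0, voxel_size_mm: float | None = None
    ) -> "BOLDDataset":
        arrays, volumes = [], []
        vox = voxel_size_mm
        for p in paths:
            img = nib.load(str(p))
            arr = np.asarray(img.dataobj, dtype=float)
            if arr.ndim != 4:
                raise ValueError(f"{p} is not a 4D image")
            arrays.append(arr)
            volumes.append(arr.shape[3])
            if vox is None:
                vox = float(img.header.get_zooms()[0])
        if not arrays:
            raise ValueError("no run images supplied")
        return cls(
            np.concatenate(arrays, axis=3),
            tr_s=tr_s,
            voxel_size_mm=float(vox),
            run_volumes=tuple(volumes),
        )


@dataclass
class VolumeMask:
    """A named 3D boolean mask aligned to a :class:`BOLDDataset` grid."""

    name: str
    grid: np.ndarray
    voxel_size_mm: float = 1.1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) array of the included voxel indices, lexicographic order."""
        return np.argwhere(self.grid)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(
            self.grid.astype(np.uint8), np.diag([self.voxel_size_mm] * 3 + [1.0])
        )
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, name: str | None = None) -> "VolumeMask":
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj) > 0
        vox = float(img.header.get_zooms()[0])
        return cls(name or Path(path).stem, grid, voxel_size_mm=vox)


@dataclass
class TrialFeatureMatrix:
    """Trials x voxels feature matrix with labels and run ids.

    ``values`` are in z-units after run-wise standardisation.  ``voxel_index``
    maps each column back to its (i, j, k) grid position.
    """

    values: np.ndarray
    labels: np.ndarray
    runs: np.ndarray
    voxel_index: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.runs = np.asarray(self.runs, dtype=int)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        n, p = self.values.shape
        if len(self.labels) != n or len(self.runs) != n:
            raise ValueError("labels/runs length must match trial count")
        if self.voxel_index.shape != (p, 3):
            raise ValueError("voxel_index must be (n_voxels, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def with_labels(self, labels: np.ndarray) -> "TrialFeatureMatrix":
        return TrialFeatureMatrix(self.values, labels, self.runs, self.voxel_index)

    def select_voxels(self, columns: np.ndarray) -> "TrialFeatureMatrix":
        return TrialFeatureMatrix(
            self.values[:, columns], self.labels, self.runs, self.voxel_index[columns]
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"label": self.labels, "run": self.runs}
        frame = pd.DataFrame(cols)
        vox = pd.DataFrame(
            self.values,
            columns=[f"v_{i}_{j}_{k}" for i, j, k in self.voxel_index],
        )
        return pd.concat([frame, vox], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialFeatureMatrix":
        frame = pd.read_csv(path)
        vox_cols = [c for c in frame.columns if c.startswith("v_")]
        voxel_index = np.array([[int(x) for x in c.split("_")[1:]] for c in vox_cols])
        return cls(
            frame[vox_cols].to_numpy(float),
            frame["label"].to_numpy(int),
            frame["run"].to_numpy(int),
            voxel_index,
        )


@dataclass
class GazeRecording:
    """Monocular gaze samples with pupil aspect ratio and trial annotation.

    ``trial`` is the 1-based global trial number (0 between trials);
    ``condition`` is the imagined direction label (0 between trials).
    Blink-removed recordings may have gaps in ``time_s``.
    """

    time_s: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil_aspect_ratio: np.ndarray
    trial: np.ndarray
    condition: np.ndarray
    sampling_rate_hz: float
    injected_saccades: pd.DataFrame | None = field(default=None, repr=False)
    injected_blinks: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arrays = [self.time_s, self.x_deg, self.y_deg, self.pupil_aspect_ratio,
                  self.trial, self.condition]
        n = len(self.time_s)
        if any(len(a) != n for a in arrays):
            raise ValueError("gaze channels must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    def trial_ids(self) -> np.ndarray:
        ids = np.unique(self.trial)
        return ids[ids > 0]

    def samples_of(self, trial_id: int) -> np.ndarray:
        return np.flatnonzero(self.trial == trial_id)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time": self.time_s,
                "x": self.x_deg,
                "y": self.y_deg,
                "par": self.pupil_aspect_ratio,
                "trial": self.trial,
                "condition": self.condition,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sampling_rate_hz: float | None = None) -> "GazeRecording":
        frame = pd.read_csv(path)
        t = frame["time"].to_numpy(float)
        if sampling_rate_hz is None:
            sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(
            t,
            frame["x"].to_numpy(float),
            frame["y"].to_numpy(float),
            frame["par"].to_numpy(float),
            frame["trial"].to_numpy(int),
            frame["condition"].to_numpy(int),
            float(sampling_rate_hz),
        )


@dataclass
class StatMap:
    """A 3D lattice of per-voxel statistics, NaN outside the swept set.

    ``kind`` tags the value type: ``"accuracy"``, ``"chi2"``, ``"p"``,
    ``"t"``, ``"label"`` or ``"mask"``.
    """

    values: np.ndarray
    kind: str
    voxel_size_mm: float = 1.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("stat map must be 3D")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(
            self.values.astype(np.float32), np.diag([self.voxel_size_mm] * 3 + [1.0])
        )
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, kind: str) -> "StatMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), kind,
                   voxel_size_mm=float(img.header.get_zooms()[0]))
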