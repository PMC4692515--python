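"""Univariate GLM analysis with a canonical two-gamma HRF.

Condition regressors are unit boxcars over each trial, sampled at the TR
and discretely convolved with the hemodynamic response; contrasts test
each imagined direction against the mean of the other three.  The model
is ordinary least squares per voxel; no temporal autocorrelation model is
fitted (the high-pass filter of :mod:`imdec.preprocess` is assumed).

Organised statsmodels-style: :class:`VoxelGLM` is built from data and a
design; :meth:`VoxelGLM.fit` returns :class:`VoxelGLMResults` carrying
betas, residual variances and degrees of freedom, from which t-maps,
FDR thresholding and preference maps are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BOLDDataset, EventTable, StatMap, VolumeMask

__all__ = [
    "two_gamma_hrf",
    "build_design",
    "DesignMatrix",
    "VoxelGLM",
    "VoxelGLMResults",
    "fit_glm",
    "contrast_t",
    "fdr_threshold_t",
    "preference_map",
]

# Canonical two-gamma parameterisation: response delay 6 s, undershoot
# delay 16 s, unit dispersions, peak:undershoot amplitude ratio 6.
HRF_PEAK_DELAY_S = 6.0
HRF_UNDER_DELAY_S = 16.0
HRF_PEAK_DISP_S = 1.0
HRF_UNDER_DISP_S = 1.0
HRF_RATIO = 6.0


def two_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = HRF_PEAK_DELAY_S,
    under_delay: float = HRF_UNDER_DELAY_S,
    peak_disp: float = HRF_PEAK_DISP_S,
    under_disp: float = HRF_UNDER_DISP_S,
    ratio: float = HRF_RATIO,
) -> np.ndarray:
    """Canonical two-gamma hemodynamic impulse response, peak-normalised.

    The response is the difference of two gamma densities (peak minus a
    scaled undershoot).  The output is scaled so the global maximum of
    the continuous response is 1, independent of the sampling grid
    supplied in ``t``.
    """
    t = np.asarray(t, dtype=float)

    def _shape(x: np.ndarray) -> np.ndarray:
        peak = stats.gamma.pdf(x, peak_delay / peak_disp, scale=peak_disp)
        under = stats.gamma.pdf(x, under_delay / under_disp, scale=under_disp)
        return peak - under / ratio

    dense = _shape(np.arange(0.0, under_delay + 16.0, 0.01))
    return _shape(t) / dense.max()


@dataclass
class DesignMatrix:
    """Volumes x regressors design with named columns.

    The first ``len(condition_labels)`` columns are the HRF-convolved
    condition predictors (one per direction), followed by per-run
    intercepts and optional per-run linear drifts.
    """

    matrix: np.ndarray
    names: list[str]
    condition_labels: list[int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("design matrix shape does not match column names")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def condition_column(self, label: int) -> int:
        return self.condition_labels.index(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def build_design(
    events: EventTable,
    tr_s: float,
    run_volumes: tuple[int, ...] | None = None,
    drift: bool = True,
    conditions: tuple[int, ...] = (1, 2, 3, 4),
) -> DesignMatrix:
    """HRF-convolved condition boxcars plus per-run intercept/drift columns.

    Convolution is volume-wise at the TR (all paradigm times are TR
    multiples) and restarts at each run boundary.  One predictor is built
    for every label in ``conditions``; a condition with no trials yields
    an all-zero column and the rank check fails.
    """
    if run_volumes is None:
        run_volumes = events.run_volumes
    if run_volumes is None:
        raise ValueError("run_volumes not provided and not stored on the event table")
    runs = list(events.runs)
    if len(run_volumes) != len(runs):
        raise ValueError("run_volumes length does not match the number of runs")
    labels = [int(c) for c in conditions]
    extra = set(int(c) for c in events.conditions) - set(labels)
    if extra:
        raise ValueError(f"events contain conditions {sorted(extra)} not in {labels}")
    hrf = two_gamma_hrf(np.arange(0.0, 32.0 + tr_s, tr_s))

    cond_cols = {c: [] for c in labels}
    intercepts, drifts = [], []
    for idx, run in enumerate(runs):
        nv = int(run_volumes[idx])
        g = events.for_run(run)
        for c in labels:
            box = np.zeros(nv)
            for _, row in g[g["condition"] == c].iterrows():
                v0 = int(round(row["onset"] / tr_s))
                v1 = int(round((row["onset"] + row["duration"]) / tr_s))
                if v1 > nv:
                    raise ValueError(
                        f"trial at {row['onset']} s in run {run} exceeds run length"
                    )
                box[v0:v1] = 1.0
            cond_cols[c].append(np.convolve(box, hrf)[:nv])
        block = np.zeros((nv, len(runs)))
        block[:, idx] = 1.0
        intercepts.append(block)
        dblock = np.zeros((nv, len(runs)))
        dblock[:, idx] = np.linspace(-1.0, 1.0, nv)
        drifts.append(dblock)

    columns = [np.concatenate(cond_cols[c]) for c in labels]
    names = [f"cond_{c}" for c in labels]
    columns.append(np.vstack(intercepts))
    names += [f"const_run{r}" for r in runs]
    if drift:
        columns.append(np.vstack(drifts))
        names += [f"drift_run{r}" for r in runs]
    X = np.column_stack(
        [c if c.ndim == 2 else c[:, None] for c in columns]
    )
    design = DesignMatrix(X, names, condition_labels=labels)
    if design.rank < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (empty condition predictor or "
            "collinear drift terms)"
        )
    return design


class VoxelGLM:
    """Mass-univariate OLS model of voxel time courses.

    Parameters
    ----------
    data : (n_volumes, n_voxels) array or BOLDDataset
        Voxel time courses.  A 4D dataset is flattened over the optional
        ``mask`` (all voxels when no mask is given); ``voxel_index`` then
        records the grid position of each column.
    design : DesignMatrix
    """

    def __init__(
        self,
        data: np.ndarray | BOLDDataset,
        design: DesignMatrix,
        mask: VolumeMask | None = None,
    ):
        if isinstance(data, BOLDDataset):
            grid = mask.grid if mask is not None else np.ones(data.shape, bool)
            self.voxel_index = np.argwhere(grid)
            self.shape3d: tuple[int, int, int] | None = data.shape
            Y = data.data[grid].T  # (t, voxels)
        else:
            Y = np.asarray(data, dtype=float)
            self.voxel_index = None
            self.shape3d = None
        if not np.all(np.isfinite(Y)):
            raise ValueError("GLM input contains non-finite values")
        if Y.shape[0] != design.n_volumes:
            raise ValueError("data and design disagree on the number of volumes")
        if design.rank < design.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.endog = Y
        self.design = design

    def fit(self) -> "VoxelGLMResults":
        X = self.design.matrix
        beta, _, _, _ = np.linalg.lstsq(X, self.endog, rcond=None)
        resid = self.endog - X @ beta
        dof = X.shape[0] - self.design.rank
        sigma2 = (resid**2).sum(axis=0) / dof
        return VoxelGLMResults(self, beta, sigma2, dof)


@dataclass
class VoxelGLMResults:
    """OLS estimates per voxel: betas, residual variance, dof."""

    model: VoxelGLM
    beta: np.ndarray  # (n_regressors, n_voxels)
    sigma2: np.ndarray  # (n_voxels,)
    dof: int

    def contrast_t(self, weights: np.ndarray) -> np.ndarray:
        """t-statistics for the linear contrast ``weights`` per voxel.

        Voxels with zero residual variance get ±inf (flagged, not an
        error) where the contrast estimate is nonzero, and 0 otherwise.
        """
        w = np.asarray(weights, dtype=float)
        X = self.model.design.matrix
        xtx_inv = np.linalg.pinv(X.T @ X)
        est = w @ self.beta
        var = self.sigma2 * float(w @ xtx_inv @ w)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(var)
        t[np.isnan(t) & (est == 0)] = 0.0
        return t

    def one_vs_all_weights(self, condition: int) -> np.ndarray:
        """+1 on ``condition``, -1/3 on the other directions, 0 elsewhere."""
        labels = self.model.design.condition_labels
        if condition not in labels:
            raise ValueError(f"condition {condition} not in design")
        w = np.zeros(self.model.design.matrix.shape[1])
        others = [c for c in labels if c != condition]
        w[self.model.design.condition_column(condition)] = 1.0
        for c in others:
            w[self.model.design.condition_column(c)] = -1.0 / len(others)
        return w

    def one_vs_all_t(self, condition: int) -> np.ndarray:
        return self.contrast_t(self.one_vs_all_weights(condition))

    def t_map(self, condition: int) -> StatMap:
        """One-vs-all t-statistics as a 3D map (requires a gridded model)."""
        return self._to_map(self.one_vs_all_t(condition), "t")

    def _to_map(self, values: np.ndarray, kind: str) -> StatMap:
        if self.model.voxel_index is None or self.model.shape3d is None:
            raise ValueError("model was built from a flat array, not a volume")
        grid = np.full(self.model.shape3d, np.nan)
        idx = self.model.voxel_index
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = values
        return StatMap(grid, kind)

    def summary(self) -> str:
        lines = [
            "Voxel-wise GLM (OLS)",
            f"  volumes:    {self.model.design.n_volumes}",
            f"  regressors: {len(self.model.design.names)}",
            f"  voxels:     {self.endog_voxels}",
            f"  residual dof: {self.dof}",
            f"  median residual variance: {np.median(self.sigma2):.4g}",
        ]
        return "\n".join(lines)

    @property
    def endog_voxels(self) -> int:
        return self.beta.shape[1]


def fit_glm(
    data: np.ndarray | BOLDDataset, design: DesignMatrix, mask: VolumeMask | None = None
) -> VoxelGLMResults:
    """Convenience wrapper: ``VoxelGLM(data, design, mask).fit()``."""
    return VoxelGLM(data, design, mask=mask).fit()


def contrast_t(results: VoxelGLMResults, condition: int) -> np.ndarray:
    """One-vs-all contrast t-statistics for ``condition``."""
    return results.one_vs_all_t(condition)


def fdr_threshold_t(
    t: np.ndarray, dof: int, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided t-test p-values with BH-FDR thresholding.

    Returns ``(mask, p_adjusted)`` where ``mask`` is True for voxels whose
    adjusted p falls below ``q``.  Infinite t-values get p = 0.
    """
    if dof <= 0:
        raise ValueError("dof must be positive")
    t = np.asarray(t, dtype=float)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[np.isinf(t)] = 0.0
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def preference_map(tmaps: dict[int, StatMap], sig_mask: StatMap | np.ndarray) -> StatMap:
    """Per-voxel argmax direction label inside the significance mask.

    ``tmaps`` maps condition labels to one-vs-all t-maps on a common grid.
    Ties go to the lowest label; voxels outside the mask are 0/NaN.
    """
    labels = sorted(tmaps)
    grids = [tmaps[c].values for c in labels]
    shapes = {g.shape for g in grids}
    mask = sig_mask.values > 0 if isinstance(sig_mask, StatMap) else np.asarray(sig_mask, bool)
    if len(shapes) != 1 or mask.shape not in shapes:
        raise ValueError("t-maps and significance mask must share one grid shape")
    stack = np.stack(grids)  # (4, i, j, k)
    best = np.argmax(stack, axis=0)  # first max -> lowest label on ties
    out = np.full(mask.shape, np.nan)
    out[mask] = np.asarray(labels)[best[mask]]
    return StatMap(out, "label")
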