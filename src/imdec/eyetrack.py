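"""Eye-movement confound analysis.

Blink samples are rejected per trial by a +/- 2 SD interval on the pupil
aspect ratio.  Saccades are detected with the velocity-threshold
(Engbert-Kliegl style) algorithm: a 5-sample moving-window velocity, a
median-based robust SD per axis, and an elliptic threshold at ``lambda``
robust SDs sustained for a minimum duration.  Saccade directions and
per-trial gaze-ellipse rotations are compared across imagined directions
with circular statistics: Fisher's common-median test and the
circular-circular (Jammalamadaka-SenGupta) correlation.  Ellipse
rotations are axial (180-degree periodic) and are doubled before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GazeRecording

__all__ = [
    "SaccadeParams",
    "SaccadeEvent",
    "EllipseFit",
    "CircTestResult",
    "remove_blinks",
    "detect_saccades",
    "saccade_table",
    "circ_median",
    "circ_median_test",
    "circ_corr",
    "fit_mvee",
    "ellipse_rotation_tests",
]


@dataclass
class SaccadeParams:
    """Velocity-threshold detector settings.

    ``lam`` multiplies the per-axis robust velocity SD to form the
    elliptic detection threshold; events must exceed it for at least
    ``min_duration_samples`` consecutive samples.
    """

    lam: float = 6.0
    min_duration_samples: int = 3
    velocity_window: int = 5

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.min_duration_samples < 1:
            raise ValueError("min_duration_samples must be >= 1")
        if self.velocity_window != 5:
            raise ValueError("only the canonical 5-sample velocity window is supported")


@dataclass
class SaccadeEvent:
    """One detected saccade within a trial."""

    trial: int
    condition: int
    onset_index: int
    offset_index: int
    amplitude_deg: float
    direction_deg: float  # [0, 360), atan2 of net displacement

    def __post_init__(self) -> None:
        if self.offset_index <= self.onset_index:
            raise ValueError("offset must come after onset")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class EllipseFit:
    """Minimum-volume enclosing ellipse of one trial's gaze samples."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b) with a >= b
    rotation_deg: float  # axial angle of the major axis in [0, 180)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not a >= b > 0:
            raise ValueError("semi-axes must satisfy a >= b > 0")

    def contains(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        """Boolean per point: inside or on the ellipse within tolerance."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.center)
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        uv = pts @ rot.T
        a, b = self.semi_axes
        return (uv[:, 0] / a) ** 2 + (uv[:, 1] / b) ** 2 <= 1 + tol

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


@dataclass
class CircTestResult:
    """Outcome of a circular test (common-median P or correlation r)."""

    statistic_name: str
    statistic_value: float
    p_value: float
    n: tuple[int, ...]
    note: str = ""


# ---------------------------------------------------------------------------
# blink rejection
# ---------------------------------------------------------------------------

def remove_blinks(gaze: GazeRecording) -> tuple[GazeRecording, pd.DataFrame]:
    """Discard samples whose pupil aspect ratio leaves the per-trial CI.

    Per trial, samples with aspect ratio outside mean +/- 2 SD of that
    trial are dropped.  Returns the cleaned recording (between-trial
    samples are kept untouched) and a per-trial report with the retention
    fraction; trials retaining nothing are flagged for downstream
    exclusion.
    """
    keep = np.ones(gaze.n_samples, dtype=bool)
    rows = []
    for tid in gaze.trial_ids():
        sel = gaze.samples_of(int(tid))
        par = gaze.pupil_aspect_ratio[sel]
        mean, sd = par.mean(), par.std()
        inside = np.abs(par - mean) <= 2 * sd  # sd == 0 keeps all equal values
        keep[sel[~inside]] = False
        rows.append(
            {
                "trial": int(tid),
                "n_samples": len(sel),
                "retained": int(inside.sum()),
                "retention": float(inside.mean()),
                "excluded": bool(inside.sum() == 0),
            }
        )
    report = pd.DataFrame(rows, columns=["trial", "n_samples", "retained", "retention", "excluded"])
    cleaned = GazeRecording(
        time_s=gaze.time_s[keep],
        x_deg=gaze.x_deg[keep],
        y_deg=gaze.y_deg[keep],
        pupil_aspect_ratio=gaze.pupil_aspect_ratio[keep],
        trial=gaze.trial[keep],
        condition=gaze.condition[keep],
        sampling_rate_hz=gaze.sampling_rate_hz,
        injected_saccades=gaze.injected_saccades,
        injected_blinks=gaze.injected_blinks,
    )
    return cleaned, report


# ---------------------------------------------------------------------------
# saccade detection
# ---------------------------------------------------------------------------

def _window_velocity(p: np.ndarray, dt: float) -> np.ndarray:
    """5-sample moving-window derivative; endpoints get zero velocity."""
    v = np.zeros_like(p)
    v[2:-2] = (p[4:] + p[3:-1] - p[1:-3] - p[:-4]) / (6.0 * dt)
    return v


def detect_saccades(
    gaze: GazeRecording, params: SaccadeParams | None = None
) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection per trial.

    Velocities come from a 5-sample moving window; the per-axis robust
    SD is sqrt(median(v^2) - median(v)^2).  Samples satisfying the
    elliptic criterion (vx / (lam * sx))^2 + (vy / (lam * sy))^2 > 1 for
    at least ``min_duration_samples`` in a row form one saccade whose
    direction is the atan2 of the net displacement.
    """
    params = params or SaccadeParams()
    dt = 1.0 / gaze.sampling_rate_hz
    events: list[SaccadeEvent] = []
    for tid in gaze.trial_ids():
        sel = gaze.samples_of(int(tid))
        if len(sel) < params.velocity_window:
            continue
        x = gaze.x_deg[sel]
        y = gaze.y_deg[sel]
        vx = _window_velocity(x, dt)
        vy = _window_velocity(y, dt)
        core = slice(2, len(sel) - 2)  # velocities defined away from edges
        sx = np.sqrt(np.median(vx[core] ** 2) - np.median(vx[core]) ** 2)
        sy = np.sqrt(np.median(vy[core] ** 2) - np.median(vy[core]) ** 2)
        if sx == 0 or sy == 0:
            raise ValueError(f"degenerate gaze trace in trial {tid} (zero robust SD)")
        crit = (vx / (params.lam * sx)) ** 2 + (vy / (params.lam * sy)) ** 2 > 1
        crit[:2] = crit[len(sel) - 2:] = False
        for on, off in _runs(crit, params.min_duration_samples):
            dx = x[off - 1] - x[on]
            dy = y[off - 1] - y[on]
            events.append(
                SaccadeEvent(
                    trial=int(tid),
                    condition=int(gaze.condition[sel[on]]),
                    onset_index=int(sel[on]),
                    offset_index=int(sel[off - 1]),
                    amplitude_deg=float(np.hypot(dx, dy)),
                    direction_deg=float(np.rad2deg(np.arctan2(dy, dx)) % 360.0),
                )
            )
    return events


def _runs(flags: np.ndarray, min_len: int):
    """Yield (start, stop) of True runs with length >= min_len."""
    padded = np.concatenate([[False], flags, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    for a, b in zip(starts, stops):
        if b - a >= min_len:
            yield int(a), int(b)


def saccade_table(events: list[SaccadeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial": e.trial,
                "condition": e.condition,
                "onset_index": e.onset_index,
                "offset_index": e.offset_index,
                "amplitude_deg": e.amplitude_deg,
                "direction_deg": e.direction_deg,
            }
            for e in events
        ],
        columns=["trial", "condition", "onset_index", "offset_index",
                 "amplitude_deg", "direction_deg"],
    )


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def _circ_dist(a: np.ndarray, b: float) -> np.ndarray:
    """Signed circular distance a - b wrapped to (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a) - b)))


def circ_median(angles: np.ndarray) -> float:
    """Circular median: the sample angle minimising mean absolute deviation.

    Candidates are the data points themselves (deterministic argmin on
    ties by first occurrence), matching the usual toolbox convention.
    """
    a = np.asarray(angles, dtype=float)
    if len(a) == 0:
        raise ValueError("empty angle sample")
    devs = [np.mean(np.abs(_circ_dist(a, m))) for m in a]
    return float(a[int(np.argmin(devs))])


def circ_median_test(groups: list[np.ndarray]) -> CircTestResult:
    """Fisher's non-parametric multi-sample test for equal median directions.

    Counts, per group, the angles on the negative side of the pooled
    circular median's diameter; the P statistic is chi-square distributed
    with (#groups - 1) df under the common-median null.  Degenerate
    pooled samples (all counts on one side) are flagged with p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 angles")
    pooled = np.concatenate(groups)
    if np.allclose(_circ_dist(pooled, pooled[0]), 0):
        return CircTestResult("P", 0.0, 1.0, tuple(len(g) for g in groups),
                              note="all angles identical; degenerate")
    med = circ_median(pooled)
    m = np.array([float(np.sum(_circ_dist(g, med) < 0)) for g in groups])
    n = np.array([len(g) for g in groups], dtype=float)
    N, M = n.sum(), m.sum()
    if M == 0 or M == N:
        return CircTestResult("P", 0.0, 1.0, tuple(len(g) for g in groups),
                              note="degenerate side counts")
    P = N**2 / (M * (N - M)) * float(np.sum(m**2 / n)) - N * M / (N - M)
    p = float(stats.chi2.sf(P, len(groups) - 1))
    return CircTestResult("P", float(P), p, tuple(len(g) for g in groups))


def circ_corr(a: np.ndarray, b: np.ndarray) -> CircTestResult:
    """Circular-circular correlation (Jammalamadaka-SenGupta) with its
    large-sample p-value.

    r = sum sin(a - abar) sin(b - bbar) /
        sqrt(sum sin^2(a - abar) sum sin^2(b - bbar))
    with abar, bbar the circular mean directions.  A zero denominator
    (one sample concentrated exactly on its mean direction) is flagged
    as undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired angle vectors must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired angles")
    abar = float(np.angle(np.mean(np.exp(1j * a))))
    bbar = float(np.angle(np.mean(np.exp(1j * b))))
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    den = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if den == 0:
        return CircTestResult("r", float("nan"), float("nan"), (n,),
                              note="zero denominator; r undefined")
    r = float(np.sum(sa * sb) / den)
    l20 = np.mean(sa**2)
    l02 = np.mean(sb**2)
    l22 = np.mean(sa**2 * sb**2)
    if l22 == 0:
        return CircTestResult("r", r, float("nan"), (n,), note="degenerate variance")
    z = np.sqrt(n * l20 * l02 / l22) * r
    p = float(2 * stats.norm.sf(abs(z)))
    return CircTestResult("r", r, p, (n,))


# ---------------------------------------------------------------------------
# minimum-volume enclosing ellipse
# ---------------------------------------------------------------------------

def fit_mvee(points: np.ndarray, tolerance: float = 1e-4, max_iter: int = 10_000) -> EllipseFit:
    """Khachiyan's algorithm for the minimum-volume enclosing ellipse.

    Iteratively reweights the points until the relative weight change
    falls below ``tolerance``; the ellipse is then rescaled minimally so
    every input point is contained (guarding against the last iteration
    stopping marginally short).  Requires >= 3 non-collinear points.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.linalg.matrix_rank(P - P.mean(axis=0)) < 2:
        raise ValueError("points are collinear; ellipse is degenerate")

    d = 2
    Q = np.column_stack([P, np.ones(n)]).T  # (3, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T @ np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        mx = M[j]
        step = (mx - d - 1.0) / ((d + 1.0) * (mx - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        err = np.linalg.norm(new_u - u)
        u = new_u
        if err < tolerance:
            break

    center = P.T @ u
    A = np.linalg.inv(P.T @ np.diag(u) @ P - np.outer(center, center)) / d
    # guarantee containment: rescale so the farthest point sits on the boundary
    rel = P - center
    radii = np.einsum("ij,jk,ik->i", rel, A, rel)
    scale = max(1.0, float(radii.max()))
    A = A / scale

    eigval, eigvec = np.linalg.eigh(A)
    axes = 1.0 / np.sqrt(eigval)  # ascending eigval -> descending axis
    order = np.argsort(axes)[::-1]
    a, b = float(axes[order[0]]), float(axes[order[1]])
    major = eigvec[:, order[0]]
    rotation = float(np.rad2deg(np.arctan2(major[1], major[0])) % 180.0)
    return EllipseFit(center=(float(center[0]), float(center[1])),
                      semi_axes=(a, b), rotation_deg=rotation)


def ellipse_rotation_tests(
    fits: list[EllipseFit], condition_angles_deg: np.ndarray
) -> tuple[CircTestResult, CircTestResult]:
    """Equal-median test and circular correlation on ellipse rotations.

    Rotations are axial (a line, not a direction), so they are doubled to
    the full circle before testing; results are reported on the doubled
    scale.  ``condition_angles_deg`` gives the imagined direction per
    trial; the median test groups the doubled rotations by condition.
    """
    if len(fits) != len(condition_angles_deg):
        raise ValueError("one condition angle per fitted trial is required")
    doubled = np.deg2rad(2.0 * np.array([f.rotation_deg for f in fits]))
    cond = np.asarray(condition_angles_deg, dtype=float)
    groups = [doubled[cond == c] for c in np.unique(cond)]
    for g in groups:
        if len(g) < 2:
            raise ValueError("need at least 2 trials per condition")
    median_res = circ_median_test(groups)
    corr_res = circ_corr(doubled, np.deg2rad(cond))
    return median_res, corr_res
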