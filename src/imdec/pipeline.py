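"""Configuration and end-to-end orchestration of the synthetic pipeline.

``RunConfig`` holds every stage parameter with the analysis defaults
(k = 1000 selected voxels, 1000 permutations, radius-4 searchlight,
q = 0.05 FDR, lambda = 6 saccade threshold) plus one master seed that is
fanned out into named substreams.  ``run_pipeline`` executes the
requested stages — simulate, preprocess, decode, searchlight,
univariate, eyetrack — writing JSON/CSV/NIfTI outputs and a provenance
sidecar (config hash, seed, package versions) so that a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._seeds import substream
from .containers import BOLDDataset, EventTable, VolumeMask
from .decode import DirectionDecoder
from .eyetrack import (
    SaccadeParams,
    detect_saccades,
    ellipse_rotation_tests,
    fit_mvee,
    remove_blinks,
    saccade_table,
)
from .paradigm import ParadigmSpec, generate_events
from .preprocess import extract_trial_features, highpass_fourier, zscore_runs
from .searchlight import run_searchlight, sphere_offsets
from .synth import GroundTruth, dilate_mask, generate_bold, generate_gaze
from .univariate import VoxelGLM, build_design, fdr_threshold_t, preference_map

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "preprocess", "decode", "searchlight", "univariate", "eyetrack")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the analysis defaults."""

    # paradigm
    tr_s: float = 2.0
    n_runs: int = 4
    blocks_per_run: int = 10
    # simulation
    shape: tuple[int, int, int] = (8, 8, 6)
    n_informative: int = 16
    amplitude: float = 1.5
    noise_sd: float = 1.0
    drift_amplitude: float = 2.0
    baseline: float = 100.0
    # decoding
    k: int = 1000
    n_perm: int = 1000
    C: float = 1.0
    perm_scheme: str = "global"
    # searchlight
    radius: int = 4
    q: float = 0.05
    # eye tracking
    lam: float = 6.0
    sampling_rate_hz: float = 60.0
    blink_rate_hz: float = 0.05
    direction_locked_gaze: bool = False
    # bookkeeping
    seed: int = 0
    out_dir: str = "imdec_out"

    def validate(self) -> None:
        ParadigmSpec(
            tr_s=self.tr_s, n_runs=self.n_runs, blocks_per_run=self.blocks_per_run,
            seed=self.seed,
        )
        n_vox = int(np.prod(self.shape))
        if self.k > n_vox:
            raise ValueError(
                f"k={self.k} exceeds the {n_vox} voxels of shape {self.shape}; "
                "lower k or enlarge the grid"
            )
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def spec(self) -> ParadigmSpec:
        return ParadigmSpec(
            tr_s=self.tr_s, n_runs=self.n_runs, blocks_per_run=self.blocks_per_run,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["shape"] = tuple(raw.get("shape", (8, 8, 6)))
        return cls(**raw)


def _provenance(config: RunConfig) -> dict:
    import scipy
    import sklearn

    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "imdec": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
    }


def _simulate(config: RunConfig, out: Path) -> dict:
    spec = config.spec()
    events = generate_events(spec)
    rng = substream(config.seed, "truth-layout")
    n_vox = int(np.prod(config.shape))
    flat = rng.choice(n_vox, size=min(config.n_informative, n_vox), replace=False)
    informative = np.column_stack(np.unravel_index(flat, config.shape))
    # each informative voxel prefers one direction (round-robin)
    amp = np.zeros((len(spec.conditions), len(informative)))
    for v in range(len(informative)):
        amp[v % len(spec.conditions), v] = config.amplitude
    truth = GroundTruth(
        informative_voxels=informative,
        amplitude_matrix=amp,
        noise_sd=config.noise_sd,
        drift_amplitude=config.drift_amplitude,
        baseline=config.baseline,
        seed=config.seed,
    )
    bold = generate_bold(events, truth, config.shape, spec)
    roi = VolumeMask("roi", np.ones(config.shape, bool))
    seed_grid = np.zeros(config.shape, bool)
    seed_grid[tuple(informative[0])] = True
    dilated = dilate_mask(VolumeMask("seed", seed_grid), 2)

    events.to_tsv(out / "events.tsv")
    bold.to_nifti_runs(out, stem="bold")
    roi.to_nifti(out / "roi.nii")
    dilated.to_nifti(out / "seed_dilated.nii")
    lock = (
        {c: spec.condition_angles_deg[c] for c in spec.conditions}
        if config.direction_locked_gaze
        else None
    )
    gaze = generate_gaze(
        events, spec, direction_lock=lock, blink_rate_hz=config.blink_rate_hz,
        sampling_rate_hz=config.sampling_rate_hz, seed=config.seed,
    )
    gaze.to_csv(out / "gaze.csv")
    (out / "truth.json").write_text(
        json.dumps(
            {
                "informative_voxels": informative.tolist(),
                "amplitude": config.amplitude,
                "noise_sd": config.noise_sd,
                "run_volumes": list(events.run_volumes),
            },
            indent=2,
        )
    )
    return {"events": events, "bold": bold, "roi": roi, "gaze": gaze, "spec": spec}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Execute the requested stages on one synthetic session.

    Returns a result bundle (in-memory objects per stage) and writes all
    artefacts under ``config.out_dir``.  Deterministic for a fixed
    config and seed.
    """
    config.validate()
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; choose from {ALL_STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"provenance": _provenance(config)}
    (out / "provenance.json").write_text(json.dumps(bundle["provenance"], indent=2))
    config.to_json(out / "config.json")

    sim = _simulate(config, out)
    bundle.update(sim)
    if set(stages) == {"simulate"}:
        return bundle

    filtered = highpass_fourier(sim["bold"])
    zscored, flagged = zscore_runs(filtered)
    bundle["zscored"] = zscored
    bundle["constant_voxels"] = flagged
    if "preprocess" in stages or "decode" in stages:
        k = min(config.k, int(np.prod(config.shape)))
        features = extract_trial_features(zscored, sim["events"], mask=sim["roi"])
        features.to_csv(out / "features.csv")
        bundle["features"] = features
        if "decode" in stages:
            decoder = DirectionDecoder(
                features, n_features=k, C=config.C, scheme=config.perm_scheme
            )
            result = decoder.fit(n_perm=config.n_perm, seed=config.seed)
            result.to_json(out / "decoding.json")
            bundle["decoding"] = result

    if "searchlight" in stages:
        ribbon = VolumeMask("ribbon", np.ones(config.shape, bool))
        radius = min(config.radius, (min(config.shape) - 1) // 2)
        sl = run_searchlight(
            zscored, sim["events"], ribbon, sphere=sphere_offsets(radius), C=config.C
        )
        sl.accuracy.to_nifti(out / "searchlight_accuracy.nii")
        chi, p = sl.chi_square_maps()
        chi.to_nifti(out / "searchlight_chi2.nii")
        p.to_nifti(out / "searchlight_p.nii")
        sig = sl.significant(q=config.q)
        sig.to_nifti(out / "searchlight_sig.nii")
        bundle["searchlight"] = sl
        bundle["searchlight_sig"] = sig

    if "univariate" in stages:
        design = build_design(sim["events"], config.tr_s)
        fit = VoxelGLM(zscored, design).fit()
        tmaps = {c: fit.t_map(c) for c in design.condition_labels}
        for c, tm in tmaps.items():
            tm.to_nifti(out / f"tmap_cond{c}.nii")
            mask, _ = fdr_threshold_t(fit.one_vs_all_t(c), fit.dof, q=config.q)
            bundle.setdefault("t_fdr_masks", {})[c] = mask
        bundle["glm"] = fit
        bundle["tmaps"] = tmaps
        if "searchlight_sig" in bundle:
            pref = preference_map(tmaps, bundle["searchlight_sig"])
            pref.to_nifti(out / "preference.nii")
            bundle["preference"] = pref

    if "eyetrack" in stages:
        cleaned, report = remove_blinks(sim["gaze"])
        report.to_csv(out / "blink_report.csv", index=False)
        events_list = detect_saccades(cleaned, SaccadeParams(lam=config.lam))
        saccade_table(events_list).to_csv(out / "saccades.csv", index=False)
        bundle["saccades"] = events_list
        spec = sim["spec"]
        fits, angles = [], []
        for tid in cleaned.trial_ids():
            sel = cleaned.samples_of(int(tid))
            if len(sel) < 3:
                continue
            pts = np.column_stack([cleaned.x_deg[sel], cleaned.y_deg[sel]])
            try:
                fits.append(fit_mvee(pts))
            except ValueError:
                continue
            angles.append(spec.condition_angles_deg[int(cleaned.condition[sel[0]])])
        bundle["ellipses"] = fits
        if fits:
            med, corr = ellipse_rotation_tests(fits, np.asarray(angles))
            bundle["ellipse_tests"] = {"median": med, "corr": corr}
            (out / "eyetrack_tests.json").write_text(
                json.dumps(
                    {
                        "median_P": med.statistic_value,
                        "median_p": med.p_value,
                        "corr_r": corr.statistic_value,
                        "corr_p": corr.p_value,
                    },
                    indent=2,
                )
            )
    return bundle
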