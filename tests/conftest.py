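"""Shared fixtures: small seeded paradigms and synthetic datasets.

Everything is generated programmatically at test time; the sizes are
deliberately small so the whole suite stays within a desk-scale budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from imdec.containers import TrialFeatureMatrix
from imdec.paradigm import ParadigmSpec, generate_events
from imdec.synth import GroundTruth, generate_bold


@pytest.fixture
def default_spec():
    """The full session: 4 runs x 10 blocks x 4 trials."""
    return ParadigmSpec(seed=11)


@pytest.fixture
def small_spec():
    """A light session for expensive loops: 4 runs x 3 blocks."""
    return ParadigmSpec(n_runs=4, blocks_per_run=3, seed=7)


@pytest.fixture
def tiny_spec():
    """Minimal valid session: 2 runs x 2 blocks."""
    return ParadigmSpec(n_runs=2, blocks_per_run=2, seed=3)


def make_noise_features(
    spec: ParadigmSpec, n_voxels: int, seed: int
) -> TrialFeatureMatrix:
    """Trial features that carry no label information (pure iid noise)."""
    events = generate_events(
        ParadigmSpec(
            n_runs=spec.n_runs, blocks_per_run=spec.blocks_per_run, seed=seed
        )
    )
    rng = np.random.default_rng(seed + 1_000_003)
    values = rng.normal(size=(events.n_trials, n_voxels))
    voxel_index = np.column_stack(
        [np.arange(n_voxels), np.zeros(n_voxels, int), np.zeros(n_voxels, int)]
    )
    return TrialFeatureMatrix(
        values,
        events.frame["condition"].to_numpy(),
        events.frame["run"].to_numpy(),
        voxel_index,
    )


def make_informative_dataset(
    spec: ParadigmSpec,
    shape: tuple[int, int, int],
    informative: np.ndarray,
    amplitude: float,
    noise_sd: float,
    seed: int,
    drift: float = 0.0,
):
    """BOLD data where each informative voxel prefers one direction.

    Voxel v of the informative set responds with ``amplitude`` to
    condition (v mod 4) + 1 and nothing else.
    """
    events = generate_events(spec)
    informative = np.asarray(informative)
    amp = np.zeros((len(spec.conditions), len(informative)))
    for v in range(len(informative)):
        amp[v % len(spec.conditions), v] = amplitude
    truth = GroundTruth(
        informative_voxels=informative,
        amplitude_matrix=amp,
        noise_sd=noise_sd,
        drift_amplitude=drift,
        seed=seed,
    )
    bold = generate_bold(events, truth, shape, spec)
    return events, truth, bold
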