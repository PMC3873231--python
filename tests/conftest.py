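"""Shared fixtures: one default synthetic dataset built once per session."""

import numpy as np
import pytest

from chromabind import acme
from chromabind.core import dedup_transcripts
from chromabind.damid import lowess_residual_normalize, quantile_normalize
from chromabind.synth import (
    SimParams,
    make_genome_annotation,
    simulate_chip_tracks,
    simulate_damid_arrays,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def sim_params():
    return SimParams(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def annotation(sim_params):
    ann, truth = make_genome_annotation(sim_params)
    return ann, truth


@pytest.fixture(scope="session")
def damid_chips(annotation, sim_params):
    """Replicate DamID chips, fully normalized (within- and between-chip)."""
    ann, truth = annotation
    chips = simulate_damid_arrays(ann, truth, sim_params)
    for chip in chips:
        lowess_residual_normalize(chip)
    mat = quantile_normalize(np.stack([c.normalized for c in chips], axis=1))
    for j, chip in enumerate(chips):
        chip.normalized = mat[:, j]
    return chips


@pytest.fixture(scope="session")
def called_peaks(damid_chips):
    window_stats, pop = acme.probe_enrichment_pvalues(damid_chips)
    peaks = acme.call_peaks(window_stats)
    return window_stats, pop, peaks


@pytest.fixture(scope="session")
def chip_tracks(annotation, sim_params):
    ann, truth = annotation
    return simulate_chip_tracks(ann, truth, sim_params)


@pytest.fixture(scope="session")
def transcripts(annotation):
    ann, _ = annotation
    return dedup_transcripts(ann.transcripts)
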