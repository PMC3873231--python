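"""Shared plumbing for the numbered analysis scripts: one seeded cohort,
its normalized DamID chips, called peaks, and the results/ directory."""

from pathlib import Path

import numpy as np

from chromabind import acme
from chromabind.core import dedup_transcripts
from chromabind.damid import lowess_residual_normalize, quantile_normalize
from chromabind.synth import SimParams, make_genome_annotation, simulate_damid_arrays

RESULTS = Path(__file__).resolve().parent.parent / "results"


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS


def default_params(seed: int = 1) -> SimParams:
    return SimParams(seed=seed)


def cohort(seed: int = 1):
    params = default_params(seed)
    ann, truth = make_genome_annotation(params)
    return params, ann, truth


def damid_pipeline(params, ann, truth):
    """Simulate chips, run both normalization steps, call peaks."""
    chips = simulate_damid_arrays(ann, truth, params)
    for chip in chips:
        lowess_residual_normalize(chip)
    mat = quantile_normalize(np.stack([c.normalized for c in chips], axis=1))
    for j, chip in enumerate(chips):
        chip.normalized = mat[:, j]
    ws, pop = acme.probe_enrichment_pvalues(chips)
    peaks = acme.call_peaks(ws)
    return chips, ws, pop, peaks


def deduped(ann):
    return dedup_transcripts(ann.transcripts)
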