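"""Shared cohort builder for the numbered analysis scripts.

Simulates the full-size study (101 subjects x 3 replicates x 2 modes x 2
mass-range methods, 220-metabolite panel, 30 planted gender markers plus
contraceptive and alcohol effects) and runs the preprocessing chain once,
caching the result under scratch/ so the later scripts are fast to re-run.
"""

from __future__ import annotations

import pickle
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

from breathomics.pipeline import PipelineConfig, process_cohort  # noqa: E402
from breathomics.refdata import build_reference_list, default_calibrants  # noqa: E402
from breathomics.simulate import (  # noqa: E402
    CohortDesign,
    EffectSpec,
    generate_panel,
    simulate_study,
)

SEED = 1
EFFECTS = [
    EffectSpec("gender", 30, (2.0, 4.0)),
    EffectSpec("oc_use", 8, (2.0, 3.0)),
    EffectSpec("alcohol", 6, (2.0, 3.0)),
]


def get_study(seed: int = SEED):
    """(reference, dataset, artifacts, markers), cached on disk."""
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cache = SCRATCH / f"cohort_seed{seed}.pkl"
    if cache.exists():
        with cache.open("rb") as fh:
            return pickle.load(fh)
    reference = build_reference_list()
    panel, markers = generate_panel(220, EFFECTS, seed=seed, reference=reference)
    design = CohortDesign(n_subjects=101, replicates_per_subject=3, seed=seed)
    data = simulate_study(design, panel, marker_manifest=markers)
    art = process_cohort(
        data.peak_lists, reference, PipelineConfig(seed=seed),
        calibrants=default_calibrants(),
    )
    bundle = (reference, data, art, markers)
    with cache.open("wb") as fh:
        pickle.dump(bundle, fh)
    return bundle
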