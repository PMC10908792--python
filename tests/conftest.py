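"""Shared fixtures: reference lists, hand-built feature tables, cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from breathomics.preprocess import FeatureTable
from breathomics.refdata import build_reference_list, default_calibrants


@pytest.fixture(scope="session")
def reference():
    return build_reference_list()


@pytest.fixture(scope="session")
def calibrants():
    return default_calibrants()


def make_table(
    values,
    formulas=None,
    columns=None,
    subjects=None,
    replicates=None,
    is_qc=None,
    batches=None,
    mode="positive",
    method="small",
    mz=None,
    db_ids=None,
    classes=None,
):
    """Hand-build a FeatureTable for unit tests."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    fids = [f"f{i}" for i in range(n_feat)]
    columns = list(columns) if columns is not None else [f"s{j}" for j in range(n_samp)]
    formulas = list(formulas) if formulas is not None else [""] * n_feat
    vdf = pd.DataFrame(values, index=fids, columns=columns)
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 200, n_feat),
            "formula": formulas,
            "name": ["" for _ in fids],
            "db_id": db_ids if db_ids is not None else ["" for _ in fids],
            "main_class": classes if classes is not None else ["" for _ in fids],
            "adduct": ["" for _ in fids],
            "mode": mode,
            "method": method,
            "ppm_error": np.nan,
            "isotope_score": np.nan,
        },
        index=fids,
    )
    samples = pd.DataFrame(
        {
            "subject_id": subjects if subjects is not None else columns,
            "replicate_index": replicates if replicates is not None else 1,
            "batch": batches if batches is not None else "B1",
            "is_qc": is_qc if is_qc is not None else False,
        },
        index=pd.Index(columns),
    )
    return FeatureTable(vdf, features, samples)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def small_cohort(reference, calibrants):
    """A 40-subject cohort with 12 planted gender markers (fold 2-4),
    processed end to end. Session-scoped: several tests read from it."""
    from breathomics.pipeline import PipelineConfig, process_cohort
    from breathomics.simulate import CohortDesign, EffectSpec, generate_panel, simulate_study

    panel, markers = generate_panel(
        60, [EffectSpec("gender", 12, (2.0, 4.0))], seed=1, reference=reference
    )
    design = CohortDesign(n_subjects=40, replicates_per_subject=3, seed=1)
    data = simulate_study(design, panel, marker_manifest=markers)
    art = process_cohort(data.peak_lists, reference, PipelineConfig(), calibrants=calibrants)
    return {"data": data, "art": art, "markers": markers, "panel": panel}


@pytest.fixture(scope="session")
def separable_cohort(reference, calibrants):
    """The full-size study layout (101 subjects x 3 replicates x 2 modes x
    2 methods) with 30 strong fold-4 gender markers."""
    from breathomics.pipeline import PipelineConfig, process_cohort
    from breathomics.simulate import CohortDesign, EffectSpec, generate_panel, simulate_study

    panel, markers = generate_panel(
        120, [EffectSpec("gender", 30, (4.0, 4.0))], seed=7, reference=reference
    )
    design = CohortDesign(n_subjects=101, replicates_per_subject=3, seed=7)
    data = simulate_study(design, panel, marker_manifest=markers)
    art = process_cohort(data.peak_lists, reference, PipelineConfig(), calibrants=calibrants)
    return {"data": data, "art": art, "markers": markers, "panel": panel}
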