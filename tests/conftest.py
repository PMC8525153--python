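"""Shared fixtures: panels, small event matrices, and one full gated run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytoilc import (
    Cohort,
    EventMatrix,
    PanelConfig,
    SyntheticSpec,
    classify_events,
    default_panel,
    generate_cohort,
    transform_cohort,
)
from cytoilc.pregating import PregateConfig, pool, pregate_and_subsample

GATING_MARKERS = ("CD45", "CD3", "CD19", "CD14", "ILT3", "CD56", "CD127",
                  "CRTH2", "c-Kit", "NKp44")


@pytest.fixture(scope="session")
def panel() -> PanelConfig:
    return default_panel()


@pytest.fixture(scope="session")
def mini_panel() -> PanelConfig:
    """Ten-marker panel: just the gating machinery, no functional markers."""
    return PanelConfig(
        markers=tuple((m, m) for m in GATING_MARKERS),
        lineage_markers=frozenset({"CD3", "CD19", "CD14", "ILT3"}),
        identification_markers=frozenset(
            {"CD45", "CD56", "CD127", "CRTH2", "c-Kit", "NKp44"}),
        functional_markers=frozenset(),
    )


def make_events(values: np.ndarray, panel: PanelConfig,
                sample_id: str = "S", stage: str | None = None,
                scale_state: str = "raw") -> EventMatrix:
    return EventMatrix(
        data=pd.DataFrame(values, columns=panel.marker_names),
        sample_id=sample_id, stage=stage, scale_state=scale_state,
    )


@pytest.fixture(scope="session")
def full_run():
    """One default synthetic cohort pushed through pregate -> transform ->
    gate, with ground-truth labels riding along as annotations.

    Used by the frequency-recovery, recall and marker-ordering tests so the
    expensive transform runs once per session.
    """
    spec = SyntheticSpec(seed=0)
    cohort, truth = generate_cohort(spec)
    # attach ground truth as annotations so row operations keep it aligned;
    # pipeline stages never read these columns
    annotated = []
    offset = 0
    for s in cohort.samples:
        t = truth.iloc[offset: offset + s.n_events].reset_index(drop=True)
        offset += s.n_events
        annotated.append(EventMatrix(
            data=s.data, sample_id=s.sample_id, stage=s.stage,
            scale_state=s.scale_state,
            annotations=pd.DataFrame({
                "truth_population": t["population"].to_numpy(),
                "truth_cluster": t["cluster"].to_numpy(),
            }),
        ))
    cohort = Cohort(samples=annotated, panel=cohort.panel)
    gated, retention = pregate_and_subsample(
        cohort, PregateConfig(seed=spec.seed))
    transformed = transform_cohort(gated)
    classified = Cohort(
        samples=[classify_events(s) for s in transformed.samples],
        panel=transformed.panel)
    pooled = pool(classified)
    return {
        "spec": spec,
        "retention": retention,
        "pooled": pooled,
    }
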