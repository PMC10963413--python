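"""Shared fixtures: one fully simulated task-session (all modalities)
and its extracted feature table, built once per test run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mwload import pipeline, synthio
from mwload.config import SynthConfig


@pytest.fixture(scope="session")
def wm_session() -> synthio.TaskSessionData:
    """One working-memory task-session, every modality, fixed seed."""
    return synthio.simulate_task_session("sub001", "WorkingMemory", 1, seed=11)


@pytest.fixture(scope="session")
def wm_table(wm_session) -> pd.DataFrame:
    return pipeline.extract_task_session(wm_session)


@pytest.fixture(scope="session")
def small_design():
    cfg = SynthConfig()
    return synthio.build_block_design("sub001", "SituationAwareness", 1, cfg)


@pytest.fixture(scope="session")
def small_truth(small_design):
    return synthio.make_ground_truth(small_design, SynthConfig(), seed=3)


def make_lmm_table(
    rng: np.random.Generator,
    n_subjects: int = 20,
    n_blocks: int = 3,
    subject_sd: float = 0.8,
    condition_effect: float = 0.0,
    session_effect: float = 0.0,
    measure_name: str = "m",
) -> pd.DataFrame:
    """Balanced subject x session x condition x block table with optional
    injected fixed effects (in within-cell SD units, noise SD = 1)."""
    rows = []
    for s in range(n_subjects):
        b0 = rng.normal(0.0, subject_sd)
        for sess in (1, 2, 3):
            for ci, cond in enumerate(("easy", "hard")):
                for k in range(n_blocks):
                    rows.append(
                        dict(
                            subject_id=f"s{s:02d}",
                            task_name="T",
                            task_session=sess,
                            condition=cond,
                            block_index=k,
                            modality="sim",
                            measure_name=measure_name,
                            value=b0
                            + condition_effect * ci
                            + session_effect * (sess - 2)
                            + rng.normal(0.0, 1.0),
                        )
                    )
    return pd.DataFrame(rows)
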