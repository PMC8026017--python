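"""End-to-end convenience: cohort -> windowed profiles -> correlations."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import stats as st
from .synthetic_data import CohortGeneratorParams, generate_cohort
from .text_processing import TokenSequence
from .windowed_analysis import WindowConfig, profile_narrative

__all__ = ["profile_cohort", "run_synthetic_pipeline"]


def profile_cohort(
    narratives: Sequence[TokenSequence],
    cfg: WindowConfig = WindowConfig(),
) -> pd.DataFrame:
    """Windowed attribute profiles for a set of cleaned token sequences."""
    return pd.DataFrame([profile_narrative(seq, cfg).as_row() for seq in narratives])


def run_synthetic_pipeline(
    params: CohortGeneratorParams,
    covariates: Sequence[str] = (),
    cfg: WindowConfig = WindowConfig(),
    threshold_family_size: int = 4,
    alpha: float = 0.05,
) -> list[st.CorrelationResult]:
    """Generate a cohort and run the full analysis on it in memory."""
    narratives, metadata = generate_cohort(params)
    profiles = profile_cohort(narratives, cfg)
    cohort = st.build_cohort_table(profiles, metadata)
    return st.correlation_table(
        cohort,
        covariates=covariates,
        threshold_family_size=threshold_family_size,
        alpha=alpha,
    )
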