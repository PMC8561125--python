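import numpy as np
import pandas as pd
import pytest

from cvh_windows.simulate import (
    CohortDesign,
    GeneratorConfig,
    TrueModel,
    generate_scores,
    preset,
)


@pytest.fixture(scope="session")
def single_break_data() -> pd.DataFrame:
    """Seeded realization of the single-break preset (n=300 subjects)."""
    return generate_scores(preset("single_break", seed=1))


@pytest.fixture(scope="session")
def small_break_data() -> pd.DataFrame:
    """Small (n=150) single-break cohort for oracle comparisons."""
    return generate_scores(preset("single_break", seed=7, n_subjects=150))


@pytest.fixture(scope="session")
def noiseless_break_data() -> pd.DataFrame:
    """Noise-free piecewise data: exact recovery expected."""
    model = TrueModel(
        intercept_at_age8=7.0, psi=(25.0,), segment_slopes=(0.0, -0.08)
    )
    config = GeneratorConfig(
        model, (CohortDesign("sim", 80, (8.0, 30.0), 5.0, 6),), seed=3
    )
    return generate_scores(config)


@pytest.fixture(scope="session")
def paper_preset_data() -> pd.DataFrame:
    """One seeded realization of the published-estimate preset."""
    from cvh_windows.scoring import apply_completeness_filter

    df = generate_scores(preset("paper2021", seed=11))
    df, _ = apply_completeness_filter(df)
    return df
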