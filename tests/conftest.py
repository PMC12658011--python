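import numpy as np
import pytest

import socdisc as sd


@pytest.fixture(scope="session")
def schedule():
    return sd.build_trial_schedule()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across test modules."""
    cfg = sd.CohortConfig(n_control=80, n_high=60, seed=11)
    return cfg, sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_cohort):
    """One end-to-end pipeline run on the small cohort (report stage)."""
    cfg, _ = small_cohort
    run = sd.RunConfig(
        cohort=cfg,
        mediation_sims=300,
        seed=cfg.seed,
        output_dir=str(tmp_path_factory.mktemp("bundle")),
        make_figure=False,
    )
    return run, sd.run_pipeline(run)


def hyperbolic_profile(v0: float, k: float) -> sd.IndifferenceProfile:
    """Noiseless profile generated from the hyperbolic curve (may be off-grid)."""
    n = np.asarray(sd.task.SOCIAL_DISTANCES, float)
    v = v0 / (1 + k * n)
    return profile_from_v(v)


def profile_from_v(v) -> sd.IndifferenceProfile:
    v = np.clip(np.asarray(v, float), 0.0, 80.0)
    return sd.IndifferenceProfile(
        social_distances=sd.task.SOCIAL_DISTANCES,
        indifference_points=tuple(v + 75.0),
        forgone_v=tuple(v),
        violations=(False,) * 7,
    )
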