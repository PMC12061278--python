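import numpy as np
import pytest

from bridgemil import CohortSpec, LatentSpec, RunConfig, generate_cohort


def tiny_config(**train_overrides) -> RunConfig:
    """A configuration small enough for second-scale unit tests."""
    cfg = RunConfig()
    cfg.encoder.patch_dim = 32
    cfg.encoder.d_wsi = 32
    cfg.encoder.n_heads = 2
    cfg.encoder.n_landmarks = 4
    cfg.encoder.d_omics = 16
    cfg.encoder.snn_hidden = 16
    cfg.bridge.hidden = 16
    cfg.train.head_hidden = 16
    cfg.train.epochs = 3
    for k, v in train_overrides.items():
        setattr(cfg.train, k, v)
    return cfg


def tiny_cohort(n=40, seed=7, **latent_kw):
    spec = CohortSpec(n_patients=n, patch_dim=32, n_omics_features=40,
                      bag_size_range=(6, 14), target_censoring_rate=0.3,
                      seed=seed)
    latent = LatentSpec(d_shared=4, d_wsi_private=2, d_omics_private=2,
                        beta=np.full(4, 0.5), **latent_kw)
    return generate_cohort(spec, latent)


@pytest.fixture(scope="session")
def small_cohort():
    return tiny_cohort()


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One cross-validated multimodal fit shared across interpretability
    and model tests."""
    from bridgemil import BridgedSurvivalModel
    model = BridgedSurvivalModel.from_synthetic(small_cohort, tiny_config())
    return model.fit(seed=3, n_folds=2)


# ---- reference study conditions (shared by the acceptance module) -------

COHORT_SEED = 11
FIT_SEED = 5


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: n=600, 40% censoring, shared+private
    latent signal partially expressed in each modality."""
    return generate_cohort(CohortSpec(n_patients=600, seed=COHORT_SEED),
                           LatentSpec())


@pytest.fixture(scope="session")
def bridge_fit(default_cohort):
    from bridgemil import BridgedSurvivalModel
    model = BridgedSurvivalModel.from_synthetic(default_cohort, RunConfig())
    return model.fit(seed=FIT_SEED)


@pytest.fixture(scope="session")
def wsi_only_fit(default_cohort):
    from bridgemil import BridgedSurvivalModel
    model = BridgedSurvivalModel.from_synthetic(default_cohort, RunConfig(),
                                                modality="wsi_only")
    return model.fit(seed=FIT_SEED)


@pytest.fixture(scope="session")
def omics_only_fit(default_cohort):
    from bridgemil import BridgedSurvivalModel
    model = BridgedSurvivalModel.from_synthetic(default_cohort, RunConfig(),
                                                modality="omics_only")
    return model.fit(seed=FIT_SEED)


@pytest.fixture(scope="session")
def non_bridge_fold0_fit(default_cohort):
    """Late-concatenation ablation, fold 0 only (used for the alignment
    ordering comparison)."""
    from bridgemil import BridgedSurvivalModel
    from bridgemil.io import make_folds
    cfg = RunConfig()
    cfg.bridge.mode = "non_bridge"
    model = BridgedSurvivalModel.from_synthetic(default_cohort, cfg)
    folds = make_folds(model.patient_ids, cfg.n_folds, FIT_SEED)
    return model.fit(seed=FIT_SEED, folds=folds[:1])
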