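import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from liversize.ingest import ingest, read_exams, read_heights
from liversize.model import LiverCentileModel
from liversize.screen import screen
from liversize.simulate import build_truth, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

RECOVERY_N = 20_000
AGE_SEED = 101
HEIGHT_SEED = 202


def run_recovery(table: str, seed: int, tmp_dir, n: int = RECOVERY_N):
    """Full pipeline on a synthetic cohort from an anchored truth:
    generate -> write/read CSV -> ingest -> screen -> fit."""
    truth = build_truth(table, tau=2.0)
    cohort = generate(truth, n, seed=seed)
    exams_path = tmp_dir / "exams.csv"
    heights_path = tmp_dir / "heights.csv"
    cohort.write(exams_path, heights_path)
    records = ingest(read_exams(exams_path), read_heights(heights_path))
    result = screen(records)
    covariate = "age_years" if table.startswith("age") else "height_cm"
    res = LiverCentileModel.from_records(result.retained, covariate=covariate).fit()
    return truth, cohort, result, res


@pytest.fixture(scope="session")
def age_recovery(tmp_path_factory):
    """Age-model recovery experiment shared across the suite."""
    return run_recovery("age_all", AGE_SEED, tmp_path_factory.mktemp("age"))


@pytest.fixture(scope="session")
def height_recovery(tmp_path_factory):
    """Height-model recovery experiment shared across the suite."""
    return run_recovery("height_all", HEIGHT_SEED, tmp_path_factory.mktemp("height"))


class TruthResults:
    """Adapter exposing a GeneratorTruth through the fitted-results
    interface used by the residual diagnostics (the 'true model')."""

    def __init__(self, truth, x, y):
        self.truth = truth
        self.tau_hat = truth.tau
        self.converged = True
        self.model = type("M", (), {})()
        self.model.x = np.asarray(x)
        self.model.y = np.asarray(y)

    def _param_arrays(self, x):
        return self.truth.params_at(x)


@pytest.fixture(scope="session")
def constant_fit():
    """Model fitted to data from a single constant BCPE law, using the
    GAIC smoothing policy (a flat truth is exactly the case where the
    criterion's preference for heavy smoothing is appropriate)."""
    from liversize.bcpe import BCPEParams, bcpe_sample
    from liversize.smooth import SmoothConfig

    rng = np.random.default_rng(7)
    y = bcpe_sample(5000, BCPEParams(10.0, 0.1, 1.0, 2.0), seed=8)
    x = rng.uniform(0.0, 18.0, size=5000)
    cfg = SmoothConfig(lam_mu="gaic", lam_sigma="gaic", lam_nu="gaic",
                       x_power=0.5)
    res = LiverCentileModel(y, x, covariate="age_years", config=cfg).fit()
    return y, x, res
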