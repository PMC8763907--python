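import numpy as np
import pytest

from coginfer.task import MAX_SEQ_LEN, TaskConfig, TrialSet


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


def trials_from_llr(llr_rows, kappa: float = 0.5, config: TaskConfig | None = None) -> TrialSet:
    """Build a TrialSet whose evidence matches the given per-stimulus values.

    Orientations are placed so that 2*kappa*sin(2*(theta - theta_star))
    reproduces each requested log-likelihood ratio exactly.
    """
    config = config or TaskConfig(kappa=kappa)
    rows = [np.asarray(r, dtype=float) for r in llr_rows]
    n = len(rows)
    llr = np.zeros((n, MAX_SEQ_LEN))
    theta = np.zeros((n, MAX_SEQ_LEN))
    n_stim = np.zeros(n, dtype=int)
    for i, r in enumerate(rows):
        if np.any(np.abs(r) > 2 * kappa):
            raise ValueError("llr magnitude above 2*kappa is unreachable")
        n_stim[i] = len(r)
        llr[i, : len(r)] = r
        theta[i, : len(r)] = np.arcsin(r / (2 * kappa)) / 2.0
    return TrialSet(
        config=config,
        theta_star=np.zeros(n),
        category=np.ones(n, dtype=int),
        n_stimuli=n_stim,
        theta=np.mod(theta, np.pi),
        llr=llr,
        lottery_prob=np.full(n, 0.75),
        kappa_trial=np.full(n, kappa),
    )
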