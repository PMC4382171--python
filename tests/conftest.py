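import numpy as np
import pytest

from affectcpt import CPTParams, DesignSpec, Lottery, simulate_cohort
from affectcpt.synth import build_design, build_templates, sample_wtp


def random_loss_lottery(rng, max_branches=4, max_magnitude=60.0) -> Lottery:
    """A random small loss prospect with distinct outcomes."""
    k = int(rng.integers(2, max_branches + 1))
    outcomes = [0.0] + list(-rng.uniform(0.5, max_magnitude, size=k - 1))
    probs = rng.dirichlet(np.ones(k))
    # renormalize exactly to avoid tripping the sum-to-one invariant
    probs = probs / probs.sum()
    return Lottery(outcomes, probs)


@pytest.fixture(scope="session")
def default_templates():
    return build_templates(DesignSpec())


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-participant simulated cohort with the default design."""
    return simulate_cohort(n_participants=4, seed=42)


@pytest.fixture()
def one_participant_design(default_templates):
    rng = np.random.default_rng(7)
    ranking, wtp = sample_wtp(1, seed=0, rng=rng)[0]
    wtp_by_rank = {r + 1: wtp[label] for r, label in enumerate(ranking)}
    rank_labels = {r + 1: label for r, label in enumerate(ranking)}
    problems, trials = build_design(
        DesignSpec(), wtp_by_rank, rank_labels, seed=7, templates=default_templates
    )
    return ranking, wtp, problems, trials
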