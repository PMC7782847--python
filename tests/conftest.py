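import numpy as np
import pytest

from multicue import design as design_mod
from multicue.pipeline import RunConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_design():
    """One full participant design at the default geometry (seed fixed)."""
    return design_mod.build_design(7)


@pytest.fixture(scope="session")
def shared_layout(default_design):
    """Layout reconstructed from the session design, for cheap reuse."""
    return design_mod.Layout(
        candidates=default_design.candidates,
        true_idx={
            lb: default_design.items.loc[
                default_design.items["set_id"] == lb, "cand_idx"
            ].to_numpy()
            for lb in default_design.candidates
        },
        sizes={
            lb: int((default_design.items["set_id"] == lb).sum())
            for lb in default_design.candidates
        },
    )


@pytest.fixture(scope="session")
def prh_cohort(shared_layout):
    """A small cued cohort under parallel reactivation (8 participants)."""
    cfg = RunConfig(master_seed=42, n_participants=8, eeg_enabled=False)
    scored, summaries, _, _, _ = simulate_cohort(cfg, layout=shared_layout)
    return scored, summaries


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
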