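"""Shared setup for the analysis drivers: one seeded simulation of the
release-and-spread system, with pre-release and recent archive points, and
the four source baselines built from the founder frequency table."""

from pathlib import Path

from genmon.ancestry import baseline_from_freq_table
from genmon.simulate import SimConfig, simulate_release_and_spread

SEED = 7
MID_GEN = 4          # "1999-like" intermediate sampling point
RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_state():
    cfg = SimConfig(seed=SEED)
    state = simulate_release_and_spread(
        cfg, archive_generations=(0, MID_GEN, cfg.generations))
    RESULTS.mkdir(exist_ok=True)
    return state


def make_baselines(state):
    return [baseline_from_freq_table(state.founder_freqs, p, n_individuals=5000)
            for p in state.founder_freqs.pops]
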