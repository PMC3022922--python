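import numpy as np
import pytest

from ap2erf.profile import build_profile, scan_proteome
from ap2erf.simulate import (SimConfig, make_ct_table, make_reference_panel,
                             make_target_genome)


@pytest.fixture(scope="session")
def zero_noise_study():
    """Fully deterministic study: no substitutions, no replicate noise."""
    cfg = SimConfig(seed=11, substitution_rate=0.0, rep_noise_sd=0.0)
    panel = make_reference_panel(cfg)
    genome = make_target_genome(cfg, panel)
    profiles = {k: build_profile(v, k) for k, v in panel.seed_alignments.items()}
    hits = scan_proteome(genome.proteins, profiles)
    return {"cfg": cfg, "panel": panel, "genome": genome,
            "profiles": profiles, "hits": hits}


@pytest.fixture(scope="session")
def noisy_study():
    """Default study conditions (5% substitutions, 0.3 Ct replicate noise)."""
    cfg = SimConfig(seed=12)
    panel = make_reference_panel(cfg)
    genome = make_target_genome(cfg, panel)
    profiles = {k: build_profile(v, k) for k, v in panel.seed_alignments.items()}
    hits = scan_proteome(genome.proteins, profiles)
    ct, ct_truth = make_ct_table(cfg)
    return {"cfg": cfg, "panel": panel, "genome": genome,
            "profiles": profiles, "hits": hits, "ct": ct,
            "ct_truth": ct_truth}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
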