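import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import admixkit as ak
from admixkit import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def flat_markers(M, chrom="1", spacing_bp=100_000, cm_per_marker=0.1):
    """Evenly spaced single-chromosome marker frame for hand-built fixtures."""
    return pd.DataFrame({
        "chrom": chrom,
        "pos_bp": np.arange(1, M + 1) * spacing_bp,
        "pos_cm": np.arange(M) * cm_per_marker,
        "ref": "A",
        "alt": "G",
        "ancestral_is_ref": True,
    })


@pytest.fixture(scope="session")
def sources6k():
    """Two differentiated source populations (FST 0.15) on a 6000-marker map."""
    rng = np.random.default_rng(42)
    M = 6000
    markers = sim.simulate_markers(M, sim.DEFAULT_CHROM_LENGTHS_CM, rng)
    p_anc = rng.uniform(0.1, 0.9, M)
    freqs = sim.draw_population_freqs(p_anc, 0.15, 2, rng)
    mats = sim.simulate_source_haplotypes(freqs, 160, 0.3, markers, rng)
    return dict(markers=markers, p_anc=p_anc, freqs=freqs, mats=mats, M=M)


@pytest.fixture(scope="session")
def cohort6k(sources6k):
    """Admixed cohort (T=12, z ~ U(0.1, 0.9)) with ground truth."""
    cfg = sim.SimulationConfig(K=2, fst=0.15, M=sources6k["M"], T=12,
                               n_individuals=40, z_dist=(0.1, 0.9), seed=7)
    panel, truth, z, info = sim.simulate_admixed_cohort(
        cfg, {"anc0": sources6k["mats"][0], "anc1": sources6k["mats"][1]},
        sources6k["markers"], rng=np.random.default_rng(7))
    return dict(panel=panel, truth=truth, z=z, info=info, config=cfg,
                sources=sources6k)


@pytest.fixture(scope="session")
def substructure_cohort():
    """Admixed cohort whose target ancestry splits into two subgroups at FST 0.01."""
    rng = np.random.default_rng(11)
    M = 4000
    markers = sim.simulate_markers(M, sim.DEFAULT_CHROM_LENGTHS_CM, rng)
    p_anc = rng.uniform(0.1, 0.9, M)
    sub = sim.draw_population_freqs(p_anc, 0.01, 2, rng)
    other = sim.draw_population_freqs(p_anc, 0.15, 1, rng)
    mats_sub = sim.simulate_source_haplotypes(sub, 160, 0.3, markers, rng)
    mats_other = sim.simulate_source_haplotypes(other, 160, 0.3, markers, rng)
    N = 100
    assignment = np.repeat([0, 1], N // 2)
    cfg = sim.SimulationConfig(K=2, fst=0.01, M=M, T=12, n_individuals=N,
                               z_dist=0.5, seed=2)
    panel, truth, z, info = sim.simulate_admixed_cohort(
        cfg, {"EUR": mats_sub, "OTH": mats_other[0]}, markers,
        source_assignment=assignment, rng=np.random.default_rng(2))
    return dict(panel=panel, truth=truth, z=z, assignment=assignment,
                markers=markers, config=cfg)
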