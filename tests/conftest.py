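import pytest

from slabmc.interface import generate_fixtures
from slabmc.transport import run_simulation


@pytest.fixture(scope="session")
def membrane_run():
    """Moderate-statistics run of the characterized thin membrane."""
    cfg = generate_fixtures("membrane")
    cfg.n_photons = 800_000
    cfg.seed = 202
    rec = run_simulation(cfg.pulse, cfg.beam, cfg.slab, cfg.n_photons, cfg.seed,
                         time_cap=cfg.time_cap_ps)
    det = cfg.detectors()
    det.accumulate(rec)
    return cfg, rec, det


@pytest.fixture(scope="session")
def thick_run():
    """Optically thick (L = 20·ls) index-matched slab: the diffusion-theory
    reference geometry."""
    cfg = generate_fixtures("thick_slab")
    cfg.n_photons = 1_000_000
    cfg.seed = 303
    rec = run_simulation(cfg.pulse, cfg.beam, cfg.slab, cfg.n_photons, cfg.seed,
                         time_cap=cfg.time_cap_ps)
    det = cfg.detectors()
    det.accumulate(rec)
    return cfg, rec, det
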