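"""Configuration, fixtures and result persistence.

Configs are flat, human-editable YAML key-value documents with units spelled
out in the key names (``slab_thickness_um``, ``pulse_fwhm_fs`` …) — the
cheapest insurance against unit drift in a μm/ps code. Unknown keys are
rejected; fixture configs for the canonical experiments are generated
programmatically.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import fit_decay_rate, fit_msw_growth
from .detectors import DetectorSet, energy_balance, mean_square_width
from .optics_utils import PulseSpec
from .sources import BeamSpec
from .transport import SlabSpec, run_simulation

__all__ = ["SimulationConfig", "load_config", "save_config", "write_results",
           "read_results", "generate_fixtures", "FIXTURES", "run_from_config"]

log = logging.getLogger("slabmc")


@dataclass
class SimulationConfig:
    """Flat simulation configuration. All lengths μm, times ps unless the
    field name says otherwise (pulse width in fs)."""

    # pulse
    pulse_shape: str = "sech2"
    pulse_fwhm_fs: float = 94.0
    # beam
    beam_kind: str = "ray_bundle"
    beam_waist_um: float = 5.0
    beam_wavelength_um: float = 1.51
    beam_focus_z_um: float = 0.0
    # slab
    slab_thickness_um: float = 164.0
    slab_index: float = 1.526
    index_front: float = 1.0
    index_back: float = 1.0
    mu_s_per_um: float = 0.0
    mu_a_per_um: float = 0.0
    anisotropy_g: float = 0.0
    # run
    n_photons: int = 1_000_000
    seed: int = 1
    time_cap_ps: float = 50.0
    # detectors
    time_max_ps: float = 10.0
    time_bin_ps: float = 0.025
    rho_max_um: float = 1500.0
    rho_bin_um: float = 5.0
    frame_pixel_um: float = 13.5
    # analysis; the decay window starts where the log-slope has stabilized
    # (the thin-slab transmittance is still curving before ~3 ps because
    # TIR-trapped grazing light releases over the first few ps)
    decay_window_ps: tuple = (3.0, 9.0)
    msw_window_ps: tuple = (1.0, 3.5)

    def __post_init__(self):
        self.decay_window_ps = tuple(float(v) for v in self.decay_window_ps)
        self.msw_window_ps = tuple(float(v) for v in self.msw_window_ps)
        errors = []
        for name in ("pulse_fwhm_fs", "beam_waist_um", "beam_wavelength_um",
                     "slab_thickness_um", "time_cap_ps", "time_max_ps",
                     "time_bin_ps", "rho_max_um", "rho_bin_um", "frame_pixel_um"):
            if not getattr(self, name) > 0:
                errors.append(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("mu_s_per_um", "mu_a_per_um"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("slab_index", "index_front", "index_back"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1, got {getattr(self, name)}")
        if not -1.0 < self.anisotropy_g < 1.0:
            errors.append(f"anisotropy_g must lie in (-1, 1), got {self.anisotropy_g}")
        if self.n_photons < 0:
            errors.append(f"n_photons must be >= 0, got {self.n_photons}")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    # --- spec builders -----------------------------------------------------
    @property
    def pulse(self) -> PulseSpec:
        return PulseSpec(self.pulse_shape, self.pulse_fwhm_fs)

    @property
    def beam(self) -> BeamSpec:
        return BeamSpec(self.beam_kind, self.beam_waist_um,
                        self.beam_wavelength_um, focus_z=self.beam_focus_z_um)

    @property
    def slab(self) -> SlabSpec:
        return SlabSpec(self.slab_thickness_um, self.slab_index,
                        self.index_front, self.index_back,
                        self.mu_s_per_um, self.mu_a_per_um, self.anisotropy_g)

    def detectors(self, frame_delays=None) -> DetectorSet:
        d = DetectorSet.default(self.time_max_ps, self.time_bin_ps,
                                self.rho_max_um, self.rho_bin_um, frame_delays)
        if d.frames is not None:
            d.frames.pixel_size = self.frame_pixel_um
        return d

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decay_window_ps"] = list(self.decay_window_ps)
        d["msw_window_ps"] = list(self.msw_window_ps)
        return d


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a key-value document")
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
    return SimulationConfig(**raw)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


FIXTURES = ("clear_slab", "membrane", "thick_slab", "gpb_vs_grb")


def generate_fixtures(name: str) -> SimulationConfig:
    """Canned configurations for the canonical experiments.

    * ``clear_slab`` — scattering-free 164-μm polymer slab (n = 1.509),
      delta pulse, pencil beam: ballistic transit and internally reflected
      replica timing.
    * ``membrane`` — the characterized membrane: L = 164 μm, n = 1.526,
      ls′ = 41.2 μm, g = 0.165, μa = 4.5×10⁻⁵ μm⁻¹, 94-fs sech² pulse,
      ray bundle focused to w0 = 5 μm at the entrance.
    * ``thick_slab`` — L = 20·ls′, index-matched, isotropic: the diffusion
      oracle geometry.
    * ``gpb_vs_grb`` — membrane geometry with μa = 0 for the source-model
      comparison (run once per beam kind).
    """
    ls_prime = 41.2
    g = 0.165
    mu_s = 1.0 / (ls_prime * (1.0 - g))
    if name == "clear_slab":
        return SimulationConfig(pulse_shape="delta", beam_kind="pencil",
                                slab_thickness_um=164.0, slab_index=1.509,
                                mu_s_per_um=0.0, mu_a_per_um=0.0, anisotropy_g=0.0,
                                time_max_ps=6.0, time_bin_ps=0.005)
    if name == "membrane":
        return SimulationConfig(pulse_shape="sech2", pulse_fwhm_fs=94.0,
                                beam_kind="ray_bundle", beam_waist_um=5.0,
                                beam_wavelength_um=1.51,
                                slab_thickness_um=164.0, slab_index=1.526,
                                mu_s_per_um=mu_s, mu_a_per_um=4.5e-5,
                                anisotropy_g=g)
    if name == "thick_slab":
        ls = 20.0
        return SimulationConfig(pulse_shape="delta", beam_kind="pencil",
                                slab_thickness_um=20 * ls, slab_index=1.526,
                                index_front=1.526, index_back=1.526,
                                mu_s_per_um=1.0 / ls, mu_a_per_um=0.0,
                                anisotropy_g=0.0, time_max_ps=80.0,
                                time_bin_ps=0.2, time_cap_ps=200.0,
                                rho_max_um=6000.0, rho_bin_um=20.0,
                                decay_window_ps=(30.0, 60.0),
                                msw_window_ps=(10.0, 30.0))
    if name == "gpb_vs_grb":
        return SimulationConfig(pulse_shape="sech2", pulse_fwhm_fs=94.0,
                                beam_kind="ray_bundle", beam_waist_um=5.0,
                                beam_wavelength_um=1.51,
                                slab_thickness_um=164.0, slab_index=1.526,
                                mu_s_per_um=mu_s, mu_a_per_um=0.0,
                                anisotropy_g=g, time_max_ps=3.0,
                                time_bin_ps=0.01, rho_max_um=600.0,
                                rho_bin_um=2.5)
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")


def run_from_config(cfg: SimulationConfig, frame_delays=None):
    """Run the simulation described by ``cfg``; returns (records, detectors).

    Logs photon count, seed, runtime, truncation tally and energy balance.
    """
    t_start = _time.perf_counter()
    records = run_simulation(cfg.pulse, cfg.beam, cfg.slab, cfg.n_photons,
                             cfg.seed, time_cap=cfg.time_cap_ps)
    det = cfg.detectors(frame_delays)
    det.accumulate(records)
    balance = energy_balance(records, launched=float(cfg.n_photons) or None)
    log.info("run: N=%d seed=%d runtime=%.1fs balance=%s truncated=%.3e",
             cfg.n_photons, cfg.seed, _time.perf_counter() - t_start,
             {k: round(v, 6) for k, v in balance.items()}, balance["truncated"])
    return records, det


def make_forward_model(cfg: SimulationConfig, n_photons: int | None = None,
                       seed: int | None = None):
    """μa = 0 Monte Carlo forward model for the two-step retrieval.

    Returns ``forward(ls_prime) -> (msw_slope, tau)`` using the geometry,
    source and fit windows of ``cfg`` with common random numbers across
    evaluations. The decay time is NaN when the window has no decaying tail
    (e.g. at very small ls′ the transmittance peaks after the window start);
    the retrieval only needs τ at the final, physical ls′.
    """
    import math as _math

    from .transport import SlabSpec as _SlabSpec

    n = n_photons if n_photons is not None else cfg.n_photons
    s = seed if seed is not None else cfg.seed

    def forward(ls_prime: float):
        slab = _SlabSpec.from_transport_mfp(
            cfg.slab_thickness_um, ls_prime, cfg.anisotropy_g, mu_a=0.0,
            n_slab=cfg.slab_index, n_front=cfg.index_front, n_back=cfg.index_back)
        rec = run_simulation(cfg.pulse, cfg.beam, slab, n, s,
                             time_cap=cfg.time_cap_ps)
        det = cfg.detectors()
        det.accumulate(rec)
        slope = fit_msw_growth(det.msw_map, window=cfg.msw_window_ps).value
        try:
            tau = fit_decay_rate(det.histogram_t, cfg.decay_window_ps).value
        except ValueError:
            tau = _math.nan
        return slope, tau

    return forward


def write_results(det: DetectorSet, fits: dict, cfg: SimulationConfig,
                  outdir) -> Path:
    """Persist a completed run.

    CSV for the time histograms and the MSW series, a ``.npz`` array
    container for the radial map (and frames if present), and a JSON
    provenance block embedding the config, seed and package version.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "t_ps": det.histogram_t.centers,
        "transmit_weight": det.histogram_t.weights,
        "reflect_weight": det.histogram_r.weights,
    }).to_csv(outdir / "histograms.csv", index=False)
    t, msw, se = mean_square_width(det.msw_map)
    pd.DataFrame({"t_ps": t, "msw_um2": msw, "stderr_um2": se}).to_csv(
        outdir / "msw.csv", index=False)
    arrays = {
        "time_edges": det.msw_map.time_edges,
        "sum_w": det.msw_map.sum_w,
        "sum_wr2": det.msw_map.sum_wr2,
    }
    if det.msw_map.hist is not None:
        arrays["radial_edges"] = det.msw_map.radial_edges
        arrays["radial_hist"] = det.msw_map.hist
    if det.frames is not None:
        arrays["frames"] = det.frames.frames
        arrays["gate_delays"] = det.frames.gate_delays
    np.savez_compressed(outdir / "maps.npz", **arrays)
    provenance = {"config": cfg.to_dict(), "seed": cfg.seed,
                  "version": __version__, "fits": fits}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return outdir


def read_results(outdir):
    """Read back a persisted bundle: (histograms df, msw df, arrays, provenance)."""
    import pandas as pd

    outdir = Path(outdir)
    hist = pd.read_csv(outdir / "histograms.csv")
    msw = pd.read_csv(outdir / "msw.csv")
    arrays = dict(np.load(outdir / "maps.npz"))
    prov = json.loads((outdir / "provenance.json").read_text())
    return hist, msw, arrays, prov
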