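"""Stage loop tying the macro and micro scales together.

One stage (a fifth of a day by default) performs, in order: the nutrient
steady-state solve on the current tumour domain; assembly of the
treatment kill rates for the stage window; the Heun advance of the
cancer field with anisotropic diffusion, non-local adhesion and
kinetics; the exponential ECM decay; the cancer-flux-driven micro-fibre
rearrangement; the boundary MDE micro-process; and the induced domain
relocation.  The loop is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import h5py

from .fields import Grid3D, TissueState, TumourDomain, extract_boundary
from . import macro, numerics, treatment as trt
from .nutrients import solve_nutrients, psi_p, psi_d
from .phantom import generate_phantom, make_cavity_mask
from .fibre import MicroFibreField, init_micro_fibres, rearrangement_flux, \
    reallocate_micro_fibres
from .boundary import boundary_micro_stage, DomainEvolver
from .seeding import seed_oedema_field, init_noncancer_fields
from .config import SimulationConfig
from .assimilation import mismatch, ObservationSet


@dataclass
class StageLog:
    stage: int
    time_days: float
    total_c: float
    detected_volume: int
    domain_volume: int
    dose_rate: float
    clipped_mass: float


class Simulation:
    """A configured multiscale run on a synthetic phantom."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.detect_threshold = 0.05
        self._setup()

    def _setup(self) -> None:
        cfg = self.config
        self.phantom = generate_phantom(cfg.phantom.to_spec())
        self.grid: Grid3D = self.phantom["spec"].grid

        cavity, shell = make_cavity_mask(
            self.phantom["tumour_mask"], self.phantom["oedema_mask"]
        )
        self.cavity_mask = cavity
        self.oedema_mask = self.phantom["oedema_mask"]

        self.D_T = macro.build_diffusion_tensor(
            self.phantom["tensor_field"], self.phantom["wm_fraction"],
            self.phantom["gm_fraction"], cfg.macro.D_c,
        )

        self.micro = init_micro_fibres(
            self.phantom["wm_fraction"], self.phantom["gm_fraction"],
            self.grid, seed=cfg.run.seed,
            tract_directions=self.phantom["tract_directions"],
            n=cfg.fibre.micro_n, fill=cfg.fibre.fill,
            library_size=cfg.fibre.library_size,
        )
        self.theta_f = self.micro.theta_f()

        c0 = seed_oedema_field(
            cfg.seeding, self.oedema_mask, cavity, self.grid,
            initial_tumour_mask=self.phantom["tumour_mask"],
        )
        l0, sigma0 = init_noncancer_fields(c0, self.grid)
        F0 = np.linalg.norm(self.theta_f, axis=-1)
        self.state = TissueState(self.grid, c0, l0, F0, sigma0)

        self.domain: TumourDomain = extract_boundary(self.oedema_mask, self.grid)
        self.face_open = numerics.interface_face_open(self.domain.indicator)
        self.evolver = DomainEvolver(self.grid)

        if cfg.run.treatment and cfg.timeline.protocol == "stupp":
            self.timeline = trt.build_stupp_timeline(
                total_days=cfg.timeline.total_days,
                fraction_dose=cfg.timeline.fraction_dose,
                n_fractions=cfg.timeline.n_fractions,
                concurrent_dose=cfg.timeline.concurrent_dose,
                adjuvant_dose=cfg.timeline.adjuvant_dose,
                stages_per_day=cfg.timeline.stages_per_day,
            )
        else:
            self.timeline = None

        self.stage = 0
        self.logs: list[StageLog] = []

    # ------------------------------------------------------------------ #

    def _treatment_rates(self, t0: float, t1: float):
        """Kill-rate fields at the two Heun evaluation times, plus
        activity flags for the therapy-induced ECM decay."""
        if self.timeline is None:
            return 0.0, 0.0, False, False, 0.0
        r0 = trt.radio_rate(t0, self.timeline, self.config.therapy)
        r1 = trt.radio_rate(t1, self.timeline, self.config.therapy)
        ch0 = trt.chemo_rate(self.state.c, t0, self.timeline, self.config.therapy)
        ch1 = trt.chemo_rate(self.state.c, t1, self.timeline, self.config.therapy)
        radio_active = (r0 > 0) or (r1 > 0)
        chemo_active = bool(np.any(ch0 > 0) or np.any(ch1 > 0))
        rate0 = r0 + ch0
        rate1 = r1 + ch1
        return rate0, rate1, chemo_active, radio_active, r0

    def run_stage(self) -> StageLog:
        cfg = self.config
        dt = cfg.macro.dt
        t0 = self.stage * dt
        t1 = t0 + dt
        inside = self.domain.indicator.astype(bool)

        # 1. Nutrient steady state on the current domain.
        self.state.sigma = solve_nutrients(
            self.state, self.domain, cfg.nutrients, sigma0=self.state.sigma
        )
        pp = psi_p(self.state.sigma, cfg.nutrients)
        pd = psi_d(self.state.sigma, cfg.nutrients)

        # 2. Treatment kill rates for this stage window.
        rate0, rate1, chemo_on, radio_on, r0 = self._treatment_rates(t0, t1)

        # 3. Macro advance of the cancer field.
        diag = macro.StepDiagnostics()
        adh = macro.adhesion_vector(self.state, self.theta_f, cfg.macro)
        c_new = macro.advance_stage(
            self.state, self.D_T, self.theta_f, cfg.macro, pp, pd, dt,
            treatment_rate_t0=rate0, treatment_rate_t1=rate1,
            face_open=self.face_open, diagnostics=diag, adhesion=adh,
        )
        self.state.c = np.where(inside, c_new, 0.0)

        # 4. ECM decay (exact exponential), mirrored onto the micro mass.
        F_new, l_new = macro.ecm_decay_step(
            self.state, cfg.macro, dt, chemo_active=chemo_on, radio_active=radio_on
        )
        self.state.l = l_new
        factor = np.divide(F_new, self.state.F,
                           out=np.ones_like(F_new), where=self.state.F > 1e-300)
        factor = np.clip(factor, 0.0, 1.0)
        self.micro.scale_mass(factor)
        # Uniform per-voxel scaling leaves the fibre direction unchanged.
        self.theta_f = self.theta_f * factor[..., None]
        self.state.F = np.linalg.norm(self.theta_f, axis=-1)

        # 5. Micro-fibre rearrangement driven by the cancer flux.
        if cfg.run.fibre_rearrangement and \
                (self.stage % cfg.fibre.update_every == 0):
            flux = macro.cancer_flux(self.state, self.D_T, self.theta_f,
                                     cfg.macro, adhesion=adh)
            r = rearrangement_flux(flux, self.state.c, self.state.F, self.theta_f)
            # Rearrangement is triggered by cancer cells: where c = 0 the
            # weight w vanishes and fibres should not self-advect.
            active = inside & (self.state.c > 1e-6)
            moved = reallocate_micro_fibres(
                self.micro, r, dt * cfg.fibre.update_every,
                gain=cfg.fibre.realloc_gain, active=active,
                deposition=cfg.fibre.deposition,
            )
            if moved > 0:
                self.theta_f = self.micro.theta_f()
                self.state.F = np.linalg.norm(self.theta_f, axis=-1)

        # 6. Boundary MDE micro-process and domain relocation.
        if cfg.run.boundary_micro:
            relocations = boundary_micro_stage(
                self.state.c, self.domain, cfg.boundary, dt
            )
            if relocations:
                new_domain = self.evolver.apply(self.domain, relocations)
                if new_domain is not self.domain:
                    self.domain = new_domain
                    self.face_open = numerics.interface_face_open(
                        self.domain.indicator)

        self.stage += 1
        log = StageLog(
            stage=self.stage,
            time_days=t1,
            total_c=float(self.state.c.sum() * self.grid.voxel_volume),
            detected_volume=int(np.sum(self.state.c >= self.detect_threshold)),
            domain_volume=self.domain.volume_voxels,
            dose_rate=float(r0),
            clipped_mass=diag.clipped_mass,
        )
        self.logs.append(log)
        return log

    def run(self, n_stages: int | None = None,
            observe_at: dict[int, np.ndarray] | None = None) -> list[StageLog]:
        """Run ``n_stages`` stages (default from config).

        ``observe_at`` maps stage index -> container; after that stage the
        cancer field is stored there (used by the assimilation forward
        model).
        """
        n = self.config.run.stages if n_stages is None else n_stages
        for _ in range(n):
            self.run_stage()
            if observe_at is not None and self.stage in observe_at:
                observe_at[self.stage] = self.state.c.copy()
        return self.logs

    # ------------------------------------------------------------------ #

    def save_checkpoint(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["stage"] = self.stage
            f.attrs["config_hash"] = self.config.config_hash()
            f.create_dataset("c", data=self.state.c)
            f.create_dataset("l", data=self.state.l)
            f.create_dataset("F", data=self.state.F)
            f.create_dataset("sigma", data=self.state.sigma)
            f.create_dataset("indicator", data=self.domain.indicator.astype(np.uint8))
            f.create_dataset("micro_mass", data=self.micro.mass)
            f.create_dataset("micro_dirvec", data=self.micro.dirvec)
            f.create_dataset("advance", data=self.evolver.advance)
            f.create_dataset("advance_dir", data=self.evolver.direction)

    def load_checkpoint(self, path) -> None:
        with h5py.File(path, "r") as f:
            self.stage = int(f.attrs["stage"])
            self.state.c = f["c"][()]
            self.state.l = f["l"][()]
            self.state.F = f["F"][()]
            self.state.sigma = f["sigma"][()]
            indicator = f["indicator"][()].astype(bool)
            self.micro = MicroFibreField(
                self.grid, self.config.fibre.micro_n,
                f["micro_mass"][()], f["micro_dirvec"][()],
            )
            self.evolver = DomainEvolver(self.grid)
            self.evolver.advance = f["advance"][()]
            self.evolver.direction = f["advance_dir"][()]
        self.domain = extract_boundary(indicator, self.grid)
        self.face_open = numerics.interface_face_open(self.domain.indicator)
        self.theta_f = self.micro.theta_f()


def run_experiment(config: SimulationConfig, output_dir=None) -> dict:
    """Seeding -> stage loop -> metrics; optionally writes outputs.

    Returns a metrics dict (per-stage logs plus final summaries); when
    ``output_dir`` is given, writes the final cancer field as NIfTI, the
    metrics as JSON and the config as YAML.
    """
    sim = Simulation(config)
    snapshots = []
    every = config.run.snapshot_every
    for _ in range(config.run.stages):
        sim.run_stage()
        if output_dir is not None and every > 0 and sim.stage % every == 0:
            snapshots.append((sim.stage, sim.state.c.copy()))
    metrics = {
        "config_hash": config.config_hash(),
        "stages": sim.stage,
        "final_total_c": sim.logs[-1].total_c if sim.logs else 0.0,
        "final_detected_volume": sim.logs[-1].detected_volume if sim.logs else 0,
        "final_domain_volume": sim.domain.volume_voxels,
        "log": [vars(l) for l in sim.logs],
    }
    if output_dir is not None:
        from . import io as gio

        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for stage, c in snapshots:
            gio.write_volume(c, out / f"c_stage{stage:04d}.nii.gz", sim.grid)
        gio.write_volume(sim.state.c, out / "c_final.nii.gz", sim.grid)
        gio.write_volume(sim.domain.indicator.astype(np.uint8),
                         out / "domain_final.nii.gz", sim.grid)
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        config.to_yaml(out / "config.yaml")
    return metrics


def make_forward_model(config: SimulationConfig, observations: ObservationSet,
                       detect_threshold: float = 0.05):
    """Forward model ``f(xi, halt_voxels) -> (fields_by_time, halted)``
    for the dyadic fit: reruns the pipeline with the seeding controller
    replaced, truncating as soon as an observation disagrees by more
    than ``halt_voxels`` voxels."""
    stages_per_day = config.timeline.stages_per_day
    obs_stages = {int(round(t * stages_per_day)): t for t in observations.times}
    masks = dict(zip(observations.times, observations.masks))

    def forward(xi: float, halt_voxels: int):
        cfg = config.replace(seeding={"xi": float(xi)})
        sim = Simulation(cfg)
        sim.detect_threshold = detect_threshold
        fields: dict[float, np.ndarray] = {}
        max_stage = max(obs_stages)
        for _ in range(max_stage):
            sim.run_stage()
            if sim.stage in obs_stages:
                t = obs_stages[sim.stage]
                fields[t] = sim.state.c.copy()
                _, count = mismatch(fields[t], masks[t], detect_threshold)
                if count > halt_voxels:
                    return fields, True
        return fields, False

    return forward


def hypothesis_h_volumes(config: SimulationConfig, xis, case: int) -> dict:
    """Final detected tumour volumes across seeding controllers.

    The relapse-containment hypothesis predicts the volume is
    non-increasing in ``xi`` (mass concentrated at the cavity edge
    spreads less).
    """
    out = {}
    for xi in xis:
        cfg = config.replace(seeding={"xi": float(xi), "case": case})
        metrics = run_experiment(cfg)
        out[xi] = metrics["final_detected_volume"]
    return out
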