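"""Whole-swarm simulations: motility + collisions + growth + QS + signal field.

The engine advances every population on a single global clock of 0.07 s
(the NanoBEADS frame interval).  NanoBEADS replay their track library every
step; BacteriaBots replay theirs every 11th step (0.77 s, their native
frame rate); free bacteria run-and-tumble every step.  Collisions between
the spherical agents (2 um diameter for bacteria and NanoBEADS, 6 um for
BacteriaBots) are inelastic: an agent whose proposed move would overlap
another simply pauses until reorientation clears the contact.  Growth
doubles agents on per-agent timers; a BacteriaBot's daughter detaches as a
free-swimming bacterium.  Every QS sync (10 global steps = 0.7 s by
default) each bacterial cell perceives the extracellular AHL at its body's
position, integrates its reporter ODEs, and deposits the AHL it produced
into the signal grid, which then diffuses and degrades.

Scenario families
-----------------
* ``isotropic``  -- agents in a square motility domain, no chemoeffector.
* ``gradient``   -- same, plus a linear attractant gradient driving
  run-and-tumble chemotaxis (bacteria) and group-gated track sampling
  (biohybrids with a calibrated library split).
* ``sweep``      -- activation-time mean/SD matrices over RBS strength
  (eta) and migration bias: the sensitivity/robustness surfaces.
* ``two_population`` -- decentralized control: two colonized patches in a
  large domain exchanging signal only by diffusion.

Concentration bookkeeping equates *total bacteria*: with the 1-um slab a
concentration c per ml over an A um^2 domain means ``c * A * 1e-12`` cells,
so 4.8e7 ml^-1 over 1000x1000 um^2 is 48 bacteria = 48 NanoBEADS = 4
BacteriaBots (12 cells each).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import qs_dynamics
from .motility_sampler import SamplerPopulation, TrackBank
from .qs_dynamics import QSParams, SignalGrid, activation_time, gfp_step, production_rate
from .run_tumble import (
    ChemotaxisParams,
    RunTumblePopulation,
    isotropic_field,
    linear_gradient_field,
)
from .synthetic_tracks import generate_library, preset
from .trajectory_stats import cpc

__all__ = [
    "GLOBAL_DT",
    "KIND_TRAITS",
    "Agent",
    "PopulationSpec",
    "SimulationConfig",
    "ScenarioResult",
    "SwarmSimulation",
    "run_scenario",
    "sweep",
    "resolve_collisions",
    "agents_for_concentration",
    "two_population_config",
]

GLOBAL_DT = 0.07  # s, the NanoBEADS frame interval and global clock
BACTERIA_DOUBLING_S = 43.0 * 60.0
BIOHYBRID_DOUBLING_S = 121.0 * 60.0

# radius um, bacterial cells per agent, global steps between motility updates
KIND_TRAITS = {
    "bacterium": dict(radius=1.0, n_bacteria=1, stride=1),
    "nanobeads": dict(radius=1.0, n_bacteria=1, stride=1),
    "bacteriabot": dict(radius=3.0, n_bacteria=12, stride=11),
}


@dataclass
class Agent:
    """Flat per-agent record (snapshot export of a population row)."""

    kind: str
    position: tuple
    heading: float
    radius: float
    n_bacteria: int
    Gi: float  # mean over the agent's cells
    Gm: float
    growth_timer: float | None
    population_tag: str


@dataclass
class PopulationSpec:
    """One population in a scenario: kind, size and (optional) own domain."""

    kind: str
    n: int
    tag: str = ""
    domain: tuple | None = None  # (x0, x1, y0, y1); None -> motility domain

    def __post_init__(self) -> None:
        if self.kind not in KIND_TRAITS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if not self.tag:
            self.tag = self.kind


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulation run."""

    populations: list = field(default_factory=lambda: [PopulationSpec("bacterium", 48)])
    seed: int = 0
    domain_um: float = 1000.0  # square motility domain edge
    field_margin_um: float = 1000.0  # Dirichlet-0 x margins beyond the domain
    grid_dx: float = 10.0  # um; 25 um is the coarse mode for long sweeps
    y_periodic: bool = True
    gradient_slope: float | None = None  # uM/um; None -> isotropic
    gradient_midpoint: float = 18.0  # uM at the domain midline
    migration_bias_groups: tuple | None = None  # (group_pos, group_neg) for samplers
    eta: float = 1.0
    qs_enabled: bool = True
    growth: str = "off"  # off | half | full
    horizon_s: float = 20.0 * 3600.0
    qs_stride: int = 10  # global steps between QS/field syncs
    record_stride: int = 1  # syncs between recorded samples
    stop_on: str = "overall"  # overall | populations | none
    collisions: bool = True
    diffusivity_scale: float = 1.0  # e.g. 0.75 for extracellular-matrix transport
    chemotaxis: ChemotaxisParams = field(default_factory=ChemotaxisParams)
    qs: QSParams = field(default_factory=QSParams)
    inherit_reporter: bool = True  # daughters copy the mother's Gi/Gm
    track_overrides: dict = field(default_factory=dict)  # kind -> TrackGenSpec kwargs

    def __post_init__(self) -> None:
        if self.growth not in ("off", "half", "full"):
            raise ValueError("growth must be off, half or full")
        if self.migration_bias_groups is not None and not any(
            p.kind in ("nanobeads", "bacteriabot") for p in self.populations
        ):
            raise ValueError("migration bias groups given but no sampler population")


def agents_for_concentration(
    conc_per_ml: float, kind: str, domain_area_um2: float = 1000.0 * 1000.0
) -> int:
    """Agent count equivalent to a bacterial concentration under the 1-um slab.

    ``conc_per_ml`` counts *bacteria*; BacteriaBots carry 12 each, so their
    agent count is 1/12th of the bacterial count.
    """
    total_bacteria = conc_per_ml * domain_area_um2 * 1e-12  # slab volume in ml
    n = total_bacteria / KIND_TRAITS[kind]["n_bacteria"]
    out = int(round(n))
    if out < 1:
        raise ValueError("concentration corresponds to fewer than one agent")
    return out


def two_population_config(
    kind: str = "nanobeads",
    n_large: int = 44,
    n_small: int = 4,
    separation_um: float = 2700.0,
    domain_um: float = 4000.0,
    patch_um: float = 100.0,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Decentralized-control scenario: two colonized patches in a big domain.

    Patch centers sit ``separation_um`` apart along x, centered in y; each
    population is confined to its patch (colonization).  The AHL diffusivity
    is reduced to 75% of its value in water (extracellular-matrix estimate)
    and all four domain edges are zero-concentration sinks.  The edge sinks
    are load-bearing: they keep the background signal from an activated
    patch marginal at the other patch, which is what makes a critical
    minority fraction exist at all (with generous far-field margins every
    minority size tips over).
    """
    cx = 0.5 * domain_um
    half = 0.5 * patch_um
    centers = (cx - 0.5 * separation_um, cx + 0.5 * separation_um)
    pops = []
    for name, n, c in (("large", n_large, centers[0]), ("small", n_small, centers[1])):
        if n > 0:
            pops.append(
                PopulationSpec(
                    kind,
                    n,
                    tag=name,
                    domain=(c - half, c + half, cx - half, cx + half),
                )
            )
    cfg = dict(
        populations=pops,
        seed=seed,
        domain_um=domain_um,
        field_margin_um=0.0,
        grid_dx=25.0,
        y_periodic=False,
        diffusivity_scale=0.75,
        stop_on="populations",
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def resolve_collisions(
    positions: np.ndarray,
    proposed: np.ndarray,
    radii: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inelastic collision rule: reject moves that would overlap spheres.

    Agents are visited in random order; a move is accepted only if the
    proposed position keeps the agent at least the sum of radii away from
    every other agent's current (or already-accepted) position, otherwise
    the agent pauses for this step.  Neighbor search uses uniform spatial
    hashing, so the cost is linear in agent count at low density.
    """
    n = len(positions)
    accept = np.ones(n, dtype=bool)
    if n < 2:
        return accept
    rmax = float(radii.max())
    cell = 2.0 * rmax * 1.0001
    cur = positions.copy()

    def key(p):
        return (int(np.floor(p[0] / cell)), int(np.floor(p[1] / cell)))

    buckets: dict[tuple, list[int]] = {}
    for i in range(n):
        buckets.setdefault(key(cur[i]), []).append(i)

    for i in rng.permutation(n):
        p = proposed[i]
        kx, ky = key(p)
        ok = True
        for bx in (kx - 1, kx, kx + 1):
            for by in (ky - 1, ky, ky + 1):
                for j in buckets.get((bx, by), ()):
                    if j == i:
                        continue
                    d2 = (p[0] - cur[j, 0]) ** 2 + (p[1] - cur[j, 1]) ** 2
                    if d2 < (radii[i] + radii[j]) ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            old = key(cur[i])
            new = (kx, ky)
            if old != new:
                buckets[old].remove(i)
                buckets.setdefault(new, []).append(i)
            cur[i] = p
        else:
            accept[i] = False
    return accept


class _Population:
    """Internal bundle: motility state + per-cell reporter + growth timers."""

    def __init__(self, spec, motility, qs_params, growth_mode, rng):
        traits = KIND_TRAITS[spec.kind]
        self.spec = spec
        self.kind = spec.kind
        self.tag = spec.tag
        self.radius = traits["radius"]
        self.cells_per_agent = traits["n_bacteria"]
        self.stride = traits["stride"]
        self.motility = motility
        n_cells = spec.n * self.cells_per_agent
        self.Gi = np.zeros(n_cells)
        self.Gm = np.zeros(n_cells)
        base_dbl = (
            BACTERIA_DOUBLING_S if spec.kind == "bacterium" else BIOHYBRID_DOUBLING_S
        )
        if growth_mode == "off":
            self.tau_dbl = None
            self.mu = 0.0
            self.timers = None
        else:
            self.tau_dbl = base_dbl * (2.0 if growth_mode == "half" else 1.0)
            self.mu = np.log(2.0) / self.tau_dbl
            self.timers = rng.uniform(0.0, self.tau_dbl, spec.n)

    @property
    def n(self) -> int:
        return len(self.motility.headings)

    @property
    def positions(self) -> np.ndarray:
        return self.motility.positions

    def cell_positions(self) -> np.ndarray:
        """Position of every bacterial cell (BacteriaBot cells share the body)."""
        if self.cells_per_agent == 1:
            return self.positions
        return np.repeat(self.positions, self.cells_per_agent, axis=0)

    def snapshot(self) -> list[Agent]:
        out = []
        c = self.cells_per_agent
        for i in range(self.n):
            out.append(
                Agent(
                    kind=self.kind,
                    position=tuple(self.positions[i]),
                    heading=float(self.motility.headings[i]),
                    radius=self.radius,
                    n_bacteria=c,
                    Gi=float(self.Gi[i * c : (i + 1) * c].mean()),
                    Gm=float(self.Gm[i * c : (i + 1) * c].mean()),
                    growth_timer=None if self.timers is None else float(self.timers[i]),
                    population_tag=self.tag,
                )
            )
        return out


@dataclass
class ScenarioResult:
    """Recorded time series and activation outcomes of one run."""

    config: SimulationConfig
    times: np.ndarray
    mean_gm: np.ndarray  # over all living bacterial cells
    mean_gm_by_pop: dict
    mean_q_by_pop: dict  # perceived signal, nM
    counts_by_kind: dict
    cpc_series: np.ndarray
    activation_s: float | None
    activation_by_pop: dict
    steady_nonactivated_by_pop: dict
    final_agents: list

    def save(self, outdir) -> None:
        """Write activation.json, timeseries.csv and a final position table."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["chemotaxis"] = asdict(self.config.chemotaxis)
        cfg["qs"] = asdict(self.config.qs)
        with open(out / "activation.json", "w") as fh:
            json.dump(
                {
                    "activation_s": self.activation_s,
                    "activation_by_pop": self.activation_by_pop,
                    "steady_nonactivated_by_pop": self.steady_nonactivated_by_pop,
                    "config": cfg,
                },
                fh,
                indent=2,
                default=str,
            )
        cols = {"t_s": self.times, "mean_gm": self.mean_gm, "cpc": self.cpc_series}
        for tag, v in self.mean_gm_by_pop.items():
            cols[f"mean_gm_{tag}"] = v
        for tag, v in self.mean_q_by_pop.items():
            cols[f"mean_q_nM_{tag}"] = v
        for kind, v in self.counts_by_kind.items():
            cols[f"n_{kind}"] = v
        pd.DataFrame(cols).to_csv(out / "timeseries.csv", index=False)
        rows = [asdict(a) for a in self.final_agents]
        pd.DataFrame(rows).to_csv(out / "positions_final.csv", index=False)

    def save_field(self, grid: SignalGrid, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("Q_nM", data=grid.Q)
            for k in ("nx", "ny", "dx", "dy", "x0", "y0", "depth"):
                fh.attrs[k] = getattr(grid, k)


class SwarmSimulation:
    """The coupled simulation engine.  Build from a :class:`SimulationConfig`."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        c = config
        self.dt = GLOBAL_DT
        root = np.random.SeedSequence(c.seed)
        (
            ss_lib,
            ss_motility,
            ss_growth,
            ss_collide,
        ) = root.spawn(4)
        self.rng_growth = np.random.default_rng(ss_growth)
        self.rng_collide = np.random.default_rng(ss_collide)

        self.domain = (0.0, c.domain_um, 0.0, c.domain_um)
        self.midline = 0.5 * c.domain_um

        # chemoeffector landscape for run-and-tumble bacteria
        if c.gradient_slope is not None:
            self.chemo_field = linear_gradient_field(
                slope=c.gradient_slope,
                midpoint=c.gradient_midpoint,
                x_mid=self.midline,
            )
            self.gradient_direction = (1.0, 0.0)
        else:
            self.chemo_field = isotropic_field()
            self.gradient_direction = None

        # one shared track bank per sampler kind, deterministic per seed
        lib_seeds = ss_lib.spawn(2)
        self.banks = {}
        for kind, seed_seq in zip(("nanobeads", "bacteriabot"), lib_seeds):
            if any(p.kind == kind for p in c.populations):
                preset_kind = "bacteriabots" if kind == "bacteriabot" else kind
                overrides = dict(c.track_overrides.get(kind, {}))
                overrides["seed"] = int(seed_seq.generate_state(1)[0] % 2**31)
                lib = generate_library(preset(preset_kind, **overrides))
                if c.migration_bias_groups is not None:
                    lib.group_pos = np.asarray(c.migration_bias_groups[0], dtype=np.intp)
                    lib.group_neg = np.asarray(c.migration_bias_groups[1], dtype=np.intp)
                self.banks[kind] = TrackBank(lib)

        # populations
        self.populations: list[_Population] = []
        pop_seeds = ss_motility.spawn(len(c.populations))
        for spec, seq in zip(c.populations, pop_seeds):
            rng = np.random.default_rng(seq)
            dom = spec.domain if spec.domain is not None else self.domain
            # periodic y applies to free motion in the full domain; patch
            # confinement (colonized populations) pauses on all walls
            wrap = c.y_periodic and spec.domain is None
            if spec.kind == "bacterium":
                mot = RunTumblePopulation(
                    spec.n, rng, params=c.chemotaxis, field=self.chemo_field,
                    domain=dom, y_periodic=wrap,
                )
            else:
                mot = SamplerPopulation(
                    self.banks[spec.kind],
                    spec.n,
                    rng,
                    domain=dom,
                    use_groups=c.migration_bias_groups is not None,
                    y_periodic=wrap,
                )
            self.populations.append(
                _Population(spec, mot, c.qs, c.growth, self.rng_growth)
            )
        # BacteriaBot daughters detach as free bacteria into a companion
        # population sharing the mother's domain
        self._bb_daughters: dict[int, _Population] = {}

        # signal grid: zero-concentration boundaries sit field_margin_um
        # beyond the motility domain in x (and in y too when y is not
        # periodic); periodic y wraps at the domain edges
        self.qs = QSParams(**{**asdict(c.qs), "eta": c.eta})
        self.Dsignal = self.qs.Dsignal * c.diffusivity_scale
        dx = c.grid_dx
        x_lo, x_hi = -c.field_margin_um, c.domain_um + c.field_margin_um
        nx = int(round((x_hi - x_lo) / dx))
        if c.y_periodic:
            y_lo, ny = 0.0, int(round(c.domain_um / dx))
        else:
            y_lo = -c.field_margin_um
            ny = nx if x_lo == y_lo else int(round((c.domain_um + 2 * c.field_margin_um) / dx))
        self.grid = SignalGrid(
            nx=nx, ny=ny, dx=dx, dy=dx, x0=x_lo, y0=y_lo, y_periodic=c.y_periodic
        )

        self.time = 0.0
        self._step_count = 0
        self._vmax = max(
            [c.chemotaxis.speed]
            + [b.max_speed for b in self.banks.values()]
        )
        self._collision_timer = 0
        self._pairs: np.ndarray | None = None
        self._pair_contact: np.ndarray | None = None
        self._radii: np.ndarray | None = None
        self._records = {
            "t": [],
            "mean_gm": [],
            "cpc": [],
            "gm_by_pop": {},
            "q_by_pop": {},
            "n_by_kind": {},
        }
        self._deriv_hist: dict[str, list] = {}

    # ---- bookkeeping helpers -------------------------------------------

    def _all_pops(self) -> list[_Population]:
        return self.populations + list(self._bb_daughters.values())

    def _all_positions(self) -> np.ndarray:
        return np.vstack([p.positions for p in self._all_pops() if p.n])

    def total_cells(self) -> int:
        return sum(p.n * p.cells_per_agent for p in self._all_pops())

    def mean_gm(self) -> float:
        num = sum(p.Gi.size and p.Gm.sum() for p in self._all_pops())
        den = self.total_cells()
        return num / den if den else 0.0

    # ---- collision gating ----------------------------------------------

    def _collision_refresh(self, refresh_steps: int = 16) -> None:
        """Rebuild the candidate pair list: agents that could touch in the window."""
        from scipy.spatial import cKDTree

        pops = [p for p in self._all_pops() if p.n]
        pos = np.vstack([p.positions for p in pops])
        self._radii = np.concatenate([np.full(p.n, p.radius) for p in pops])
        horizon = (
            2.0 * self._radii.max() + 2.0 * self._vmax * self.dt * refresh_steps
        )
        pairs = cKDTree(pos).query_pairs(horizon, output_type="ndarray")
        if len(pairs):
            self._pairs = pairs
            self._pair_contact = self._radii[pairs[:, 0]] + self._radii[pairs[:, 1]]
        else:
            self._pairs = None
        self._collision_timer = refresh_steps

    def _resolve_step(self, proposed: np.ndarray) -> np.ndarray:
        """Accept mask over the concatenated agent list for this step.

        Cheap path: a cached near-pair list is screened with one vectorized
        distance check; the sequential collision resolver only runs on the
        few agents whose proposed moves actually threaten contact.
        """
        n = len(proposed)
        accept = np.ones(n, dtype=bool)
        if not self.config.collisions or n < 2:
            return accept
        if self._collision_timer <= 0:
            self._collision_refresh()
        self._collision_timer -= 1
        if self._pairs is None:
            return accept
        i, j = self._pairs[:, 0], self._pairs[:, 1]
        d = proposed[i] - proposed[j]
        d2 = d[:, 0] ** 2 + d[:, 1] ** 2
        # margin covers the proposed-vs-current geometry the resolver uses
        margin = 2.0 * self._vmax * self.dt
        near = d2 < (self._pair_contact + margin) ** 2
        if not near.any():
            return accept
        # exact conflict test: an agent is safe if its proposed position
        # clears every neighbor's current AND proposed position -- then its
        # acceptance cannot depend on the resolution order
        pops = [p for p in self._all_pops() if p.n]
        pos = np.vstack([p.positions for p in pops])
        ni, nj = i[near], j[near]
        contact2 = self._pair_contact[near] ** 2
        dpc = proposed[ni] - pos[nj]
        dcp = pos[ni] - proposed[nj]
        conflict = (
            (d2[near] < contact2)
            | (dpc[:, 0] ** 2 + dpc[:, 1] ** 2 < contact2)
            | (dcp[:, 0] ** 2 + dcp[:, 1] ** 2 < contact2)
        )
        if not conflict.any():
            return accept
        idx = np.unique(np.concatenate([ni[conflict], nj[conflict]]))
        accept[idx] = resolve_collisions(
            pos[idx], proposed[idx], self._radii[idx], self.rng_collide
        )
        return accept

    # ---- growth ---------------------------------------------------------

    def _growth_sync(self, dt_sync: float) -> None:
        if self.config.growth == "off":
            return
        spawned = False
        for pi, pop in enumerate(list(self.populations) + list(self._bb_daughters.values())):
            if pop.timers is None:
                continue
            pop.timers -= dt_sync
            expired = np.flatnonzero(pop.timers <= 0.0)
            if expired.size == 0:
                continue
            spawned = True
            pop.timers[expired] = pop.tau_dbl
            mothers = pop.positions[expired]
            c = pop.cells_per_agent
            if pop.kind == "bacteriabot":
                # daughter detaches as a free-swimming bacterium
                target = self._get_daughter_pop(pi, pop)
                # daughter reporter state: mean of the mother's attached cells
                if self.config.inherit_reporter:
                    gi = np.array(
                        [pop.Gi[e * c : (e + 1) * c].mean() for e in expired]
                    )
                    gm = np.array(
                        [pop.Gm[e * c : (e + 1) * c].mean() for e in expired]
                    )
                else:
                    gi = np.zeros(expired.size)
                    gm = np.zeros(expired.size)
                target.motility.spawn(mothers)
                target.Gi = np.concatenate([target.Gi, gi])
                target.Gm = np.concatenate([target.Gm, gm])
                target.timers = np.concatenate(
                    [target.timers, np.full(expired.size, target.tau_dbl)]
                )
            else:
                pop.motility.spawn(mothers)
                if self.config.inherit_reporter:
                    gi, gm = pop.Gi[expired].copy(), pop.Gm[expired].copy()
                else:
                    gi = np.zeros(expired.size)
                    gm = np.zeros(expired.size)
                pop.Gi = np.concatenate([pop.Gi, gi])
                pop.Gm = np.concatenate([pop.Gm, gm])
                pop.timers = np.concatenate(
                    [pop.timers, np.full(expired.size, pop.tau_dbl)]
                )
        if spawned:
            # agent indices changed; force a collision-neighborhood rebuild
            self._collision_timer = 0

    def _get_daughter_pop(self, pi: int, mother: _Population) -> _Population:
        if pi not in self._bb_daughters:
            spec = PopulationSpec(
                "bacterium", 1, tag=f"{mother.tag}_daughters", domain=mother.spec.domain
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([self.config.seed, 7919, pi])
            )
            dom = spec.domain if spec.domain is not None else self.domain
            mot = RunTumblePopulation(
                0, rng, params=self.config.chemotaxis, field=self.chemo_field,
                domain=dom, y_periodic=self.config.y_periodic and spec.domain is None,
            )
            pop = _Population(
                PopulationSpec("bacterium", 1, tag=spec.tag, domain=spec.domain),
                mot,
                self.qs,
                self.config.growth,
                self.rng_growth,
            )
            # spec.n was a placeholder; reset state to empty
            pop.Gi = np.zeros(0)
            pop.Gm = np.zeros(0)
            pop.timers = np.zeros(0)
            self._bb_daughters[pi] = pop
        return self._bb_daughters[pi]

    # ---- QS / field sync -------------------------------------------------

    def _qs_sync(self, dt_sync: float) -> None:
        grid = self.grid
        for pop in self._all_pops():
            if pop.n == 0 or not self.config.qs_enabled:
                continue
            cell_pos = pop.cell_positions()
            ix, iy = grid.cell_index(cell_pos)
            q = grid.Q[ix, iy]
            pop._last_q = q
            pop.Gi, pop.Gm = gfp_step(pop.Gi, pop.Gm, q, dt_sync, self.qs, mu=pop.mu)
            produced = production_rate(q, self.qs) * dt_sync
            if pop.cells_per_agent == 1:
                grid.deposit(cell_pos, produced)
            else:
                per_agent = produced.reshape(pop.n, pop.cells_per_agent).sum(axis=1)
                grid.deposit(pop.positions, per_agent)
        if self.config.qs_enabled:
            grid.diffuse_decay(dt_sync, self.Dsignal, self.qs.Rd)

    def _record(self) -> None:
        r = self._records
        r["t"].append(self.time)
        r["mean_gm"].append(self.mean_gm())
        r["cpc"].append(cpc(self._all_positions()[:, 0], self.midline))
        for pop in self._all_pops():
            gm = r["gm_by_pop"].setdefault(pop.tag, [])
            qv = r["q_by_pop"].setdefault(pop.tag, [])
            # backfill populations created mid-run (BB daughters)
            while len(gm) < len(r["t"]) - 1:
                gm.append(0.0)
                qv.append(0.0)
            gm.append(pop.Gm.mean() if pop.Gm.size else 0.0)
            q = getattr(pop, "_last_q", None)
            qv.append(float(np.mean(q)) if q is not None and np.size(q) else 0.0)
        counts: dict[str, int] = {}
        for pop in self._all_pops():
            counts[pop.kind] = counts.get(pop.kind, 0) + pop.n
        for kind in ("bacterium", "nanobeads", "bacteriabot"):
            ks = r["n_by_kind"].setdefault(kind, [])
            while len(ks) < len(r["t"]) - 1:
                ks.append(0)
            ks.append(counts.get(kind, 0))

    # ---- main loop --------------------------------------------------------

    def step(self) -> None:
        """Advance one global 0.07 s step (motility + collisions)."""
        pops = [p for p in self._all_pops() if p.n]
        proposals = []
        moving = []
        for p in pops:
            if self._step_count % p.stride == 0:
                if p.kind == "bacterium":
                    proposals.append(p.motility.propose(self.dt))
                else:
                    proposals.append(p.motility.propose(self.gradient_direction))
                moving.append(True)
            else:
                proposals.append(p.positions)
                moving.append(False)
        proposed = np.vstack(proposals) if proposals else np.empty((0, 2))
        accept = self._resolve_step(proposed)
        i0 = 0
        for p, mv in zip(pops, moving):
            a = accept[i0 : i0 + p.n]
            i0 += p.n
            if not mv:
                continue
            if p.kind == "bacterium":
                p.motility.commit(self.dt * p.stride, a)
            else:
                p.motility.commit(a)
        self._step_count += 1
        self.time = self._step_count * self.dt

    def run(self) -> ScenarioResult:
        """Run to activation / steady state / horizon and bundle the results."""
        c = self.config
        dt_sync = self.dt * c.qs_stride
        n_steps = int(np.ceil(c.horizon_s / self.dt))
        self._record()
        sync_i = 0
        threshold = self.qs.gfp_threshold
        steady: dict[str, float | None] = {}
        # steady-non-activated detection state per population
        runmax: dict[str, float] = {}
        below_since: dict[str, float | None] = {}
        steady_window = 30.0 * 60.0
        for s in range(n_steps):
            self.step()
            if (s + 1) % c.qs_stride:
                continue
            self._qs_sync(dt_sync)
            self._growth_sync(dt_sync)
            sync_i += 1
            if sync_i % c.record_stride == 0:
                self._record()
                if c.stop_on != "none" and self._should_stop(
                    threshold, runmax, below_since, steady, steady_window
                ):
                    break
        return self._bundle(steady)

    def _should_stop(self, threshold, runmax, below_since, steady, window) -> bool:
        r = self._records
        c = self.config
        if c.stop_on == "overall":
            return r["mean_gm"][-1] > threshold
        # per-population: stop when every population is activated or steady
        if len(r["t"]) < 3:
            return False
        t_now = r["t"][-1]
        dt = r["t"][-1] - r["t"][-2]
        done = True
        for tag, series in r["gm_by_pop"].items():
            if series[-1] > threshold:
                continue
            d = abs(series[-1] - series[-2]) / dt
            qd = abs(r["q_by_pop"][tag][-1] - r["q_by_pop"][tag][-2]) / dt
            mg = max(runmax.get((tag, "gm"), 0.0), d)
            mq = max(runmax.get((tag, "q"), 0.0), qd)
            runmax[(tag, "gm")] = mg
            runmax[(tag, "q")] = mq
            if mg > 0 and mq > 0 and d <= 1e-6 * mg and qd <= 1e-6 * mq:
                if below_since.get(tag) is None:
                    below_since[tag] = t_now
                if t_now - below_since[tag] >= window:
                    steady[tag] = t_now
                    continue
            else:
                below_since[tag] = None
            done = False
        return done

    def _bundle(self, steady) -> ScenarioResult:
        r = self._records
        times = np.asarray(r["t"])
        mean_gm = np.asarray(r["mean_gm"])
        threshold = self.qs.gfp_threshold

        def pad(series):
            out = list(series)
            while len(out) < len(times):
                out.append(out[-1] if out else 0.0)
            return np.asarray(out)

        gm_by_pop = {k: pad(v) for k, v in r["gm_by_pop"].items()}
        q_by_pop = {k: pad(v) for k, v in r["q_by_pop"].items()}
        act_by_pop = {
            k: activation_time(times, v, threshold) for k, v in gm_by_pop.items()
        }
        steady_by_pop = {
            k: steady.get(k) is not None for k in gm_by_pop
        }
        agents = []
        for p in self._all_pops():
            agents.extend(p.snapshot())
        return ScenarioResult(
            config=self.config,
            times=times,
            mean_gm=mean_gm,
            mean_gm_by_pop=gm_by_pop,
            mean_q_by_pop=q_by_pop,
            counts_by_kind={k: pad(v) for k, v in r["n_by_kind"].items()},
            cpc_series=np.asarray(r["cpc"]),
            activation_s=activation_time(times, mean_gm, threshold),
            activation_by_pop=act_by_pop,
            steady_nonactivated_by_pop=steady_by_pop,
            final_agents=agents,
        )


def run_scenario(config: SimulationConfig) -> ScenarioResult:
    """Build the engine from ``config``, run it, and return the result bundle."""
    return SwarmSimulation(config).run()


def sweep(
    base_config: SimulationConfig,
    eta_grid,
    bias_grid=(0.0,),
    replicates: int = 5,
    bias_ladder: list | None = None,
):
    """Activation-time mean/SD matrices over (eta, migration bias).

    Runs ``replicates`` seeds per grid cell and returns
    ``(mean, sd, not_activated_mask)`` arrays of shape
    ``(len(eta_grid), len(bias_grid))``.  Nonzero biases need a
    ``bias_ladder`` (from :func:`~swarmqs.motility_sampler.migration_bias_ladder`)
    for sampler kinds, or use the gradient-slope scaling for bacteria.
    """
    from dataclasses import replace

    eta_grid = list(eta_grid)
    bias_grid = list(bias_grid)
    mean = np.full((len(eta_grid), len(bias_grid)), np.nan)
    sd = np.full_like(mean, np.nan)
    mask = np.zeros(mean.shape, dtype=bool)
    for i, eta in enumerate(eta_grid):
        for j, bias in enumerate(bias_grid):
            vals = []
            for rep in range(replicates):
                kw = dict(eta=eta, seed=base_config.seed + 1000 * rep + 17 * j + i)
                if bias > 0:
                    if bias_ladder is not None:
                        entry = min(
                            bias_ladder,
                            key=lambda e: abs(e["migration_bias"] - bias),
                        )
                        kw["migration_bias_groups"] = (
                            entry["group_pos"],
                            entry["group_neg"],
                        )
                    kw["gradient_slope"] = 0.017 * bias
                cfg = replace(base_config, **kw)
                res = run_scenario(cfg)
                vals.append(np.nan if res.activation_s is None else res.activation_s)
            vals = np.asarray(vals, dtype=float)
            ok = ~np.isnan(vals)
            if ok.any():
                mean[i, j] = vals[ok].mean()
                sd[i, j] = vals[ok].std(ddof=0) if ok.sum() > 1 else 0.0
            mask[i, j] = not ok.all()
    return mean, sd, mask
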