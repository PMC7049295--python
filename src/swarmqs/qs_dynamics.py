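"""Quorum-sensing circuit kinetics and the extracellular signal field.

The QS circuit (LuxI/LuxR-type, abstracted to its production rate) makes a
small diffusible signal, AHL, at a basal rate A1 plus a Hill-upregulated
rate A2 * Q^H / (Q^H + Q0^H), the whole production scaled by the
ribosome-binding-site strength eta in (0, 1].  The positive feedback is
bistable: an isolated cell's perceived signal stays below the threshold Q0,
while a dense-enough population pushes the local field past Q0 and switches
to high production -- the number-density dependence that defines quorum
sensing.  Activation is read out through a GFP reporter: immature GFP is
translated under the same Hill drive, matures, and both forms are diluted
by growth and degraded by a saturable protease.

The extracellular signal obeys a diffusion--reaction equation

    dQ/dt = div(D grad Q) - Rd * Q

solved on a uniform 2D grid (one-cell-thick slab; see below) with an
explicit 5-point stencil, periodic in y and zero-concentration (Dirichlet)
beyond the x extremes.  Agents deposit produced molecules into their
containing cell and perceive the concentration of that same cell.

Units: Q is nM; GFP is molecules per cell (the threshold's native unit);
lengths um; time s.  The slab depth of 1 um is what makes the packaged
agent-count <-> concentration mapping exact (e.g. 48 agents over a
1000x1000 um^2 domain = 4.8e7 ml^-1); all molecule->molar conversions use
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QSParams",
    "CellState",
    "SignalGrid",
    "production_rate",
    "gfp_step",
    "field_step",
    "perceive",
    "activation_time",
]

AVOGADRO = 6.02214076e23
# nM per (molecule / um^3): 1e9 [M->nM] / (N_A * 1e-15 [um^3->L])
_NM_PER_MOLEC_UM3 = 1e9 / (AVOGADRO * 1e-15)


@dataclass
class QSParams:
    """QS circuit, GFP reporter and signal-transport parameters.

    Defaults are the packaged fitted/estimated values for the engineered
    lux-type circuit.  ``eta`` is the RBS strength (relative translation
    initiation rate) in (0, 1]; by default it scales the *whole* AHL
    production rate, basal term included -- set ``eta_on_basal=False`` for
    the alternative reading where it scales only the upregulated term.
    ``Rd`` is the first-order AHL degradation rate constant, stored per
    second (tabulated as 10.8% per hour).
    """

    A1: float = 3.19  # molecules/s, basal AHL production
    A2: float = 234.0  # molecules/s, upregulated AHL production
    H: float = 2.5  # Hill coefficient
    Q0: float = 1.87  # nM, upregulation threshold
    eta: float = 1.0  # RBS strength, (0, 1]
    ktr: float = 0.40  # molecules/s, max immature-GFP translation
    kGm: float = 3.02e-3  # 1/s, GFP maturation
    kdeg: float = 5.54  # molecules/s, max protease degradation
    Km: float = 6650.0  # molecules/cell, degradation half-max
    Dsignal: float = 490.0  # um^2/s, AHL diffusivity in water
    Rd: float = 0.108 / 3600.0  # 1/s, AHL degradation
    gfp_threshold: float = 218.0  # molecules/bacterium, activation readout
    eta_on_basal: bool = True

    def __post_init__(self) -> None:
        for name in ("A1", "A2", "H", "Q0", "ktr", "kGm", "kdeg", "Km", "Dsignal", "Rd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")


@dataclass
class CellState:
    """Intracellular reporter state of one bacterium.

    ``mu`` is the growth-dilution rate (ln 2 / doubling time, 1/s; 0 when
    growth is off).
    """

    Gi: float = 0.0  # immature GFP, molecules/cell
    Gm: float = 0.0  # mature GFP, molecules/cell
    mu: float = 0.0  # 1/s


def production_rate(Q_local, params: QSParams):
    """Total AHL production rate (molecules/s) at local signal Q (nM).

    eta * (A1 + A2 * Q^H / (Q^H + Q0^H)) with the packaged default of eta
    scaling the whole rate; monotone in Q with limits eta*A1 and
    eta*(A1 + A2).
    """
    Q = np.asarray(Q_local, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        qh = np.where(Q > 0, Q, np.nan) ** params.H
        hill = np.where(Q > 0, qh / (qh + params.Q0**params.H), 0.0)
    if params.eta_on_basal:
        return params.eta * (params.A1 + params.A2 * hill)
    return params.A1 + params.eta * params.A2 * hill


def hill_drive(Q_local, params: QSParams):
    """The Hill occupancy Q^H/(Q^H + Q0^H) driving GFP translation."""
    Q = np.asarray(Q_local, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        qh = np.where(Q > 0, Q, np.nan) ** params.H
        return np.where(Q > 0, qh / (qh + params.Q0**params.H), 0.0)


def gfp_rhs(Gi, Gm, Q_local, params: QSParams, mu=0.0):
    """Right-hand sides (dGi/dt, dGm/dt) of the reporter kinetics."""
    drive = hill_drive(Q_local, params)
    pool = Gi + Gm + params.Km
    dGi = params.ktr * drive - params.kGm * Gi - mu * Gi - params.kdeg * Gi / pool
    dGm = params.kGm * Gi - mu * Gm - params.kdeg * Gm / pool
    return dGi, dGm


def gfp_step(Gi, Gm, Q_local, dt: float, params: QSParams, mu=0.0, max_substep: float = 0.1):
    """Explicit-Euler advance of the GFP reporter over ``dt`` (vectorized).

    Internally sub-steps so no Euler step exceeds ``max_substep`` (0.1 s,
    comfortably stable at the packaged rates); non-negativity is enforced by
    clipping at zero.  Accepts scalars or aligned arrays of cells.
    """
    Gi = np.asarray(Gi, dtype=float).copy()
    Gm = np.asarray(Gm, dtype=float).copy()
    n_sub = max(int(np.ceil(dt / max_substep)), 1)
    h = dt / n_sub
    for _ in range(n_sub):
        dGi, dGm = gfp_rhs(Gi, Gm, Q_local, params, mu)
        Gi = np.maximum(Gi + h * dGi, 0.0)
        Gm = np.maximum(Gm + h * dGm, 0.0)
    return Gi, Gm


@dataclass
class SignalGrid:
    """Discretized extracellular AHL concentration field (nM) on a 1 um slab.

    The grid covers ``[x0, x0 + nx*dx] x [y0, y0 + ny*dy]``; ``Q[ix, iy]``
    is the concentration of cell (ix, iy).  x boundaries are
    zero-concentration (Dirichlet, ghost cells at 0); y boundaries are
    periodic by default (``y_periodic=False`` switches y to Dirichlet as
    well, used for closed square domains).
    """

    nx: int
    ny: int
    dx: float
    dy: float
    x0: float = 0.0
    y0: float = 0.0
    depth: float = 1.0  # um
    y_periodic: bool = True
    Q: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("dx, dy must be > 0")
        if self.Q is None:
            self.Q = np.zeros((self.nx, self.ny))
        else:
            self.Q = np.asarray(self.Q, dtype=float)
            if self.Q.shape != (self.nx, self.ny):
                raise ValueError("Q must have shape (nx, ny)")

    @property
    def cell_volume_um3(self) -> float:
        return self.dx * self.dy * self.depth

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.x0 + self.nx * self.dx,
            self.y0,
            self.y0 + self.ny * self.dy,
        )

    def cell_index(self, positions) -> tuple[np.ndarray, np.ndarray]:
        """Containing cell of each position; edge points go to the lower-index cell."""
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        ix = np.floor((p[:, 0] - self.x0) / self.dx).astype(np.intp)
        iy = np.floor((p[:, 1] - self.y0) / self.dy).astype(np.intp)
        # a point exactly on the upper boundary belongs to the last cell
        on_xedge = p[:, 0] == self.x0 + self.nx * self.dx
        on_yedge = p[:, 1] == self.y0 + self.ny * self.dy
        ix[on_xedge] -= 1
        iy[on_yedge] -= 1
        if np.any((ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)):
            raise ValueError("position outside the signal grid")
        # interior edge points: floor already assigns x==k*dx to cell k; the
        # documented tie rule is the lower-index cell, so shift those down
        interior_x = (p[:, 0] - self.x0) % self.dx == 0
        interior_y = (p[:, 1] - self.y0) % self.dy == 0
        ix = np.where(interior_x & (ix > 0) & ~on_xedge, ix - 1, ix)
        iy = np.where(interior_y & (iy > 0) & ~on_yedge, iy - 1, iy)
        return ix, iy

    def deposit(self, positions, molecules) -> None:
        """Add point-source molecules into their containing cells (nM)."""
        ix, iy = self.cell_index(positions)
        dq = (
            np.broadcast_to(np.asarray(molecules, dtype=float), ix.shape)
            * _NM_PER_MOLEC_UM3
            / self.cell_volume_um3
        )
        np.add.at(self.Q, (ix, iy), dq)

    def total_molecules(self) -> float:
        """Total AHL in the grid, in molecules (for conservation checks)."""
        return float(self.Q.sum() * self.cell_volume_um3 / _NM_PER_MOLEC_UM3)

    def stable_dt(self, D: float) -> float:
        """Largest stable explicit step for diffusivity ``D`` (with 0.9 margin)."""
        if D == 0.0:
            return np.inf
        h2 = 1.0 / (1.0 / self.dx**2 + 1.0 / self.dy**2)
        return 0.9 * h2 / (2.0 * D)

    def diffuse_decay(self, dt: float, D: float, Rd: float) -> None:
        """Advance diffusion + first-order decay by ``dt`` (sub-stepped to CFL)."""
        dt_max = self.stable_dt(D)
        n_sub = max(int(np.ceil(dt / dt_max)), 1)
        h = dt / n_sub
        decay = np.exp(-Rd * h)
        Q = self.Q
        for _ in range(n_sub):
            lap = np.empty_like(Q)
            # x: Dirichlet-0 ghost cells
            lap[1:-1] = (Q[2:] - 2.0 * Q[1:-1] + Q[:-2]) / self.dx**2
            lap[0] = (Q[1] - 2.0 * Q[0]) / self.dx**2
            lap[-1] = (Q[-2] - 2.0 * Q[-1]) / self.dx**2
            # y: periodic or Dirichlet-0
            if self.y_periodic:
                lap += (
                    np.roll(Q, 1, axis=1) - 2.0 * Q + np.roll(Q, -1, axis=1)
                ) / self.dy**2
            else:
                lap[:, 1:-1] += (
                    Q[:, 2:] - 2.0 * Q[:, 1:-1] + Q[:, :-2]
                ) / self.dy**2
                lap[:, 0] += (Q[:, 1] - 2.0 * Q[:, 0]) / self.dy**2
                lap[:, -1] += (Q[:, -2] - 2.0 * Q[:, -1]) / self.dy**2
            Q = (Q + h * D * lap) * decay
        self.Q = Q


def field_step(grid: SignalGrid, sources, dt: float, params: QSParams) -> SignalGrid:
    """Deposit point sources, then advance diffusion and degradation by ``dt``.

    ``sources`` is a list of ``(position, molecules)`` pairs (or an empty
    list); positions must lie inside the grid.
    """
    if sources:
        pos = np.array([p for p, _ in sources], dtype=float)
        mol = np.array([m for _, m in sources], dtype=float)
        grid.deposit(pos, mol)
    grid.diffuse_decay(dt, params.Dsignal, params.Rd)
    return grid


def perceive(grid: SignalGrid, position) -> np.ndarray | float:
    """Signal concentration (nM) of the cell containing each position.

    The same cell an agent deposits into, so deposition and perception are
    consistent by construction.
    """
    ix, iy = grid.cell_index(position)
    out = grid.Q[ix, iy]
    return float(out[0]) if np.ndim(position) == 1 else out


def activation_time(times, mean_gm, threshold: float = 218.0) -> float | None:
    """First time the population-mean mature GFP exceeds the threshold.

    Linear interpolation between the bracketing samples; returns 0 if the
    history starts above threshold and ``None`` if it never crosses.
    """
    times = np.asarray(times, dtype=float)
    g = np.asarray(mean_gm, dtype=float)
    if times.size == 0 or g.size != times.size:
        raise ValueError("times and mean_gm must be equal-length and nonempty")
    above = g > threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    g0, g1 = g[i - 1], g[i]
    return float(t0 + (threshold - g0) / (g1 - g0) * (t1 - t0))
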