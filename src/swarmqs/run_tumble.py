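"""Run-and-tumble motility and chemotaxis for free-swimming bacteria.

Free bacteria are the comparative baseline for the biohybrid agents: they
alternate straight "runs" at constant speed with reorienting "tumbles"
during which they are stationary.  Phase durations are exponentially
distributed; chemotaxis enters through the mean run duration

    tau(+/-) = tau0 * exp( +/- sigma_chemo * C_T * Kd / (Kd + s)^2
                           * (ds/dt + V_b . grad s) ),

i.e. runs up an attractant gradient are lengthened and runs down it are
shortened, with receptor saturation through Michaelis--Menten occupancy
C(s) = C_T s / (Kd + s).  Only the fitted product ``sigma_chemo * C_T`` is
known, so occupancy is carried in units of C_T throughout.  For attractants
tau = tau(+).  The run time is fixed when the run starts (evaluated at the
bacterium's position and new heading at the end of the tumble) and is not
re-evaluated mid-run.

Tumble angles have a log-normal magnitude whose *arithmetic* mean and SD
are the tabulated 68 deg and 36 deg (the underlying log-space parameters
are solved from the moment relations), with a random sign in 2D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChemotaxisParams",
    "ChemoField",
    "isotropic_field",
    "linear_gradient_field",
    "receptor_occupancy",
    "mean_run_time",
    "draw_phase_duration",
    "draw_tumble_angle",
    "RunTumblePopulation",
]


@dataclass
class ChemotaxisParams:
    """Run-and-tumble chemotaxis parameters (defaults are the packaged fits).

    ``sigma_chemo_CT`` is the fitted product of chemotactic sensitivity and
    total receptor count (units s); ``Kd`` is the l-aspartic-acid receptor
    dissociation constant.  ``exponent_clamp`` bounds the chemotactic
    exponent (numerical hygiene for pathologically steep synthetic fields,
    far outside the physiological regime).
    """

    tau0: float = 0.86  # s, mean run with no gradient
    tauT: float = 0.14  # s, mean tumble
    sigma_chemo_CT: float = 35.0  # s
    Kd: float = 18.0  # uM
    speed: float = 34.0  # um/s
    theta_mu: float = 68.0  # deg, arithmetic mean |tumble angle|
    theta_sigma: float = 36.0  # deg, arithmetic SD |tumble angle|
    exponent_clamp: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tau0", "tauT", "sigma_chemo_CT", "Kd", "speed", "theta_mu", "theta_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """(mu_log, sigma_log) giving arithmetic mean theta_mu and SD theta_sigma."""
        cv2 = (self.theta_sigma / self.theta_mu) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(self.theta_mu) - 0.5 * sigma2
        return mu, np.sqrt(sigma2)


@dataclass
class ChemoField:
    """Static chemoeffector landscape: concentration, gradient and rate of change.

    ``profile(x, y)`` returns concentration in uM, ``gradient(x, y)`` the
    (ds/dx, ds/dy) pair in uM/um, ``ds_dt(x, y)`` in uM/s.  The field is
    imposed and unconsumed.
    """

    profile: callable
    gradient: callable
    ds_dt: callable


def isotropic_field(concentration: float = 0.0) -> ChemoField:
    """Spatially uniform, steady chemoeffector field (no chemotactic signal)."""

    def profile(x, y):
        return np.broadcast_to(float(concentration), np.shape(x)).copy()

    def gradient(x, y):
        z = np.zeros(np.shape(x))
        return z, z.copy()

    def ds_dt(x, y):
        return np.zeros(np.shape(x))

    return ChemoField(profile, gradient, ds_dt)


def linear_gradient_field(
    slope: float = 0.017,
    midpoint: float = 18.0,
    x_mid: float = 500.0,
) -> ChemoField:
    """Linear attractant gradient along +x, clipped at zero concentration.

    Defaults reproduce the microfluidic assay this model was fit against:
    a 1.7e-5 M/mm (0.017 uM/um) l-aspartic-acid gradient whose midpoint
    concentration equals the receptor Kd.
    """

    def profile(x, y):
        return np.maximum(midpoint + slope * (np.asarray(x, dtype=float) - x_mid), 0.0)

    def gradient(x, y):
        s = midpoint + slope * (np.asarray(x, dtype=float) - x_mid)
        gx = np.where(s > 0, slope, 0.0)
        return gx, np.zeros(np.shape(x))

    def ds_dt(x, y):
        return np.zeros(np.shape(x))

    return ChemoField(profile, gradient, ds_dt)


def receptor_occupancy(s, params: ChemotaxisParams):
    """Bound-receptor fraction in units of the total receptor count C_T.

    Michaelis--Menten occupancy s/(Kd + s); 0 at s=0, 1/2 at s=Kd,
    saturating at 1 (i.e. C_T).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("chemoeffector concentration must be >= 0")
    return s / (params.Kd + s)


def mean_run_time(position, heading_deg, field: ChemoField, params: ChemotaxisParams):
    """Mean run duration tau(+) at a position and heading (vectorized).

    Evaluates the chemotactic run-length modulation with the bacterium's
    velocity vector V_b = speed * (cos heading, sin heading); the exponent
    is clamped to +-``params.exponent_clamp``.
    """
    position = np.asarray(position, dtype=float)
    x, y = position[..., 0], position[..., 1]
    th = np.radians(np.asarray(heading_deg, dtype=float))
    s = field.profile(x, y)
    gx, gy = field.gradient(x, y)
    advect = params.speed * (np.cos(th) * gx + np.sin(th) * gy)
    material = field.ds_dt(x, y) + advect
    arg = params.sigma_chemo_CT * params.Kd / (params.Kd + s) ** 2 * material
    arg = np.clip(arg, -params.exponent_clamp, params.exponent_clamp)
    return params.tau0 * np.exp(arg)


def draw_phase_duration(mean, rng: np.random.Generator, size=None):
    """Exponential phase duration with the given mean (run or tumble)."""
    if np.any(np.asarray(mean) <= 0):
        raise ValueError("mean duration must be positive")
    return rng.exponential(mean, size=size)


def draw_tumble_angle(params: ChemotaxisParams, rng: np.random.Generator, size=None):
    """Signed tumble angle: log-normal magnitude, equiprobable sign (2D)."""
    mu, sigma = params.lognormal_params
    mag = rng.lognormal(mu, sigma, size=size)
    sign = rng.integers(0, 2, size=size) * 2 - 1
    return sign * mag


class RunTumblePopulation:
    """Vectorized run-and-tumble dynamics for ``n`` bacteria.

    Timers are decremented by the simulation step ``dt`` (which must not
    exceed the global 0.07 s clock for phase-boundary resolution); runs
    translate at the fixed swimming speed, tumbles are stationary.  Walls
    follow the pause rule: a proposed position outside ``domain`` is
    rejected for that step.  With ``y_periodic=True`` the y extent wraps
    instead and only the x walls pause.  Use :meth:`propose`/
    :meth:`commit` when an external collision resolver gates the moves.
    """

    def __init__(
        self,
        n_agents: int,
        rng: np.random.Generator,
        params: ChemotaxisParams | None = None,
        field: ChemoField | None = None,
        domain: tuple[float, float, float, float] | None = (0.0, 1000.0, 0.0, 1000.0),
        positions: np.ndarray | None = None,
        headings: np.ndarray | None = None,
        y_periodic: bool = False,
    ):
        self.params = params or ChemotaxisParams()
        self.field = field or isotropic_field()
        self.rng = rng
        self.domain = domain
        self.y_periodic = y_periodic
        if positions is None:
            if domain is None:
                positions = np.zeros((n_agents, 2))
            else:
                positions = np.column_stack(
                    (
                        rng.uniform(domain[0], domain[1], n_agents),
                        rng.uniform(domain[2], domain[3], n_agents),
                    )
                )
        self.positions = np.array(positions, dtype=float)
        if headings is None:
            headings = rng.uniform(-180.0, 180.0, n_agents)
        self.headings = np.array(headings, dtype=float)
        self.running = np.ones(n_agents, dtype=bool)
        tau = mean_run_time(self.positions, self.headings, self.field, self.params)
        self.t_left = draw_phase_duration(tau, rng)
        self._proposed: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.headings)

    def propose(self, dt: float) -> np.ndarray:
        """Proposed positions after translating the running agents by ``dt``."""
        th = np.radians(self.headings)
        d = np.where(self.running, self.params.speed * dt, 0.0)
        self._proposed = self.positions + np.column_stack(
            (d * np.cos(th), d * np.sin(th))
        )
        return self._proposed

    def commit(self, dt: float, accept: np.ndarray | None = None) -> None:
        """Accept moves (wall rule applied), then advance the phase clocks."""
        prop = self._proposed
        if prop is None:
            raise RuntimeError("commit() before propose()")
        ok = np.ones(self.n, dtype=bool) if accept is None else accept.copy()
        if self.domain is not None:
            x0, x1, y0, y1 = self.domain
            ok &= (prop[:, 0] >= x0) & (prop[:, 0] <= x1)
            if self.y_periodic:
                prop[:, 1] = (prop[:, 1] - y0) % (y1 - y0) + y0
            else:
                ok &= (prop[:, 1] >= y0) & (prop[:, 1] <= y1)
        self.positions[ok] = prop[ok]
        self._proposed = None

        self.t_left -= dt
        expired = self.t_left <= 0.0
        if not expired.any():
            return
        end_run = expired & self.running
        end_tumble = expired & ~self.running
        k_run = int(end_run.sum())
        if k_run:
            self.running[end_run] = False
            self.t_left[end_run] = self.rng.exponential(self.params.tauT, k_run)
        k_tum = int(end_tumble.sum())
        if k_tum:
            self.headings[end_tumble] = (
                self.headings[end_tumble] + draw_tumble_angle(self.params, self.rng, k_tum)
                + 180.0
            ) % 360.0 - 180.0
            tau = mean_run_time(
                self.positions[end_tumble],
                self.headings[end_tumble],
                self.field,
                self.params,
            )
            self.running[end_tumble] = True
            self.t_left[end_tumble] = self.rng.exponential(tau)

    def step(self, dt: float) -> None:
        """One full update: translate runners, walls, phase transitions."""
        self.propose(dt)
        self.commit(dt)

    def spawn(self, positions: np.ndarray, headings: np.ndarray | None = None) -> None:
        """Append newly created bacteria (daughters) starting in a fresh run."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        k = len(positions)
        if headings is None:
            headings = self.rng.uniform(-180.0, 180.0, k)
        headings = np.asarray(headings, dtype=float)
        tau = mean_run_time(positions, headings, self.field, self.params)
        self.positions = np.vstack([self.positions, positions])
        self.headings = np.concatenate([self.headings, headings])
        self.running = np.concatenate([self.running, np.ones(k, dtype=bool)])
        self.t_left = np.concatenate(
            [self.t_left, draw_phase_duration(tau, self.rng)]
        )
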