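"""Synthetic-data generators for the three benchmark systems.

Each generator simulates a known ground-truth dynamical system, samples it
under a measurement protocol, corrupts the measurements with multiplicative
Gaussian noise, and returns a :class:`~phenodyn.fit.TimeSeriesSet` together
with the noiseless truth oracle, so downstream evaluation never re-implements
the true model.

Benchmarks
----------
* **gravity** -- reduced radial Kepler motion: a particle released with fixed
  tangential speed v0 at a varying distance r0 from the sun; only the
  distance r is observed, once per condition at a random time.  The release
  distance is also exposed as a constant input (it is experimentally
  controlled and sets the angular momentum ell = r0*v0).
* **phosphorylation** -- a receptor with 5 modification sites in a linear
  chain; each site (de)phosphorylates with Michaelis-Menten kinetics whose
  constants depend on the occupancy of its nearest neighbours, giving 2^5=32
  microstate ODEs.  The observable is total phosphorylation; the input V is
  the maximum rate of cooperative phosphorylation of site 2 when site 3 is
  occupied.
* **glycolysis** -- the 7-species yeast glycolysis oscillator (constants in
  :mod:`phenodyn.glycolysis_constants`); 3 of the 7 species are observed at
  a single random time per condition, with all 7 initial concentrations
  drawn from configured ranges.

All generators are seed-deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import odeint
from scipy.signal import find_peaks

from . import glycolysis_constants as glyco
from .fit import Condition, Record, TimeSeriesSet
from .simulate import InputSignal, gravity_rhs

__all__ = [
    "BenchmarkConfig",
    "generate_gravity_data",
    "GravityOracle",
    "build_phospho_network",
    "PhosphoNetwork",
    "generate_phospho_data",
    "simple_phospho_model",
    "build_glycolysis_model",
    "GlycolysisModel",
    "generate_glycolysis_data",
]


@dataclass
class BenchmarkConfig:
    """Sampling protocol for one benchmark study.

    ``n_conditions`` is the number of experimental conditions; the total
    record count N is ``n_conditions * records_per_condition`` (one record
    per observed variable per sampled time).  ``noise_frac`` is the
    multiplicative Gaussian noise scale; reported sigmas get a floor of 1%
    of the observable's dynamic range so zero-valued observations keep a
    positive uncertainty.
    """

    system: str
    n_conditions: int
    noise_frac: float
    seed: int = 0
    records_per_condition: int = 1
    t_max: float = 5.0
    range_scale: float = 1.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def gravity(cls, N: int = 150, seed: int = 0, noise_frac: float = 0.05):
        """N single-observation release experiments (one record each)."""
        return cls(
            system="gravity", n_conditions=N, noise_frac=noise_frac, seed=seed,
            records_per_condition=1, t_max=5.0,
            extra={"mu": 1.0, "v0": 1.0, "r0_range": (0.5, 3.0)},
        )

    @classmethod
    def phosphorylation(
        cls, N: int = 100, seed: int = 0, noise_frac: float = 0.10,
        records_per_condition: int = 5,
    ):
        """Time-course measurements of total phosphorylation, N records total."""
        n_cond = max(1, math.ceil(N / records_per_condition))
        return cls(
            system="phosphorylation", n_conditions=n_cond,
            noise_frac=noise_frac, seed=seed,
            records_per_condition=records_per_condition, t_max=10.0,
            extra={"v_range": (0.1, 10.0), "rate_seed": 42},
        )

    @classmethod
    def glycolysis(
        cls, N: int = 40, seed: int = 0, noise_frac: float = 0.10,
        range_scale: float = 1.0,
    ):
        """N conditions, 3 observed species at one random time each."""
        return cls(
            system="glycolysis", n_conditions=N, noise_frac=noise_frac,
            seed=seed, records_per_condition=1, t_max=1.0,
            range_scale=range_scale,
        )


def _noisy(rng, value: float, noise_frac: float, dyn_range: float):
    """Multiplicative Gaussian noise plus its reported sigma (floored)."""
    sigma = max(noise_frac * abs(value), 0.01 * dyn_range)
    return value + rng.normal() * noise_frac * abs(value), sigma


# ---------------------------------------------------------------------------
# Gravity
# ---------------------------------------------------------------------------

@dataclass
class GravityOracle:
    """Noiseless radial Kepler dynamics for fixed mu and release speed v0."""

    mu: float = 1.0
    v0: float = 1.0

    def trajectory(self, r0: float, times) -> np.ndarray:
        """True r(t) for a release at distance r0 (ell = r0 * v0)."""
        times = np.asarray(times, float)
        ell = r0 * self.v0
        teval = times if times[0] == 0.0 else np.concatenate([[0.0], times])

        def f(y, t):
            return gravity_rhs(y[0], y[1], ell, self.mu)

        sol = odeint(f, [r0, 0.0], teval, rtol=1e-9, atol=1e-11, mxstep=20000)
        return sol[-len(times):, 0]

    @property
    def circular_radius(self) -> float:
        """Release distance giving a circular orbit: r0 = mu / v0**2."""
        return self.mu / self.v0**2

    def is_bound(self, r0: float) -> bool:
        return 0.5 * self.v0**2 - self.mu / r0 < 0


def generate_gravity_data(config: BenchmarkConfig):
    """Single noisy observation of r at a random time per release distance.

    r0 is sampled uniformly from a range straddling the circular-orbit
    radius, so the data mix oscillatory (elliptical) and monotonically
    growing (hyperbolic) trajectories.  Returns (TimeSeriesSet, oracle).
    """
    rng = np.random.default_rng(config.seed)
    mu = config.extra.get("mu", 1.0)
    v0 = config.extra.get("v0", 1.0)
    lo, hi = config.extra.get("r0_range", (0.5, 3.0))
    oracle = GravityOracle(mu=mu, v0=v0)
    dyn_range = hi - lo
    conditions = []
    for c in range(config.n_conditions):
        r0 = rng.uniform(lo, hi)
        t_obs = rng.uniform(0.0, config.t_max)
        r_true = float(oracle.trajectory(r0, [t_obs])[0])
        value, sigma = _noisy(rng, r_true, config.noise_frac, dyn_range)
        conditions.append(
            Condition(
                id=f"release_{c}",
                inputs=np.array([r0]),
                observed_x0=np.array([r0]),
                records=[Record(t_obs, "r", value, sigma)],
            )
        )
    return TimeSeriesSet(["r"], conditions), oracle


# ---------------------------------------------------------------------------
# Multisite phosphorylation
# ---------------------------------------------------------------------------

def _neighbour_config(state: tuple[int, ...], site: int) -> tuple[int, ...]:
    """Occupancies of the existing nearest neighbours of ``site``."""
    cfg = []
    if site - 1 >= 0:
        cfg.append(state[site - 1])
    if site + 1 < len(state):
        cfg.append(state[site + 1])
    return tuple(cfg)


def draw_phospho_rates(n_sites: int, seed: int = 42) -> dict:
    """Neighbour-dependent Michaelis-Menten (V, K) pairs, log-uniform [0.1, 10].

    Keyed by (site, direction, neighbour_config): direction +1 is
    phosphorylation, -1 dephosphorylation; neighbour_config lists the
    occupancies of the site's existing nearest neighbours.  Drawn once from
    a fixed seed so the ground-truth model is exactly known.
    """
    rng = np.random.default_rng(seed)
    rates = {}
    for site in range(n_sites):
        n_nb = (site > 0) + (site < n_sites - 1)
        for direction in (+1, -1):
            for cfg in itertools.product((0, 1), repeat=n_nb):
                V, K = np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=2))
                rates[(site, direction, cfg)] = (float(V), float(K))
    return rates


class PhosphoNetwork:
    """Microstate ODE system of an n-site linearly-chained receptor.

    State space: all 2^n site-occupancy patterns; each transition flips one
    site with Michaelis-Menten rate V * x / (K + x) in the source
    microstate's concentration, so total concentration is conserved.
    """

    def __init__(self, n_sites: int, rate_params: dict):
        self.n_sites = n_sites
        self.rate_params = dict(rate_params)
        self.states = list(itertools.product((0, 1), repeat=n_sites))
        self.index = {s: i for i, s in enumerate(self.states)}
        self.occupancy = np.array([sum(s) for s in self.states], float)

        src, dst, Vs, Ks, is_input = [], [], [], [], []
        for s in self.states:
            for site in range(n_sites):
                direction = -1 if s[site] else +1
                t = list(s)
                t[site] = 1 - t[site]
                cfg = _neighbour_config(s, site)
                V, K = self.rate_params[(site, direction, cfg)]
                src.append(self.index[s])
                dst.append(self.index[tuple(t)])
                Vs.append(V)
                Ks.append(K)
                # the controllable input: max rate of cooperative
                # phosphorylation of site 2 (index 1) due to site 3
                # (index 2, the right neighbour) being occupied
                right_occupied = site + 1 < n_sites and s[site + 1] == 1
                is_input.append(site == 1 and direction == +1 and right_occupied)
        self._src = np.array(src)
        self._dst = np.array(dst)
        self._V = np.array(Vs)
        self._K = np.array(Ks)
        self._input_mask = np.array(is_input)

    @property
    def n_equations(self) -> int:
        return len(self.states)

    @property
    def n_parameters(self) -> int:
        """Number of generator constants (V and K of every transition class)."""
        return 2 * len(self.rate_params)

    def rhs(self, x: np.ndarray, V_input: float | None = None) -> np.ndarray:
        V = self._V
        if V_input is not None:
            V = np.where(self._input_mask, V_input, V)
        flux = V * x[self._src] / (self._K + x[self._src])
        dx = np.zeros_like(x)
        np.subtract.at(dx, self._src, flux)
        np.add.at(dx, self._dst, flux)
        return dx

    def initial_state(self) -> np.ndarray:
        """Unit concentration, all in the unphosphorylated microstate."""
        x = np.zeros(self.n_equations)
        x[self.index[(0,) * self.n_sites]] = 1.0
        return x

    def total_phosphorylation(self, x: np.ndarray) -> float | np.ndarray:
        """Expected number of occupied sites: sum_states occupancy * conc."""
        return x @ self.occupancy

    def observable(self, V_signal, times) -> np.ndarray:
        """Noiseless total phosphorylation time course from the naive state."""
        times = np.asarray(times, float)
        signal = (
            V_signal
            if isinstance(V_signal, InputSignal)
            else InputSignal.constant([float(V_signal)])
        )
        bounds = [0.0] + [float(t) for t in signal.times if 0 < t < times[-1]]
        bounds.append(float(times[-1]))
        out = np.full(len(times), np.nan)
        state = self.initial_state()
        if times[0] == 0.0:
            out[0] = self.total_phosphorylation(state)
        for s in range(len(bounds) - 1):
            a, b = bounds[s], bounds[s + 1]
            if a == b:
                continue
            V_in = float(signal.at(a)[0])
            mask = (times > a) & (times <= b)
            teval = np.concatenate([[a], times[mask]])
            if teval[-1] < b:
                teval = np.concatenate([teval, [b]])
            sol = odeint(
                lambda x, t: self.rhs(x, V_in), state, teval,
                rtol=1e-9, atol=1e-11, mxstep=20000,
            )
            out[mask] = sol[1:1 + int(mask.sum())] @ self.occupancy
            state = sol[-1]
        return out


def build_phospho_network(n_sites: int, rate_params: dict | None = None) -> PhosphoNetwork:
    """Build the 2^n-microstate Michaelis-Menten network of an n-site chain."""
    if n_sites < 1:
        raise ValueError("need at least one site")
    if rate_params is None:
        rate_params = draw_phospho_rates(n_sites)
    return PhosphoNetwork(n_sites, rate_params)


def generate_phospho_data(config: BenchmarkConfig):
    """Noisy total-phosphorylation time courses across input levels V.

    Each condition fixes the input V (log-uniform in its range) and records
    total phosphorylation, starting from the unphosphorylated state, at
    ``records_per_condition`` random times; 10%-scale multiplicative noise.
    Returns (TimeSeriesSet, network) where the network is the truth oracle.
    """
    rng = np.random.default_rng(config.seed)
    network = build_phospho_network(
        5, draw_phospho_rates(5, config.extra.get("rate_seed", 42))
    )
    v_lo, v_hi = config.extra.get("v_range", (0.1, 10.0))
    dyn_range = float(network.n_sites)
    conditions = []
    for c in range(config.n_conditions):
        V = float(np.exp(rng.uniform(np.log(v_lo), np.log(v_hi))))
        t_obs = np.sort(rng.uniform(0.0, config.t_max, config.records_per_condition))
        truth = network.observable(V, t_obs)
        records = []
        for t, y in zip(t_obs, truth):
            value, sigma = _noisy(rng, float(y), config.noise_frac, dyn_range)
            records.append(Record(float(t), "total_phos", value, sigma))
        conditions.append(
            Condition(
                id=f"V_{c}",
                inputs=np.array([V]),
                observed_x0=np.array([0.0]),
                records=records,
            )
        )
    return TimeSeriesSet(["total_phos"], conditions), network


def simple_phospho_model(params):
    """Hand-built 5-parameter phenomenological model of total phosphorylation.

    ``x(t; V) = A * xi((V0 - V) / w) * (1 - exp(-t / tau)) + c`` --
    exponential saturation in time with an asymptote depending sigmoidally
    on the input V.  Returns a callable f(t, V).
    """
    A, V0, w, tau, c = (float(p) for p in params)

    def f(t, V):
        t = np.asarray(t, float)
        sat = 1.0 / (1.0 + np.exp(np.clip((V0 - V) / w, -700, 700)))
        return A * sat * (1.0 - np.exp(-t / tau)) + c

    return f


# ---------------------------------------------------------------------------
# Yeast glycolysis
# ---------------------------------------------------------------------------

class GlycolysisModel:
    """The 7-species yeast glycolysis oscillator (truth model).

    Equations and the 16 parameters are in
    :mod:`phenodyn.glycolysis_constants`; sustains limit-cycle oscillations
    with a period near one minute.
    """

    def __init__(self, params: dict | None = None):
        self.params = dict(params or glyco.PARAMETERS)
        self.species = list(glyco.SPECIES)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_parameters(self) -> int:
        return len(self.params)

    def rhs(self, S: np.ndarray) -> np.ndarray:
        p = self.params
        S1, S2, S3, S4, S5, S6, S7 = S
        v1 = p["k1"] * S1 * S6 / (1.0 + (S6 / p["K1"]) ** p["q"])
        v2 = p["k2"] * S2 * (p["N"] - S5)
        v3 = p["k3"] * S3 * (p["A"] - S6)
        v4 = p["k4"] * S4 * S5
        v6 = p["k6"] * S2 * S5
        J_mem = p["kappa"] * (S4 - S7)
        return np.array([
            p["J0"] - v1,
            p["s_upper"] * v1 - v2 - v6,
            v2 - v3,
            v3 - v4 - J_mem,
            v2 - v4 - v6,
            -p["s_upper"] * v1 + p["s_lower"] * v3 - p["k5"] * S6,
            p["psi"] * J_mem - p["k"] * S7,
        ])

    def trajectory(self, S0, times) -> np.ndarray:
        """Integrate the truth model; rows are times, columns species."""
        times = np.asarray(times, float)
        teval = times if times[0] == 0.0 else np.concatenate([[0.0], times])
        sol = odeint(
            lambda S, t: self.rhs(S), np.asarray(S0, float), teval,
            rtol=1e-8, atol=1e-10,
        )
        return sol[-len(times):]

    def oscillation_period(self, t_run: float = 20.0) -> float:
        """Mean peak-to-peak period of S1 after discarding the transient."""
        t = np.linspace(0.0, t_run, int(t_run * 1000))
        sol = self.trajectory(glyco.REFERENCE_STATE, t)
        half = t > t_run / 2
        peaks, _ = find_peaks(sol[half, 0])
        if len(peaks) < 2:
            raise RuntimeError("no sustained oscillations found")
        return float(np.mean(np.diff(t[half][peaks])))

    def limit_cycle_ranges(self) -> np.ndarray:
        """Per-species [min, max] over the limit cycle (shape (7, 2))."""
        return _limit_cycle_ranges_cached()


@lru_cache(maxsize=1)
def _limit_cycle_ranges_cached() -> np.ndarray:
    model = GlycolysisModel()
    t = np.linspace(0.0, 20.0, 8000)
    sol = model.trajectory(glyco.REFERENCE_STATE, t)
    post = sol[t > 10.0]
    return np.stack([post.min(axis=0), post.max(axis=0)], axis=1)


def build_glycolysis_model() -> GlycolysisModel:
    """The ground-truth 7-species yeast glycolysis oscillator."""
    return GlycolysisModel()


#: the three species measured in the glycolysis protocol
GLYCOLYSIS_OBSERVED = ("S1", "S2", "S3")


def glycolysis_sampling_ranges(range_scale: float = 1.0) -> np.ndarray:
    """Initial-condition sampling ranges, (7, 2).

    Centred on the limit cycle with half-width equal to the cycle's
    amplitude times ``range_scale``, clipped to non-negative concentrations.
    """
    base = _limit_cycle_ranges_cached()
    mid = base.mean(axis=1)
    half = (base[:, 1] - base[:, 0]) / 2.0 * range_scale
    lo = np.clip(mid - half, 1e-4, None)
    return np.stack([lo, mid + half], axis=1)


def generate_glycolysis_data(config: BenchmarkConfig):
    """Noisy single-time measurements of 3 of the 7 glycolytic species.

    Per condition all 7 initial concentrations are drawn uniformly from the
    sampling ranges (scaled by ``config.range_scale``); the three observed
    species are recorded at one uniform random time in [0, t_max] minutes.
    Returns (TimeSeriesSet, model) where the model is the truth oracle.
    """
    rng = np.random.default_rng(config.seed)
    model = build_glycolysis_model()
    ranges = glycolysis_sampling_ranges(config.range_scale)
    obs_idx = [model.species.index(s) for s in GLYCOLYSIS_OBSERVED]
    dyn_range = float(np.max(ranges[obs_idx, 1] - ranges[obs_idx, 0]))
    conditions = []
    full_ics = {}
    for c in range(config.n_conditions):
        S0 = rng.uniform(ranges[:, 0], ranges[:, 1])
        full_ics[f"ic_{c}"] = S0.copy()
        t_obs = rng.uniform(0.0, config.t_max)
        truth = model.trajectory(S0, [t_obs])[0]
        records = []
        for name, j in zip(GLYCOLYSIS_OBSERVED, obs_idx):
            value, sigma = _noisy(rng, float(truth[j]), config.noise_frac, dyn_range)
            records.append(Record(t_obs, name, value, sigma))
        conditions.append(
            Condition(
                id=f"ic_{c}",
                inputs=np.zeros(0),
                observed_x0=S0[obs_idx].copy(),
                records=records,
            )
        )
    data = TimeSeriesSet(list(GLYCOLYSIS_OBSERVED), conditions)
    # truth ICs (incl. hidden species), keyed by condition id, for evaluation
    data.full_initial_conditions = full_ics
    return data, model
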