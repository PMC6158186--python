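"""Two-step vesicle pool model over independent docking sites.

Each active zone has ``n_docking_sites`` (default 4) independent sites; a
site consists of a replacement site (RS, occupancy rho) feeding a docking
site (DS, occupancy delta). Vesicles flow

    recycling pool  --S_f-->  RS  --R_f-->  DS  --P_r-->  fused
                    <--S_b--      <--R_b--

R_f and S_f are Michaelis-Menten functions of the global [Ca2+] (docking
and supply are Ca2+-dependent); the fusion hazard P_r comes from the
allosteric sensor driven by the local (40 nm contour) [Ca2+]. R_b and S_b
are calibrated so that the resting occupancies equal (delta0, rho0) at
50 nM Ca2+. Dual occupancy (RS and DS simultaneously occupied) is allowed;
R_b returns a docked vesicle to its own RS and requires that RS to be
empty; the recycling pool is infinite.

The per-site state space at rest is the path 00 - 10 - 01 - 11 (RS,DS
occupancy bits), a birth-death chain, which gives the calibration a closed
form checked against a generator eigen-solve in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calcium3d import CalciumTransient
from .sensor import (
    AllostericParams,
    FatigueSchedule,
    hazard_family,
    propagate_sensor,
)

__all__ = [
    "TwoStepParams",
    "DeterministicResult",
    "MonteCarloResult",
    "michaelis_rate",
    "calibrate_backward_rates",
    "stationary_distribution",
    "integrate_deterministic",
    "simulate_monte_carlo",
    "paired_pulse_scan",
    "classify_origin",
    "ORIGIN_LABELS",
]

ORIGIN_LABELS = np.array(["docked", "replacement", "recycling"])
_DOCKED, _REPLACEMENT, _RECYCLING = 0, 1, 2


def michaelis_rate(ca_uM: float | np.ndarray, vmax_per_s: float, kd_uM: float):
    """Michaelis-Menten rate vmax*ca/(ca+kd), in s^-1."""
    ca = np.asarray(ca_uM, dtype=float)
    if np.any(ca < 0) or vmax_per_s < 0 or kd_uM < 0:
        raise ValueError("negative input to michaelis_rate")
    out = vmax_per_s * ca / (ca + kd_uM)
    return float(out) if np.isscalar(ca_uM) else out


@dataclass(frozen=True)
class TwoStepParams:
    """Parameters of the two-step pool model (rates in s^-1, Kd in uM)."""

    n_docking_sites: int = 4
    delta0: float = 0.3
    rho0: float = 0.9
    rf_vmax: float = 800.0
    rf_kd: float = 2.0
    sf_vmax: float = 60.0
    sf_kd: float = 2.0
    rb: float | None = None  # calibrated if None
    sb: float | None = None
    resting_ca_uM: float = 0.05
    dt_ms: float = 0.01
    n_trials: int = 5000

    def __post_init__(self) -> None:
        if not (0 < self.delta0 < 1 and 0 < self.rho0 < 1):
            raise ValueError("resting occupancies must lie strictly in (0, 1)")
        if self.n_docking_sites < 1:
            raise ValueError("need at least one docking site")

    def with_calibrated_backward_rates(self) -> "TwoStepParams":
        rb, sb = calibrate_backward_rates(self)
        return replace(self, rb=rb, sb=sb)


def calibrate_backward_rates(params: TwoStepParams) -> tuple[float, float]:
    """Backward rates (R_b, S_b) in s^-1 giving the resting occupancies.

    At rest the chain 00-10-01-11 satisfies detailed balance with
    a = S_f/S_b and r = R_f/R_b, so rho = a/(1+a) and delta = ar/(1+ar);
    inverting gives the unique positive solution.
    """
    d, p = params.delta0, params.rho0
    if not (0 < d < 1 and 0 < p < 1):
        raise ValueError("calibration infeasible: occupancies must be in (0, 1)")
    sf0 = michaelis_rate(params.resting_ca_uM, params.sf_vmax, params.sf_kd)
    rf0 = michaelis_rate(params.resting_ca_uM, params.rf_vmax, params.rf_kd)
    a = p / (1.0 - p)
    ar = d / (1.0 - d)
    r = ar / a
    sb = sf0 / a
    rb = rf0 / r
    # round-trip check against the solved chain
    pi = stationary_distribution(sf0, sb, rf0, rb)
    delta = pi[2] + pi[3]
    rho = pi[1] + pi[3]
    if abs(delta - d) > 1e-9 or abs(rho - p) > 1e-9:  # pragma: no cover
        raise RuntimeError("calibration round-trip failed")
    return rb, sb


def _initial_site_law(params: TwoStepParams, sf0: float, rf0: float) -> np.ndarray:
    """Initial joint (RS, DS) law: resting stationary distribution, or the
    product of the target marginals when the chain is degenerate (frozen
    pool rates, used in controlled experiments)."""
    if sf0 + params.sb <= 0 or rf0 + params.rb <= 0:
        d, r = params.delta0, params.rho0
        return np.array([(1 - r) * (1 - d), r * (1 - d), (1 - r) * d, r * d])
    return stationary_distribution(sf0, params.sb, rf0, params.rb)


def stationary_distribution(sf: float, sb: float, rf: float, rb: float) -> np.ndarray:
    """Stationary law of the resting per-site chain over (00, 10, 01, 11).

    Solved from the generator null space (no detailed-balance shortcut), so
    it can serve as an independent check of the closed-form calibration.
    """
    q = np.zeros((4, 4))
    q[0, 1] = sf  # 00 -> 10
    q[1, 0] = sb
    q[1, 2] = rf  # 10 -> 01
    q[2, 1] = rb
    q[2, 3] = sf  # 01 -> 11
    q[3, 2] = sb
    np.fill_diagonal(q, -q.sum(axis=1))
    w, v = np.linalg.eig(q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    return pi


# --------------------------------------------------------------------------
# deterministic (mean-field) integration


@dataclass
class DeterministicResult:
    time_ms: np.ndarray
    release_rate_per_ms: np.ndarray  # per AZ
    delta: np.ndarray
    rho: np.ndarray
    hazard_per_ms: np.ndarray
    cumulative_release: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        dt = np.diff(self.time_ms, prepend=self.time_ms[0])
        self.cumulative_release = np.cumsum(self.release_rate_per_ms * dt)


def integrate_deterministic(
    params: TwoStepParams,
    transients: CalciumTransient,
    sensor_params: AllostericParams | None = None,
    replenishment: bool = True,
    hazard_per_ms: np.ndarray | None = None,
) -> DeterministicResult:
    """Mean-field occupancy ODEs on the transient's time grid.

    With ``replenishment=False`` the model reduces to the two-parameter
    single-AP description (initial occupancy delta0 and the sensor hazard):
    d(delta)/dt = -h(t) * delta.
    """
    sensor_params = sensor_params or AllostericParams()
    t = transients.time_ms
    if hazard_per_ms is None:
        hazard_per_ms = propagate_sensor(t, transients.local_uM, sensor_params).hazard_per_ms
    if len(hazard_per_ms) != len(t):
        raise ValueError("mismatched time grids for hazard and transient")

    if replenishment:
        p = params.with_calibrated_backward_rates() if params.rb is None else params
        rf_ms = michaelis_rate(transients.global_uM, p.rf_vmax, p.rf_kd) * 1e-3
        sf_ms = michaelis_rate(transients.global_uM, p.sf_vmax, p.sf_kd) * 1e-3
        rb_ms = p.rb * 1e-3
        sb_ms = p.sb * 1e-3
        sf0 = michaelis_rate(p.resting_ca_uM, p.sf_vmax, p.sf_kd)
        rf0 = michaelis_rate(p.resting_ca_uM, p.rf_vmax, p.rf_kd)
        pi = _initial_site_law(p, sf0, rf0)
    else:
        p = params
        z = np.zeros_like(t)
        rf_ms, sf_ms = z, z
        rb_ms = sb_ms = 0.0
        # independent product start: P(DS)=delta0, P(RS)=rho0
        d0, r0 = p.delta0, p.rho0
        pi = np.array([(1 - r0) * (1 - d0), r0 * (1 - d0), (1 - r0) * d0, r0 * d0])

    n = len(t)
    states = np.empty((n, 4))
    states[0] = pi
    y = pi.copy()
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        h = hazard_per_ms[i]
        rf, sf = rf_ms[i] if replenishment else 0.0, sf_ms[i] if replenishment else 0.0
        max_rate = max(h, rf, sf, rb_ms, sb_ms, 1e-12)
        n_sub = max(1, int(np.ceil(max_rate * dt / 0.05)))
        hsub = dt / n_sub
        for _ in range(n_sub):
            p00, p10, p01, p11 = y
            d00 = sb_ms * p10 + h * p01 - sf * p00
            d10 = sf * p00 + rb_ms * p01 + h * p11 - (sb_ms + rf) * p10
            d01 = rf * p10 + sb_ms * p11 - (rb_ms + sf + h) * p01
            d11 = sf * p01 - (sb_ms + h) * p11
            y = y + hsub * np.array([d00, d10, d01, d11])
        states[i + 1] = y

    delta = states[:, 2] + states[:, 3]
    rho = states[:, 1] + states[:, 3]
    rate = params.n_docking_sites * hazard_per_ms * delta
    return DeterministicResult(t, rate, delta, rho, hazard_per_ms)


# --------------------------------------------------------------------------
# Monte Carlo


@dataclass
class MonteCarloResult:
    events: pd.DataFrame  # trial, site, time_ms, stim_index, latency_ms, origin
    time_ms: np.ndarray  # occupancy sampling grid
    delta: np.ndarray  # trial-averaged DS occupancy
    rho: np.ndarray
    n_trials: int
    ap_times_ms: np.ndarray


def simulate_monte_carlo(
    params: TwoStepParams,
    transients: CalciumTransient,
    sensor_params: AllostericParams | None = None,
    fatigue: FatigueSchedule | None = None,
    seed: int | np.random.SeedSequence | None = None,
    ap_times_ms: np.ndarray | None = None,
    n_trials: int | None = None,
    record_every_ms: float = 0.1,
    n_phi: int = 21,
) -> MonteCarloResult:
    """Stochastic simulation of all docking sites of many independent trials.

    Per 0.01 ms step and site, Bernoulli draws with p = 1 - exp(-rate*dt)
    are applied in the order S_b, R_f, R_b, S_f, fusion (docking before
    fusion, enabling same-step two-step release). Fatigue bookkeeping: the
    first two release events of an AZ, and any site that has never released,
    use the normal sensor parameters; afterwards a site's hazard is
    interpolated between the slow and normal hazard trajectories according
    to its time since last release.

    Origin labels are maintained online: at every AP, vesicles on a DS are
    relabelled "docked" and vesicles on an RS "replacement"; vesicles
    supplied later from the pool carry "recycling" until the next AP.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible Monte Carlo runs")
    sensor_params = sensor_params or AllostericParams()
    fatigue = fatigue or FatigueSchedule()
    rng = np.random.default_rng(seed)
    p = params.with_calibrated_backward_rates() if params.rb is None else params
    nt = int(n_trials if n_trials is not None else p.n_trials)
    if nt < 1:
        raise ValueError("n_trials must be >= 1")
    ns = p.n_docking_sites
    dt = p.dt_ms

    t = np.arange(0.0, transients.time_ms[-1] + 1e-12, dt)
    local = transients.local_interp(t)
    glob = transients.global_interp(t)
    if ap_times_ms is None:
        ap_times_ms = np.array([])
    ap_times_ms = np.asarray(ap_times_ms, dtype=float)

    phi_grid, h_grid = hazard_family(t, local, sensor_params, fatigue, n_phi=n_phi)
    h_normal = h_grid[-1]
    rf_ms = michaelis_rate(glob, p.rf_vmax, p.rf_kd) * 1e-3
    sf_ms = michaelis_rate(glob, p.sf_vmax, p.sf_kd) * 1e-3
    for name, r in (("R_f", rf_ms.max()), ("S_f", sf_ms.max()),
                    ("R_b", p.rb * 1e-3), ("S_b", p.sb * 1e-3)):
        if r * dt >= 0.1:
            raise ValueError(f"per-step transition probability too large for {name}")
    p_rf = 1.0 - np.exp(-rf_ms * dt)
    p_sf = 1.0 - np.exp(-sf_ms * dt)
    p_rb = 1.0 - np.exp(-p.rb * 1e-3 * dt)
    p_sb = 1.0 - np.exp(-p.sb * 1e-3 * dt)

    # initial joint state from the resting stationary law
    sf0 = michaelis_rate(p.resting_ca_uM, p.sf_vmax, p.sf_kd)
    rf0 = michaelis_rate(p.resting_ca_uM, p.rf_vmax, p.rf_kd)
    pi = _initial_site_law(p, sf0, rf0)
    joint = rng.choice(4, size=(nt, ns), p=pi)
    rs = (joint == 1) | (joint == 3)
    ds = (joint == 2) | (joint == 3)

    rs_label = np.full((nt, ns), _REPLACEMENT, dtype=np.int8)
    ds_label = np.full((nt, ns), _DOCKED, dtype=np.int8)
    clock = np.full((nt, ns), np.inf)
    az_count = np.zeros(nt, dtype=np.int32)
    never_released = np.ones((nt, ns), dtype=bool)

    ap_steps = set(int(round(a / dt)) for a in ap_times_ms)
    rec_every = max(1, int(round(record_every_ms / dt)))
    rec_t, rec_d, rec_r = [0.0], [float(ds.mean())], [float(rs.mean())]

    ev_trial, ev_site, ev_time, ev_origin = [], [], [], []

    n_steps = len(t) - 1
    recovery = fatigue.recovery_ms
    for s in range(n_steps):
        if s in ap_steps:  # snapshot locations just before this AP
            ds_label[ds] = _DOCKED
            rs_label[rs] = _REPLACEMENT

        u = rng.random((5, nt, ns))
        # 1) S_b: RS vesicle returns to the pool
        fire = rs & (u[0] < p_sb)
        rs[fire] = False
        # 2) R_f: docking RS -> DS (empty DS), carries the vesicle label
        fire = rs & ~ds & (u[1] < p_rf[s])
        ds[fire] = True
        rs[fire] = False
        ds_label[fire] = rs_label[fire]
        # 3) R_b: undocking DS -> RS, requires empty RS
        fire = ds & ~rs & (u[2] < p_rb)
        ds[fire] = False
        rs[fire] = True
        rs_label[fire] = ds_label[fire]
        # 4) S_f: pool supplies an empty RS
        fire = ~rs & (u[3] < p_sf[s])
        rs[fire] = True
        rs_label[fire] = _RECYCLING
        # 5) fusion, with per-site (possibly fatigued) hazard
        exempt = never_released | (az_count < fatigue.exempt_events_per_az)[:, None]
        phi = np.minimum(clock / recovery, 1.0)
        h = np.where(
            exempt, h_normal[s],
            np.interp(np.where(np.isfinite(phi), phi, 1.0).ravel(),
                      phi_grid, h_grid[:, s]).reshape(nt, ns),
        )
        fire = ds & (u[4] < 1.0 - np.exp(-h * dt))
        if fire.any():
            tr_i, si_i = np.nonzero(fire)
            ev_trial.append(tr_i)
            ev_site.append(si_i)
            ev_time.append(np.full(len(tr_i), t[s + 1]))
            ev_origin.append(ds_label[fire].copy())
            ds[fire] = False
            clock[fire] = 0.0
            never_released[fire] = False
            np.add.at(az_count, tr_i, 1)

        clock += dt
        if (s + 1) % rec_every == 0:
            rec_t.append(t[s + 1])
            rec_d.append(float(ds.mean()))
            rec_r.append(float(rs.mean()))

    if ev_trial:
        trial = np.concatenate(ev_trial)
        site = np.concatenate(ev_site)
        time = np.concatenate(ev_time)
        origin = np.concatenate(ev_origin)
    else:
        trial = site = origin = np.array([], dtype=int)
        time = np.array([], dtype=float)

    if len(ap_times_ms):
        stim = np.searchsorted(ap_times_ms, time + 1e-9) - 1
        latency = np.where(stim >= 0, time - ap_times_ms[np.clip(stim, 0, None)], np.nan)
    else:
        stim = np.full(len(time), -1)
        latency = np.full(len(time), np.nan)

    events = pd.DataFrame(
        {
            "trial": trial.astype(int),
            "site": site.astype(int),
            "time_ms": time,
            "stim_index": stim.astype(int) + 1,  # 1-based stimulus number
            "latency_ms": latency,
            "origin": ORIGIN_LABELS[origin.astype(int)] if len(time) else [],
        }
    ).sort_values(["trial", "time_ms"], kind="stable").reset_index(drop=True)

    return MonteCarloResult(
        events, np.array(rec_t), np.array(rec_d), np.array(rec_r), nt, ap_times_ms
    )


def classify_origin(events: pd.DataFrame, ap_times_ms: np.ndarray) -> pd.Series:
    """Origin labels of a release event table.

    The label is the vesicle's compartment immediately before the most
    recent AP preceding its release; it is tracked online by
    ``simulate_monte_carlo`` and validated/extracted here. Raises for
    events occurring before the first AP.
    """
    ap_times_ms = np.asarray(ap_times_ms, dtype=float)
    if len(ap_times_ms) and (events["time_ms"] < ap_times_ms[0]).any():
        raise ValueError("event before the first AP has no defined origin")
    if "origin" not in events:
        raise ValueError("event table carries no origin tracking information")
    return events["origin"]


def paired_pulse_scan(
    params: TwoStepParams,
    make_transient,
    intervals_ms: tuple[float, ...] = (3.0, 5.0, 10.0, 20.0, 40.0, 80.0),
    sensor_params: AllostericParams | None = None,
    fatigue: FatigueSchedule | None = None,
    seed: int = 0,
    n_trials: int | None = None,
    window_ms: float = 5.0,
) -> pd.DataFrame:
    """Paired-pulse ratios and count covariance over a grid of intervals.

    ``make_transient(interval_ms) -> (CalciumTransient, ap_times)`` supplies
    the Ca2+ input for each interval (usually the template-superposition
    train mode). Counting windows are 5 ms, except 3 ms windows for the
    3 ms interval.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for interval, child in zip(intervals_ms, ss.spawn(len(intervals_ms))):
        # 5 ms windows, except the special 3 ms windows at the 3 ms interval
        win = 3.0 if interval == 3.0 else window_ms
        if interval < win:
            raise ValueError(f"interval {interval} shorter than counting window")
        tr, ap_times = make_transient(interval)
        res = simulate_monte_carlo(
            params, tr, sensor_params, fatigue, seed=child,
            ap_times_ms=ap_times, n_trials=n_trials,
        )
        ev = res.events
        s_counts = np.zeros((res.n_trials, 2))
        for k, t_ap in enumerate(ap_times[:2]):
            sel = ev[(ev.time_ms > t_ap) & (ev.time_ms <= t_ap + win)]
            np.add.at(s_counts[:, k], sel.trial.to_numpy(), 1)
        s1 = s_counts[:, 0].mean()
        s2 = s_counts[:, 1].mean()
        cov = float(np.cov(s_counts[:, 0], s_counts[:, 1], ddof=1)[0, 1])
        rows.append(
            {"interval_ms": interval, "s1": s1, "s2": s2,
             "ppr": s2 / s1 if s1 > 0 else np.nan, "covariance": cov,
             "window_ms": win}
        )
    return pd.DataFrame(rows)
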