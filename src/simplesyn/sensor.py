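"""Allosteric Ca2+-sensor model of vesicle fusion.

The sensor binds up to five Ca2+ ions (states V0..V5). Binding from state
Vn proceeds at (5-n)*k_on*[Ca]; unbinding at n*k_off*b**(n-1), where b < 1
expresses positive cooperativity (successive ions dissociate more slowly).
Every state can fuse, at a rate that grows geometrically with occupancy:
fusion from Vn occurs at l_plus * f**n, with l_plus = gamma / f**5 so that
the fully occupied state fuses at gamma. The hazard h(t) produced here is
the fusion rate of a docked vesicle conditioned on not having fused yet;
it is the per-occupied-docking-site release rate that drives the two-step
pool model.

Activity-dependent "fatigue" (slow release) is expressed as a reduction of
k_on by 10x and of k_off by 2.5x immediately after a docking site has
released, with linear recovery of both parameters over a recovery time
(40 ms in control, 1 s under latrunculin B).

Units: time in ms, [Ca2+] in uM; rate constants are stored in the
conventional M^-1 s^-1 / s^-1 units and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AllostericParams",
    "FatigueSchedule",
    "SensorTrajectory",
    "equilibrium_occupancy",
    "propagate_sensor",
    "fatigued_params",
    "hazard_family",
    "generator_matrix",
]

N_SITES = 5

# unit conversions: k_on [M^-1 s^-1] * Ca [uM] -> per ms
_KON_TO_PER_MS = 1e-6 * 1e-3  # uM -> M, s^-1 -> ms^-1
_PER_S_TO_PER_MS = 1e-3


@dataclass(frozen=True)
class AllostericParams:
    """Rate constants of the five-site allosteric fusion sensor.

    Attributes
    ----------
    k_on : float
        Ca2+ association rate constant per free site, M^-1 s^-1.
    k_off : float
        Dissociation rate constant per bound ion, s^-1.
    b : float
        Cooperativity factor (<= 1) applied to unbinding as b**(n-1).
    f : float
        Fold increase of the fusion rate per bound Ca2+.
    gamma : float
        Fusion rate of the fully (5 Ca) occupied state, s^-1.
    """

    k_on: float = 5e8
    k_off: float = 5000.0
    b: float = 0.75
    f: float = 31.3
    gamma: float = 2100.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "b", "f", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.b > 1:
            raise ValueError("cooperativity factor b must be <= 1")

    @property
    def l_plus(self) -> float:
        """Spontaneous fusion rate of the empty sensor, s^-1 (gamma / f^5)."""
        return self.gamma / self.f**N_SITES

    def fusion_rates_per_ms(self) -> np.ndarray:
        """Fusion rate from V0..V5 in ms^-1."""
        n = np.arange(N_SITES + 1)
        return self.l_plus * self.f**n * _PER_S_TO_PER_MS


@dataclass(frozen=True)
class FatigueSchedule:
    """Linear slow-to-normal interpolation of sensor parameters after release.

    slow parameters = (k_on * slow_kon_factor, k_off * slow_koff_factor)
    apply right after a site releases; both recover linearly to the normal
    values over ``recovery_ms``. The first ``exempt_events_per_az`` release
    events of an active zone always use normal parameters (bookkeeping is
    owned by the pool model).
    """

    slow_kon_factor: float = 1.0 / 10.0
    slow_koff_factor: float = 1.0 / 2.5
    recovery_ms: float = 40.0
    exempt_events_per_az: int = 2

    def phi(self, t_since_release_ms: float | np.ndarray) -> float | np.ndarray:
        """Recovery fraction: 0 right after release, 1 at/after full recovery."""
        return np.clip(np.asarray(t_since_release_ms, dtype=float) / self.recovery_ms, 0.0, 1.0)


LATB_FATIGUE = FatigueSchedule(recovery_ms=1000.0)


def fatigued_params(
    base: AllostericParams, schedule: FatigueSchedule, t_since_release_ms: float
) -> AllostericParams:
    """Sensor parameters of a docking site ``t_since_release_ms`` after fusion.

    At t = 0 the slow parameters apply; at t >= recovery the normal ones;
    in between k_on and k_off are interpolated linearly in time. b, f and
    gamma are unaffected by fatigue.
    """
    if t_since_release_ms < 0:
        raise ValueError("t_since_release_ms must be >= 0")
    phi = float(schedule.phi(t_since_release_ms))
    return interpolated_params(base, schedule, phi)


def interpolated_params(
    base: AllostericParams, schedule: FatigueSchedule, phi: float
) -> AllostericParams:
    """Parameters at recovery fraction ``phi`` (0 = slow, 1 = normal)."""
    slow_kon = base.k_on * schedule.slow_kon_factor
    slow_koff = base.k_off * schedule.slow_koff_factor
    return replace(
        base,
        k_on=slow_kon + phi * (base.k_on - slow_kon),
        k_off=slow_koff + phi * (base.k_off - slow_koff),
    )


def generator_matrix(ca_uM: float, params: AllostericParams) -> np.ndarray:
    """CTMC generator over (V0..V5, fused), rates in ms^-1.

    Row-stochastic convention: dP/dt = P @ Q for a row vector P.
    """
    if ca_uM < 0:
        raise ValueError("negative Ca concentration")
    q = np.zeros((N_SITES + 2, N_SITES + 2))
    kon_ms = params.k_on * ca_uM * _KON_TO_PER_MS
    koff_ms = params.k_off * _PER_S_TO_PER_MS
    fus = params.fusion_rates_per_ms()
    for n in range(N_SITES + 1):
        if n < N_SITES:
            q[n, n + 1] = (N_SITES - n) * kon_ms
        if n > 0:
            q[n, n - 1] = n * koff_ms * params.b ** (n - 1)
        q[n, N_SITES + 1] = fus[n]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def equilibrium_occupancy(ca_uM: float, params: AllostericParams) -> np.ndarray:
    """Stationary occupancy of the binding chain (fusion ignored).

    Detailed balance of the pure binding/unbinding chain gives
    pi_{n+1}/pi_n = (5-n) k_on Ca / ((n+1) k_off b^n).
    """
    if ca_uM < 0:
        raise ValueError("negative Ca concentration")
    w = np.ones(N_SITES + 1)
    for n in range(N_SITES):
        ratio = ((N_SITES - n) * params.k_on * ca_uM * 1e-6) / (
            (n + 1) * params.k_off * params.b**n
        )
        w[n + 1] = w[n] * ratio
    return w / w.sum()


@dataclass
class SensorTrajectory:
    """Time course of sensor occupancies driven by a Ca2+ transient."""

    time_ms: np.ndarray
    occupancies: np.ndarray  # (T, 7): V0..V5 and fused
    hazard_per_ms: np.ndarray  # fusion rate conditioned on survival
    survival: np.ndarray  # P(not fused by t)
    cumulative_release: np.ndarray = field(init=False)  # P(fused by t)

    def __post_init__(self) -> None:
        self.cumulative_release = 1.0 - self.survival


def _hazard_from_state(p: np.ndarray, fus_per_ms: np.ndarray) -> np.ndarray:
    """Fusion hazard of the not-yet-fused population, ms^-1."""
    alive = p[..., : N_SITES + 1]
    surv = alive.sum(axis=-1)
    flux = alive @ fus_per_ms
    return np.where(surv > 1e-300, flux / np.maximum(surv, 1e-300), fus_per_ms[-1])


def propagate_sensor(
    time_ms: np.ndarray,
    ca_uM: np.ndarray,
    params: AllostericParams,
    max_substep_rate: float = 0.05,
    initial_state: np.ndarray | None = None,
) -> SensorTrajectory:
    """Integrate the sensor master equation along a Ca2+ transient.

    [Ca2+] is treated as piecewise-constant on the input grid; each interval
    is integrated by forward-Euler substeps small enough that the largest
    transition probability per substep stays below ``max_substep_rate``.
    The initial state defaults to the binding-chain equilibrium at the
    first Ca2+ sample (no fused fraction).
    """
    time_ms = np.asarray(time_ms, dtype=float)
    ca_uM = np.asarray(ca_uM, dtype=float)
    if time_ms.shape != ca_uM.shape:
        raise ValueError("time and Ca arrays must have equal shape")
    if np.any(ca_uM < 0):
        raise ValueError("negative Ca in transient")
    n_t = time_ms.size
    p = np.zeros(N_SITES + 2)
    if initial_state is None:
        p[: N_SITES + 1] = equilibrium_occupancy(ca_uM[0], params)
    else:
        initial_state = np.asarray(initial_state, dtype=float)
        if initial_state.size not in (N_SITES + 1, N_SITES + 2):
            raise ValueError("initial state must have 6 or 7 entries")
        if abs(initial_state.sum() - 1.0) > 1e-8:
            raise ValueError("initial state must be normalized")
        p[: initial_state.size] = initial_state

    fus = params.fusion_rates_per_ms()
    occ = np.empty((n_t, N_SITES + 2))
    occ[0] = p
    for i in range(n_t - 1):
        dt = time_ms[i + 1] - time_ms[i]
        q = generator_matrix(ca_uM[i], params)
        max_rate = float(np.max(-np.diag(q)))
        n_sub = max(1, int(np.ceil(max_rate * dt / max_substep_rate)))
        h = dt / n_sub
        m = np.eye(N_SITES + 2) + h * q
        for _ in range(n_sub):
            p = p @ m
        occ[i + 1] = p
    surv = occ[:, : N_SITES + 1].sum(axis=1)
    hazard = _hazard_from_state(occ, fus)
    return SensorTrajectory(time_ms, occ, hazard, surv)


def hazard_family(
    time_ms: np.ndarray,
    ca_uM: np.ndarray,
    params: AllostericParams,
    schedule: FatigueSchedule,
    n_phi: int = 21,
) -> tuple[np.ndarray, np.ndarray]:
    """Fusion-hazard trajectories for a grid of fatigue recovery fractions.

    Returns (phi_grid, hazards) with hazards of shape (n_phi, T) in ms^-1.
    Each trajectory propagates the sensor with parameters interpolated at a
    fixed phi, the quasi-static treatment appropriate because fatigue
    recovery (>= 40 ms) is slow compared with sensor equilibration (<1 ms).
    """
    phi_grid = np.linspace(0.0, 1.0, n_phi)
    hazards = np.empty((n_phi, len(time_ms)))
    for i, phi in enumerate(phi_grid):
        pars = interpolated_params(params, schedule, float(phi))
        hazards[i] = propagate_sensor(time_ms, ca_uM, pars).hazard_per_ms
    return phi_grid, hazards
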