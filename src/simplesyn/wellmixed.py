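"""Single-compartment (well-mixed) bouton Ca2+ mass balance.

Used for the slowly varying global [Ca2+] during AP trains: total influx is
distributed over the bouton volume, buffered by the same buffer set as the
3D model, and extruded by the same linear surface pump integrated over the
box surface. Solved as a stiff ODE (LSODA) rather than on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .calcium3d import AVOGADRO, BufferSpec, InfluxSpec, influx_timecourse

__all__ = ["WellMixedConfig", "WellMixedResult", "run_well_mixed"]


@dataclass(frozen=True)
class WellMixedConfig:
    box_um: tuple[float, float, float] = (0.9, 0.5, 0.5)
    resting_ca_uM: float = 0.05
    extrusion_p_um_per_ms: float = 0.15


@dataclass
class WellMixedResult:
    time_ms: np.ndarray
    global_uM: np.ndarray


def run_well_mixed(
    cfg: WellMixedConfig,
    buffers: list[BufferSpec],
    influx: InfluxSpec,
    n_channels: int,
    t_end_ms: float,
    dt_ms: float = 0.01,
) -> WellMixedResult:
    """Integrate the compartment model and sample it every ``dt_ms``."""
    lx, ly, lz = cfg.box_um
    vol_um3 = lx * ly * lz
    vol_l = vol_um3 * 1e-15
    area_um2 = 2.0 * (lx * ly + lx * lz + ly * lz)
    ions_to_uM = 1.0 / (AVOGADRO * vol_l) * 1e6

    simple = [b for b in buffers if b.scheme == "simple"]
    coop = [b for b in buffers if b.scheme == "cooperative2"]
    if len(coop) > 1:
        raise ValueError("at most one cooperative buffer is supported")
    cs = coop[0] if coop else None

    ca0 = cfg.resting_ca_uM
    y0 = [ca0]
    for b in simple:
        y0.append(b.total_uM * ca0 / (ca0 + b.K_D_uM))
    if cs is not None:
        r1 = cs.k_on * 1e-6 * ca0 / cs.k_off
        r2 = cs.k_on2 * 1e-6 * ca0 / cs.k_off2
        c0 = cs.total_uM / (1.0 + r1 + r1 * r2)
        y0 += [c0 * r1, c0 * r1 * r2]

    pump_per_ms = cfg.extrusion_p_um_per_ms * area_um2 / vol_um3  # ms^-1

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        ca = y[0]
        dy = np.zeros_like(y)
        idx = 1
        for b in simple:
            bound = y[idx]
            rate = b.k_on * 1e-9 * ca * (b.total_uM - bound) - b.k_off * 1e-3 * bound
            dy[idx] = rate
            dy[0] -= rate
            idx += 1
        if cs is not None:
            c1, c2 = y[idx], y[idx + 1]
            c0 = cs.total_uM - c1 - c2
            r1 = cs.k_on * 1e-9 * ca * c0 - cs.k_off * 1e-3 * c1
            r2 = cs.k_on2 * 1e-9 * ca * c1 - cs.k_off2 * 1e-3 * c2
            dy[idx] = r1 - r2
            dy[idx + 1] = r2
            dy[0] -= r1 + r2
        dy[0] += influx_timecourse(influx, t) * n_channels * ions_to_uM
        dy[0] -= pump_per_ms * (ca - cfg.resting_ca_uM)
        return dy

    t_eval = np.arange(0.0, t_end_ms + 1e-12, dt_ms)
    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), np.array(y0), method="LSODA",
        t_eval=t_eval, rtol=1e-7, atol=1e-10, max_step=0.05,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"well-mixed integration failed: {sol.message}")
    return WellMixedResult(sol.t, sol.y[0])
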