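"""Fused-loop explicit-Euler kernel for the 3D reaction-diffusion model.

Numerically identical (up to float rounding) to the numpy reference path in
``calcium3d.step_diffusion_reaction``; the two are cross-checked in the test
suite. One kernel call advances every species by one time step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .geometry import AZGeometry


@njit(cache=True, fastmath=False)
def _step_kernel(
    ca, ca_new, bound, bound_new, coop1, coop2, coop1_new, coop2_new,
    alpha_ca, alpha_b, alpha_coop,
    kon_ms, koff_ms, btot,
    has_coop, ckon1_ms, ckoff1_ms, ckon2_ms, ckoff2_ms, ctot,
    pump_k, rest, dt_ms,
):
    nx, ny, nz = ca.shape
    nb = bound.shape[0]
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            for k in range(nz):
                km = k - 1 if k > 0 else 0
                kp = k + 1 if k < nz - 1 else nz - 1
                c = ca[i, j, k]

                lap = (
                    ca[im, j, k] + ca[ip, j, k] + ca[i, jm, k] + ca[i, jp, k]
                    + ca[i, j, km] + ca[i, j, kp] - 6.0 * c
                )
                dca = alpha_ca * lap

                # simple buffers
                for b in range(nb):
                    bb = bound[b, i, j, k]
                    if alpha_b[b] > 0.0:
                        lapb = (
                            bound[b, im, j, k] + bound[b, ip, j, k]
                            + bound[b, i, jm, k] + bound[b, i, jp, k]
                            + bound[b, i, j, km] + bound[b, i, j, kp] - 6.0 * bb
                        )
                        db = alpha_b[b] * lapb
                    else:
                        db = 0.0
                    rate = kon_ms[b] * c * (btot[b] - bb) - koff_ms[b] * bb
                    bound_new[b, i, j, k] = bb + db + dt_ms * rate
                    dca -= dt_ms * rate

                # cooperative two-site buffer
                if has_coop:
                    c1 = coop1[i, j, k]
                    c2 = coop2[i, j, k]
                    if alpha_coop > 0.0:
                        lap1 = (
                            coop1[im, j, k] + coop1[ip, j, k] + coop1[i, jm, k]
                            + coop1[i, jp, k] + coop1[i, j, km] + coop1[i, j, kp]
                            - 6.0 * c1
                        )
                        lap2 = (
                            coop2[im, j, k] + coop2[ip, j, k] + coop2[i, jm, k]
                            + coop2[i, jp, k] + coop2[i, j, km] + coop2[i, j, kp]
                            - 6.0 * c2
                        )
                        d1 = alpha_coop * lap1
                        d2 = alpha_coop * lap2
                    else:
                        d1 = 0.0
                        d2 = 0.0
                    c0 = ctot - c1 - c2
                    r1 = ckon1_ms * c * c0 - ckoff1_ms * c1
                    r2 = ckon2_ms * c * c1 - ckoff2_ms * c2
                    coop1_new[i, j, k] = c1 + d1 + dt_ms * (r1 - r2)
                    coop2_new[i, j, k] = c2 + d2 + dt_ms * r2
                    dca -= dt_ms * (r1 + r2)

                # surface pump on every box face the voxel touches
                if pump_k > 0.0:
                    faces = 0.0
                    if i == 0:
                        faces += 1.0
                    if i == nx - 1:
                        faces += 1.0
                    if j == 0:
                        faces += 1.0
                    if j == ny - 1:
                        faces += 1.0
                    if k == 0:
                        faces += 1.0
                    if k == nz - 1:
                        faces += 1.0
                    if faces > 0.0:
                        dca -= pump_k * faces * (c - rest)

                ca_new[i, j, k] = c + dca


class StepRunner:
    """Double-buffered driver around the fused kernel."""

    def __init__(self, state, geometry: AZGeometry, cfg) -> None:
        self.state = state
        self.geometry = geometry
        self.cfg = cfg
        self.dt_ms = cfg.dt_us * 1e-3
        dx_um = geometry.voxel_nm * 1e-3

        specs = state.simple_specs
        self._alpha_ca = cfg.d_ca_um2_s * 1e-3 * self.dt_ms / dx_um**2
        self._alpha_b = np.array([b.D_um2_s * 1e-3 * self.dt_ms / dx_um**2 for b in specs])
        self._kon = np.array([b.k_on * 1e-9 for b in specs])
        self._koff = np.array([b.k_off * 1e-3 for b in specs])
        self._btot = np.array([b.total_uM for b in specs])

        cs = state.coop_spec
        self._has_coop = cs is not None
        if cs is not None:
            self._alpha_coop = cs.D_um2_s * 1e-3 * self.dt_ms / dx_um**2
            self._ck = (cs.k_on * 1e-9, cs.k_off * 1e-3, cs.k_on2 * 1e-9, cs.k_off2 * 1e-3)
            self._ctot = cs.total_uM
        else:
            self._alpha_coop = 0.0
            self._ck = (0.0, 0.0, 0.0, 0.0)
            self._ctot = 0.0
            state.coop1 = np.zeros((1, 1, 1))
            state.coop2 = np.zeros((1, 1, 1))

        self._pump_k = (
            cfg.extrusion_p_um_per_ms / dx_um * self.dt_ms
            if cfg.extrusion_on and cfg.extrusion_p_um_per_ms > 0
            else 0.0
        )

        s = state
        self._a = (s.ca, s.bound, s.coop1, s.coop2)
        self._b = (s.ca.copy(), s.bound.copy(),
                   s.coop1.copy(), s.coop2.copy())
        self._cv = geometry.channel_voxels

    def step(self, influx_uM_per_channel: float) -> None:
        ca, bound, c1, c2 = self._a
        ca_n, bound_n, c1_n, c2_n = self._b
        _step_kernel(
            ca, ca_n, bound, bound_n, c1, c2, c1_n, c2_n,
            self._alpha_ca, self._alpha_b, self._alpha_coop,
            self._kon, self._koff, self._btot,
            self._has_coop, *self._ck, self._ctot,
            self._pump_k, self.cfg.resting_ca_uM, self.dt_ms,
        )
        if influx_uM_per_channel > 0.0:
            for ix, iy in self._cv:
                ca_n[ix, iy, 0] += influx_uM_per_channel
        self._a, self._b = self._b, self._a
        st = self.state
        st.ca, st.bound = self._a[0], self._a[1]
        if self._has_coop:
            st.coop1, st.coop2 = self._a[2], self._a[3]
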