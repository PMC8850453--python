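"""Compiled forward-Euler integration kernel.

The kernel mirrors the scalar force laws in :mod:`roamsim.forces` (the unit
tests assert exact agreement).  Wall contributions are accumulated as
``E + W + (N + S)`` so that reflection about the x-axis — which swaps the N
and S walls — maps to a bit-identical negation of the y components: float
addition is commutative, so pairing the two swapped walls into a single sum
preserves exact reflection equivariance of the whole trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate"]

SPEED_FLOOR = 1e-6


@njit(cache=True)
def _step_forces(pos, vel, head, chi, hw, hh,
                 mu, v_d, r0, A_P, B_p, eps, A_w1, A_w2, B_w,
                 gamma, damping_range, tp_enabled, nearest_only, out):
    n = pos.shape[0]
    contact = 2.0 * r0
    for i in range(n):
        # propulsion
        sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2)
        f = mu * (v_d - sp)
        fx = f * head[i, 0]
        fy = f * head[i, 1]

        # pair repulsion
        for j in range(n):
            if j == i:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            r = np.sqrt(dx * dx + dy * dy)
            if r > contact:
                m = A_P * np.exp(-(r - contact) / B_p)
            else:
                m = eps * (1.0 - r / contact) ** 1.5
            fx += m * dx / r
            fy += m * dy / r

        # wall distances: E, N, W, S
        dE = hw - pos[i, 0]
        dN = hh - pos[i, 1]
        dW = pos[i, 0] + hw
        dS = pos[i, 1] + hh

        # per-wall scalar magnitude of the normal force
        wE = wN = wW = wS = 0.0
        uE = uN = uW = uS = True
        if nearest_only:
            uE = uN = uW = uS = False
            dmin = dE
            k = 0
            if dN < dmin:
                dmin = dN
                k = 1
            if dW < dmin:
                dmin = dW
                k = 2
            if dS < dmin:
                dmin = dS
                k = 3
            if k == 0:
                uE = True
            elif k == 1:
                uN = True
            elif k == 2:
                uW = True
            else:
                uS = True

        # E wall: n=(-1,0) -> v_n = -vx
        if uE:
            if dE > r0:
                wE = A_w1 * np.exp(-(dE - r0) / B_w)
                if dE - r0 <= damping_range:
                    wE -= gamma * (-vel[i, 0])
            else:
                wE = eps * (1.0 - dE / r0) ** 1.5
        # N wall: n=(0,-1) -> v_n = -vy
        if uN:
            if dN > r0:
                wN = A_w1 * np.exp(-(dN - r0) / B_w)
                if dN - r0 <= damping_range:
                    wN -= gamma * (-vel[i, 1])
            else:
                wN = eps * (1.0 - dN / r0) ** 1.5
        # W wall: n=(1,0) -> v_n = vx
        if uW:
            if dW > r0:
                wW = A_w1 * np.exp(-(dW - r0) / B_w)
                if dW - r0 <= damping_range:
                    wW -= gamma * vel[i, 0]
            else:
                wW = eps * (1.0 - dW / r0) ** 1.5
        # S wall: n=(0,1) -> v_n = vy
        if uS:
            if dS > r0:
                wS = A_w1 * np.exp(-(dS - r0) / B_w)
                if dS - r0 <= damping_range:
                    wS -= gamma * vel[i, 1]
            else:
                wS = eps * (1.0 - dS / r0) ** 1.5

        # n_hat: E=(-1,0), N=(0,-1), W=(1,0), S=(0,1); pair N+S for mirror exactness
        fx += -wE
        fx += wW
        fy += -wN + wS

        # turning force along t_plus (chirality +1) / t_minus (-1)
        # t_plus: E=(0,1), N=(-1,0), W=(0,-1), S=(1,0)
        if tp_enabled and chi[i] != 0:
            c = float(chi[i])
            tx = 0.0
            ty = 0.0
            tyE = tyW = 0.0
            txN = txS = 0.0
            # cos(alpha) = heading . (wall-ward direction) = -heading . n_hat
            if uE:
                ca = head[i, 0]
                if ca > 0.0:
                    tyE = A_w2 * np.exp(-(dE - r0) / B_w) * ca * c
            if uW:
                ca = -head[i, 0]
                if ca > 0.0:
                    tyW = -A_w2 * np.exp(-(dW - r0) / B_w) * ca * c
            if uN:
                ca = head[i, 1]
                if ca > 0.0:
                    txN = -A_w2 * np.exp(-(dN - r0) / B_w) * ca * c
            if uS:
                ca = -head[i, 1]
                if ca > 0.0:
                    txS = A_w2 * np.exp(-(dS - r0) / B_w) * ca * c
            tx = txN + txS
            ty = tyE + tyW
            fx += tx
            fy += ty

        out[i, 0] = fx
        out[i, 1] = fy


@njit(cache=True)
def _integrate(pos, vel, head, chi, hw, hh,
               mu, v_d, r0, A_P, B_p, eps, A_w1, A_w2, B_w,
               gamma, damping_range, mass, tp_enabled, nearest_only,
               dt, n_steps, record_every,
               rec_pos, rec_vel):
    n = pos.shape[0]
    force = np.empty((n, 2))
    rec_pos[0] = pos
    rec_vel[0] = vel
    k = 1
    for step in range(n_steps):
        _step_forces(pos, vel, head, chi, hw, hh,
                     mu, v_d, r0, A_P, B_p, eps, A_w1, A_w2, B_w,
                     gamma, damping_range, tp_enabled, nearest_only, force)
        # forward Euler: position advances with the old velocity
        for i in range(n):
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            vel[i, 0] += dt * force[i, 0] / mass
            vel[i, 1] += dt * force[i, 1] / mass
            sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2)
            if sp > SPEED_FLOOR:
                head[i, 0] = vel[i, 0] / sp
                head[i, 1] = vel[i, 1] / sp
            if not (-hw < pos[i, 0] < hw and -hh < pos[i, 1] < hh):
                return i, step  # escaped
        if (step + 1) % record_every == 0:
            rec_pos[k] = pos
            rec_vel[k] = vel
            k += 1
    return -1, -1


def compute_forces(positions, velocities, headings, chiralities, arena, params):
    """Vectorized total force on every agent; same laws as :mod:`roamsim.forces`."""
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    vel = np.ascontiguousarray(velocities, dtype=np.float64)
    head = np.ascontiguousarray(headings, dtype=np.float64)
    chi = np.ascontiguousarray(chiralities, dtype=np.int64)
    out = np.empty_like(pos)
    _step_forces(pos, vel, head, chi, arena.half_width, arena.half_height,
                 params.mu, params.v_d, params.r0, params.A_P, params.B_p,
                 params.eps, params.A_w1, params.A_w2, params.B_w,
                 params.gamma, params.damping_range, params.tp_enabled,
                 params.wall_mode == "nearest_only", out)
    return out


def integrate(positions, velocities, headings, chiralities, arena, params,
              dt, n_steps, record_every):
    """Run ``n_steps`` of forward Euler, recording every ``record_every`` steps.

    Returns ``(rec_pos, rec_vel, escaped_agent, escaped_step)`` where the
    recorded arrays have shape ``(n_steps // record_every + 1, n, 2)`` and the
    escape markers are ``(-1, -1)`` on success.  The input arrays are not
    modified.
    """
    pos = np.array(positions, dtype=np.float64, order="C", copy=True)
    vel = np.array(velocities, dtype=np.float64, order="C", copy=True)
    head = np.array(headings, dtype=np.float64, order="C", copy=True)
    chi = np.ascontiguousarray(chiralities, dtype=np.int64)
    n_rec = n_steps // record_every + 1
    rec_pos = np.empty((n_rec, pos.shape[0], 2))
    rec_vel = np.empty((n_rec, pos.shape[0], 2))
    esc_agent, esc_step = _integrate(
        pos, vel, head, chi, arena.half_width, arena.half_height,
        params.mu, params.v_d, params.r0, params.A_P, params.B_p, params.eps,
        params.A_w1, params.A_w2, params.B_w, params.gamma,
        params.damping_range, params.mass, params.tp_enabled,
        params.wall_mode == "nearest_only",
        dt, n_steps, record_every, rec_pos, rec_vel)
    return rec_pos, rec_vel, int(esc_agent), int(esc_step)
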