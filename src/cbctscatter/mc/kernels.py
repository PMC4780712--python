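"""Numba photon-transport kernels.

One kernel call transports every history of a single view through the
phantom (Woodcock delta-tracking inside the body cylinder) and into the
flat-panel detector, scoring per-pixel weighted counts into the
total/primary/scatter channel images.

Physics: free-electron Klein-Nishina Compton sampling (Kahn's rejection
scheme), Thomson angular law for Rayleigh, photoelectric absorption
terminating the history.  The air gap is treated as vacuum; the body
cylinder (with its rod inserts) is the only scattering object besides the
optional CsI scintillator slab.  A photon is classified primary iff it
underwent no Compton and no Rayleigh interaction in the phantom (optionally
also in the detector).
"""

from __future__ import annotations

import numpy as np
from numba import njit

ELECTRON_REST_KEV = 510.99895
MAX_INTERACTIONS = 1000


@njit(cache=True, inline="always")
def _cyl_interval(px, py, pz, dx, dy, dz, r2, hz):
    """Ray / (cylinder & z-slab) intersection interval (t0, t1); t0>t1 if miss."""
    a = dx * dx + dy * dy
    if a > 1e-16:
        b = px * dx + py * dy
        c = px * px + py * py - r2
        disc = b * b - a * c
        if disc <= 0.0:
            return 1.0, 0.0
        sq = np.sqrt(disc)
        tc0 = (-b - sq) / a
        tc1 = (-b + sq) / a
    else:
        if px * px + py * py >= r2:
            return 1.0, 0.0
        tc0, tc1 = -1e30, 1e30
    if abs(dz) > 1e-16:
        ta = (-hz - pz) / dz
        tb = (hz - pz) / dz
        tz0 = min(ta, tb)
        tz1 = max(ta, tb)
    else:
        if abs(pz) >= hz:
            return 1.0, 0.0
        tz0, tz1 = -1e30, 1e30
    return max(tc0, tz0), min(tc1, tz1)


@njit(cache=True, inline="always")
def _material_at(x, y, z, body_mat, reg_cx, reg_cy, reg_r2, reg_hz, reg_mat):
    for k in range(reg_cx.size):
        if abs(z) <= reg_hz[k]:
            ddx = x - reg_cx[k]
            ddy = y - reg_cy[k]
            if ddx * ddx + ddy * ddy <= reg_r2[k]:
                return reg_mat[k]
    return body_mat


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    s = np.sqrt(max(0.0, 1.0 - dz * dz))
    if s > 1e-10:
        nx = dx * cost + sint * (dx * dz * cphi - dy * sphi) / s
        ny = dy * cost + sint * (dy * dz * cphi + dx * sphi) / s
        nz = dz * cost - s * sint * cphi
    else:
        sign = 1.0 if dz > 0.0 else -1.0
        nx = sint * cphi
        ny = sint * sphi
        nz = cost * sign
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _sample_compton(energy_kev):
    """Kahn's Klein-Nishina sampling; returns (scattered energy, cos theta)."""
    alpha = energy_kev / ELECTRON_REST_KEV
    t = 1.0 + 2.0 * alpha
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= t / (t + 8.0):
            x = 1.0 + 2.0 * alpha * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                break
        else:
            x = t / (1.0 + 2.0 * alpha * r2)
            mu = 1.0 - (x - 1.0) / alpha
            if r3 <= 0.5 * (mu * mu + 1.0 / x):
                break
    cost = 1.0 - (x - 1.0) / alpha
    return energy_kev / x, cost


@njit(cache=True, inline="always")
def _sample_thomson():
    while True:
        mu = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + mu * mu):
            return mu


@njit(cache=True, inline="always")
def _eidx(energy_kev, e_min, e_step, n_e):
    i = int((energy_kev - e_min) / e_step + 0.5)
    if i < 0:
        i = 0
    elif i >= n_e:
        i = n_e - 1
    return i


@njit(cache=True)
def transport_view(seed, n_photons, weight,
                   sad, det_x, det_pitch_cm, n_rows, n_cols,
                   emit_y_half, emit_z0, emit_z1,
                   body_r2, body_hz, body_mat,
                   reg_cx, reg_cy, reg_r2, reg_hz, reg_mat,
                   e_min, e_step,
                   mu_pe, mu_co, mu_ra, mu_tot, mu_maj,
                   spec_cdf, spec_energies,
                   det_mat, det_thickness, ideal_detector,
                   classify_with_detector,
                   total, primary, scatter,
                   record, rec_row, rec_col, rec_energy,
                   rec_co_ph, rec_ra_ph, rec_co_det, rec_ra_det):
    np.random.seed(seed)
    n_e = mu_tot.shape[1]
    det_y_half = n_cols * det_pitch_cm / 2.0
    det_z_half = n_rows * det_pitch_cm / 2.0
    n_detected = 0
    n_runaway = 0
    for _ in range(n_photons):
        # ---- emission: uniform over the illuminated detector-band rectangle
        ty = (2.0 * np.random.random() - 1.0) * emit_y_half
        tz = emit_z0 + np.random.random() * (emit_z1 - emit_z0)
        px, py, pz = -sad, 0.0, 0.0
        dx = det_x + sad
        dy = ty
        dz = tz
        norm = np.sqrt(dx * dx + dy * dy + dz * dz)
        dx /= norm
        dy /= norm
        dz /= norm
        u = np.random.random()
        energy = spec_energies[np.searchsorted(spec_cdf, u)]
        ei = _eidx(energy, e_min, e_step, n_e)
        n_co_ph = 0
        n_ra_ph = 0
        n_co_det = 0
        n_ra_det = 0
        alive = True
        n_inter = 0

        # ---- phantom phase: delta tracking inside the body cylinder
        while alive:
            t0, t1 = _cyl_interval(px, py, pz, dx, dy, dz, body_r2, body_hz)
            if t0 > t1 or t1 <= 1e-9:
                break  # no phantom ahead: ballistic flight
            if t0 > 1e-9:  # outside, entering ahead
                px += t0 * dx
                py += t0 * dy
                pz += t0 * dz
                t1 -= t0
            # woodcock loop within the body
            left_body = False
            while True:
                s = -np.log(np.random.random()) / mu_maj[ei]
                if s >= t1:
                    px += (t1 + 1e-9) * dx
                    py += (t1 + 1e-9) * dy
                    pz += (t1 + 1e-9) * dz
                    left_body = True
                    break
                px += s * dx
                py += s * dy
                pz += s * dz
                t1 -= s
                mat = _material_at(px, py, pz, body_mat,
                                   reg_cx, reg_cy, reg_r2, reg_hz, reg_mat)
                mt = mu_tot[mat, ei]
                if np.random.random() * mu_maj[ei] >= mt:
                    continue  # virtual collision
                n_inter += 1
                if n_inter > MAX_INTERACTIONS:
                    n_runaway += 1
                    alive = False
                    break
                xi = np.random.random() * mt
                if xi < mu_pe[mat, ei]:
                    alive = False  # photoelectric absorption
                    break
                elif xi < mu_pe[mat, ei] + mu_co[mat, ei]:
                    energy, cost = _sample_compton(energy)
                    n_co_ph += 1
                    if energy < e_min:
                        alive = False
                        break
                    ei = _eidx(energy, e_min, e_step, n_e)
                else:
                    cost = _sample_thomson()
                    n_ra_ph += 1
                phi = 2.0 * np.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cost, phi)
                break  # direction changed: recompute body interval
            if left_body:
                break
            if not alive:
                break

        if not alive:
            continue
        # ---- ballistic flight to the detector plane
        if dx <= 1e-12:
            continue
        t = (det_x - px) / dx
        if t < 0.0:
            continue
        hy = py + t * dy
        hz_ = pz + t * dz
        if abs(hy) >= det_y_half or abs(hz_) >= det_z_half:
            continue

        detected = False
        if ideal_detector:
            detected = True
        else:
            # ---- transport in the scintillator slab
            sx, sy, sz = det_x, hy, hz_
            while True:
                l = -np.log(np.random.random()) / mu_tot[det_mat, ei]
                # distance to slab exit (x in [det_x, det_x+th], lateral bounds)
                t_exit = 1e30
                if dx > 1e-12:
                    t_exit = min(t_exit, (det_x + det_thickness - sx) / dx)
                elif dx < -1e-12:
                    t_exit = min(t_exit, (det_x - sx) / dx)
                if dy > 1e-12:
                    t_exit = min(t_exit, (det_y_half - sy) / dy)
                elif dy < -1e-12:
                    t_exit = min(t_exit, (-det_y_half - sy) / dy)
                if dz > 1e-12:
                    t_exit = min(t_exit, (det_z_half - sz) / dz)
                elif dz < -1e-12:
                    t_exit = min(t_exit, (-det_z_half - sz) / dz)
                if l >= t_exit:
                    break  # escapes the scintillator
                sx += l * dx
                sy += l * dy
                sz += l * dz
                n_inter += 1
                if n_inter > MAX_INTERACTIONS:
                    n_runaway += 1
                    break
                mt = mu_tot[det_mat, ei]
                xi = np.random.random() * mt
                if xi < mu_pe[det_mat, ei]:
                    detected = True
                    hy, hz_ = sy, sz
                    break
                elif xi < mu_pe[det_mat, ei] + mu_co[det_mat, ei]:
                    energy, cost = _sample_compton(energy)
                    n_co_det += 1
                    if energy < e_min:
                        detected = True  # absorbed locally
                        hy, hz_ = sy, sz
                        break
                    ei = _eidx(energy, e_min, e_step, n_e)
                else:
                    cost = _sample_thomson()
                    n_ra_det += 1
                phi = 2.0 * np.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cost, phi)

        if not detected:
            continue
        row = int((hz_ + det_z_half) / det_pitch_cm)
        col = int((hy + det_y_half) / det_pitch_cm)
        if row < 0 or row >= n_rows or col < 0 or col >= n_cols:
            continue
        n_scat = n_co_ph + n_ra_ph
        if classify_with_detector:
            n_scat += n_co_det + n_ra_det
        total[row, col] += weight
        if n_scat == 0:
            primary[row, col] += weight
        else:
            scatter[row, col] += weight
        if record:
            rec_row[n_detected] = row
            rec_col[n_detected] = col
            rec_energy[n_detected] = energy
            rec_co_ph[n_detected] = n_co_ph
            rec_ra_ph[n_detected] = n_ra_ph
            rec_co_det[n_detected] = n_co_det
            rec_ra_det[n_detected] = n_ra_det
        n_detected += 1
    return n_detected, n_runaway


@njit(cache=True)
def sample_compton_batch(seed, energy_kev, n):
    """Standalone Klein-Nishina sampling for validation studies."""
    np.random.seed(seed)
    energies = np.empty(n)
    cosines = np.empty(n)
    for i in range(n):
        e, c = _sample_compton(energy_kev)
        energies[i] = e
        cosines[i] = c
    return energies, cosines
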