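"""Numba inner loops for energy and force evaluation.

All kernels use minimum-image convention in a cubic box and accumulate
energies in kBT, forces in kBT/nm.  Pairwise exclusions (directly bonded
neighbours) are passed as a padded per-particle table.

The systems handled here are desk-scale (N up to a few thousand), where a
straight O(N^2) pair loop under numba costs well under a millisecond per
step; no neighbour lists are used.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _excluded(excl, i, j):
    for k in range(excl.shape[1]):
        e = excl[i, k]
        if e < 0:
            return False
        if e == j:
            return True
    return False


@njit(cache=True, fastmath=True)
def nonbonded(pos, q, dia, excl, box, l_bjerrum, r_cut, eps_tlj, coulomb_on):
    """TLJ + (optionally truncated) Coulomb over all non-excluded pairs.

    r_cut <= 0 means full minimum-image Coulomb (no truncation).  The TLJ
    term acts only inside the contact diameter sigma_ij, which is always
    smaller than any sensible Coulomb cutoff.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e_el = 0.0
    e_tlj = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if _excluded(excl, i, j):
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            r = math.sqrt(r2)
            sij = 0.5 * (dia[i] + dia[j])
            coeff = 0.0
            if r < sij:
                sr6 = (sij * sij / r2) ** 3
                sr12 = sr6 * sr6
                e_tlj += eps_tlj * (sr12 - 2.0 * sr6 + 1.0)
                coeff += eps_tlj * 12.0 * (sr12 - sr6) / r2
            if coulomb_on and q[i] != 0.0 and q[j] != 0.0:
                if r_cut <= 0.0 or r < r_cut:
                    u = l_bjerrum * q[i] * q[j] / r
                    e_el += u
                    coeff += u / r2
            if coeff != 0.0:
                f[i, 0] += coeff * dx
                f[i, 1] += coeff * dy
                f[i, 2] += coeff * dz
                f[j, 0] -= coeff * dx
                f[j, 1] -= coeff * dy
                f[j, 2] -= coeff * dz
    return e_el, e_tlj, f


@njit(cache=True, fastmath=True)
def ewald_real(pos, q, excl, box, l_bjerrum, r_cut, alpha):
    """Short-range (erfc-screened) Ewald part plus exclusion corrections.

    Excluded pairs contribute the negative of the smooth erf part so that,
    combined with the reciprocal sum, their total Coulomb interaction is
    exactly zero.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    two_over_sqrt_pi = 2.0 / math.sqrt(math.pi)
    for i in range(n):
        for j in range(i + 1, n):
            if q[i] == 0.0 or q[j] == 0.0:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            r = math.sqrt(r2)
            qq = l_bjerrum * q[i] * q[j]
            if _excluded(excl, i, j):
                # remove the erf (reciprocal-space) part for excluded pairs
                erf_r = math.erf(alpha * r)
                e -= qq * erf_r / r
                coeff = -qq * (
                    erf_r / r - two_over_sqrt_pi * alpha * math.exp(-(alpha * r) ** 2)
                ) / r2
            elif r < r_cut:
                erfc_r = math.erfc(alpha * r)
                e += qq * erfc_r / r
                coeff = qq * (
                    erfc_r / r + two_over_sqrt_pi * alpha * math.exp(-(alpha * r) ** 2)
                ) / r2
            else:
                continue
            f[i, 0] += coeff * dx
            f[i, 1] += coeff * dy
            f[i, 2] += coeff * dz
            f[j, 0] -= coeff * dx
            f[j, 1] -= coeff * dy
            f[j, 2] -= coeff * dz
    return e, f


@njit(cache=True, fastmath=True)
def bonded(pos, bonds, r0, kb, box):
    """Harmonic bonds u = (1/2) kb (r - r0)^2."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[m]
        e += 0.5 * kb[m] * dr * dr
        if r > 0.0:
            coeff = -kb[m] * dr / r
            f[i, 0] += coeff * dx
            f[i, 1] += coeff * dy
            f[i, 2] += coeff * dz
            f[j, 0] -= coeff * dx
            f[j, 1] -= coeff * dy
            f[j, 2] -= coeff * dz
    return e, f


@njit(cache=True, fastmath=True)
def angular(pos, angles, ka, box):
    """Harmonic angles u = (1/2) ka (theta - pi)^2 (straight equilibrium).

    The theta -> pi limit of the force is finite for theta0 = pi and is
    taken analytically when sin(theta) underflows.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    for m in range(angles.shape[0]):
        a = angles[m, 0]
        b = angles[m, 1]
        c = angles[m, 2]
        ux = pos[a, 0] - pos[b, 0]
        uy = pos[a, 1] - pos[b, 1]
        uz = pos[a, 2] - pos[b, 2]
        vx = pos[c, 0] - pos[b, 0]
        vy = pos[c, 1] - pos[b, 1]
        vz = pos[c, 2] - pos[b, 2]
        ux -= box * round(ux / box)
        uy -= box * round(uy / box)
        uz -= box * round(uz / box)
        vx -= box * round(vx / box)
        vy -= box * round(vy / box)
        vz -= box * round(vz / box)
        cu = math.sqrt(ux * ux + uy * uy + uz * uz)
        cv = math.sqrt(vx * vx + vy * vy + vz * vz)
        h = (ux * vx + uy * vy + uz * vz) / (cu * cv)
        if h > 1.0:
            h = 1.0
        elif h < -1.0:
            h = -1.0
        theta = math.acos(h)
        dth = theta - math.pi
        e += 0.5 * ka[m] * dth * dth
        sin_t = math.sqrt(1.0 - h * h)
        if sin_t < 1.0e-8:
            coeff = -ka[m]  # lim theta->pi of ka*(theta-pi)/sin(theta)
        else:
            coeff = ka[m] * dth / sin_t
        # force on end sites: coeff * grad_a h etc.
        fax = coeff * (vx / (cu * cv) - h * ux / (cu * cu))
        fay = coeff * (vy / (cu * cv) - h * uy / (cu * cu))
        faz = coeff * (vz / (cu * cv) - h * uz / (cu * cu))
        fcx = coeff * (ux / (cu * cv) - h * vx / (cv * cv))
        fcy = coeff * (uy / (cu * cv) - h * vy / (cv * cv))
        fcz = coeff * (uz / (cu * cv) - h * vz / (cv * cv))
        f[a, 0] += fax
        f[a, 1] += fay
        f[a, 2] += faz
        f[c, 0] += fcx
        f[c, 1] += fcy
        f[c, 2] += fcz
        f[b, 0] -= fax + fcx
        f[b, 1] -= fay + fcy
        f[b, 2] -= faz + fcz
    return e, f
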