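"""Ray / union-of-spheres intersection utilities.

Shared by the cavity exterior quadrature and the electron escape-fraction
integrals: both need, for a ray from an origin, the exact sub-intervals of
the radial coordinate that lie inside a union of spheres.  Working with
exact ray intervals (instead of masking grid nodes against the spheres)
removes the discontinuity error of the sharp boundary from the radial
direction entirely.
"""

from __future__ import annotations

import numpy as np


def ray_sphere_interval(origin, direction, center, radius):
    """Interval [t0, t1] (t >= 0) of the ray inside one sphere, or None."""
    oc = np.asarray(center, float) - np.asarray(origin, float)
    beta = float(np.dot(direction, oc))
    gamma = float(np.dot(oc, oc)) - radius * radius
    disc = beta * beta - gamma
    if disc <= 0.0:
        return None
    half = np.sqrt(disc)
    t0, t1 = beta - half, beta + half
    if t1 <= 0.0:
        return None
    return max(t0, 0.0), t1


def ray_union_intervals(origin, direction, centers, radii, t_max):
    """Merged intervals of [0, t_max] inside the union of spheres."""
    raw = []
    for c, r in zip(centers, radii):
        iv = ray_sphere_interval(origin, direction, c, r)
        if iv is not None and iv[0] < t_max:
            raw.append((iv[0], min(iv[1], t_max)))
    if not raw:
        return []
    raw.sort()
    merged = [list(raw[0])]
    for t0, t1 in raw[1:]:
        if t0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t1)
        else:
            merged.append([t0, t1])
    return [(a, b) for a, b in merged]


def complement_intervals(inside, t_max):
    """Sub-intervals of [0, t_max] not covered by `inside` (sorted, merged)."""
    out = []
    t = 0.0
    for a, b in inside:
        if a > t:
            out.append((t, a))
        t = max(t, b)
    if t < t_max:
        out.append((t, t_max))
    return out


def angular_grid(n_theta: int, n_phi: int):
    """Product angular grid: Gauss-Legendre in cos(theta) x uniform phi.

    Returns unit direction vectors (n,3) and weights summing to 4*pi.
    """
    u, wu = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    su = np.sqrt(1.0 - u**2)
    dirs = np.empty((n_theta * n_phi, 3))
    w = np.empty(n_theta * n_phi)
    k = 0
    for i in range(n_theta):
        cp, sp = np.cos(phi), np.sin(phi)
        dirs[k:k + n_phi, 0] = su[i] * cp
        dirs[k:k + n_phi, 1] = su[i] * sp
        dirs[k:k + n_phi, 2] = u[i]
        w[k:k + n_phi] = wu[i] * (2.0 * np.pi / n_phi)
        k += n_phi
    return dirs, w
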