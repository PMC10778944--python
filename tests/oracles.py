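"""Independent reference implementations used only to check the package.

Each oracle solves the same problem as a package operation by a different
route (finite differences, exhaustive search, enumeration), so agreement is
evidence of correctness rather than repetition.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import solve_banded


def crank_nicolson_sphere(
    taus, n_shells: int = 400, dt: float = 1e-5, theta: float = 0.5,
    n_startup: int = 20,
):
    """Finite-difference solution of radial diffusion into a sphere.

    Solves du/dtau = u_rr + (2/r) u_r on r in [0, 1] with u(1) = 1 and
    u(r, 0) = 0 via the substitution v = r u (which reduces the problem to
    the 1-D heat equation v_t = v_rr with v(0) = 0, v(1) = 1), advanced by
    the theta scheme (Crank-Nicolson for theta = 0.5) with a few fully
    implicit startup steps to damp the boundary discontinuity.

    Returns (profiles, volume_uptake, slice_uptake) at the requested taus:
    ``profiles`` is a list of (r, u(r)) pairs, ``volume_uptake`` the
    fractional mass uptake 3*int u r^2 dr, ``slice_uptake`` the equatorial
    disc average 2*int u r dr.
    """
    taus = np.sort(np.asarray(taus, dtype=float))
    n = n_shells
    dr = 1.0 / n
    r = np.arange(n + 1) * dr
    v = np.zeros(n + 1)
    v[-1] = 1.0

    lam = dt / dr**2

    def banded_matrix(th):
        # (I - th*lam*L) on interior nodes, tridiagonal in banded form
        ab = np.zeros((3, n - 1))
        ab[0, 1:] = -th * lam
        ab[1, :] = 1.0 + 2.0 * th * lam
        ab[2, :-1] = -th * lam
        return ab

    def step(vv, th):
        interior = vv[1:-1]
        if th < 1.0:
            rhs = interior + (1 - th) * lam * (vv[2:] - 2 * interior + vv[:-2])
        else:
            rhs = interior.copy()
        rhs[-1] += th * lam * 1.0  # Dirichlet v(1) = 1
        out = vv.copy()
        out[1:-1] = solve_banded((1, 1), banded_matrix(th), rhs)
        return out

    profiles, vol_uptake, slc_uptake = [], [], []
    t = 0.0
    i_tau = 0
    max_steps = int(np.ceil(taus[-1] / dt)) + n_startup + 2
    for k in range(max_steps):
        if i_tau >= len(taus):
            break
        th = 1.0 if k < n_startup else theta
        # land exactly on requested taus
        dt_k = min(dt, taus[i_tau] - t)
        if dt_k < dt:
            lam_save = lam
            lam = dt_k / dr**2
            v = step(v, th) if dt_k > 0 else v
            lam = lam_save
            t = taus[i_tau]
        else:
            v = step(v, th)
            t += dt
        while i_tau < len(taus) and t >= taus[i_tau] - 1e-15:
            with np.errstate(invalid="ignore", divide="ignore"):
                u = np.where(r > 0, v / np.where(r > 0, r, 1.0), 0.0)
            u[0] = 2 * u[1] - u[2]  # r -> 0 limit by linear extrapolation
            profiles.append((r.copy(), u.copy()))
            vol_uptake.append(3.0 * np.trapezoid(v * r, r))   # u r^2 = v r
            slc_uptake.append(2.0 * np.trapezoid(v, r))       # u r = v
            i_tau += 1
    return profiles, np.array(vol_uptake), np.array(slc_uptake)


def otsu_bruteforce(histogram) -> int:
    """Exhaustive search of the between-class-variance maximizing threshold
    over all 256 candidates (foreground = strictly greater than T)."""
    hist = np.asarray(histogram, dtype=float)
    best_t, best_var = None, -np.inf
    total = hist.sum()
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1:] * np.arange(t + 1, 256)).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:  # strict: keeps the smallest maximizing t
            best_var, best_t = var, t
    return best_t


def optimal_assignment(features_a, features_b, centroids_a, centroids_b,
                       max_displacement):
    """Minimum-total-distance one-to-one assignment by exhaustive enumeration
    (largest matching first, then least total feature distance)."""
    na, nb = len(features_a), len(features_b)
    fa, fb = np.asarray(features_a, float), np.asarray(features_b, float)
    ca, cb = np.asarray(centroids_a, float), np.asarray(centroids_b, float)
    allowed = {
        (i, j)
        for i in range(na)
        for j in range(nb)
        if np.linalg.norm(ca[i] - cb[j]) <= max_displacement
    }
    best_pairs, best_key = [], None
    k_max = min(na, nb)
    for k in range(k_max, 0, -1):
        for subset_a in itertools.combinations(range(na), k):
            for subset_b in itertools.permutations(range(nb), k):
                pairs = list(zip(subset_a, subset_b))
                if not all(p in allowed for p in pairs):
                    continue
                cost = sum(np.linalg.norm(fa[i] - fb[j]) for i, j in pairs)
                key = (-k, cost)
                if best_key is None or key < best_key:
                    best_key, best_pairs = key, pairs
        if best_pairs:
            break
    return sorted(best_pairs)


def endpoint_bruteforce(q1, std, constants):
    """Evaluate every (frame, criterion) combination independently and pick
    the earliest frame, priority I > II > III."""
    q1 = np.asarray(q1, float)
    std = np.asarray(std, float)
    firings = []  # (frame, priority, name)
    for k in range(len(q1)):
        if k >= 2:
            ddq1 = (q1[k] - q1[k - 1]) - (q1[k - 1] - q1[k - 2])
            if ddq1 < constants.q1_accel_drop and q1[k] > constants.q1_shoulder:
                firings.append((k, 0, "I"))
        if q1[k] > constants.q1_bright:
            firings.append((k, 1, "II"))
        if k >= 1:
            if (abs(std[k] - std[k - 1]) < constants.std_change
                    and std[k] < constants.std_level
                    and q1[k] > constants.q1_shoulder):
                firings.append((k, 2, "III"))
    if not firings:
        return None, "none"
    frame, _, name = min(firings)
    return frame, name


def point_in_polygon(px: float, py: float, vertices) -> bool:
    """Ray casting with an explicit on-boundary check (boundary counts in)."""
    verts = np.asarray(vertices, float)
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-segment check
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
                return True
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside
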