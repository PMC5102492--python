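"""Numba kernels for the Metropolis-style copy dynamics.

The incremental energy change of a copy attempt is implemented once, in
:func:`delta_h_site`, and used both by the per-MCS kernel and by the Python
wrapper exposed for testing against the full-Hamiltonian oracle.

The kernel uses numba's internal per-thread RNG; seed it through
:func:`seed_kernel_rng` before a run for reproducibility.
"""

import numpy as np
from numba import njit

# 8-neighborhood offsets (dy, dx): nearest + next-nearest neighbors
_OFF_Y = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_OFF_X = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def delta_h_site(sigma, ctypes, areas, c, J, lam, At, chi, sat,
                 ys, xs, yt, xt, pair_factor):
    """ΔH of copying σ(source) into the target site.

    Adhesion and area-constraint terms change only around the target site, so
    they are evaluated incrementally over the target's 8-neighborhood (pairs
    with both sites inside the lattice).  The chemotaxis term applies when
    exactly one participant is the ECM.
    """
    h, w = sigma.shape
    s_sig = sigma[ys, xs]
    t_sig = sigma[yt, xt]
    s_ct = ctypes[s_sig]
    t_ct = ctypes[t_sig]

    dh = 0.0
    for k in range(8):
        ny = yt + _OFF_Y[k]
        nx = xt + _OFF_X[k]
        if ny < 0 or ny >= h or nx < 0 or nx >= w:
            continue
        n_sig = sigma[ny, nx]
        n_ct = ctypes[n_sig]
        if n_sig != s_sig:
            dh += J[s_ct, n_ct]
        if n_sig != t_sig:
            dh -= J[t_ct, n_ct]
    dh *= pair_factor

    if s_sig > 0:
        a = areas[s_sig]
        da = At[s_ct] - a
        dh += lam[s_ct] * (1.0 - 2.0 * da)  # (a+1-A)^2 - (a-A)^2
    if t_sig > 0:
        a = areas[t_sig]
        da = At[t_ct] - a
        dh += lam[t_ct] * (1.0 + 2.0 * da)  # (a-1-A)^2 - (a-A)^2

    if (s_sig == 0) != (t_sig == 0):
        cell_ct = s_ct if s_sig > 0 else t_ct
        x = chi[cell_ct]
        ctv = c[yt, xt]
        csv = c[ys, xs]
        dh += -x * (ctv / (1.0 + sat * ctv) - csv / (1.0 + sat * csv))
    return dh


@njit(cache=True)
def euler_steps(c, source, decay, k, n_steps):
    """Forward-Euler steps of the reaction-diffusion field, in place.

    5-point Laplacian with factor k = D*dt/dx^2; ``source`` and ``decay`` are
    the per-site dt-scaled secretion and ECM-decay maps; the boundary ring is
    held at 0 (absorbing boundaries).
    """
    h, w = c.shape
    buf = np.empty_like(c)
    for _ in range(n_steps):
        for y in range(1, h - 1):
            for x in range(1, w - 1):
                lap = (c[y - 1, x] + c[y + 1, x] + c[y, x - 1] + c[y, x + 1]
                       - 4.0 * c[y, x])
                buf[y, x] = (c[y, x] + k * lap + source[y, x]
                             - decay[y, x] * c[y, x])
        for y in range(1, h - 1):
            for x in range(1, w - 1):
                c[y, x] = buf[y, x]
        for y in range(h):
            c[y, 0] = 0.0
            c[y, w - 1] = 0.0
        for x in range(w):
            c[0, x] = 0.0
            c[h - 1, x] = 0.0


@njit(cache=True)
def run_mcs_kernel(sigma, ctypes, areas, c, J, lam, At, mu, chi, sat,
                   pair_factor):
    """One Monte Carlo step: width*height random copy attempts, in place."""
    h, w = sigma.shape
    n_attempts = h * w
    for _ in range(n_attempts):
        ys = np.random.randint(0, h)
        xs = np.random.randint(0, w)
        k = np.random.randint(0, 8)
        yt = ys + _OFF_Y[k]
        xt = xs + _OFF_X[k]
        if yt < 0 or yt >= h or xt < 0 or xt >= w:
            continue  # attempts targeting outside the box are not generated
        s_sig = sigma[ys, xs]
        t_sig = sigma[yt, xt]
        if s_sig == t_sig:
            continue
        dh = delta_h_site(sigma, ctypes, areas, c, J, lam, At, chi, sat,
                          ys, xs, yt, xt, pair_factor)
        if dh > 0.0:
            if s_sig > 0 and t_sig > 0:
                f = min(mu[ctypes[s_sig]], mu[ctypes[t_sig]])
            else:
                f = max(mu[ctypes[s_sig]], mu[ctypes[t_sig]])
            if np.random.random() >= np.exp(-dh / f):
                continue
        sigma[yt, xt] = s_sig
        if s_sig > 0:
            areas[s_sig] += 1
        if t_sig > 0:
            areas[t_sig] -= 1
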