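"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the Langevin escape
rate integrates the overdamped equation of motion directly, and the
geometry oracles are O(n^2) pairwise loops.
"""

from __future__ import annotations

import numpy as np

KT_300 = 1.380649e-2 * 300.0  # pN nm


def langevin_escape_rate(
    deltaG: float,
    x_b: float,
    D: float,
    shape: str = "linear-cubic",
    n_walkers: int = 10000,
    seed: int = 0,
    dt_over_tau: float = 0.02,
) -> float:
    """Escape rate from mean first passage of Euler-Maruyama trajectories.

    The landscape is the same family the library models: linear-cubic
    (well at -x_b/2, barrier at +x_b/2, absorbing where the potential
    returns to the well level, x = x_b) or harmonic-cusp (well at 0,
    absorbing cusp at x_b).  deltaG in kT units, lengths nm, D nm^2/s.
    """
    rng = np.random.default_rng(seed)
    if shape == "linear-cubic":
        # beta*U = 1.5 dG (x/xb) - 2 dG (x/xb)^3
        def beta_force(x):  # -d(beta U)/dx
            return -1.5 * deltaG / x_b + 6.0 * deltaG * x**2 / x_b**3

        x0 = -x_b / 2
        curv = 6.0 * deltaG / x_b**2  # beta * kappa_well
        absorb = x_b
    elif shape == "cusp":
        def beta_force(x):
            return -2.0 * deltaG * x / x_b**2

        x0 = 0.0
        curv = 2.0 * deltaG / x_b**2
        absorb = x_b
    else:
        raise ValueError(shape)

    tau = 1.0 / (curv * D)  # well relaxation time
    dt = dt_over_tau * tau
    sqrt_term = np.sqrt(2.0 * D * dt)
    # start from thermal equilibrium in the (locally harmonic) well
    x = x0 + rng.normal(0.0, np.sqrt(1.0 / curv), n_walkers)
    t_exit = np.full(n_walkers, np.nan)
    active = np.arange(n_walkers)
    t = 0.0
    max_steps = int(5e7 / n_walkers) * 100  # generous cap
    for _ in range(max_steps):
        t += dt
        x = x + D * beta_force(x) * dt + sqrt_term * rng.normal(size=x.size)
        out = x >= absorb
        if np.any(out):
            t_exit[active[out]] = t
            keep = ~out
            x, active = x[keep], active[keep]
            if active.size == 0:
                break
    n_censored = active.size
    if n_censored > 0.01 * n_walkers:
        raise RuntimeError(f"{n_censored} walkers never escaped")
    # memoryless correction for the few censored walkers:
    # E[T | T > t_cap] = t_cap + E[T] for an exponential escape process
    total = float(np.nansum(t_exit)) + n_censored * t
    return (n_walkers - n_censored) / total


def brute_force_contacts(xyz_a: np.ndarray, xyz_b: np.ndarray, cutoff: float) -> int:
    """Atoms of A strictly closer than cutoff to any atom of B (O(n^2))."""
    d2 = ((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2).sum(axis=2)
    return int(np.count_nonzero((d2 < cutoff**2).any(axis=1)))


def brute_force_min_distance(xyz_a: np.ndarray, xyz_b: np.ndarray) -> float:
    d2 = ((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))
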