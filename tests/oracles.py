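"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written along a different path from the
library code: pure-Python loops, generic recursions, or numerical
optimization, so agreement is meaningful.
"""

import numpy as np


def brute_force_theta(pop_genotypes):
    """Variance-components theta, transcribed literally with Python loops.

    ``pop_genotypes``: list (one entry per population) of genotype rows; each
    row is a list of allele counts over loci, -1 = missing.
    """
    first = pop_genotypes[0][0]
    n_loci = len(first) if isinstance(first, list) else 1
    A = B = C = 0.0
    for locus in range(n_loci):
        per_pop = []
        for pop in pop_genotypes:
            calls = [g[locus] if isinstance(g, list) else g for g in pop]
            calls = [g for g in calls if g >= 0]
            if calls:
                per_pop.append(calls)
        r = len(per_pop)
        if r < 2:
            continue
        n_i = [len(c) for c in per_pop]
        p_i = [sum(c) / (2 * n) for c, n in zip(per_pop, n_i)]
        h_i = [sum(1 for g in c if g == 1) / n for c, n in zip(per_pop, n_i)]
        nsum = sum(n_i)
        nbar = nsum / r
        nc = (nsum - sum(n * n for n in n_i) / nsum) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / nsum
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) \
            / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / nsum
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        A += a
        B += b
        C += hbar / 2
    return A / (A + B + C)


def mspline_numeric(knot_seq, i, k, x):
    """Generic M-spline recursion (de Boor style), order k, basis i."""
    t = knot_seq
    if k == 1:
        if t[i + 1] <= t[i]:
            return 0.0
        inside = t[i] <= x < t[i + 1] or (x == t[-1] and t[i + 1] == t[-1])
        return 1.0 / (t[i + 1] - t[i]) if inside else 0.0
    if t[i + k] == t[i]:
        return 0.0
    return k * ((x - t[i]) * mspline_numeric(t, i, k - 1, x)
                + (t[i + k] - x) * mspline_numeric(t, i + 1, k - 1, x)) \
        / ((k - 1) * (t[i + k] - t[i]))


def procrustes_brute_force(X, Y, rng, n_restarts=40):
    """Minimum residual sum of squares over similarity transforms of Y onto X.

    Numerical Nelder-Mead search over 3-D rotations (proper and reflected),
    with the optimal scale profiled out analytically and translation handled
    by centring.  Returns the best residual sum of squares found.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    flip = np.diag([1.0, 1.0, -1.0])

    def objective(theta, reflect):
        rot = Rotation.from_rotvec(theta).as_matrix()
        if reflect:
            rot = flip @ rot
        aligned = Yc @ rot
        s = (Xc * aligned).sum() / (aligned ** 2).sum()
        return ((Xc - s * aligned) ** 2).sum()

    best = np.inf
    for reflect in (False, True):
        for _ in range(n_restarts):
            x0 = rng.uniform(-np.pi, np.pi, 3)
            out = minimize(objective, x0, args=(reflect,),
                           method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14,
                                    "maxiter": 20000})
            best = min(best, out.fun)
    return best
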