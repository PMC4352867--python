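"""Independent oracles used by the tests.

These deliberately avoid the closed-form SVD route used by the package:
the superposition oracle samples rotations and polishes numerically, and
the paired-test oracle enumerates sign flips exhaustively.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def grid_superpose_rmsd(fixed, mobile, n_rotations=500, seed=0, polish=False):
    """Min RMSD over sampled rotations (optimal translation per rotation).

    With ``polish=True`` the best grid rotation seeds a Nelder-Mead
    refinement over the rotation vector, closing the quadratic basin gap
    of the finite grid.
    """
    fixed = np.asarray(fixed, float)
    mobile = np.asarray(mobile, float)
    y = fixed - fixed.mean(axis=0)
    x = mobile - mobile.mean(axis=0)

    def rmsd_of(matrix):
        return float(np.sqrt(np.mean(np.sum((x @ matrix.T - y) ** 2, axis=1))))

    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_rotations, rng=rng)
    rmsds = [rmsd_of(r.as_matrix()) for r in rots]
    best_i = int(np.argmin(rmsds))
    best = rmsds[best_i]
    if not polish:
        return best

    def objective(rotvec):
        return rmsd_of(Rotation.from_rotvec(rotvec).as_matrix())

    res = minimize(objective, rots[best_i].as_rotvec(), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return min(best, float(res.fun))


def sign_flip_permutation_p(gp, p):
    """Exact one-tailed sign-flip permutation p-value for paired data.

    Enumerates all 2^n assignments of signs to the paired differences and
    counts how often the permuted t statistic is at least the observed
    one (upper tail, alternative: p > gp).
    """
    d = np.asarray(p, float) - np.asarray(gp, float)
    n = len(d)

    def t_stat(v):
        sd = v.std(ddof=1)
        if sd == 0:
            return np.inf if v.mean() > 0 else (-np.inf if v.mean() < 0 else 0.0)
        return v.mean() / (sd / np.sqrt(n))

    t_obs = t_stat(d)
    count = 0
    for signs in itertools.product((1.0, -1.0), repeat=n):
        if t_stat(d * np.array(signs)) >= t_obs - 1e-12:
            count += 1
    return count / 2 ** n
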