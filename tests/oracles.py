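"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: rigid
superposition is minimized by a dense Euler-angle grid plus simplex
refinement (no SVD), feature-match acceptance is re-derived by exhaustive
correspondence enumeration on top of that fit, and Boltzmann sums are
evaluated in 50-digit decimal arithmetic.
"""

from __future__ import annotations

import itertools
import math
from decimal import Decimal, getcontext

import numpy as np
from scipy.optimize import minimize


def _euler_matrix(angles):
    a, b, c = angles
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def brute_force_superpose(P, Q, grid_step_deg=20.0):
    """Best rigid fit of P onto Q by rotation grid search + simplex refinement.

    Returns (R, t, rmsd). Translation is optimal per rotation (centroid
    matching), so only the 3 rotational degrees of freedom are searched.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq

    def cost(angles):
        R = _euler_matrix(angles)
        d = Pc @ R.T - Qc
        return float(np.sqrt((d ** 2).sum(axis=1).mean()))

    step = np.radians(grid_step_deg)
    best = None
    for a in np.arange(0, 2 * np.pi, step):
        for b in np.arange(0, np.pi + 1e-9, step):
            for c in np.arange(0, 2 * np.pi, step):
                v = cost((a, b, c))
                if best is None or v < best[1]:
                    best = ((a, b, c), v)
    res = minimize(cost, best[0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    R = _euler_matrix(res.x)
    t = cq - R @ cp
    return R, t, float(res.fun)


def _oracle_collinear(points):
    if len(points) <= 2:
        return True
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[1] <= 1e-8 * max(1.0, s[0]))


def _oracle_clash(placed, exclusions):
    return any(np.any(np.linalg.norm(placed - s.center, axis=1) < s.radius)
               for s in exclusions)


def _axis_matrix(u, theta):
    """Rodrigues rotation about unit axis u by theta (radians)."""
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)


def brute_force_match(cgm, conf_features, heavy_coords):
    """Exhaustive re-derivation of the catalophore matching acceptance set.

    Returns {frozenset(correspondence items): rmsd} for every accepted
    injective kind-preserving correspondence, using the grid+simplex fit.
    A collinear matched set leaves the fit rotation free about the
    segment axis; the steric veto then holds only if every spin angle
    (1° scan) clashes, matching the matcher's existential contract.
    """
    by_kind_conf = {}
    for j, f in enumerate(conf_features):
        by_kind_conf.setdefault(f.kind, []).append(j)
    n = len(cgm.features)
    k_max = n if cgm.allow_full else n - 1
    accepted = {}
    for k in range(cgm.min_match, k_max + 1):
        for subset in itertools.combinations(range(n), k):
            kinds = [cgm.features[i].kind for i in subset]
            pools = [by_kind_conf.get(kind, []) for kind in kinds]
            for choice in itertools.product(*pools):
                if len(set(choice)) != len(choice):
                    continue
                mapping = dict(zip(subset, choice))
                P = np.array([conf_features[mapping[i]].position for i in subset])
                Q = np.array([cgm.features[i].position for i in subset])
                R, t, rmsd = brute_force_superpose(P, Q)
                fitted = P @ R.T + t
                if any(np.linalg.norm(fitted[r] - Q[r]) > cgm.features[i].tolerance
                       for r, i in enumerate(subset)):
                    continue
                if cgm.exclusions and len(heavy_coords):
                    if _oracle_collinear(P):
                        axis = fitted[-1] - fitted[0]
                        nrm = np.linalg.norm(axis)
                        if nrm < 1e-9:
                            if _oracle_clash(heavy_coords @ R.T + t, cgm.exclusions):
                                continue
                        else:
                            u = axis / nrm
                            ctr = fitted.mean(axis=0)
                            ok = False
                            for theta in np.radians(np.arange(0.0, 360.0, 1.0)):
                                S = _axis_matrix(u, theta)
                                placed = (heavy_coords @ (S @ R).T
                                          + ctr + S @ (t - ctr))
                                if not _oracle_clash(placed, cgm.exclusions):
                                    ok = True
                                    break
                            if not ok:
                                continue
                    elif _oracle_clash(heavy_coords @ R.T + t, cgm.exclusions):
                        continue
                accepted[frozenset(mapping.items())] = rmsd
    return accepted


def decimal_boltzmann_ee(records, T, R=Decimal("1.987204259e-3")):
    """ee%% from (stereo, G) pairs in 50-digit decimal arithmetic."""
    getcontext().prec = 50
    rt = R * Decimal(repr(T))
    gmin = min(Decimal(repr(g)) for _, g in records)
    ws = [(s, ((gmin - Decimal(repr(g))) / rt).exp()) for s, g in records]
    z = sum(w for _, w in ws)
    w_r = sum(w for s, w in ws if s == "R") / z
    w_s = sum(w for s, w in ws if s == "S") / z
    return float(100 * abs(w_r - w_s))
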