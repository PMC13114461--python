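"""Brute-force dense multivariate-normal likelihood oracle.

Assembles the full n x n marginal covariance from pairwise same-class /
same-student / same-school indicators (no per-block factorization, no code
shared with the engine's likelihood path beyond the theta unpacking) and
evaluates the profiled ML/REML log-likelihood by dense linear algebra.
"""

import numpy as np

from motorprof.cohort import Z_DOMAIN
from motorprof.lmm import _unpack_theta
from motorprof.scores import DOMAINS


def dense_v0(bundle, theta):
    spec = bundle.spec
    lam_c, lam_s, school = _unpack_theta(theta, spec)
    df = bundle.df
    n = len(df)
    dom = df["domain"].map({d: i for i, d in enumerate(DOMAINS)}).to_numpy()
    Z = Z_DOMAIN[dom]
    cls = df["class_id"].to_numpy()
    stu = df["child_id"].to_numpy()
    sch = df["school_id"].to_numpy()
    V = np.eye(n)
    V += (Z @ lam_s @ Z.T) * (stu[:, None] == stu[None, :])
    if spec.class_re == "full":
        V += (Z @ lam_c @ Z.T) * (cls[:, None] == cls[None, :])
    elif spec.class_re == "intercept":
        V += lam_c * (cls[:, None] == cls[None, :])
    if school is not None:
        V += school * (sch[:, None] == sch[None, :])
    return V


def oracle_loglik(bundle, theta, method):
    n, p = bundle.n_obs, bundle.p
    X, y = bundle.X, bundle.y
    V0 = dense_v0(bundle, theta)
    _, logdet = np.linalg.slogdet(V0)
    Vi = np.linalg.inv(V0)
    xtvx = X.T @ Vi @ X
    beta = np.linalg.solve(xtvx, X.T @ Vi @ y)
    r = y - X @ beta
    rss = r @ Vi @ r
    if method.upper() == "ML":
        s2 = rss / n
        return -0.5 * (n * (np.log(2 * np.pi) + 1 + np.log(s2)) + logdet)
    s2 = rss / (n - p)
    _, ld_xtvx = np.linalg.slogdet(xtvx)
    _, ld_xtx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * (np.log(2 * np.pi) + 1 + np.log(s2))
                   + logdet + ld_xtvx - ld_xtx)
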