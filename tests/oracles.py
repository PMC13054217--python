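"""Independent oracles used to cross-check the package's numerics.

Everything here is deliberately written without importing the package's
own estimation or enumeration code paths: a plain Newton-Raphson
logistic MLE, a brute-force wound-state counter working on raw strings,
and adaptive-quadrature marginalization of a random-intercept logistic
probability.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate


def logistic_mle(y, X, tol=1e-12, max_iter=200):
    """Maximum-likelihood logistic regression by Newton-Raphson."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    raise RuntimeError("logistic MLE did not converge")


# Raw attribute vocabularies, restated independently of the package enums.
_FIELDS = {
    "phase": ["acute", "chronic"],
    "depth": ["shallow", "deep"],
    "surface": ["intact_blister", "erosion_shallow_ulcer", "open_deep_ulcer"],
    "necrosis": ["none", "black_dry", "yellow_moist"],
    "infection": ["absent", "present"],
    "pocket": ["absent", "present_with_necrosis"],
    "granulation": ["not_applicable", "insufficient", "healthy_sufficient"],
    "exudate": ["minimal", "high"],
}


def _valid(rec: dict[str, str]) -> bool:
    if rec["phase"] == "acute":
        if (
            rec["depth"] != "shallow"
            or rec["necrosis"] != "none"
            or rec["pocket"] != "absent"
            or rec["granulation"] != "not_applicable"
        ):
            return False
    if rec["granulation"] != "not_applicable" and not (
        rec["phase"] == "chronic" and rec["depth"] == "deep"
    ):
        return False
    return True


def brute_force_states() -> list[dict[str, str]]:
    """All valid wound states as raw dicts, by cross-product filtering."""
    names = list(_FIELDS)
    out = []
    for combo in itertools.product(*(_FIELDS[n] for n in names)):
        rec = dict(zip(names, combo))
        if _valid(rec):
            out.append(rec)
    return out


def marginal_probability(p: float, sd: float) -> float:
    """E[expit(logit(p) + sd*U)], U ~ N(0,1), by adaptive quadrature."""
    base = math.log(p / (1.0 - p))

    def integrand(u):
        return (1.0 / (1.0 + np.exp(-(base + sd * u)))) * (
            np.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)
        )

    val, _ = integrate.quad(integrand, -12, 12, epsabs=1e-12, epsrel=1e-12)
    return val
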