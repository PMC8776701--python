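"""Gaussian-process Bayesian optimization over a rectangular box.

A compact sequential optimizer for expensive black-box objectives: after a
space-filling initial design, a Gaussian process surrogate (Matern 5/2 with
a white-noise term) is fit to the observed values and the next point is
chosen by maximizing expected improvement over a random candidate set.
Inputs are handled in the unit cube; callers map to their own (often
log-scaled) parameter box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel


@dataclass
class BayesOptResult:
    best_x: np.ndarray          # in the caller's box coordinates
    best_value: float
    xs: np.ndarray              # all evaluated points, box coordinates
    values: np.ndarray = field(default_factory=lambda: np.empty(0))


def maximize(
    objective,
    bounds: np.ndarray,
    n_calls: int = 30,
    n_initial: int = 10,
    rng: np.random.Generator | None = None,
    n_candidates: int = 256,
) -> BayesOptResult:
    """Maximize ``objective`` over the box ``bounds`` (shape (d, 2)).

    ``n_calls`` total evaluations, the first ``n_initial`` from a random
    uniform design.  Deterministic for a fixed ``rng``.
    """
    rng = np.random.default_rng() if rng is None else rng
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    span = bounds[:, 1] - bounds[:, 0]
    n_initial = min(n_initial, n_calls)

    def to_box(u: np.ndarray) -> np.ndarray:
        return bounds[:, 0] + u * span

    us = list(rng.uniform(size=(n_initial, d)))
    ys = [float(objective(to_box(u))) for u in us]

    # fixed, well-scaled kernel on the unit cube: the objective surfaces here
    # are smooth and a full marginal-likelihood fit per step is not worth it
    kernel = Matern(length_scale=0.3, nu=2.5) + WhiteKernel(noise_level=1e-3)
    gp = GaussianProcessRegressor(kernel=kernel, optimizer=None, normalize_y=True)

    while len(us) < n_calls:
        X = np.vstack(us)
        y = np.asarray(ys)
        gp.fit(X, y)
        cand = rng.uniform(size=(n_candidates, d))
        mu, sd = gp.predict(cand, return_std=True)
        sd = np.maximum(sd, 1e-12)
        best = y.max()
        z = (mu - best) / sd
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        nxt = cand[int(np.argmax(ei))]
        us.append(nxt)
        ys.append(float(objective(to_box(nxt))))

    ys_arr = np.asarray(ys)
    xs_arr = np.vstack([to_box(u) for u in us])
    i_best = int(np.argmax(ys_arr))
    return BayesOptResult(best_x=xs_arr[i_best], best_value=float(ys_arr[i_best]),
                          xs=xs_arr, values=ys_arr)
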