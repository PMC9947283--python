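"""Independent random-walk Metropolis sampler for validating the Gibbs fit.

Targets exactly ``exp(log_joint_density)`` restricted to the constraint
manifold by parameterising the model in free coordinates: the structured
effects u and ub through the positive eigenspace of the graph Laplacian,
v through an orthonormal basis of its doubly-constrained subspace, and
each standard deviation through its logarithm (with the Jacobian added
to the target).  Component-wise Gaussian proposals are scale-adapted
during burn-in only, so the post-burn-in chain is a valid sampler of the
same posterior the Gibbs scheme targets.  This module shares no sampling
code with :mod:`bstmort.model`'s Gibbs updates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import null_space

from . import panel_io
from .adjacency import AdjacencyGraph
from .model import McmcState, ModelConfig, _SD_NAMES, log_joint_density
from .panel_io import MortalityPanel

_EIG_TOL = 1e-9


class _FreeCoords:
    """Bijection between free coordinates and constrained model states."""

    def __init__(self, graph: AdjacencyGraph, n: int, T: int):
        lam, V = np.linalg.eigh(graph.laplacian())
        pos = lam > _EIG_TOL
        self.Vu = V[:, pos]
        self.rank = int(pos.sum())
        cols = np.arange(T, dtype=float)
        tt = cols - cols.mean()
        A = np.vstack([np.ones(T), tt])
        self.Bv = null_space(A)  # T x (T-2), orthonormal
        self.n, self.T = n, T
        self.dim = 2 + self.rank + n + self.rank + n + (T - 2) + 6
        self.slices = {}
        k = 0
        for name, d in (("alpha", 1), ("b0", 1), ("zu", self.rank), ("nu", n),
                        ("zub", self.rank), ("nub", n), ("zv", T - 2), ("logsd", 6)):
            self.slices[name] = slice(k, k + d)
            k += d

    def to_state(self, x: np.ndarray) -> McmcState:
        g = lambda name: x[self.slices[name]]
        sds = np.exp(g("logsd"))
        return McmcState(
            alpha=float(g("alpha")[0]), b0=float(g("b0")[0]),
            u=self.Vu @ g("zu"), nu=g("nu").copy(),
            ub=self.Vu @ g("zub"), nub=g("nub").copy(),
            v=self.Bv @ g("zv"),
            **{name: float(s) for name, s in zip(_SD_NAMES, sds)})

    def from_state(self, state: McmcState) -> np.ndarray:
        x = np.empty(self.dim)
        x[self.slices["alpha"]] = state.alpha
        x[self.slices["b0"]] = state.b0
        x[self.slices["zu"]] = self.Vu.T @ state.u
        x[self.slices["nu"]] = state.nu
        x[self.slices["zub"]] = self.Vu.T @ state.ub
        x[self.slices["nub"]] = state.nub
        x[self.slices["zv"]] = self.Bv.T @ state.v
        x[self.slices["logsd"]] = [math.log(getattr(state, s)) for s in _SD_NAMES]
        return x


def fit_metropolis_reference(panel: MortalityPanel, graph: AdjacencyGraph,
                             config: ModelConfig, n_iter: int = 40000,
                             n_burnin: int = 8000, seed: int = 0) -> dict:
    """Run the oracle sampler; returns post-burn-in draws of alpha and b0.

    ``n_iter`` counts full sweeps (one proposal per coordinate per sweep).
    Returns a dict with ``alpha``/``b0`` draw arrays and the final
    per-coordinate acceptance rates.
    """
    Y = panel_io.log_matrix(panel)
    n, T = Y.shape
    fc = _FreeCoords(graph, n, T)
    rng = np.random.default_rng(seed)

    def target(x: np.ndarray) -> float:
        st = fc.to_state(x)
        return log_joint_density(st, Y, graph, config) + float(np.sum(x[fc.slices["logsd"]]))

    # start from a rough data-driven state
    cols = np.arange(T, dtype=float)
    tt = cols - cols.mean()
    b0 = float((Y.mean(axis=0) @ tt) / (tt @ tt))
    alpha = float(Y.mean())
    resid_sd = max(float(np.std(Y - alpha - b0 * tt[None, :])), 1e-3)
    state0 = McmcState(alpha=alpha, b0=b0, u=np.zeros(n), nu=np.zeros(n),
                       ub=np.zeros(n), nub=np.zeros(n), v=np.zeros(T),
                       sigma_u=0.1, sigma_nu=0.1, sigma_ub=0.05, sigma_nub=0.05,
                       sigma_v=0.1, sigma_eps=resid_sd)
    x = fc.from_state(state0)
    lp = target(x)

    scales = np.full(fc.dim, 0.2)
    accepted = np.zeros(fc.dim)
    window = np.zeros(fc.dim)
    alpha_draws = np.empty(n_iter - n_burnin)
    b0_draws = np.empty(n_iter - n_burnin)

    ia, ib = fc.slices["alpha"].start, fc.slices["b0"].start
    for it in range(n_iter):
        order = rng.permutation(fc.dim)
        for j in order:
            prop = x.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_prop = target(prop)
            if math.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted[j] += 1
                window[j] += 1
        if it < n_burnin and (it + 1) % 50 == 0:
            rate = window / 50.0
            scales[rate > 0.5] *= 1.4
            scales[rate < 0.3] /= 1.4
            window[:] = 0.0
        if it >= n_burnin:
            alpha_draws[it - n_burnin] = x[ia]
            b0_draws[it - n_burnin] = x[ib]
    return {"alpha": alpha_draws, "b0": b0_draws,
            "acceptance": accepted / n_iter}


def batch_means_se(x: np.ndarray, n_batches: int = 10) -> float:
    """Monte-Carlo standard error of the mean by the batch-means method.

    Few, long batches: batch means must be nearly uncorrelated for the
    estimate to be honest, and MCMC output can carry long autocorrelation.
    """
    x = np.asarray(x, dtype=float)
    n = len(x) // n_batches * n_batches
    batches = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / math.sqrt(n_batches))
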