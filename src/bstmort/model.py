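"""Bayesian spatiotemporal decomposition of log-mortality panels.

The observation model for the log rate of country i in year t is

    ln y_it ~ Normal(mu_it, sigma_eps^2)
    mu_it = alpha + s_i + b0*t~ + v_t + b1i*t~

with t~ the midpoint-centred year, s_i = u_i + nu_i and
b1i = ub_i + nub_i convolutions (BYM) of an intrinsic-CAR structured
part and an iid unstructured part, and v_t a common nonlinear temporal
effect.  Priors: N(0, 1000) on alpha and b0, half-normal (variance 10)
on every random-effect standard deviation.

Identifiability constraints: u and ub sum to zero within each connected
component of the adjacency graph (island countries have both pinned at
0), and v satisfies sum(v) = 0 and sum(t~ * v) = 0 so that alpha carries
the level and b0 the global linear trend.

The sampler is a Gibbs scheme.  All Gaussian blocks have closed-form
full conditionals; u and ub are drawn jointly in the positive eigenspace
of the graph Laplacian, which is an exact draw from the constrained full
conditional (the restriction of the joint posterior to the constraint
manifold).  Standard deviations get univariate slice updates on the log
scale.  Every update leaves exp(log_joint_density) restricted to the
constraint manifold invariant, so an independent sampler targeting the
same density is a valid oracle.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import panel_io
from ._slice import slice_sample
from .adjacency import AdjacencyGraph
from .panel_io import MortalityPanel
from .reporting import TrendSummary, classify_trend

_EIG_TOL = 1e-9
_CONSTRAINT_TOL = 1e-8
_LOG_SD_LO, _LOG_SD_HI = -15.0, 5.0  # numerical guard for slice updates

_SD_NAMES = ("sigma_u", "sigma_nu", "sigma_ub", "sigma_nub", "sigma_v", "sigma_eps")


@dataclass
class ModelConfig:
    """Priors, MCMC schedule and seeds.

    The default schedule (2 chains of 200,000 iterations, 180,000
    burn-in, thinning 10) is the full-run protocol; `desk_scale` gives
    the short schedule used throughout the test suite.
    """

    n_chains: int = 2
    n_iter: int = 200_000
    n_burnin: int = 180_000
    thin: int = 10
    prior_sd_fixed: float = math.sqrt(1000.0)
    halfnormal_variance: float = 10.0
    time_centering: str = "midpoint"
    seeds: tuple[int, ...] | None = None
    bgr_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_sd_fixed <= 0 or self.halfnormal_variance <= 0:
            raise ValueError("prior variances must be positive")
        if self.time_centering != "midpoint":
            raise ValueError("only midpoint time centering is supported")
        if self.seeds is not None:
            self.seeds = tuple(int(s) for s in self.seeds)
            if len(self.seeds) != self.n_chains:
                raise ValueError("need one seed per chain")

    def chain_seeds(self) -> tuple[int, ...]:
        if self.seeds is not None:
            return self.seeds
        return tuple(range(1, self.n_chains + 1))

    @classmethod
    def desk_scale(cls, **kwargs) -> "ModelConfig":
        """Short schedule: 2 chains x 4,000 iterations, 2,000 burn-in, thin 2."""
        defaults = dict(n_iter=4000, n_burnin=2000, thin=2)
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class McmcState:
    alpha: float
    b0: float
    u: np.ndarray
    nu: np.ndarray
    ub: np.ndarray
    nub: np.ndarray
    v: np.ndarray
    sigma_u: float
    sigma_nu: float
    sigma_ub: float
    sigma_nub: float
    sigma_v: float
    sigma_eps: float


@dataclass
class PosteriorSamples:
    """Retained post-burn-in, thinned draws, kept per chain."""

    alpha: np.ndarray      # chains x draws
    b0: np.ndarray
    u: np.ndarray          # chains x draws x countries
    nu: np.ndarray
    ub: np.ndarray
    nub: np.ndarray
    v: np.ndarray          # chains x draws x years
    sigma_u: np.ndarray
    sigma_nu: np.ndarray
    sigma_ub: np.ndarray
    sigma_nub: np.ndarray
    sigma_v: np.ndarray
    sigma_eps: np.ndarray
    countries: list[str]
    years: list[int]
    metadata: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def parameter_dict(self) -> dict[str, np.ndarray]:
        """Every scalar parameter as a name -> chains x draws array."""
        out: dict[str, np.ndarray] = {"alpha": self.alpha, "b0": self.b0}
        for name in _SD_NAMES:
            out[name] = getattr(self, name)
        for k, c in enumerate(self.countries):
            out[f"u[{c}]"] = self.u[:, :, k]
            out[f"nu[{c}]"] = self.nu[:, :, k]
            out[f"ub[{c}]"] = self.ub[:, :, k]
            out[f"nub[{c}]"] = self.nub[:, :, k]
        for j, y in enumerate(self.years):
            out[f"v[{y}]"] = self.v[:, :, j]
        return out


class _Problem:
    """Precomputed fixed structure for one model fit."""

    def __init__(self, Y: np.ndarray, graph: AdjacencyGraph, years: list[int]):
        self.Y = Y
        self.n, self.T = Y.shape
        self.N = self.n * self.T
        yrs = np.asarray(years, dtype=float)
        self.tt = yrs - yrs.mean()
        self.st2 = float(self.tt @ self.tt)
        self.L = graph.laplacian()
        lam, V = np.linalg.eigh(self.L)
        pos = lam > _EIG_TOL
        self.lam_pos = lam[pos]
        self.V_pos = V[:, pos]
        self.rank = int(pos.sum())  # non-island nodes minus number of components
        if self.T < 3:
            raise ValueError("at least 3 years are required (v has two constraints)")


def icar_full_conditional(node: int, values: np.ndarray, graph: AdjacencyGraph,
                          sigma: float) -> tuple[float, float]:
    """Full conditional of one iCAR component given the others.

    Mean is the average of the node's neighbour values, variance
    sigma^2 / m_i.  Errors on isolated nodes: the caller must apply the
    island rule (effect pinned at 0) instead.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    nb = graph.neighbors[node]
    m = len(nb)
    if m == 0:
        raise ValueError(
            f"node {graph.node_ids[node]} has no neighbours; "
            "the iCAR full conditional is undefined (apply the island rule)")
    values = np.asarray(values, dtype=float)
    return float(values[nb].mean()), float(sigma ** 2 / m)


def _graph_structure(graph: AdjacencyGraph) -> dict:
    """Laplacian, its rank and components, cached on the graph instance."""
    cached = getattr(graph, "_bst_structure", None)
    if cached is None:
        from .adjacency import connected_components
        L = graph.laplacian()
        rank = int(np.sum(np.linalg.eigvalsh(L) > _EIG_TOL))
        cached = {"L": L, "rank": rank,
                  "components": [sorted(c) for c in connected_components(graph)]}
        graph._bst_structure = cached
    return cached


def _check_constraints(state: McmcState, graph: AdjacencyGraph,
                       tt: np.ndarray) -> None:
    for idx in _graph_structure(graph)["components"]:
        if len(idx) == 1:
            if abs(state.u[idx[0]]) > _CONSTRAINT_TOL or abs(state.ub[idx[0]]) > _CONSTRAINT_TOL:
                raise ValueError("island structured effects must be 0")
        else:
            if abs(float(np.sum(state.u[idx]))) > _CONSTRAINT_TOL:
                raise ValueError("u violates per-component sum-to-zero")
            if abs(float(np.sum(state.ub[idx]))) > _CONSTRAINT_TOL:
                raise ValueError("ub violates per-component sum-to-zero")
    if abs(float(np.sum(state.v))) > _CONSTRAINT_TOL:
        raise ValueError("v violates sum-to-zero")
    if abs(float(state.v @ tt)) > _CONSTRAINT_TOL:
        raise ValueError("v violates orthogonality to the time covariate")


def log_joint_density(state: McmcState, log_rates: np.ndarray,
                      graph: AdjacencyGraph, config: ModelConfig) -> float:
    """Unnormalised log posterior on the constraint manifold.

    Additive constants independent of the state are dropped, but every
    sd-dependent normalisation carries the dimension of the subspace the
    corresponding block actually lives on: rank(D-W) for u and ub, T-2
    for the doubly-constrained v.  States violating the constraints are
    rejected with an error.
    """
    Y = np.asarray(log_rates, dtype=float)
    n, T = Y.shape
    cols = np.arange(T, dtype=float)
    tt = cols - cols.mean()  # consecutive years: identical to year - mean(year)
    _check_constraints(state, graph, tt)
    for name in _SD_NAMES:
        if getattr(state, name) <= 0:
            raise ValueError(f"{name} must be positive")
    structure = _graph_structure(graph)
    L, rank = structure["L"], structure["rank"]

    s = state.u + state.nu
    b1 = state.ub + state.nub
    mu = state.alpha + s[:, None] + np.outer(state.b0 + b1, tt) + state.v[None, :]
    resid = Y - mu
    lp = -n * T * math.log(state.sigma_eps) - float(np.sum(resid ** 2)) / (2 * state.sigma_eps ** 2)

    lp += -rank * math.log(state.sigma_u) - float(state.u @ L @ state.u) / (2 * state.sigma_u ** 2)
    lp += -rank * math.log(state.sigma_ub) - float(state.ub @ L @ state.ub) / (2 * state.sigma_ub ** 2)
    lp += -n * math.log(state.sigma_nu) - float(state.nu @ state.nu) / (2 * state.sigma_nu ** 2)
    lp += -n * math.log(state.sigma_nub) - float(state.nub @ state.nub) / (2 * state.sigma_nub ** 2)
    lp += -(T - 2) * math.log(state.sigma_v) - float(state.v @ state.v) / (2 * state.sigma_v ** 2)

    pv = config.prior_sd_fixed ** 2
    lp += -(state.alpha ** 2 + state.b0 ** 2) / (2 * pv)
    hv = config.halfnormal_variance
    for name in _SD_NAMES:
        lp += -getattr(state, name) ** 2 / (2 * hv)
    return float(lp)


def _init_state(prob: _Problem, rng: np.random.Generator) -> McmcState:
    colmeans = prob.Y.mean(axis=0)
    b0 = float((colmeans @ prob.tt) / prob.st2) + 0.01 * rng.standard_normal()
    alpha = float(prob.Y.mean()) + 0.1 * rng.standard_normal()
    resid_sd = float(np.std(prob.Y - alpha - b0 * prob.tt[None, :]))
    sds = {name: 0.1 * math.exp(0.3 * rng.standard_normal()) for name in _SD_NAMES}
    sds["sigma_eps"] = max(resid_sd, 1e-3) * math.exp(0.3 * rng.standard_normal())
    return McmcState(alpha=alpha, b0=b0,
                     u=np.zeros(prob.n), nu=np.zeros(prob.n),
                     ub=np.zeros(prob.n), nub=np.zeros(prob.n),
                     v=np.zeros(prob.T), **sds)


def _sd_logpost(k: int, q: float, hn_var: float):
    """Log density of log(sd) given dimension k and quadratic form q."""
    def f(ls: float) -> float:
        return (-k * ls - q * math.exp(-2.0 * ls) / 2.0
                - math.exp(2.0 * ls) / (2.0 * hn_var) + ls)
    return f


def _sweep(state: McmcState, prob: _Problem, config: ModelConfig,
           rng: np.random.Generator) -> None:
    Y, tt, n, T = prob.Y, prob.tt, prob.n, prob.T
    st2, N = prob.st2, prob.N
    se2 = state.sigma_eps ** 2
    prior_prec_fixed = 1.0 / config.prior_sd_fixed ** 2
    hv = config.halfnormal_variance

    s = state.u + state.nu
    b1 = state.ub + state.nub

    # alpha
    r = Y - s[:, None] - np.outer(state.b0 + b1, tt) - state.v[None, :]
    prec = N / se2 + prior_prec_fixed
    state.alpha = float(r.sum()) / se2 / prec + rng.standard_normal() / math.sqrt(prec)

    # b0
    r = Y - state.alpha - s[:, None] - np.outer(b1, tt) - state.v[None, :]
    prec = n * st2 / se2 + prior_prec_fixed
    state.b0 = float((r @ tt).sum()) / se2 / prec + rng.standard_normal() / math.sqrt(prec)

    # u: joint draw in the positive eigenspace of the Laplacian
    r = Y - state.alpha - state.nu[:, None] - np.outer(state.b0 + b1, tt) - state.v[None, :]
    b_lin = r.sum(axis=1) / se2
    q = prob.lam_pos / state.sigma_u ** 2 + T / se2
    z = (prob.V_pos.T @ b_lin) / q + rng.standard_normal(prob.rank) / np.sqrt(q)
    state.u = prob.V_pos @ z

    # nu
    r = Y - state.alpha - state.u[:, None] - np.outer(state.b0 + b1, tt) - state.v[None, :]
    prec = T / se2 + 1.0 / state.sigma_nu ** 2
    mean = r.sum(axis=1) / se2 / prec
    state.nu = mean + rng.standard_normal(n) / math.sqrt(prec)
    s = state.u + state.nu

    # ub: joint constrained draw
    r = Y - state.alpha - s[:, None] - np.outer(state.b0 + state.nub, tt) - state.v[None, :]
    b_lin = (r @ tt) / se2
    q = prob.lam_pos / state.sigma_ub ** 2 + st2 / se2
    z = (prob.V_pos.T @ b_lin) / q + rng.standard_normal(prob.rank) / np.sqrt(q)
    state.ub = prob.V_pos @ z

    # nub
    r = Y - state.alpha - s[:, None] - np.outer(state.b0 + state.ub, tt) - state.v[None, :]
    prec = st2 / se2 + 1.0 / state.sigma_nub ** 2
    mean = (r @ tt) / se2 / prec
    state.nub = mean + rng.standard_normal(n) / math.sqrt(prec)
    b1 = state.ub + state.nub

    # v: isotropic full conditional, projected onto the constraint subspace
    r = Y - state.alpha - s[:, None] - np.outer(state.b0 + b1, tt)
    prec = n / se2 + 1.0 / state.sigma_v ** 2
    draw = r.sum(axis=0) / se2 / prec + rng.standard_normal(T) / math.sqrt(prec)
    draw -= draw.mean()
    state.v = draw - (draw @ tt) / st2 * tt

    # standard deviations: slice updates on the log scale
    resid = Y - (state.alpha + s[:, None] + np.outer(state.b0 + b1, tt) + state.v[None, :])
    updates = (
        ("sigma_eps", N, float(np.sum(resid ** 2))),
        ("sigma_u", prob.rank, float(state.u @ prob.L @ state.u)),
        ("sigma_nu", n, float(state.nu @ state.nu)),
        ("sigma_ub", prob.rank, float(state.ub @ prob.L @ state.ub)),
        ("sigma_nub", n, float(state.nub @ state.nub)),
        ("sigma_v", T - 2, float(state.v @ state.v)),
    )
    for name, k, qf in updates:
        ls = slice_sample(_sd_logpost(k, qf, hv), math.log(getattr(state, name)),
                          rng, w=1.0, lo=_LOG_SD_LO, hi=_LOG_SD_HI)
        setattr(state, name, math.exp(ls))


def fit(panel: MortalityPanel, graph: AdjacencyGraph,
        config: ModelConfig | None = None) -> PosteriorSamples:
    """Fit the model by Gibbs sampling; deterministic given config seeds.

    The graph must already be bound to the panel's country order
    (see :func:`bstmort.adjacency.bind_order`).  Convergence is assessed
    with the BGR ratio; if more than 10% of parameters exceed the
    threshold the run completes but is flagged in ``metadata``.
    """
    config = config if config is not None else ModelConfig()
    if not panel.complete:
        raise ValueError("fit requires a complete panel")
    if graph.node_ids != panel.countries:
        raise ValueError(
            "graph nodes do not match panel countries in order; call bind_order first")
    Y = panel_io.log_matrix(panel)
    years = panel.years
    prob = _Problem(Y, graph, years)
    n_keep = (config.n_iter - config.n_burnin) // config.thin

    store = {name: np.empty((config.n_chains, n_keep)) for name in
             ("alpha", "b0", *_SD_NAMES)}
    for name, d in (("u", prob.n), ("nu", prob.n), ("ub", prob.n),
                    ("nub", prob.n), ("v", prob.T)):
        store[name] = np.empty((config.n_chains, n_keep, d))

    for c, seed in enumerate(config.chain_seeds()):
        rng = np.random.default_rng(seed)
        state = _init_state(prob, rng)
        kept = 0
        for it in range(config.n_iter):
            _sweep(state, prob, config, rng)
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                store["alpha"][c, kept] = state.alpha
                store["b0"][c, kept] = state.b0
                store["u"][c, kept] = state.u
                store["nu"][c, kept] = state.nu
                store["ub"][c, kept] = state.ub
                store["nub"][c, kept] = state.nub
                store["v"][c, kept] = state.v
                for name in _SD_NAMES:
                    store[name][c, kept] = getattr(state, name)
                kept += 1

    samples = PosteriorSamples(countries=list(panel.countries), years=list(years),
                               **store)
    meta = {"config": _config_dict(config), "indicator": panel.indicator}
    if config.n_chains >= 2:
        report = diag.convergence_report(samples, threshold=config.bgr_threshold)
        meta["fraction_above_threshold"] = report.fraction_above_threshold
        meta["converged"] = bool(report.fraction_above_threshold <= 0.10)
    samples.metadata = meta
    return samples


def posterior_summary(samples: PosteriorSamples, indicator: str | None = None,
                      class_tol: float = 1e-6) -> TrendSummary:
    """Pool chains and summarise the trend decomposition.

    Per-country posterior medians of s_i = u_i + nu_i, b1i = ub_i + nub_i
    and b0 + b1i (computed on per-draw sums), the global b0 median, and
    the v_t trajectory with central 95% intervals.
    """
    if samples.n_draws == 0:
        raise ValueError("empty posterior samples")
    nctry = len(samples.countries)
    s_draws = (samples.u + samples.nu).reshape(-1, nctry)
    b1_draws = (samples.ub + samples.nub).reshape(-1, nctry)
    b0_draws = samples.b0.reshape(-1)
    v_draws = samples.v.reshape(-1, len(samples.years))

    s_med = np.median(s_draws, axis=0)
    b1_med = np.median(b1_draws, axis=0)
    b0b1_med = np.median(b0_draws[:, None] + b1_draws, axis=0)
    b0_med = float(np.median(b0_draws))
    v_q = np.quantile(v_draws, [0.025, 0.5, 0.975], axis=0)
    classes = [classify_trend(b0_med, float(b), tol=class_tol) for b in b1_med]
    return TrendSummary(
        countries=list(samples.countries),
        s_i_median=s_med, b1i_median=b1_med, b0_plus_b1i_median=b0b1_med,
        trend_class=classes, b0_median=b0_med,
        years=list(samples.years),
        v_median=v_q[1], v_lower95=v_q[0], v_upper95=v_q[2],
        indicator=indicator or samples.metadata.get("indicator", "NMR"),
        metadata=dict(samples.metadata),
    )


def _config_dict(config: ModelConfig) -> dict:
    d = asdict(config)
    d["seeds"] = list(config.chain_seeds())
    return d


# ---------------------------------------------------------------------------
# on-disk representation of posterior samples (one CSV per parameter block)

def save_samples(samples: PosteriorSamples, out_dir: str | os.PathLike) -> None:
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    m, d = samples.n_chains, samples.n_draws
    chain = np.repeat(np.arange(m), d)
    draw = np.tile(np.arange(d), m)

    scalars = {"chain": chain, "draw": draw,
               "alpha": samples.alpha.reshape(-1), "b0": samples.b0.reshape(-1)}
    for name in _SD_NAMES:
        scalars[name] = getattr(samples, name).reshape(-1)
    _write_csv(pd.DataFrame(scalars), os.path.join(out_dir, "scalars.csv"))

    for block in ("u", "nu", "ub", "nub"):
        arr = getattr(samples, block).reshape(m * d, -1)
        df = pd.DataFrame(arr, columns=samples.countries)
        df.insert(0, "draw", draw)
        df.insert(0, "chain", chain)
        _write_csv(df, os.path.join(out_dir, f"{block}.csv"))

    dfv = pd.DataFrame(samples.v.reshape(m * d, -1),
                       columns=[str(y) for y in samples.years])
    dfv.insert(0, "draw", draw)
    dfv.insert(0, "chain", chain)
    _write_csv(dfv, os.path.join(out_dir, "v.csv"))

    meta = {"countries": samples.countries, "years": samples.years,
            "n_chains": m, "n_draws": d, "metadata": samples.metadata}
    panel_io._atomic_write_text(os.path.join(out_dir, "meta.json"),
                                json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _write_csv(df: pd.DataFrame, path: str) -> None:
    panel_io._atomic_write_text(path, df.to_csv(index=False))


def load_samples(samples_dir: str | os.PathLike) -> PosteriorSamples:
    samples_dir = os.fspath(samples_dir)
    with open(os.path.join(samples_dir, "meta.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    m, d = meta["n_chains"], meta["n_draws"]
    countries = [str(c) for c in meta["countries"]]
    years = [int(y) for y in meta["years"]]
    sc = pd.read_csv(os.path.join(samples_dir, "scalars.csv"), float_precision="round_trip")
    kw = {"alpha": sc["alpha"].to_numpy().reshape(m, d),
          "b0": sc["b0"].to_numpy().reshape(m, d)}
    for name in _SD_NAMES:
        kw[name] = sc[name].to_numpy().reshape(m, d)
    for block in ("u", "nu", "ub", "nub"):
        df = pd.read_csv(os.path.join(samples_dir, f"{block}.csv"), float_precision="round_trip")
        kw[block] = df[countries].to_numpy().reshape(m, d, len(countries))
    dfv = pd.read_csv(os.path.join(samples_dir, "v.csv"), float_precision="round_trip")
    kw["v"] = dfv[[str(y) for y in years]].to_numpy().reshape(m, d, len(years))
    return PosteriorSamples(countries=countries, years=years,
                            metadata=meta.get("metadata", {}), **kw)
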