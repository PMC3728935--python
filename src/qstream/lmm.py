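"""Bayesian (Gibbs) and REML inference for Gaussian linear mixed models.

The trait model is the standard variance-component LMM

    y = X beta + sum_r Z_r u_r + e,
    u_r ~ N(0, sigma2_r I),   e ~ N(0, sigma2_e I),

where the fixed design X holds the intercept and any of population, stream
and their interaction (treatment coding), and each random term r is a
grouping factor (family/cross, sire, dam, population, stream).  Priors are
flat (improper) on beta and scaled inverse-gamma with shape = scale = 1e-3
on every variance — the conventional "locally uninformative" choice for
animal-model software.

The Gibbs sampler alternates two blocks.  All location effects theta =
(beta, u_1, ..., u_k) are drawn jointly from their full conditional — the
mixed-model-equations (Henderson) form

    theta | variances, y ~ N(C^-1 W'y, sigma2_e C^-1),
    C = W'W + blockdiag(0_p, lambda_1 I, ..., lambda_k I),
    W = [X Z_1 ... Z_k],  lambda_r = sigma2_e / sigma2_r,

which avoids the slow mixing of separate beta/u updates when random factors
are nested within fixed ones.  The variances are then conjugate draws:

* sigma2_r | u_r   ~ InvGamma(a + q_r/2, b + u_r'u_r/2)
* sigma2_e | resid ~ InvGamma(a + n/2,  b + e'e/2)

REML estimates of the same models (direct numerical optimization of the
restricted log-likelihood over log-variances) serve as an independent
frequentist cross-check on the sampler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

logger = logging.getLogger("qstream")

__all__ = [
    "ModelSpec",
    "McmcSpec",
    "PosteriorChains",
    "HeritabilityPosterior",
    "RemlResult",
    "MODEL_PRESETS",
    "MCMC_PRESETS",
    "gibbs_fit",
    "reml_fit",
    "gelman_rubin",
    "gelman_rubin_quantile",
    "autocorr",
    "max_abs_autocorr",
    "estimate_h2",
]

# maps model-term names to phenotype-table columns
_FACTOR_COLUMNS = {
    "population": "population",
    "stream": "stream",
    "family": "cross_id",
    "sire": "sire_id",
    "dam": "dam_id",
}

_FIXED_TERMS = ("population", "stream", "population:stream")


@dataclass(frozen=True)
class ModelSpec:
    """Which terms are fixed and which are random; the intercept is always fixed."""

    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ("family",)
    response: str = "length"

    def __post_init__(self) -> None:
        for t in self.fixed:
            if t not in _FIXED_TERMS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random:
            if t not in _FACTOR_COLUMNS:
                raise ValueError(f"unknown random term {t!r}")
        both = set(self.fixed) & set(self.random)
        if both:
            raise ValueError(f"terms cannot be both fixed and random: {sorted(both)}")
        if not self.random:
            raise ValueError("at least one random term is required")


@dataclass(frozen=True)
class McmcSpec:
    """Chain bookkeeping: retained draws = n_chains * (n_iter - n_burnin) // thin."""

    n_chains: int = 4
    n_iter: int = 20_000
    n_burnin: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if min(self.n_chains, self.thin) < 1:
            raise ValueError("n_chains and thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain


# the full-scale regime: six chains of two million iterations, 40% burn-in,
# keep every 800th draw -> 6 x 1500 = 9000 retained
MCMC_PRESETS: dict[str, McmcSpec] = {
    "full": McmcSpec(n_chains=6, n_iter=2_000_000, n_burnin=800_000, thin=800),
    "desk": McmcSpec(n_chains=4, n_iter=20_000, n_burnin=5_000, thin=10),
    "smoke": McmcSpec(n_chains=2, n_iter=2_000, n_burnin=500, thin=5),
}

MODEL_PRESETS: dict[str, ModelSpec] = {
    # reaction norms: population/stream/interaction fixed, family random
    "M1": ModelSpec(fixed=_FIXED_TERMS, random=("family",)),
    # per-stream divergence: random population + family, intercept only
    "M2": ModelSpec(fixed=(), random=("population", "family")),
    # variance partitioning for ICC: all structure random
    "M_icc": ModelSpec(fixed=(), random=("population", "stream", "family")),
    # heritability, unique-pair design
    "M_h2_fullsib": ModelSpec(fixed=(), random=("population", "family")),
    # heritability, diallel design
    "M_h2_diallel": ModelSpec(fixed=(), random=("sire", "dam")),
}


@dataclass
class PosteriorChains:
    """Per-chain retained draws of fixed effects and variance components.

    ``draws`` has shape (n_chains, n_retained, n_params); fixed-effect
    parameters are named ``(Intercept)``, ``population[LEVEL]``, ... and
    variances ``sigma2_<term>`` plus ``sigma2_resid``.
    """

    param_names: list[str]
    draws: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws must be (n_chains, n_retained, n_params)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained_total(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def variance_names(self) -> list[str]:
        return [n for n in self.param_names if n.startswith("sigma2_")]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_retained)."""
        try:
            j = self.param_names.index(name)
        except ValueError:
            raise KeyError(name) from None
        return self.draws[:, :, j]

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated, shape (n_chains * n_retained,)."""
        return self.get(name).reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.flat(name).mean())

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.flat(name)))

    def to_dataframe(self) -> pd.DataFrame:
        c, d, p = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * d, p), columns=self.param_names)
        df.insert(0, "draw", np.tile(np.arange(d), c))
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: dict | None = None) -> "PosteriorChains":
        params = [c for c in df.columns if c not in ("chain", "draw")]
        chains = sorted(df["chain"].unique())
        arrs = [df.loc[df["chain"] == c, params].to_numpy(float) for c in chains]
        return cls(param_names=params, draws=np.stack(arrs), meta=meta or {})


@dataclass
class HeritabilityPosterior:
    """Draws of narrow-sense heritability, clipped to [0, 1]."""

    draws: np.ndarray  # (n_chains, n_retained)
    mode: str
    n_clipped: int

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1)

    def median(self) -> float:
        return float(np.median(self.draws))

    def clip_fraction(self) -> float:
        return self.n_clipped / self.draws.size


# ---------------------------------------------------------------------------
# design-matrix assembly


def _drop_degenerate(df: pd.DataFrame, model: ModelSpec) -> ModelSpec:
    """Remove terms whose factor has a single level in this subset (logged)."""

    def levels(term: str) -> int:
        return df[_FACTOR_COLUMNS[term]].nunique()

    fixed = []
    for t in model.fixed:
        parts = t.split(":")
        if all(levels(p) >= 2 for p in parts):
            fixed.append(t)
        else:
            logger.warning("dropping degenerate fixed term %r (single level)", t)
    random = []
    for t in model.random:
        if levels(t) >= 2:
            random.append(t)
        else:
            logger.warning("dropping degenerate random term %r (single level)", t)
    if not random:
        raise ValueError("no random term left after dropping degenerate factors")
    return ModelSpec(fixed=tuple(fixed), random=tuple(random), response=model.response)


def _fixed_matrix(df: pd.DataFrame, fixed: tuple[str, ...]):
    """Treatment-coded fixed design matrix with human-readable column names."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    factors: dict[str, list] = {}
    for term in ("population", "stream"):
        col = _FACTOR_COLUMNS[term]
        if col in df.columns:
            factors[term] = sorted(df[col].unique())
    for term in fixed:
        if ":" in term:
            a, b = term.split(":")
            for la in factors[a][1:]:
                for lb in factors[b][1:]:
                    ind = ((df[_FACTOR_COLUMNS[a]] == la)
                           & (df[_FACTOR_COLUMNS[b]] == lb)).to_numpy(float)
                    cols.append(ind)
                    names.append(f"{a}[{la}]:{b}[{lb}]")
        else:
            for level in factors[term][1:]:  # first level is the reference
                cols.append((df[_FACTOR_COLUMNS[term]] == level).to_numpy(float))
                names.append(f"{term}[{level}]")
    X = np.column_stack(cols)
    return X, names, factors


def _random_codes(df: pd.DataFrame, random: tuple[str, ...]):
    codes, sizes, level_names = [], [], []
    for term in random:
        col = _FACTOR_COLUMNS[term]
        if col not in df.columns:
            raise ValueError(f"table lacks column {col!r} needed for random term {term!r}")
        cats = pd.Categorical(df[col])
        codes.append(np.asarray(cats.codes, dtype=np.intp))
        sizes.append(len(cats.categories))
        level_names.append(list(cats.categories))
    return codes, sizes, level_names


# ---------------------------------------------------------------------------
# Gibbs sampler

_PRIOR_SHAPE = 1e-3
_PRIOR_SCALE = 1e-3


def gibbs_fit(table: pd.DataFrame, model: ModelSpec, mcmc: McmcSpec) -> PosteriorChains:
    """Sample the LMM posterior with a blocked Gibbs sampler.

    Chains are seeded from independent substreams of ``mcmc.seed`` (one
    ``SeedSequence`` child per chain) so runs are reproducible and chains are
    statistically independent.  Returns the retained (post-burn-in, thinned)
    draws of the fixed effects and all variance components.
    """
    if len(table) == 0:
        raise ValueError("empty phenotype table")
    y = table[model.response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")

    model = _drop_degenerate(table, model)
    X, fixed_names, factors = _fixed_matrix(table, model.fixed)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design (confounded factors)")
    codes, sizes, _ = _random_codes(table, model.random)
    k = len(codes)

    # W = [X | Z_1 ... Z_k]; Henderson's coefficient matrix is W'W plus the
    # per-term shrinkage lambda_r = s2e/s2r on the random diagonal blocks
    q = sum(sizes)
    W = np.zeros((n, p + q))
    W[:, :p] = X
    offs = []
    off = p
    for r in range(k):
        W[np.arange(n), off + codes[r]] = 1.0
        offs.append(off)
        off += sizes[r]
    WtW = W.T @ W
    Wty = W.T @ y
    lam_idx = np.concatenate(
        [np.full(sizes[r], r) for r in range(k)]
    )  # which term each random diagonal entry belongs to

    param_names = fixed_names + [f"sigma2_{t}" for t in model.random] + ["sigma2_resid"]
    n_params = len(param_names)
    retained = mcmc.retained_per_chain

    children = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    all_draws = np.empty((mcmc.n_chains, retained, n_params))

    var_y = float(np.var(y)) or 1.0
    diag_ix = np.arange(p, p + q)

    for c, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        # dispersed initial values: variances jittered around the sample variance
        s2e = var_y * math.exp(rng.uniform(-1, 1))
        s2r = np.array([var_y / (k + 1) * math.exp(rng.uniform(-1, 1)) for _ in range(k)])

        out = all_draws[c]
        idx = 0
        C = WtW.copy()
        for it in range(1, mcmc.n_iter + 1):
            # all location effects jointly | variances
            C[diag_ix, diag_ix] = WtW[diag_ix, diag_ix] + (s2e / s2r)[lam_idx]
            L = linalg.cholesky(C, lower=True)
            mean = linalg.cho_solve((L, True), Wty)
            z = rng.standard_normal(p + q)
            theta = mean + math.sqrt(s2e) * linalg.solve_triangular(L.T, z, lower=False)

            # variances | effects
            for r in range(k):
                u_r = theta[offs[r]:offs[r] + sizes[r]]
                s2r[r] = 1.0 / rng.gamma(
                    _PRIOR_SHAPE + sizes[r] / 2.0,
                    1.0 / (_PRIOR_SCALE + 0.5 * float(u_r @ u_r)),
                )
            e = y - W @ theta
            s2e = 1.0 / rng.gamma(
                _PRIOR_SHAPE + n / 2.0, 1.0 / (_PRIOR_SCALE + 0.5 * float(e @ e))
            )

            if it > mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                out[idx, :p] = theta[:p]
                out[idx, p:p + k] = s2r
                out[idx, p + k] = s2e
                idx += 1
        assert idx == retained

    meta = {
        "factors": factors,
        "model": {"fixed": list(model.fixed), "random": list(model.random)},
        "mcmc": {
            "n_chains": mcmc.n_chains,
            "n_iter": mcmc.n_iter,
            "n_burnin": mcmc.n_burnin,
            "thin": mcmc.thin,
            "seed": mcmc.seed,
        },
        "n_records": n,
    }
    return PosteriorChains(param_names=param_names, draws=all_draws, meta=meta)


# ---------------------------------------------------------------------------
# REML


@dataclass
class RemlResult:
    """REML point estimates: fixed effects and variance components."""

    fixed: dict[str, float]
    variances: dict[str, float]
    loglik: float
    converged: bool
    grad_norm: float


def _reml_neg2ll(theta, XtX, XtZ, ZtZ, Xty, Zty, yty, n, p, sizes):
    """-2 x restricted log-likelihood at log-variances theta (resid last).

    Uses the Woodbury identity so only q x q factorizations are needed:
    V = s2e I + Z G Z',  A = Z'Z + s2e G^-1,
    V^-1 = (I - Z A^-1 Z')/s2e,   log|V| = (n-q) log s2e + log|G| + log|A|.
    """
    s2 = np.exp(theta)
    s2e = s2[-1]
    g = np.repeat(s2[:-1], sizes)  # diagonal of G
    q = len(g)
    A = ZtZ + np.diag(s2e / g)
    try:
        cA = linalg.cho_factor(A)
    except linalg.LinAlgError:
        return 1e30
    logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
    logdetV = (n - q) * math.log(s2e) + np.sum(np.log(g)) + logdetA

    AinvZtX = linalg.cho_solve(cA, XtZ.T)
    AinvZty = linalg.cho_solve(cA, Zty)
    XtVX = (XtX - XtZ @ AinvZtX) / s2e
    XtVy = (Xty - XtZ @ AinvZty) / s2e
    ytVy = (yty - Zty @ AinvZty) / s2e
    try:
        cX = linalg.cho_factor(XtVX)
    except linalg.LinAlgError:
        return 1e30
    beta = linalg.cho_solve(cX, XtVy)
    logdetXtVX = 2.0 * np.sum(np.log(np.diag(cX[0])))
    quad = ytVy - XtVy @ beta
    return logdetV + logdetXtVX + quad


def reml_fit(table: pd.DataFrame, model: ModelSpec) -> RemlResult:
    """Restricted maximum likelihood fit of the same LMM.

    Directly minimizes -2 l_R over the log-variances with L-BFGS-B (Nelder-
    Mead fallback), then recovers GLS fixed effects at the optimum.
    """
    if len(table) == 0:
        raise ValueError("empty phenotype table")
    y = table[model.response].to_numpy(float)
    model = _drop_degenerate(table, model)
    X, fixed_names, _ = _fixed_matrix(table, model.fixed)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design (confounded factors)")
    codes, sizes, _ = _random_codes(table, model.random)
    k = len(codes)

    # concatenated indicator Z, assembled sparsely via bincount-style products
    q = sum(sizes)
    Z = np.zeros((n, q))
    off = 0
    for r in range(k):
        Z[np.arange(n), off + codes[r]] = 1.0
        off += sizes[r]

    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)
    args = (XtX, XtZ, ZtZ, Xty, Zty, yty, n, p, np.asarray(sizes))

    var_y = float(np.var(y)) or 1.0
    x0 = np.log(np.full(k + 1, var_y / (k + 1)))
    bounds = [(-30.0, math.log(var_y) + 10.0)] * (k + 1)
    res = optimize.minimize(_reml_neg2ll, x0, args=args, method="L-BFGS-B",
                            bounds=bounds, options={"ftol": 1e-14, "gtol": 1e-9})
    if not res.success:
        res2 = optimize.minimize(_reml_neg2ll, res.x, args=args, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
        if res2.fun <= res.fun:
            res = res2
    # the restricted likelihood is nearly flat in log sigma2 as a component
    # approaches zero; snap such components to the boundary when that does
    # not worsen the fit
    x = res.x.copy()
    for j in range(k):
        if x[j] < x[-1] - 6.0:  # component < ~2.5e-3 of the residual variance
            trial = x.copy()
            trial[j] = bounds[j][0]
            if _reml_neg2ll(trial, *args) <= res.fun + 1e-6:
                x = trial
    if not np.array_equal(x, res.x):
        res = optimize.minimize(_reml_neg2ll, x, args=args, method="L-BFGS-B",
                                bounds=bounds, options={"ftol": 1e-14, "gtol": 1e-9})
    grad = optimize.approx_fprime(res.x, _reml_neg2ll, 1e-6, *args)

    s2 = np.exp(res.x)
    s2e = s2[-1]
    g = np.repeat(s2[:-1], sizes)
    A = ZtZ + np.diag(s2e / g)
    cA = linalg.cho_factor(A)
    XtVX = (XtX - XtZ @ linalg.cho_solve(cA, XtZ.T)) / s2e
    XtVy = (Xty - XtZ @ linalg.cho_solve(cA, Zty)) / s2e
    beta = np.linalg.solve(XtVX, XtVy)

    variances = {f"sigma2_{t}": float(s2[r]) for r, t in enumerate(model.random)}
    variances["sigma2_resid"] = float(s2e)
    return RemlResult(
        fixed=dict(zip(fixed_names, map(float, beta))),
        variances=variances,
        loglik=-0.5 * float(res.fun),
        converged=bool(res.success or float(np.linalg.norm(grad)) < 1e-2),
        grad_norm=float(np.linalg.norm(grad)),
    )


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains: PosteriorChains | np.ndarray, parameter: str | None = None) -> float:
    """Classic potential-scale-reduction factor for one parameter.

    R-hat = sqrt(((n-1)/n W + B/n) / W) with W the mean within-chain variance
    and B/n the variance of the chain means.  Identical chains give a value
    just below 1; separated chains give values well above 1.2.
    """
    if isinstance(chains, PosteriorChains):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorChains input")
        x = chains.get(parameter)
    else:
        x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    m, n = x.shape
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else math.inf
    var_plus = (n - 1) / n * W + B_over_n
    return math.sqrt(var_plus / W)


def gelman_rubin_quantile(chains: PosteriorChains, q: float = 0.975) -> float:
    """Quantile (default 97.5%) of the PSRF across all model parameters."""
    stats = [gelman_rubin(chains, name) for name in chains.param_names]
    return float(np.quantile(stats, q))


def autocorr(chain: np.ndarray, lag: int = 1) -> float:
    """Sample autocorrelation of one chain at the given lag.

    Raises on constant chains (the correlation is undefined, and silently
    returning 0 would mask a degenerate sampler).
    """
    x = np.asarray(chain, dtype=float).reshape(-1)
    if lag < 1 or lag >= len(x):
        raise ValueError(f"lag must be in [1, len(chain)-1], got {lag}")
    if np.var(x) == 0.0:
        raise ValueError("autocorrelation undefined for a constant chain")
    a, b = x[:-lag], x[lag:]
    return float(np.corrcoef(a, b)[0, 1])


def max_abs_autocorr(chains: PosteriorChains, lag: int = 1) -> float:
    """Max |autocorrelation| of the retained draws over parameters and chains."""
    worst = 0.0
    for name in chains.param_names:
        x = chains.get(name)
        for c in range(x.shape[0]):
            if np.var(x[c]) == 0.0:
                continue  # e.g. a variance pinned at a bound; nothing to mix
            worst = max(worst, abs(autocorr(x[c], lag)))
    return worst


# ---------------------------------------------------------------------------
# heritability


def estimate_h2(chains: PosteriorChains, mode: str, family_factor: float = 2.0) -> HeritabilityPosterior:
    """Draw-wise narrow-sense heritability from the fitted variance components.

    fullsib: full-sib family variance holds half the additive variance, so
        h2 = family_factor * s2_family / (s2_family + s2_resid)  (factor 2 default;
        factor 1 treats the family variance as broad-sense V_A directly).
    diallel: V_A = 2 (s2_sire + s2_dam) and
        h2 = V_A / (s2_sire + s2_dam + s2_resid).

    A population variance term, if present, is excluded from the denominator:
    heritability is a within-population quantity.  Draws above 1 are clipped
    (possible because estimated family/parental variance can exceed its
    additive expectation) and the clip count is reported.
    """
    if mode == "fullsib":
        s2f = chains.get("sigma2_family")
        s2e = chains.get("sigma2_resid")
        h2 = family_factor * s2f / (s2f + s2e)
    elif mode == "diallel":
        try:
            s2s = chains.get("sigma2_sire")
            s2d = chains.get("sigma2_dam")
        except KeyError:
            raise ValueError("diallel mode requires sire and dam variance draws") from None
        s2e = chains.get("sigma2_resid")
        h2 = 2.0 * (s2s + s2d) / (s2s + s2d + s2e)
    else:
        raise ValueError(f"mode must be 'fullsib' or 'diallel', got {mode!r}")
    n_clipped = int(np.sum((h2 < 0) | (h2 > 1)))
    return HeritabilityPosterior(draws=np.clip(h2, 0.0, 1.0), mode=mode, n_clipped=n_clipped)
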