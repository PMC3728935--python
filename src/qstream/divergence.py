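"""Phenotypic divergence statistics: P_ST/Q_ST, F_ST comparison, ICC, reaction norms.

Q_ST measures standardized additive-genetic divergence among populations,

    Q_ST = sigma2_AB / (sigma2_AB + 2 sigma2_AW),

and is compared against neutral F_ST: credible mass well above F_ST implies
divergent selection, well below implies stabilizing selection.  When only
phenotypic variance components are available (common-garden data with low
survival), the Brommer proxy P_ST substitutes assumptions for the unknown
additive fractions:

    P_ST = c sigma2_B / (c sigma2_B + 2 h^2 sigma2_W),

where ``c`` is the assumed additive proportion of the between-population
variance and ``h^2`` the within-population narrow-sense heritability.  With
c = 1 and known additive components, P_ST equals Q_ST.

All posterior operations here act draw-wise on paired MCMC output, so the
resulting P_ST and ICC distributions are proper Monte-Carlo posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import HeritabilityPosterior, PosteriorChains

__all__ = [
    "PstConfig",
    "PstPosterior",
    "IccResult",
    "pst_from_components",
    "pst_posterior",
    "compare_to_fst",
    "icc",
    "reaction_norm_summary",
]


@dataclass(frozen=True)
class PstConfig:
    """Assumption knobs for the P_ST calculation.

    c: proportion of the between-population variance assumed additive
       (conventionally 1 in common-garden studies).
    h2: None to use the heritability posterior draw-wise, a scalar to fix it,
        or a sequence of scalars to sweep a sensitivity grid.
    fst_upper: the neutral reference — upper 95% quantile of F_ST from
        molecular markers (supplied, not estimated here).
    within: 'total' uses sigma2_family + sigma2_resid as the within-population
        phenotypic variance; 'residual' uses sigma2_resid alone.
    """

    c: float = 1.0
    h2: float | tuple[float, ...] | None = None
    fst_upper: float = 0.05
    within: str = "total"

    def __post_init__(self) -> None:
        if not (0.0 < self.c <= 1.0):
            raise ValueError(f"c must be in (0, 1], got {self.c}")
        if not (0.0 <= self.fst_upper < 1.0):
            raise ValueError(f"fst_upper must be in [0, 1), got {self.fst_upper}")
        if self.within not in ("total", "residual"):
            raise ValueError("within must be 'total' or 'residual'")


@dataclass
class PstPosterior:
    """Posterior distribution of P_ST for one rearing stream."""

    stream: str
    draws: np.ndarray
    median: float
    q025: float
    q975: float
    verdict: str
    c: float
    within: str

    def summary(self) -> dict:
        return {
            "stream": self.stream,
            "median": self.median,
            "q025": self.q025,
            "q975": self.q975,
            "verdict": self.verdict,
            "c": self.c,
            "within": self.within,
        }


@dataclass
class IccResult:
    """Draw-wise intraclass correlations (fraction of total variance per factor)."""

    components: dict[str, np.ndarray]
    medians: dict[str, float] = field(init=False)
    q025: dict[str, float] = field(init=False)
    q975: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.medians = {k: float(np.median(v)) for k, v in self.components.items()}
        self.q025 = {k: float(np.quantile(v, 0.025)) for k, v in self.components.items()}
        self.q975 = {k: float(np.quantile(v, 0.975)) for k, v in self.components.items()}

    def summary(self) -> dict:
        return {
            k: {"median": self.medians[k], "q025": self.q025[k], "q975": self.q975[k]}
            for k in self.components
        }


def pst_from_components(sigma2_B, sigma2_W, c: float = 1.0, h2: float = 1.0):
    """Evaluate P_ST = c*s2B / (c*s2B + 2*h2*s2W); vectorized over components.

    Undefined (raises) when both variances are zero anywhere.
    """
    sigma2_B = np.asarray(sigma2_B, dtype=float)
    sigma2_W = np.asarray(sigma2_W, dtype=float)
    if np.any(sigma2_B < 0) or np.any(sigma2_W < 0):
        raise ValueError("variance components must be non-negative")
    if np.any(np.asarray(c) <= 0) or np.any(np.asarray(h2) <= 0):
        raise ValueError("c and h2 must be positive")
    num = c * sigma2_B
    den = num + 2.0 * h2 * sigma2_W
    if np.any(den == 0):
        raise ValueError("P_ST undefined: between- and within-variance both zero")
    out = num / den
    return float(out) if out.ndim == 0 else out


def pst_posterior(
    stream_chains: PosteriorChains,
    h2: HeritabilityPosterior | float,
    config: PstConfig = PstConfig(),
    stream: str = "",
) -> PstPosterior:
    """Combine the per-stream divergence fit with a heritability posterior.

    ``stream_chains`` must come from a model with random population and
    family terms fit to one stream's records; per retained draw i,

        P_ST(i) = c*s2_pop(i) / (c*s2_pop(i) + 2*h2(i)*s2_W(i)),

    with h2 draws paired by index (valid when both fits used the same MCMC
    regime so the draw counts agree) and s2_W(i) = s2_family(i) +
    s2_resid(i) by default.
    """
    s2_pop = stream_chains.flat("sigma2_population")
    s2_resid = stream_chains.flat("sigma2_resid")
    if config.within == "total":
        s2_w = stream_chains.flat("sigma2_family") + s2_resid
    else:
        s2_w = s2_resid
    if isinstance(h2, HeritabilityPosterior):
        h2_draws = h2.flat()
        if h2_draws.shape != s2_pop.shape:
            raise ValueError(
                f"draw-count mismatch: {h2_draws.shape[0]} heritability draws vs "
                f"{s2_pop.shape[0]} divergence draws"
            )
    else:
        h2_draws = float(h2)
    draws = pst_from_components(s2_pop, s2_w, config.c, h2_draws)
    q025, med, q975 = np.quantile(draws, [0.025, 0.5, 0.975])
    verdict = compare_to_fst((q025, q975), config.fst_upper)
    return PstPosterior(
        stream=stream,
        draws=draws,
        median=float(med),
        q025=float(q025),
        q975=float(q975),
        verdict=verdict,
        c=config.c,
        within=config.within,
    )


def compare_to_fst(pst, fst_upper: float) -> str:
    """Classify a P_ST posterior against the neutral F_ST reference.

    divergent if the entire 95% interval lies above fst_upper, stabilizing if
    entirely below, neutral if the interval straddles it.
    """
    if isinstance(pst, PstPosterior):
        q025, q975 = pst.q025, pst.q975
    elif isinstance(pst, tuple) and len(pst) == 2:
        q025, q975 = pst
    else:
        draws = np.asarray(pst, dtype=float)
        q025, q975 = np.quantile(draws, [0.025, 0.975])
    if q025 > fst_upper:
        return "divergent"
    if q975 < fst_upper:
        return "stabilizing"
    return "neutral"


def icc(chains: PosteriorChains) -> IccResult:
    """Intraclass correlations from a variance-partitioning fit.

    For each retained draw, every variance component (each random factor plus
    the residual) is divided by the sum of all components, so the ICCs of one
    draw sum to one exactly.
    """
    names = [n for n in chains.param_names if n.startswith("sigma2_")]
    if len(names) < 2:
        raise ValueError("ICC needs at least one random term plus the residual")
    parts = {n.removeprefix("sigma2_"): chains.flat(n) for n in names}
    total = np.sum(list(parts.values()), axis=0)
    return IccResult(components={k: v / total for k, v in parts.items()})


def reaction_norm_summary(m1_chains: PosteriorChains):
    """Population-by-stream cell means with 95% credible intervals.

    Reconstructs each (population, stream) cell mean per draw from the
    fixed-effect draws of the reaction-norm model (population + stream +
    interaction), then summarizes.  Also returns a draw-wise parallelism
    ratio: the standard deviation of the interaction deviations of the
    reconstructed cell-mean matrix divided by the standard deviation of its
    population main-effect deviations.  Ratios near zero mean parallel
    reaction norms (divergence is consistent across streams).

    Returns ``(table, ratio_summary)`` where ``table`` is a DataFrame with
    columns population, stream, mean, q025, q975.
    """
    meta = m1_chains.meta
    pops = meta["factors"]["population"]
    streams = meta["factors"]["stream"]
    n_p, n_s = len(pops), len(streams)

    def coef(name: str) -> np.ndarray:
        if name in m1_chains.param_names:
            return m1_chains.flat(name)
        return np.zeros(m1_chains.n_retained_total)

    cells = np.empty((m1_chains.n_retained_total, n_p, n_s))
    intercept = m1_chains.flat("(Intercept)")
    for i, p in enumerate(pops):
        for j, s in enumerate(streams):
            cells[:, i, j] = (
                intercept
                + coef(f"population[{p}]")
                + coef(f"stream[{s}]")
                + coef(f"population[{p}]:stream[{s}]")
            )

    grand = cells.mean(axis=(1, 2), keepdims=True)
    pop_dev = cells.mean(axis=2, keepdims=True) - grand
    str_dev = cells.mean(axis=1, keepdims=True) - grand
    int_dev = cells - grand - pop_dev - str_dev
    sd_pop = pop_dev[:, :, 0].std(axis=1, ddof=1)
    sd_int = int_dev.reshape(cells.shape[0], -1).std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd_pop > 0, sd_int / sd_pop, np.nan)

    rows = []
    for i, p in enumerate(pops):
        for j, s in enumerate(streams):
            q025, med, q975 = np.quantile(cells[:, i, j], [0.025, 0.5, 0.975])
            rows.append(
                {"population": p, "stream": s, "mean": med, "q025": q025, "q975": q975}
            )
    table = pd.DataFrame(rows)
    ratio = ratio[~np.isnan(ratio)]
    ratio_summary = {
        "median": float(np.median(ratio)),
        "q025": float(np.quantile(ratio, 0.025)),
        "q975": float(np.quantile(ratio, 0.975)),
    }
    return table, ratio_summary
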