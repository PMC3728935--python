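"""End-to-end orchestration: simulate/load -> fit -> divergence/ICC/survival -> report.

A single :class:`RunConfig` (YAML/JSON) drives the whole analysis with one
root seed.  The seed is fanned out to named substreams (simulation, each
model fit, bootstrap) so each stage is individually reproducible.  The run
writes machine-readable outputs (JSON report, chain CSVs, TSV summaries) to
an output directory; a failed per-stream fit is logged and marked in the
report without aborting the other streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import design as dz
from . import io as qio
from . import lmm
from .divergence import PstConfig, pst_posterior, icc, reaction_norm_summary
from .simulate import SimulationParams, ground_truth, simulate_phenotypes, simulate_survival
from .survival import BootstrapSpec, bootstrap_survival

logger = logging.getLogger("qstream")

__all__ = ["RunConfig", "RunReport", "read_config", "run_pipeline"]


def _derive_seed(root: int, label: str) -> int:
    """Stable per-stage substream seed (root seed hashed with the stage label)."""
    h = hashlib.sha256(f"{root}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Validated run configuration (see ``read_config`` for the file format)."""

    experiment: int
    populations: list[dz.PopulationSpec]
    allocation: dict
    exclude: dict
    sim_params: SimulationParams | None
    phenotype_path: str | None
    survival_path: str | None
    model_mcmc: lmm.McmcSpec
    pst: PstConfig
    bootstrap: BootstrapSpec
    experimental_stream: str
    outdir: str
    seed: int
    h2_mode: str = "fullsib"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        errors: list[str] = []

        def need(key, default=None):
            if key not in doc and default is None:
                errors.append(f"missing config key {key!r}")
                return None
            return doc.get(key, default)

        experiment = need("experiment")
        pops_doc = need("populations") or []
        populations = []
        for p in pops_doc:
            try:
                populations.append(dz.PopulationSpec(**p))
            except (TypeError, ValueError) as exc:
                errors.append(f"bad population spec {p!r}: {exc}")
        allocation = need("allocation") or {}
        seed = int(doc.get("seed", 0))

        sim_doc = doc.get("simulation")
        sim_params = None
        if sim_doc is not None:
            sim_doc = dict(sim_doc)
            inter = {
                tuple(k.split(":", 1)): v
                for k, v in (sim_doc.pop("interaction_effects", {}) or {}).items()
            }
            try:
                sim_params = SimulationParams(
                    interaction_effects=inter,
                    seed=_derive_seed(seed, "simulate"),
                    **sim_doc,
                )
            except (TypeError, ValueError) as exc:
                errors.append(f"bad simulation params: {exc}")
        phenotype_path = doc.get("phenotypes")
        survival_path = doc.get("survival")
        if sim_doc is None and phenotype_path is None:
            errors.append("either 'simulation' or 'phenotypes' must be given")
        for key, path in (("phenotypes", phenotype_path), ("survival", survival_path)):
            if path is not None and not Path(path).exists():
                errors.append(f"{key} path does not exist: {path}")

        mcmc_doc = doc.get("mcmc", "desk")
        if isinstance(mcmc_doc, str):
            if mcmc_doc not in lmm.MCMC_PRESETS:
                errors.append(f"unknown MCMC preset {mcmc_doc!r}")
                mcmc = lmm.MCMC_PRESETS["desk"]
            else:
                mcmc = lmm.MCMC_PRESETS[mcmc_doc]
        else:
            try:
                mcmc = lmm.McmcSpec(**mcmc_doc)
            except (TypeError, ValueError) as exc:
                errors.append(f"bad MCMC spec: {exc}")
                mcmc = lmm.MCMC_PRESETS["desk"]

        try:
            pst = PstConfig(**doc.get("pst", {}))
        except (TypeError, ValueError) as exc:
            errors.append(f"bad pst config: {exc}")
            pst = PstConfig()
        boot_doc = dict(doc.get("bootstrap", {}))
        boot_doc.setdefault("seed", _derive_seed(seed, "bootstrap"))
        try:
            bootstrap = BootstrapSpec(**boot_doc)
        except (TypeError, ValueError) as exc:
            errors.append(f"bad bootstrap spec: {exc}")
            bootstrap = BootstrapSpec()

        if errors:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
        return cls(
            experiment=int(experiment),
            populations=populations,
            allocation=allocation,
            exclude=doc.get("exclude", {}) or {},
            sim_params=sim_params,
            phenotype_path=phenotype_path,
            survival_path=survival_path,
            model_mcmc=mcmc,
            pst=pst,
            bootstrap=bootstrap,
            experimental_stream=doc.get("experimental_stream", "EXP"),
            outdir=doc.get("outdir", "qstream-out"),
            seed=seed,
            h2_mode=doc.get("h2_mode", "diallel" if int(experiment or 1) == 2 else "fullsib"),
        )


def read_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    return RunConfig.from_dict(qio.load_structured(path))


@dataclass
class RunReport:
    """Aggregated outputs of one pipeline run."""

    pst: dict
    icc: dict
    reaction_norms: list[dict]
    parallelism: dict
    survival: dict
    diagnostics: dict
    provenance: dict
    ground_truth: dict | None = None
    failures: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pst": self.pst,
            "icc": self.icc,
            "reaction_norms": self.reaction_norms,
            "parallelism": self.parallelism,
            "survival": self.survival,
            "diagnostics": self.diagnostics,
            "provenance": self.provenance,
            "ground_truth": self.ground_truth,
            "failures": self.failures,
        }


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage of the analysis and write outputs to config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = config.seed

    design = dz.build_design(config.populations, config.experiment, seed=root)
    plan = dz.build_stocking(design, config.allocation, config.exclude or None)

    truth_block = None
    if config.sim_params is not None:
        logger.info("simulating phenotype and survival tables")
        phenotypes = simulate_phenotypes(design, plan, config.sim_params)
        survival_records = simulate_survival(plan, config.sim_params, design)
        gt = ground_truth(config.sim_params, c=config.pst.c, mode=config.h2_mode)
        truth_block = {
            "true_sigma2_B": gt.true_sigma2_B,
            "true_sigma2_W": gt.true_sigma2_W,
            "true_h2": gt.true_h2,
            "true_pst": gt.true_pst,
        }
        qio.write_phenotypes(phenotypes, outdir / "phenotypes.csv")
        qio.write_survival(survival_records, outdir / "survival.csv")
    else:
        phenotypes = qio.read_phenotypes(config.phenotype_path)
        survival_records = (
            qio.read_survival(config.survival_path) if config.survival_path else None
        )

    if config.h2_mode == "diallel":
        phenotypes = dz.attach_parents(phenotypes, design)

    failures: dict[str, str] = {}
    gr_stats: list[float] = []
    ac_stats: list[float] = []

    def fit(tag: str, table, model: lmm.ModelSpec):
        mcmc = lmm.McmcSpec(
            n_chains=config.model_mcmc.n_chains,
            n_iter=config.model_mcmc.n_iter,
            n_burnin=config.model_mcmc.n_burnin,
            thin=config.model_mcmc.thin,
            seed=_derive_seed(root, f"fit:{tag}"),
        )
        chains = lmm.gibbs_fit(table, model, mcmc)
        chains.to_dataframe().to_csv(outdir / f"chains_{tag}.csv", index=False)
        gr_stats.append(lmm.gelman_rubin_quantile(chains))
        ac_stats.append(lmm.max_abs_autocorr(chains))
        return chains

    # reaction-norm model on the full table
    logger.info("fitting reaction-norm model")
    m1 = fit("m1", phenotypes, lmm.MODEL_PRESETS["M1"])
    rn_table, parallelism = reaction_norm_summary(m1)

    # heritability from the experimental stream (lowest mortality)
    exp_table = phenotypes[phenotypes["stream"] == config.experimental_stream]
    h2_model = lmm.MODEL_PRESETS[
        "M_h2_diallel" if config.h2_mode == "diallel" else "M_h2_fullsib"
    ]
    logger.info("fitting heritability model on stream %s", config.experimental_stream)
    h2_chains = fit("h2", exp_table, h2_model)
    h2_post = lmm.estimate_h2(h2_chains, mode=config.h2_mode)

    # per-stream divergence fits
    pst_block: dict[str, dict] = {}
    for stream in sorted(phenotypes["stream"].unique()):
        sub = phenotypes[phenotypes["stream"] == stream]
        try:
            chains = fit(f"m2_{stream}", sub, lmm.MODEL_PRESETS["M2"])
            pst = pst_posterior(chains, config.pst.h2 if config.pst.h2 is not None
                                else h2_post, config.pst, stream=stream)
            pst_block[stream] = pst.summary()
        except Exception as exc:  # keep other streams alive
            logger.error("divergence fit failed for stream %s: %s", stream, exc)
            failures[f"m2_{stream}"] = str(exc)

    # variance partitioning
    logger.info("fitting variance-partitioning model")
    icc_chains = fit("icc", phenotypes, lmm.MODEL_PRESETS["M_icc"])
    icc_block = icc(icc_chains).summary()

    # survival bootstrap on natural streams only
    surv_block: dict = {}
    if survival_records is not None:
        natural = survival_records[
            survival_records["stream"] != config.experimental_stream
        ]
        if len(natural) and natural["n_recaptured"].sum() > 0:
            res = bootstrap_survival(natural, config.bootstrap)
            res.summary_table().to_csv(outdir / "survival_ci.tsv", sep="\t", index=False)
            res.pairwise_table().to_csv(outdir / "survival_pairwise.tsv", sep="\t", index=False)
            surv_block = {
                "cutoff": res.cutoff,
                "n_excluded": res.n_excluded,
                "populations": [
                    {
                        "population": p,
                        "stream": s,
                        "survival": res.estimates[(p, s)],
                        "q025": res.ci[(p, s)][0],
                        "q975": res.ci[(p, s)][1],
                    }
                    for (p, s) in sorted(res.replicates)
                ],
                "pairwise": [
                    {
                        "population_a": a,
                        "population_b": b,
                        "stream": s,
                        "difference": est,
                        "q025": lo,
                        "q975": hi,
                        "contains_zero": cz,
                    }
                    for (a, b, s), (est, lo, hi, cz) in sorted(res.pairwise.items())
                ],
            }
        else:
            failures["survival"] = "no recaptures in natural streams"

    rn_table.to_csv(outdir / "reaction_norms.tsv", sep="\t", index=False)

    config_digest = hashlib.sha256(
        json.dumps(
            {
                "experiment": config.experiment,
                "populations": [vars(p) for p in config.populations],
                "allocation": config.allocation,
                "seed": root,
            },
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()

    report = RunReport(
        pst=pst_block,
        icc=icc_block,
        reaction_norms=rn_table.to_dict(orient="records"),
        parallelism=parallelism,
        survival=surv_block,
        diagnostics={
            "gelman_rubin_q975": max(gr_stats) if gr_stats else None,
            "max_abs_autocorr": max(ac_stats) if ac_stats else None,
            "h2_median": h2_post.median(),
            "h2_clip_fraction": h2_post.clip_fraction(),
        },
        provenance={
            "config_sha256": config_digest,
            "seed": root,
            "package": "qstream 0.1.0",
        },
        ground_truth=truth_block,
        failures=failures,
    )
    payload = json.dumps(_round_floats(report.to_dict()), indent=2, sort_keys=True)
    (outdir / "report.json").write_text(payload + "\n")
    return report
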