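"""End-to-end analysis pipeline and its declarative configuration.

Stages: (optional) synthetic-data generation -> kinship/relatedness ->
network statistics with randomization nulls -> social relations model fit
-> goodness-of-fit and model ranking -> gift-count inference -> gift-game
accounting. Every stochastic stage consumes an explicit seed from the
configuration, so a full run is deterministic; outputs land in a run
directory together with a JSON manifest recording seeds and SHA-256 hashes
of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, gifts, networks, srm
from .io import (
    Roster,
    gift_summary,
    read_edges,
    read_gifts,
    read_kin,
    read_roster,
)
from .kinship import build_relatedness_matrix
from .synthetic import (
    CommunityConfig,
    GiftGameParams,
    SRMGenerativeParams,
    generate_community,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGE_SEEDS = ("simulate", "nulls", "srm", "predictive", "gifts")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to/from YAML.

    Either ``simulate`` holds the synthetic-community settings, or
    ``inputs`` maps the four table names (roster, kin, edges, gifts) to CSV
    paths. ``seeds`` must name a seed for every stochastic stage.
    """

    output_dir: str
    seeds: dict = field(default_factory=dict)
    simulate: dict | None = None
    inputs: dict | None = None
    n_rep: int = 1000
    srm_mcmc: dict = field(
        default_factory=lambda: {"iterations": 10_000, "burn_in": 2_000, "thin": 10}
    )
    gift_mcmc: dict = field(
        default_factory=lambda: {"n_walkers": 16, "n_steps": 800, "burn_in": 300}
    )
    n_predictive: int = 200
    gift_count_convention: str = "events"

    def __post_init__(self) -> None:
        missing = [s for s in STAGE_SEEDS if s not in self.seeds]
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either 'simulate' settings or 'inputs' paths")
        if self.simulate is not None and "simulate" in missing:
            raise ValueError("simulation requested but no 'simulate' seed given")
        needed = [s for s in missing if s != "simulate" or self.simulate is not None]
        if needed:
            raise ValueError(f"every stochastic stage needs a seed; missing: {needed}")
        for s, v in self.seeds.items():
            if not isinstance(v, int):
                raise ValueError(f"seed for stage {s!r} must be an integer, got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    from decimal import Decimal

    if isinstance(o, Decimal):
        return str(o)
    raise TypeError(f"cannot serialize {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _load_or_simulate(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        sim_cfg = dict(config.simulate)
        community = sim_cfg.pop("community", {})
        srm_gen = sim_cfg.pop("srm", {})
        gift_gen = sim_cfg.pop("gift_game", {})
        layer_coupling = sim_cfg.pop("layer_coupling", 0.0)
        cc = CommunityConfig(**{**community, "random_seed": config.seeds["simulate"]})
        dataset = generate_community(
            cc,
            SRMGenerativeParams(**srm_gen),
            GiftGameParams(**gift_gen),
            layer_coupling=layer_coupling,
        )
        datadir = outdir / "data"
        dataset.write(datadir)
        return (
            dataset.roster,
            dataset.kin_table,
            dataset.edge_table,
            dataset.gift_ledger,
        )
    paths = config.inputs
    roster = read_roster(paths["roster"])
    kin = read_kin(paths["kin"])
    edges = read_edges(paths["edges"], roster=roster)
    ledger = read_gifts(paths["gifts"])
    return roster, kin, edges, ledger


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    Any stage failure raises with the stage name; artifacts written by
    earlier stages are left in place for inspection.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    stage = "setup"
    try:
        stage = "data"
        roster, kin_table, edge_table, ledger = _load_or_simulate(config, outdir)

        stage = "kinship"
        rel = build_relatedness_matrix(roster, kin_table)
        rel.to_frame().to_csv(outdir / "relatedness.csv", index=False)

        stage = "network_stats"
        layer_names = sorted(edge_table["layer"].unique())
        layers = [
            networks.network_from_edge_table(edge_table, roster.ids, layer=name)
            for name in layer_names
        ]
        coop = networks.aggregate_layers(*layers)
        gift_net = networks.gift_network(ledger, roster.ids)
        named = [*layers, gift_net, coop]
        stats_rows = []
        null_rows = []
        null_seed = config.seeds["nulls"]
        for k, net in enumerate(named):
            rec = networks.edge_reciprocity(net)
            asrt = networks.siida_assortment(net, roster)
            stats_rows.append(
                {
                    "network": net.layer_name,
                    "n_nodes": net.n_nodes,
                    "n_edges": net.n_edges,
                    "reciprocity": rec,
                    "assortment": asrt,
                }
            )
            if net.layer_name != "cooperation":
                for stat_name, fn, extra in (
                    ("reciprocity", networks.edge_reciprocity, {}),
                    ("assortment", networks.siida_assortment, {"roster": roster}),
                ):
                    null = networks.random_network_null(
                        net, fn, n_rep=config.n_rep,
                        seed=null_seed + 7 * k + (0 if stat_name == "reciprocity" else 1),
                        **extra,
                    )
                    null_rows.append(
                        {
                            "network": net.layer_name,
                            "statistic": stat_name,
                            "observed": null.observed_value,
                            "null_mean": float(null.null_values.mean()),
                            "null_q025": float(np.quantile(null.null_values, 0.025)),
                            "null_q975": float(np.quantile(null.null_values, 0.975)),
                            "quantile": null.quantile,
                            "p_two_sided": null.p_two_sided,
                        }
                    )
        jac_rows = [
            {
                "network_a": a.layer_name,
                "network_b": b.layer_name,
                "jaccard": networks.jaccard(a, b),
            }
            for i, a in enumerate(named)
            for b in named[i + 1 :]
        ]
        report["network_stats"] = {
            "statistics": stats_rows,
            "nulls": null_rows,
            "jaccard": jac_rows,
            "interviewed_reciprocity": networks.interviewed_subgraph_reciprocity(
                coop, roster
            ),
        }
        pd.DataFrame(stats_rows).to_csv(outdir / "network_statistics.csv", index=False)
        pd.DataFrame(null_rows).to_csv(outdir / "null_distributions.csv", index=False)
        pd.DataFrame(jac_rows).to_csv(outdir / "jaccard.csv", index=False)

        stage = "srm"
        srm_settings = srm.MCMCSettings(seed=config.seeds["srm"], **config.srm_mcmc)
        data_full = srm.build_srm_data(coop, roster, rel, gift_network=gift_net)
        post = srm.fit_srm(data_full, mcmc=srm_settings)
        vp = srm.variance_partition(post)
        recip = srm.reciprocity_correlations(post)
        or_siida = srm.odds_ratio(
            post,
            contrast={"relatedness": 0.0, "same_siida": 1.0, "gift": 0.0, "interviewed": 1.0},
            reference={"relatedness": 0.0, "same_siida": 0.0, "gift": 0.0, "interviewed": 1.0},
        )
        report["srm"] = {
            "summary": post.summary(),
            "variance_partition": {
                k: v for k, v in vp.items() if k != "per_draw_shares"
            },
            "reciprocity": recip,
            "odds_ratio_same_siida": {
                k: v for k, v in or_siida.items() if k != "draws"
            },
        }
        pd.DataFrame(
            post.beta, columns=[f"beta_{c}" for c in post.covariate_names]
        ).assign(
            sigma2_g=post.sigma2_g, sigma2_r=post.sigma2_r,
            cor_gr=post.cor_gr, rho=post.rho,
        ).to_csv(outdir / "srm_draws.csv", index=False)
        curves = []
        grid = np.linspace(0.0, 0.5, 11)
        for same in (0, 1):
            for gift_flag in (0, 1):
                c = srm.predict_tie_probability(
                    post, grid, same_siida=same, gift=gift_flag,
                    extra={"interviewed": 1.0},
                )
                curves.append(
                    pd.DataFrame(
                        {
                            "relatedness": c["relatedness"],
                            "median": c["median"],
                            "lo95": c["lo95"],
                            "hi95": c["hi95"],
                            "same_siida": same,
                            "gift": gift_flag,
                        }
                    )
                )
        pd.concat(curves).to_csv(outdir / "srm_predicted_probabilities.csv", index=False)

        stage = "model_eval"
        pred_seed = config.seeds["predictive"]
        obs_stats = evaluation.gof_statistics(data_full.y)
        data_null = srm.SRMData(
            y=data_full.y,
            dyadic_covariates={},
            ego_covariates={"interviewed": data_full.ego_covariates["interviewed"]},
            node_ids=data_full.node_ids,
        )
        post_null = srm.fit_srm(data_null, mcmc=srm_settings)
        assessments = []
        for name, d, p in (
            ("additive", data_full, post),
            ("intercept_only", data_null, post_null),
        ):
            sims = srm.simulate_from_posterior(
                p, d, n_networks=config.n_predictive, seed=pred_seed
            )
            pred_stats = [evaluation.gof_statistics(s) for s in sims]
            rmse = evaluation.gof_rmse(obs_stats, pred_stats)
            scores = evaluation.classification_scores(p.tie_probability_mean, d.y)
            assessments.append(
                evaluation.ModelAssessment(
                    name=name,
                    rmse=rmse,
                    f1=scores["f1"],
                    accuracy=scores["accuracy"],
                    n_parameters=p.beta.shape[1],
                )
            )
        ranking = evaluation.rank_models(assessments)
        report["model_eval"] = {
            "observed_gof": {
                k: getattr(obs_stats, k) for k in evaluation.GOF_NAMES
            },
            "ranking": ranking,
        }
        _write_json(report["model_eval"], outdir / "model_comparison.json")

        stage = "gift_inference"
        indeg = networks.in_degree_vector(coop, roster)
        count_data = gifts.build_gift_count_data(
            indeg, ledger, roster, count=config.gift_count_convention
        )
        gift_mcmc = gifts.CountMCMC(seed=config.seeds["gifts"], **config.gift_mcmc)
        stack = gifts.stacking_weights(count_data, mcmc=gift_mcmc)
        best = stack.posteriors[stack.best_family()]
        grid = np.arange(0, max(int(count_data.x.max()), 1) + 1)
        curve = gifts.intervals(best, grid, seed=config.seeds["gifts"] + 1)
        report["gift_inference"] = {
            "stacking": {
                "families": stack.families,
                "weights": stack.weights.tolist(),
                "best": stack.best_family(),
            },
            "best_model_summary": best.summary(),
        }
        pd.DataFrame(curve).to_csv(outdir / "gift_intervals.csv", index=False)
        count_data.table.to_csv(outdir / "gift_counts.csv", index=False)

        stage = "gift_summary"
        report["gift_summary"] = {
            k: (str(v) if not isinstance(v, int) else v)
            for k, v in gift_summary(ledger).items()
        }

        stage = "manifest"
        _write_json(report, outdir / "report.json")
        artifacts = sorted(
            p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "seeds": dict(config.seeds),
            "config": config.to_dict(),
            "artifacts": {
                str(p.relative_to(outdir)): _sha256(p) for p in artifacts
            },
        }
        manifest["hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()
        ).hexdigest()
        _write_json(manifest, outdir / "manifest.json")
        report["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return report
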