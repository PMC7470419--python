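"""End-to-end orchestration: impute -> filter -> pseudotime -> network ->
rank -> integrate -> signature -> Cox evaluation, with deterministic
per-stage seeding and TSV outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .integration import (IntegrationWeights, integrate_scores,
                          normalize_scores, top_genes, tune_weights)
from .io_formats import (ExpressionMatrix, ValidationError, read_clinical,
                         read_expression, write_scores)
from .network import build_network
from .preprocess import ImputationParams, filter_genes, magic_impute
from .pseudotime import order_cells, vim_time, wanderlust_time
from .ranking import score_table
from .survival import (SurvivalDataset, c_index, cross_validate, fit_cox,
                       km_logrank, hazard_ratio, risk_score, stratify)

log = logging.getLogger("scprognosis")


@dataclass
class PipelineConfig:
    """Resolved parameters for a full run.

    A single global ``seed`` fans out to per-stage seeds through a stable
    stage-name hash, so each stage is independently reproducible. Desk-scale
    defaults (n_perm, cv_runs) are deliberately smaller than a full
    publication-scale protocol; both are plain flags.
    """

    # inputs
    sc_path: str | None = None
    bulk_path: str | None = None
    clinical_path: str | None = None
    out_dir: str = "."
    # global
    seed: int = 1
    log_level: str = "INFO"
    # preprocessing
    skip_impute: bool = False
    n_pca: int = 20
    k_impute: int = 30
    ka: int = 10
    t_diffusion: int = 6
    min_coverage: float = 0.1
    min_mean_expr: float | None = None
    # pseudotime
    pt_method: str = "wanderlust"
    marker_gene: str = "VIM"
    k_traj: int = 25
    l_traj: int = 15
    n_graphs: int = 20
    # network
    max_genes: int = 2000
    fdr: float = 0.05
    n_perm: int = 50
    # ranking / integration
    damping: float = 0.85
    sde_q_threshold: float = 0.05
    weights: tuple[float, float, float] | None = (1 / 3, 1 / 3, 1 / 3)
    tune: bool = False
    grid_step: float = 0.1
    n_candidates: tuple[int, ...] = (5, 10, 15, 20, 30, 50)
    top_n: int = 10
    # survival
    no_survival: bool = False
    cv_folds: int = 10
    cv_runs: int = 5
    ridge: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)

    def config_hash(self) -> str:
        # hash the analysis parameters, not where the outputs land
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    network_edges: pd.DataFrame
    pseudotime: pd.Series
    signature: list[str]
    model: pd.DataFrame | None
    risk: pd.DataFrame | None
    report: dict


def _header(config: PipelineConfig) -> list[str]:
    return [f"scprognosis {__version__} config_hash={config.config_hash()}"]


def run_pipeline(config: PipelineConfig,
                 sc: ExpressionMatrix | None = None,
                 bulk: SurvivalDataset | None = None) -> PipelineResult:
    """Execute the full pipeline; inputs may be in-memory or file paths.

    Writes scores.tsv, edges.tsv, pt.tsv, signature.txt and (with bulk data)
    model.tsv, risk.tsv and report.json under ``config.out_dir``, plus a
    manifest of the files produced so far; stage failures propagate with the
    stage name attached.
    """
    logging.basicConfig(level=config.log_level)
    log.info("resolved config: %s", dataclasses.asdict(config))
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: list[str] = []
    stage = "load"

    def emit(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        manifest.append(name)
        with open(os.path.join(config.out_dir, "manifest.txt"), "w") as fh:
            fh.write("\n".join(manifest) + "\n")
        return path

    try:
        if sc is None:
            if config.sc_path is None:
                raise ValidationError("no single-cell input given")
            sc = read_expression(config.sc_path)
        if bulk is None and not config.no_survival:
            if config.bulk_path is None or config.clinical_path is None:
                raise ValidationError(
                    "bulk expression and clinical paths are required unless "
                    "no_survival is set")
            bulk = SurvivalDataset(read_expression(config.bulk_path),
                                   read_clinical(config.clinical_path))

        stage = "impute"
        mat = sc
        if not config.skip_impute:
            mat = magic_impute(mat, ImputationParams(
                n_pca=config.n_pca, k=config.k_impute,
                ka=config.ka, t=config.t_diffusion))

        stage = "filter"
        mat = filter_genes(mat, config.min_coverage, config.min_mean_expr)

        stage = "pseudotime"
        if config.pt_method == "vim":
            pt = vim_time(mat, config.marker_gene)
        elif config.pt_method == "wanderlust":
            pt = wanderlust_time(mat, k=config.k_traj, l=config.l_traj,
                                 n_graphs=config.n_graphs,
                                 seed=config.stage_seed("pseudotime"),
                                 marker_gene=config.marker_gene)
        else:
            raise ValidationError(f"unknown pseudotime method {config.pt_method!r}")
        series = order_cells(mat, pt)
        pd.Series(pt.score, index=pt.cell_ids, name="score").to_csv(
            emit("pt.tsv"), sep="\t", index_label="cell")

        stage = "network"
        net = build_network(series, max_genes=config.max_genes, fdr=config.fdr,
                            n_perm=config.n_perm,
                            seed=config.stage_seed("network"))
        net.edges.to_csv(emit("edges.tsv"), sep="\t", index=False)

        stage = "rank"
        table = score_table(mat, pt, net,
                            sde_q_threshold=config.sde_q_threshold,
                            damping=config.damping,
                            seed=config.stage_seed("rank"))

        stage = "integrate"
        table = normalize_scores(table)
        if config.tune:
            if bulk is None:
                raise ValidationError("weight tuning requires bulk survival data")
            tuned = tune_weights(table, bulk, grid_step=config.grid_step,
                                 N_candidates=config.n_candidates,
                                 folds=config.cv_folds, runs=config.cv_runs,
                                 seed=config.stage_seed("tune"))
            weights, top_n = tuned.weights, tuned.N
        else:
            weights = IntegrationWeights(*config.weights)
            top_n = config.top_n
        table = integrate_scores(table, weights)
        write_scores(table.rename(columns={}), emit("scores.tsv"),
                     header_lines=_header(config))

        stage = "signature"
        if bulk is not None:
            shared = table.index[table.index.isin(bulk.expression.gene_ids)]
            signature = top_genes(table.loc[shared], top_n)
        else:
            signature = top_genes(table, top_n)
        with open(emit("signature.txt"), "w") as fh:
            fh.write("\n".join(signature) + "\n")

        model_df = risk_df = None
        report: dict = {"signature": signature, "weights": weights.as_tuple(),
                        "top_n": top_n}
        if bulk is not None and not config.no_survival:
            stage = "survival"
            model = fit_cox(bulk, signature, ridge=config.ridge)
            model_df = model.to_frame()
            model_df.to_csv(emit("model.tsv"), sep="\t")
            scores = risk_score(model, bulk.expression)
            groups = stratify(scores.to_numpy())
            risk_df = pd.DataFrame({"score": scores, "group": groups})
            risk_df.to_csv(emit("risk.tsv"), sep="\t", index_label="sample")
            hr, ci = hazard_ratio(groups, bulk.clinical)
            _, logrank_p = km_logrank(groups, bulk.clinical)
            cv = cross_validate(bulk, signature, folds=config.cv_folds,
                                runs=config.cv_runs,
                                seed=config.stage_seed("evaluate"),
                                ridge=config.ridge)
            report.update({
                "train_cindex": c_index(bulk.clinical.time, bulk.clinical.event,
                                        scores.to_numpy()),
                "cv_cindex": cv.mean_cindex,
                "cv_hr": cv.mean_hr,
                "hazard_ratio": hr,
                "hazard_ratio_ci95": list(ci),
                "logrank_p": logrank_p,
            })
            with open(emit("report.json"), "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)

        return PipelineResult(table, net.edges, pd.Series(pt.score, index=pt.cell_ids),
                              signature, model_df, risk_df, report)
    except Exception as exc:
        exc.args = (f"[stage: {stage}] {exc}",)
        raise
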