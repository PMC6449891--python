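"""End-to-end orchestration: cluster -> extend -> fuse -> structure -> evaluate.

The four stages run in order, every intermediate artifact (soft
memberships tau, confidence C, refined scores R, averaged network) is kept
and optionally persisted as self-describing TSV (headers record the stage
parameters and seed), and the whole run is reproducible from the seeds in
the configuration.

``mode="expression-only"`` runs the ablation used as a baseline: plain
mixture memberships, candidate ranking by co-membership alone, and a flat
(zero) structure prior — no protein-interaction evidence anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import bgm_structure as bgm
from . import ghmm_fusion as ghmm
from . import gmm_pathways as gmm
from . import ppin_extend as ppx
from .evaluation import EvaluationReport, evaluate_network
from .io_formats import (EdgeList, ExpressionMatrix, ScoredNetwork,
                         read_edge_list, read_expression, write_edge_list,
                         write_scores)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_files"]


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run."""

    L_max: int | None = None
    L_min: int = 1
    tol: float = 1e-6
    covariance_type: str = "diag"
    damping: float = 0.85
    c_cutoff: float = 0.5
    k: int = 5
    membership_cutoff: float = 0.1
    K_max: int = 5
    n_iter: int = 1000
    n_models: int = 10
    grn_threshold: float = 0.5
    seed: int = 0
    mode: str = "fused"  # "fused" | "expression-only"

    def __post_init__(self) -> None:
        if self.mode not in ("fused", "expression-only"):
            raise ValueError("mode must be 'fused' or 'expression-only'")
        for name in ("c_cutoff", "grn_threshold", "membership_cutoff"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class PipelineResult:
    """Artifacts of a full run; ``report`` is None without a reference network."""

    tau: gmm.MembershipMatrix
    G: ScoredNetwork
    C: ScoredNetwork | None
    R: ScoredNetwork
    averaged: ScoredNetwork
    grn: EdgeList
    report: EvaluationReport | None
    L_selected: int
    mml_value: float


def _stage_header(stage: str, cfg: PipelineConfig) -> str:
    return f"stage: {stage}\nconfig: {asdict(cfg)}"


def run_pipeline(
    expr: ExpressionMatrix,
    ppin: EdgeList | None,
    truth: EdgeList | None = None,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full fusion pipeline on in-memory inputs.

    ``ppin`` may be None only in expression-only mode.  With ``outdir``
    given, tau/C/R/grn artifacts are written there as TSV.
    """
    cfg = cfg or PipelineConfig()
    if cfg.mode == "fused" and ppin is None:
        raise ValueError("fused mode requires a protein-interaction network")

    try:
        if cfg.mode == "fused":
            # Stage 2: transitive extension and confidence scoring
            C = ppx.extend_ppin_scores(expr, ppin, damping=cfg.damping)
            n_ext = len(ppx.extend_ppin(C, cfg.c_cutoff))
            logger.info("stage extend: %d edges at C >= %.2f", n_ext, cfg.c_cutoff)
            # Stage 3: field-regularized pathway fit and refined scores
            params, tau, trace = ghmm.fit_ghmm(
                expr, ghmm.FieldPrior(C), L_max=cfg.L_max, L_min=cfg.L_min,
                seed=cfg.seed, tol=cfg.tol, covariance_type=cfg.covariance_type,
            )
            G = gmm.co_membership(tau)
            R = ghmm.refine_scores(G, C)
        else:
            # Stage 1 only: plain mixture; candidate ranking by co-membership
            C = None
            params, tau, trace = gmm.fit_gmm_cem(
                expr, L_max=cfg.L_max, L_min=cfg.L_min, seed=cfg.seed,
                tol=cfg.tol, covariance_type=cfg.covariance_type,
            )
            G = gmm.co_membership(tau)
            R = G
        L_sel, mml_val, _ = trace.best()
        logger.info("stage cluster (%s): L=%d, MML=%.3f", cfg.mode, L_sel, mml_val)
    except Exception as err:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline failed in clustering/extension stage: {err}") from err

    try:
        # Stage 4: constrained structure MCMC with model averaging
        mix = bgm.cluster_experiments(expr, K_max=min(cfg.K_max, expr.n_experiments),
                                      seed=cfg.seed)
        cands = bgm.parent_candidates(tau, R, k=cfg.k,
                                      membership_cutoff=cfg.membership_cutoff)
        prior = R if cfg.mode == "fused" else R.copy_with(
            np.zeros_like(R.scores), score_range=(0.0, 0.0))
        chains = bgm.run_chains(expr, mix, cands, prior,
                                n_models=cfg.n_models, n_iter=cfg.n_iter,
                                seed=cfg.seed)
        averaged = bgm.model_average(chains)
        grn = bgm.grn_edges(averaged, cfg.grn_threshold)
        rates = [c.acceptance_rate for c in chains]
        logger.info("stage bgm: %d chains, mean acceptance %.3f, %d edges at %.2f",
                    len(chains), float(np.mean(rates)), len(grn), cfg.grn_threshold)
    except Exception as err:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline failed in structure-learning stage: {err}") from err

    report = None
    if truth is not None:
        und = averaged.scores + averaged.scores.T
        und_net = ScoredNetwork(gene_ids=list(averaged.gene_ids),
                                scores=(und + und.T) / 2, symmetric=True,
                                score_range=(0.0, 1.0))
        report = evaluate_network(grn, truth, scores=und_net)
        logger.info("evaluation: %s", report.as_dict())

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(tau.tau, index=tau.gene_ids, columns=tau.pathway_ids).to_csv(
            outdir / "tau.tsv", sep="\t", float_format="%.12g")
        if C is not None:
            write_scores(C, outdir / "C.tsv")
        write_scores(R, outdir / "R.tsv")
        write_scores(averaged, outdir / "grn_confidence.tsv")
        write_edge_list(grn, outdir / "grn.tsv", header=_stage_header("grn", cfg))

    return PipelineResult(tau=tau, G=G, C=C, R=R, averaged=averaged, grn=grn,
                          report=report, L_selected=L_sel, mml_value=mml_val)


def run_pipeline_files(
    expr_path: str | Path,
    ppin_path: str | Path | None,
    truth_path: str | Path | None = None,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """File-based front end: load TSV inputs, run, persist artifacts."""
    expr = read_expression(expr_path)
    ppin = read_edge_list(ppin_path).restrict_to(expr.gene_ids) if ppin_path else None
    truth = read_edge_list(truth_path).restrict_to(expr.gene_ids) if truth_path else None
    return run_pipeline(expr, ppin, truth, cfg=cfg, outdir=outdir)
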