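"""End-to-end pipeline orchestration.

read -> QC -> log -> min-max -> latent spaces -> base ensemble -> initial
consensus -> silhouette direction -> BOFOA pruning -> final consensus ->
(optional) external metrics. Every stochastic stage derives its seed from
the single master seed in the config.
"""

from __future__ import annotations

import csv
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import ensemble as ens
from . import metrics as met
from . import objectives as obj
from . import pruning as pru
from .consensus import ConsensusPartition
from .consensus import consensus as _consensus
from .io import ExpressionMatrix, log_transform, minmax_normalize, qc_filter
from .latent import LatentSpaces, _child_seed, fit_latent_spaces

__all__ = ["RunConfig", "run_pipeline", "run_from_matrix", "write_outputs"]


@dataclass
class RunConfig:
    """All pipeline knobs with their working defaults.

    The optimizer constants (eps_direction=-0.6, alpha=13, max_fes=20,
    flies=9, T=10) are the framework's standard operating point; restarts
    defaults to 1 (independent optimizer restarts with averaged metrics are
    available via ``restarts``).
    """

    # input
    input_path: str | None = None
    input_format: str = "mtx_triplet"
    orientation: str = "cells_rows"
    truth_path: str | None = None
    # preprocessing
    do_qc: bool = True
    min_cells: int = 3
    min_features: int = 200
    max_mito_frac: float = 0.05
    mito_prefix: str = "MT-"
    do_log: bool = True
    do_minmax: bool = True
    # latent
    embedding_mode: str = "autoencoder"
    hidden_dim: int = 64
    latent_dim: int = 15
    n_keep: int = 5000
    d: int = 3
    epochs_nnkae: int = 30
    epochs_vae: int = 50
    beta_kl: float = 0.005
    # ensemble
    k: int | None = None
    k_range: tuple[int, int] | None = None
    T: int = 10
    base_method: str = "uspec"
    p: int | None = None
    K: int = 5
    mix_frac: float = 0.5
    resolution: float = 1.0
    knn: int = 15
    # pruning / consensus
    eps_direction: float = -0.6
    alpha: float = 13.0
    max_fes: int = 20
    flies: int = 9
    theta: float = 0.4
    restarts: int = 1
    # misc
    seed: int = 0
    outdir: str | None = None

    def to_json(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range) if self.k_range else None
        return d


def _preprocess(X: ExpressionMatrix, config: RunConfig):
    prov = []
    if config.do_qc:
        X = qc_filter(X, config.min_cells, config.min_features,
                      config.max_mito_frac, config.mito_prefix)
        prov.append(f"qc(min_cells={config.min_cells}, min_features={config.min_features})")
    if config.do_log:
        X = log_transform(X)
        prov.append("log1p")
    M = minmax_normalize(X, provenance=prov)
    return M


def run_from_matrix(
    X: ExpressionMatrix,
    config: RunConfig,
    truth: np.ndarray | None = None,
) -> tuple[ConsensusPartition, dict]:
    """Run the pipeline on an in-memory matrix; see :func:`run_pipeline`."""
    import numpy
    import depf

    report: dict = {
        "config": config.to_json(),
        "versions": {"depf": depf.__version__, "numpy": numpy.__version__},
        "stages": {},
    }
    t0 = time.time()

    M = _preprocess(X, config)
    report["stages"]["preprocess"] = {
        "n_cells": len(M.cell_ids), "n_genes": len(M.gene_ids),
        "provenance": M.provenance, "elapsed_s": round(time.time() - t0, 3),
    }

    t0 = time.time()
    Z = fit_latent_spaces(
        M, n_keep=config.n_keep, hidden_dim=config.hidden_dim,
        latent_dim=config.latent_dim, d=config.d,
        epochs_nnkae=config.epochs_nnkae, epochs_vae=config.epochs_vae,
        beta_kl=config.beta_kl, seed=_child_seed(config.seed, 1),
        embedding_mode=config.embedding_mode,
    )
    report["stages"]["latent"] = {
        "d": Z.d, "latent_dim": Z.spaces[0].shape[1], "mode": Z.mode,
        "space_seeds": Z.seed_record, "elapsed_s": round(time.time() - t0, 3),
    }

    if config.k is None:
        if config.k_range is None:
            raise ValueError("either k or k_range must be given")
        k_best, curve = obj.estimate_k(
            Z, k_range=config.k_range, T=config.T,
            seed=_child_seed(config.seed, 2), theta=config.theta,
            eps_direction=config.eps_direction, p=config.p,
        )
        config.k = k_best
        report["stages"]["estimate_k"] = {"k_best": k_best, "msc_curve": curve}

    partition, run_report = _cluster_given_latent(Z, config, truth)
    report["stages"].update(run_report)
    report["final"] = run_report["consensus"]
    return partition, report


def _cluster_given_latent(Z: LatentSpaces, config: RunConfig, truth):
    report: dict = {}
    k = config.k
    t0 = time.time()
    ensemble = ens.generate_ensemble(
        Z, k=k, T=config.T, method=config.base_method,
        seed=_child_seed(config.seed, 3), p=config.p, K=config.K,
        mix_frac=config.mix_frac, resolution=config.resolution, knn=config.knn,
    )
    report["ensemble"] = {
        "D": ensemble.D, "T": ensemble.T,
        "n_partitions": len(ensemble.partitions),
        "elapsed_s": round(time.time() - t0, 3),
    }

    t0 = time.time()
    initial = _consensus(ensemble, k=k, theta=config.theta)
    coords = Z.concatenated()
    sil = obj.silhouette(initial.labels, coords)
    direction = obj.decide_direction(sil, eps=config.eps_direction)
    report["direction"] = {
        "min_sc": sil.min_sc, "msc": sil.msc, "eps": config.eps_direction,
        "direction": "+" if direction == 1 else "-",
        "elapsed_s": round(time.time() - t0, 3),
    }

    results = []
    metrics_per_restart = []
    for r in range(config.restarts):
        t0 = time.time()
        pr = pru.prune(
            ensemble, Z, direction=direction, max_fes=config.max_fes,
            alpha=config.alpha, flies=config.flies,
            seed=_child_seed(config.seed, 4, r),
        )
        final = _consensus(pr.pruned_ensemble, k=k, theta=config.theta)
        results.append((pr, final))
        if truth is not None:
            metrics_per_restart.append(
                {"nmi": met.nmi(truth, final.labels), "ari": met.ari(truth, final.labels)}
            )
    pr, final = results[0]
    report["pruning"] = {
        "selected": {str(s): m.astype(int).tolist() for s, m in pr.selected.items()},
        "n_selected": int(sum(m.sum() for m in pr.selected.values())),
        "n_total": len(ensemble.partitions),
        "iterations": len(pr.trace),
    }
    report["consensus"] = {
        "k": int(final.k),
        "cluster_sizes": np.bincount(final.labels).tolist(),
    }
    if truth is not None:
        vals = metrics_per_restart
        report["metrics"] = dict(vals[0])
        report["metrics"]["n_cells"] = int(final.labels.size)
        report["metrics"]["k_pred"] = int(final.k)
        report["metrics"]["k_true"] = int(np.unique(truth).size)
        if config.restarts > 1:
            report["metrics"]["restarts_mean"] = {
                m: float(np.mean([v[m] for v in vals])) for m in ("nmi", "ari")
            }
            report["metrics"]["restarts_sd"] = {
                m: float(np.std([v[m] for v in vals])) for m in ("nmi", "ari")
            }
    report["_trace"] = pr.trace
    return final, report


def run_pipeline(config: RunConfig) -> tuple[ConsensusPartition, dict]:
    """Run the full pipeline from the configured input file."""
    from .io import read_labels, read_matrix

    if config.input_path is None:
        raise ValueError("config.input_path is required")
    X = read_matrix(config.input_path, config.input_format, config.orientation)
    truth = None
    if config.truth_path:
        truth = read_labels(config.truth_path, X.cell_ids)
    partition, report = run_from_matrix(X, config, truth)
    if config.outdir:
        cells = report["stages"]["preprocess"]["n_cells"]
        cell_ids = X.cell_ids if cells == len(X.cell_ids) else None
        write_outputs(partition, report, config.outdir, cell_ids=cell_ids)
    return partition, report


def write_outputs(partition, report: dict, outdir: str, cell_ids=None) -> list[str]:
    """Write labels.csv, report.json and trace.csv into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    labels_path = os.path.join(outdir, "labels.csv")
    with open(labels_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "label"])
        ids = cell_ids or [f"cell{i}" for i in range(partition.labels.size)]
        for cid, lab in zip(ids, partition.labels):
            w.writerow([cid, int(lab)])
    written.append(labels_path)

    trace = report.get("stages", {}).pop("_trace", None) or report.pop("_trace", None)
    trace_path = os.path.join(outdir, "trace.csv")
    with open(trace_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "subswarm", "dev", "cp"])
        for it, row in enumerate(trace or []):
            for s, (dev, cp) in enumerate(row):
                w.writerow([it, s, dev, cp])
    written.append(trace_path)

    report_path = os.path.join(outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    written.append(report_path)
    return written


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
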