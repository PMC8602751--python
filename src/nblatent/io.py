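"""File I/O, preprocessing filters, and the end-to-end pipeline driver.

Counts are read either as MatrixMarket triplets with companion
``genes.tsv`` / ``barcodes.tsv`` files (10x convention) or as dense CSV/TSV
(genes x cells, first column gene ids, header cell ids). Datasets are
aligned on the intersection of gene ids, keeping the first dataset's order.

The quality filters mirror standard scRNA-seq practice: cells expressing too
few genes are dropped first, then whole datasets left with too few cells,
then genes expressed in too few cells across the retained datasets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .clustering import cluster_latent, module_means
from .evaluate import (
    PartitionPair,
    adjusted_rand_index,
    calinski_harabasz,
    davies_bouldin,
    dunn_index,
)
from .inference import FitConfig, fit, select_lambda_bic
from .types import DatasetCollection

logger = logging.getLogger("nblatent")

__all__ = [
    "FilterPolicy",
    "read_counts",
    "write_counts_mtx",
    "write_counts_csv",
    "apply_filters",
    "read_gmt",
    "run_pipeline",
]


@dataclass
class FilterPolicy:
    """Quality-control thresholds applied before fitting.

    Defaults: cells keeping >= 200 expressed genes, datasets keeping >= 200
    cells, genes expressed in >= 300 cells summed across retained datasets.
    """

    min_genes_per_cell: int = 200
    min_cells_per_sample: int = 200
    min_cells_per_gene: int = 300

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_cells_per_sample, self.min_cells_per_gene) < 0:
            raise ValueError("filter thresholds must be >= 0")


def _read_one(path: Path, fmt: str) -> tuple[np.ndarray, list[str], list[str]]:
    path = Path(path)
    if fmt == "mtx":
        mat = spio.mmread(path)
        mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
        genes_file = path.with_name("genes.tsv")
        cells_file = path.with_name("barcodes.tsv")
        genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_file, sep="\t", header=None)[0].astype(str).tolist()
        if len(genes) != mat.shape[0] or len(cells) != mat.shape[1]:
            raise ValueError(f"{path}: gene/barcode annotations do not match matrix shape")
        return mat, genes, cells
    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ValueError(f"{path}: failed to parse dense count table: {exc}") from exc
        if df.shape[1] == 0 or not all(
            pd.api.types.is_numeric_dtype(t) for t in df.dtypes
        ):
            raise ValueError(f"{path}: malformed header or non-numeric count columns")
        return df.to_numpy(dtype=np.float64), df.index.astype(str).tolist(), df.columns.astype(str).tolist()
    raise ValueError(f"unknown format {fmt!r} (expected 'mtx' or 'csv')")


def read_counts(paths, fmt: str = "csv", dataset_ids=None) -> DatasetCollection:
    """Read K count files and align them on the shared gene intersection.

    Gene order follows the first dataset. Non-integer entries beyond 1e-6
    and negative entries are rejected by the collection invariants.
    """
    paths = [Path(p) for p in paths]
    mats, gene_lists = [], []
    for p in paths:
        mat, genes, _cells = _read_one(p, fmt)
        mats.append(mat)
        gene_lists.append(genes)
    shared = set(gene_lists[0])
    for genes in gene_lists[1:]:
        shared &= set(genes)
    if not shared:
        raise ValueError("gene-id intersection across datasets is empty")
    ordered = [g for g in gene_lists[0] if g in shared]
    aligned = []
    for mat, genes in zip(mats, gene_lists):
        pos = {g: i for i, g in enumerate(genes)}
        aligned.append(mat[[pos[g] for g in ordered], :])
    if dataset_ids is None:
        dataset_ids = [p.stem if p.stem != "matrix" else p.parent.name for p in paths]
    return DatasetCollection(datasets=aligned, gene_ids=ordered, dataset_ids=list(dataset_ids))


def write_counts_mtx(x: DatasetCollection, outdir) -> list[Path]:
    """One directory per dataset: matrix.mtx + genes.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    written = []
    for k, d in enumerate(x.datasets):
        sub = outdir / x.dataset_ids[k]
        sub.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(sub / "matrix.mtx", sparse.coo_matrix(d.astype(int)))
        pd.Series(x.gene_ids).to_csv(sub / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series([f"cell_{j}" for j in range(d.shape[1])]).to_csv(
            sub / "barcodes.tsv", sep="\t", index=False, header=False
        )
        written.append(sub / "matrix.mtx")
    return written


def write_counts_csv(x: DatasetCollection, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for k, d in enumerate(x.datasets):
        path = outdir / f"{x.dataset_ids[k]}.csv"
        pd.DataFrame(
            d.astype(int),
            index=pd.Index(x.gene_ids, name="gene_id"),
            columns=[f"cell_{j}" for j in range(d.shape[1])],
        ).to_csv(path)
        written.append(path)
    return written


def apply_filters(
    x: DatasetCollection, policy: FilterPolicy
) -> tuple[DatasetCollection, list[dict]]:
    """Apply the QC policy; returns the filtered collection and a removal report.

    Order of operations: low-coverage cells, then under-sized datasets, then
    genes expressed in too few cells summed across what remains.
    """
    report: list[dict] = []
    kept_mats, kept_ids = [], []
    for k, d in enumerate(x.datasets):
        expressed = (d > 0).sum(axis=0)
        cell_mask = expressed >= policy.min_genes_per_cell
        for j in np.where(~cell_mask)[0]:
            report.append(
                {
                    "rule": "min_genes_per_cell",
                    "dataset": x.dataset_ids[k],
                    "item": f"cell_{j}",
                    "value": int(expressed[j]),
                    "threshold": policy.min_genes_per_cell,
                }
            )
        d2 = d[:, cell_mask]
        if d2.shape[1] < max(policy.min_cells_per_sample, 1):
            report.append(
                {
                    "rule": "min_cells_per_sample",
                    "dataset": x.dataset_ids[k],
                    "item": x.dataset_ids[k],
                    "value": int(d2.shape[1]),
                    "threshold": policy.min_cells_per_sample,
                }
            )
            continue
        kept_mats.append(d2)
        kept_ids.append(x.dataset_ids[k])
    if not kept_mats:
        raise ValueError(f"all datasets removed by filtering; report: {report}")
    cells_expressing = sum((d > 0).sum(axis=1) for d in kept_mats)
    gene_mask = cells_expressing >= policy.min_cells_per_gene
    for i in np.where(~gene_mask)[0]:
        report.append(
            {
                "rule": "min_cells_per_gene",
                "dataset": "*",
                "item": x.gene_ids[i],
                "value": int(cells_expressing[i]),
                "threshold": policy.min_cells_per_gene,
            }
        )
    if gene_mask.sum() < 2:
        raise ValueError(f"fewer than two genes survive filtering; report: {report}")
    filtered = DatasetCollection(
        datasets=[d[gene_mask, :] for d in kept_mats],
        gene_ids=[g for g, keep in zip(x.gene_ids, gene_mask) if keep],
        dataset_ids=kept_ids,
    )
    return filtered, report


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT rows need name, description and >= 1 gene")
        sets[parts[0]] = set(parts[2:])
    return sets


def run_pipeline(config_path) -> dict:
    """Execute read -> filter -> fit -> cluster -> evaluate from a JSON config.

    The config declares inputs (paths + format), FilterPolicy fields, a
    FitConfig section, optional ``lambda_candidates`` for BIC selection, an
    output directory and a seed. Writes modules.tsv, embedding.tsv,
    fit_trace.tsv, index_report.tsv, and manifest.json; returns the manifest.
    """
    config_path = Path(config_path)
    cfg = json.loads(config_path.read_text())
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "seed": cfg.get("seed", 0),
        "stages": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("read")
        x = read_counts(cfg["inputs"], fmt=cfg.get("format", "csv"))
        stage("filter")
        policy = FilterPolicy(**cfg.get("filters", {}))
        x, report = apply_filters(x, policy)
        manifest["filter_report"] = report
        stage("fit")
        fit_cfg = FitConfig(rng_seed=cfg.get("seed", 0), **cfg.get("fit", {}))
        if cfg.get("lambda_candidates"):
            best, table = select_lambda_bic(x, cfg["lambda_candidates"], fit_cfg)
            manifest["bic_table"] = table
            manifest["selected_lambda"] = best
            from dataclasses import replace

            fit_cfg = replace(fit_cfg, lambda_dim=best)
        res = fit(x, fit_cfg)
        manifest["converged"] = res.converged
        manifest["lambda_dim"] = fit_cfg.lambda_dim
        stage("cluster")
        assign = cluster_latent(res.embedding, fit_cfg.lambda_dim, seed=cfg.get("seed", 0))
        stage("evaluate")
        Zm = res.embedding.Z
        indices = {
            "calinski_harabasz": calinski_harabasz(Zm, assign.labels),
            "davies_bouldin": davies_bouldin(Zm, assign.labels),
            "dunn": dunn_index(Zm, assign.labels),
        }
        truth_path = cfg.get("true_labels")
        if truth_path:
            truth = pd.read_csv(truth_path, sep="\t")
            truth = truth.set_index(truth.columns[0]).iloc[:, 0]
            indices["ari_vs_truth"] = adjusted_rand_index(
                PartitionPair(truth.loc[x.gene_ids].to_numpy(), assign.labels)
            )
        manifest["indices"] = indices

        stage("write")
        pd.DataFrame({"gene_id": x.gene_ids, "module": assign.labels}).to_csv(
            outdir / "modules.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            Zm, index=pd.Index(x.gene_ids, name="gene_id"),
            columns=[f"z{l + 1}" for l in range(Zm.shape[1])],
        ).to_csv(outdir / "embedding.tsv", sep="\t")
        pd.DataFrame({"iteration": range(1, len(res.loglik_trace) + 1),
                      "penalized_loglik": res.loglik_trace}).to_csv(
            outdir / "fit_trace.tsv", sep="\t", index=False
        )
        pd.DataFrame([indices]).to_csv(outdir / "index_report.tsv", sep="\t", index=False)
        scores = module_means(x, assign)
        for k, s in enumerate(scores.scores):
            pd.DataFrame(
                s,
                index=[f"module_{c}" for c in range(1, assign.n_clusters + 1)],
                columns=[f"cell_{j}" for j in range(s.shape[1])],
            ).to_csv(outdir / f"module_scores_{scores.dataset_ids[k]}.tsv", sep="\t")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
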