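"""One-shot execution of the full panel-diagnostic workflow.

Stages, in order: consensus similarity matrix -> consensus-limit
discrimination summary and heatmap -> Ward/Euclidean clustering with
silhouette sweep and profile -> per-group Cochran's Q screening and
correspondence analysis (total panel, good and poor clusters) -> liking
ANOVA/Tukey letters per group (when a liking table is supplied) ->
CATATIS agreement.  Every artifact is a CSV named after its role; a JSON
manifest records the configuration, package versions and the produced
files.  A stage failure aborts the run, keeps partial outputs and leaves a
FAILED marker naming the stage in the manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_vs_discrimination, catatis_homogeneity
from .cluster import ahc_cluster, profile_export
from .discrimination import heatmap_export, summarize
from .metrics import pairwise_matrix, registry, registry_frame
from .panel import CATAPanel, LikingTable, write_matrix
from .stats import (
    build_counts,
    cochran_q_table,
    correspondence,
    liking_anova_tukey,
    significant_attributes,
    tukey_frame,
)

__all__ = ["RunConfig", "PipelineError", "run"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one workflow run needs, besides the data itself."""

    outdir: str
    alpha: float = 0.05
    k: int = 2
    k_range: tuple[int, int] = (2, 6)
    metric_subset: tuple[str, ...] | None = None
    render_image: bool = False
    ca_all_attributes: bool = False  # CA on every attribute, not only significant
    seed: int = 0  # echoed into the manifest; the pipeline itself is deterministic

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha}")


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _ca_exports(
    panel: CATAPanel,
    subset: Sequence[str],
    group: str,
    cfg: RunConfig,
    outdir: Path,
    manifest_files: list[str],
) -> dict:
    qtab = cochran_q_table(panel, subset, cfg.alpha)
    qpath = outdir / f"cochran_q_{group}.csv"
    write_matrix(qtab, str(qpath))
    manifest_files.append(qpath.name)
    sig = significant_attributes(panel, subset, cfg.alpha)
    attrs = list(panel.attributes) if cfg.ca_all_attributes else sig
    info: dict = {"group": group, "n_assessors": len(subset), "n_significant": len(sig)}
    if len(attrs) >= 2:
        counts = build_counts(panel, subset, attrs)
        ca = correspondence(counts)
        coords = outdir / f"ca_coords_{group}.csv"
        eigen = outdir / f"ca_eigen_{group}.csv"
        write_matrix(ca.coords_frame(), str(coords))
        write_matrix(ca.eigen_frame(), str(eigen))
        manifest_files += [coords.name, eigen.name]
        info.update(
            total_inertia=ca.total_inertia, plane_explained_pct=ca.plane_explained
        )
    else:
        info["ca_skipped"] = f"only {len(attrs)} usable attributes"
    return info


def run(
    config: RunConfig,
    panel: CATAPanel,
    liking: LikingTable | None = None,
) -> dict:
    """Execute the whole workflow; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    manifest: dict = {
        "package": f"catadiscrim {__version__}",
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "started_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config": {
            "alpha": config.alpha,
            "k": config.k,
            "k_range": list(config.k_range),
            "metric_subset": list(config.metric_subset) if config.metric_subset else None,
            "render_image": config.render_image,
            "ca_all_attributes": config.ca_all_attributes,
            "seed": config.seed,
        },
        "panel": {
            "n_assessors": panel.n_assessors,
            "n_samples": panel.n_samples,
            "n_attributes": panel.n_attributes,
        },
        "outputs": files,
    }
    stage = "similarity"
    try:
        specs = registry(config.metric_subset)
        matrix = pairwise_matrix(panel, specs)
        write_matrix(matrix.to_frame(), str(outdir / "pair_similarity.csv"))
        write_matrix(registry_frame(), str(outdir / "metric_registry.csv"))
        files += ["pair_similarity.csv", "metric_registry.csv"]

        stage = "discrimination"
        summary = summarize(matrix)
        summ = pd.DataFrame(
            {
                "value": [
                    summary.consensus_limit,
                    summary.n_good,
                    summary.n_poor,
                    summary.row_min,
                    summary.row_max,
                    summary.discrimination_index,
                ]
            },
            index=pd.Index(
                [
                    "consensus_limit",
                    "selected_assessors",
                    "remaining_assessors",
                    "row_minimum",
                    "row_maximum",
                    "discrimination_index_pct",
                ],
                name="statistic",
            ),
        )
        write_matrix(summ, str(outdir / "discrimination_summary.csv"))
        image = str(outdir / "heatmap.png") if config.render_image else None
        heatmap_export(matrix, summary, str(outdir / "heatmap.csv"), image)
        files += ["discrimination_summary.csv", "heatmap.csv"]
        if image:
            files.append("heatmap.png")
        manifest["discrimination"] = {
            "consensus_limit": summary.consensus_limit,
            "discrimination_index_pct": summary.discrimination_index,
            "n_good_by_limit": summary.n_good,
        }

        stage = "clustering"
        lo, hi = config.k_range
        k_range = range(lo, min(hi, panel.n_assessors - 1) + 1)
        result = ahc_cluster(matrix, config.k, k_range)
        write_matrix(result.to_frame(), str(outdir / "cluster_labels.csv"))
        sil = pd.DataFrame(
            {"avg_silhouette": list(result.silhouette_by_k.values())},
            index=pd.Index(list(result.silhouette_by_k), name="k"),
        )
        write_matrix(sil, str(outdir / "silhouette.csv"))
        profile_export(matrix, result, str(outdir / "cluster_profile.csv"))
        merges = pd.DataFrame(
            result.linkage_tree,
            columns=["node_i", "node_j", "height", "size"],
            index=pd.Index(range(len(result.linkage_tree)), name="merge"),
        )
        write_matrix(merges, str(outdir / "linkage.csv"))
        files += ["cluster_labels.csv", "silhouette.csv", "cluster_profile.csv", "linkage.csv"]
        manifest["clustering"] = {
            "k": result.k,
            "cluster_sizes": {int(c): len(result.members(c)) for c in result.cluster_means},
            "cluster_means": {int(c): v for c, v in result.cluster_means.items()},
            "roles": {int(c): r for c, r in result.roles.items()},
            "silhouette_by_k": {int(k): v for k, v in result.silhouette_by_k.items()},
        }

        stage = "panel_stats"
        groups = {
            "total": list(panel.assessors),
            "good": list(result.members(result.good_cluster)),
            "poor": [
                a for a in panel.assessors
                if a not in set(result.members(result.good_cluster))
            ],
        }
        manifest["panel_stats"] = [
            _ca_exports(panel, members, name, config, outdir, files)
            for name, members in groups.items()
            if members
        ]

        if liking is not None:
            stage = "liking"
            manifest["liking"] = {}
            for name, members in groups.items():
                if name == "total" or not members:
                    continue
                letters = liking_anova_tukey(liking, members, config.alpha)
                path = outdir / f"tukey_letters_{name}.csv"
                write_matrix(tukey_frame(letters), str(path))
                files.append(path.name)
                manifest["liking"][name] = {
                    t.sample: {"mean": t.mean, "letters": t.letters} for t in letters
                }

        stage = "agreement"
        agree = catatis_homogeneity(panel)
        table, corr = agreement_vs_discrimination(panel, matrix)
        write_matrix(table, str(outdir / "agreement.csv"))
        write_matrix(agree.cosine_frame(), str(outdir / "agreement_cosine.csv"))
        files += ["agreement.csv", "agreement_cosine.csv"]
        manifest["agreement"] = {
            "homogeneity_pct": agree.homogeneity,
            "agreement_discrimination_corr": corr,
        }
    except Exception as exc:  # keep partial outputs, mark the failed stage
        manifest["FAILED"] = {"stage": stage, "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
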