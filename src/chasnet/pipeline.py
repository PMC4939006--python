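"""End-to-end pipeline: build -> features -> ChAs -> nulls -> topology.

A run is driven by a :class:`RunConfig` (loadable from a YAML file with one
section per stage); every output is a TSV under the run's output directory
and a machine-readable manifest records versions, seeds and parameters so
the run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assortativity import chas_all, chas_by_class, classify_other_ends, compare_subnetworks
from .features import build_matrix, read_manifest, write_matrix
from .network import OTHER_END, ContactNetwork, read_interactions, read_sizes, subnetwork
from .nulls import label_shuffle_null, null_summary
from .topology import (
    betweenness,
    communities_greedy,
    communities_overlapping,
    module_feature_enrichment,
    top_node_enrichment,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    pairs: str
    peaks_manifest: str
    outdir: str
    pairs_format: str = "bedpe"
    baits: str | None = None
    sizes: str | None = None
    score_min: float = 5.0
    window: int = 200
    reps: int = 100
    seed: int = 0
    top_n: int = 500
    subnetworks: tuple[str, ...] = ("all", "PP", "PO")
    null_features: tuple[str, ...] = ()  # empty = all features
    enhancer_marks: tuple[str, str, str] = ("H3K4me1", "H3K27ac", "H3K27me3")
    run_topology: bool = True
    run_nulls: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):  # stage sections are flattened
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("subnetworks", "null_features", "enhancer_marks"):
            if key in flat and isinstance(flat[key], list):
                flat[key] = tuple(flat[key])
        cfg = cls(**flat)
        base = Path(path).parent
        for attr in ("pairs", "peaks_manifest", "baits", "sizes"):
            val = getattr(cfg, attr)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        return cfg

    def validate(self) -> None:
        for attr in ("pairs", "peaks_manifest", "baits", "sizes"):
            val = getattr(self, attr)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{attr}: {val} does not exist")
        if self.score_min < 0 or self.window <= 0 or self.reps < 1 or self.top_n < 1:
            raise ValueError("parameter out of range")
        bad = set(self.subnetworks) - {"all", "PP", "PO", "OO"}
        if bad:
            raise ValueError(f"unknown subnetwork selections: {sorted(bad)}")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the table of written outputs.

    Stage order: build -> features -> chas (per selected subnetwork,
    plus class-restricted P-O tables when the enhancer marks are present)
    -> label-shuffle nulls -> topology.  A stage failure aborts with the
    stage name; completed outputs are preserved.  Warnings (undefined ChAs,
    empty subnetworks) never abort the run.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "build"
    try:
        sizes = read_sizes(config.sizes) if config.sizes else None
        bait_ids = (
            set(Path(config.baits).read_text().split()) if config.baits else None
        )
        net = read_interactions(
            config.pairs,
            fmt=config.pairs_format,
            score_threshold=config.score_min,
            bait_ids=bait_ids,
            sizes=sizes,
        )
        nodes_path, edges_path = net.write(outdir / "network")
        outputs["nodes"], outputs["edges"] = nodes_path, edges_path

        stage = "features"
        tracks = read_manifest(config.peaks_manifest)
        matrix = build_matrix(net, tracks, window_size=config.window, sizes=sizes)
        outputs["matrix"] = write_matrix(matrix, outdir / "feature_matrix.tsv")

        stage = "chas"
        nets = {"all": net}
        for sel in config.subnetworks:
            if sel != "all":
                nets[sel] = subnetwork(net, edge_classes={sel})
        tables = [
            chas_all(sub, matrix, label=sel)
            for sel, sub in nets.items()
            if sel in config.subnetworks
        ]
        chas_table = pd.concat(tables, ignore_index=True)
        chas_path = outdir / "chas.tsv"
        chas_table.to_csv(chas_path, sep="\t", index=False, float_format="%.6g")
        outputs["chas"] = chas_path
        if {"PP", "PO"} <= set(config.subnetworks):
            comp = compare_subnetworks(net, matrix)
            comp_path = outdir / "chas_PP_vs_PO.tsv"
            comp.to_csv(comp_path, sep="\t", index=False, float_format="%.6g")
            outputs["chas_compare"] = comp_path

        marks = config.enhancer_marks
        if set(marks) <= set(matrix.columns) and "PO" in config.subnetworks:
            stage = "classify"
            other_ends = [
                fid
                for fid, f in net.fragments.items()
                if f.node_class == OTHER_END
            ]
            flags = classify_other_ends(matrix, other_ends, *marks)
            flags_path = outdir / "other_end_classes.tsv"
            flags.rename_axis("fragment_id").to_csv(flags_path, sep="\t")
            outputs["classes"] = flags_path
            class_tables = []
            for flag in flags.columns:
                tab = chas_by_class(net, matrix, flags, flag)
                if len(tab):
                    class_tables.append(tab)
            if class_tables:
                cls_path = outdir / "chas_by_class.tsv"
                pd.concat(class_tables, ignore_index=True).to_csv(
                    cls_path, sep="\t", index=False, float_format="%.6g"
                )
                outputs["chas_by_class"] = cls_path

        if config.run_nulls:
            stage = "nulls"
            feats = config.null_features or tuple(matrix.columns)
            ensembles = [
                label_shuffle_null(
                    net, matrix, f, n_reps=config.reps, seed=config.seed
                )
                for f in feats
            ]
            null_path = outdir / "null_label_shuffle.tsv"
            null_summary(ensembles).to_csv(
                null_path, sep="\t", index=False, float_format="%.6g"
            )
            outputs["nulls"] = null_path

        if config.run_topology:
            stage = "topology"
            bc = betweenness(net, lcc_only=True)
            overlapping = communities_overlapping(net)
            bridge = overlapping.bridgeness_series()
            scores_path = outdir / "node_scores.tsv"
            pd.DataFrame({"betweenness": bc, "bridgeness": bridge}).rename_axis(
                "fragment_id"
            ).to_csv(scores_path, sep="\t", float_format="%.6g")
            outputs["node_scores"] = scores_path
            comm_path = outdir / "communities.tsv"
            overlapping.to_table().to_csv(comm_path, sep="\t", index=False)
            outputs["communities"] = comm_path
            bridge_scores = bridge.loc[bridge.index.intersection(matrix.index)]
            bc_scores = bc.loc[bc.index.intersection(matrix.index)]
            top_n = min(config.top_n, len(bridge_scores), len(bc_scores))
            enr_b = top_node_enrichment(
                matrix, bridge_scores, top_n=top_n,
                n_reps=config.reps, seed=config.seed,
            )
            enr_c = top_node_enrichment(
                matrix, bc_scores, top_n=top_n,
                n_reps=config.reps, seed=config.seed,
            )
            enr_path = outdir / "top_node_enrichment.tsv"
            enr = enr_b.merge(enr_c, on="feature", suffixes=("_bridgeness", "_betweenness"))
            enr.to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
            outputs["enrichment"] = enr_path
            greedy = communities_greedy(net)
            mfe = module_feature_enrichment(
                greedy, matrix, n_reps=config.reps, seed=config.seed, min_size=5
            )
            mfe_path = outdir / "module_feature_p.tsv"
            mfe.to_csv(mfe_path, sep="\t", float_format="%.6g")
            outputs["module_enrichment"] = mfe_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "chasnet_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
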