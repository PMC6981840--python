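"""End-to-end orchestration: files in, analysis artifacts out.

The run flow mirrors the study design: merge diagnoses onto samples, reverse
the RMA log scaling, filter probes (CV/intensity window then group ANOVA),
summarise per-probe directions vs NC, build the six signed networks per
threshold, score node rewiring on the low-threshold networks, and infer the
consensus differential networks of the conditions against the reference.
Every run writes a JSON manifest with the resolved parameters and artifact
counts so results can be reproduced and audited.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexnet, diffexpr, netcompare, preprocess
from .containers import STATES, ExpressionMatrix
from .preprocess import FilterConfig

logger = logging.getLogger("coexrewire")


@dataclass
class PipelineConfig:
    expression: str = "expression.csv"
    diagnosis: str = "diagnosis.csv"
    outdir: str = "results"
    filter: FilterConfig = field(default_factory=FilterConfig)
    thresholds: tuple[float, ...] = (0.1, 0.3)
    #: threshold whose networks feed the rewiring and consensus comparisons
    comparison_threshold: float = 0.1
    #: threshold of the plain per-state co-expression networks
    basic_threshold: float = 0.3
    score_mode: str = "binary"  # binary | weighted
    score_variant: str = "raw"  # raw | degree_corrected | distance
    rewiring_cutoff: float = 5.0
    fdr_method: str = "fdr_bh"
    reference_state: str = "NC"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.thresholds):
            raise ValueError("thresholds must be nonnegative")
        if self.comparison_threshold not in self.thresholds:
            raise ValueError("comparison_threshold must be one of thresholds")
        if self.reference_state not in STATES:
            raise ValueError(f"reference state must be one of {list(STATES)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        filt = raw.pop("filter", {})
        cfg = cls(**raw)
        if filt:
            cfg.filter = FilterConfig(**filt)
        return cfg

    def resolved(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("load")
def _load(cfg: PipelineConfig):
    values = pd.read_csv(cfg.expression, index_col=0)
    matrix = ExpressionMatrix(values, scale="log2")
    diagnoses = preprocess.load_diagnosis_table(cfg.diagnosis)
    return matrix, diagnoses


@_stage("merge")
def _merge(matrix, diagnoses):
    meta = preprocess.sample_meta_from_ids(matrix.samples)
    return preprocess.assign_diagnosis(meta, diagnoses)


@_stage("filter")
def _filter(matrix, labels, cfg: PipelineConfig):
    return preprocess.run_filter_cascade(matrix, labels, cfg.filter)


@_stage("diffexpr")
def _directions(dataset, cfg: PipelineConfig):
    return diffexpr.direction_table(dataset, fdr_method=cfg.fdr_method)


@_stage("networks")
def _networks(dataset, cfg: PipelineConfig):
    return coexnet.build_state_networks(dataset, thresholds=cfg.thresholds)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, diagnoses = _load(cfg)
    labels = _merge(matrix, diagnoses)
    dataset, report = _filter(matrix, labels, cfg)
    report.to_tsv(outdir / "filter_report.tsv")
    if dataset.matrix.n_probes < 2:
        raise RuntimeError(
            f"only {dataset.matrix.n_probes} probe(s) survived filtering; "
            "cannot build networks"
        )

    directions = _directions(dataset, cfg)
    diffexpr.write_direction_table(directions, outdir / "direction_table.tsv")

    networks = _networks(dataset, cfg)
    edge_tables = []
    edge_counts: dict[str, int] = {}
    for t, per_state in networks.items():
        for state, per_sign in per_state.items():
            for sign, net in per_sign.items():
                name = f"edges_T{t:g}_{state}_{sign}.tsv"
                coexnet.export_edge_table(net, outdir / name)
                edge_tables.append(name)
                edge_counts[name] = net.graph.number_of_edges()

    comp = networks[cfg.comparison_threshold]
    states = list(comp)
    conditions = [s for s in states if s != cfg.reference_state]

    rewiring_files = []
    rewiring_top_counts = {}
    diff_files = []
    diff_counts = {}
    for sign in coexnet.SIGNS:
        per_state = {s: comp[s][sign] for s in states}
        table = netcompare.rewiring_scores(
            per_state, mode=cfg.score_mode, score=cfg.score_variant
        )
        name = f"rewiring_{sign}.tsv"
        netcompare.write_rewiring_table(table, outdir / name)
        rewiring_files.append(name)
        rewiring_top_counts[sign] = int(
            (table["score"] >= cfg.rewiring_cutoff).sum()
        )

        diff = netcompare.consensus_differential(
            comp[cfg.reference_state][sign], [comp[c][sign] for c in conditions]
        )
        gname = f"differential_{sign}.graphml"
        sname = f"differential_{sign}.sif"
        netcompare.export_differential_graphml(diff, outdir / gname)
        netcompare.export_differential_sif(diff, outdir / sname)
        diff_files.append(gname)
        diff_counts[sign] = {"gained": len(diff.gained), "lost": len(diff.lost)}

    manifest = {
        "config": cfg.resolved(),
        "n_samples": matrix.n_samples,
        "n_samples_labeled": int(labels.notna().sum()),
        "probes_in": report.n_in,
        "probes_stage1": report.n_stage1,
        "probes_stage2": report.n_stage2,
        "states": states,
        "edge_tables": sorted(edge_tables),
        "edge_counts": edge_counts,
        "rewiring_tables": rewiring_files,
        "rewiring_top_counts": rewiring_top_counts,
        "differential_networks": diff_files,
        "differential_counts": diff_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
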