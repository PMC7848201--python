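"""End-to-end orchestration: input loading, per-region execution, manifest.

The pipeline consumes a directory-level configuration (plain YAML with CLI
overrides), validates inputs against each other, runs
filter -> DE -> transitions -> clustering -> splicing on every region
independently, and writes a run manifest recording the configuration
snapshot, input checksums, per-stage row counts and warnings.  No
timestamps are written, so identical inputs and seeds give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import (
    STATES,
    ClusterConfig,
    DEConfig,
    FilterRule,
    SpliceConfig,
    StateGraph,
)
from .clustering import DEFAULT_TEMPLATES, assign_clusters, load_templates, state_means
from .expression import (
    de_lrt,
    estimate_dispersions,
    filter_genes,
    pairwise_de,
    size_factors,
    transform,
    transition_summary,
)
from .simulate import read_counts, read_design, read_lsv_table
from .splicing import (
    cluster_dpsi_patterns,
    classify_intron_retention,
    estimate_psi,
    lsv_records_from_table,
    select_control_introns,
    significant_lsvs,
)

__all__ = ["PipelineConfig", "load_inputs", "run_all"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    counts: str | None = None
    design: str | None = None
    lsv_table: str | None = None
    templates: str | None = None
    out_dir: str = "hiberseq_out"
    seed: int = 0
    states: tuple[str, ...] = STATES
    filter_rule: FilterRule = dataclasses.field(default_factory=FilterRule)
    de: DEConfig = dataclasses.field(default_factory=DEConfig)
    cluster: ClusterConfig = dataclasses.field(default_factory=ClusterConfig)
    splice: SpliceConfig = dataclasses.field(default_factory=SpliceConfig)
    graph: StateGraph = dataclasses.field(default_factory=StateGraph)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        simple = {"counts", "design", "lsv_table", "templates", "out_dir", "seed"}
        for key, val in raw.items():
            if key in simple:
                setattr(cfg, key, val)
            elif key == "states":
                cfg.states = tuple(val)
            elif key == "filter_rule":
                cfg.filter_rule = FilterRule(**val)
            elif key == "de":
                cfg.de = DEConfig(**val)
            elif key == "cluster":
                cfg.cluster = ClusterConfig(**val)
            elif key == "splice":
                cfg.splice = SpliceConfig(**val)
            else:
                raise ValueError(f"unknown configuration key: {key!r}")
        return cfg

    def snapshot(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(config: PipelineConfig) -> dict:
    """Load and cross-validate the declared inputs."""
    data: dict = {"checksums": {}, "warnings": []}
    if not config.counts or not config.design:
        raise ValueError("counts and design paths are required")
    for name in ("counts", "design", "lsv_table", "templates"):
        path = getattr(config, name)
        if path:
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file does not exist: {path}")
            data["checksums"][name] = _sha256(path)
    counts = read_counts(config.counts)
    if counts.empty:
        raise ValueError(f"empty counts file: {config.counts}")
    design = read_design(config.design)
    for col in ("sample_id", "state", "sex", "region"):
        if col not in design.columns:
            raise ValueError(f"design is missing required column {col!r}")
    missing = set(counts.columns) - set(design["sample_id"])
    if missing:
        raise ValueError(f"design missing samples present in counts: {sorted(missing)[:5]}")
    unknown = set(design["state"]) - set(config.states)
    if unknown:
        raise ValueError(f"design contains undeclared states: {sorted(unknown)}")
    data["counts"] = counts
    data["design"] = design
    if config.lsv_table:
        data["lsv_table"] = read_lsv_table(config.lsv_table)
    templates = (
        load_templates(config.templates) if config.templates else DEFAULT_TEMPLATES
    )
    data["templates"] = templates
    return data


def _run_region(
    region: str,
    counts: pd.DataFrame,
    design: pd.DataFrame,
    lsv_table: pd.DataFrame | None,
    templates,
    config: PipelineConfig,
    out_dir: Path,
) -> dict:
    stage_counts: dict = {}
    out_dir.mkdir(parents=True, exist_ok=True)

    factors = size_factors(counts)
    expr = transform(counts, factors)
    keep = filter_genes(expr, design, config.filter_rule)
    pd.Series(keep, name="gene_id").to_csv(out_dir / "pass_filter.tsv", sep="\t", index=False)
    stage_counts["pass_filter"] = len(keep)

    sub = counts.loc[keep]
    dispersions = estimate_dispersions(sub, factors, design)
    lrt = de_lrt(sub, design, config.de, factors=factors, dispersions=dispersions)
    lrt.to_csv(out_dir / "de_lrt.tsv", sep="\t")
    de_genes = list(lrt.index[(lrt["padj"] <= config.de.lrt_alpha).fillna(False)])
    stage_counts["de_lrt_significant"] = len(de_genes)

    pairwise = {}
    for a, b in config.graph.transitions:
        if (a, b) in pairwise:
            continue
        res = pairwise_de(sub, design, a, b, config.de, factors=factors, dispersions=dispersions)
        res.to_csv(out_dir / f"pairwise_{a}_vs_{b}.tsv", sep="\t")
        pairwise[(a, b)] = res
    trans = transition_summary(pairwise, config.graph, config.de)
    trans.to_csv(out_dir / "transitions.tsv", sep="\t", index=False)
    stage_counts["total_de_over_transitions"] = trans.attrs["total_de"]

    means = state_means(expr.loc[de_genes], design, config.states) if de_genes else None
    if means is not None and len(means):
        clusters = assign_clusters(means, templates, config.cluster)
        clusters.to_csv(out_dir / "clusters.tsv", sep="\t")
        stage_counts["clustered_units"] = int((clusters["cluster"] != config.cluster.unassigned_label).sum())
    else:
        stage_counts["clustered_units"] = 0

    if lsv_table is not None and len(lsv_table):
        records = lsv_records_from_table(lsv_table)
        estimates = [
            estimate_psi(r, design, config.splice, config.states) for r in records
        ]
        psi_rows = []
        for est in estimates:
            for state in config.states:
                for j in est.junction_ids:
                    psi_rows.append(
                        {
                            "lsv_id": est.lsv_id,
                            "state": state,
                            "junction_id": j,
                            "psi_mean": est.psi_mean.loc[state, j],
                            "psi_low": est.psi_low.loc[state, j],
                            "psi_high": est.psi_high.loc[state, j],
                        }
                    )
        pd.DataFrame(psi_rows).to_csv(out_dir / "psi.tsv", sep="\t", index=False)
        informative = [
            e
            for e in estimates
            if all(e.informative.get(s, False) for s in config.states)
        ]
        sig = significant_lsvs(informative, config.splice, config.states)
        pd.Series(sorted(sig), name="lsv_id").to_csv(
            out_dir / "significant_lsvs.tsv", sep="\t", index=False
        )
        stage_counts["significant_lsvs"] = len(sig)
        sig_est = [e for e in informative if e.lsv_id in sig]
        if sig_est:
            sc = cluster_dpsi_patterns(sig_est, templates, config.splice, config.cluster, config.states)
            sc.to_csv(out_dir / "splice_clusters.tsv", sep="\t")
            ir_rows = [
                {"lsv_id": e.lsv_id, "orientation": classify_intron_retention(e, config.splice)}
                for e in sig_est
                if e.is_retained_intron.any()
            ]
            pd.DataFrame(ir_rows).to_csv(out_dir / "intron_retention.tsv", sep="\t", index=False)
        controls = select_control_introns(informative, config.splice)
        controls.to_csv(out_dir / "control_introns.bed", sep="\t", index=False, header=False)
        stage_counts["control_introns"] = len(controls)
    return stage_counts


def run_all(config: PipelineConfig) -> dict:
    """Run every stage per region; returns the manifest (also written)."""
    data = load_inputs(config)
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    design = data["design"]
    manifest = {
        "package_version": __version__,
        "config": config.snapshot(),
        "input_checksums": data["checksums"],
        "regions": {},
        "warnings": data["warnings"],
        "outputs": [],
    }
    for region in sorted(design["region"].unique()):
        region_design = design[design["region"] == region]
        samples = [s for s in data["counts"].columns if s in set(region_design["sample_id"])]
        region_counts = data["counts"][samples]
        lsv = data.get("lsv_table")
        if lsv is not None:
            lsv = lsv[lsv["sample"].isin(samples)]
        region_dir = out_root / region
        stage_counts = _run_region(
            region, region_counts, region_design, lsv, data["templates"], config, region_dir
        )
        manifest["regions"][region] = stage_counts
    manifest["outputs"] = sorted(
        str(p.relative_to(out_root)) for p in out_root.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
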