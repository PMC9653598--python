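"""Pipeline orchestration: one config file in, one deterministic run report out.

``run_all`` executes the stages in order — per-dataset differential
expression with the anchor gate, cross-dataset commonality ranking,
per-level over-representation analysis with the consensus rule, the
reference-set overlap test, and minimum-order subnetwork extraction with
clustering — skipping the optional stages whose inputs are not configured.
The report is a plain JSON-serializable dict with sorted, fully
deterministic content (no timestamps), so identical config plus seed yields
byte-identical report files.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from pydantic import ValidationError as PydanticValidationError

from . import commonality as cm
from . import enrichment as en
from . import io
from . import network as nw
from . import overlap as ov
from .de import GateConfig, gate_and_extract, run_de
from .errors import ConfigError, PipelineError

logger = logging.getLogger("anchorsig")

_PATH_FIELDS = ("gmt", "reference", "universe", "edges", "group_map")


class DatasetEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    matrix: Path
    groups: Path


class PipelineConfig(BaseModel):
    """Every fixed constant of the analysis, one field each."""

    model_config = ConfigDict(extra="forbid")

    anchor: str
    direction: Literal["up", "down"]
    datasets: list[DatasetEntry] = Field(min_length=1)
    levels: list[int] = Field(min_length=1)
    alpha: float = 0.05
    top_n: int = 1000
    min_overlap: int = 2
    min_levels: int = 3
    n_perm: int = 10
    seed: int = 0
    k_clusters: int = 4
    gmt: Optional[Path] = None
    reference: Optional[Path] = None
    universe: Optional[Path] = None
    edges: Optional[Path] = None
    group_map: Optional[Path] = None
    bh: bool = False
    slice_from_ranked: bool = False

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        return v

    @field_validator("levels")
    @classmethod
    def _levels_sorted(cls, v: list[int]) -> list[int]:
        if any(k < 1 for k in v):
            raise ValueError("levels must all be >= 1")
        if len(set(v)) != len(v):
            raise ValueError("levels must be distinct")
        return sorted(v)

    @field_validator("top_n", "min_overlap", "n_perm", "k_clusters")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be positive")
        return v

    @model_validator(mode="after")
    def _min_levels_feasible(self) -> "PipelineConfig":
        if not 1 <= self.min_levels <= len(self.levels):
            raise ValueError("min_levels must lie between 1 and the number of levels")
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) pipeline config file.

    Relative paths are resolved against the config file's directory, and
    every referenced path must exist.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        cfg = PipelineConfig(**data)
    except PydanticValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: {problems}") from exc

    base = path.parent

    def _resolve(p: Path) -> Path:
        return p if p.is_absolute() else base / p

    for entry in cfg.datasets:
        entry.matrix = _resolve(entry.matrix)
        entry.groups = _resolve(entry.groups)
        for fld in ("matrix", "groups"):
            target = getattr(entry, fld)
            if not target.exists():
                raise ConfigError(f"datasets[{entry.id}].{fld}: no such file: {target}")
    for fld in _PATH_FIELDS:
        val = getattr(cfg, fld)
        if val is not None:
            val = _resolve(val)
            setattr(cfg, fld, val)
            if not val.exists():
                raise ConfigError(f"{fld}: no such file: {val}")
    return cfg


def _config_echo(cfg: PipelineConfig) -> dict:
    out = cfg.model_dump(mode="json")
    out["datasets"] = [
        {"id": d.id, "matrix": str(d.matrix), "groups": str(d.groups)}
        for d in cfg.datasets
    ]
    return out


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every configured stage and write the run artifacts.

    Writes ``report.json``, ``ranked_genes.tsv``, per-level ORA tables and,
    when the network stage runs, ``subnetwork.sif`` under ``out_dir``.
    Returns the report dict. Any stage failure raises
    :class:`~anchorsig.errors.PipelineError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_echo(cfg), "stages": {}}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(cfg, out_dir, report)
    report["warnings"] = sorted(str(w.message) for w in caught)

    io.write_json(report, out_dir / "report.json")
    logger.info("run complete: %s", out_dir / "report.json")
    return report


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def _run_stages(cfg: PipelineConfig, out_dir: Path, report: dict) -> None:
    gate = GateConfig(
        anchor=cfg.anchor, direction=cfg.direction, alpha=cfg.alpha, adjust=cfg.bh
    )

    # --- differential expression + anchor gate --------------------------
    @_stage("de_gate")
    def de_stage():
        de_lists: dict[str, set[str]] = {}
        universe: set[str] = set()
        entries = []
        for entry in cfg.datasets:
            ds = io.read_expression(entry.matrix, entry.groups, dataset_id=entry.id)
            records = run_de(ds)
            passed, de_genes = gate_and_extract(records, gate)
            anchor_rec = next(r for r in records if r.gene == gate.anchor)
            entries.append({
                "id": entry.id,
                "passed": bool(passed),
                "n_genes_tested": len(records),
                "n_de": len(de_genes),
                "anchor_p": anchor_rec.p_value,
                "anchor_log2fc": anchor_rec.log2fc,
            })
            if passed:
                de_lists[entry.id] = de_genes
                universe |= {r.gene for r in records}
            logger.info("dataset %s: gate %s, %d DE genes",
                        entry.id, "passed" if passed else "failed", len(de_genes))
        report["stages"]["de_gate"] = {
            "datasets": entries,
            "n_passed": len(de_lists),
        }
        return de_lists, universe

    de_lists, tested_universe = de_stage()

    # --- commonality ----------------------------------------------------
    @_stage("commonality")
    def common_stage():
        matrix = cm.build_matrix(de_lists)
        ranked = cm.rank_genes(matrix, top_n=cfg.top_n)
        ranked.table.to_csv(out_dir / "ranked_genes.tsv", sep="\t", index=False)
        slices: dict[int, set[str]] = {}
        skipped_levels = []
        for k in cfg.levels:
            if k > len(matrix.datasets):
                skipped_levels.append(k)
                warnings.warn(
                    f"level {k} exceeds the {len(matrix.datasets)} gated "
                    f"dataset(s); slice skipped"
                )
                continue
            slices[k] = cm.slice_at(
                matrix, k, from_ranked=ranked if cfg.slice_from_ranked else None
            )
        report["stages"]["commonality"] = {
            "n_datasets": len(matrix.datasets),
            "dataset_ids": matrix.datasets,
            "n_genes": len(matrix.genes),
            "level_counts": {str(k): v for k, v in cm.level_counts(matrix).items()},
            "ranked_len": len(ranked.genes),
            "slices": {str(k): len(v) for k, v in slices.items()},
            "skipped_levels": skipped_levels,
        }
        return matrix, ranked, slices

    matrix, ranked, slices = common_stage()

    # --- universe for enrichment / overlap ------------------------------
    if cfg.universe is not None:
        ora_universe = io.read_gene_list(cfg.universe)
    else:
        ora_universe = tested_universe

    # --- enrichment + consensus -----------------------------------------
    consensus_results = None
    if cfg.gmt is None:
        report["stages"]["enrichment"] = {"skipped": "no gmt configured"}
    else:
        @_stage("enrichment")
        def ora_stage():
            coll = io.read_gmt(cfg.gmt)
            per_level = {}
            ora_report = {}
            for k, genes in slices.items():
                if not genes:
                    warnings.warn(f"level {k}: empty slice, no enrichment run")
                    continue
                recs = en.run_ora(
                    genes, coll, ora_universe, min_overlap=cfg.min_overlap,
                    alpha=cfg.alpha, adjust=cfg.bh,
                )
                per_level[k] = recs
                _write_ora_tsv(recs, out_dir / f"ora_level_{k}.tsv")
                ora_report[str(k)] = {
                    "n_records": len(recs),
                    "n_significant": sum(r.significant for r in recs),
                    "significant": sorted(r.set_id for r in recs if r.significant),
                }
            consensus = en.consensus_over_levels(per_level, min_levels=cfg.min_levels)
            report["stages"]["enrichment"] = {
                "per_level": ora_report,
                "consensus": [
                    {
                        "set_id": c.set_id,
                        "levels_significant": list(c.levels_significant),
                        "consensus": c.consensus,
                    }
                    for c in consensus if c.levels_significant
                ],
                "n_consensus": sum(c.consensus for c in consensus),
            }
            return consensus

        consensus_results = ora_stage()

    # --- reference-set overlap ------------------------------------------
    intersection: set[str] | None = None
    if cfg.reference is None:
        report["stages"]["overlap"] = {"skipped": "no reference configured"}
    else:
        @_stage("overlap")
        def overlap_stage():
            reference = io.read_gene_list(cfg.reference)
            cohort = set(ranked.genes)
            result, inter = ov.overlap_test(
                cohort, reference, ora_universe, n_perm=cfg.n_perm, seed=cfg.seed
            )
            report["stages"]["overlap"] = {
                "observed": result.observed,
                "n_perm": result.n_perm,
                "null_mean": result.null_mean,
                "null_sem": result.null_sem,
                "z_score": result.z_score if result.z_score not in
                           (float("inf"), float("-inf")) else None,
                "z_infinite": abs(result.z_score) == float("inf"),
                "empirical_p": result.empirical_p,
                "intersection": sorted(inter),
            }
            return inter

        intersection = overlap_stage()

    # --- PPI network ----------------------------------------------------
    if cfg.edges is None:
        report["stages"]["network"] = {"skipped": "no edges configured"}
    elif intersection is None:
        report["stages"]["network"] = {
            "skipped": "no reference/overlap stage to provide seed proteins"
        }
    else:
        @_stage("network")
        def network_stage():
            graph = io.read_edges(cfg.edges)
            net = nw.minimum_order(graph, intersection)
            io.write_sif(
                io.InteractionGraph.from_edges(net.edges), out_dir / "subnetwork.sif"
            )
            in_graph = [p for p in sorted(intersection) if p in graph.nodes]
            k_eff = min(cfg.k_clusters, len(in_graph))
            clusters = nw.graph_kmeans(graph, in_graph, k=k_eff, seed=cfg.seed)
            net_report = {
                "n_seeds": len(net.seeds),
                "connectors": list(net.connectors),
                "n_edges": len(net.edges),
                "dropped_seeds": list(net.dropped_seeds),
                "isolated_seeds": list(net.isolated_seeds),
                "k_clusters": k_eff,
                "cluster_labels": dict(sorted(clusters.labels.items())),
            }
            if cfg.gmt is not None:
                coll = io.read_gmt(cfg.gmt)
                ann = nw.annotate_network(
                    net, coll, ora_universe, min_overlap=cfg.min_overlap,
                    alpha=cfg.alpha, adjust=cfg.bh,
                )
                net_report["enrichment_significant"] = sorted(
                    r.set_id for r in ann.records if r.significant
                )
            report["stages"]["network"] = net_report

        network_stage()


def _write_ora_tsv(records, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "set_id": r.set_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "p_value": r.p_value, "q_value": r.q_value,
            "significant": r.significant,
            "overlap_genes": ",".join(r.overlap_genes),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["set_id", "k", "K", "n", "N", "p_value", "q_value",
                 "significant", "overlap_genes"],
    ).to_csv(path, sep="\t", index=False)
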