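"""End-to-end orchestration: maps -> projection -> meta-analysis -> synteny.

The pipeline consumes a single configuration (YAML file or
:class:`PipelineConfig`), validates every referenced path before any stage
runs, executes the stages in order, and writes tab-separated artifacts plus
a plain-text run log with per-stage in/out counts.  Identical config and
seed produce byte-identical outputs: nothing in the pipeline itself is
random (the seed is recorded for provenance and used only by upstream
simulation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError
from .maps import GeneticMap, merge_maps, read_map
from .meta import MetaResult, run_meta_analysis
from .qtl import ProjectionResult, project_qtl_table, read_qtl_table, records_to_frame
from .report import write_mqtl_report
from .synteny import (
    anchor_syntenome,
    genes_in_interval,
    rank_candidates,
    read_backbone,
    read_hsps,
    read_syntenome,
    score_pairs,
)


@dataclass
class PipelineConfig:
    map_paths: list[str]
    qtl_paths: list[tuple[str, str]]  # (qtl table path, source map path)
    out_dir: str
    merge_order: str = "by-size"
    criterion: str = "awe"
    ci_impute_width: float = 20.0
    syntenome_path: str | None = None
    backbone_path: str | None = None
    hsp_path: str | None = None
    query_length_path: str | None = None
    min_cip: float = 60.0
    min_calp: float = 70.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(
                map_paths=list(raw["maps"]),
                qtl_paths=[(s["qtl_table"], s["map"]) for s in raw["studies"]],
                out_dir=raw["out_dir"],
                merge_order=raw.get("merge_order", "by-size"),
                criterion=raw.get("criterion", "awe"),
                ci_impute_width=float(raw.get("ci_impute_width", 20.0)),
                syntenome_path=raw.get("syntenome"),
                backbone_path=raw.get("backbone"),
                hsp_path=raw.get("hsps"),
                query_length_path=raw.get("query_lengths"),
                min_cip=float(raw.get("min_cip", 60.0)),
                min_calp=float(raw.get("min_calp", 70.0)),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as e:
            raise ConfigError(f"{path}: missing config key {e}") from e

    def validate(self) -> None:
        paths = list(self.map_paths)
        for q, m in self.qtl_paths:
            paths.extend([q, m])
        for p in (self.syntenome_path, self.backbone_path, self.hsp_path, self.query_length_path):
            if p:
                paths.append(p)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        if not (0 <= self.min_cip <= 100 and 0 <= self.min_calp <= 100):
            raise ConfigError("CIP/CALP thresholds must be in [0, 100]")
        if self.ci_impute_width <= 0:
            raise ConfigError("ci_impute_width must be > 0")


@dataclass
class PipelineResult:
    consensus: GeneticMap
    projections: list[ProjectionResult]
    meta: MetaResult
    repertoires: dict[str, pd.DataFrame] = field(default_factory=dict)
    candidates: pd.DataFrame | None = None
    log_lines: list[str] = field(default_factory=list)


def integrate(
    maps: list[GeneticMap],
    studies: list[tuple[list, GeneticMap]],
    criterion: str = "awe",
    merge_order: str = "by-size",
    ci_impute_width: float = 20.0,
    syntenome: pd.DataFrame | None = None,
    backbone: pd.DataFrame | None = None,
    hsps: pd.DataFrame | None = None,
    query_lengths: dict[str, int] | None = None,
    min_cip: float = 60.0,
    min_calp: float = 70.0,
) -> PipelineResult:
    """Run the full integration from in-memory objects.

    ``studies`` is a list of (QTL records, source GeneticMap) pairs.
    """
    log: list[str] = []
    merged = merge_maps(maps, order=merge_order)
    log.append(
        f"maps: {len(maps)} input maps -> consensus {len(merged.consensus)} markers, "
        f"{len(merged.conflicts)} conflicted markers removed, "
        f"{len(merged.unplaced)} unplaced"
    )
    projections: list[ProjectionResult] = []
    projected_all = []
    n_in = n_excl = 0
    for records, source_map in studies:
        res = project_qtl_table(
            records, source_map, merged.consensus, ci_impute_width=ci_impute_width
        )
        projections.append(res)
        projected_all.extend(res.projected)
        n_in += len(records)
        n_excl += len(res.excluded)
    log.append(f"projection: {n_in} QTLs in -> {len(projected_all)} projected, {n_excl} excluded")
    meta = run_meta_analysis(projected_all, criterion=criterion)
    log.append(
        f"meta-analysis: {len(projected_all)} projected QTLs -> {len(meta.mqtls)} MQTLs, "
        f"{int((meta.audit['status'] == 'unresolved').sum())} QTLs in unresolved clusters"
    )
    result = PipelineResult(merged.consensus, projections, meta, log_lines=log)
    result.merge = merged
    if syntenome is not None and backbone is not None:
        anchored = anchor_syntenome(syntenome, backbone)
        for m in meta.mqtls:
            try:
                result.repertoires[m.mqtl_id] = genes_in_interval(
                    anchored, m.chromosome, (m.ci_left, m.ci_right)
                )
            except Exception:
                result.repertoires[m.mqtl_id] = anchored.iloc[0:0]
        log.append(
            "synteny: gene repertoires for "
            f"{len(result.repertoires)} MQTLs, "
            f"{sum(len(v) for v in result.repertoires.values())} genes total"
        )
    if hsps is not None and query_lengths is not None:
        scored = score_pairs(hsps, query_lengths)
        result.candidates = rank_candidates(scored, min_cip=min_cip, min_calp=min_calp)
        log.append(
            f"candidates: {scored['query_id'].nunique() if len(scored) else 0} queries scored, "
            f"{int(result.candidates['passed'].sum()) if len(result.candidates) else 0} passing"
        )
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Validate the config, run every configured stage, write all artifacts."""
    config.validate()
    maps = [read_map(p, Path(p).stem) for p in config.map_paths]
    studies = []
    for q_path, m_path in config.qtl_paths:
        studies.append((read_qtl_table(q_path), read_map(m_path, Path(m_path).stem)))
    syntenome = read_syntenome(config.syntenome_path) if config.syntenome_path else None
    backbone = read_backbone(config.backbone_path) if config.backbone_path else None
    hsps = read_hsps(config.hsp_path) if config.hsp_path else None
    query_lengths = None
    if config.query_length_path:
        ql = pd.read_csv(config.query_length_path, sep="\t")
        query_lengths = dict(zip(ql["query_id"], ql["length"].astype(int)))
    result = integrate(
        maps,
        studies,
        criterion=config.criterion,
        merge_order=config.merge_order,
        ci_impute_width=config.ci_impute_width,
        syntenome=syntenome,
        backbone=backbone,
        hsps=hsps,
        query_lengths=query_lengths,
        min_cip=config.min_cip,
        min_calp=config.min_calp,
    )
    _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.consensus.to_tsv(out / "consensus.tsv")
    result.merge.conflicts_frame().to_csv(out / "conflicts.tsv", sep="\t", index=False)
    projected = [p for res in result.projections for p in res.projected]
    records_to_frame(projected).to_csv(
        out / "projected.tsv", sep="\t", index=False, float_format="%.6g"
    )
    write_mqtl_report(result.meta.mqtls, out / "mqtl.tsv")
    audit = result.meta.audit.copy()
    excluded = pd.concat(
        [r.excluded for r in result.projections], ignore_index=True
    ) if result.projections else pd.DataFrame()
    audit.to_csv(out / "audit.tsv", sep="\t", index=False)
    excluded.to_csv(out / "excluded_qtls.tsv", sep="\t", index=False)
    if result.repertoires:
        rows = []
        for mid, rep in sorted(result.repertoires.items()):
            r = rep.copy()
            r.insert(0, "mqtl_id", mid)
            rows.append(r)
        pd.concat(rows, ignore_index=True).to_csv(
            out / "repertoire.tsv", sep="\t", index=False, float_format="%.4f"
        )
    if result.candidates is not None:
        cand = result.candidates.copy()
        for col in ("cip", "calp"):
            cand[col] = cand[col].map(lambda v: f"{v:.2f}")
        cand.to_csv(out / "candidates.tsv", sep="\t", index=False)
    with open(out / "run.log", "w") as fh:
        fh.write("resolved config:\n")
        for k, v in sorted(dataclasses.asdict(config).items()):
            fh.write(f"  {k}: {v}\n")
        for line in result.log_lines:
            fh.write(line + "\n")
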