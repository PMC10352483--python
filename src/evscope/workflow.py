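"""Pipeline orchestration: simulate -> decode -> diffexp -> combos ->
cluster -> roc, driven by one YAML config, with a JSON manifest of outputs.

Every stage also runs standalone from the previous stage's on-disk outputs;
the manifest records file paths, row counts, seeds and parameter hashes so
reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, combinations, decode, expression, roc, simulate
from .matrix import SingleEVMatrix, summarize_matrix
from .panel import PanelSpec, default_panel

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "decode", "diffexp", "combos", "cluster", "roc"]


@dataclass
class RunConfig:
    stages: list[str]
    outdir: Path
    seed: int = 0
    case_group: str = "OVCA"
    params: dict = field(default_factory=dict)  # per-stage parameter blocks

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if not self.stages or self.stages != STAGE_ORDER[: len(self.stages)]:
            raise ValueError(f"stages must be a nonempty prefix of "
                             f"{STAGE_ORDER}, got {self.stages}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(stages=data["stages"], outdir=Path(data["outdir"]),
                   seed=int(data.get("seed", 0)),
                   case_group=data.get("case_group", "OVCA"),
                   params=data.get("params", {}))


def _hash_params(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _load_decoded(outdir: Path) -> tuple[dict[str, SingleEVMatrix], pd.Series,
                                         PanelSpec]:
    panel = PanelSpec.from_tsv(outdir / "panel.tsv")
    sheet = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0)
    groups = sheet["group"]
    matrices = {
        sid: SingleEVMatrix.from_long_tsv(
            outdir / "decoded" / f"{sid}.counts.tsv", sid,
            list(panel.proteins))
        for sid in groups.index}
    return matrices, groups, panel


def run(config: RunConfig) -> dict:
    """Execute the configured stage prefix; returns the manifest dict."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}

    for stage in config.stages:
        params = dict(config.params.get(stage, {}))
        entry: dict = {"params_hash": _hash_params(params)}

        if stage == "simulate":
            sim_kwargs = {k: v for k, v in params.items()
                          if k in simulate.SimConfig.__dataclass_fields__}
            sim_cfg = simulate.SimConfig(seed=config.seed, **sim_kwargs)
            panel, subclusters = simulate.default_scenario(
                planted_weight=params.get("planted_weight", 0.3))
            truth = simulate.simulate_population(sim_cfg, panel, subclusters)
            truth.write(outdir)
            fastqs = simulate.emit_reads(truth, outdir / "reads")
            state.update(truth=truth, panel=panel, fastqs=fastqs,
                         groups=truth.sample_groups)
            entry.update(n_samples=len(fastqs),
                         files=[str(p) for p in fastqs.values()])

        elif stage == "decode":
            if "fastqs" not in state:
                fastq_dir = Path(params.get("fastq_dir", outdir / "reads"))
                fq = sorted(fastq_dir.glob("*.fastq")) + \
                    sorted(fastq_dir.glob("*.fastq.gz"))
                if not fq:
                    raise FileNotFoundError(
                        "decode: no FASTQ input (run simulate first or set "
                        "params.decode.fastq_dir)")
                state["fastqs"] = {p.name.split(".")[0]: p for p in fq}
                state["panel"] = PanelSpec.from_tsv(
                    params.get("panel", outdir / "panel.tsv"))
                sheet = pd.read_csv(outdir / "samples.tsv", sep="\t",
                                    index_col=0)
                state["groups"] = sheet["group"]
            dec_dir = outdir / "decoded"
            dec_dir.mkdir(exist_ok=True)
            matrices, summaries = {}, []
            for sid, path in state["fastqs"].items():
                mat, st = decode.decode_sample(
                    path, state["panel"],
                    max_mismatch=params.get("max_mismatch", 0))
                matrices[sid] = mat
                mat.to_long_tsv(dec_dir / f"{sid}.counts.tsv")
                summaries.append({**summarize_matrix(mat), **st.as_dict()})
            pd.DataFrame(summaries).to_csv(dec_dir / "summary.tsv",
                                           sep="\t", index=False)
            state["matrices"] = matrices
            entry.update(n_samples=len(matrices),
                         files=[str(dec_dir / "summary.tsv")])

        elif stage == "diffexp":
            if "matrices" not in state:
                state["matrices"], state["groups"], state["panel"] = \
                    _load_decoded(outdir)
            expr = expression.aggregate(state["matrices"], state["groups"])
            expression.tmm_normalize(expr)
            de = expression.differential_test(
                expr, config.case_group,
                use_normalized=params.get("use_normalized", True))
            expr.normalized.to_csv(outdir / "expression_normalized.tsv",
                                   sep="\t")
            de.to_csv(outdir / "differential_expression.tsv", sep="\t")
            state["expr"] = expr
            entry.update(n_proteins=len(de),
                         n_significant=int((de.q_value < 0.05).sum()),
                         files=[str(outdir / "differential_expression.tsv")])

        elif stage == "combos":
            tables = [combinations.cpm_normalize(
                combinations.count_combinations(m))
                for m in state["matrices"].values()]
            frame = combinations.combination_frame(tables)
            frame.to_csv(outdir / "combination_cpm.tsv", sep="\t")
            dc = combinations.differential_combinations(
                tables, state["groups"], config.case_group)
            dc.to_csv(outdir / "differential_combinations.tsv", sep="\t")
            state["tables"] = tables
            focal = params.get("focal")
            if focal:
                partners = combinations.focal_partners(dc, focal)
                entry["focal_partners"] = {focal: partners}
            entry.update(n_pairs=len(frame),
                         files=[str(outdir / "differential_combinations.tsv")])

        elif stage == "cluster":
            model, assignment = clustering.cluster_evs(
                state["matrices"], state["groups"],
                grid_w=params.get("grid_w", 10),
                grid_h=params.get("grid_h", 10),
                k=params.get("k", 28), seed=config.seed)
            X, _ = clustering.featurize(state["matrices"], state["groups"],
                                        mode="binary")
            panel_proteins = list(state["panel"].proteins)
            profiles = clustering.profile_clusters(assignment, X,
                                                   panel_proteins)
            enr = clustering.enrichment_test(profiles, assignment,
                                             config.case_group)
            assignment.to_csv(outdir / "cluster_assignment.tsv", sep="\t",
                              index=False)
            profiles.to_csv(outdir / "cluster_profiles.tsv", sep="\t")
            enr.to_csv(outdir / "cluster_enrichment.tsv", sep="\t")
            state.update(profiles=profiles, assignment=assignment)
            entry.update(n_clusters=int(assignment.metacluster.nunique()),
                         files=[str(outdir / "cluster_profiles.tsv")])

        elif stage == "roc":
            marker = params.get("marker", "CDCP1")
            pair = params.get("pair", ["CDCP1", "ITGA6"])
            single = roc.roc_single(state["expr"], marker, config.case_group)
            pair_res = roc.roc_pair(pair[0], pair[1], config.case_group,
                                    tables=state["tables"],
                                    groups=state["groups"])
            summary = pd.DataFrame([
                {"marker": single.marker, "auc": single.auc},
                {"marker": pair_res.marker, "auc": pair_res.auc}])
            summary.to_csv(outdir / "roc_auc.tsv", sep="\t", index=False)
            entry.update(auc={r.marker: r.auc for r in (single, pair_res)},
                         files=[str(outdir / "roc_auc.tsv")])

        manifest["stages"][stage] = entry
        logger.info("stage %s done", stage)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
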