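"""End-to-end orchestration: simulate -> ingest -> anthropometry -> summaries
-> clustering -> networks, with a resolved-config manifest for reproducibility.

Every run is driven by a :class:`PipelineConfig` (YAML/JSON/dict); one root
seed feeds named substreams per stage, so any artifact is reproducible from
the manifest (config + seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    anthropometry,
    cohort_stats,
    consumption_clustering,
    correlation_networks,
    ffq_ingest,
    synthetic_cohort,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_inputs", "load_config"]

logger = logging.getLogger("dietnet")


@dataclass
class PipelineConfig:
    outdir: str = "dietnet_out"
    seed: int = 0
    # inputs; when simulate=True they are generated instead
    simulate: bool = True
    responses_csv: str | None = None
    roster_csv: str | None = None
    reference_csv: str | None = None  # BMI percentile cut-offs
    map_csv: str | None = None
    # stage parameters
    B: int = 100
    alpha: float = 0.05
    rho_min: float = 0.5
    support_min: float = 0.5
    k_food_groups: int = 4
    k_participants: int = 3
    cluster_bootstrap_B: int = 100
    uniform_correction_kg: float = anthropometry.DEFAULT_UNIFORM_CORRECTION_KG
    stratify_by: str = "anthro_class"
    min_stratum_rows: int = 20
    adjust_within_bootstrap: bool = True

    def validate(self) -> None:
        if self.B < 1 or self.cluster_bootstrap_B < 1:
            raise ValueError("bootstrap counts must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.rho_min <= 1 and 0 <= self.support_min <= 1):
            raise ValueError("rho_min and support_min must be in [0, 1]")
        if not self.simulate and (self.responses_csv is None or self.roster_csv is None):
            raise ValueError(
                "with simulate disabled, responses_csv and roster_csv are required"
            )

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {seconds, artifacts}
    input_checksums: dict = field(default_factory=dict)
    error: str | None = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig(**data)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Schema-check input CSVs; returns a list of violations (report-only)."""
    violations: list[dict] = []

    def viol(file, row, message):
        violations.append({"file": str(file), "row": row, "message": message})

    resp = paths.get("responses_csv")
    if resp:
        if not Path(resp).exists():
            viol(resp, None, "file does not exist")
        else:
            df = pd.read_csv(resp)
            required = {"participant_id", "item_id", "frequency_category", "times", "portion_grams"}
            missing = required - set(df.columns)
            if missing:
                viol(resp, None, f"missing columns: {sorted(missing)}")
            else:
                for i, r in df.iterrows():
                    if not (1 <= int(r.item_id) <= ffq_ingest.N_ITEMS):
                        viol(resp, int(i), f"item_id {r.item_id} outside 1..97")
                    if r.frequency_category not in ffq_ingest.FREQUENCY_CATEGORIES:
                        viol(
                            resp,
                            int(i),
                            f"unknown frequency {r.frequency_category!r}; allowed: "
                            f"{', '.join(ffq_ingest.FREQUENCY_CATEGORIES)}",
                        )
                    if float(r.portion_grams) < 0:
                        viol(resp, int(i), "negative portion_grams")

    ros = paths.get("roster_csv")
    if ros:
        if not Path(ros).exists():
            viol(ros, None, "file does not exist")
        else:
            df = pd.read_csv(ros)
            required = {"id", "sex", "age", "weight", "height"}
            missing = required - set(df.columns)
            if missing:
                viol(ros, None, f"missing columns: {sorted(missing)}")
            else:
                for i, r in df.iterrows():
                    if float(r.height) <= 0:
                        viol(ros, int(i), "non-positive height")
                    if r.sex not in ("male", "female"):
                        viol(ros, int(i), f"unknown sex {r.sex!r}")
    return violations


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; stage failure halts downstream stages but the
    manifest (with the error recorded) is always written."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config), config_hash=config.content_hash(), seed=config.seed
    )
    manifest_path = out / "manifest.json"
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: s
        for name, s in zip(
            ("simulate", "cluster", "network"), root.spawn(3)
        )
    }

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            logger.info("stage %s starting", name)
            artifacts = fn()
            manifest.stages[name] = {
                "seconds": round(time.time() - t0, 3),
                "artifacts": artifacts,
            }
            logger.info("stage %s done (%.2fs)", name, time.time() - t0)

        return wrap

    try:
        ref = (
            anthropometry.BMIReferenceTable.from_csv(config.reference_csv)
            if config.reference_csv
            else anthropometry.make_synthetic_reference_table()
        )
        gm = (
            ffq_ingest.read_food_group_map(config.map_csv)
            if config.map_csv
            else ffq_ingest.load_default_food_group_map()
        )

        state: dict = {}

        @stage("simulate" if config.simulate else "load")
        def _inputs():
            if config.simulate:
                sim_seed = int(streams["simulate"].generate_state(1)[0] % (2**31))
                sim_cfg = synthetic_cohort.default_simulation_config(seed=sim_seed)
                cohort = synthetic_cohort.simulate_cohort(
                    sim_cfg, reference=ref, uniform_correction_kg=config.uniform_correction_kg
                )
                state["roster"] = cohort.roster
                state["consumption"] = cohort.consumption
                return synthetic_cohort.write_cohort(cohort, out)
            state["roster"] = pd.read_csv(config.roster_csv, dtype={"id": str})
            responses = ffq_ingest.read_responses_csv(config.responses_csv)
            state["consumption"] = ffq_ingest.aggregate_food_groups(responses, gm)
            manifest.input_checksums = {
                "responses_csv": _checksum(config.responses_csv),
                "roster_csv": _checksum(config.roster_csv),
            }
            cons_path = out / "consumption.csv"
            ffq_ingest.write_consumption_csv(state["consumption"], cons_path)
            return {"consumption": str(cons_path)}

        @stage("anthropometry")
        def _anthro():
            roster = anthropometry.classify_roster(
                state["roster"], ref, config.uniform_correction_kg
            )
            state["roster"] = roster
            path = out / "roster_classified.csv"
            roster.to_csv(path, index=False)
            return {"roster_classified": str(path)}

        @stage("summaries")
        def _summaries():
            roster = state["roster"].copy()
            roster.index = roster["id"].astype(str)
            rows = cohort_stats.build_cohort_summary(
                roster, state["consumption"], stratify_by=config.stratify_by
            )
            path = out / "cohort_summary.csv"
            cohort_stats.summary_to_frame(rows).to_csv(path, index=False)
            screen = cohort_stats.bmi_spearman_screen(state["consumption"], roster)
            screen_path = out / "bmi_spearman_screen.csv"
            screen.to_csv(screen_path, index=False)
            return {"cohort_summary": str(path), "bmi_spearman_screen": str(screen_path)}

        @stage("clustering")
        def _cluster():
            z = consumption_clustering.zscore_normalize(state["consumption"])
            seeds = streams["cluster"].spawn(2)
            artifacts = {}
            for axis, k, sseq in (
                ("food_groups", config.k_food_groups, seeds[0]),
                ("participants", config.k_participants, seeds[1]),
            ):
                tree = consumption_clustering.ward_cluster(z, axis)
                assign = consumption_clustering.cut_tree(tree, k)
                nwk = out / f"dendrogram_{axis}.nwk"
                nwk.write_text(consumption_clustering.tree_to_newick(tree))
                rows = [
                    {"id": leaf, "axis": axis, "cluster": c}
                    for leaf, c in assign.labels.items()
                ]
                if axis == "participants":
                    labels = consumption_clustering.consumption_level_labels(assign, z)
                    for r in rows:
                        r["level"] = labels[r["cluster"]]
                acsv = out / f"clusters_{axis}.csv"
                pd.DataFrame(rows).to_csv(acsv, index=False)
                support = consumption_clustering.bootstrap_cluster_support(
                    z,
                    axis,
                    B=config.cluster_bootstrap_B,
                    seed=int(sseq.generate_state(1)[0] % (2**31)),
                )
                scsv = out / f"cluster_support_{axis}.csv"
                pd.DataFrame(
                    [
                        {
                            "bipartition": "|".join(sorted(bp)),
                            "support": s,
                            "B": support.n_replicates,
                        }
                        for bp, s in support.support.items()
                    ]
                ).to_csv(scsv, index=False)
                artifacts[f"dendrogram_{axis}"] = str(nwk)
                artifacts[f"clusters_{axis}"] = str(acsv)
                artifacts[f"cluster_support_{axis}"] = str(scsv)
            return artifacts

        @stage("networks")
        def _networks():
            roster = state["roster"].copy()
            roster.index = roster["id"].astype(str)
            cons = state["consumption"]
            strata = sorted(roster[config.stratify_by].unique())
            nets, density = {}, {}
            sub = streams["network"].spawn(len(strata))
            artifacts = {}
            for s, sseq in zip(strata, sub):
                ids = roster.index[roster[config.stratify_by] == s]
                block = cons.loc[cons.index.intersection(ids)]
                if len(block) < config.min_stratum_rows:
                    logger.warning("stratum %s too small (%d rows); skipped", s, len(block))
                    continue
                net, samples = correlation_networks.bootstrap_network(
                    block,
                    stratum=str(s),
                    B=config.B,
                    alpha=config.alpha,
                    rho_min=config.rho_min,
                    support_min=config.support_min,
                    seed=int(sseq.generate_state(1)[0] % (2**31)),
                    adjust_within_bootstrap=config.adjust_within_bootstrap,
                    min_rows=config.min_stratum_rows,
                )
                nets[str(s)] = net
                density[str(s)] = samples
                gpath = out / f"network_{s}.graphml"
                correlation_networks.network_to_graphml(net, gpath)
                epath = out / f"edges_{s}.tsv"
                correlation_networks.edges_to_frame(net).to_csv(epath, sep="\t", index=False)
                artifacts[f"network_{s}"] = str(gpath)
                artifacts[f"edges_{s}"] = str(epath)
            all_samples = [x for v in density.values() for x in v]
            dpath = out / "density_samples.csv"
            correlation_networks.density_samples_to_frame(all_samples).to_csv(
                dpath, index=False
            )
            artifacts["density_samples"] = str(dpath)
            if len(density) >= 2:
                h, p, dunn = correlation_networks.compare_density(density)
                cpath = out / "density_comparison.csv"
                dunn.assign(kruskal_H=h, kruskal_p=p).to_csv(cpath, index=False)
                artifacts["density_comparison"] = str(cpath)
            if nets:
                npath = out / "node_degrees.csv"
                correlation_networks.node_degree_profile(nets).to_csv(npath)
                artifacts["node_degrees"] = str(npath)
            return artifacts

    except Exception as exc:  # manifest must record failures
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest
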