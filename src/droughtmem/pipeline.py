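"""End-to-end orchestration: simulate -> normalize -> DE -> classify ->
hierarchy -> enrich -> switch -> hubs, with a reproducible run manifest.

A :class:`PipelineConfig` either points at input files (counts + design,
gene lengths, regulator list, orthogroups, annotation, interaction edges,
leaf weights) or requests a synthetic dataset; optional stages run only
when their inputs are present.  All randomness flows from one top-level
seed.  The manifest records a hash of the resolved configuration, the
package version, and per-stage row counts, so two runs with identical
config and inputs produce identical stage outputs and manifests (modulo
timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import MEMORY_CATEGORIES, NONE_CATEGORY, classify_all, summarize
from .de import estimate_size_factors, nb_test
from .enrichment import enrich, load_annotation
from .errors import ConfigurationError, StageError
from .expression import (
    CountMatrix,
    ECOTYPES,
    compute_fpkm,
    effective_mapped_reads,
    log_fpkm,
    read_counts,
    read_gene_lengths,
)
from .hubs import load_edges, score_table, top_hubs
from .orthology import load_orthogroups, partition, venn_counts
from .physiology import read_weight_records, summarize_groups
from .simulate import SimulationConfig, simulate
from .switch import correlate, detect_switch_modules, filter_edges, split_regulatory

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05
    lfc_min: float = 1.0
    r_min: float = 0.9
    p_max: float = 0.05
    min_module_size: int = 5
    total_genes: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = raw.pop("thresholds", {})
        cfg = cls(
            outdir=Path(raw.pop("outdir", "droughtmem_out")),
            seed=int(raw.pop("seed", 0)),
            simulate=raw.pop("simulate", None),
            inputs={k: str(v) for k, v in (raw.pop("inputs", {}) or {}).items()},
            total_genes=raw.pop("total_genes", None),
            **{k: v for k, v in thresholds.items()},
        )
        if raw:
            raise ConfigurationError(f"unknown config keys: {sorted(raw)}")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.p_max < 1:
            raise ConfigurationError("alpha and p_max must lie in (0, 1)")
        if self.lfc_min < 0 or not 0 < self.r_min < 1 or self.min_module_size < 1:
            raise ConfigurationError("invalid threshold configuration")
        if self.simulate is None and not {"counts", "design"} <= set(self.inputs):
            raise ConfigurationError(
                "either a 'simulate' block or counts+design inputs are required"
            )
        for key, p in self.inputs.items():
            if not Path(p).exists():
                raise ConfigurationError(f"input '{key}' does not exist: {p}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=str))


def ddct_relative_expression(
    ct_target: float,
    ct_reference: float | list[float],
    ct_target_cal: float,
    ct_reference_cal: float | list[float],
) -> float:
    """Relative expression by the 2^-ddCt method.

    Multiple reference-gene Ct values are combined by their geometric mean
    before forming dCt.
    """

    def combine(ct) -> float:
        arr = np.atleast_1d(np.asarray(ct, dtype=float))
        if np.any(arr <= 0):
            raise ConfigurationError("Ct values must be positive")
        return float(np.exp(np.mean(np.log(arr))))

    ddct = (ct_target - combine(ct_reference)) - (ct_target_cal - combine(ct_reference_cal))
    return float(2.0 ** -ddct)


def _stage(manifest: RunManifest, outdir: Path, name: str):
    """Context manager recording stage success/failure in the manifest."""

    class _Ctx:
        def __enter__(self):
            return manifest.stages.setdefault(name, {})

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                failed = outdir / "failed"
                failed.mkdir(parents=True, exist_ok=True)
                (failed / f"{name}.txt").write_text(f"{exc_type.__name__}: {exc}\n")
                manifest.write(outdir / "manifest.json")
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every configured stage; returns the populated manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    inputs = dict(config.inputs)
    dataset = None

    if config.simulate is not None:
        with _stage(manifest, outdir, "simulate") as st:
            sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulate})
            dataset = simulate(sim_cfg)
            simdir = outdir / "simulated"
            dataset.write(simdir)
            inputs.setdefault("counts", str(simdir / "counts.tsv"))
            inputs.setdefault("design", str(simdir / "design.tsv"))
            inputs.setdefault("lengths", str(simdir / "gene_lengths.tsv"))
            inputs.setdefault("regulators", str(simdir / "regulators.txt"))
            inputs.setdefault("weights", str(simdir / "weights.tsv"))
            st["n_genes"] = len(dataset.counts.gene_ids)
            st["n_samples"] = len(dataset.counts.sample_ids)
            st["n_truth_modules"] = len(dataset.truth_modules)

    with _stage(manifest, outdir, "normalize") as st:
        counts = read_counts(inputs["counts"], inputs["design"])
        if "lengths" in inputs:
            ann = read_gene_lengths(inputs["lengths"])
            fpkm = compute_fpkm(counts, ann)
            fpkm.rename_axis("gene_id").to_csv(outdir / "fpkm.tsv", sep="\t")
            st["fpkm_genes"] = int(fpkm.shape[0])
        else:
            fpkm = None
        st["n_genes"] = len(counts.gene_ids)
        st["n_samples"] = len(counts.sample_ids)

    total_genes = config.total_genes or len(counts.gene_ids)
    records_by_eco: dict[str, pd.DataFrame] = {}
    with _stage(manifest, outdir, "differential_expression") as st:
        for eco in ECOTYPES:
            if not counts.samples_for(ecotype=eco):
                continue
            sf = estimate_size_factors(counts.subset(ecotype=eco))
            c_s1 = nb_test(counts, "R0", "S1", ecotype=eco, alpha=config.alpha,
                           lfc_min=config.lfc_min, size_factors=sf)
            c_s3 = nb_test(counts, "S1", "S3", ecotype=eco, alpha=config.alpha,
                           lfc_min=config.lfc_min, size_factors=sf)
            c_s1.to_csv(outdir / f"contrast_{eco}_S1_vs_R0.tsv", sep="\t", index=False)
            c_s3.to_csv(outdir / f"contrast_{eco}_S3_vs_S1.tsv", sep="\t", index=False)
            recs = classify_all(c_s1, c_s3, eco)
            recs.to_csv(outdir / f"dmg_records_{eco}.tsv", sep="\t", index=False)
            records_by_eco[eco] = recs
            summ = summarize(recs, total_genes)
            (outdir / f"summary_{eco}.json").write_text(
                json.dumps(summ.to_dict(), indent=1)
            )
            st[eco] = {
                "deg": summ.deg, "memory": summ.memory,
                "non_memory": summ.non_memory, "late": summ.late,
            }

    dmg_sets = {
        eco: set(r.loc[r["category"] != NONE_CATEGORY, "gene"])
        for eco, r in records_by_eco.items()
    }

    if "orthogroups" in inputs:
        with _stage(manifest, outdir, "hierarchy") as st:
            ogs = load_orthogroups(inputs["orthogroups"])
            outgroup_sp = [s for s in ogs.species if s not in ECOTYPES]
            og_dmgs = dict(dmg_sets)
            for sp in outgroup_sp:
                # every outgroup member listed in the table counts as a DMG
                og_dmgs[sp] = {
                    g for cell in ogs.groups.values() for g in cell.get(sp, [])
                }
            part = partition(ogs, og_dmgs, focal=("AEX", "WW"), outgroups=outgroup_sp)
            counts_by_tier = venn_counts(part)
            (outdir / "hierarchy.json").write_text(
                json.dumps(
                    {"venn": counts_by_tier,
                     "og_tier": part.og_tier,
                     "singletons": {k: sorted(v) for k, v in part.singletons.items()}},
                    indent=1,
                )
            )
            st.update(counts_by_tier)

    if "annotation" in inputs:
        with _stage(manifest, outdir, "enrichment") as st:
            ann = load_annotation(inputs["annotation"], background=set(counts.gene_ids))
            for eco, recs in records_by_eco.items():
                memory = set(recs.loc[recs["category"].isin(MEMORY_CATEGORIES), "gene"])
                res = enrich(memory, ann, alpha=config.alpha)
                res.to_csv(outdir / f"enrichment_{eco}.tsv", sep="\t", index=False)
                st[eco] = int(res["significant"].sum()) if len(res) else 0

    if "regulators" in inputs and fpkm is not None:
        with _stage(manifest, outdir, "switch") as st:
            regulators = {
                line.strip()
                for line in Path(inputs["regulators"]).read_text().splitlines()
                if line.strip()
            }
            # co-expression runs on FPKM with composition-robust depths so
            # that depth correction does not leak treatment signal
            fpkm_corr = compute_fpkm(counts, ann, effective_mapped_reads(counts))
            all_modules = []
            for eco, recs in records_by_eco.items():
                dmgs = dmg_sets[eco]
                reg, func = split_regulatory(dmgs, regulators)
                cols = counts.samples_for(ecotype=eco)
                expr = log_fpkm(fpkm_corr[cols])
                edges = filter_edges(
                    correlate(expr, reg, func), r_min=config.r_min, p_max=config.p_max
                )
                edges.to_csv(outdir / f"switch_edges_{eco}.tsv", sep="\t", index=False)
                mods = detect_switch_modules(
                    edges, min_module_size=config.min_module_size, ecotype=eco
                )
                all_modules.extend(mods)
                st[eco] = {"edges": int(len(edges)), "modules": len(mods)}
            (outdir / "switch_modules.json").write_text(
                json.dumps([m.to_dict() for m in all_modules], indent=1)
            )

    if "edges" in inputs:
        with _stage(manifest, outdir, "hubs") as st:
            net = load_edges(inputs["edges"])
            table = score_table(net)
            table.to_csv(outdir / "hub_scores.tsv", sep="\t", index=False)
            st["nodes"] = net.number_of_nodes()
            st["top5_mcc"] = [g for g, _ in top_hubs(
                dict(zip(table["gene"], table["mcc"])), k=5)]

    if "weights" in inputs:
        with _stage(manifest, outdir, "physiology") as st:
            recs = read_weight_records(inputs["weights"])
            for index in ("rwc", "water_loss"):
                summ = summarize_groups(recs, index=index, alpha=config.alpha)
                summ.to_csv(outdir / f"physiology_{index}.tsv", sep="\t", index=False)
            st["n_records"] = len(recs)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
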