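"""End-to-end orchestration: run the analysis stages from one config + seed.

A run loads (or simulates) its inputs, executes the requested stages in
dependency order (io → diversity → compositional → network / assembly / rda),
and writes every artifact with a manifest.  All randomness flows from the one
global seed through a fixed per-stage fan-out, so re-running the same config
is bit-identical and changing one stage's replicate count cannot perturb
another stage's random stream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import assembly as assembly_mod
from . import compositional, diversity, env_selection, network, simulate
from .data_io import (
    OtuTable,
    PhyloTree,
    ResultBundle,
    SampleFrame,
    read_otu_table,
    read_sample_frame,
    read_tree,
    write_results,
)


class ConfigurationError(ValueError):
    pass


STAGES = ("diversity", "cluster", "network", "assembly", "rda")

# fixed fan-out indexes: stage streams never move when other stages change
_STAGE_STREAM = {
    "simulate": 0,
    "diversity": 1,
    "cluster": 2,
    "network": 3,
    "assembly": 4,
    "rda": 5,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_STREAM[stage]])
    return int(ss.generate_state(1)[0] >> 1)


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "guyot_out"
    stages: tuple[str, ...] = STAGES
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    params: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)
    subset: list[str] | None = None  # matched-arrangement re-analysis

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")
        if self.simulate is None and self.inputs is None:
            raise ConfigurationError("config needs either 'simulate' or 'inputs'")
        for stage, p in self.params.items():
            for key in ("n_perm", "n_null_bnti", "n_null_rc"):
                if key in p and p[key] < 100:
                    raise ConfigurationError(
                        f"{stage}.{key} = {p[key]} < 100 permutations"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def subset_samples(
    table: OtuTable,
    meta: SampleFrame | None,
    sample_ids: Iterable[str],
) -> tuple[OtuTable, SampleFrame | None]:
    """Consistently filter all inputs to a sample list (matched arrangements)."""
    ids = list(sample_ids)
    table = table.subset_samples(ids)
    if meta is not None:
        meta = meta.subset_samples(ids)
    return table, meta


def _load_inputs(
    config: RunConfig,
) -> tuple[OtuTable, SampleFrame | None, PhyloTree | None]:
    if config.simulate is not None:
        sim = simulate.SimulationConfig(
            seed=stage_seed(config.seed, "simulate"), **config.simulate
        )
        table, meta, tree, _truth = simulate.simulate_dataset(sim)
        return table, meta, tree
    paths = config.inputs or {}
    if "otu_table" not in paths:
        raise ConfigurationError("inputs.otu_table is required")
    table = read_otu_table(paths["otu_table"], paths.get("orientation", "rows-are-samples"))
    meta = read_sample_frame(paths["metadata"]) if "metadata" in paths else None
    tree = read_tree(paths["tree"]) if "tree" in paths else None
    return table, meta, tree


def run(config: RunConfig) -> tuple[ResultBundle, pd.DataFrame]:
    """Execute the configured stages; return the bundle and written manifest."""
    table, meta, tree = _load_inputs(config)
    if config.subset:
        table, meta = subset_samples(table, meta, config.subset)
    if meta is not None:
        meta = meta.aligned_to(table)

    stages = list(config.stages)
    if "assembly" in stages and tree is None:
        raise ConfigurationError("stage 'assembly' requires a tree input")
    if "rda" in stages and meta is None:
        raise ConfigurationError("stage 'rda' requires sample metadata")
    needs_clr = bool({"cluster", "network", "rda"} & set(stages))

    bundle = ResultBundle()
    bundle.metadata = {
        "seed": config.seed,
        "stages": stages,
        "params": config.params,
        "simulate": config.simulate,
        "n_samples": table.n_samples,
        "n_otus": table.n_otus,
    }

    p_div = config.params.get("diversity", {})
    norm = diversity.normalize_to_min_depth(table, seed=stage_seed(config.seed, "diversity"))
    bundle.add_table("normalized_counts", norm.counts)

    if "diversity" in stages:
        if meta is not None:
            groups = meta.meta["layer"]
            res = diversity.richness_by_group(
                norm, groups, alpha=p_div.get("alpha", 0.05)
            )
            bundle.add_table("richness", res.table)
            bundle.add_summary(
                "diversity_test",
                {
                    "branch": res.report.branch,
                    "statistic": res.report.statistic,
                    "p_value": res.report.p_value,
                    "bartlett_p": res.report.bartlett_p,
                    "shapiro_p": res.report.shapiro_p,
                    "letters": res.report.letters,
                },
            )
        else:
            bundle.add_table(
                "richness",
                diversity.observed_richness(norm).to_frame(),
            )

    clr = None
    if needs_clr:
        positive = compositional.replace_zeros(norm)
        clr = compositional.clr_transform(positive)
        bundle.add_matrix("clr", clr)

    if "cluster" in stages:
        p = config.params.get("cluster", {})
        dist = compositional.aitchison_distance(clr)
        bundle.add_matrix("aitchison_distance", dist)
        cres = compositional.cluster_samples(
            dist,
            clr_matrix=clr,
            linkage=p.get("linkage", "ward"),
            n_perm=p.get("n_perm", 999),
            alpha=p.get("alpha", 0.05),
            seed=stage_seed(config.seed, "cluster"),
        )
        bundle.add_table("cluster_groups", cres.groups.rename("group").to_frame())
        bundle.add_summary(
            "simprof",
            {"tests": cres.simprof_tests, "n_groups": int(cres.groups.nunique())},
        )

    if "network" in stages:
        p = config.params.get("network", {})
        phi = network.phi_matrix(clr)
        bundle.add_matrix("phi", phi)
        g = network.build_network(phi, meta=meta, threshold=p.get("threshold", 0.15))
        bundle.add_graph("sample_network", g)
        mod = network.modularity(g, seed=stage_seed(config.seed, "network"))
        cc = network.mean_clustering_coefficient(g)
        bundle.add_summary(
            "network_stats",
            {
                "modularity": mod.q,
                "mean_clustering_coefficient": cc,
                "clustering_convention": "unweighted; nodes of degree < 2 contribute 0",
                "n_edges": g.number_of_edges(),
                "partition": mod.partition,
                "threshold": p.get("threshold", 0.15),
            },
        )
        if meta is not None:
            horiz = network.shared_otu_horizontal(table, meta.meta["layer"])
            bundle.add_table("shared_otu_horizontal", horiz)
            for label, window in (
                ("upper", (None, p.get("upper_max_depth", 1000.0))),
                ("lower", (p.get("lower_min_depth", 2000.0), None)),
            ):
                vert = network.shared_otu_vertical(table, meta, depth_window=window)
                bundle.add_table(f"shared_otu_vertical_{label}", vert)

    if "assembly" in stages:
        p = config.params.get("assembly", {})
        bres = assembly_mod.bnti(
            norm,
            tree,
            n_null=p.get("n_null_bnti", 999),
            seed=stage_seed(config.seed, "assembly"),
        )
        rres = assembly_mod.raup_crick(
            norm,
            n_null=p.get("n_null_rc", 9999),
            seed=stage_seed(config.seed, "assembly"),
            weighting=p.get("weighting", "occupancy"),
        )
        part = assembly_mod.partition_processes(bres.bnti, rres.brc)
        bundle.add_matrix("bnti", bres.bnti)
        bundle.add_matrix("brc", rres.brc)
        bundle.add_table("process_pairs", part.pairs)
        bundle.add_summary(
            "process_fractions",
            {
                "fractions": part.fractions,
                "n_pairs": part.n_pairs,
                "n_excluded": part.n_excluded,
                "n_null_bnti": bres.n_null,
                "n_null_rc": rres.n_null,
                "weighting": rres.weighting,
            },
        )

    if "rda" in stages:
        p = config.params.get("rda", {})
        env = meta.env.drop(columns=[c for c in ("depth",) if p.get("exclude_depth")], errors="ignore")
        sel = env_selection.forward_select(
            clr,
            env,
            alpha=p.get("alpha", 0.01),
            n_perm=p.get("n_perm", 999),
            seed=stage_seed(config.seed, "rda"),
        )
        bundle.add_summary(
            "rda",
            {
                "selected_factors": sel.selected_factors,
                "admission_p": sel.admission_p,
                "cumulative_r2_adjusted": sel.cumulative_r2_adjusted,
                "global_r2": sel.global_fit.r2,
                "global_r2_adjusted": sel.global_r2_adjusted,
                "global_model_p": sel.global_fit.model_p,
                "permutations": sel.global_fit.permutations,
                "n_samples": sel.global_fit.n_samples,
                "n_dropped": sel.global_fit.n_dropped,
            },
        )

    manifest = write_results(bundle, config.out_dir)
    return bundle, manifest
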