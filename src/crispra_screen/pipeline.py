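"""End-to-end orchestration: simulate -> analyze rounds -> call hits.

A run is driven by a :class:`RunConfig` (loadable from YAML); every source
of randomness derives from one master seed split per stage, and a manifest
records seeds and parameters so the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .castle import CastleConfig, EnrichmentModel
from .hits import HitConfig, call_hits
from .simulate import (
    CountTable,
    ScreenDesign,
    SimulationParams,
    simulate_screen,
)

logger = logging.getLogger("crispra_screen")

__all__ = ["RunConfig", "run_screen_analysis", "split_seed"]


_STAGE_IDS = {"simulate": 1, "analyze": 2}


def split_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a master seed."""
    import zlib

    ss = np.random.SeedSequence(
        [int(master_seed), _STAGE_IDS.get(stage, zlib.crc32(stage.encode()))]
    )
    return int(ss.generate_state(1)[0] % (2**31))


_stage_seed = split_seed


@dataclass
class RunConfig:
    """Configuration of one screen analysis run."""

    seed: int = 0
    counts_path: str | None = None  # analyze an existing count table ...
    n_genes: int = 200  # ... or simulate one with these settings
    guides_per_gene: int = 10
    n_controls: int = 200
    true_receptors: dict = field(default_factory=dict)
    n_rounds: int = 3
    coverage: int = 1000
    capture_base: float = 0.005
    capture_max: float = 0.5
    efficacy_dispersion: float = 4.0
    sequencing_depth: int = 1_000_000
    abundance_cv: float = 0.5
    pseudocount: float = 0.5
    grid_min: float = -15.0
    grid_max: float = 15.0
    grid_step: float = 0.1
    n_perm: int = 10_000
    effect_cutoff: float = 2.0
    score_cutoff: float = 2.0
    p_cutoff: float = 0.05
    trajectory_tolerance: float = 0.1
    annotation_path: str | None = None
    blacklist: list = field(default_factory=list)
    output_dir: str = "run_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def castle_config(self) -> CastleConfig:
        return CastleConfig(
            pseudocount=self.pseudocount,
            grid_min=self.grid_min,
            grid_max=self.grid_max,
            grid_step=self.grid_step,
            n_perm=self.n_perm,
            seed=_stage_seed(self.seed, "analyze"),
        )

    def hit_config(self) -> HitConfig:
        return HitConfig(
            n_perm=self.n_perm,
            trajectory_tolerance=self.trajectory_tolerance,
            effect_cutoff=self.effect_cutoff,
            score_cutoff=self.score_cutoff,
            p_cutoff=self.p_cutoff,
            blacklist=frozenset(self.blacklist),
        )


def _load_annotation(path: str | None) -> dict[str, str]:
    if path is None:
        return {}
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def run_screen_analysis(config: RunConfig) -> dict:
    """Run the full analysis arm and write the output bundle.

    Returns a dict with the count table, per-round results, the hit table
    and the manifest path.  Deterministic given ``config.seed``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.counts_path is not None:
        table = CountTable.read_tsv(config.counts_path)
        logger.info("loaded counts: %d guides, samples %s",
                    len(table.counts), table.samples)
    else:
        design = ScreenDesign(
            gene_ids=tuple(f"GENE{i:04d}" for i in range(config.n_genes)),
            guides_per_gene=config.guides_per_gene,
            n_controls=config.n_controls,
            true_receptors=config.true_receptors,
        )
        params = SimulationParams(
            coverage=config.coverage,
            n_rounds=config.n_rounds,
            capture_base=config.capture_base,
            capture_max=config.capture_max,
            efficacy_dispersion=config.efficacy_dispersion,
            sequencing_depth=config.sequencing_depth,
            abundance_cv=config.abundance_cv,
            seed=_stage_seed(config.seed, "simulate"),
        )
        sim = simulate_screen(design, params)
        table = sim.counts
        sim.write(outdir / "counts.tsv", outdir / "truth.json")
        logger.info("simulated screen: %d guides, %d rounds",
                    len(table.counts), params.n_rounds)

    round_samples = [s for s in table.samples if table.sample_rounds[s] > 0]
    round_samples.sort(key=lambda s: table.sample_rounds[s])
    castle_cfg = config.castle_config()
    per_round = {}
    for sample in round_samples:
        res = EnrichmentModel(table, sample, "naive", castle_cfg).fit()
        res.write_tsv(outdir / f"results_{sample}.tsv")
        per_round[sample] = res.table
        logger.info("analyzed %s: %d genes", sample, len(res.table))

    annotation = _load_annotation(config.annotation_path)
    if not annotation:
        if config.annotation_path is not None:
            warnings.warn("annotation file empty; all genes are class 'other'")
        else:
            warnings.warn(
                "no annotation provided; all genes are class 'other' and no "
                "gene can pass the proteome filter"
            )
    hit_cfg = config.hit_config()
    hit_table = call_hits(per_round, annotation, config.blacklist, hit_cfg)
    hit_table.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    n_called = int(hit_table["called"].sum()) if len(hit_table) else 0
    logger.info("called %d hits", n_called)

    # rank-plot and trajectory-plot data exports
    if len(hit_table):
        hit_table[["final_rank", "esp", "gene"]].to_csv(
            outdir / "rank_plot.tsv", sep="\t", index=False
        )
        esp_cols = [c for c in hit_table.columns if c.startswith("esp_")]
        hit_table[["gene", *esp_cols]].to_csv(
            outdir / "trajectory_plot.tsv", sep="\t", index=False
        )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in _STAGE_IDS},
        "config": dataclasses.asdict(config),
        "rounds": round_samples,
        "n_called": n_called,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return {
        "counts": table,
        "per_round": per_round,
        "hits": hit_table,
        "manifest": manifest_path,
    }
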