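"""Configuration loading, run manifests, and batch execution.

A run is fully determined by its resolved configuration and master seed;
replicate seeds are pre-assigned from the master seed so results are
identical regardless of execution order or worker count.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

import enksim
from enksim import seeds
from enksim.engine import (
    SimulationConfig,
    StructureConfig,
    records_to_frame,
    run_replicate,
    structure_preset,
)
from enksim.exceptions import ConfigurationError

_SIM_KEYS = {
    "k_target", "scenario", "n_cycles", "n_reps", "h2", "n_testers",
    "master_seed", "n_et", "n_loci", "concentration_scale", "kernel_width",
    "tpe_concentration", "gca_corr_every", "pct_gca_max_lines",
}
_STRUCT_KEYS = {
    "structure", "n_programs", "subpop_size", "n_selected_parents",
    "n_experimental_hybrids", "p_max", "exchange_cycles",
}


def load_config(source) -> tuple[SimulationConfig, StructureConfig]:
    """Build validated configurations from a JSON file path or a dict.

    The only required key is ``k_target``; ``structure`` (default
    ``distributed``) selects a preset whose fields individual keys may
    override. Unknown keys are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = dict(source)
    unknown = set(doc) - _SIM_KEYS - _STRUCT_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    if "k_target" not in doc:
        raise ConfigurationError("k_target is required")
    sim = SimulationConfig(**{k: doc[k] for k in _SIM_KEYS if k in doc})
    name = doc.get("structure", "distributed")
    struct = structure_preset(name, sim.n_cycles, doc.get("p_max", 0.25))
    overrides = {
        k: doc[k] for k in _STRUCT_KEYS - {"structure", "p_max"} if k in doc
    }
    if overrides:
        if "exchange_cycles" in overrides and overrides["exchange_cycles"] is not None:
            overrides["exchange_cycles"] = frozenset(overrides["exchange_cycles"])
        struct = StructureConfig(
            name=struct.name,
            n_programs=overrides.get("n_programs", struct.n_programs),
            subpop_size=overrides.get("subpop_size", struct.subpop_size),
            n_selected_parents=overrides.get(
                "n_selected_parents", struct.n_selected_parents
            ),
            n_experimental_hybrids=overrides.get(
                "n_experimental_hybrids", struct.n_experimental_hybrids
            ),
            p_max=struct.p_max,
            exchange_cycles=overrides.get("exchange_cycles", struct.exchange_cycles),
        )
    return sim, struct


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    structure: dict
    simulation: dict
    master_seed: int
    replicate_seeds: list
    version: str
    timestamp: str
    deviates_from_full_scale: bool

    @classmethod
    def create(cls, structure: StructureConfig, sim: SimulationConfig) -> "RunManifest":
        sd = asdict(structure)
        sd["exchange_cycles"] = (
            None if structure.exchange_cycles is None
            else sorted(structure.exchange_cycles)
        )
        return cls(
            structure=sd,
            simulation=asdict(sim),
            master_seed=sim.master_seed,
            replicate_seeds=[
                seeds.subseed(sim.master_seed, rep, seeds.LANDSCAPE)
                for rep in range(sim.n_reps)
            ],
            version=enksim.__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            deviates_from_full_scale=sim.n_reps != 350,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _one_replicate(args):
    structure, sim, rep = args
    records = run_replicate(structure, sim, rep)
    return rep, records


def run_batch(
    configs,
    out_dir,
    parallel_workers: int = 1,
) -> Path:
    """Run one or more configurations and write tidy outputs.

    ``configs`` is an iterable of (SimulationConfig, StructureConfig) pairs or
    config dicts. Writes ``metrics.csv``, ``hybrids.csv`` and one manifest per
    configuration into ``out_dir``. Replicate seeds are pre-assigned, so the
    merged output is independent of the worker count.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metric_frames = []
    hybrid_rows = []
    statuses = []
    for ci, cfg in enumerate(configs):
        sim, struct = cfg if isinstance(cfg, tuple) else load_config(cfg)
        manifest = RunManifest.create(struct, sim)
        (out / f"manifest_{ci}_{struct.name}.json").write_text(manifest.to_json())
        tasks = [(struct, sim, rep) for rep in range(sim.n_reps)]
        results = {}
        if parallel_workers > 1:
            from concurrent.futures import ProcessPoolExecutor

            with ProcessPoolExecutor(max_workers=parallel_workers) as ex:
                for rep, records in ex.map(_one_replicate, tasks):
                    results[rep] = records
        else:
            for t in tasks:
                try:
                    rep, records = _one_replicate(t)
                    results[rep] = records
                except Exception as err:  # pragma: no cover - partial failure log
                    statuses.append(dict(config=ci, rep=t[2], status=f"failed: {err}"))
                    continue
        ordered = [results[r] for r in sorted(results)]
        metric_frames.append(records_to_frame(ordered, struct, sim))
        for rep in sorted(results):
            for rec in results[rep]:
                hybrid_rows.append(
                    dict(rep=rep, cycle=rec.cycle, structure=struct.name,
                         K=sim.k_target, scenario=sim.scenario,
                         top_hybrid_performance=rec.top_hybrid)
                )
        statuses.extend(
            dict(config=ci, rep=r, status="ok") for r in sorted(results)
        )
    pd.concat(metric_frames, ignore_index=True).to_csv(
        out / "metrics.csv", index=False
    )
    pd.DataFrame(hybrid_rows).to_csv(out / "hybrids.csv", index=False)
    pd.DataFrame(statuses).to_csv(out / "status.csv", index=False)
    return out
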