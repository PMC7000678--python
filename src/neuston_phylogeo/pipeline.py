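"""End-to-end orchestration: simulate/load -> diversity -> networks ->
composition -> motifs, with a machine-readable run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import ConfigError
from .io_formats import (
    SequenceSet,
    GroupMap,
    dealign,
    read_fasta,
    read_group_map,
    write_fasta,
    write_group_map,
    write_report,
)
from .mjn_network import median_joining, write_network
from .motif_uvr import count_all, records_frame, summarize_by_group
from .popgen_stats import (
    collapse_haplotypes,
    composition_chisq,
    composition_frame,
    diversity_summary,
    p_distance_matrix,
    pooled_mean_differences,
)
from .synthetic_data import SimulationConfig, simulate_dataset

log = logging.getLogger("neuston_phylogeo")


@dataclass
class PipelineConfig:
    """One source of sequences (file or simulation) plus analysis switches."""

    fasta: str | None = None
    group_map: str | None = None
    simulation: SimulationConfig | None = None
    clades: list[str] | None = None  # None = all clades in the group map
    pooled: bool = False
    deletion: str = "complete"
    epsilon: int = 0
    network_format: str = "graphml"
    out_dir: str = "results"
    seed: int = 0
    report_format: str = "tsv"

    def __post_init__(self):
        if (self.fasta is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of a FASTA path or a simulation config is required"
            )
        if self.fasta is not None and self.group_map is None:
            raise ConfigError("a group map is required with an input FASTA")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "base_freqs" in sim:
                sim["base_freqs"] = tuple(sim["base_freqs"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    exit_status: int = 0

    def record_output(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _stage(manifest: RunManifest, name: str):
    """Context manager recording wall-clock and errors per stage."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            self.caught: list[str] = []
            self._wcm = warnings.catch_warnings(record=True)
            self.wlist = self._wcm.__enter__()
            warnings.simplefilter("always")
            return self

        def __exit__(self, exc_type, exc, tb):
            self._wcm.__exit__(None, None, None)
            entry = {
                "seconds": round(time.perf_counter() - self.t0, 4),
                "warnings": [str(w.message) for w in self.wlist],
            }
            if exc is not None:
                entry["error"] = f"{exc_type.__name__}: {exc}"
                manifest.exit_status = 1
                log.error("stage %s failed: %s", name, exc)
            manifest.stages[name] = entry
            return exc is not None  # swallow; siblings keep running

    return _Ctx()


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage; a stage failure aborts its dependents only.

    The manifest is always written to <out_dir>/manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_echo = dataclasses.asdict(config)
    manifest = RunManifest(version=__version__, config=cfg_echo)

    seqs: SequenceSet | None = None
    gm: GroupMap | None = None

    with _stage(manifest, "input"):
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            seqs, gm, truth = simulate_dataset(sim)
            fasta_path = out / "simulated.fasta"
            write_fasta(seqs, fasta_path)
            gm_path = out / "simulated.groups.tsv"
            write_group_map(gm, gm_path)
            truth.to_json(out / "simulated.truth.json")
            for p in (fasta_path, gm_path, out / "simulated.truth.json"):
                manifest.record_output(p)
        else:
            seqs = read_fasta(config.fasta, assert_alignment=True)
            gm = read_group_map(config.group_map, seqs)
            for p in (config.fasta, config.group_map):
                manifest.record_output(Path(p))

    if seqs is None or gm is None:
        manifest.write(out / "manifest.json")
        return manifest

    clades = config.clades or gm.clades
    ext = config.report_format

    with _stage(manifest, "diversity"):
        rows = []
        for clade in clades:
            members = gm.members(clade)
            if len(members) < 2:
                warnings.warn(f"clade {clade!r} has < 2 members; skipped")
                continue
            s = diversity_summary(seqs, members, clade)
            rows.append(
                {
                    "clade": s.clade_label,
                    "n": s.n,
                    "h": s.h,
                    "Hd": s.Hd,
                    "K": s.K,
                    "pi": s.pi,
                    "analyzed_sites": s.analyzed_sites,
                }
            )
        if config.pooled and len(clades) >= 2:
            a, b = clades[0], clades[1]
            kt = pooled_mean_differences(seqs, gm.members(a), gm.members(b))
            rows.append(
                {
                    "clade": f"{a}+{b}",
                    "n": len(gm.members(a)) + len(gm.members(b)),
                    "h": None,
                    "Hd": None,
                    "K": kt,
                    "pi": None,
                    "analyzed_sites": None,
                }
            )
        path = out / f"diversity.{ext}"
        write_report(rows, path, ext)
        manifest.record_output(path)

    with _stage(manifest, "network"):
        for clade in clades:
            members = gm.members(clade)
            if not members:
                continue
            table = collapse_haplotypes(seqs, members)
            net = median_joining(table, epsilon=config.epsilon)
            suffix = {"graphml": "graphml", "gml": "gml", "tsv-edgelist": "tsv"}[
                config.network_format
            ]
            path = out / f"network_{clade}.{suffix}"
            write_network(net, path, config.network_format)
            manifest.record_output(path)

    with _stage(manifest, "composition"):
        results = composition_chisq(seqs)
        path = out / f"composition.{ext}"
        write_report(composition_frame(results), path, ext)
        manifest.record_output(path)

    with _stage(manifest, "motifs"):
        records = count_all(dealign(seqs))
        counts_path = out / f"motif_counts.{ext}"
        write_report(records_frame(records), counts_path, ext)
        summary_path = out / f"motif_summary.{ext}"
        write_report(summarize_by_group(records, gm), summary_path, ext)
        manifest.record_output(counts_path)
        manifest.record_output(summary_path)

    with _stage(manifest, "pdist"):
        dm = p_distance_matrix(seqs)
        path = out / "pdist.tsv"
        dm.to_frame().to_csv(path, sep="\t", float_format="%.6g")
        manifest.record_output(path)

    manifest.write(out / "manifest.json")
    return manifest
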