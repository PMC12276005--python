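"""Scenario orchestration: the two headline synthetic experiments.

``run_scenario`` ties the stages together on simulated libraries sharing
one genome and site map:

* the **peak-calling strategy contrast** — threshold-mode calling at a
  sweep of thresholds versus control-mode calling against the matched
  untargeted library, both benchmarked against the ground-truth G4 sites;
* the **differential-enrichment contrast** — the number of significantly
  target-enriched peaks with deduplication only versus after library
  complexity normalization.

All randomness is routed through per-stage child seeds derived from one
global seed by hashing the stage name, so stages can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import complexity as cx
from . import coverage as cov
from . import differential as de
from . import intervals as iv
from . import peaks as pk
from . import simulate as sim
from .fragments import FragmentLibrary, write_fragments

logger = logging.getLogger("tagbench")


def child_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage name mixed with the
    global seed, reduced below 2**31."""
    return int((zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31 - 1))


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the default synthetic scenario.

    Targeted replicates capture G4 sites on top of the shared accessibility
    background; untargeted replicates are background-only and sequenced
    shallower, as matched negative-control libraries typically are.
    """

    base: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    n_targeted: int = 3
    n_untargeted: int = 3
    untargeted_n_unique: int = 12_000
    f_values: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1)
    f_reference: float = 0.01  # threshold the control mode is contrasted with
    stringency: str = "stringent"
    bin_size: int = 50
    min_unique: int = 0
    background_bin: int = 15_000
    seed: int = 1


def simulate_scenario_libraries(
    config: ScenarioConfig,
) -> tuple[iv.GenomeLayout, sim.SiteMap, list[FragmentLibrary], list[FragmentLibrary]]:
    """Simulate the scenario genome and its targeted/untargeted libraries."""
    genome_cfg = replace(config.base, seed=child_seed(config.seed, "genome"))
    layout, sites = sim.simulate_genome(genome_cfg)
    targeted, untargeted = [], []
    for i in range(config.n_targeted):
        cfg = replace(config.base, seed=child_seed(config.seed, f"targeted_{i}"))
        targeted.append(
            sim.simulate_library(layout, sites, cfg, library_id=f"targeted_{i + 1}")
        )
    for i in range(config.n_untargeted):
        cfg = replace(
            config.base,
            p_target=0.0,
            n_unique_molecules=config.untargeted_n_unique,
            seed=child_seed(config.seed, f"untargeted_{i}"),
        )
        untargeted.append(
            sim.simulate_library(layout, sites, cfg, library_id=f"untargeted_{i + 1}")
        )
    return layout, sites, targeted, untargeted


def run_scenario(config: ScenarioConfig | None = None, outdir=None) -> dict:
    """Run the full synthetic experiment; returns a JSON-ready summary."""
    if config is None:
        config = ScenarioConfig()
    t0 = time.time()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    layout, sites, targeted, untargeted = simulate_scenario_libraries(config)
    libs = targeted + untargeted
    logger.info("simulated %d libraries in %.1fs", len(libs), time.time() - t0)

    report = cx.complexity_report(libs)
    # filter per role so a zero-p_target "targeted" arm keeps its identity
    targeted = cx.filter_min_unique(targeted, config.min_unique)
    untargeted = cx.filter_min_unique(untargeted, config.min_unique)
    kept = targeted + untargeted

    dedup = {lib.library_id: cx.deduplicate(lib) for lib in kept}
    tracks = {
        lid: cov.fragments_to_coverage(lib, layout, bin_size=config.bin_size, mode="span")
        for lid, lib in dedup.items()
    }
    t_tracks = [tracks[lib.library_id] for lib in targeted]
    u_tracks = [tracks[lib.library_id] for lib in untargeted]

    # strategy 1: threshold sweep, all-replicate consensus vs ground truth
    sweep = pk.threshold_sweep(t_tracks, list(config.f_values), sites.g4_true)

    # strategy 2: control mode, each replicate against its matched control
    ctrl_calls = []
    for i, track in enumerate(t_tracks):
        control = u_tracks[i % len(u_tracks)]
        ctrl_calls.append(pk.call_peaks_with_control(track, control, config.stringency))
    if any(len(c) for c in ctrl_calls):
        ctrl_consensus = iv.multi_consensus(ctrl_calls, min_count=len(ctrl_calls))
    else:
        ctrl_consensus = iv.IntervalSet()
    ctrl_pr = iv.precision_recall_f1(ctrl_consensus, sites.g4_true)

    # differential contrast on the non-deduplicated libraries
    f_ref = config.f_reference
    per_lib_peaks = [pk.call_peaks_threshold(tr, f_ref) for tr in tracks.values()]
    regions = iv.multi_consensus(per_lib_peaks, min_count=1) if per_lib_peaks else iv.IntervalSet()
    group = ["targeted"] * len(targeted) + ["untargeted"] * len(untargeted)
    n_dedup, n_norm = de.complexity_contrast(
        targeted + untargeted, group, regions, layout,
        seed=child_seed(config.seed, "downsample"),
        background_bin=config.background_bin,
    )

    ref_row = sweep[np.isclose(sweep["f"], f_ref)].iloc[0] if len(sweep) else None
    summary = {
        "seed": config.seed,
        "n_libraries": len(kept),
        "n_g4_true": len(sites.g4_true),
        "complexity": report.to_dict(orient="records"),
        "threshold_sweep": sweep.to_dict(orient="records"),
        "threshold_reference": {
            "f": f_ref,
            "n_peaks": int(ref_row["n_peaks"]) if ref_row is not None else 0,
            "precision": float(ref_row["precision"]) if ref_row is not None else float("nan"),
            "recall": float(ref_row["recall"]) if ref_row is not None else float("nan"),
        },
        "control_mode": {
            "n_peaks": len(ctrl_consensus),
            "precision": ctrl_pr.precision,
            "recall": ctrl_pr.recall,
            "f1": ctrl_pr.f1,
        },
        "differential": {
            "n_regions": len(regions),
            "n_significant_up_dedup_only": n_dedup,
            "n_significant_up_complexity_normalized": n_norm,
        },
    }

    if out is not None:
        for lib in kept:
            write_fragments(lib, out / f"{lib.library_id}.bed4", fmt="bed4")
        report.to_csv(out / "complexity.tsv", sep="\t", index=False)
        sweep.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
        iv.write_bed(sites.g4_true, out / "g4_true.bed")
        iv.write_bed(ctrl_consensus, out / "peaks_control_mode.bed", names=True)
        for lid, track in tracks.items():
            cov.write_bedgraph(track, out / f"{lid}.bedgraph")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("scenario finished in %.1fs", time.time() - t0)
    return summary


def depth_confound_experiment(
    seed: int = 1,
    n_targeted_unique: int = 50_000,
    n_untargeted_unique: int = 10_000,
    p_target: float = 0.25,
    n_replicates: int = 3,
    region_f: float = 0.1,
) -> dict:
    """Differential-enrichment collapse under a depth/complexity imbalance.

    Simulates targeted libraries that are deeper (more unique molecules) than
    their matched untargeted controls but only modestly enriched per site
    (every accessible site carries a target, ``p_target`` of molecules are
    target-derived), then counts significantly target-enriched peaks with
    deduplication only versus after complexity normalization.  With
    marginal per-peak excess, the extra depth is what carries significance,
    and normalizing complexity collapses the significant-peak count; with
    ``n_targeted_unique == n_untargeted_unique`` the two branches are
    statistically indistinguishable.
    """
    base = sim.SimulationConfig(
        g4_fraction=1.0,
        p_target=p_target,
        n_unique_molecules=n_targeted_unique,
        seed=child_seed(seed, "genome"),
    )
    layout, sites = sim.simulate_genome(base)
    libs = []
    for i in range(n_replicates):
        cfg = replace(base, seed=child_seed(seed, f"deep_t{i}"))
        libs.append(sim.simulate_library(layout, sites, cfg, f"targeted_{i + 1}"))
    for i in range(n_replicates):
        cfg = replace(
            base, p_target=0.0, n_unique_molecules=n_untargeted_unique,
            seed=child_seed(seed, f"deep_u{i}"),
        )
        libs.append(sim.simulate_library(layout, sites, cfg, f"untargeted_{i + 1}"))
    dedup = [cx.deduplicate(lib) for lib in libs]
    tracks = [cov.fragments_to_coverage(lib, layout, 50, mode="span") for lib in dedup]
    per_lib = [pk.call_peaks_threshold(tr, region_f) for tr in tracks]
    regions = iv.multi_consensus(per_lib, min_count=1)
    group = ["targeted"] * n_replicates + ["untargeted"] * n_replicates
    n_dedup, n_norm = de.complexity_contrast(
        libs, group, regions, layout, seed=child_seed(seed, "deep_downsample")
    )
    return {
        "n_regions": len(regions),
        "n_significant_up_dedup_only": n_dedup,
        "n_significant_up_complexity_normalized": n_norm,
    }


def make_fixtures(seed: int = 0, outdir="fixtures") -> dict:
    """Write a small deterministic fixture bundle used by the test suite.

    4 untargeted libraries spanning unique-read counts above and below a
    5000-read minimum-unique filter, 3 targeted libraries, the genome
    layout, site map and ground truth, all as plain-text files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    base = sim.SimulationConfig(
        n_accessible=80,
        n_unique_molecules=8000,
        seed=child_seed(seed, "fixture_genome"),
    )
    layout, sites = sim.simulate_genome(base)
    manifest = {"seed": seed, "min_unique": 5000, "libraries": []}

    with open(out / "genome.tsv", "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")
    iv.write_bed(layout.blacklist, out / "blacklist.bed")
    iv.write_bed(sites.accessible, out / "accessible.bed")
    iv.write_bed(sites.g4_true, out / "g4_true.bed")

    u_sizes = [2000, 4000, 8000, 16000]
    for i, n in enumerate(u_sizes):
        cfg = replace(
            base, p_target=0.0, n_unique_molecules=n,
            seed=child_seed(seed, f"fixture_u{i}"),
        )
        lib = sim.simulate_library(layout, sites, cfg, library_id=f"untargeted_{i + 1}")
        write_fragments(lib, out / f"{lib.library_id}.bed4", fmt="bed4")
        manifest["libraries"].append(
            {"id": lib.library_id, "targeted": False, "n_unique": lib.n_unique}
        )
    for i in range(3):
        cfg = replace(
            base, n_unique_molecules=20000, seed=child_seed(seed, f"fixture_t{i}")
        )
        lib = sim.simulate_library(layout, sites, cfg, library_id=f"targeted_{i + 1}")
        write_fragments(lib, out / f"{lib.library_id}.bed4", fmt="bed4")
        manifest["libraries"].append(
            {"id": lib.library_id, "targeted": True, "n_unique": lib.n_unique}
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
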