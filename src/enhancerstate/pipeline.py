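"""End-to-end orchestration: simulate/load -> consensus -> differential ->
classify -> annotate -> gene-set overlap, with a machine-readable report.

Default parameters follow the analysis design this package implements:
2-of-3 replicate consensus; 500 bp summit half-width (150 bp for H3K4me3,
i.e. 1000/300 bp testing windows); FDR < 0.05 for DBR calling; 1000 bp
maximum gap for cross-mark overlap; promoter windows from 5000 bp upstream
to 100 bp downstream of the TSS.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import simulate as sim
from .annotation import (
    annotate_regions,
    gene_sets_from_dbrs,
    overlap_chi_squared,
    read_gene_models,
)
from .consensus import consensus
from .differential import (
    DiffRegion,
    count_fragments,
    run_differential_binding,
    summit_windows,
)
from .enhancers import ENHANCER_STATES, classify_differential_enhancers
from .intervals import (
    IntervalSet,
    check_chrom_dialects,
    merge_intervals,
    read_regions,
    write_regions,
)

__all__ = ["PipelineParams", "run_pipeline", "DEFAULT_PARAMS"]

log = logging.getLogger("enhancerstate")


@dataclass
class PipelineParams:
    min_support: int = 2
    half_width: int = 500
    half_width_per_mark: dict[str, int] = field(
        default_factory=lambda: {"H3K4me3": 150}
    )
    alpha: float = 0.05
    max_gap: int = 1000
    promoter_upstream: int = 5000
    promoter_downstream: int = 100
    consensus_extent: str = "support"

    def half_width_for(self, mark: str) -> int:
        return self.half_width_per_mark.get(mark, self.half_width)

    def as_dict(self) -> dict:
        return {
            "min_support": self.min_support,
            "half_width": self.half_width,
            "half_width_per_mark": dict(self.half_width_per_mark),
            "alpha": self.alpha,
            "max_gap": self.max_gap,
            "promoter_upstream": self.promoter_upstream,
            "promoter_downstream": self.promoter_downstream,
            "consensus_extent": self.consensus_extent,
        }


DEFAULT_PARAMS = PipelineParams()


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_es_tag", None) for h in log.handlers}
    if "console" not in have:
        h = logging.StreamHandler()
        h._es_tag = "console"
        log.addHandler(h)
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh._es_tag = "file"
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    for h in list(log.handlers):
        if getattr(h, "_es_tag", None) == "file":
            log.removeHandler(h)
    log.addHandler(fh)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _diffregions_to_frame(results: list[DiffRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.region.chrom for r in results],
            "start": [r.region.start for r in results],
            "end": [r.region.end for r in results],
            "log2fc": [r.log2fc for r in results],
            "pvalue": [r.pvalue for r in results],
            "qvalue": [r.qvalue for r in results],
            "call": [r.call for r in results],
        }
    )


def run_pipeline(config, outdir=None) -> dict:
    """Run the full analysis described by a YAML config (path or mapping).

    Config keys: ``output_dir``; either a ``simulation`` block (passed to
    :class:`enhancerstate.simulate.SimulationConfig`) or an ``inputs`` block
    with ``peaks: {mark: {WT: [paths], KO: [paths]}}``, ``fragments`` in the
    same shape, and ``genes``; optional ``params`` overriding
    :class:`PipelineParams` fields. Returns the report dict (also written to
    ``report.json``).
    """
    cfg = _load_config(config)
    outdir = Path(outdir or cfg.get("output_dir", "enhancerstate_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    params = PipelineParams(**cfg.get("params", {}))
    report: dict = {"parameters": params.as_dict(), "stages": {}}

    # ---- stage 0: inputs ---------------------------------------------------
    truth_diff = truth_states = None
    if "simulation" in cfg:
        sim_cfg = sim.SimulationConfig.from_dict(cfg.get("simulation") or {})
        log.info("simulating experiment (seed %d)", sim_cfg.seed)
        manifest = sim.simulate_experiment(sim_cfg, outdir / "simulated")
        peaks_spec = manifest["peaks"]
        frags_spec = manifest["fragments"]
        genes_path = manifest["genes"]
        genome = {k: int(v) for k, v in manifest["genome"].items()}
        truth_diff = pd.read_csv(manifest["truth_differential"], sep="\t")
        truth_states = pd.read_csv(manifest["truth_states"], sep="\t")
        report["simulation"] = {
            "seed": sim_cfg.seed,
            "log2fc": sim_cfg.log2fc,
            "dispersion": sim_cfg.dispersion,
            "n_replicates": sim_cfg.n_replicates,
        }
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        peaks_spec = inputs["peaks"]
        frags_spec = inputs["fragments"]
        genes_path = inputs["genes"]
        genome = inputs.get("genome")
    else:
        raise ValueError("config needs a 'simulation' or 'inputs' block")

    marks = sorted(peaks_spec)
    missing = [
        p
        for mark in marks
        for cond in peaks_spec[mark]
        for p in list(peaks_spec[mark][cond]) + list(frags_spec[mark][cond])
        if not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing[:5]}")

    peaksets = {
        (mark, cond): [read_regions(p, genome=genome) for p in peaks_spec[mark][cond]]
        for mark in marks
        for cond in peaks_spec[mark]
    }
    check_chrom_dialects(
        {
            f"{mark}/{cond}/rep{i + 1}": s
            for (mark, cond), sets in peaksets.items()
            for i, s in enumerate(sets)
        }
    )

    # ---- stage 1: consensus ------------------------------------------------
    cons: dict[tuple[str, str], IntervalSet] = {}
    report["stages"]["consensus"] = {}
    for (mark, cond), sets in sorted(peaksets.items()):
        c = consensus(sets, params.min_support, extent=params.consensus_extent)
        cons[(mark, cond)] = c
        write_regions(c, outdir / f"consensus_{mark}_{cond}.bed")
        report["stages"]["consensus"][f"{mark}_{cond}"] = len(c)
        log.info("consensus %s/%s: %d regions", mark, cond, len(c))

    # ---- stage 2: differential binding per mark ----------------------------
    dbr_sets: dict[str, dict[str, IntervalSet]] = {}
    diff_results: dict[str, list[DiffRegion]] = {}
    report["stages"]["differential"] = {}
    for mark in marks:
        both = IntervalSet(
            list(cons[(mark, "WT")]) + list(cons[(mark, "KO")]),
            genome=cons[(mark, "WT")].genome,
        )
        testing = merge_intervals(both, 0)
        hw = params.half_width_for(mark)
        windows = summit_windows(testing, hw)
        samples, groups, fragsets = [], {}, []
        for cond in ("WT", "KO"):
            for i, p in enumerate(frags_spec[mark][cond], start=1):
                name = f"{cond}_rep{i}"
                samples.append(name)
                groups[name] = cond
                fragsets.append(read_regions(p, genome=genome))
        cm = count_fragments(windows, fragsets, samples, groups)
        results = run_differential_binding(cm, alpha=params.alpha)
        diff_results[mark] = results
        gained = IntervalSet([r.region for r in results if r.call == "gained"])
        lost = IntervalSet([r.region for r in results if r.call == "lost"])
        dbr_sets[mark] = {"gained": gained, "lost": lost}
        frame = _diffregions_to_frame(results)
        frame.to_csv(outdir / f"dbr_{mark}.tsv", sep="\t", index=False)
        write_regions(gained, outdir / f"dbr_{mark}_gained.bed")
        write_regions(lost, outdir / f"dbr_{mark}_lost.bed")
        report["stages"]["differential"][mark] = {
            "tested": len(results),
            "half_width": hw,
            "gained": len(gained),
            "lost": len(lost),
            "ns": len(results) - len(gained) - len(lost),
        }
        log.info(
            "differential %s: %d tested, %d gained, %d lost",
            mark, len(results), len(gained), len(lost),
        )

    # ---- stage 3: enhancer classification ----------------------------------
    report["stages"]["enhancers"] = {}
    calls = []
    if "H3K4me1" in marks and "H3K27ac" in marks:
        calls = classify_differential_enhancers(
            dbr_sets["H3K4me1"]["gained"],
            dbr_sets["H3K4me1"]["lost"],
            dbr_sets["H3K27ac"]["gained"],
            dbr_sets["H3K27ac"]["lost"],
            cons[("H3K4me1", "KO")],
            cons[("H3K27ac", "KO")],
            max_gap=params.max_gap,
        )
        pd.DataFrame(
            {
                "chrom": [c.region.chrom for c in calls],
                "start": [c.region.start for c in calls],
                "end": [c.region.end for c in calls],
                "state": [c.state for c in calls],
                "evidence_mark": [c.mark for c in calls],
                "evidence_direction": [c.direction for c in calls],
                "partner_distance": [
                    c.partner_distance if c.partner_distance is not None else -1
                    for c in calls
                ],
            }
        ).to_csv(outdir / "enhancer_calls.tsv", sep="\t", index=False)
        counts = {s: 0 for s in ENHANCER_STATES}
        for c in calls:
            counts[c.state] = counts.get(c.state, 0) + 1
        report["stages"]["enhancers"] = counts
        log.info("enhancer states: %s", counts)

    # ---- stage 4: gene annotation + bivalency overlap ----------------------
    report["stages"]["bivalency"] = {}
    if "H3K4me3" in marks and "H3K27me3" in marks:
        genes = read_gene_models(genes_path)
        up, down = params.promoter_upstream, params.promoter_downstream

        def assigned_genes(iset: IntervalSet) -> set[str]:
            if len(iset) == 0:
                return set()
            return gene_sets_from_dbrs(annotate_regions(iset, genes, up, down))

        set_a = assigned_genes(dbr_sets["H3K4me3"]["gained"])
        set_b = assigned_genes(dbr_sets["H3K27me3"]["lost"])
        universe = set()
        for mark in ("H3K4me3", "H3K27me3"):
            tested = IntervalSet([r.region for r in diff_results[mark]])
            universe |= assigned_genes(tested)
        biv = {
            "k4me3_gained_genes": len(set_a),
            "k27me3_lost_genes": len(set_b),
            "universe": len(universe),
            "overlap": len(set_a & set_b),
        }
        if set_a and set_b:
            n_ab, chi2, pval = overlap_chi_squared(set_a, set_b, universe)
            biv.update({"chi2": chi2, "pvalue": pval})
        biv["genes"] = sorted(set_a & set_b)
        report["stages"]["bivalency"] = biv
        log.info("bivalency resolution: %s", {k: biv[k] for k in list(biv)[:6]})

    # ---- stage 5: truth evaluation (simulated runs only) -------------------
    if truth_diff is not None:
        ev: dict = {"dbr": {}, "enhancer_states": None}
        for mark in marks:
            ev["dbr"][mark] = sim.evaluate_dbr_calls(
                dbr_sets[mark]["gained"], dbr_sets[mark]["lost"], truth_diff, mark
            )
        if calls and truth_states is not None and len(truth_states):
            ev["enhancer_states"] = sim.evaluate_enhancer_states(calls, truth_states)
        report["evaluation"] = ev

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    log.info("report written to %s", outdir / "report.json")
    return report
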