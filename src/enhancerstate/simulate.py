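"""Synthetic ChIP-seq experiment with planted ground truth.

Emulates a 3-clones x 2-genotypes (WT/KO) x 4-histone-marks design on a
small synthetic genome: loci are laid out as promoters (H3K4me3 + H3K27me3,
i.e. bivalent), poised enhancers (H3K4me1 only) and active enhancers
(H3K27ac with or without H3K4me1). A configurable subset of loci per mark
carries a planted log2 fold-change between genotypes; replicate peak files
get boundary jitter and dropout; per-sample fragment files carry
negative-binomially distributed fragment counts per locus plus uniform
background. Truth tables record every locus's class, planted differential
direction, and expected differential enhancer state, so pipeline output can
be scored exactly.

What this does NOT emulate: read-level sequence, mappability/GC bias,
peak-caller artefacts, or spatially structured background — recovery rates
here bound what the statistics can do under their own model, not performance
on real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gene_models
from .enhancers import ENHANCER_STATES
from .intervals import GenomicInterval, IntervalSet, subset_by_overlap, write_regions

__all__ = [
    "SimulationConfig",
    "PlantedLocus",
    "simulate_experiment",
    "evaluate_dbr_calls",
    "evaluate_enhancer_states",
]

MARKS = ("H3K4me3", "H3K27me3", "H3K4me1", "H3K27ac")
CONDITIONS = ("WT", "KO")

#: called peak width per mark (bp); promoter marks are narrower
PEAK_WIDTH = {"H3K4me3": 800, "H3K27me3": 1500, "H3K4me1": 1500, "H3K27ac": 1500}
#: span around the locus center over which fragment midpoints scatter
FRAG_SPAN = {"H3K4me3": 240, "H3K27me3": 800, "H3K4me1": 800, "H3K27ac": 800}


@dataclass
class SimulationConfig:
    """Design of the planted experiment.

    Defaults plant 200 differential loci per mark at |log2fc| = 2 with NB
    dispersion 0.1 and 3 replicates per condition, and a 40-gene overlap
    between H3K4me3-gained and H3K27me3-lost promoters (bivalency
    resolution).
    """

    genome: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 10_000_000, "chrS2": 10_000_000}
    )
    n_promoters: int = 300
    n_poised: int = 300
    n_active_with_k4me1: int = 300
    n_active_no_k4me1: int = 300
    #: (n_gained, n_lost) planted per mark
    n_differential: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {m: (100, 100) for m in MARKS}
    )
    #: promoters with both H3K4me3 gain and H3K27me3 loss
    bivalent_overlap: int = 40
    log2fc: float = 2.0
    dispersion: float = 0.1
    mean_fragments: float = 100.0
    n_replicates: int = 3
    jitter_sd: float = 50.0
    dropout: float = 0.05
    background_per_mb: float = 100.0
    fragment_length: int = 200
    min_spacing: int = 5000
    seed: int = 1

    def __post_init__(self):
        for name in ("n_promoters", "n_poised", "n_active_with_k4me1",
                     "n_active_no_k4me1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be a probability")
        if self.dispersion < 0 or self.mean_fragments <= 0:
            raise ValueError("dispersion >= 0 and mean_fragments > 0 required")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate per condition")
        for mark, (g, l) in self.n_differential.items():
            if mark not in MARKS:
                raise ValueError(f"unknown mark {mark!r}")
            if g < 0 or l < 0:
                raise ValueError("differential counts must be >= 0")
        ng4, _ = self.n_differential.get("H3K4me3", (0, 0))
        _, nl27 = self.n_differential.get("H3K27me3", (0, 0))
        if self.bivalent_overlap > min(ng4, nl27):
            raise ValueError("bivalent_overlap exceeds planted differential counts")

    @classmethod
    def noise_free(cls, **overrides) -> "SimulationConfig":
        """Zero-noise preset: no jitter, no dropout, no overdispersion,
        high coverage — the pipeline should be lossless on this."""
        params = dict(
            jitter_sd=0.0, dropout=0.0, dispersion=0.0, mean_fragments=300.0
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "n_differential" in d:
            d["n_differential"] = {
                k: tuple(v) for k, v in dict(d["n_differential"]).items()
            }
        return cls(**d)


@dataclass
class PlantedLocus:
    locus_id: str
    chrom: str
    center: int
    cls: str  # promoter | poised | active_with_k4me1 | active_no_k4me1
    gene_id: str | None = None
    #: mark -> planted direction ('gained'/'lost') for differential marks
    diff: dict[str, str] = field(default_factory=dict)
    #: expected differential enhancer state, when one is defined
    state: str | None = None

    def marks_present(self) -> tuple[str, ...]:
        return {
            "promoter": ("H3K4me3", "H3K27me3"),
            "poised": ("H3K4me1",),
            "active_with_k4me1": ("H3K27ac", "H3K4me1"),
            "active_no_k4me1": ("H3K27ac",),
        }[self.cls]

    def span(self, mark: str) -> tuple[int, int]:
        w = PEAK_WIDTH[mark]
        return self.center - w // 2, self.center + w // 2


def _place_loci(cfg: SimulationConfig, rng: np.random.Generator) -> list[PlantedLocus]:
    classes = (
        ["promoter"] * cfg.n_promoters
        + ["poised"] * cfg.n_poised
        + ["active_with_k4me1"] * cfg.n_active_with_k4me1
        + ["active_no_k4me1"] * cfg.n_active_no_k4me1
    )
    n = len(classes)
    max_width = max(PEAK_WIDTH.values())
    pitch = cfg.min_spacing + max_width + 500
    chroms = sorted(cfg.genome)
    slots: list[tuple[str, int]] = []
    for chrom in chroms:
        length = cfg.genome[chrom]
        pos = pitch
        while pos + pitch < length:
            slots.append((chrom, pos))
            pos += pitch
    if len(slots) < n:
        raise ValueError(
            f"cannot place {n} loci with >= {cfg.min_spacing} bp spacing in a "
            f"{sum(cfg.genome.values())} bp genome; use a larger genome"
        )
    # interleave classes across the genome so no chromosome is class-pure
    chosen = sorted(rng.choice(len(slots), size=n, replace=False))
    order = rng.permutation(n)
    loci = []
    gene_counter = 0
    for rank, slot_i in enumerate(chosen):
        cls = classes[order[rank]]
        chrom, pos = slots[slot_i]
        loci.append(PlantedLocus(f"locus{rank:05d}", chrom, pos, cls))
    # stable per-class indices for differential assignment
    for cls in ("promoter", "poised", "active_with_k4me1", "active_no_k4me1"):
        members = [l for l in loci if l.cls == cls]
        for i, loc in enumerate(members):
            if cls == "promoter":
                loc.gene_id = f"gene{i:05d}"
    return loci


def _assign_differentials(cfg: SimulationConfig, loci: list[PlantedLocus]) -> None:
    by_cls = {
        cls: [l for l in loci if l.cls == cls]
        for cls in ("promoter", "poised", "active_with_k4me1", "active_no_k4me1")
    }
    prom = by_cls["promoter"]
    ng4, nl4 = cfg.n_differential.get("H3K4me3", (0, 0))
    ng27, nl27 = cfg.n_differential.get("H3K27me3", (0, 0))
    if ng4 + nl4 > len(prom) or ng27 + nl27 > len(prom):
        raise ValueError("more promoter differentials requested than promoters")
    for loc in prom[:ng4]:
        loc.diff["H3K4me3"] = "gained"
    for loc in prom[ng4 : ng4 + nl4]:
        loc.diff["H3K4me3"] = "lost"
    # K27me3 losses start so that `bivalent_overlap` promoters carry both
    # a K4me3 gain and a K27me3 loss
    start27 = max(0, ng4 - cfg.bivalent_overlap)
    if start27 + nl27 + ng27 > len(prom):
        raise ValueError("promoter differential layout does not fit; add promoters")
    for loc in prom[start27 : start27 + nl27]:
        loc.diff["H3K27me3"] = "lost"
    for loc in prom[len(prom) - ng27 :]:
        if "H3K27me3" in loc.diff:
            raise ValueError("H3K27me3 gained/lost assignments collide; add promoters")
        loc.diff["H3K27me3"] = "gained"

    ng1, nl1 = cfg.n_differential.get("H3K4me1", (0, 0))
    poised = by_cls["poised"]
    if ng1 + nl1 > len(poised):
        raise ValueError("more H3K4me1 differentials requested than poised loci")
    for loc in poised[:ng1]:
        loc.diff["H3K4me1"] = "gained"
        loc.state = "poised_gained"
    for loc in poised[ng1 : ng1 + nl1]:
        loc.diff["H3K4me1"] = "lost"
        loc.state = "poised_lost"

    ngac, nlac = cfg.n_differential.get("H3K27ac", (0, 0))
    for cls, tag in (
        ("active_with_k4me1", "active_withK4me1"),
        ("active_no_k4me1", "active_noK4me1"),
    ):
        members = by_cls[cls]
        g = ngac // 2 if cls == "active_with_k4me1" else ngac - ngac // 2
        l = nlac // 2 if cls == "active_with_k4me1" else nlac - nlac // 2
        if g + l > len(members):
            raise ValueError(f"more H3K27ac differentials than {cls} loci")
        for loc in members[:g]:
            loc.diff["H3K27ac"] = "gained"
            loc.state = f"{tag}_gained"
        for loc in members[g : g + l]:
            loc.diff["H3K27ac"] = "lost"
            loc.state = f"{tag}_lost"


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi < 1e-12:
        return int(rng.poisson(mean))
    size = 1.0 / phi
    return int(rng.negative_binomial(size, size / (size + mean)))


def simulate_experiment(cfg: SimulationConfig, outdir) -> dict:
    """Write the full synthetic bundle and return a manifest.

    Bundle layout (all plain text)::

        peaks/{mark}_{cond}_rep{i}.narrowPeak
        fragments/{mark}_{cond}_rep{i}.bed
        genes.tsv
        truth_loci.tsv  truth_differential.tsv  truth_states.tsv
        manifest.json

    The manifest maps marks/conditions/replicates to file paths. Identical
    seeds give byte-identical bundles.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    loci = _place_loci(cfg, rng)
    _assign_differentials(cfg, loci)

    manifest: dict = {
        "genome": dict(cfg.genome),
        "marks": list(MARKS),
        "conditions": list(CONDITIONS),
        "n_replicates": cfg.n_replicates,
        "peaks": {},
        "fragments": {},
        "genes": str(outdir / "genes.tsv"),
        "truth_loci": str(outdir / "truth_loci.tsv"),
        "truth_differential": str(outdir / "truth_differential.tsv"),
        "truth_states": str(outdir / "truth_states.tsv"),
    }

    # genotype-specific NB mean multiplier per (locus, mark)
    def multiplier(loc: PlantedLocus, mark: str, cond: str) -> float:
        direction = loc.diff.get(mark)
        if direction is None:
            return 1.0
        half = cfg.log2fc / 2.0
        up = cond == "KO"
        if direction == "lost":
            up = not up
        return 2.0 ** (half if up else -half)

    for mark in MARKS:
        manifest["peaks"][mark] = {}
        manifest["fragments"][mark] = {}
        mark_loci = [l for l in loci if mark in l.marks_present()]
        for cond in CONDITIONS:
            peak_paths, frag_paths = [], []
            for rep in range(1, cfg.n_replicates + 1):
                peaks = []
                for loc in mark_loci:
                    if cfg.dropout > 0 and rng.random() < cfg.dropout:
                        continue
                    lo, hi = loc.span(mark)
                    if cfg.jitter_sd > 0:
                        lo += int(round(rng.normal(0, cfg.jitter_sd)))
                        hi += int(round(rng.normal(0, cfg.jitter_sd)))
                    if hi <= lo:
                        hi = lo + 1
                    lo = max(0, lo)
                    hi = min(hi, cfg.genome[loc.chrom])
                    summit = min(max(loc.center - lo, 0), hi - lo - 1)
                    peaks.append(
                        GenomicInterval(loc.chrom, lo, hi, name=loc.locus_id,
                                        summit_offset=summit)
                    )
                ppath = outdir / "peaks" / f"{mark}_{cond}_rep{rep}.narrowPeak"
                write_regions(IntervalSet(peaks, genome=cfg.genome), ppath,
                              dialect="narrowPeak")
                peak_paths.append(str(ppath))

                frags: list[GenomicInterval] = []
                fl = cfg.fragment_length
                for loc in mark_loci:
                    mean = cfg.mean_fragments * multiplier(loc, mark, cond)
                    k = _nb_draw(rng, mean, cfg.dispersion)
                    if k == 0:
                        continue
                    span = FRAG_SPAN[mark]
                    mids = rng.integers(
                        loc.center - span // 2, loc.center + span // 2, size=k
                    )
                    for m in mids:
                        s = max(0, int(m) - fl // 2)
                        frags.append(
                            GenomicInterval(loc.chrom, s,
                                            min(s + fl, cfg.genome[loc.chrom]))
                        )
                for chrom in sorted(cfg.genome):
                    length = cfg.genome[chrom]
                    n_bg = int(rng.poisson(cfg.background_per_mb * length / 1e6))
                    starts = rng.integers(0, max(1, length - fl), size=n_bg)
                    for s in starts:
                        frags.append(GenomicInterval(chrom, int(s), int(s) + fl))
                fpath = outdir / "fragments" / f"{mark}_{cond}_rep{rep}.bed"
                write_regions(IntervalSet(frags, genome=cfg.genome), fpath,
                              dialect="bed6")
                frag_paths.append(str(fpath))
            manifest["peaks"][mark][cond] = peak_paths
            manifest["fragments"][mark][cond] = frag_paths

    genes = [
        GeneModel(l.gene_id, l.chrom, l.center, "+" if i % 2 == 0 else "-")
        for i, l in enumerate(loc for loc in loci if loc.cls == "promoter")
    ]
    write_gene_models(genes, outdir / "genes.tsv")

    loci_df = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [min(l.span(m)[0] for m in l.marks_present()) for l in loci],
            "end": [max(l.span(m)[1] for m in l.marks_present()) for l in loci],
            "class": [l.cls for l in loci],
            "gene_id": [l.gene_id if l.gene_id else "." for l in loci],
        }
    )
    loci_df.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)

    rows = []
    for l in loci:
        for mark, direction in sorted(l.diff.items()):
            rows.append((l.locus_id, l.chrom, *l.span(mark), mark, direction,
                         cfg.log2fc if direction == "gained" else -cfg.log2fc))
    pd.DataFrame(
        rows,
        columns=["locus_id", "chrom", "start", "end", "mark", "direction", "log2fc"],
    ).to_csv(outdir / "truth_differential.tsv", sep="\t", index=False)

    srows = [
        (l.locus_id, l.chrom, *l.span("H3K4me1" if l.cls == "poised" else "H3K27ac"),
         l.state)
        for l in loci
        if l.state is not None
    ]
    pd.DataFrame(
        srows, columns=["locus_id", "chrom", "start", "end", "state"]
    ).to_csv(outdir / "truth_states.tsv", sep="\t", index=False)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Scoring against truth
# ---------------------------------------------------------------------------


def _truth_sets(truth_diff: pd.DataFrame, mark: str) -> dict[str, IntervalSet]:
    out = {}
    for direction in ("gained", "lost"):
        sub = truth_diff[(truth_diff["mark"] == mark)
                         & (truth_diff["direction"] == direction)]
        out[direction] = IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.locus_id)
            for r in sub.itertuples()
        )
    return out


def evaluate_dbr_calls(
    gained: IntervalSet,
    lost: IntervalSet,
    truth_differential: pd.DataFrame,
    mark: str,
) -> dict:
    """Sensitivity / precision / empirical FDR of DBR calls for one mark.

    A call is a true positive when it overlaps (>= 1 bp) a planted
    differential locus of the same mark and direction; a planted locus is
    recovered when >= 1 call of the right direction overlaps it.
    """
    truth = _truth_sets(truth_differential, mark)
    n_called = len(gained) + len(lost)
    tp = sum(
        len(subset_by_overlap(calls, truth[d], 0))
        for d, calls in (("gained", gained), ("lost", lost))
    )
    recovered = sum(
        len(subset_by_overlap(truth[d], calls, 0))
        for d, calls in (("gained", gained), ("lost", lost))
    )
    n_true = len(truth["gained"]) + len(truth["lost"])
    return {
        "mark": mark,
        "n_called": n_called,
        "n_true": n_true,
        "sensitivity": recovered / n_true if n_true else float("nan"),
        "precision": tp / n_called if n_called else float("nan"),
        "fdr": (n_called - tp) / n_called if n_called else float("nan"),
    }


def evaluate_enhancer_states(calls, truth_states: pd.DataFrame) -> dict:
    """Fraction of planted enhancer-state loci recovered with the right label.

    ``calls`` is the classifier output (list of EnhancerCall). A planted
    locus counts as recovered when >= 1 bp of it is covered by a call of the
    matching state. Also reports per-state recall and the precision of
    classified calls.
    """
    call_sets: dict[str, IntervalSet] = {}
    for c in calls:
        call_sets.setdefault(c.state, []).append(c.region)
    call_sets = {k: IntervalSet(v) for k, v in call_sets.items()}

    per_state: dict[str, dict] = {}
    correct = 0
    total = 0
    for state, sub in truth_states.groupby("state"):
        truth_set = IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.locus_id)
            for r in sub.itertuples()
        )
        hits = (
            len(subset_by_overlap(truth_set, call_sets[state], 0))
            if state in call_sets
            else 0
        )
        per_state[state] = {"n_true": len(truth_set), "recovered": hits,
                            "recall": hits / len(truth_set)}
        correct += hits
        total += len(truth_set)

    n_classified = sum(len(s) for k, s in call_sets.items() if k in ENHANCER_STATES)
    tp_calls = 0
    for state, cset in call_sets.items():
        sub = truth_states[truth_states["state"] == state]
        tset = IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sub.itertuples()
        )
        tp_calls += len(subset_by_overlap(cset, tset, 0))
    return {
        "accuracy": correct / total if total else float("nan"),
        "n_true": total,
        "recovered": correct,
        "precision": tp_calls / n_classified if n_classified else float("nan"),
        "per_state": per_state,
    }
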