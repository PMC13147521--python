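"""End-to-end orchestration: simulate -> filter -> call -> classify ->
stats, with plain-TSV intermediates so every stage can be re-run and
tested in isolation.  A run is fully determined by its RunConfig (and
input files, when not simulating)."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (
    SegmentationConfig,
    call_cross_gap_event,
    calls_from_segmentation,
    calls_to_frame,
    segment_track,
    segmentation_to_frame,
)
from .classify import (
    CategorizerConfig,
    categorize_cause,
    category_breakdown,
    classify_division,
    events_to_frame,
)
from .calling import state_paths_batch
from .filtering import FilterConfig, read_counts_tsv, run_filters, write_counts_tsv
from .genome import ChromosomeMap, chromosome_map_to_dict, default_chr2_map
from .simulate import (
    SimulationConfig,
    build_bivalent,
    make_snp_panel,
    segregate,
    simulate_cohort,
    write_simulation,
)
from .stats import arm_association, co_class_fractions, zero_co_chromosome_fraction

log = logging.getLogger("ndjmap")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class RunConfig:
    out_dir: str = "ndjmap_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    categorizer: CategorizerConfig = field(default_factory=CategorizerConfig)
    write_vcf: bool = False

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulation": self.simulation.to_dict(),
            "filters": self.filters.to_dict(),
            "segmentation": self.segmentation.to_dict(),
            "categorizer": self.categorizer.to_dict(),
            "write_vcf": self.write_vcf,
        }


def config_hash(config: RunConfig, cmap: ChromosomeMap) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # where a run lands must not change its identity
    payload = yaml.safe_dump(
        {"config": d, "map": chromosome_map_to_dict(cmap)}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_counts(
    counts: pd.DataFrame,
    cmap: ChromosomeMap,
    seg_config: SegmentationConfig,
    cat_config: CategorizerConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Segment, call and classify every sample in a filtered counts table.

    Returns (events, calls, segments) frames.  Counts must carry the
    chromosome-2 arms of ``cmap``; other chromosomes present are ignored
    here (they are analyzed by the cross-chromosome statistics instead).
    """
    arm_names = set(cmap.arm_names)
    left_arm, right_arm = cmap.arm_names[0], cmap.arm_names[-1]
    event_rows, all_calls, all_segs = [], [], []
    for sample, sub in counts[counts["chrom"].isin(arm_names)].groupby("sample", sort=True):
        segs = {}
        calls = []
        for arm in cmap.arm_names:
            track = sub[sub["chrom"] == arm]
            # only the telomeric track end may keep short evidence-backed
            # terminal segments; the centromeric end abuts crossover-free
            # heterochromatin
            cen_end = cmap.centromeric_end(arm)
            exempt = (cen_end == "end", cen_end == "start")
            seg = segment_track(track, seg_config, sample=str(sample), chrom=arm,
                                exempt_ends=exempt)
            segs[arm] = seg
            calls.extend(calls_from_segmentation(seg))
            all_segs.append(seg)
        if cmap.shape == "metacentric":
            gap_call = call_cross_gap_event(segs[left_arm], segs[right_arm], cmap)
            if gap_call == "undetermined":
                log.info("sample %s: cross-gap state undetermined", sample)
            elif gap_call is not None:
                calls.append(gap_call)
        division = classify_division(segs, cmap, cat_config)
        category = categorize_cause(calls, cmap, cat_config)
        n_left = sum(c.chrom == left_arm for c in calls)
        n_right = sum(c.chrom == right_arm for c in calls)
        event_rows.append(
            {
                "sample": sample,
                "division": division.division,
                "rescue_flag": division.monosomy_rescue,
                "category": category,
                "n_calls_left": n_left,
                "n_calls_right": n_right,
                "n_calls_total": len(calls),
            }
        )
        all_calls.extend(calls)
    return events_to_frame(event_rows), calls_to_frame(all_calls), segmentation_to_frame(all_segs)


def cohort_stats(events: pd.DataFrame, cmap: ChromosomeMap) -> dict:
    """Fig 4/5-style cohort summaries from the per-event table."""
    if events.empty:
        return {"n_events": 0}
    left_arm, right_arm = cmap.arm_names[0], cmap.arm_names[-1]
    arm_rows = []
    for _, r in events.iterrows():
        cls = {"MI": "MI", "MII": "MII"}.get(r["division"], r["division"])
        arm_rows.append({"event": r["sample"], "event_class": cls, "arm": left_arm, "n_co": r["n_calls_left"]})
        arm_rows.append({"event": r["sample"], "event_class": cls, "arm": right_arm, "n_co": r["n_calls_right"]})
    arm_counts = pd.DataFrame(arm_rows)
    determinate = arm_counts[arm_counts["event_class"].isin(["MI", "MII"])]
    out: dict = {
        "n_events": int(len(events)),
        "division_counts": events["division"].value_counts().to_dict(),
        "category_breakdown": category_breakdown(events).to_dict(orient="records"),
    }
    if not determinate.empty:
        out["co_class_fractions"] = co_class_fractions(determinate).to_dict(orient="records")
        out["arm_association"] = arm_association(determinate, left_arm, right_arm).to_dict(orient="records")
        mi = determinate[determinate["event_class"] == "MI"]
        if not mi.empty:
            out["zero_co_chromosome_fraction_MI"] = zero_co_chromosome_fraction(mi)
    return out


def mc_single_co_detection(
    mode: str,
    n_samples: int,
    cmap: ChromosomeMap | None = None,
    sim_config: SimulationConfig | None = None,
    seg_config=None,
    seed: int = 0,
    chunk: int = 2000,
) -> dict:
    """Monte-Carlo single-crossover detection fraction through the full
    simulator + segmentation pipeline.

    Simulates ``n_samples`` meioses each carrying exactly one crossover
    (uniform position over euchromatin, uniform non-sister chromatid
    pair), segregates them under ``mode``, generates pooled read counts,
    segments every track, and reports the fraction of samples with at
    least one genotype-state transition.  Also reports the fraction whose
    noiseless dose track is non-constant (the enumeration oracle's notion
    of detectability) for comparison.
    """
    from .calling import SegmentationConfig

    cmap = cmap or default_chr2_map()
    sim = sim_config or SimulationConfig()
    seg = seg_config or SegmentationConfig()
    rng = np.random.default_rng(seed)
    panel = make_snp_panel(cmap, sim.snp_spacing)
    gpos = panel["gpos"].to_numpy()
    arm_slices = {
        arm: np.flatnonzero((panel["chrom"] == arm).to_numpy()) for arm in cmap.arm_names
    }
    eu = cmap.euchromatin_intervals()
    eu_lens = np.array([hi - lo for _, lo, hi in eu], dtype=float)
    eu_p = eu_lens / eu_lens.sum()
    cen = cmap.centromere_gpos

    detected = 0
    truth_detectable = 0
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        alt = np.empty((m, len(gpos)), dtype=np.int32)
        ref = np.empty((m, len(gpos)), dtype=np.int32)
        for i in range(m):
            a = int(rng.choice(len(eu), p=eu_p))
            arm_name, lo, hi = eu[a]
            pos = cmap.to_global(arm_name, int(rng.integers(lo, hi)))
            biv = build_bivalent([pos], pairs=[int(rng.integers(4))], centromere_gpos=cen)
            inherited = segregate(biv, mode, rng)
            dose = np.zeros(len(gpos), dtype=np.int64)
            for cd in inherited:
                dose = dose + cd.doses_at(gpos)
            truth_detectable += int(len(np.unique(dose)) > 1)
            k = int(rng.binomial(sim.pool_size, 0.5))
            if len(inherited) == 1:
                p1 = k * inherited[0].doses_at(gpos)
            else:
                p1 = k * inherited[0].doses_at(gpos) + (sim.pool_size - k) * inherited[1].doses_at(gpos)
            f = p1 / (2.0 * sim.pool_size)
            p_read = f * (1 - sim.seq_error) + (1 - f) * sim.seq_error
            depth = rng.poisson(sim.mean_depth, size=len(gpos))
            alt[i] = rng.binomial(depth, p_read)
            ref[i] = depth - alt[i]
        any_transition = np.zeros(m, dtype=bool)
        for arm_name, idx in arm_slices.items():
            cen_end = cmap.centromeric_end(arm_name)
            exempt = (cen_end == "end", cen_end == "start")
            paths = state_paths_batch(alt[:, idx], ref[:, idx], seg, exempt_ends=exempt)
            any_transition |= (np.diff(paths, axis=1) != 0).any(axis=1)
        detected += int(any_transition.sum())
        done += m
    return {
        "mode": mode,
        "n": n_samples,
        "detected_fraction": detected / n_samples,
        "truth_detectable_fraction": truth_detectable / n_samples,
    }


def run_pipeline(config: RunConfig, cmap: ChromosomeMap | None = None) -> str:
    """Simulate a cohort under ``config`` and run the full analysis,
    writing every stage's output plus a machine-readable summary with a
    provenance block.  Returns the run directory."""
    cmap = cmap or default_chr2_map()
    os.makedirs(config.out_dir, exist_ok=True)
    sim = SimulationConfig(**{**config.simulation.to_dict(), "seed": config.seed})

    log.info("simulating %d events (seed %d)", sim.n_events, sim.seed)
    samples, _panel = simulate_cohort(sim, cmap)
    write_simulation(samples, config.out_dir, cmap=cmap, vcf=config.write_vcf)

    counts = read_counts_tsv(os.path.join(config.out_dir, "counts.tsv"))
    if counts.empty:
        filtered = counts.assign(masked=pd.Series(dtype=bool))
        report = {"before": {"rows": 0}, "after": {"rows": 0}}
    else:
        filtered, report = run_filters(counts, config.filters)
    write_counts_tsv(filtered, os.path.join(config.out_dir, "counts.filtered.tsv"))
    with open(os.path.join(config.out_dir, "filter_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)

    events, calls, segments = analyze_counts(filtered, cmap, config.segmentation, config.categorizer)
    events.to_csv(os.path.join(config.out_dir, "events.tsv"), sep="\t", index=False)
    calls.to_csv(os.path.join(config.out_dir, "calls.tsv"), sep="\t", index=False)
    segments.to_csv(os.path.join(config.out_dir, "segments.tsv"), sep="\t", index=False)

    summary = {
        "provenance": {
            "package": "ndjmap",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config, cmap),
        },
        "stats": cohort_stats(events, cmap),
        "events": events.to_dict(orient="records"),
    }
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    log.info("run complete: %s", config.out_dir)
    return config.out_dir


def run_config_from_yaml(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    sim = d.get("simulation", {})
    kwargs: dict = {}
    if "out_dir" in d:
        kwargs["out_dir"] = d["out_dir"]
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    if sim:
        sim = dict(sim)
        if "co_count_dist" in sim:
            sim["co_count_dist"] = {int(k): float(v) for k, v in sim["co_count_dist"].items()}
        kwargs["simulation"] = SimulationConfig(**sim)
    if "filters" in d:
        f = dict(d["filters"])
        if "third_stock_chroms" in f:
            f["third_stock_chroms"] = frozenset(map(str, f["third_stock_chroms"]))
        kwargs["filters"] = FilterConfig(**f)
    if "segmentation" in d:
        s = dict(d["segmentation"])
        if "state_set" in s:
            s["state_set"] = tuple((str(n), float(v)) for n, v in s["state_set"])
        kwargs["segmentation"] = SegmentationConfig(**s)
    if "categorizer" in d:
        kwargs["categorizer"] = CategorizerConfig(**d["categorizer"])
    if "write_vcf" in d:
        kwargs["write_vcf"] = bool(d["write_vcf"])
    return RunConfig(**kwargs)
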