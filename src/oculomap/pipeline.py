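"""End-to-end driver: simulate (or load), parse, map, test, report.

The pipeline wires the stages together in the order the analysis is
meant to run: gaze samples -> events -> per-observer duration-weighted
maps -> smoothed group maps -> pooled Z-maps and differential Z-map ->
random-field clusters -> observer ROI scores with the mixed ANOVA ->
ROI time courses with percentile-bootstrap inference.  Every artifact
carries the seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import fixmap, io, roi_stats, timecourse
from .events import ParserSpec, parse_events
from .pixel_test import PixelTestSpec, significant_clusters
from .synthetic import (
    NOSE_PROFILE,
    WC_PROFILE,
    ExperimentDesign,
    ObserverProfile,
    simulate_experiment,
)

__all__ = ["PROFILES", "run_pipeline"]

log = logging.getLogger("oculomap.pipeline")

PROFILES: Dict[str, ObserverProfile] = {
    "eye_biased": WC_PROFILE,
    "nose_biased": NOSE_PROFILE,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _simulate(config: dict, seed: int):
    sim = config.get("simulation", {})
    design = ExperimentDesign(
        n_learn=sim.get("n_learn", 14),
        n_recog=2 * sim.get("n_learn", 14),
        blocks_per_race=sim.get("blocks_per_race", 2),
        races=tuple(sim.get("races", ("WC", "EA"))),
    )
    cohorts = {
        sim.get("group_a", "A"): (sim.get("n_per_group", 10),
                                  PROFILES[sim.get("profile_a", "eye_biased")]),
        sim.get("group_b", "B"): (sim.get("n_per_group", 10),
                                  PROFILES[sim.get("profile_b", "nose_biased")]),
    }
    return simulate_experiment(
        design, cohorts,
        aperture_deg=sim.get("aperture_deg", 8.0),
        seed=seed,
        synthesize_samples=sim.get("synthesize_samples", False),
    )


def run_pipeline(config: dict, outdir: Optional[str] = None) -> dict:
    """Run the full analysis described by ``config``; return the report.

    The configuration must contain a ``simulation`` block (there is no
    deposited human dataset); a fixed seed makes the whole run, and all
    written artifacts, bit-reproducible.
    """
    seed = int(config.get("seed", 0))
    chash = io.config_hash(config)
    report: dict = {"seed": seed, "config_hash": chash}
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- simulate -------------------------------------------------------
    try:
        exp = _simulate(config, seed)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e
    log.info("simulated %d trials", len(exp.trials))

    # ---- parse ----------------------------------------------------------
    pconf = config.get("parser", {})
    pspec = ParserSpec(
        v_thresh=pconf.get("v_thresh", 30.0),
        a_thresh=pconf.get("a_thresh", 4000.0),
        merge_gap=pconf.get("merge_gap", 20.0),
        merge_dist=pconf.get("merge_dist", 0.30),
        blink_min_missing=pconf.get("blink_min_missing", 3),
    )
    try:
        if exp.recordings:
            events = {tid: parse_events(rec, pspec) for tid, rec in exp.recordings.items()}
        else:
            events = exp.events  # ground-truth plans, no sample stream synthesised
    except Exception as e:  # noqa: BLE001
        raise PipelineError("parse", str(e)) from e

    trials = exp.trials
    phase = config.get("map", {}).get("phase", "learning")
    correct_only = config.get("map", {}).get("correct_only", True)
    sel = trials[trials.phase == phase]
    if correct_only:
        sel = sel[sel.correct]
    if sel.empty:
        raise PipelineError("map", "no qualifying trials")

    fix_counts = {
        obs: float(np.mean([len(events[t].fixations) for t in sub.trial_id]))
        for obs, sub in sel.groupby("observer")
    }
    report["mean_fixations_per_trial"] = fix_counts

    # ---- maps -----------------------------------------------------------
    mconf = config.get("map", {})
    sigma = mconf.get("sigma", 10.0)
    shape = tuple(mconf.get("dims", fixmap.DEFAULT_SHAPE))
    groups = dict(zip(trials.observer, trials.group))
    try:
        obs_maps = {}
        for obs, sub in sel.groupby("observer"):
            raw = fixmap.accumulate_map([events[t] for t in sub.trial_id], shape)
            obs_maps[obs] = fixmap.smooth_map(raw, sigma)
        labels = sorted(set(groups.values()))
        by_group = {
            g: fixmap.group_map([m for o, m in obs_maps.items() if groups[o] == g])
            for g in labels
        }
        ga, gb = by_group[labels[0]], by_group[labels[1]]
        mu, sd = fixmap.pooled_moments(ga, gb)
        z_a, z_b = fixmap.zscore_pooled(ga, gb)
        dz = fixmap.differential_zmap(ga, gb)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("map", str(e)) from e

    # ---- pixel test -----------------------------------------------------
    tconf = config.get("pixel_test", {})
    ptspec = PixelTestSpec(
        alpha=tconf.get("alpha", 0.05),
        tails=tconf.get("tails", "two"),
        sigma_smooth_px=sigma,
    )
    clusters = significant_clusters(dz, ptspec)
    report["z_crit"] = clusters.z_crit
    report["n_significant_clusters"] = len(clusters)
    report["clusters"] = [
        {"sign": c.sign, "peak_z": c.peak_z, "area_px": c.area_px}
        for c in clusters
    ]

    # ---- ROI statistics -------------------------------------------------
    if len(clusters) >= 2:
        try:
            obs_z = {o: fixmap.zscore_with(m, mu, sd) for o, m in obs_maps.items()}
            # the two dominant opposite-sign clusters form the 2-level factor
            pos = max((c for c in clusters if c.sign == "+"),
                      key=lambda c: c.area_px, default=None)
            neg = max((c for c in clusters if c.sign == "-"),
                      key=lambda c: c.area_px, default=None)
            if pos is not None and neg is not None:
                from .pixel_test import ClusterSet

                two = ClusterSet([pos, neg], clusters.z_crit, clusters.shape)
                table = roi_stats.observer_roi_scores(
                    obs_z, groups, two, region_names=["roi_pos", "roi_neg"])
                aov = roi_stats.mixed_anova(table)
                comps = roi_stats.region_comparisons(table)
                report["mixed_anova"] = {
                    "F": aov.F, "df": list(aov.df), "p": aov.p,
                    "partial_eta_sq": aov.partial_eta_sq,
                }
                report["region_tests"] = comps.to_dict(orient="records")

                # ---- time course ---------------------------------------
                bconf = config.get("timecourse", None)
                if bconf is not None:
                    tspec = timecourse.TimecourseSpec(
                        B=bconf.get("B", 5000),
                        alpha=bconf.get("alpha", 0.05),
                        mode=bconf.get("mode", "learning"),
                    )
                    roi_mask = two.cluster_mask(0)
                    curves = {g: [] for g in labels}
                    for obs, sub in sel.groupby("observer"):
                        evs = [events[t] for t in sub.trial_id]
                        curves[groups[obs]].append(
                            timecourse.fixation_frequency(evs, roi_mask, tspec))
                    boot = timecourse.bootstrap_difference(
                        np.array(curves[labels[0]]), np.array(curves[labels[1]]),
                        tspec, rng=seed + 1)
                    report["timecourse"] = {
                        "roi": "roi_pos",
                        "frac_significant": float(boot["significant"].mean()),
                        "bootstrap_B": tspec.B,
                    }
                else:
                    report["timecourse"] = {"skipped": True, "reason": "no bootstrap configured"}
        except Exception as e:  # noqa: BLE001
            raise PipelineError("roi_stats", str(e)) from e

    # ---- artifacts ------------------------------------------------------
    if out:
        for name, m in (("group_a_z", z_a), ("group_b_z", z_b), ("differential_z", dz)):
            m.meta.update(config_hash=chash, seed=seed)
            io.write_map(m, out / name)
        io.write_clusters(clusters, out / "clusters.json")
        io.write_events(list(events.values()), out / "events.csv")
        import json

        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
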