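"""End-to-end orchestration: one reproducible run from a config mapping.

A self-contained synthetic run executes
simulate -> quantify -> call (gain, depletion, neuronal filter, adult
re-call, control selection) -> cluster -> overlap -> footprint,
writes BED/TSV/JSON outputs plus a run manifest, and scores every stage
against the generator's truth tables into ``report.json``.

One global seed is expanded into per-stage child seeds through
``numpy.random.SeedSequence([seed, stage_index])`` so any stage can be
re-run in isolation reproducibly.  All thresholds live in the config;
there are no hidden constants.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from crosspeak.errors import ValidationError
from crosspeak.evo_footprint import (
    MotifPattern,
    archaic_fraction,
    compare_groups,
    count_hsas,
    hsa_rates,
    hsas_to_frame,
    motif_events,
    motif_gain_loss_table,
    motif_site_counts,
)
from crosspeak.genomic_io import (
    peak_lengths,
    write_alignment_blocks,
    write_annotations,
    write_count_matrix,
    write_peaks,
    write_sample_table,
)
from crosspeak.perm_stats import enrichment_test
from crosspeak.quantify import correlation_summary, normalize_density, sample_correlations
from crosspeak.species_calls import (
    AnalysisConfig,
    call_depletion,
    call_gain,
    calls_to_frame,
    filter_celltype_enriched,
    intersect_calls,
    select_control_peaks,
)
from crosspeak.synthetic_data import GeneratorSpec, gen_alignment_blocks, gen_annotations, gen_counts, gen_peak_pool

_VERSION = "0.1.0"

STAGES = ("simulate", "quantify", "call", "cluster", "overlap", "footprint")

DEFAULT_CONFIG = {
    "seed": 17,
    "n_sims": 2000,
    "generator": {},
    "analysis": {},
    "stages": list(STAGES),
    "n_control_peaks": 32,
    "motif": {"name": "GATA-1", "pattern": "WGATTAG"},
}


def _stage_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        user = dict(source)
    elif source is None:
        user = {}
    else:
        raise ValidationError(f"unsupported config source {type(source)!r}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def run_pipeline(config=None, outdir="crosspeak_run", seed: int | None = None) -> dict:
    """Execute the configured stages; return the run manifest."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    run_seed = int(cfg["seed"])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.perf_counter()

    gen_kwargs = dict(cfg["generator"])
    gen_kwargs["rng_seed"] = run_seed
    spec = GeneratorSpec(**gen_kwargs)
    acfg = AnalysisConfig(**{**cfg["analysis"], "rng_seed": run_seed})
    n_sims = int(cfg["n_sims"])
    stages = list(cfg["stages"])
    report: dict = {"seed": run_seed, "n_sims": n_sims}
    outputs: list[str] = []

    def log(msg):
        log_lines.append(f"[{time.perf_counter() - t0:8.2f}s] {msg}")

    # ---- simulate -------------------------------------------------------
    if "simulate" not in stages:
        raise ValidationError("only self-contained synthetic runs are supported; "
                              "include the 'simulate' stage")
    s = _stage_seed(run_seed, 0)
    peaks, pool_truth = gen_peak_pool(spec, seed=s)
    counts, samples, count_truth = gen_counts(peaks, spec, seed=_stage_seed(run_seed, 1))
    planted_ids = list(count_truth.index[count_truth["planted_gain"]])
    annot_target, annot_other, annot_truth = gen_annotations(
        peaks, spec, seed=_stage_seed(run_seed, 2), enriched_ids=planted_ids)
    lengths = peak_lengths(peaks)

    write_peaks(peaks, out / "peaks.bed")
    write_sample_table(samples, out / "samples.tsv")
    write_count_matrix(counts, out / "counts.tsv")
    write_annotations(annot_target, out / "annot_target.bed")
    write_annotations(annot_other, out / "annot_other.bed")
    pool_truth.to_csv(out / "truth_peaks.tsv", sep="\t")
    count_truth.to_csv(out / "truth_counts.tsv", sep="\t")
    annot_truth.to_csv(out / "truth_annotations.tsv", sep="\t")
    outputs += ["peaks.bed", "samples.tsv", "counts.tsv", "annot_target.bed",
                "annot_other.bed", "truth_peaks.tsv", "truth_counts.tsv",
                "truth_annotations.tsv"]
    log(f"simulate: {len(peaks)} peaks, {len(samples)} samples, "
        f"{len(planted_ids)} planted gains")

    # ---- quantify -------------------------------------------------------
    density = normalize_density(counts, samples, lengths)
    if "quantify" in stages:
        corr = sample_correlations(density)
        write_count_matrix(density, out / "density.tsv")
        corr.to_csv(out / "correlations.tsv", sep="\t", index_label="sample_id")
        correlation_summary(corr, samples).to_csv(
            out / "correlation_summary.tsv", sep="\t", index=False)
        outputs += ["density.tsv", "correlations.tsv", "correlation_summary.tsv"]
        log("quantify: density + correlations written")

    # ---- call -----------------------------------------------------------
    gain_ids: list[str] = []
    control_ids: list[str] = []
    if "call" in stages:
        gains = call_gain(density, samples, "human", ["chimpanzee", "macaque"],
                          lengths, acfg)
        losses = call_depletion(density, samples, "human",
                                ["chimpanzee", "macaque"], lengths, acfg)
        gain_ids = [c.peak_id for c in gains if c.label == "gain"]
        loss_ids = [c.peak_id for c in losses if c.label == "loss"]
        neuhp = filter_celltype_enriched(gains, density, samples, acfg)
        neuhp_ids = [c.peak_id for c in neuhp]

        adult_cols = [smp.sample_id for smp in samples
                      if not (smp.species == "human" and smp.age_group == "child")]
        adult_samples = [smp for smp in samples if smp.sample_id in set(adult_cols)]
        adult_cfg = replace(acfg, fold_threshold=1.5)
        n_adult_h = sum(1 for smp in adult_samples
                        if smp.species == "human" and smp.cell_type == "NeuN+")
        adult_gain_ids: list[str] = []
        if n_adult_h >= 2:
            adult = call_gain(density[adult_cols], adult_samples, "human",
                              ["chimpanzee", "macaque"], lengths, adult_cfg)
            adult_gain_ids = [c.peak_id for c in adult if c.label == "gain"]
        recall = intersect_calls(gain_ids, adult_gain_ids)

        control_ids = select_control_peaks(density, samples,
                                           int(cfg["n_control_peaks"]), acfg)

        calls_to_frame(gains).to_csv(out / "calls_gain.tsv", sep="\t")
        calls_to_frame(losses).to_csv(out / "calls_loss.tsv", sep="\t")
        write_peaks([p for p in peaks if p.id in set(gain_ids)], out / "calls_gain.bed")
        pd.Series(neuhp_ids, name="peak_id").to_csv(out / "calls_neuronal.tsv",
                                                    sep="\t", index=False)
        pd.Series(control_ids, name="peak_id").to_csv(out / "control_peaks.tsv",
                                                      sep="\t", index=False)
        outputs += ["calls_gain.tsv", "calls_loss.tsv", "calls_gain.bed",
                    "calls_neuronal.tsv", "control_peaks.tsv"]

        truth_gain = set(planted_ids)
        called = set(gain_ids)
        tp = len(called & truth_gain)
        report["calls"] = {
            "n_gain": len(gain_ids),
            "n_loss": len(loss_ids),
            "n_neuronal": len(neuhp_ids),
            "sensitivity": tp / len(truth_gain) if truth_gain else float("nan"),
            "false_discovery_proportion": (len(called) - tp) / len(called) if called else 0.0,
            "adult_recall_intersection": {k: recall[k] for k in
                                          ("n_a", "n_b", "n_intersection", "jaccard")},
        }
        restricted = set(count_truth.index[count_truth["neuron_restricted"]])
        if restricted:
            report["calls"]["neuronal_sensitivity"] = (
                len(set(neuhp_ids) & restricted) / len(restricted))
        log(f"call: {len(gain_ids)} gains, {len(loss_ids)} losses, "
            f"{len(neuhp_ids)} neuronal")

    # ---- cluster --------------------------------------------------------
    if "cluster" in stages:
        clustered_ids = list(pool_truth.index[pool_truth["cluster_id"] >= 0])
        subset = clustered_ids if clustered_ids else gain_ids
        result = {}
        if len(subset) >= 2:
            for i, d in enumerate(acfg.distance_thresholds):
                r = enrichment_test(subset, peaks, d=int(d), n_sims=n_sims,
                                    seed=_stage_seed(run_seed, 10 + i))
                result[f"d_{d}"] = r.as_dict()
        report["clustering"] = {"subset_size": len(subset), "results": result}
        _json_dump(report["clustering"], out / "clustering.json")
        outputs.append("clustering.json")
        log("cluster: done")

    # ---- overlap --------------------------------------------------------
    if "overlap" in stages:
        subset = gain_ids if gain_ids else planted_ids
        directions = {"target_only": "greater", "both": "greater",
                      "other_only": "less", "neither": "less"}
        per_cat = {}
        for i, (cat, direction) in enumerate(sorted(directions.items())):
            res = enrichment_test(subset, peaks,
                                  annotations=(annot_target, annot_other),
                                  n_sims=n_sims, direction=direction,
                                  seed=_stage_seed(run_seed, 20 + i))
            per_cat[cat] = res[cat].as_dict()
        report["overlap"] = {"subset_size": len(subset), "categories": per_cat}
        _json_dump(report["overlap"], out / "overlap.json")
        outputs.append("overlap.json")
        log("overlap: done")

    # ---- footprint ------------------------------------------------------
    if "footprint" in stages:
        if not gain_ids or not control_ids:
            raise ValidationError("footprint stage requires gain calls and "
                                  "control peaks (run the 'call' stage)")
        foot_ids = list(dict.fromkeys(gain_ids + control_ids))
        foot_peaks = [p for p in peaks if p.id in set(foot_ids)]
        blocks, block_truth = gen_alignment_blocks(
            foot_peaks, spec, seed=_stage_seed(run_seed, 30),
            elevated_ids=planted_ids)
        write_alignment_blocks(blocks, out / "alignments.fasta")
        block_truth.to_csv(out / "truth_alignments.tsv", sep="\t", index=False)

        comparison = list(spec.comparison_taxa)
        all_hsas = [h for b in blocks
                    for h in count_hsas(b, comparison, spec.archaic_taxa)]
        hsas_to_frame(all_hsas).to_csv(out / "hsas.tsv", sep="\t", index=False)

        rates = hsa_rates(blocks, comparison)
        gain_rates = rates.reindex(gain_ids).dropna()
        control_rates = rates.reindex(control_ids).dropna()
        comp = compare_groups(gain_rates, control_rates, n_sims=n_sims,
                              seed=_stage_seed(run_seed, 31))

        n_subs = sum(1 for h in all_hsas if h.kind == "substitution")
        arch = {}
        for taxon in spec.archaic_taxa:
            try:
                arch[taxon] = archaic_fraction(all_hsas, taxon)
            except ValidationError:
                arch[taxon] = None

        motif = MotifPattern(cfg["motif"]["name"], cfg["motif"]["pattern"])
        gained = lost = human_sites = shared_sites = 0
        for b in blocks:
            for ev in motif_events(b, motif, comparison):
                if ev.kind == "gained":
                    gained += 1
                else:
                    lost += 1
            nh, ns = motif_site_counts(b, motif, comparison)
            human_sites += nh
            shared_sites += ns
        motif_summary = {"pattern": motif.pattern, "gained": gained, "lost": lost,
                         "human_sites": human_sites, "shared_sites": shared_sites}
        if shared_sites and human_sites:
            motif_summary["chi2"] = motif_gain_loss_table(
                lost, shared_sites, gained, human_sites)

        report["footprint"] = {
            "n_blocks": len(blocks),
            "n_hsas": len(all_hsas),
            "substitution_fraction": n_subs / len(all_hsas) if all_hsas else None,
            "rate_gain_mean": float(gain_rates.mean()),
            "rate_control_mean": float(control_rates.mean()),
            "group_comparison": comp.as_dict(),
            "archaic_postsplit_fraction": arch,
            "motif": motif_summary,
        }
        _json_dump(report["footprint"], out / "footprint.json")
        outputs += ["alignments.fasta", "truth_alignments.tsv", "hsas.tsv",
                    "footprint.json"]
        log(f"footprint: {len(all_hsas)} HSAs over {len(blocks)} blocks")

    # ---- report + manifest ---------------------------------------------
    _json_dump(report, out / "report.json")
    outputs.append("report.json")

    manifest = {
        "tool": "crosspeak",
        "version": _VERSION,
        "config": cfg,
        "seed": run_seed,
        "stage_seeds": {name: _stage_seed(run_seed, i)
                        for i, name in enumerate(STAGES)},
        "outputs": {name: _digest(out / name) for name in sorted(set(outputs))},
    }
    _json_dump(manifest, out / "manifest.json")
    with open(out / "pipeline.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return manifest
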