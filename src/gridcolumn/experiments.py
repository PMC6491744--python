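"""Experiment harnesses: convergence, capacity, and union-size analyses.

All harnesses are deterministic functions of (config, seed): every source of
randomness -- object sets, feature encodings, learning-cell choices,
traversal orders -- descends from the seed.  Results come back as pandas
DataFrames of per-episode records plus aggregate summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .baselines import BagOfFeatures, IdealObserver
from .config import Config, build_network, build_world
from .network import RecognitionStatus
from .synthetic_objects import make_traversal, rarest_feature_counts

__all__ = [
    "ExperimentResult",
    "CapacityResult",
    "run_recognition",
    "convergence_experiment",
    "measure_accuracy",
    "find_capacity",
    "capacity_experiment",
    "union_size_analysis",
]


@dataclass
class ExperimentResult:
    """Per-episode records and per-sensation summary curves."""

    records: pd.DataFrame
    densities: pd.DataFrame
    summary: pd.DataFrame


@dataclass
class CapacityResult:
    """Capacity (max objects at >=90% recognition) per sweep value and seed."""

    sweep_param: str
    records: pd.DataFrame
    summary: pd.DataFrame


def _seed_rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def run_recognition(config: Config, seed: int, record_density: bool = False):
    """Train a network on one generated object set and infer every object.

    Returns (records, densities) DataFrames: one row per episode with the
    outcome and sensation counts for the network, the ideal observer, and the
    bag-of-features detector, all given the identical traversal.
    """
    rng = _seed_rng(seed, 0)
    objects, encoding = build_world(config, rng)
    net = build_network(config, encoding)
    net.train(objects, rng)
    ideal = IdealObserver(objects)
    bag = BagOfFeatures(objects)
    k_by_object = rarest_feature_counts(objects)

    rows = []
    density_rows = []
    infer_rng = _seed_rng(seed, 1)
    for obj in objects:
        for trial in range(config.run.traversals_per_object):
            seq = make_traversal(obj, infer_rng, passes=config.run.passes_limit)
            out = net.infer_sequence(obj, seq, record_density=record_density)
            rows.append(
                {
                    "seed": seed,
                    "object": obj.id,
                    "trial": trial,
                    "k": k_by_object[obj.id],
                    "status": out.status.value,
                    "recognized": out.recognized,
                    "sensations_net": out.sensations_to_recognition,
                    "sensations_ideal": ideal.infer(seq),
                    "sensations_bag": bag.infer(seq),
                }
            )
            for t, d in enumerate(out.densities, start=1):
                density_rows.append(
                    {"seed": seed, "object": obj.id, "trial": trial,
                     "sensation": t, "density": d}
                )
    records = pd.DataFrame(rows).astype(
        {f"sensations_{m}": "float64" for m in ("net", "ideal", "bag")}
    )
    return records, pd.DataFrame(density_rows)


def convergence_experiment(config: Config, seeds=None) -> ExperimentResult:
    """Recognition-time and activation-density curves over object-set seeds.

    For each seed a fresh object set is generated and learned; every object
    is traversed in random order while the location-layer activation density
    is recorded after each sensation.  The summary holds, per sensation
    index, the cumulative fraction of objects recognized by each detector and
    the 5th/50th/95th percentiles of both metrics across seeds.
    """
    if seeds is None:
        seeds = range(config.run.seeds)
    all_records = []
    all_densities = []
    for seed in seeds:
        rec, dens = run_recognition(config, seed, record_density=True)
        all_records.append(rec)
        all_densities.append(dens)
    records = pd.concat(all_records, ignore_index=True)
    densities = pd.concat(all_densities, ignore_index=True)

    max_t = config.objects.points * config.run.passes_limit
    summary_rows = []
    for seed, group in records.groupby("seed"):
        n = len(group)
        for t in range(1, max_t + 1):
            row = {"seed": seed, "sensation": t}
            for method in ("net", "ideal", "bag"):
                s = group[f"sensations_{method}"]
                if method == "net":
                    done = group["recognized"] & (s <= t)
                else:
                    done = s.notna() & (s <= t)
                row[f"pct_recognized_{method}"] = 100.0 * done.mean()
            d = densities[(densities["seed"] == seed) & (densities["sensation"] == t)]
            row["mean_density"] = d["density"].mean() if len(d) else np.nan
            summary_rows.append(row)
    per_seed = pd.DataFrame(summary_rows)
    summary = (
        per_seed.groupby("sensation")
        .agg(
            pct_net_p5=("pct_recognized_net", lambda x: np.percentile(x, 5)),
            pct_net_p50=("pct_recognized_net", "median"),
            pct_net_p95=("pct_recognized_net", lambda x: np.percentile(x, 95)),
            pct_ideal_p50=("pct_recognized_ideal", "median"),
            pct_bag_p50=("pct_recognized_bag", "median"),
            density_p5=("mean_density", lambda x: np.percentile(x.dropna(), 5) if x.notna().any() else np.nan),
            density_p50=("mean_density", "median"),
            density_p95=("mean_density", lambda x: np.percentile(x.dropna(), 95) if x.notna().any() else np.nan),
        )
        .reset_index()
    )
    return ExperimentResult(records=records, densities=densities, summary=summary)


def measure_accuracy(config: Config, num_objects: int, seed: int) -> float:
    """Fraction of objects recognized after the full pass budget."""
    cfg = config.with_(objects={"num": int(num_objects)})
    records, _ = run_recognition(cfg, seed)
    return float(records["recognized"].mean())


def find_capacity(
    accuracy_fn,
    threshold: float = 0.9,
    start: int = 4,
    max_objects: int = 512,
    step: int = 1,
) -> int:
    """Largest object count whose accuracy stays at or above the threshold.

    Coarse doubling from ``start`` until accuracy drops below threshold (or
    ``max_objects`` is hit), then bisection between the last passing and
    first failing counts, down to a resolution of ``step`` objects.  The
    threshold is inclusive (>= passes).
    """
    lo = 0
    n = start
    while n <= max_objects:
        if accuracy_fn(n) >= threshold:
            lo = n
            n *= 2
        else:
            break
    if n > max_objects:
        if lo < max_objects and accuracy_fn(max_objects) >= threshold:
            return max_objects
        return lo
    hi = n  # first failing count
    while hi - lo > step:
        mid = (lo + hi) // 2
        if accuracy_fn(mid) >= threshold:
            lo = mid
        else:
            hi = mid
    return lo


def capacity_experiment(
    config: Config,
    sweep_param: str,
    sweep_values,
    seeds=None,
    threshold: float = 0.9,
    start: int = 4,
    max_objects: int = 512,
    step: int = 1,
) -> CapacityResult:
    """Capacity as a function of one model or object parameter.

    ``sweep_param`` is one of ``'num_modules'``, ``'cells_per_axis'``,
    ``'pool_size'``.  For each sweep value and object-set seed, the capacity
    search trains fresh networks at increasing object counts; the summary
    reports the 5th/50th/95th percentiles across seeds.
    """
    section_field = {
        "num_modules": ("modules", "n"),
        "cells_per_axis": ("modules", "cells_per_axis"),
        "pool_size": ("objects", "pool"),
    }
    if sweep_param not in section_field:
        raise ValueError(f"unknown sweep parameter: {sweep_param!r}")
    section, fieldname = section_field[sweep_param]

    if seeds is None:
        seeds = range(config.run.seeds)
    rows = []
    for value in sweep_values:
        cfg = config.with_(**{section: {fieldname: int(value)}})
        for seed in seeds:
            cap = find_capacity(
                lambda n: measure_accuracy(cfg, n, seed),
                threshold=threshold,
                start=start,
                max_objects=max_objects,
                step=step,
            )
            rows.append({"sweep_value": value, "seed": seed, "capacity": cap})
    records = pd.DataFrame(rows)
    summary = (
        records.groupby("sweep_value")["capacity"]
        .agg(
            p5=lambda x: np.percentile(x, 5),
            p50="median",
            p95=lambda x: np.percentile(x, 95),
        )
        .reset_index()
    )
    return CapacityResult(sweep_param=sweep_param, records=records, summary=summary)


def union_size_analysis(
    config: Config,
    distributions=("uniform",),
    seeds=None,
    bins=(1, 5, 10, 20, 40, 1_000_000),
) -> pd.DataFrame:
    """Recognition rate binned by the rarest-feature occurrence count k.

    An object's k is the total number of times its rarest feature occurs
    across all learned objects -- the size of the smallest union that sensing
    that feature can invoke.  Recognition should degrade as k grows, at a
    breaking point that is stable across feature distributions.
    Returns one row per (distribution, k bin) with the pooled recognition
    rate and episode count.
    """
    if seeds is None:
        seeds = range(config.run.seeds)
    frames = []
    for distribution in distributions:
        cfg = config.with_(objects={"distribution": distribution})
        for seed in seeds:
            rec, _ = run_recognition(cfg, seed)
            rec = rec.assign(distribution=distribution)
            frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    edges = list(bins)
    records["k_bin"] = pd.cut(records["k"], edges, include_lowest=True)
    out = (
        records.groupby(["distribution", "k_bin"], observed=True)
        .agg(recognition_rate=("recognized", "mean"), episodes=("recognized", "size"),
             mean_k=("k", "mean"))
        .reset_index()
    )
    return out
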