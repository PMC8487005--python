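"""End-to-end pipeline: binarize -> tuples -> reconstruct -> ensembles -> analytics.

One :class:`PipelineConfig` carries every tunable of the pipeline; all
stage seeds derive deterministically from its ``master_seed``, so a run is
exactly reproducible from its manifest.  The pipeline runs each individual
independently and finishes with a rank-based comparison of the configured
groups (e.g. young vs aged) over the replicate-level ensemble metrics.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    MetricsRecord,
    activity_probabilities,
    compare_groups,
    graph_metrics,
    landscape_stats,
    metrics_table,
)
from .binarize import BinaryMatrix, binarize_matrix
from .boolnet_io import write_attractor_report
from .ensemble import Ensemble, ensemble_campaign, write_manifest
from .io import read_expression, write_binary_matrix
from .network import Attractor, GeneUniverse, find_attractors
from .pseudotime import (
    TransitionPair,
    TupleSample,
    replicate_samples,
    write_tuple_samples,
)
from .reconstruct import write_candidates

__all__ = [
    "PipelineConfig",
    "IndividualResult",
    "PipelineReport",
    "run_pipeline",
    "consecutive_samples",
]

_STEP_RE = re.compile(r"^(?P<prefix>.+)_s(?P<step>\d+)$")


@dataclass
class PipelineConfig:
    """All pipeline tunables; round-trips losslessly through YAML."""

    # binarization
    alpha: float = 0.05
    binarize_method: str = "basc_a"
    n_boot: int = 999
    # pseudo-time tuples
    n_pairs: int = 1000
    n_replicates: int = 20
    pair_mode: str = "random"  # "random" (pseudo-time) or "consecutive"
    sample_with_replacement: bool = False
    # reconstruction
    threshold: float = 0.03
    k_max: int = 5
    cap: int = 1024
    max_candidates: int = 16
    error_mode: str = "weighted"
    # ensembles
    n_networks: int = 100
    # attractor search
    attractor_mode: str = "auto"  # auto / exhaustive / sampled
    exhaustive_cap: int = 25
    n_starts: int = 500
    # bookkeeping
    master_seed: int = 0
    groups: dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def consecutive_samples(
    bin_matrix: BinaryMatrix,
    n_pairs: int,
    n_replicates: int,
    master_seed: int,
) -> list[TupleSample]:
    """Transition pairs from consecutive cells of ordered trajectories.

    Used when cells are ordered measurements (simulated series, fixtures
    whose cell ids end in ``_s<step>`` with a shared trajectory prefix)
    rather than an unordered snapshot.  Cells without step-encoded ids are
    treated as one trajectory in column order.  Each replicate subsamples
    ``n_pairs`` consecutive pairs without replacement (or takes all pairs
    when fewer exist).
    """
    frame = bin_matrix.binary
    cells = list(frame.columns)
    matches = [_STEP_RE.match(str(c)) for c in cells]
    if all(m is not None for m in matches):
        keyed = [
            (m.group("prefix"), int(m.group("step")), c)
            for m, c in zip(matches, cells)
        ]
        trajectories: dict[str, list[tuple[int, str]]] = {}
        for prefix, step, cell in keyed:
            trajectories.setdefault(prefix, []).append((step, cell))
        ordered = [
            [c for _, c in sorted(members)] for _, members in sorted(trajectories.items())
        ]
    else:
        ordered = [cells]
    values = frame.to_numpy(dtype=np.uint8)
    col = {c: k for k, c in enumerate(cells)}
    all_pairs = [
        TransitionPair(
            predecessor=tuple(values[:, col[a]]),
            successor=tuple(values[:, col[b]]),
            source_cells=(str(a), str(b)),
        )
        for traj in ordered
        for a, b in zip(traj, traj[1:])
    ]
    if not all_pairs:
        raise ValueError("no consecutive pairs could be formed")
    samples = []
    for r in range(1, n_replicates + 1):
        seed = master_seed + r
        if n_pairs < len(all_pairs):
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(len(all_pairs), size=n_pairs, replace=False))
            chosen = tuple(all_pairs[i] for i in idx)
        else:
            chosen = tuple(all_pairs)
        samples.append(TupleSample(pairs=chosen, seed=seed, replicate_index=r))
    return samples


@dataclass
class IndividualResult:
    """Everything the pipeline computed for one individual."""

    name: str
    binary: BinaryMatrix
    samples: list[TupleSample]
    ensembles: list[Ensemble]
    landscapes: list[list[list[Attractor]]]  # per ensemble, per network
    metrics: pd.DataFrame
    records: list[MetricsRecord]
    activity: pd.Series


@dataclass
class PipelineReport:
    config: PipelineConfig
    individuals: dict[str, IndividualResult]
    comparison: dict | None


def _attractor_landscape(
    ensembles: list[Ensemble], cfg: PipelineConfig
) -> list[list[list[Attractor]]]:
    out = []
    for e_idx, ens in enumerate(ensembles):
        per_network = []
        n = len(ens.universe)
        mode = cfg.attractor_mode
        if mode == "auto":
            mode = "exhaustive" if n <= cfg.exhaustive_cap else "sampled"
        for net_idx, net in enumerate(ens.networks):
            seed = cfg.master_seed + 7919 * (e_idx + 1) + net_idx
            if mode == "exhaustive":
                atts = find_attractors(
                    net, mode="exhaustive", exhaustive_cap=cfg.exhaustive_cap
                )
            else:
                atts = find_attractors(
                    net, mode="sampled", n_starts=cfg.n_starts, seed=seed
                )
            per_network.append(atts)
        out.append(per_network)
    return out


def _run_individual(
    name: str, expr: pd.DataFrame, cfg: PipelineConfig
) -> IndividualResult:
    binary = binarize_matrix(
        expr,
        alpha=cfg.alpha,
        method=cfg.binarize_method,
        n_boot=cfg.n_boot,
        seed=cfg.master_seed,
    )
    universe = GeneUniverse(tuple(binary.genes))
    if cfg.pair_mode == "random":
        samples = replicate_samples(
            binary,
            cfg.n_pairs,
            cfg.n_replicates,
            cfg.master_seed,
            replace=cfg.sample_with_replacement,
        )
    elif cfg.pair_mode == "consecutive":
        samples = consecutive_samples(
            binary, cfg.n_pairs, cfg.n_replicates, cfg.master_seed
        )
    else:
        raise ValueError(f"unknown pair mode {cfg.pair_mode!r}")
    ensembles = ensemble_campaign(
        samples,
        universe,
        cfg.n_networks,
        cfg.master_seed,
        threshold=cfg.threshold,
        k_max=cfg.k_max,
        cap=cfg.cap,
        max_candidates=cfg.max_candidates,
        error_mode=cfg.error_mode,
    )
    landscapes = _attractor_landscape(ensembles, cfg)
    metrics = metrics_table(ensembles)
    records = []
    activities = []
    for ens, land in zip(ensembles, landscapes):
        rec = graph_metrics(ens)
        rec.n_attractors, rec.mean_attractor_length = landscape_stats(land)
        records.append(rec)
        activities.append(activity_probabilities(land))
    activity = pd.Series(
        np.mean(activities, axis=0), index=list(universe.names), name=name
    )
    return IndividualResult(
        name=name,
        binary=binary,
        samples=samples,
        ensembles=ensembles,
        landscapes=landscapes,
        metrics=metrics,
        records=records,
        activity=activity,
    )


def run_pipeline(
    config: PipelineConfig,
    expression: dict,
    outdir=None,
) -> PipelineReport:
    """Run the full pipeline for every individual and compare the groups.

    ``expression`` maps individual name -> genes x cells DataFrame or a
    path readable by :func:`boolense.io.read_expression`.  With ``outdir``
    set, every stage artifact plus a run manifest is written there.
    """
    if not expression:
        raise ValueError("at least one individual is required")
    individuals: dict[str, IndividualResult] = {}
    for name, source in expression.items():
        expr = source if isinstance(source, pd.DataFrame) else read_expression(source)
        try:
            individuals[name] = _run_individual(name, expr, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed for individual {name!r}: {exc}") from exc

    comparison = None
    labels = {n: config.groups.get(n) for n in individuals}
    distinct = sorted({v for v in labels.values() if v is not None})
    if len(distinct) == 2:
        group_records = {
            lab: [
                rec
                for n, res in individuals.items()
                if labels[n] == lab
                for rec in res.records
            ]
            for lab in distinct
        }
        comparison = {
            "groups": distinct,
            "tests": {
                metric: {"statistic": s, "p": p, "p_bonferroni": padj}
                for metric, (s, p, padj) in compare_groups(
                    group_records[distinct[0]],
                    group_records[distinct[1]],
                    correction="bonferroni",
                ).items()
            },
        }

    report = PipelineReport(config=config, individuals=individuals, comparison=comparison)
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: PipelineReport, outdir) -> None:
    """Persist all pipeline artifacts plus a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    activity_frames = []
    for name, res in report.individuals.items():
        d = outdir / name
        d.mkdir(exist_ok=True)
        write_binary_matrix(res.binary, d / "binary.tsv", d / "binarization_stats.tsv")
        write_tuple_samples(res.samples, d / "tuples.tsv")
        write_candidates(
            {e.replicate_index: e.candidates for e in res.ensembles},
            d / "candidates.tsv",
        )
        write_manifest(res.ensembles, d / "ensemble_manifest.json")
        write_attractor_report(res.landscapes[0][0], d / "attractors_rep1_net0.json")
        res.metrics.to_csv(d / "metrics.tsv", sep="\t", index=False)
        summary = pd.DataFrame([rec.as_dict() for rec in res.records])
        summary.insert(0, "replicate", [e.replicate_index for e in res.ensembles])
        summary.to_csv(d / "metrics_summary.tsv", sep="\t", index=False)
        activity_frames.append(res.activity)
    activity = pd.concat(activity_frames, axis=1)
    activity.to_csv(outdir / "activity.tsv", sep="\t")
    if report.comparison is not None:
        (outdir / "group_comparison.json").write_text(
            json.dumps(report.comparison, indent=1)
        )
    manifest = {
        "version": __version__,
        "config": asdict(report.config),
        "individuals": {
            name: {
                "n_genes_retained": len(res.binary.genes),
                "n_cells": len(res.binary.cells),
                "n_replicates": len(res.ensembles),
                "n_networks_total": sum(len(e) for e in res.ensembles),
            }
            for name, res in report.individuals.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
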