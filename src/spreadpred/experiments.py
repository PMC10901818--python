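"""Experiment orchestration: K-sweeps, correlation profiles, lambda sweeps.

A manifest (a small dataclass, loadable from YAML) names the input
networks — edge-list files or LFR configurations — and the sweep
parameters; the runners produce tidy tables, one row per condition,
reproducible from the manifest's root seed.  Ground-truth influence for
a (graph, lambda) pair is computed once and cached, both in memory and
(optionally) as CSV in the output directory, keyed on the graph hash,
lambda, run count and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import Partition, UndirectedGraph, coverage_curve, read_edge_list
from .lfr import LFRConfig, generate_lfr
from .metrics import (CentralityVector, benchmark_feature_matrix,
                      convergence_profile, coreness, eigenvector_centrality,
                      hi_iterate, nwc_iterate, pagerank, vp_iterate)
from .prediction import ExperimentConfig, kendall_tau, run_experiment
from .sir import (InfluenceTable, SIRConfig, estimate_influence,
                  estimate_threshold)

log = logging.getLogger("spreadpred")

METRIC_FAMILIES = ("NWC", "VP", "HI")


@dataclass
class GraphSource:
    """One input network: an edge-list path or an LFR configuration."""

    name: str
    path: str | None = None
    lfr: dict | None = None

    def load(self, root_seed: int) -> tuple[UndirectedGraph, Partition | None]:
        if (self.path is None) == (self.lfr is None):
            raise ValueError(f"source {self.name!r}: give exactly one of "
                             "path or lfr")
        if self.path is not None:
            from .graph import largest_connected_component

            return largest_connected_component(read_edge_list(self.path)), None
        cfg = LFRConfig(**{"rng_seed": root_seed, **self.lfr})
        return generate_lfr(cfg)


@dataclass
class ExperimentManifest:
    """Everything needed to reproduce one experiment grid."""

    graphs: list[GraphSource]
    k_max: int = 8
    metric_sets: tuple[str, ...] = METRIC_FAMILIES
    lambda_multipliers: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    sir_runs: int = 1000
    threshold_runs: int = 300
    threshold_grid: tuple[float, float, float] = (0.01, 0.20, 0.01)  # a:b:step
    threshold_sample: int | None = None
    evaluation: dict = field(default_factory=dict)   # ExperimentConfig overrides
    out_dir: str | None = None
    root_seed: int = 0

    def __post_init__(self):
        self.graphs = [g if isinstance(g, GraphSource) else GraphSource(**g)
                       for g in self.graphs]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentManifest":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land must not change what they are
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def eval_config(self, **extra) -> ExperimentConfig:
        return ExperimentConfig(**{"rng_seed": self.root_seed,
                                   **self.evaluation, **extra})

    def write_lock(self) -> None:
        if self.out_dir:
            out = Path(self.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            with open(out / "manifest.lock.json", "w") as fh:
                json.dump({"hash": self.hash(), "manifest": asdict(self)},
                          fh, indent=1, default=str)


def _graph_hash(g: UndirectedGraph) -> str:
    h = hashlib.sha256()
    h.update(g.indptr.tobytes())
    h.update(g.indices.tobytes())
    return h.hexdigest()[:12]


class _Stage:
    """Context manager logging wall time per pipeline stage."""

    def __init__(self, label: str):
        self.label = label

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s ...", self.label)

    def __exit__(self, *exc):
        log.info("stage %s done in %.1fs", self.label, time.perf_counter() - self.t0)


class ExperimentRunner:
    """Shared caches (graphs, thresholds, influence tables) across sweeps."""

    def __init__(self, manifest: ExperimentManifest):
        self.manifest = manifest
        self._graphs: dict[str, tuple[UndirectedGraph, Partition | None]] = {}
        self._thresholds: dict[str, float] = {}
        self._influence: dict[tuple, InfluenceTable] = {}
        manifest.write_lock()

    # -- cached stages -------------------------------------------------

    def graph(self, name: str) -> tuple[UndirectedGraph, Partition | None]:
        if name not in self._graphs:
            src = next(s for s in self.manifest.graphs if s.name == name)
            with _Stage(f"load {name}"):
                self._graphs[name] = src.load(self.manifest.root_seed)
        return self._graphs[name]

    def lambda_c(self, name: str) -> float:
        if name not in self._thresholds:
            g, _ = self.graph(name)
            a, b, step = self.manifest.threshold_grid
            grid = np.round(np.arange(a, b + step / 2, step), 10)
            cfg = SIRConfig(beta=1.0, runs=self.manifest.threshold_runs,
                            rng_seed=self._seed(name, "threshold"))
            with _Stage(f"threshold {name}"):
                scan = estimate_threshold(
                    g, grid, cfg,
                    node_sample_size=self.manifest.threshold_sample)
            self._write(scan.to_frame(), "influence", f"{name}_threshold.csv")
            self._thresholds[name] = scan.lambda_c
        return self._thresholds[name]

    def influence(self, name: str, lam: float) -> InfluenceTable:
        g, _ = self.graph(name)
        key = (name, _graph_hash(g), round(lam, 10), self.manifest.sir_runs)
        if key not in self._influence:
            cached = self._read_cached_influence(key, lam)
            if cached is not None:
                self._influence[key] = cached
                return cached
            cfg = SIRConfig(beta=lam, runs=self.manifest.sir_runs,
                            rng_seed=self._seed(name, "influence"))
            with _Stage(f"influence {name} lambda={lam:g}"):
                tbl = estimate_influence(g, cfg)
            self._write(tbl.to_frame(), "influence",
                        self._influence_filename(key))
            self._influence[key] = tbl
        return self._influence[key]

    def features(self, name: str, family: str, K: int) -> np.ndarray:
        g, _ = self.graph(name)
        if family == "benchmark":
            return benchmark_feature_matrix(g)
        fn = {"NWC": nwc_iterate, "VP": vp_iterate, "HI": hi_iterate}[family]
        return fn(g, K).values.astype(float)

    # -- sweeps --------------------------------------------------------

    def run_k_sweep(self, k_values: list[int] | None = None) -> pd.DataFrame:
        """Prediction quality per (graph, metric family, K) at lambda_c."""
        ks = k_values or list(range(1, self.manifest.k_max + 1))
        rows = []
        for src in self.manifest.graphs:
            lam = self.lambda_c(src.name)
            tbl = self.influence(src.name, lam)
            for family in self.manifest.metric_sets:
                for K in ks:
                    rep = run_experiment(
                        self.features(src.name, family, K), tbl,
                        self.manifest.eval_config(K=K),
                        metric_name=family, graph_id=src.name)
                    rows.append({"graph": src.name, "metric": family, "K": K,
                                 "lambda": lam, **rep.mean.to_dict()})
        df = self._finalize(pd.DataFrame(rows))
        self._write(df, "eval", "k_sweep.csv")
        return df

    def run_correlation_profiles(self, k_max: int | None = None) -> pd.DataFrame:
        """tau(M(k), s) and tau(M(k), M*) per order, plus coverage curves."""
        k_max = k_max or self.manifest.k_max
        rows = []
        for src in self.manifest.graphs:
            g, _ = self.graph(src.name)
            lam = self.lambda_c(src.name)
            s = self.influence(src.name, lam).influence
            targets = {"NWC": eigenvector_centrality(g),
                       "VP": pagerank(g), "HI": coreness(g)}
            for family in self.manifest.metric_sets:
                fn = {"NWC": nwc_iterate, "VP": vp_iterate,
                      "HI": hi_iterate}[family]
                ms = fn(g, k_max)
                conv = convergence_profile(ms, targets[family])
                for k in range(1, k_max + 1):
                    rows.append({"graph": src.name, "metric": family, "k": k,
                                 "tau_vs_influence": kendall_tau(ms.order(k), s),
                                 "tau_vs_global": conv[k - 1]})
            cov = coverage_curve(g)
            for k, c in enumerate(cov, start=1):
                rows.append({"graph": src.name, "metric": "coverage", "k": k,
                             "tau_vs_influence": np.nan, "tau_vs_global": np.nan,
                             "coverage": c})
        df = self._finalize(pd.DataFrame(rows))
        self._write(df, "eval", "correlation_profiles.csv")
        return df

    def run_lambda_sweep(self, K: int = 4) -> pd.DataFrame:
        """Prediction quality at lambda = multiplier * lambda_c."""
        rows = []
        for src in self.manifest.graphs:
            lam_c = self.lambda_c(src.name)
            for mult in self.manifest.lambda_multipliers:
                tbl = self.influence(src.name, mult * lam_c)
                for family in (*self.manifest.metric_sets, "benchmark"):
                    rep = run_experiment(
                        self.features(src.name, family, K), tbl,
                        self.manifest.eval_config(K=K),
                        metric_name=family, graph_id=src.name)
                    rows.append({"graph": src.name, "metric": family,
                                 "multiplier": mult, "lambda": mult * lam_c,
                                 **rep.mean.to_dict()})
        df = self._finalize(pd.DataFrame(rows))
        self._write(df, "eval", "lambda_sweep.csv")
        return df

    # -- helpers -------------------------------------------------------

    def _seed(self, name: str, stage: str) -> int:
        digest = hashlib.sha256(
            f"{self.manifest.root_seed}:{name}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") >> 1

    def _finalize(self, df: pd.DataFrame) -> pd.DataFrame:
        df.insert(0, "manifest_hash", self.manifest.hash())
        df.insert(1, "root_seed", self.manifest.root_seed)
        return df

    def _influence_filename(self, key: tuple) -> str:
        name, ghash, lam, runs = key
        return f"{name}_{ghash}_lam{lam:g}_r{runs}.csv"

    def _read_cached_influence(self, key: tuple, lam: float):
        if not self.manifest.out_dir:
            return None
        path = Path(self.manifest.out_dir) / "influence" / \
            self._influence_filename(key)
        if path.exists():
            return InfluenceTable.from_csv(path, effective_rate=lam)
        return None

    def _write(self, df: pd.DataFrame, sub: str, fname: str) -> None:
        if self.manifest.out_dir:
            d = Path(self.manifest.out_dir) / sub
            d.mkdir(parents=True, exist_ok=True)
            df.to_csv(d / fname, index=False)


def run_k_sweep(manifest: ExperimentManifest, **kw) -> pd.DataFrame:
    return ExperimentRunner(manifest).run_k_sweep(**kw)


def run_correlation_profiles(manifest: ExperimentManifest, **kw) -> pd.DataFrame:
    return ExperimentRunner(manifest).run_correlation_profiles(**kw)


def run_lambda_sweep(manifest: ExperimentManifest, **kw) -> pd.DataFrame:
    return ExperimentRunner(manifest).run_lambda_sweep(**kw)
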