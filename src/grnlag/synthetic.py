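"""Synthetic pseudotime trajectories with planted time-lagged regulatory edges.

The generator emulates the structure the sliding-window method assumes: a
regulator's expression signal reappears in its target after a lag of a fixed
number of cells along the pseudotime axis.  Each transcription factor gets a
smooth latent trajectory (a sum of low-frequency sinusoids); each planted edge
copies that trajectory into the target, shifted right by the edge's lag and
scaled by ``effect``; decoy genes carry independent smooth trajectories.
Independent Gaussian noise is added to every gene.

Signals and noise are drawn from separate seeded streams, so two datasets
generated with the same seed but different ``noise_sd`` share their latent
signals exactly — convenient for noise-calibration checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, ReferenceNetwork

__all__ = ["SyntheticConfig", "simulate_dataset", "make_benchmark", "DEFAULT_BENCHMARK"]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-edge trajectory generator.

    n_cells is the trajectory length T (pseudotime is simply 1..T); lags are
    drawn uniformly from ``lag_range`` (inclusive, in cells); ``smoothness``
    is the shortest wavelength (in cells) allowed in the latent sinusoids, so
    larger values give slower trajectories.
    """

    n_genes: int = 60
    n_cells: int = 600
    n_tfs: int = 10
    n_edges: int = 30
    lag_range: tuple[int, int] = (5, 40)
    effect: float = 1.0
    noise_sd: float = 0.5
    smoothness: float = 50.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_tfs >= self.n_genes:
            raise ValueError("need at least one non-TF gene")
        if self.n_edges > self.n_tfs * (self.n_genes - 1):
            raise ValueError("n_edges exceeds the number of possible TF->gene pairs")
        if self.lag_range[1] > self.n_cells / 4:
            raise ValueError("max lag must not exceed T/4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


def _smooth_signal(rng: np.random.Generator, T: int, smoothness: float, n_harmonics: int = 3) -> np.ndarray:
    """Sum of low-frequency sinusoids: wavelengths >= ``smoothness`` cells."""
    t = np.arange(T, dtype=float)
    max_freq = max(1.0, T / smoothness)
    sig = np.zeros(T)
    for _ in range(n_harmonics):
        freq = rng.uniform(0.5, max_freq)
        amp = rng.uniform(0.5, 1.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        sig += amp * np.sin(2 * np.pi * freq * t / T + phase)
    return sig


def _shift_right(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift a signal right by ``lag`` cells, constant-padding the start."""
    if lag == 0:
        return x.copy()
    out = np.empty_like(x)
    out[:lag] = x[0]
    out[lag:] = x[:-lag]
    return out


def simulate_dataset(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, ReferenceNetwork]:
    """Generate a pseudotime-ordered matrix and the planted gold-standard network.

    Returns the expression matrix (per-gene shifted to be nonnegative;
    pseudotime 1..T attached) and the network of planted edges, whose
    ``lags`` table records each edge's true lag in cells.
    """
    sig_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    T = cfg.n_cells
    tf_ids = [f"TF{i + 1}" for i in range(cfg.n_tfs)]
    gene_ids = tf_ids + [f"G{i + 1}" for i in range(cfg.n_genes - cfg.n_tfs)]

    signals = {g: None for g in gene_ids}
    for tf in tf_ids:
        signals[tf] = _smooth_signal(sig_rng, T, cfg.smoothness)

    # plant edges: uniform without replacement over (tf, non-tf gene) pairs,
    # targets chosen among non-TF genes so each target has a single regulator
    targets = gene_ids[cfg.n_tfs:]
    candidates = [(tf, g) for tf in tf_ids for g in targets]
    if cfg.n_edges > len(candidates):
        raise ValueError(
            f"n_edges={cfg.n_edges} exceeds TF x non-TF pair count ({len(candidates)})"
        )
    # at most one incoming edge per target keeps lags well-defined
    if cfg.n_edges > len(targets):
        raise ValueError(
            f"n_edges={cfg.n_edges} exceeds the number of non-TF genes ({len(targets)})"
        )
    chosen_targets = sig_rng.choice(len(targets), size=cfg.n_edges, replace=False)
    edges: set[tuple[str, str]] = set()
    lags: dict[tuple[str, str], int] = {}
    for ti in sorted(chosen_targets):
        tgt = targets[ti]
        tf = tf_ids[int(sig_rng.integers(0, cfg.n_tfs))]
        lag = int(sig_rng.integers(cfg.lag_range[0], cfg.lag_range[1] + 1))
        edges.add((tf, tgt))
        lags[(tf, tgt)] = lag
        signals[tgt] = cfg.effect * _shift_right(signals[tf], lag)

    for g in gene_ids:
        if signals[g] is None:  # decoy gene
            signals[g] = _smooth_signal(sig_rng, T, cfg.smoothness)

    values = np.stack([signals[g] for g in gene_ids])
    if cfg.noise_sd > 0:
        values = values + noise_rng.normal(0.0, cfg.noise_sd, size=values.shape)
    values = values - values.min(axis=1, keepdims=True)  # per-gene nonnegative shift

    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=[f"cell{t + 1}" for t in range(T)],
        values=values,
        pseudotime=np.arange(1, T + 1, dtype=float),
    )
    net = ReferenceNetwork(edges=edges, label="gold", lags=lags)
    return expr, net


DEFAULT_BENCHMARK = SyntheticConfig()


def make_benchmark(cfg: SyntheticConfig, out_dir: str) -> dict[str, str]:
    """Write a pipeline-ready benchmark directory and return the file paths.

    Produces ``expression.tsv`` (genes x cells), ``pseudotime.tsv`` (cell id,
    pseudotime), ``gold.tsv`` (tf, target) and ``manifest.tsv`` (tf, target,
    lag) — the same formats the loaders consume.
    """
    expr, net = simulate_dataset(cfg)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "pseudotime": os.path.join(out_dir, "pseudotime.tsv"),
        "gold": os.path.join(out_dir, "gold.tsv"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
    }
    expr.to_frame().to_csv(paths["expression"], sep="\t")
    pd.DataFrame({"cell": expr.cell_ids, "pseudotime": expr.pseudotime}).to_csv(
        paths["pseudotime"], sep="\t", header=False, index=False
    )
    edge_rows = sorted(net.edges)
    pd.DataFrame(edge_rows).to_csv(paths["gold"], sep="\t", header=False, index=False)
    lag_rows = [(tf, tg, net.lags[(tf, tg)]) for tf, tg in edge_rows]
    pd.DataFrame(lag_rows, columns=["tf", "target", "lag"]).to_csv(
        paths["manifest"], sep="\t", index=False
    )
    return paths
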