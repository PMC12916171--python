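"""Time-delay correlation matrices from sliding windows along pseudotime.

For a candidate pair (TF i, target j) the trajectory is cut into p TF windows
of width w cells, stepped by m cells.  Against the k-th TF window the target
is read at q successive delays stepped by n cells, so entry (k, l) of the
p x q matrix M(i, j) is the Pearson correlation between

    TF cells      (k-1)m + 1            ... (k-1)m + w
    target cells  (k-1)m + (l-1)n + 1   ... (k-1)m + (l-1)n + w

(1-based inclusive, mirroring how window indices are reported in outputs).
A genuine regulatory delay of tau cells shows up as a high-correlation band
at delay column 1 + tau/n.  Delays are one-sided: the target lags the TF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "WindowConfig",
    "DelayCorrelationMatrix",
    "segment_bounds",
    "required_cells",
    "default_window_config",
    "build_delay_matrix",
    "plot_delay_heatmap",
    "DATASET_PRESETS",
]

logger = logging.getLogger(__name__)

# published per-dataset sliding-window presets for the real benchmarks
DATASET_PRESETS: dict[str, dict[str, int]] = {
    "mHSC-E": {"p": 64, "q": 64, "m": 5, "n": 5, "w": 441},
    "mHSC-L": {"p": 64, "q": 64, "m": 5, "n": 5, "w": 217},
    "mHSC-GM": {"p": 64, "q": 64, "m": 5, "n": 5, "w": 259},
    "hESC": {"p": 64, "q": 64, "m": 5, "n": 5, "w": 128},
    "hHep": {"p": 64, "q": 64, "m": 2, "n": 2, "w": 173},
}


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: p TF windows, q delays, steps m/n, width w."""

    p: int = 64
    q: int = 64
    m: int = 5
    n: int = 5
    w: int = 441

    def __post_init__(self) -> None:
        for name in ("p", "q", "m", "n", "w"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"window parameter {name} must be a positive integer, got {v!r}")
        if self.w < 3:
            raise ValueError("window width w must be >= 3 for a meaningful correlation")


@dataclass
class DelayCorrelationMatrix:
    """The p x q matrix of lagged segment correlations for one gene pair."""

    tf_id: str
    target_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("delay matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("delay matrix contains non-finite entries")
        if self.values.min() < -1.0 - 1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError("delay matrix entries must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def segment_bounds(k: int, l: int, cfg: WindowConfig) -> tuple[tuple[int, int], tuple[int, int]]:
    """1-based inclusive [start, end] cell ranges of the TF and target segments.

    The TF segment of window k spans (k-1)m+1 .. (k-1)m+w; the target segment
    at delay l additionally shifts right by (l-1)n cells.
    """
    if not (1 <= k <= cfg.p):
        raise ValueError(f"window index k={k} out of range 1..{cfg.p}")
    if not (1 <= l <= cfg.q):
        raise ValueError(f"delay index l={l} out of range 1..{cfg.q}")
    tf_start = (k - 1) * cfg.m + 1
    tgt_start = tf_start + (l - 1) * cfg.n
    return (tf_start, tf_start + cfg.w - 1), (tgt_start, tgt_start + cfg.w - 1)


def required_cells(cfg: WindowConfig) -> int:
    """Minimal trajectory length T populating all p x q segment pairs.

    Equals the end index of the last target segment (k=p, l=q):
    (p-1)m + (q-1)n + w.
    """
    return (cfg.p - 1) * cfg.m + (cfg.q - 1) * cfg.n + cfg.w


def default_window_config(
    T: int, p: int = 64, q: int = 64, m: int = 5, n: int = 5
) -> WindowConfig:
    """Solve for the widest window w using the whole trajectory of length T.

    w = T - (p-1)m - (q-1)n.  If that leaves w < 3, p and q are halved (and
    finally the steps reduced to 1) until a feasible geometry exists; the
    adjustment is logged.  Raises if even p=q=1, m=n=1 cannot fit.
    """
    if T < 3:
        raise ValueError(f"T={T} too small; need at least 3 cells")
    p_, q_, m_, n_ = p, q, m, n
    while True:
        w = T - (p_ - 1) * m_ - (q_ - 1) * n_
        if w >= 3:
            break
        if p_ > 1 or q_ > 1:
            p_, q_ = max(1, p_ // 2), max(1, q_ // 2)
        elif m_ > 1 or n_ > 1:
            m_, n_ = 1, 1
        else:
            raise ValueError(f"no feasible window geometry for T={T}")
    if (p_, q_, m_, n_) != (p, q, m, n):
        logger.info(
            "window geometry adjusted for T=%d: p=%d q=%d m=%d n=%d (w=%d)",
            T, p_, q_, m_, n_, w,
        )
    return WindowConfig(p=p_, q=q_, m=m_, n=n_, w=w)


def _standardized_windows(row: np.ndarray, starts: np.ndarray, w: int) -> np.ndarray:
    """Each requested window standardized to zero mean, unit L2 norm.

    Zero-variance windows become zero vectors, so their dot product with any
    other window — i.e. their correlation — is 0.
    """
    windows = np.lib.stride_tricks.sliding_window_view(row, w)[starts]
    centered = windows - windows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    return np.where(norms > 0, centered / np.where(norms == 0, 1.0, norms), 0.0)


def build_delay_matrix(
    tf_row: np.ndarray, target_row: np.ndarray, cfg: WindowConfig,
    tf_id: str = "tf", target_id: str = "target",
) -> DelayCorrelationMatrix:
    """Compute M[k, l] = Pearson correlation of the (k, l) segment pair.

    Vectorized as dot products of standardized windows; segments with zero
    variance contribute correlation 0.  Entries are clamped to [-1, 1]
    against floating-point rounding.
    """
    tf_row = np.asarray(tf_row, dtype=float)
    target_row = np.asarray(target_row, dtype=float)
    T = tf_row.shape[0]
    if target_row.shape[0] != T:
        raise ValueError("tf and target vectors must have equal length")
    need = required_cells(cfg)
    if T < need:
        raise ValueError(f"trajectory too short: need {need} cells, got {T}")
    # 0-based window start offsets
    tf_starts = np.arange(cfg.p) * cfg.m
    offsets = np.arange(cfg.q) * cfg.n
    all_tgt_starts = np.unique(tf_starts[:, None] + offsets[None, :])
    Z_tf = _standardized_windows(tf_row, tf_starts, cfg.w)
    Z_tgt = _standardized_windows(target_row, all_tgt_starts, cfg.w)
    pos = {s: i for i, s in enumerate(all_tgt_starts)}
    M = np.empty((cfg.p, cfg.q))
    for k in range(cfg.p):
        idx = [pos[tf_starts[k] + off] for off in offsets]
        M[k] = Z_tgt[idx] @ Z_tf[k]
    np.clip(M, -1.0, 1.0, out=M)
    return DelayCorrelationMatrix(tf_id=tf_id, target_id=target_id, values=M)


def plot_delay_heatmap(M: DelayCorrelationMatrix, path: str) -> None:
    """Write a heatmap of M (rows = TF windows, cols = delays), scale [-1, 1]."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(M.values, cmap="RdBu_r", vmin=-1.0, vmax=1.0, aspect="auto")
    ax.set_xlabel("delay offset index l")
    ax.set_ylabel("TF window index k")
    ax.set_title(f"{M.tf_id} → {M.target_id}")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
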