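"""Metric multidimensional scaling of a network distance matrix.

Uses SMACOF stress majorization (Guttman transform) with several random
restarts under a single master seed, keeping the lowest-stress solution.
Raw stress is reported: sum over unordered pairs of squared differences
between embedded and target distances. The per-iteration stress trace of
the winning restart is retained; majorization guarantees it is
non-increasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import matplotlib
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .correlation_distance import DistanceMatrix
from .errors import ValidationError

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

logger = logging.getLogger("dgcd")

__all__ = ["EmbeddingResult", "embed_mds", "plot_embedding"]


@dataclass
class EmbeddingResult:
    network_ids: tuple[str, ...]
    coordinates: np.ndarray  # (n, dims)
    stress: float
    seed: int
    stress_trace: np.ndarray  # stress after each majorization step, best restart
    n_iter: int

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"dim{k+1}" for k in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "network_id", list(self.network_ids))
        return df

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")
        return path


def _raw_stress(X: np.ndarray, dvec: np.ndarray) -> float:
    return float(((pdist(X) - dvec) ** 2).sum())


def _smacof_single(
    D: np.ndarray,
    dims: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, np.ndarray]:
    """One SMACOF run from a random start; returns (coords, stress, trace)."""
    n = D.shape[0]
    dvec = squareform(D, checks=False)
    scale = dvec.mean() if dvec.size and dvec.mean() > 0 else 1.0
    X = rng.normal(scale=scale, size=(n, dims))
    trace = [_raw_stress(X, dvec)]
    for _ in range(max_iter):
        dis = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dis > 0, D / dis, 0.0)
        B = -ratio
        B[np.arange(n), np.arange(n)] += ratio.sum(axis=1)
        X = (B @ X) / n
        stress = _raw_stress(X, dvec)
        prev = trace[-1]
        trace.append(stress)
        if prev - stress < tol * max(prev, np.finfo(float).tiny):
            break
    return X, trace[-1], np.asarray(trace)


def embed_mds(
    d: DistanceMatrix,
    dims: int = 2,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> EmbeddingResult:
    """Embed a distance matrix into ``dims`` dimensions by metric MDS.

    Runs ``n_init`` SMACOF restarts seeded deterministically from ``seed``
    and keeps the lowest-stress configuration. ``tol`` is the relative
    stress-change convergence threshold.
    """
    if dims < 1:
        raise ValidationError(f"dims must be >= 1, got {dims}")
    D = np.asarray(d.values, dtype=float)
    if np.isnan(D).any():
        raise ValidationError("distance matrix contains NaN")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, np.ndarray] | None = None
    for _ in range(max(1, n_init)):
        child = np.random.default_rng(rng.integers(2**31))
        X, stress, trace = _smacof_single(D, dims, child, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, trace)
    X, stress, trace = best
    X = X - X.mean(axis=0)  # center for reproducible coordinates
    logger.info(
        "MDS: n=%d dims=%d stress=%.6g iterations=%d",
        len(d.network_ids),
        dims,
        stress,
        len(trace) - 1,
    )
    return EmbeddingResult(
        network_ids=d.network_ids,
        coordinates=X,
        stress=stress,
        seed=seed,
        stress_trace=trace,
        n_iter=len(trace) - 1,
    )


def plot_embedding(
    e: EmbeddingResult,
    labels: Mapping[str, str] | None = None,
    out_png: str | Path | None = None,
    out_svg: str | Path | None = None,
    focal_group: str | None = None,
    title: str | None = None,
) -> list[Path]:
    """Scatter the 2D embedding, one color per group label.

    The ``focal_group`` (e.g. the species-interaction networks) is drawn
    with triangle markers; ids absent from ``labels`` fall into an "other"
    group with a warning. Output bytes are deterministic for a fixed
    embedding and style (SVG metadata dates are suppressed).
    """
    labels = labels or {}
    groups: dict[str, list[int]] = {}
    for i, net in enumerate(e.network_ids):
        lab = labels.get(net)
        if lab is None:
            if labels:
                logger.warning("network %s has no group label; plotted as 'other'", net)
            lab = "other"
        groups.setdefault(lab, []).append(i)

    plt.rcParams["svg.hashsalt"] = "dgcd"
    fig, ax = plt.subplots(figsize=(7, 6))
    cmap = plt.get_cmap("tab10")
    for k, lab in enumerate(sorted(groups)):
        idx = groups[lab]
        marker = "^" if lab == focal_group else "o"
        color = "0.6" if lab == "other" and labels else cmap(k % 10)
        ax.scatter(
            e.coordinates[idx, 0],
            e.coordinates[idx, 1],
            s=28,
            marker=marker,
            color=color,
            label=lab,
            alpha=0.85,
            linewidths=0,
        )
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.set_title(title or f"Metric MDS of pairwise DGCD (stress {e.stress:.3g})")
    if groups and (labels or len(groups) > 1):
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    written: list[Path] = []
    if out_png is not None:
        out_png = Path(out_png)
        fig.savefig(out_png, dpi=150)
        written.append(out_png)
    if out_svg is not None:
        out_svg = Path(out_svg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fig.savefig(out_svg, metadata={"Date": None})
        written.append(out_svg)
    plt.close(fig)
    return written
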