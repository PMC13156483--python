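"""Procrustes superimposition and shape PCA, from scratch.

Ordinary Procrustes analysis (OPA) superimposes one configuration on another
by translation, uniform scaling, and a proper rotation (reflections are never
part of the optimal transform; mirroring is always explicit via
:func:`mirror_outline`). Generalized Procrustes analysis (GPA) iterates OPA
rotations against a running consensus until the total Procrustes objective
stops decreasing, leaving pure shape variation in the aligned coordinates.

The API follows the fitted-model idiom: ``GeneralizedProcrustes(configs).fit()``
returns a :class:`ProcrustesResult`, and ``ShapePCA(fit_result).fit()`` returns
a :class:`ShapeModel` whose retained axes are those explaining more than the
retention threshold (default 10%) of shape variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import LandmarkConfiguration


def mirror_outline(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a 2D outline across the vertical axis (negate x); an involution."""
    if config.dimension != 2:
        raise ValueError("mirror_outline is defined for 2D outlines only")
    out = config.copy()
    out.points = out.points * np.array([-1.0, 1.0])
    out.side = {"left": "right", "right": "left"}.get(out.side, out.side)
    return out


def _center_scale(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered * centered)))
    if cs == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return centered, cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||source @ R - target||_F."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    sign = np.ones(h.shape[0])
    sign[-1] = d
    return (u * sign) @ vt


def ordinary_procrustes(a: LandmarkConfiguration | np.ndarray,
                        b: LandmarkConfiguration | np.ndarray
                        ) -> tuple[np.ndarray, float]:
    """Superimpose B on A by translation, scaling to A's centroid size, and rotation.

    Returns ``(aligned_b, distance)`` where ``aligned_b`` lives in A's frame
    (A's centroid restored) and ``distance`` is the root summed squared
    coordinate difference after superimposition.
    """
    pa = a.points if isinstance(a, LandmarkConfiguration) else np.asarray(a, float)
    pb = b.points if isinstance(b, LandmarkConfiguration) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ValueError(f"configuration shapes differ: {pa.shape} vs {pb.shape}")
    ca, csa = _center_scale(pa)
    cb, csb = _center_scale(pb)
    scaled_b = cb * (csa / csb)
    rot = _optimal_rotation(scaled_b, ca)
    aligned = scaled_b @ rot
    distance = float(np.sqrt(np.sum((aligned - ca) ** 2)))
    return aligned + pa.mean(axis=0), distance


@dataclass
class ProcrustesResult:
    """GPA output: unit-size aligned coordinates, consensus, and the size vector."""

    aligned: np.ndarray          # (n, k, d), each configuration at unit centroid size
    consensus: np.ndarray        # (k, d), unit centroid size, centroid at origin
    centroid_sizes: np.ndarray   # (n,), pre-scaling sizes in original units
    specimen_ids: list[str]
    n_iterations: int
    objective_trace: list[float]
    converged: bool

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def shape_variance(self) -> float:
        """Total Procrustes variance: mean squared deviation from the consensus."""
        dev = self.aligned - self.consensus
        return float(np.sum(dev * dev) / self.aligned.shape[0])

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, k*d)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


class GeneralizedProcrustes:
    """Iterative GPA over a set of same-scheme configurations.

    Each configuration is centered and scaled to unit centroid size; rotations
    against the running consensus are re-estimated until the summed squared
    deviation from the consensus changes by less than ``tol`` (default 1e-10)
    or ``max_iter`` iterations.
    """

    def __init__(self, configs: Sequence[LandmarkConfiguration] | np.ndarray,
                 *, tol: float = 1e-10, max_iter: int = 200):
        if isinstance(configs, np.ndarray):
            pts = np.asarray(configs, float)
            ids = [f"c{i}" for i in range(pts.shape[0])]
        else:
            if len(configs) < 2:
                raise ValueError("GPA needs at least two configurations")
            shapes = {c.points.shape for c in configs}
            if len(shapes) != 1:
                raise ValueError(f"configurations disagree on landmark count/dimension: {shapes}")
            pts = np.stack([c.points for c in configs])
            ids = [c.specimen_id for c in configs]
        if pts.shape[0] < 2:
            raise ValueError("GPA needs at least two configurations")
        self._points = pts
        self._ids = ids
        self.tol = tol
        self.max_iter = max_iter

    def fit(self) -> ProcrustesResult:
        n = self._points.shape[0]
        sizes = np.empty(n)
        unit = np.empty_like(self._points)
        for i in range(n):
            centered, cs = _center_scale(self._points[i])
            sizes[i] = cs
            unit[i] = centered / cs
        consensus = unit[0].copy()
        trace: list[float] = []
        converged = False
        iterations = 0
        for iterations in range(1, self.max_iter + 1):
            for i in range(n):
                unit[i] = unit[i] @ _optimal_rotation(unit[i], consensus)
            consensus = unit.mean(axis=0)
            consensus -= consensus.mean(axis=0)
            norm = np.sqrt(np.sum(consensus * consensus))
            if norm == 0:
                raise ValueError("degenerate consensus: configurations cancel out")
            consensus /= norm
            objective = float(np.sum((unit - consensus) ** 2))
            trace.append(objective)
            if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < self.tol:
                converged = True
                break
        if not converged and len(trace) >= 1 and trace[-1] < self.tol:
            converged = True  # e.g. identical configurations: objective already ~0
        return ProcrustesResult(aligned=unit, consensus=consensus,
                                centroid_sizes=sizes, specimen_ids=list(self._ids),
                                n_iterations=iterations, objective_trace=trace,
                                converged=converged)


@dataclass
class ShapeModel:
    """Principal components of Procrustes-aligned shape variation."""

    components: np.ndarray        # (n_axes, k*d), orthonormal rows
    variance_pct: np.ndarray      # (n_axes,), sums to 100
    scores: np.ndarray            # (n, n_axes)
    mean_flat: np.ndarray         # (k*d,)
    retained: np.ndarray          # indices of axes with variance share > threshold
    retention_threshold: float
    specimen_ids: list[str]

    @property
    def n_axes(self) -> int:
        return self.components.shape[0]

    def retained_scores(self) -> np.ndarray:
        return self.scores[:, self.retained]

    def back_project(self, scores: np.ndarray | None = None) -> np.ndarray:
        """Reconstruct flattened aligned coordinates from (all-axis) scores."""
        s = self.scores if scores is None else scores
        return self.mean_flat + s @ self.components

    def plot_scores(self, axes=(0, 1), groups=None, ax=None):
        """Scatter of two score axes, optionally colored by group labels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        i, j = axes
        if groups is None:
            ax.scatter(self.scores[:, i], self.scores[:, j])
        else:
            groups = np.asarray(groups)
            for g in np.unique(groups):
                mask = groups == g
                ax.scatter(self.scores[mask, i], self.scores[mask, j], label=str(g))
            ax.legend()
        ax.set_xlabel(f"PC{i + 1} ({self.variance_pct[i]:.1f}%)")
        ax.set_ylabel(f"PC{j + 1} ({self.variance_pct[j]:.1f}%)")
        ax.axhline(0, lw=0.5, color="0.7")
        ax.axvline(0, lw=0.5, color="0.7")
        return ax


class ShapePCA:
    """PCA of the aligned-coordinate covariance about the consensus.

    Axes explaining more than ``retention_threshold`` (fraction, default 0.10)
    of the total shape variance form the retained set used downstream.
    """

    def __init__(self, fit_result: ProcrustesResult, *, retention_threshold: float = 0.10):
        self._fit = fit_result
        self.retention_threshold = retention_threshold

    def fit(self) -> ShapeModel:
        flat = self._fit.flat()
        mean = flat.mean(axis=0)
        centered = flat - mean
        n = centered.shape[0]
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        variances = s**2 / max(n - 1, 1)
        total = variances.sum()
        keep = s > max(s.max(initial=0.0), 1.0) * 1e-12  # drop null axes
        if total == 0 or not keep.any():
            return ShapeModel(components=np.zeros((0, flat.shape[1])),
                              variance_pct=np.zeros(0), scores=np.zeros((n, 0)),
                              mean_flat=mean, retained=np.zeros(0, dtype=int),
                              retention_threshold=self.retention_threshold,
                              specimen_ids=list(self._fit.specimen_ids))
        comps = vt[keep]
        variances = variances[keep]
        scores = centered @ comps.T
        pct = variances / total * 100.0
        retained = np.flatnonzero(pct > self.retention_threshold * 100.0)
        return ShapeModel(components=comps, variance_pct=pct, scores=scores,
                          mean_flat=mean, retained=retained,
                          retention_threshold=self.retention_threshold,
                          specimen_ids=list(self._fit.specimen_ids))
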