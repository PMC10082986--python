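"""Synthetic "large p, small n" expression data with planted nonlinear
class structure.

Each class occupies a disjoint interval of a 1-D curve parameter t; the
informative genes are smooth monotone lifts of t (random-frequency sine
arcs or cubic arcs) plus Gaussian noise, so classes are separable along the
curve; the remaining genes are standard Gaussian noise independent of the
labels.  Gene order is randomly permuted and the ground-truth informative
indices are returned alongside the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset

_GAP = 0.3          # parameter gap between consecutive class intervals
_AMPLITUDE = 1.5    # scale of the informative lifts


@dataclass
class SimSpec:
    n: int = 60
    p: int = 300
    n_classes: int = 2
    class_proportions: tuple[float, ...] | None = None
    m_info: int = 10
    manifold: str = "swiss_roll_arcs"
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_info >= self.p:
            raise ValueError("m_info must be smaller than p")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_proportions is None:
            self.class_proportions = tuple(
                [1.0 / self.n_classes] * self.n_classes
            )
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.manifold not in ("swiss_roll_arcs", "s_curve_arcs", "gaussian_linear"):
            raise ValueError(f"unknown manifold type {self.manifold!r}")


def _class_sizes(spec: SimSpec) -> list[int]:
    sizes = [int(np.floor(q * spec.n)) for q in spec.class_proportions]
    while sum(sizes) < spec.n:
        sizes[int(np.argmax(np.asarray(spec.class_proportions)
                            - np.asarray(sizes) / spec.n))] += 1
    if min(sizes) < 2:
        raise ValueError(
            f"n={spec.n} too small for {spec.n_classes} classes "
            "(every class needs >= 2 samples)"
        )
    return sizes


def generate(spec: SimSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Generate a dataset and the informative-gene ground truth indices."""
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec)
    labels = np.concatenate(
        [np.full(s, c + 1, dtype=int) for c, s in enumerate(sizes)]
    )
    n, C = spec.n, spec.n_classes

    # curve parameter: class c on [c-1 + gap/2, c - gap/2]
    t = np.empty(n)
    pos = 0
    for c, s in enumerate(sizes):
        t[pos : pos + s] = rng.uniform(c + _GAP / 2, c + 1 - _GAP / 2, size=s)
        pos += s

    info = np.empty((n, spec.m_info))
    if spec.manifold == "gaussian_linear":
        # class-mean shifts on each informative axis, no curvature
        directions = rng.choice([-1.0, 1.0], size=spec.m_info)
        means = (labels[:, None] - (C + 1) / 2.0) * 2.0 * directions
        info = means + rng.normal(0.0, spec.noise_sd, size=(n, spec.m_info))
    else:
        T = float(C)
        for j in range(spec.m_info):
            sign = rng.choice([-1.0, 1.0])
            if spec.manifold == "swiss_roll_arcs":
                # monotone sine arc: w*T <= pi and phase keeps the argument
                # inside [-pi/2, pi/2]
                w = rng.uniform(0.5, 1.0) * np.pi / T
                phi = rng.uniform(-np.pi / 2, np.pi / 2 - w * T)
                f = np.sin(w * t + phi)
            else:  # s_curve_arcs: monotone cubic
                a = rng.uniform(0.3, 1.0)
                b = rng.uniform(0.3, 1.0)
                u = 2.0 * t / T - 1.0
                f = (a * u + b * u**3) / (a + b)
            info[:, j] = sign * _AMPLITUDE * f
        info += rng.normal(0.0, spec.noise_sd, size=(n, spec.m_info))

    noise = rng.normal(size=(n, spec.p - spec.m_info))
    matrix = np.concatenate([info, noise], axis=1)
    perm = rng.permutation(spec.p)
    matrix = matrix[:, perm]
    truth = np.sort(np.argsort(perm)[: spec.m_info])

    gene_ids = [f"g{j + 1:04d}" for j in range(spec.p)]
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    order = rng.permutation(n)  # shuffle samples so classes are interleaved
    ds = ExpressionDataset(
        matrix=matrix[order],
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels[order],
    )
    return ds, truth


def swiss_roll_points(n: int = 200, seed: int = 0, noise: float = 0.0) -> np.ndarray:
    """Classic 3-D swiss-roll point cloud for manifold-geometry tests."""
    rng = np.random.default_rng(seed)
    t = 1.5 * np.pi * (1.0 + 2.0 * rng.random(n))
    height = 21.0 * rng.random(n)
    X = np.column_stack([t * np.cos(t), height, t * np.sin(t)])
    if noise:
        X += rng.normal(0.0, noise, size=X.shape)
    return X


def fixture_suite() -> dict[str, object]:
    """Deterministic small datasets shared across the test modules.

    - ``collinear4``: 1-D points (0, 1, 3, 6).
    - ``twoclusters``: 15+15 points in 2-D, cluster gap 50x the
      within-cluster spread (disconnects the k-NN graph at small k).
    - ``swissroll200``: 200-point swiss-roll cloud.
    - ``separable``: linearly separable two-class expression set
      (gaussian_linear, zero informative noise).
    - ``planted300``: the n=60, p=300, 10-informative benchmark dataset.
    """
    rng = np.random.default_rng(42)
    cluster_a = rng.normal(0.0, 1.0, size=(15, 2))
    cluster_b = rng.normal(0.0, 1.0, size=(15, 2)) + np.array([50.0, 0.0])
    suite: dict[str, object] = {
        "collinear4": np.array([[0.0], [1.0], [3.0], [6.0]]),
        "twoclusters": np.vstack([cluster_a, cluster_b]),
        "swissroll200": swiss_roll_points(200, seed=7),
    }
    suite["separable"] = generate(
        SimSpec(n=30, p=40, n_classes=2, m_info=5,
                manifold="gaussian_linear", noise_sd=0.0, seed=3)
    )
    suite["planted300"] = generate(
        SimSpec(n=60, p=300, n_classes=2, m_info=10,
                manifold="swiss_roll_arcs", noise_sd=0.1, seed=1)
    )
    return suite
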