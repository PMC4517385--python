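"""Genotype-frequency diagnostics: per-gene heterozygosity and the
empirical Hardy-Weinberg density on the de Finetti simplex.

Genotype frequencies at a diallelic locus are a point (r, h, v) on the
2-simplex (fractions hom-ref, het, hom-var).  Under random mating the
point lies on the Hardy-Weinberg parabola h = 2p(1-p) with p = r + h/2.
The empirical density is the average over qualifying loci of the
Dirichlet(1+n_r, 1+n_h, 1+n_v) posterior from the observed ingroup calls
under a uniform prior; its log is examined along each line from the
h-vertex to the r-v edge, every such line crossing the HW curve once.
Genes whose SNPs are heterozygous in almost every individual are the
signature of collapsed paralogs in the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .variants import HET, HOM_REF, HOM_VAR, UNCALLED, SnpLocus

__all__ = [
    "mean_observed_het",
    "hwe_locus_filter",
    "empirical_hw_density",
    "ridge_vs_hw_curve",
    "SimplexDensityGrid",
    "plot_definetti",
]

# 2D embedding of the simplex: equilateral triangle with the r vertex at
# the origin, v at (1, 0) and h at (1/2, sqrt(3)/2).
_VERT = np.array([[0.0, 0.0], [0.5, np.sqrt(3.0) / 2.0], [1.0, 0.0]])  # r, h, v


def barycentric_to_xy(points: np.ndarray) -> np.ndarray:
    """(N,3) barycentric (r,h,v) -> (N,2) Cartesian coordinates."""
    return np.asarray(points) @ _VERT


def mean_observed_het(
    loci: Sequence[SnpLocus],
    ingroup_indices: Sequence[int],
    outgroup_index: int,
    min_snps: int = 6,
    min_ingroup_called: int = 10,
) -> float | None:
    """Mean per-SNP observed heterozygosity for one gene.

    A SNP qualifies when it is genotyped in at least
    ``min_ingroup_called`` ingroup individuals and in the outgroup; the
    hybrid (or any individual not listed) is ignored.  Per SNP the value
    is het calls / called individuals over ingroup + outgroup.  Returns
    None when fewer than ``min_snps`` SNPs qualify.
    """
    ingroup = list(ingroup_indices)
    used = ingroup + [outgroup_index]
    values = []
    for locus in loci:
        gt_in = locus.gt[ingroup]
        if int(np.sum(gt_in != UNCALLED)) < min_ingroup_called:
            continue
        if int(locus.gt[outgroup_index]) == UNCALLED:
            continue
        gt = locus.gt[used]
        called = gt[gt != UNCALLED]
        values.append(float(np.sum(called == HET)) / len(called))
    if len(values) < min_snps:
        return None
    return float(np.mean(values))


def genotype_counts(locus: SnpLocus, ingroup_indices: Sequence[int]) -> tuple[int, int, int]:
    gt = locus.gt[list(ingroup_indices)]
    return (
        int(np.sum(gt == HOM_REF)),
        int(np.sum(gt == HET)),
        int(np.sum(gt == HOM_VAR)),
    )


def hwe_locus_filter(
    loci: Iterable[SnpLocus],
    ingroup_indices: Sequence[int],
    min_called: int = 11,
) -> list[SnpLocus]:
    """Loci usable for the HW density: >= min_called ingroup genotypes and
    at least one individual in each genotype category."""
    out = []
    for locus in loci:
        nr, nh, nv = genotype_counts(locus, ingroup_indices)
        if nr + nh + nv >= min_called and nr >= 1 and nh >= 1 and nv >= 1:
            out.append(locus)
    return out


def _simplex_lattice(resolution: int) -> np.ndarray:
    """All (r,h,v) with components i/(resolution-1) summing to 1."""
    m = resolution - 1
    pts = []
    for i in range(m + 1):
        for j in range(m + 1 - i):
            pts.append((i / m, j / m, (m - i - j) / m))
    return np.array(pts)


@dataclass
class SimplexDensityGrid:
    """Mean posterior density over loci, tabulated on a barycentric grid.

    ``alphas``/``weights`` retain the mixture of Dirichlet posteriors
    (aggregated over loci sharing a genotype-count triple) so the density
    can be evaluated at arbitrary simplex points, e.g. along ridge lines.
    """

    points: np.ndarray  # (G, 3) barycentric
    log_density: np.ndarray  # (G,) natural log of the mean density
    alphas: np.ndarray  # (U, 3) unique Dirichlet parameters
    weights: np.ndarray  # (U,) locus fractions, sum to 1
    resolution: int

    def evaluate_log(self, points: np.ndarray) -> np.ndarray:
        """ln mean Dirichlet density at (N,3) barycentric points."""
        pts = np.asarray(points, dtype=float)
        a = self.alphas  # (U, 3)
        logc = gammaln(a.sum(axis=1)) - gammaln(a).sum(axis=1)  # (U,)
        with np.errstate(divide="ignore", invalid="ignore"):
            logx = np.log(pts)  # (N, 3); -inf at 0
        expo = a - 1.0  # (U, 3)
        # terms[n, u] = sum_k expo[u,k] * logx[n,k], with 0 * -inf := 0
        terms = np.zeros((pts.shape[0], a.shape[0]))
        for k in range(3):
            with np.errstate(invalid="ignore"):
                contrib = np.outer(logx[:, k], expo[:, k])
            contrib[:, expo[:, k] == 0.0] = 0.0  # 0 * log(0) := 0
            terms += contrib
        logpdf = terms + logc[None, :]
        return logsumexp(logpdf, axis=1, b=self.weights[None, :])


def empirical_hw_density(
    loci: Sequence[SnpLocus],
    ingroup_indices: Sequence[int],
    resolution: int = 201,
) -> SimplexDensityGrid:
    """Average Dirichlet posterior density over qualifying loci.

    Each locus contributes Dirichlet(1+n_r, 1+n_h, 1+n_v) (uniform prior
    plus observed ingroup genotype counts); the grid stores the natural
    log of the locus-averaged density.
    """
    if not loci:
        raise ValueError("need at least one qualifying locus")
    triples: dict[tuple[int, int, int], int] = {}
    for locus in loci:
        key = genotype_counts(locus, ingroup_indices)
        triples[key] = triples.get(key, 0) + 1
    alphas = np.array([[1 + r, 1 + h, 1 + v] for (r, h, v) in triples], dtype=float)
    weights = np.array(list(triples.values()), dtype=float)
    weights /= weights.sum()
    points = _simplex_lattice(resolution)
    grid = SimplexDensityGrid(
        points=points,
        log_density=np.empty(len(points)),
        alphas=alphas,
        weights=weights,
        resolution=resolution,
    )
    grid.log_density = grid.evaluate_log(points)
    return grid


def hw_curve_points(n: int = 2001) -> np.ndarray:
    """Points on the Hardy-Weinberg parabola in barycentric coordinates."""
    p = np.linspace(0.0, 1.0, n)
    return np.stack([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)], axis=1)


def ridge_vs_hw_curve(
    grid: SimplexDensityGrid,
    n_lines: int | None = None,
    n_steps: int | None = None,
) -> list[tuple[np.ndarray, float]]:
    """Density argmax along each h=1 -> h=0 line, and its distance to HW.

    Lines run from the h vertex (0,1,0) to points (r0, 0, 1-r0) on the
    r-v edge.  For each line the density is evaluated at ``n_steps``
    points, and the Euclidean distance (in the equilateral embedding)
    from the argmax to the Hardy-Weinberg curve is reported.
    """
    n_lines = n_lines or grid.resolution
    n_steps = n_steps or grid.resolution
    curve_xy = barycentric_to_xy(hw_curve_points())
    out = []
    t = np.linspace(0.0, 1.0, n_steps)[1:]  # skip the shared h=1 vertex
    for r0 in np.linspace(0.0, 1.0, n_lines):
        pts = np.stack([t * r0, 1.0 - t, t * (1.0 - r0)], axis=1)
        logd = grid.evaluate_log(pts)
        best = pts[int(np.argmax(logd))]
        xy = barycentric_to_xy(best[None, :])[0]
        dist = float(np.min(np.hypot(curve_xy[:, 0] - xy[0], curve_xy[:, 1] - xy[1])))
        out.append((best, dist))
    return out


def plot_definetti(grid: SimplexDensityGrid, path: str) -> None:
    """Write a de Finetti diagram (log density heat map) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = barycentric_to_xy(grid.points)
    fig, ax = plt.subplots(figsize=(6, 5.5))
    sc = ax.tripcolor(xy[:, 0], xy[:, 1], grid.log_density, shading="gouraud")
    curve = barycentric_to_xy(hw_curve_points(400))
    ax.plot(curve[:, 0], curve[:, 1], "w--", lw=1, label="Hardy-Weinberg")
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.legend(loc="upper right")
    fig.colorbar(sc, ax=ax, label="ln mean posterior density")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
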