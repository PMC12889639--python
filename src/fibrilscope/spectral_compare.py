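"""ZNCC scoring of spectrum pairs, score matrices and hierarchical clustering.

Two spectra on the same grid are treated as images and compared by
zero-normalized cross correlation,

    ZNCC(a, b) = (1/N) * sum_i [(a_i - mu_a)/sigma_a] * [(b_i - mu_b)/sigma_b],

i.e. the Pearson correlation of the flattened intensities with population
standard deviations.  The value lies in [-1, 1]; an autocorrelation scores
exactly 1, and scores below 0.50 are conventionally not considered to
indicate structural similarity.  Nonnegative spectral images essentially
never anticorrelate, so the raw signed score is reported by default with an
optional rectification mapping negatives to 0.

Pairwise matrices feed agglomerative (average-linkage) clustering on the
distance d = 1 - score, with flat clusters cut at d = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import squareform

from fibrilscope.spectra_io import Axis, ProtomerEnsemble, ResonanceList, Spectrum2D
from fibrilscope.spectrum_sim import ExperimentSpec, enumerate_cross_peaks, render_spectrum

#: pairwise scores below this are not considered structurally similar
SIMILARITY_THRESHOLD = 0.50


def zncc(a: Spectrum2D, b: Spectrum2D, rectify: bool = False) -> float:
    """Zero-normalized cross correlation of two same-grid spectra.

    Invariant under separate affine intensity transforms (positive scale) of
    either input.  Raises if the grids differ (resample first) or if either
    image has zero intensity variance.
    """
    if a.shape != b.shape:
        raise ValueError(
            f"spectra have different grid shapes {a.shape} vs {b.shape}; "
            "use resample_to_common_grid first"
        )
    x = a.intensity.ravel()
    y = b.intensity.ravel()
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("ZNCC undefined: zero intensity variance in at least one spectrum")
    score = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    score = max(-1.0, min(1.0, score))
    if rectify:
        score = max(0.0, score)
    return score


def _resample_axis(ax_a: Axis, ax_b: Axis) -> Axis:
    lo_a, hi_a = ax_a.window()
    lo_b, hi_b = ax_b.window()
    lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
    if lo >= hi:
        raise ValueError(
            f"ppm windows do not overlap: [{lo_a}, {hi_a}] vs [{lo_b}, {hi_b}]"
        )
    step = -min(abs(ax_a.step_ppm), abs(ax_b.step_ppm))  # display convention
    n = int(np.floor((hi - lo) / abs(step))) + 1
    if n < 2:
        raise ValueError("overlap window narrower than one grid step")
    return Axis(ax_a.nucleus, hi, step, n)


def _interpolate(spec: Spectrum2D, ax1: Axis, ax2: Axis) -> Spectrum2D:
    p1 = spec.axis1.ppm()
    p2 = spec.axis2.ppm()
    z = spec.intensity
    if p1[0] > p1[-1]:
        p1, z = p1[::-1], z[::-1, :]
    if p2[0] > p2[-1]:
        p2, z = p2[::-1], z[:, ::-1]
    interp = RegularGridInterpolator((p1, p2), z, method="linear",
                                     bounds_error=False, fill_value=None)
    q1 = np.clip(ax1.ppm(), p1[0], p1[-1])
    q2 = np.clip(ax2.ppm(), p2[0], p2[-1])
    g1, g2 = np.meshgrid(q1, q2, indexing="ij")
    vals = interp(np.stack([g1.ravel(), g2.ravel()], axis=1)).reshape(ax1.n, ax2.n)
    return Spectrum2D(ax1, ax2, vals, id=spec.id)


def resample_to_common_grid(a: Spectrum2D, b: Spectrum2D) -> tuple[Spectrum2D, Spectrum2D]:
    """Bilinearly resample two spectra onto the intersection of their windows.

    Identical grids are returned unchanged.  The shared grid uses the finer
    of the two steps per axis, in display convention (ppm decreasing).
    Intensities are not renormalized (ZNCC is affine-invariant anyway).
    """
    if a.axis1 == b.axis1 and a.axis2 == b.axis2:
        return a, b
    ax1 = _resample_axis(a.axis1, b.axis1)
    ax2 = _resample_axis(a.axis2, b.axis2)
    return _interpolate(a, ax1, ax2), _interpolate(b, ax1, ax2)


@dataclass
class ZNCCMatrix:
    """Symmetric pairwise ZNCC score matrix with unit diagonal."""

    labels: list[str]
    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.labels), len(self.labels)):
            raise ValueError("score matrix shape does not match labels")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("score matrix must be symmetric")
        if not np.allclose(np.diag(s), 1.0, atol=1e-9):
            raise ValueError("score matrix must have unit diagonal")
        self.scores = s

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.scores):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def pairwise_zncc(spectra: list[Spectrum2D], rectify: bool = False) -> ZNCCMatrix:
    """Full symmetric ZNCC matrix over a list of labelled spectra.

    Off-diagonal entries are computed after pairwise resampling to the
    common grid of each pair.  ZNCC errors are re-raised naming the
    offending pair.
    """
    if len(spectra) < 2:
        raise ValueError("pairwise ZNCC needs at least 2 spectra")
    labels = [s.id if s.id is not None else f"spectrum{k}" for k, s in enumerate(spectra)]
    n = len(spectra)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                a, b = resample_to_common_grid(spectra[i], spectra[j])
                m[i, j] = m[j, i] = zncc(a, b, rectify=rectify)
            except ValueError as exc:
                raise ValueError(f"ZNCC failed for pair ({labels[i]}, {labels[j]}): {exc}") from exc
    return ZNCCMatrix(labels, m)


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray | None  # scipy linkage matrix; None for a single leaf
    flat: dict[str, int]  # label -> flat cluster id (1-based)
    newick: str

    @property
    def n_clusters(self) -> int:
        return len(set(self.flat.values()))


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6f},{right}:{dr:.6f})"


def cluster_scores(m: ZNCCMatrix, cut: float = 0.5,
                   linkage_method: str = "average") -> ClusterResult:
    """Hierarchical clustering of a ZNCC matrix on distance d = 1 - score.

    Average linkage (UPGMA) by default; flat clusters cut at d = 0.5, the
    complement of the 0.50 similarity rule.  The dendrogram serializes to
    Newick text.
    """
    if np.any(~np.isfinite(m.scores)):
        raise ValueError("score matrix contains NaN/inf")
    if len(m.labels) == 1:
        return ClusterResult(m.labels, None, {m.labels[0]: 1}, f"{m.labels[0]};")
    dist = np.clip(1.0 - m.scores, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method=linkage_method)
    flat_ids = hierarchy.fcluster(link, t=cut, criterion="distance")
    tree = hierarchy.to_tree(link)
    newick = _tree_to_newick(tree, m.labels) + ";"
    return ClusterResult(m.labels, link, dict(zip(m.labels, map(int, flat_ids))), newick)


def plot_heatmap(m: ZNCCMatrix, path, linkage_method: str = "average") -> None:
    """Write a dendrogram-ordered ZNCC heatmap figure (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    result = cluster_scores(m, linkage_method=linkage_method)
    if result.linkage is not None:
        order = hierarchy.leaves_list(result.linkage)
    else:
        order = np.array([0])
    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(6, 8), gridspec_kw={"height_ratios": [1, 4]}
    )
    if result.linkage is not None:
        hierarchy.dendrogram(result.linkage, labels=m.labels, ax=ax_d, no_labels=True)
    ax_d.set_ylabel("1 - ZNCC")
    sub = m.scores[np.ix_(order, order)]
    im = ax_h.imshow(sub, vmin=-1, vmax=1, cmap="RdBu_r")
    ticks = np.arange(len(order))
    ax_h.set_xticks(ticks, [m.labels[i] for i in order], rotation=90)
    ax_h.set_yticks(ticks, [m.labels[i] for i in order])
    fig.colorbar(im, ax=ax_h, label="ZNCC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class ValidationEntry:
    kind: str
    mixing_ms: int | None
    score: float | None
    similar: bool | None
    error: str | None = None


def validate_structure(ens: ProtomerEnsemble, res: ResonanceList,
                       experimental: list[Spectrum2D],
                       exps: list[ExperimentSpec],
                       threshold: float = SIMILARITY_THRESHOLD) -> list[ValidationEntry]:
    """Score a structural model against experimental spectra.

    For each experiment spec, simulates the spectrum from the model and the
    resonance list, resamples simulated and experimental images to a common
    grid, and reports the ZNCC together with the 0.50 similarity rule.
    Per-experiment failures (e.g. empty grid overlap) are reported in the
    entry; the remaining experiments are still computed.
    """
    if len(experimental) != len(exps):
        raise ValueError("one experimental spectrum per experiment spec")
    report = []
    for spec_exp, exp in zip(experimental, exps):
        mixing = exp.mixing_ms if exp.kind != "NCA" else None
        try:
            peaks = enumerate_cross_peaks(ens, res, exp)
            simulated = render_spectrum(peaks, exp)
            a, b = resample_to_common_grid(simulated, spec_exp)
            score = zncc(a, b)
            report.append(ValidationEntry(exp.kind, mixing, score, score >= threshold))
        except ValueError as exc:
            report.append(ValidationEntry(exp.kind, mixing, None, None, error=str(exc)))
    return report
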