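"""Two-population discrimination in (vi, v_diff) space.

At a well-chosen drive frequency (6 MHz here), viable cells undergo
positive DEP (slowed across the electrodes, v_diff > 0) and non-viable
cells negative DEP (sped up, v_diff < 0), so the per-cell scatter of
differential versus incoming velocity separates into two clusters.  A
two-component Gaussian mixture fitted by EM identifies them; the component
with the larger mean differential velocity is labelled ``pDEP`` (viable),
the other ``nDEP``.  Probability ellipses are Mahalanobis contours at the
chi-square(2 dof) quantile of the requested probability mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusterResult",
    "Ellipse",
    "fit_two_component_gmm",
    "probability_ellipse",
    "viability_and_size_stats",
]

PDEP, NDEP = "pDEP", "nDEP"


@dataclass(frozen=True)
class Ellipse:
    """Probability ellipse: center, semi-axes (descending), orientation.

    ``orientation`` is the angle (radians) of the major axis from the
    +vi axis.
    """

    center: np.ndarray
    semi_axes: tuple[float, float]
    orientation: float
    level: float

    def contains(self, points: np.ndarray, cov: np.ndarray) -> np.ndarray:
        d = points - self.center
        md2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
        return md2 <= chi2.ppf(self.level, df=2)


@dataclass
class ClusterResult:
    """Two-component GMM fit of (vi, v_diff) points.

    Component order is [pDEP, nDEP] (descending mean v_diff).  ``labels``
    holds per-point hard assignments as strings; ``posteriors`` the
    per-point membership probabilities in the same component order.
    """

    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2, 2): columns (vi, v_diff)
    covariances: np.ndarray  # (2, 2, 2)
    posteriors: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) strings PDEP/NDEP
    log_likelihood: float
    converged: bool
    stability_warning: bool = False

    @property
    def viable_fraction(self) -> float:
        return float(np.mean(self.labels == PDEP))

    def summary(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means_um_s": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "viable_fraction": self.viable_fraction,
            "log_likelihood": self.log_likelihood,
        }


def fit_two_component_gmm(points: np.ndarray, seed: int = 0,
                          n_init: int = 10, tol: float = 1e-8,
                          reg_covar: float = 1e-6) -> ClusterResult:
    """Fit a full-covariance two-component GMM to (vi, v_diff) pairs.

    Best of ``n_init`` seeded EM restarts; converged when the mean
    log-likelihood change drops below ``tol``.  The component with larger
    mean v_diff is labelled pDEP.  A stability diagnostic flags fits whose
    restarts disagree materially on the component weights (a sign the data
    do not support two components).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2): columns vi, v_diff")
    if points.shape[0] < 20:
        raise ValueError("need at least 20 points")

    weight_sets = []
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(max(n_init, 1)):
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             tol=tol, reg_covar=reg_covar, n_init=1,
                             random_state=int(rng.integers(2 ** 31)),
                             max_iter=500)
        gm.fit(points)
        weight_sets.append(np.sort(gm.weights_))
        if best is None or gm.lower_bound_ > best.lower_bound_:
            best = gm
    if not best.converged_:
        warnings.warn("EM did not converge within max_iter")
    # stability diagnostics: restarts disagreeing on weights, or component
    # means closer than 2 pooled-Mahalanobis units (a single blob split in
    # half looks "stable" across restarts but is not a real mixture)
    spread = np.ptp([w[0] for w in weight_sets])
    pooled = best.covariances_.mean(axis=0)
    dmean = best.means_[0] - best.means_[1]
    separation = math.sqrt(float(dmean @ np.linalg.inv(pooled) @ dmean))
    stability_warning = bool(spread > 0.1 or separation < 2.0)

    order = np.argsort(best.means_[:, 1])[::-1]  # descending mean v_diff
    post = best.predict_proba(points)[:, order]
    labels = np.where(post[:, 0] >= 0.5, PDEP, NDEP)
    return ClusterResult(
        weights=best.weights_[order],
        means=best.means_[order],
        covariances=best.covariances_[order],
        posteriors=post,
        labels=labels,
        log_likelihood=float(best.lower_bound_ * points.shape[0]),
        converged=bool(best.converged_),
        stability_warning=stability_warning,
    )


def probability_ellipse(mean: np.ndarray, cov: np.ndarray,
                        level: float) -> Ellipse:
    """Mahalanobis contour containing ``level`` probability mass of a 2-D
    Gaussian component."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending; order descending for (major, minor)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    scale = math.sqrt(chi2.ppf(level, df=2))
    semi = (scale * math.sqrt(max(evals[0], 0.0)),
            scale * math.sqrt(max(evals[1], 0.0)))
    orientation = math.atan2(evecs[1, 0], evecs[0, 0])
    return Ellipse(center=mean, semi_axes=semi, orientation=orientation,
                   level=level)


def viability_and_size_stats(labels: np.ndarray,
                             diameters_um: np.ndarray) -> dict:
    """Viable fraction and per-cluster normal fits of cell diameter.

    The maximum-likelihood normal fit is the sample mean and (population)
    standard deviation per cluster; clusters with no members are flagged.
    """
    labels = np.asarray(labels)
    diameters_um = np.asarray(diameters_um, float)
    if labels.shape != diameters_um.shape:
        raise ValueError("labels and diameters must align")
    out: dict = {"n_total": int(labels.size),
                 "viable_fraction": float(np.mean(labels == PDEP))}
    for name in (PDEP, NDEP):
        d = diameters_um[labels == name]
        if d.size == 0:
            out[name] = {"n": 0, "mean_um": None, "sd_um": None,
                         "flag": "empty"}
        else:
            out[name] = {"n": int(d.size),
                         "mean_um": float(d.mean()),
                         "sd_um": float(d.std())}
    return out


def cluster_velocity_table(vel: pd.DataFrame, seed: int = 0,
                           n_init: int = 10) -> tuple[pd.DataFrame, ClusterResult]:
    """Cluster a velocities table (vi_um_s, vdiff_um_s) and annotate it."""
    ok = vel.dropna(subset=["vi_um_s", "vdiff_um_s"]).copy()
    pts = ok[["vi_um_s", "vdiff_um_s"]].to_numpy()
    res = fit_two_component_gmm(pts, seed=seed, n_init=n_init)
    ok["cluster"] = res.labels
    ok["posterior_pdep"] = res.posteriors[:, 0]
    return ok, res


_COLORS = {PDEP: "tab:blue", NDEP: "tab:red"}


def plot_clusters(clustered: pd.DataFrame, result: ClusterResult, path,
                  levels: tuple[float, float] = (0.75, 0.75)) -> None:
    """Scatter of v_diff vs vi colored by cluster, with probability
    ellipses at the requested mass levels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name in (PDEP, NDEP):
        sub = clustered[clustered["cluster"] == name]
        ax.scatter(sub["vi_um_s"], sub["vdiff_um_s"], s=14,
                   color=_COLORS[name], alpha=0.7,
                   label=f"{name} (n={len(sub)})")
    for k, (name, level) in enumerate(zip((PDEP, NDEP), levels)):
        e = probability_ellipse(result.means[k], result.covariances[k],
                                level)
        ax.add_patch(MplEllipse(e.center, 2 * e.semi_axes[0],
                                2 * e.semi_axes[1],
                                angle=math.degrees(e.orientation),
                                fill=False, color=_COLORS[name], lw=1.5))
    ax.axhline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("incoming velocity vi (um/s)")
    ax.set_ylabel("differential velocity vi - vo (um/s)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_size_histograms(labels, diameters_um, path) -> None:
    """Overlaid per-cluster diameter histograms with the ML normal fits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    labels = np.asarray(labels)
    diameters_um = np.asarray(diameters_um, float)
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(diameters_um.min() - 2, diameters_um.max() + 2, 200)
    for name in (PDEP, NDEP):
        d = diameters_um[labels == name]
        if d.size == 0:
            continue
        ax.hist(d, bins="auto", density=True, alpha=0.4,
                color=_COLORS[name], label=f"{name} (n={d.size})")
        ax.plot(grid, norm.pdf(grid, d.mean(), d.std()),
                color=_COLORS[name], lw=1.5)
    ax.set_xlabel("diameter (um)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
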