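"""Simplified 3D structure inference from a regional contact map.

Contact frequencies are converted to wish distances via an inverse
power law, d_ij = (O/E_ij + eps)^(-alpha_d), and a 3D configuration is
found by weighted metric multidimensional scaling: minimize the stress

    sigma(X) = sum_ij w_ij (||x_i - x_j|| - d_ij)^2,   w_ij = 1 / d_ij^2

with multistart gradient-based optimization (L-BFGS).  This is a
deliberately simple stand-in for population-based conformation
optimizers: it recovers relative geometry (distance ranking, domain
compaction) rather than a literal single-cell structure.

The distance profile from a focus bin supports locus-centric questions
("has this gene's neighborhood decondensed?") with a paired Wilcoxon
comparison across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class Structure3D:
    coords: np.ndarray          # (n, 3), centered at the origin
    stress: float
    alpha_d: float
    stress_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_bins(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d**2).sum(-1))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"bin": np.arange(self.n_bins), "x": self.coords[:, 0],
             "y": self.coords[:, 1], "z": self.coords[:, 2]}
        ).to_csv(path, sep="\t", index=False)

    def to_pdb(self, path) -> None:
        """PDB-like text: one CA pseudo-atom per bin, chained."""
        with open(path, "w") as fh:
            scale = 10.0 / max(np.abs(self.coords).max(), 1e-9)
            for k, (x, y, z) in enumerate(self.coords * scale, start=1):
                fh.write(
                    f"ATOM  {k:5d}  CA  GLY A{k:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("END\n")


def wish_distances(oe: np.ndarray, alpha_d: float = 0.5, eps: float = 0.01) -> np.ndarray:
    """Inverse-power contact-to-distance transform; NaN-safe."""
    oe = np.asarray(oe, dtype=float)
    with np.errstate(invalid="ignore"):
        d = (np.nan_to_num(oe, nan=0.0) + eps) ** (-alpha_d)
    np.fill_diagonal(d, 0.0)
    return d


def _stress_and_grad(x_flat: np.ndarray, D: np.ndarray, W: np.ndarray):
    n = D.shape[0]
    X = x_flat.reshape(n, 3)
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, 1.0)
    resid = dist - D
    np.fill_diagonal(resid, 0.0)
    s = float((W * resid**2).sum())
    coef = 2.0 * W * resid / dist
    np.fill_diagonal(coef, 0.0)
    grad = (coef[:, :, None] * diff).sum(axis=1) - (coef[:, :, None] * (-diff)).sum(axis=1)
    return s, grad.ravel()


def embed_structure(
    oe: np.ndarray,
    alpha_d: float = 0.5,
    eps: float = 0.01,
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 500,
) -> Structure3D:
    """Best-of-restarts stress-minimizing 3D embedding of a region.

    ``oe`` is the region's observed/expected submatrix; every bin must
    have at least one finite off-diagonal contact (connectivity).
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    if n < 3:
        raise ValueError("need at least 3 bins to embed")
    off = ~np.eye(n, dtype=bool)
    finite_per_bin = np.isfinite(oe) & off
    if not finite_per_bin.any():
        raise ValueError("all-missing matrix")
    if (finite_per_bin.sum(axis=1) == 0).any():
        raise ValueError("disconnected region: a bin has no finite contact")

    D = wish_distances(oe, alpha_d, eps)
    W = np.zeros_like(D)
    nz = D > 0
    W[nz] = 1.0 / D[nz] ** 2
    # missing pixels get zero weight
    W[~(np.isfinite(oe) | np.eye(n, dtype=bool))] = 0.0

    rng = np.random.default_rng(seed)
    best = None
    best_trace = None
    for _ in range(max(restarts, 1)):
        x0 = rng.normal(0.0, D[nz].mean() / np.sqrt(n), size=(n, 3)).ravel()
        trace: list[float] = []

        def cb(xk):
            trace.append(_stress_and_grad(xk, D, W)[0])

        res = optimize.minimize(
            _stress_and_grad, x0, args=(D, W), jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter}, callback=cb,
        )
        if best is None or res.fun < best.fun:
            best = res
            best_trace = np.array(trace)
    X = best.x.reshape(n, 3)
    X = X - X.mean(axis=0)
    return Structure3D(
        coords=X, stress=float(best.fun), alpha_d=alpha_d,
        stress_trace=best_trace if best_trace is not None else np.array([]),
    )


def distance_profile(structure: Structure3D, focus_bin: int) -> np.ndarray:
    """Euclidean distance from the focus bin to every bin of the region."""
    if not 0 <= focus_bin < structure.n_bins:
        raise ValueError("focus bin outside the region")
    d = structure.coords - structure.coords[focus_bin]
    return np.sqrt((d**2).sum(axis=1))


def compare_profiles(profile_1: np.ndarray, profile_2: np.ndarray) -> dict:
    """Paired Wilcoxon comparison of two focus-distance profiles
    (bins paired by genomic position; the focus bin's zero is dropped)."""
    p1 = np.asarray(profile_1, dtype=float)
    p2 = np.asarray(profile_2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("profiles differ in length")
    keep = (p1 > 0) | (p2 > 0)
    stat, p = stats.wilcoxon(p1[keep], p2[keep])
    return {
        "statistic": float(stat),
        "p": float(p),
        "n": int(keep.sum()),
        "median_delta": float(np.median(p2[keep] - p1[keep])),
    }
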