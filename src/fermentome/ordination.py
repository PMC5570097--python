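"""Community structure: Bray-Curtis dissimilarity and principal
coordinate analysis (classical scaling) with taxon weightings.

Tables are taxa x samples DataFrames (rows = taxa, columns = samples),
matching ``OTUTable.to_dataframe``. Ordinations follow classical scaling:
double-centre -d^2/2, eigendecompose, scale eigenvectors by the square
root of their (positive) eigenvalues. Bray-Curtis matrices are generally
non-Euclidean, so negative eigenvalues occur; they are reported but
excluded from the coordinates (no Lingoes/Cailliez correction by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def top_n_taxa(table: pd.DataFrame, n: int = 30) -> pd.DataFrame:
    """Keep the n taxa with the largest total abundance across samples.

    Ties break lexicographically on the taxon name so the selection is
    deterministic.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    totals = table.sum(axis=1)
    order = sorted(table.index, key=lambda t: (-totals[t], str(t)))
    keep = set(order[:n])
    return table.loc[[t for t in table.index if t in keep]]


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity: 1 - 2 sum(min(u,v)) / (sum u + sum v)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("profiles must cover the same taxa")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = u.sum() + v.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(1.0 - 2.0 * np.minimum(u, v).sum() / denom)


def dissimilarity_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric samples x samples Bray-Curtis matrix (zero diagonal)."""
    samples = list(table.columns)
    m = np.zeros((len(samples), len(samples)))
    cols = table.to_numpy().T
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            m[i, j] = m[j, i] = bray_curtis(cols[i], cols[j])
    return pd.DataFrame(m, index=samples, columns=samples)


@dataclass
class Ordination:
    coordinates: pd.DataFrame     # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives kept)

    @property
    def explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def pcoa(d: pd.DataFrame, k: int = 2) -> Ordination:
    """Classical scaling of a dissimilarity matrix.

    Axes use only positive eigenvalues; if fewer than ``k`` are available
    the result is truncated with a warning. Axis signs are fixed so the
    first nonzero coordinate on each axis is positive.
    """
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if k > n - 1:
        raise ValueError("k must be <= n_samples - 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, abs(eigvals[0]) if n else 1.0)
    n_pos = int((eigvals > tol).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues available; returning {k_eff} axes",
            stacklevel=2,
        )
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    for a in range(k_eff):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(
        coords, index=index, columns=[f"axis{i + 1}" for i in range(k_eff)]
    )
    return Ordination(coordinates=frame, eigenvalues=eigvals)


def taxon_weightings(table: pd.DataFrame, ordination: Ordination) -> pd.DataFrame:
    """Per-taxon axis loadings plus total-abundance node sizes.

    The loading of a taxon on an axis is the covariance between its
    abundance across samples and the axis coordinates, rescaled per axis
    to unit maximum absolute value; a constant taxon loads zero everywhere.
    Node size is the taxon's total abundance (for plot circle scaling).
    """
    coords = ordination.coordinates
    if list(table.columns) != list(coords.index):
        table = table[list(coords.index)]
    x = table.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    c = coords.to_numpy() - coords.to_numpy().mean(axis=0, keepdims=True)
    n = x.shape[1]
    load = x @ c / max(n - 1, 1)
    scale = np.abs(load).max(axis=0)
    scale[scale == 0] = 1.0
    load = load / scale
    out = pd.DataFrame(load, index=table.index, columns=coords.columns)
    out["node_size"] = table.sum(axis=1).to_numpy()
    return out
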