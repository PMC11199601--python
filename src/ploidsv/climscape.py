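"""Redundancy analysis (RDA) and climatic landscapes.

RDA regresses population allele frequencies of climate-associated loci on
standardized bioclimatic variables and extracts canonical axes of the
fitted values.  The loadings of the first two axes project any
environment (a map pixel, or a future climate) onto an *adaptive index*
plane; the Euclidean distance between SV- and SNP-based index planes maps
where the two variant classes encode different climate associations, and
the distance between present and future indices (genomic offset) proxies
population vulnerability to climate change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .popgen import haversine_km


# ---------------------------------------------------------------------------
# RDA core


@dataclass
class RDAModel:
    """Fitted redundancy analysis.

    ``loadings[v, k]`` is the correlation of predictor v with canonical
    axis k site scores; predictors are standardized with the stored
    training means/sds before any prediction.
    """

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    loadings: np.ndarray
    r2: float
    adj_r2: float
    n: int
    rank: int
    fitted: np.ndarray | None = None

    def standardize(self, env: pd.DataFrame) -> np.ndarray:
        missing = set(self.variables) - set(env.columns)
        if missing:
            raise ValueError(f"environment table lacks model variables {sorted(missing)}")
        X = env[self.variables].to_numpy(dtype=float)
        return (X - self.means) / self.sds


def ezekiel_adj_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment 1 - (1-R^2)(n-1)/(n-p-1)."""
    if n - p - 1 <= 0:
        raise ValueError("adjusted R^2 needs n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - p - 1.0)


def fit_rda(Y: np.ndarray, X: pd.DataFrame | np.ndarray,
            variables: Sequence[str] | None = None) -> RDAModel:
    """Least-squares RDA of response Y (populations x loci) on predictors X.

    Y is column-centered, X standardized; canonical axes come from the SVD
    of the fitted values, with each axis sign-fixed so its
    largest-magnitude variable loading is positive.  R^2 is the fitted
    fraction of the total response sum of squares.
    """
    if isinstance(X, pd.DataFrame):
        variables = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        variables = list(variables) if variables is not None else [
            f"x{j + 1}" for j in range(Xm.shape[1])
        ]
    Y = np.asarray(Y, dtype=float)
    n, p = Xm.shape
    if Y.shape[0] != n:
        raise ValueError("Y and X disagree on the number of populations")
    if n <= p:
        raise ValueError(f"need more populations ({n}) than predictors ({p})")
    means, sds = Xm.mean(axis=0), Xm.std(axis=0)
    if np.any(sds == 0):
        bad = [variables[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant predictors: {bad}")
    Z = (Xm - means) / sds
    Yc = Y - Y.mean(axis=0)

    gram = Z.T @ Z
    if np.linalg.cond(gram) > 1e12:
        corr = np.corrcoef(Z, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear predictors (e.g. {variables[i]} vs {variables[j]}): "
            "X'X is singular"
        )
    B = np.linalg.solve(gram, Z.T @ Yc)
    Yhat = Z @ B
    tot = float((Yc**2).sum())
    fit = float((Yhat**2).sum())
    r2 = fit / tot if tot > 0 else 0.0

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    k = max(rank, 1)
    site_scores = U[:, :k] * s[:k]
    eig = (s[:k] ** 2) / max(n - 1, 1)
    # loadings: correlation of each predictor with each axis's site scores
    loadings = np.zeros((p, k))
    for axis in range(k):
        sc = site_scores[:, axis]
        if sc.std() == 0:
            continue
        for v in range(p):
            loadings[v, axis] = np.corrcoef(Z[:, v], sc)[0, 1]
    # sign convention: largest-|loading| variable positive per axis
    for axis in range(k):
        v = int(np.argmax(np.abs(loadings[:, axis])))
        if loadings[v, axis] < 0:
            loadings[:, axis] = -loadings[:, axis]
            site_scores[:, axis] = -site_scores[:, axis]
    return RDAModel(
        variables=variables,
        means=means,
        sds=sds,
        eigenvalues=eig,
        site_scores=site_scores,
        loadings=loadings,
        r2=r2,
        adj_r2=ezekiel_adj_r2(r2, n, p),
        n=n,
        rank=rank,
        fitted=Yhat,
    )


def _r2_of(Z: np.ndarray, Yc: np.ndarray, tot: float) -> float:
    B, *_ = np.linalg.lstsq(Z, Yc, rcond=None)
    return float(((Z @ B) ** 2).sum()) / tot


def forward_select(
    Y: np.ndarray,
    X: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> list[str]:
    """Permutation-gated forward selection of RDA predictors.

    Repeatedly adds the candidate with the largest added R^2, admitting it
    only if its permutation p-value (candidate rows permuted, selected
    block fixed; add-one estimator p = (1 + #perm >= obs)/(1 + n_perm))
    is below ``alpha``; stops when no candidate is admitted.
    """
    rng = np.random.default_rng(seed)
    variables = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    Z = (Xm - Xm.mean(axis=0)) / Xm.std(axis=0)
    Yc = np.asarray(Y, dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    tot = float((Yc**2).sum())
    if tot == 0:
        return []
    n = Z.shape[0]

    selected: list[int] = []
    Q = np.zeros((n, 0))  # orthonormal basis of the selected block
    base_r2 = 0.0
    remaining = list(range(len(variables)))
    while remaining and len(selected) < n - 2:
        gains = []
        units = []
        for j in remaining:
            u = Z[:, j] - Q @ (Q.T @ Z[:, j])
            norm = np.linalg.norm(u)
            if norm < 1e-10:
                gains.append(-np.inf)
                units.append(None)
                continue
            u = u / norm
            gains.append(float(((u @ Yc) ** 2).sum()) / tot)
            units.append(u)
        best = int(np.argmax(gains))
        if not np.isfinite(gains[best]) or gains[best] <= 0:
            break
        j = remaining[best]
        obs_gain = gains[best]
        # permutation null: permute the candidate's rows, re-orthogonalize
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        C = Z[:, j][perm_idx].T  # n x n_perm permuted candidate columns
        C = C - Q @ (Q.T @ C)
        norms = np.linalg.norm(C, axis=0)
        ok = norms > 1e-10
        C[:, ok] = C[:, ok] / norms[ok]
        perm_gains = ((C.T @ Yc) ** 2).sum(axis=1) / tot
        perm_gains[~ok] = 0.0
        p = (1.0 + np.sum(perm_gains >= obs_gain - 1e-15)) / (1.0 + n_perm)
        if p >= alpha:
            break
        selected.append(j)
        Q = np.column_stack([Q, units[best]])
        base_r2 += obs_gain
        remaining.remove(j)
    return [variables[j] for j in selected]


# ---------------------------------------------------------------------------
# geographic principal coordinates


def geo_pcoa(lon: np.ndarray, lat: np.ndarray, n_coords: int = 10) -> np.ndarray:
    """Classical scaling of the haversine distance matrix.

    Double-centers the squared distances and keeps up to ``n_coords``
    coordinates with positive eigenvalues.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = lon.size
    if n < 3:
        raise ValueError("need >= 3 populations")
    D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(vals.max(), 0) * 1e-12
    keep[n_coords:] = False
    return vecs[:, keep] * np.sqrt(vals[keep])


# ---------------------------------------------------------------------------
# variance partitioning


def partial_rda_decomposition(
    Y: np.ndarray,
    blocks: dict[str, pd.DataFrame | np.ndarray],
) -> dict[str, float]:
    """Unique and shared adjusted-R^2 fractions across predictor blocks.

    For each block, unique = adjR2(full) - adjR2(all other blocks); the
    shared fraction is the remainder full - sum(unique).  Negative adjusted
    values are reported as-is (standard variance-partitioning behavior).
    """
    mats = {}
    for name, X in blocks.items():
        Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        sd = Xm.std(axis=0)
        sd[sd == 0] = 1.0
        mats[name] = (Xm - Xm.mean(axis=0)) / sd
    Yc = np.asarray(Y, dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    tot = float((Yc**2).sum())
    n = Yc.shape[0]

    def adj(parts: list[str]) -> float:
        Z = np.column_stack([mats[p] for p in parts])
        # guard duplicated blocks: drop linearly dependent columns via QR
        q, r = np.linalg.qr(Z)
        keep = np.abs(np.diag(r)) > 1e-10
        p_eff = int(keep.sum())
        r2 = _r2_of(Z, Yc, tot)
        return ezekiel_adj_r2(r2, n, p_eff)

    names = list(blocks)
    full = adj(names)
    out = {"full": full}
    unique_sum = 0.0
    for name in names:
        others = [m for m in names if m != name]
        u = full - (adj(others) if others else 0.0)
        out[f"unique_{name}"] = u
        unique_sum += u
    out["shared"] = full - unique_sum
    return out


# ---------------------------------------------------------------------------
# adaptive indices and climatic distance


@dataclass
class ClimaticIndexGrid:
    """Per-pixel two-axis adaptive indices for one variant class."""

    pixels: pd.DataFrame  # pixel, lon, lat, index1, index2, raw1, raw2
    scale: tuple[float, float]

    @property
    def index(self) -> np.ndarray:
        return self.pixels[["index1", "index2"]].to_numpy()


def adaptive_index(model: RDAModel, grid: pd.DataFrame, scale: bool = True
                   ) -> ClimaticIndexGrid:
    """Project a pixel grid onto the first two RDA axes.

    index_k(pixel) = sum_v loading[v, k] * z_v(pixel), with the grid
    standardized by the model's *training* means/sds.  Axes are already
    sign-anchored at fit time; with ``scale`` each axis is divided by its
    standard deviation over the grid so SV- and SNP-based maps are
    comparable.  Raw (unscaled) indices are kept alongside.
    """
    Z = model.standardize(grid)
    k = min(2, model.loadings.shape[1])
    raw = Z @ model.loadings[:, :k]
    if k == 1:
        raw = np.column_stack([raw, np.zeros(len(raw))])
    sds = raw.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    idx = raw / sds if scale else raw.copy()
    pixels = pd.DataFrame(
        {
            "pixel": grid["pixel"].to_numpy() if "pixel" in grid else np.arange(len(grid)),
            "lon": grid["lon"].to_numpy() if "lon" in grid else np.nan,
            "lat": grid["lat"].to_numpy() if "lat" in grid else np.nan,
            "index1": idx[:, 0],
            "index2": idx[:, 1],
            "raw1": raw[:, 0],
            "raw2": raw[:, 1],
        }
    )
    return ClimaticIndexGrid(pixels=pixels, scale=(float(sds[0]), float(sds[1])))


def climatic_distance(grid_a: ClimaticIndexGrid, grid_b: ClimaticIndexGrid
                      ) -> pd.DataFrame:
    """Per-pixel normalized Euclidean distance between two index grids.

    Distances are min-max normalized to [0, 1] over the shared pixels;
    disjoint pixel sets are an error.
    """
    a, b = grid_a.pixels, grid_b.pixels
    if not a["pixel"].equals(b["pixel"]):
        shared = set(a["pixel"]) & set(b["pixel"])
        if not shared:
            raise ValueError("index grids share no pixels")
        a = a[a["pixel"].isin(shared)].reset_index(drop=True)
        b = b[b["pixel"].isin(shared)].reset_index(drop=True)
    d = np.sqrt(
        (a["index1"].to_numpy() - b["index1"].to_numpy()) ** 2
        + (a["index2"].to_numpy() - b["index2"].to_numpy()) ** 2
    )
    span = d.max() - d.min()
    norm = (d - d.min()) / span if span > 0 else np.zeros_like(d)
    return pd.DataFrame(
        {"pixel": a["pixel"], "lon": a["lon"], "lat": a["lat"],
         "distance": d, "normalized_distance": norm}
    )


def future_offset(model: RDAModel, env_now: pd.DataFrame, env_future: pd.DataFrame
                  ) -> pd.DataFrame:
    """Genomic offset: index distance between present and projected climate.

    Both tables are standardized with the model's *training* statistics so
    a pixel's offset is the raw-axis Euclidean displacement of its adaptive
    index under the projected environment.
    """
    if set(model.variables) - set(env_future.columns):
        raise ValueError("future environment lacks model variables")
    now = adaptive_index(model, env_now, scale=False)
    fut = adaptive_index(model, env_future, scale=False)
    if len(now.pixels) != len(fut.pixels):
        raise ValueError("present and future grids differ in size")
    d = np.sqrt(
        (now.pixels["raw1"].to_numpy() - fut.pixels["raw1"].to_numpy()) ** 2
        + (now.pixels["raw2"].to_numpy() - fut.pixels["raw2"].to_numpy()) ** 2
    )
    return pd.DataFrame(
        {"pixel": now.pixels["pixel"], "lon": now.pixels["lon"],
         "lat": now.pixels["lat"], "offset": d}
    )


def population_offset(offsets: pd.DataFrame, lon: np.ndarray, lat: np.ndarray,
                      populations: Sequence[str]) -> pd.DataFrame:
    """Per-population offset at the nearest occupied pixel."""
    px = offsets[["lon", "lat"]].to_numpy()
    rows = []
    for pop, lo, la in zip(populations, lon, lat):
        d = haversine_km(px[:, 0], px[:, 1], lo, la)
        rows.append((pop, float(offsets["offset"].to_numpy()[np.argmin(d)])))
    return pd.DataFrame(rows, columns=["population", "offset"])


# ---------------------------------------------------------------------------
# occurrence grid


def grid_occupancy(occurrences: pd.DataFrame, cell_km: float = 100.0) -> pd.DataFrame:
    """Occupied cells of an equal-area-approximate lon/lat grid.

    Rows are ``cell_km`` tall in latitude; within each latitude row,
    longitude is scaled by cos(row-center latitude) so cells are about
    ``cell_km`` wide.  Cell assignment is half-open (floor), so boundary
    occurrences land in exactly one cell.
    """
    if occurrences.empty:
        return pd.DataFrame(columns=["row", "col", "lon", "lat", "n"])
    km_per_deg = 2 * np.pi * 6371.0088 / 360.0
    lat = occurrences["lat"].to_numpy(dtype=float)
    lon = occurrences["lon"].to_numpy(dtype=float)
    row = np.floor(lat * km_per_deg / cell_km).astype(int)
    row_lat = (row + 0.5) * cell_km / km_per_deg
    col = np.floor(lon * km_per_deg * np.cos(np.radians(row_lat)) / cell_km).astype(int)
    cells = pd.DataFrame({"row": row, "col": col})
    counts = cells.value_counts().reset_index(name="n")
    counts["lat"] = (counts["row"] + 0.5) * cell_km / km_per_deg
    counts["lon"] = (counts["col"] + 0.5) * cell_km / (
        km_per_deg * np.cos(np.radians(counts["lat"]))
    )
    return counts[["row", "col", "lon", "lat", "n"]].sort_values(["row", "col"]).reset_index(drop=True)
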