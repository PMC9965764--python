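"""RGB spectral traits from segmented phenotype images and their dbRDA linkage.

Segmented images carry a pure-black or pure-white background; trait
extraction discards exactly those pixels and histograms the remaining pixels
per channel into 256 frequency bins.  The trait matrix (one row per image,
3 x 256 concatenated frequencies) is then related to compound-class
composition by distance-based redundancy analysis: principal coordinates of
the trait distance matrix are regressed on the centered constraint matrix,
and the constrained-inertia fraction reports how much trait variation the
constraints explain.  With Euclidean distances dbRDA coincides with
classical RDA, which anchors the implementation's tests.  Constraints can be
chosen greedily by permutation-tested forward selection, and individual
variables scored post hoc by the envfit goodness of fit (R-squared of the
variable regressed on the first two ordination axes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralTraits",
    "extract_rgb_histograms",
    "traits_matrix",
    "DbrdaResult",
    "dbrda",
    "forward_select",
    "envfit_r2",
]


@dataclass
class SpectralTraits:
    """Per-image channel histograms over retained (non-background) pixels."""

    histograms: np.ndarray  # 3 x 256, each row sums to 1
    retained_pixels: int
    excluded_pixels: int
    label: str | None = None

    def as_vector(self) -> np.ndarray:
        return self.histograms.reshape(-1)


def extract_rgb_histograms(image, label: str | None = None) -> SpectralTraits:
    """Histogram the RGB channels, dropping pure-black and pure-white pixels.

    ``image`` may be a path, a PIL image, or an (H, W, 3) uint8 array.  Pure
    black is (0,0,0) and pure white (255,255,255) on the 8-bit scale — the
    two backgrounds segmentation produces.  Raises if nothing remains.
    """
    if isinstance(image, np.ndarray):
        arr = image
    else:
        if not isinstance(image, Image.Image):
            image = Image.open(image)
        if image.mode != "RGB":
            image = image.convert("RGB")
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB raster")
    arr = arr.astype(np.uint8)
    flat = arr.reshape(-1, 3)
    black = (flat == 0).all(axis=1)
    white = (flat == 255).all(axis=1)
    keep = flat[~(black | white)]
    excluded = int(black.sum() + white.sum())
    if keep.shape[0] == 0:
        raise ValueError("image entirely background (pure black/white)")
    hist = np.stack(
        [np.bincount(keep[:, ch], minlength=256).astype(float) for ch in range(3)]
    )
    hist /= keep.shape[0]
    return SpectralTraits(
        histograms=hist,
        retained_pixels=int(keep.shape[0]),
        excluded_pixels=excluded,
        label=label,
    )


def traits_matrix(traits: list[SpectralTraits]) -> pd.DataFrame:
    """Stack trait vectors into a samples x 768 frequency matrix."""
    names = [f"{ch}{b}" for ch in ("R", "G", "B") for b in range(256)]
    rows = {t.label or f"image_{i}": t.as_vector() for i, t in enumerate(traits)}
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------


@dataclass
class DbrdaResult:
    constrained_fraction: float
    eigenvalues: np.ndarray          # constrained axes, non-increasing
    site_scores: pd.DataFrame        # samples x retained constrained axes
    constraint_scores: pd.DataFrame  # constraint variables x axes (correlations)
    total_inertia: float
    constrained_inertia: float
    negative_eigenvalue_mass: float
    rank_deficient: bool = False


def _principal_coordinates(Y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """PCoA of Euclidean-embedded or arbitrary distances via Gower centering."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(Y, metric="euclidean"))
    return _pcoa_from_distances(D)


def _pcoa_from_distances(D: np.ndarray) -> tuple[np.ndarray, float, float]:
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(abs(vals).max(), 1.0)
    neg_mass = float(abs(vals[vals < -tol]).sum())
    total_abs = float(abs(vals).sum())
    if neg_mass > 0:
        logger.info(
            "dropping negative PCoA eigenvalues (relative mass %.3g)",
            neg_mass / total_abs if total_abs else 0.0,
        )
    keep = vals > tol
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return coords, float(vals[keep].sum()), neg_mass / total_abs if total_abs else 0.0


def _constrained_inertia(coords: np.ndarray, Z: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Sum of squares of coords projected onto the span of centered Z."""
    Zc = Z - Z.mean(axis=0)
    q, r = np.linalg.qr(Zc)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * max(diag.max(), 1.0)).sum())
    q = q[:, :rank]
    fitted = q @ (q.T @ coords)
    return float((fitted ** 2).sum()), fitted, rank


def dbrda(response, constraints, distance: str = "euclidean") -> DbrdaResult:
    """Distance-based redundancy analysis.

    ``response`` is a samples x traits matrix (or list of
    :class:`SpectralTraits`); ``constraints`` a samples x variables matrix
    aligned by row.  Distances -> Gower double-centering -> principal
    coordinates (negative eigenvalues dropped, their relative mass logged) ->
    least-squares projection onto the centered constraints.
    """
    if isinstance(response, list):
        response = traits_matrix(response)
    Yf = pd.DataFrame(response)
    Zf = pd.DataFrame(constraints)
    if Yf.shape[0] != Zf.shape[0]:
        raise ValueError("response and constraints must have the same samples")
    if Yf.shape[0] < 3:
        raise ValueError("dbRDA needs at least 3 samples")
    if isinstance(Yf.index, type(Zf.index)) and list(Yf.index) != list(Zf.index):
        Zf = Zf.reindex(Yf.index)
        if Zf.isna().any().any():
            raise ValueError("constraint rows do not match response samples")
    Y = Yf.to_numpy(dtype=float)

    if distance == "euclidean":
        coords, total, neg_mass = _principal_coordinates(Y)
    else:
        from scipy.spatial.distance import pdist, squareform

        coords, total, neg_mass = _pcoa_from_distances(
            squareform(pdist(Y, metric=distance))
        )
    if total <= 0 or coords.shape[1] == 0:
        raise ValueError("constant response: no inertia to explain")

    Z = Zf.to_numpy(dtype=float)
    constrained, fitted, rank = _constrained_inertia(coords, Z)
    rank_deficient = rank < Z.shape[1]
    if rank_deficient:
        logger.warning("collinear constraints: rank %d < %d columns", rank, Z.shape[1])

    # constrained axes = principal axes of the fitted coordinates
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2
    keep = eig > 1e-12 * max(eig.max(), 1.0) if eig.size else np.zeros(0, bool)
    eig = eig[keep]
    axes = u[:, keep] * s[keep]
    axis_names = [f"dbRDA{i + 1}" for i in range(axes.shape[1])]
    site_scores = pd.DataFrame(axes, index=Yf.index, columns=axis_names)

    cscores = {}
    Zc = Z - Z.mean(axis=0)
    for jdx, name in enumerate(Zf.columns):
        col = Zc[:, jdx]
        sd = col.std()
        cscores[name] = [
            float(np.corrcoef(col, axes[:, a])[0, 1]) if sd > 0 and axes[:, a].std() > 0 else 0.0
            for a in range(axes.shape[1])
        ]
    constraint_scores = pd.DataFrame.from_dict(cscores, orient="index", columns=axis_names)

    return DbrdaResult(
        constrained_fraction=constrained / total,
        eigenvalues=eig,
        site_scores=site_scores,
        constraint_scores=constraint_scores,
        total_inertia=total,
        constrained_inertia=constrained,
        negative_eigenvalue_mass=neg_mass,
        rank_deficient=rank_deficient,
    )


def forward_select(
    response,
    candidates,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward selection of constraints by permutation-tested inertia gain.

    At each step the candidate with the largest increase in constrained
    inertia enters if its permutation p-value (response rows permuted, gain
    recomputed) is <= alpha; otherwise selection stops.  Returns the selected
    names in inclusion order and a trace (candidate, gain, p, selected).
    """
    if isinstance(response, list):
        response = traits_matrix(response)
    Yf = pd.DataFrame(response)
    Zf = pd.DataFrame(candidates)
    if Zf.shape[1] < 1:
        raise ValueError("need at least one candidate constraint")
    coords, total, _ = _principal_coordinates(Yf.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    n = coords.shape[0]

    selected: list[str] = []
    trace = []
    remaining = list(Zf.columns)
    current = 0.0
    while remaining:
        gains = {}
        for name in remaining:
            Z = Zf[selected + [name]].to_numpy(dtype=float)
            gains[name] = _constrained_inertia(coords, Z)[0] - current
        best = max(remaining, key=lambda nm: (gains[nm], str(nm)))
        Zbest = Zf[selected + [best]].to_numpy(dtype=float)
        obs_gain = gains[best]

        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pc = coords[perm]
            base = _constrained_inertia(pc, Zf[selected].to_numpy(dtype=float))[0] if selected else 0.0
            if _constrained_inertia(pc, Zbest)[0] - base >= obs_gain:
                count += 1
        p = (1 + count) / (n_perm + 1)
        accept = p <= alpha
        trace.append({"candidate": best, "gain": obs_gain / total, "p": p, "selected": accept})
        if not accept:
            break
        selected.append(best)
        remaining.remove(best)
        current += obs_gain
    return selected, pd.DataFrame(trace, columns=["candidate", "gain", "p", "selected"])


def envfit_r2(
    site_scores, variable, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Goodness of fit of a variable on the first two ordination axes.

    R-squared of the least-squares regression of the variable on the two axis
    scores (with intercept); p is the fraction of row permutations of the
    variable achieving R*^2 >= R^2.
    """
    S = np.asarray(pd.DataFrame(site_scores).iloc[:, :2], dtype=float)
    v = np.asarray(variable, dtype=float)
    n = len(v)
    if n < 4:
        raise ValueError("envfit needs at least 4 samples")
    if S.shape[0] != n:
        raise ValueError("variable and site scores must have the same samples")
    if np.var(v) == 0:
        raise ValueError("zero-variance variable")

    X = np.column_stack([np.ones(n), S])

    def _r2(vv: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, vv, rcond=None)
        resid = vv - X @ beta
        sst = float(((vv - vv.mean()) ** 2).sum())
        return 1.0 - float((resid ** 2).sum()) / sst

    r2 = _r2(v)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _r2(rng.permutation(v)) >= r2:
            count += 1
    return r2, (1 + count) / (n_perm + 1)
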