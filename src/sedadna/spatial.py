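"""Clark–Evans nearest-neighbor dispersion of taxa over a block face.

For each taxon detected at ≥3 sampling spots, the mean distance from each
positive spot to its nearest positive neighbour, D_obs, is compared with
the expectation under complete spatial randomness, 0.5·sqrt(a/n), giving

    Rn = D_obs / (0.5 · sqrt(a / n))

with a the sampled surface area (cm²) and n the number of positive spots.
Rn ≈ 0 indicates clustering, ≈ 1 spatial randomness, and ≈ 2.149 (the
triangular-lattice maximum) a uniform, over-dispersed arrangement.

Because drilled spots sit on a discrete grid, Rn for a real block is
interpreted against a permutation null that resamples positive spots from
the actual spot coordinates, so grid geometry cannot masquerade as
clustering. No edge correction is applied to block data (small n, plain
formula); a toroidal metric is available for calibration against the CSR
and lattice anchor values, which are interior/asymptotic statements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from sedadna.profiling import FamilyProfile
from sedadna.types import BlockLayout

Classification = Literal["clustered", "random", "uniform", "not_evaluated"]


def nearest_neighbor_distances(
    points: np.ndarray, toroidal: bool = False, period: float | None = None
) -> np.ndarray:
    """Distance from each point to its nearest other point.

    With ``toroidal=True`` distances are computed on a torus of side
    ``period`` (calibration mode; removes edge effects exactly).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n, 2) array with n >= 2")
    if toroidal:
        if period is None:
            raise ValueError("toroidal metric needs a period")
        tree = cKDTree(np.mod(pts, period), boxsize=period)
    else:
        tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def nearest_neighbor_rn(
    points: Sequence[tuple[float, float]] | np.ndarray,
    area: float,
    toroidal: bool = False,
    period: float | None = None,
    interior_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """(D_obs, Rn) for a point pattern in units consistent with ``area``.

    ``interior_mask`` restricts the D_obs average to interior points (their
    nearest neighbours are still searched among all points) — used when
    checking the lattice anchor, where boundary points inflate D_obs.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("Rn undefined for fewer than 2 points")
    d = nearest_neighbor_distances(pts, toroidal=toroidal, period=period)
    if interior_mask is not None:
        d = d[np.asarray(interior_mask, dtype=bool)]
        if d.size == 0:
            raise ValueError("interior mask removed all points")
    n = len(pts)
    d_obs = float(d.mean())
    expected = 0.5 * np.sqrt(area / n)
    return d_obs, d_obs / expected


def permutation_null(
    layout_points: np.ndarray,
    n_positive: int,
    area: float,
    observed_rn: float,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Null distribution of Rn under random presence on the real spot grid.

    Each replicate samples ``n_positive`` spots uniformly without
    replacement from the layout coordinates and recomputes Rn. The
    two-sided p-value measures departure from the CSR anchor 1:
    p = (1 + #{|Rn_null − 1| ≥ |Rn_obs − 1|}) / (n_perm + 1).
    """
    pts = np.asarray(layout_points, dtype=float)
    if n_positive > len(pts):
        raise ValueError("more positives than spots")
    if n_positive == len(pts):
        return np.full(n_perm, observed_rn), 1.0
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(pts), size=n_positive, replace=False)
        _, null[i] = nearest_neighbor_rn(pts[idx], area)
    p = (1 + np.sum(np.abs(null - 1.0) >= np.abs(observed_rn - 1.0))) \
        / (n_perm + 1)
    return null, float(p)


@dataclass
class DispersionResult:
    taxon: str
    n_positive: int
    d_obs_cm: float | None
    rn: float | None
    perm_p: float | None
    classification: Classification


def classify(rn: float, perm_p: float, alpha: float = 0.05) -> Classification:
    if perm_p < alpha:
        return "clustered" if rn < 1.0 else "uniform"
    return "random"


def taxon_dispersion(
    profiles: Mapping[str, FamilyProfile] | Mapping[str, set[str]],
    layout: BlockLayout,
    min_positive: int = 3,
    min_count: int = 1,
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[DispersionResult]:
    """Rn per taxon over the block, with the spot-geometry permutation null.

    ``profiles`` maps spot_id → FamilyProfile (presence: ≥ ``min_count``
    fragments of the family at the spot) or spot_id → set of present taxa.
    Taxa positive at fewer than ``min_positive`` spots are reported as
    not evaluated. Coordinates are converted mm → cm so a in cm² is
    dimensionally consistent.
    """
    coords = layout.coordinates_cm()
    presence: dict[str, list[str]] = {}
    for spot_id, prof in profiles.items():
        if isinstance(prof, FamilyProfile):
            taxa = {f for f, c in prof.families.items()
                    if c.n_fragments >= min_count}
        else:
            taxa = set(prof)
        for t in taxa:
            presence.setdefault(t, []).append(spot_id)

    results = []
    for taxon in sorted(presence):
        spots = presence[taxon]
        if len(spots) < min_positive:
            results.append(DispersionResult(taxon, len(spots), None, None,
                                            None, "not_evaluated"))
            continue
        pts = coords.loc[spots, ["x_cm", "y_cm"]].to_numpy()
        d_obs, rn = nearest_neighbor_rn(pts, layout.area_cm2)
        _, p = permutation_null(
            coords[["x_cm", "y_cm"]].to_numpy(), len(spots),
            layout.area_cm2, rn, n_perm=n_perm,
            seed=np.random.default_rng([seed, len(spots)]),
        )
        results.append(
            DispersionResult(taxon, len(spots), d_obs, rn, p,
                             classify(rn, p, alpha))
        )
    return results


def dispersion_to_frame(results: Sequence[DispersionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "n_positive": r.n_positive,
                "d_obs_cm": r.d_obs_cm,
                "rn": r.rn,
                "perm_p": r.perm_p,
                "classification": r.classification,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# calibration patterns (used by tests and the acceptance checks)

def csr_points(n: int, rng: np.random.Generator, side: float = 1.0) -> np.ndarray:
    """n uniform points in a square of the given side (binomial process)."""
    return rng.random((n, 2)) * side


def triangular_lattice(n_per_side: int, spacing: float = 1.0):
    """Triangular (hexagonal-packing) lattice and its interior mask.

    Returns (points, interior_mask, area) with one unit cell per point,
    area = n·(√3/2)·s². Interior points are those further than one lattice
    spacing from the bounding box edge.
    """
    xs, ys = [], []
    row_h = spacing * np.sqrt(3) / 2
    for r in range(n_per_side):
        offset = 0.5 * spacing if r % 2 else 0.0
        for c in range(n_per_side):
            xs.append(c * spacing + offset)
            ys.append(r * row_h)
    pts = np.column_stack([xs, ys])
    n = len(pts)
    area = n * (np.sqrt(3) / 2) * spacing**2
    lo = pts.min(axis=0) + 1.001 * spacing
    hi = pts.max(axis=0) - 1.001 * spacing
    interior = np.all((pts >= lo) & (pts <= hi), axis=1)
    return pts, interior, area
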