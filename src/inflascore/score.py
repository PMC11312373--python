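"""INFLA-Score: a composite decile-based index of low-grade systemic inflammation.

The index combines four blood markers — C-reactive protein (CRP, mg/L),
white blood cell count (WBC), platelet count (Plt) and the
neutrophil-to-lymphocyte ratio (NLR) — with equal weight.  Each marker is
ranked into population deciles; the lower five deciles contribute
−4, −3, −2, −1, 0 points and the upper five contribute 0, +1, +2, +3, +4
points, so the total ranges from −16 to +16, higher meaning a more
pro-inflammatory profile.

Two naming variants of the decile→points mapping circulate in the
literature (deciles 1–5 / 6–10 versus 1–4 / 5–6 / 7–10); written out they
are the same vector ``[-4, -3, -2, -1, 0, 0, +1, +2, +3, +4]``, so both
variant names are accepted and share one implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import BinningError, DataError

#: Markers entering the composite score, in canonical order.
MARKERS: tuple[str, ...] = ("crp", "wbc", "plt", "nlr")

#: Points assigned to deciles 1..10 (index 0..9).
DECILE_POINTS: np.ndarray = np.array([-4, -3, -2, -1, 0, 0, 1, 2, 3, 4])

_VARIANTS = ("standard", "bonaccio")

SCORE_MIN: int = int(4 * DECILE_POINTS.min())
SCORE_MAX: int = int(4 * DECILE_POINTS.max())


def compute_nlr(neutrophil, lymphocyte):
    """Neutrophil-to-lymphocyte ratio.

    Parameters are counts (10^9 cells/L); lymphocyte must be strictly
    positive or the ratio is undefined and a :class:`DataError` is raised.
    Accepts scalars or aligned array-likes.
    """
    neut = np.asarray(neutrophil, dtype=float)
    lymph = np.asarray(lymphocyte, dtype=float)
    if np.any(lymph <= 0) or np.any(~np.isfinite(lymph)):
        raise DataError("lymphocyte count must be finite and > 0 to define NLR")
    out = neut / lymph
    return float(out) if out.ndim == 0 else out


@dataclass
class DecileMap:
    """Empirical decile cut-points per marker, fitted on an analysis population.

    ``cuts[marker]`` holds the nine 10th..90th percentiles (non-decreasing).
    ``directions[marker]`` is +1 when higher values are scored as more
    inflammatory (the default for all four markers) and −1 to reverse the
    scoring direction, as some users prefer for platelets.
    """

    cuts: dict[str, np.ndarray]
    directions: dict[str, int] = field(default_factory=dict)
    variant: str = "standard"

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise DataError(f"unknown variant {self.variant!r}; use one of {_VARIANTS}")
        for m, c in self.cuts.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (9,):
                raise DataError(f"marker {m!r}: expected 9 cut-points, got {c.shape}")
            if np.any(np.diff(c) < 0):
                raise DataError(f"marker {m!r}: cut-points must be non-decreasing")
            self.cuts[m] = c
        for m in self.cuts:
            self.directions.setdefault(m, +1)

    def is_degenerate(self, marker: str) -> bool:
        """True when all nine cut-points coincide (constant marker)."""
        c = self.cuts[marker]
        return bool(np.all(c == c[0]))


def fit_decile_map(
    panel: pd.DataFrame,
    variant: str = "standard",
    directions: dict[str, int] | None = None,
    markers: tuple[str, ...] = MARKERS,
) -> DecileMap:
    """Estimate decile cut-points for each marker on the analysis population.

    Cut-points are the empirical 10th..90th percentiles (linear
    interpolation).  Requires at least 10 non-missing values per marker.
    """
    cuts = {}
    for m in markers:
        if m not in panel.columns:
            raise DataError(f"panel is missing marker column {m!r}")
        x = pd.to_numeric(panel[m], errors="coerce").dropna().to_numpy(float)
        if x.size < 10:
            raise DataError(f"marker {m!r}: need >= 10 non-missing values, got {x.size}")
        cuts[m] = np.quantile(x, np.arange(1, 10) / 10.0)
    return DecileMap(cuts=cuts, directions=dict(directions or {}), variant=variant)


def _decile_index(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    # value exactly at a cut-point goes to the lower decile (side="left")
    return np.searchsorted(cuts, values, side="left")


def decile_points(values, marker: str, dmap: DecileMap):
    """Points (−4..+4) contributed by ``marker`` at the given value(s).

    Monotone non-decreasing in the value when the marker direction is +1.
    """
    if marker not in dmap.cuts:
        raise DataError(f"decile map has no marker {marker!r}")
    x = np.asarray(values, dtype=float)
    pts = dmap.directions[marker] * DECILE_POINTS[_decile_index(x, dmap.cuts[marker])]
    return int(pts) if pts.ndim == 0 else pts


def compute_infla_score(panel: pd.DataFrame, dmap: DecileMap) -> pd.DataFrame:
    """Score a panel table; returns component points and the total.

    ``panel`` must carry the four marker columns, finite and positive.
    Rows with any missing marker raise :class:`DataError` — mirroring the
    study design in which participants without complete inflammation data
    are excluded upstream rather than imputed.

    Returns a DataFrame indexed like ``panel`` with columns
    ``infla_pts_<marker>`` and ``infla_score``.
    """
    out = pd.DataFrame(index=panel.index)
    total = np.zeros(len(panel), dtype=int)
    for m in dmap.cuts:
        if m not in panel.columns:
            raise DataError(f"panel is missing marker column {m!r}")
        x = pd.to_numeric(panel[m], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(x)):
            raise DataError(
                f"marker {m!r} has missing/non-finite values; exclude those rows first"
            )
        if np.any(x <= 0):
            raise DataError(f"marker {m!r} must be strictly positive")
        pts = decile_points(x, m, dmap)
        out[f"infla_pts_{m}"] = pts
        total = total + pts
    out["infla_score"] = total
    return out


def bin_exposure(scores, k: int = 4, prefix: str = "Q") -> pd.Series:
    """Quantile-bin an exposure into ``k`` ordered groups Q1..Qk.

    Q1 (lowest) is the conventional reference group.  Cut-points are
    empirical quantiles; a value exactly at a cut-point is assigned to the
    lower bin, so heavily tied integer scores keep whole tie-blocks
    together.  Raises :class:`BinningError` when fewer than ``k`` distinct
    values exist.
    """
    if k < 2:
        raise BinningError("need k >= 2 bins")
    s = pd.Series(np.asarray(scores, dtype=float))
    x = s.to_numpy()
    if np.any(~np.isfinite(x)):
        raise BinningError("exposure contains missing/non-finite values")
    if np.unique(x).size < k:
        raise BinningError(f"fewer than {k} distinct values; cannot form {k} bins")
    cuts = np.quantile(x, np.arange(1, k) / k)
    if np.unique(cuts).size < cuts.size:
        # tie-blocks spanning a cut collapse it; drop duplicates like qcut
        cuts = np.unique(cuts)
    idx = np.searchsorted(cuts, x, side="left")
    labels = [f"{prefix}{i + 1}" for i in range(len(cuts) + 1)]
    cat = pd.Categorical.from_codes(idx, categories=labels, ordered=True)
    out = pd.Series(cat)
    if hasattr(scores, "index"):
        out.index = scores.index
    return out
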