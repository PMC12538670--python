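"""Predictor relevance: ARD ranking and temporal correlation analysis.

Two complementary views of which variables drive the fluxes:

* **ARD ranking** — a fitted GP carries one lengthscale per predictor on
  standardized inputs; short lengthscales mean the posterior bends quickly
  along that axis, i.e. the predictor is informative.  The relevance score
  is the inverse lengthscale normalized so the most relevant predictor
  scores 1 (the polar-plot coefficients).
* **Temporal correlations** — Pearson (linear) and Spearman (monotonic)
  coefficients between regional mean 8-day series of each predictor and
  each flux, tabulated per region ("heat maps").  Coefficients only; no
  significance testing, matching how the tables are read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import gpr
from .io_formats.grids import GridScene

__all__ = [
    "RelevanceScores",
    "ard_relevance",
    "pearson",
    "spearman",
    "regional_series",
    "correlation_heatmap",
]


@dataclass(frozen=True)
class RelevanceScores:
    """Per-predictor relevance in (0, 1]; max score is exactly 1."""

    scores: dict[str, float]
    flux_variable: str
    scaling: str

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.scores.items(), key=lambda kv: -kv[1])


def ard_relevance(
    model: gpr.TrainedGPR, scaling: str = "inverse"
) -> RelevanceScores:
    """Relevance scores from the fitted ARD lengthscales.

    ``inverse``: r_b = 1/l_b, normalized to max 1 (default polar-plot
    scaling).  ``log-inverse``: r_b = -log(l_b / max_l), normalized —
    compresses extreme lengthscale ratios.  Ordering is strictly decreasing
    in lengthscale either way; ties share a score.
    """
    ell = model.hyperparameters.lengthscales
    names = list(model.training.predictor_names) or [
        f"x{b}" for b in range(ell.size)
    ]
    if scaling == "inverse":
        raw = 1.0 / ell
    elif scaling == "log-inverse":
        raw = np.log(ell.max() / ell) + 1e-12
        raw = raw / raw.max() if raw.max() > 0 else np.ones_like(raw)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    scores = raw / raw.max()
    return RelevanceScores(
        scores=dict(zip(names, scores.tolist())),
        flux_variable=model.training.flux_variable,
        scaling=scaling,
    )


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    ok = np.isfinite(x) & np.isfinite(y)  # pairwise deletion
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    return x, y


def pearson(x, y) -> float:
    """Sample Pearson correlation with pairwise deletion of missing values."""
    x, y = _clean_pair(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson on mid-ranks (average-rank ties)."""
    x, y = _clean_pair(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.spearmanr(x, y).statistic)


def regional_series(
    scene: GridScene,
    window: tuple[slice, slice] | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Spatial mean of unmasked pixels per composite, per band.

    The region is either a pixel window ``(row_slice, col_slice)`` or
    world-coordinate rectangle ``(xmin, ymin, xmax, ymax)`` selecting pixels
    whose centers fall inside.  Returns a DataFrame indexed by composite
    start date with one column per band.
    """
    if bounds is not None:
        xmin, ymin, xmax, ymax = bounds
        xc = scene.geo.x_centers(scene.width)
        yc = scene.geo.y_centers(scene.height)
        cols = np.flatnonzero((xc >= xmin) & (xc <= xmax))
        rows = np.flatnonzero((yc >= ymin) & (yc <= ymax))
        if cols.size == 0 or rows.size == 0:
            raise ValueError("region does not intersect the grid")
        window = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    if window is None:
        window = (slice(None), slice(None))
    rs, cs = window
    sub_mask = scene.mask[:, rs, cs]
    if sub_mask.size == 0:
        raise ValueError("empty region")
    out = {}
    valid = ~sub_mask
    counts = valid.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, arr in scene.bands.items():
            a = np.where(valid, arr[:, rs, cs], 0.0)
            out[name] = np.where(counts > 0, a.sum(axis=(1, 2)) /
                                 np.maximum(counts, 1), np.nan)
    return pd.DataFrame(out, index=pd.Index(scene.times, name="time"))


def correlation_heatmap(
    regions: dict[str, pd.DataFrame],
    flux_vars: list[str] | None = None,
) -> pd.DataFrame:
    """Region x predictor correlation table for each flux variable.

    ``regions`` maps a region label (e.g. biome tag) to a DataFrame of
    aligned 8-day series containing both flux columns and predictor
    columns (as produced by ``regional_series`` on flux + predictor
    scenes).  Cells hold Pearson r, Spearman rho, and the pair count after
    pairwise deletion.
    """
    rows = []
    for region, df in regions.items():
        fluxes = flux_vars or [c for c in ("GPP", "RECO", "NEE")
                               if c in df.columns]
        preds = [c for c in df.columns if c not in ("GPP", "RECO", "NEE")]
        for fv in fluxes:
            if fv not in df.columns:
                raise ValueError(f"region {region!r} has no {fv} series")
            for p in preds:
                x = df[p].to_numpy(dtype=float)
                y = df[fv].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                cell = {"region": region, "flux": fv, "predictor": p,
                        "n": int(ok.sum())}
                try:
                    cell["pearson_r"] = pearson(x, y)
                    cell["spearman_rho"] = spearman(x, y)
                except ValueError:
                    cell["pearson_r"] = np.nan
                    cell["spearman_rho"] = np.nan
                rows.append(cell)
    return pd.DataFrame(rows)
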