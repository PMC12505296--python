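"""Quantification of solid-media PCA colony arrays.

Colony sizes from 1,536-format arrays are filtered (colonies that failed
diploid selection and the border control positions are removed), log2
transformed, and corrected for plate and positional bias: the plate
median is subtracted, then one round of row/column median polish is run
within each plate.  The centered values are rescaled by the affine map
that sends the median of the stuffer-prey reference interaction to 0 and
the median of the wild-type-prey reference interaction to 1, so scores
are comparable across plates and batches.  Bait-level comparisons use a
one-sided Mann-Whitney U test against a reference bait with BH
correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stat_filters import bh_fdr, mann_whitney_u

__all__ = [
    "filter_colonies",
    "normalize_sizes",
    "rescale_colony_scores",
    "colony_scores",
    "compare_baits",
]

MIN_PLATE_COLONIES = 8


def filter_colonies(grid: pd.DataFrame) -> pd.DataFrame:
    """Drop colonies that failed diploid selection and the border controls.

    Zero-size colonies are treated as missing measurements (assay
    failure), not as zero-strength interactions.
    """
    need = {"plate", "row", "col", "bait", "prey", "size", "border", "grew"}
    if need - set(grid.columns):
        raise ValueError(f"colony grid needs columns {sorted(need)}")
    if grid.duplicated(["plate", "row", "col"]).any():
        raise ValueError("duplicate (plate, row, col) positions")
    out = grid[grid["grew"] & ~grid["border"] & (grid["size"] > 0)]
    return out.reset_index(drop=True)


def _median_polish_round(values: pd.Series, rows: pd.Series, cols: pd.Series) -> pd.Series:
    v = values - values.groupby(rows).transform("median")
    v = v - v.groupby(cols).transform("median")
    return v


def normalize_sizes(grid: pd.DataFrame, n_polish: int = 1) -> pd.DataFrame:
    """log2 sizes centered for plate and row/column position bias.

    Per plate: subtract the plate median of log2 size, then run
    ``n_polish`` rounds of row/column median polish.  Plates with fewer
    than 8 colonies are skipped with a warning.
    """
    import warnings

    out = grid.copy()
    out["norm_log2_size"] = np.nan
    for plate, idx in out.groupby("plate").groups.items():
        sub = out.loc[idx]
        if len(sub) < MIN_PLATE_COLONIES:
            warnings.warn(f"plate {plate!r} has {len(sub)} colonies; skipped")
            continue
        v = np.log2(sub["size"])
        v = v - v.median()
        for _ in range(n_polish):
            v = _median_polish_round(v, sub["row"], sub["col"])
        out.loc[idx, "norm_log2_size"] = v
    return out


def rescale_colony_scores(normalized: pd.DataFrame,
                          wt_prey: str = "Pbs2", stuffer_prey: str = "Pbs2-stuffer",
                          reference_bait: str = "Sho1") -> pd.DataFrame:
    """Affine rescaling: stuffer reference median -> 0, WT reference median -> 1."""
    v = normalized["norm_log2_size"]
    wt_ref = v[(normalized["bait"] == reference_bait) & (normalized["prey"] == wt_prey)]
    st_ref = v[(normalized["bait"] == reference_bait) & (normalized["prey"] == stuffer_prey)]
    if wt_ref.empty or st_ref.empty:
        raise ValueError("both reference interactions must be present")
    w, s = float(wt_ref.median()), float(st_ref.median())
    if w == s:
        raise ValueError("reference medians coincide; rescaling undefined")
    out = normalized.copy()
    out["score"] = (v - s) / (w - s)
    return out


def colony_scores(grid: pd.DataFrame, wt_prey: str = "Pbs2",
                  stuffer_prey: str = "Pbs2-stuffer",
                  reference_bait: str = "Sho1", n_polish: int = 1) -> pd.DataFrame:
    """Filter, normalize and rescale a colony grid in one step."""
    return rescale_colony_scores(
        normalize_sizes(filter_colonies(grid), n_polish=n_polish),
        wt_prey=wt_prey, stuffer_prey=stuffer_prey, reference_bait=reference_bait,
    )


def compare_baits(scores: pd.DataFrame, reference_bait: str = "Sho1",
                  prey: str | None = None, alpha: float = 0.05,
                  alternative: str = "less") -> pd.DataFrame:
    """One-sided Mann-Whitney of each bait's scores against the reference bait.

    ``alternative="less"`` asks whether a bait interacts more weakly than
    the reference; BH correction runs across baits.
    """
    data = scores if prey is None else scores[scores["prey"] == prey]
    ref = data.loc[data["bait"] == reference_bait, "score"].to_numpy()
    if len(ref) == 0:
        raise ValueError(f"reference bait {reference_bait!r} missing")
    rows = []
    for bait, sub in data[data["bait"] != reference_bait].groupby("bait", sort=True):
        vals = sub["score"].to_numpy()
        u, p = mann_whitney_u(vals, ref, alternative)
        rows.append({"bait": bait, "n": len(vals), "test": f"mw_{alternative}",
                     "statistic": u, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_fdr(out["p"])
        out["significant"] = out["p_adj"] < alpha
    return out
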