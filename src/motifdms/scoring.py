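"""Interaction scores, rescaling, filtering, aggregation, selection coefficients.

The interaction score of a variant in one replicate is the log2
fold-change of its pool frequency across the methotrexate selection,

    raw = log2((c_post + p) / D_post) - log2((c_pre + p) / D_pre),

with a pseudocount p = 0.5 on counts only.  Raw scores are then rescaled
per library (one library = one bait/condition/replicate) by the two-anchor
affine map

    scaled = (raw - W) / (W - N),

where W is the median raw score of the wild-type-identical and silent
variants and N the median raw score of nonsense variants, so that by
construction the wild-type anchor maps to 0 and the nonsense median to
exactly -1.  Variants with fewer than ``min_reads`` pre-selection reads
are dropped before anything else (low counts inflate fold-changes), and
per-amino-acid-change scores are medians over all synonymous codon
variants in all replicates of a condition, reported only when at least
``min_contrib`` replicate-level values survive.

Selection coefficients for pooled proliferation competitions are
wild-type-relative log2 enrichment rates per generation, with generations
counted as the log2 fold-change in optical density of each growth cycle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .library_design import LibraryDesign, VariantKey, annotate_variant

__all__ = [
    "raw_interaction_score",
    "apply_count_filter",
    "rescale_scores",
    "score_counts",
    "aggregate_aa",
    "generations_from_od",
    "selection_coefficient",
    "correlate_conditions",
]

REPLICATE_KEYS = ["bait", "condition", "replicate"]
WT_ANCHOR_CLASSES = ("wt_identical", "silent")


def raw_interaction_score(c_pre, d_pre, c_post, d_post, pseudocount: float = 0.5):
    """log2 frequency fold-change with a pseudocount on counts only."""
    c_pre = np.asarray(c_pre, dtype=float)
    c_post = np.asarray(c_post, dtype=float)
    d_pre = np.asarray(d_pre, dtype=float)
    d_post = np.asarray(d_post, dtype=float)
    if np.any(d_pre <= 0) or np.any(d_post <= 0):
        raise ValueError("sample depths must be positive")
    return np.log2((c_post + pseudocount) / d_post) - np.log2((c_pre + pseudocount) / d_pre)


def apply_count_filter(scores: pd.DataFrame, min_reads: int = 20) -> pd.DataFrame:
    """Flag records by the pre-selection read-count threshold (>= passes)."""
    out = scores.copy()
    out["pass_count_filter"] = out["c_pre"] >= min_reads
    return out


def _anchor_medians(group: pd.DataFrame, wt_policy: str,
                    excluded: set | None) -> tuple[float, float]:
    ok = group["pass_count_filter"]
    if excluded:
        ok = ok & ~group["variant_id"].isin(excluded)
    wt_classes = WT_ANCHOR_CLASSES if wt_policy == "wt_and_silent" else ("wt_identical",)
    w_vals = group.loc[ok & group["variant_class"].isin(wt_classes), "raw_score"]
    n_vals = group.loc[ok & (group["variant_class"] == "nonsense"), "raw_score"]
    if len(w_vals) == 0 or len(n_vals) == 0:
        return np.nan, np.nan
    return float(w_vals.median()), float(n_vals.median())


def rescale_scores(scores: pd.DataFrame, wt_policy: str = "wt_and_silent",
                   excluded_controls: set | None = None) -> pd.DataFrame:
    """Per-library affine rescaling to the WT = 0 / nonsense median = -1 frame.

    ``wt_policy`` chooses the wild-type anchor: ``"wt_and_silent"`` pools
    wild-type-identical with synonymous variants (the default, matching
    how WT and silent mutants are pooled downstream) or ``"wt_only"``.
    ``excluded_controls`` removes flagged control variants (by
    ``variant_id``) from the anchor sets.  Libraries whose two anchors
    coincide are left unscaled (scaled score missing) and flagged.
    """
    if wt_policy not in ("wt_and_silent", "wt_only"):
        raise ValueError(f"unknown wt_policy {wt_policy!r}")
    out = scores.copy()
    out["scaled_score"] = np.nan
    out["anchor_wt"] = np.nan
    out["anchor_nonsense"] = np.nan
    for _, idx in out.groupby(REPLICATE_KEYS, sort=False).groups.items():
        group = out.loc[idx]
        w, n = _anchor_medians(group, wt_policy, excluded_controls)
        if not np.isfinite(w) or not np.isfinite(n) or w == n:
            continue
        out.loc[idx, "scaled_score"] = (group["raw_score"] - w) / (w - n)
        out.loc[idx, "anchor_wt"] = w
        out.loc[idx, "anchor_nonsense"] = n
    return out


def score_counts(counts: pd.DataFrame, design: LibraryDesign,
                 min_reads: int = 20, pseudocount: float = 0.5,
                 wt_policy: str = "wt_and_silent") -> pd.DataFrame:
    """Per-replicate score records from a count table.

    Pairs every post-selection sample with the pre-selection sample of the
    same bait and replicate, computes raw scores for all single-codon
    variants and the pooled wild-type class, applies the count filter, and
    rescales per library.  Returns one row per (bait, condition,
    replicate, variant).
    """
    scored_classes = ["variant", "wt_identical"]
    known = list(set(counts["class"]) & {"silent", "missense", "nonsense"})
    tab = counts[counts["class"].isin(scored_classes + known)].copy()
    # simulator truth tables label variant rows by their consequence and
    # carry no depth column; normalize to the count-table convention
    tab.loc[tab["class"].isin(known), "class"] = "variant"
    if "depth" not in tab.columns:
        tab["depth"] = tab.groupby("sample_id")["count"].transform("sum")
    # NA join keys (the wild-type class has no codon) are made explicit
    tab["codon_position"] = tab["codon_position"].fillna(-1).astype(int)
    tab["mutant_codon"] = tab["mutant_codon"].fillna("")
    pre = tab[tab["timepoint"] == "pre"]
    post = tab[tab["timepoint"] == "post"]
    if pre.empty or post.empty:
        raise ValueError("count table needs both pre and post timepoints")
    join_keys = ["bait", "replicate", "class", "codon_position", "mutant_codon"]
    merged = post.merge(
        pre[join_keys + ["count", "depth"]].rename(
            columns={"count": "c_pre", "depth": "d_pre"}),
        on=join_keys, how="inner",
    ).rename(columns={"count": "c_post", "depth": "d_post"})
    if (merged["d_pre"] <= 0).any() or (merged["d_post"] <= 0).any():
        raise ValueError("samples with zero assigned depth cannot be scored")

    merged["raw_score"] = raw_interaction_score(
        merged["c_pre"], merged["d_pre"], merged["c_post"], merged["d_post"],
        pseudocount=pseudocount,
    )

    # annotate
    is_wt = merged["class"] == "wt_identical"
    ann = {
        (int(p), c): annotate_variant(design, VariantKey(int(p), c))
        for p, c in merged.loc[~is_wt, ["codon_position", "mutant_codon"]]
        .drop_duplicates().itertuples(index=False)
    }

    def _get(field, default):
        vals = []
        for wt, p, c in zip(is_wt, merged["codon_position"], merged["mutant_codon"]):
            vals.append(default if wt else getattr(ann[(int(p), c)], field))
        return vals

    merged["variant_class"] = np.where(is_wt, "wt_identical", _get("variant_class", "wt_identical"))
    merged["wt_aa"] = _get("wt_aa", "")
    merged["mut_aa"] = _get("mut_aa", "")
    merged["aa_change_key"] = np.where(is_wt, "WT", _get("aa_change_key", "WT"))
    merged["variant_id"] = np.where(
        is_wt, "WT",
        merged["codon_position"].astype(str) + ":" + merged["mutant_codon"].astype(str),
    )

    merged = apply_count_filter(merged, min_reads=min_reads)
    merged = rescale_scores(merged, wt_policy=wt_policy)
    keep = ["bait", "condition", "replicate", "variant_id", "class",
            "codon_position", "mutant_codon", "variant_class", "wt_aa", "mut_aa",
            "aa_change_key", "c_pre", "d_pre", "c_post", "d_post",
            "raw_score", "pass_count_filter", "scaled_score",
            "anchor_wt", "anchor_nonsense"]
    out = merged[keep].reset_index(drop=True)
    out["codon_position"] = out["codon_position"].astype("Int64")
    out.loc[out["class"] == "wt_identical", "codon_position"] = pd.NA
    out.loc[out["class"] == "wt_identical", "mutant_codon"] = pd.NA
    return out


def aggregate_aa(scores: pd.DataFrame, min_contrib: int = 3) -> pd.DataFrame:
    """Median per-amino-acid-change scores pooled over codons and replicates.

    Pools the scaled scores of every synonymous codon variant across the
    replicates of a (bait, condition); emits the median when at least
    ``min_contrib`` values contribute (the even-n median is the midpoint
    of the central pair).
    """
    ok = scores["pass_count_filter"] & scores["scaled_score"].notna()
    pool = scores[ok]
    rows = []
    for (bait, cond, key), grp in pool.groupby(["bait", "condition", "aa_change_key"],
                                               sort=True):
        n = len(grp)
        if n < min_contrib:
            continue
        rows.append({
            "bait": bait, "condition": cond, "aa_change_key": key,
            "codon_position": grp["codon_position"].iloc[0]
            if grp["codon_position"].notna().all() else pd.NA,
            "variant_class": grp["variant_class"].iloc[0],
            "score": float(grp["scaled_score"].median()),
            "n_contributing": n,
        })
    out = pd.DataFrame(rows, columns=["bait", "condition", "aa_change_key",
                                      "codon_position", "variant_class",
                                      "score", "n_contributing"])
    if len(out):
        out["codon_position"] = out["codon_position"].astype("Int64")
    return out


def generations_from_od(od_start, od_end):
    """Generations in one growth cycle: log2 fold-change in optical density."""
    od_start = np.asarray(od_start, dtype=float)
    od_end = np.asarray(od_end, dtype=float)
    if np.any(od_start <= 0) or np.any(od_end <= 0):
        raise ValueError("optical densities must be positive")
    return np.log2(od_end / od_start)


def selection_coefficient(f_v_start, f_v_end, f_wt_start, f_wt_end, g):
    """Wild-type-relative selection coefficient per generation.

    s = [log2(f_v_end / f_v_start) - log2(f_wt_end / f_wt_start)] / g.
    For multi-cycle competitions, pass frequencies from the first
    pre-selection and final post-selection samples and the summed
    generations of all cycles.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g == 0):
        raise ValueError("generations must be nonzero")
    fv0, fv1 = np.asarray(f_v_start, float), np.asarray(f_v_end, float)
    fw0, fw1 = np.asarray(f_wt_start, float), np.asarray(f_wt_end, float)
    if np.any(fv0 <= 0) or np.any(fv1 <= 0) or np.any(fw0 <= 0) or np.any(fw1 <= 0):
        raise ValueError("frequencies must be positive (apply a pseudocount first)")
    return (np.log2(fv1 / fv0) - np.log2(fw1 / fw0)) / g


def correlate_conditions(aa_scores_a: pd.DataFrame, aa_scores_b: pd.DataFrame):
    """Spearman correlation of per-amino-acid scores over shared keys."""
    a = aa_scores_a.set_index("aa_change_key")["score"]
    b = aa_scores_b.set_index("aa_change_key")["score"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared amino-acid changes")
    rho, _ = stats.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho), int(len(shared))
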