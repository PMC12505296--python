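"""The statistical test cascade applied to replicate-level interaction scores.

Order of operations (idempotent, each step consuming the survivors of the
previous one):

1. count filter (done upstream in scoring);
2. control outliers: each nonsense (resp. silent) variant is compared to
   the pooled scores of all other variants of its class, two-sided
   Mann-Whitney U, unadjusted P < alpha -> removed (and excluded from the
   rescaling anchors, after which the library is rescaled again);
3. control-condition defects: in the no-MTX control, each missense mutant
   is compared to the pooled nonsense scores (two-sided Mann-Whitney,
   Benjamini-Hochberg over missense); mutants *not* significantly
   different from nonsense (adjusted P > alpha) are removed — absence of
   evidence is treated as evidence of a defect, exactly as the screen
   prescribes;
4. abundance exclusion: mutants whose Hog1-bait scores differ from the
   pooled wild-type + silent Hog1 scores (two-sided Mann-Whitney, BH,
   adjusted P < alpha) are excluded from the Sho1 dataset — the Hog1
   interaction does not depend on the SH3-binding motif, so it reads out
   prey abundance;
5. classification: surviving missense mutants are classified against the
   pooled wild-type + silent scores (two-sided Mann-Whitney, BH):
   significantly stronger (positive score), significantly weaker
   (negative score), or not significantly different.

Tests operate on replicate-level scaled scores pooled over synonymous
codons per amino-acid change.  Mann-Whitney p-values are exact (by
enumeration) for small tie-free samples and use the tie-corrected normal
approximation with continuity correction otherwise; FDR correction is
Benjamini-Hochberg throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import scoring

__all__ = [
    "mann_whitney_u",
    "bh_fdr",
    "welch_t_test",
    "student_t_test",
    "flag_control_outliers",
    "flag_control_condition_defects",
    "flag_abundance_mutants",
    "classify_mutants",
    "proliferation_test",
    "run_cascade",
    "CascadeResult",
]

EXACT_MAX_N = 12  # exact Mann-Whitney path for n_x + n_y at or below this, tie-free


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U (rank-sum) test.

    U is computed from rank sums with average ranks for ties.  The p-value
    is exact (full enumeration of labelings) when the samples are small
    (n_x + n_y <= 12) and tie-free, otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Welch's unequal-variance t-test (Welch-Satterthwaite df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def student_t_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Student's pooled-variance t-test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.ttest_ind(x, y, equal_var=True, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Cascade steps (all operate on replicate-level score records)
# --------------------------------------------------------------------------


def _usable(scores: pd.DataFrame) -> pd.DataFrame:
    return scores[scores["pass_count_filter"] & scores["scaled_score"].notna()]


def flag_control_outliers(scores: pd.DataFrame, alpha: float = 0.05,
                          value: str = "scaled_score") -> pd.DataFrame:
    """Nonsense/silent variants that deviate from their own class.

    For each control variant (per bait and condition): its replicate
    scores against the pooled scores of all *other* variants of the same
    class, two-sided Mann-Whitney, unadjusted P < alpha.  Returns a table
    of tests with a ``flagged`` column.  Variants with fewer than 2
    scores, or classes with a single variant, are not tested.
    """
    rows = []
    usable = _usable(scores)
    for (bait, cond), grp in usable.groupby(["bait", "condition"], sort=True):
        for cls in ("nonsense", "silent"):
            sub = grp[grp["variant_class"] == cls]
            ids = sub["variant_id"].unique()
            if len(ids) < 2:
                continue
            for vid in ids:
                mine = sub.loc[sub["variant_id"] == vid, value].to_numpy()
                others = sub.loc[sub["variant_id"] != vid, value].to_numpy()
                if len(mine) < 2 or len(others) == 0:
                    continue
                u, p = mann_whitney_u(mine, others, "two-sided")
                rows.append({"bait": bait, "condition": cond, "variant_id": vid,
                             "variant_class": cls, "test": "control_outlier",
                             "statistic": u, "p": p, "p_adj": np.nan,
                             "flagged": p < alpha})
    return pd.DataFrame(rows, columns=["bait", "condition", "variant_id",
                                       "variant_class", "test", "statistic",
                                       "p", "p_adj", "flagged"])


def flag_control_condition_defects(scores: pd.DataFrame,
                                   control_condition: str = "noMTX",
                                   alpha: float = 0.05,
                                   value: str = "scaled_score") -> pd.DataFrame:
    """Missense mutants indistinguishable from nonsense in the no-MTX control.

    Per missense amino-acid change (pooled codons and replicates, per
    bait): two-sided Mann-Whitney against the pooled nonsense scores of
    the control condition, BH over all missense; an adjusted P *above*
    alpha flags the mutant for removal.
    """
    usable = _usable(scores)
    ctrl = usable[usable["condition"] == control_condition]
    if ctrl.empty:
        raise ValueError(f"no scores for control condition {control_condition!r}")
    rows = []
    for bait, grp in ctrl.groupby("bait", sort=True):
        nonsense = grp.loc[grp["variant_class"] == "nonsense", value].to_numpy()
        if len(nonsense) == 0:
            raise ValueError("control condition has no nonsense scores")
        tests = []
        for key, sub in grp[grp["variant_class"] == "missense"].groupby("aa_change_key"):
            vals = sub[value].to_numpy()
            if len(vals) == 0:
                continue
            u, p = mann_whitney_u(vals, nonsense, "two-sided")
            tests.append((key, u, p))
        if not tests:
            continue
        p_adj = bh_fdr([t[2] for t in tests])
        for (key, u, p), pa in zip(tests, p_adj):
            rows.append({"bait": bait, "aa_change_key": key,
                         "test": "control_condition_defect", "statistic": u,
                         "p": p, "p_adj": pa, "flagged": pa > alpha})
    return pd.DataFrame(rows, columns=["bait", "aa_change_key", "test",
                                       "statistic", "p", "p_adj", "flagged"])


def flag_abundance_mutants(hog1_scores: pd.DataFrame, alpha: float = 0.05,
                           condition: str | None = None,
                           value: str = "scaled_score") -> pd.DataFrame:
    """Mutants whose Hog1 (abundance-control) scores differ from WT + silent.

    Per mutant amino-acid change: replicate-level Hog1 scores against the
    pooled wild-type-identical and silent Hog1 scores, two-sided
    Mann-Whitney, BH across mutants; adjusted P < alpha flags the mutant
    for exclusion from the binding dataset.
    """
    usable = _usable(hog1_scores)
    if condition is not None:
        usable = usable[usable["condition"] == condition]
    pool = usable.loc[usable["variant_class"].isin(scoring.WT_ANCHOR_CLASSES), value]
    if pool.empty:
        raise ValueError("empty wild-type + silent pool in the Hog1 scores")
    pool = pool.to_numpy()
    tests = []
    for key, sub in usable[usable["variant_class"] == "missense"] \
            .groupby("aa_change_key", sort=True):
        vals = sub[value].to_numpy()
        if len(vals) == 0:
            continue
        u, p = mann_whitney_u(vals, pool, "two-sided")
        tests.append((key, u, p))
    if not tests:
        return pd.DataFrame(columns=["aa_change_key", "test", "statistic",
                                     "p", "p_adj", "flagged"])
    p_adj = bh_fdr([t[2] for t in tests])
    return pd.DataFrame(
        [{"aa_change_key": key, "test": "abundance", "statistic": u,
          "p": p, "p_adj": pa, "flagged": pa < alpha}
         for (key, u, p), pa in zip(tests, p_adj)]
    )


def classify_mutants(scores: pd.DataFrame, alpha: float = 0.05,
                     value: str = "scaled_score") -> pd.DataFrame:
    """Stronger / weaker / not-different classification per missense mutant.

    Per (bait, condition) and amino-acid change: replicate-level scores
    against the pooled wild-type + silent scores, two-sided Mann-Whitney,
    BH across mutants; significant mutants are classified by the sign of
    their aggregated (median) score.
    """
    usable = _usable(scores)
    rows = []
    for (bait, cond), grp in usable.groupby(["bait", "condition"], sort=True):
        pool = grp.loc[grp["variant_class"].isin(scoring.WT_ANCHOR_CLASSES), value]
        if pool.empty:
            continue
        pool = pool.to_numpy()
        tests = []
        for key, sub in grp[grp["variant_class"] == "missense"].groupby("aa_change_key"):
            vals = sub[value].to_numpy()
            tests.append((key, *mann_whitney_u(vals, pool, "two-sided"),
                          float(np.median(vals)), len(vals)))
        if not tests:
            continue
        p_adj = bh_fdr([t[2] for t in tests])
        for (key, u, p, med, n), pa in zip(tests, p_adj):
            if pa < alpha and med > 0:
                cls = "stronger"
            elif pa < alpha and med < 0:
                cls = "weaker"
            else:
                cls = "not_different"
            rows.append({"bait": bait, "condition": cond, "aa_change_key": key,
                         "score": med, "n_contributing": n, "statistic": u,
                         "p": p, "p_adj": pa, "classification": cls})
    return pd.DataFrame(rows, columns=["bait", "condition", "aa_change_key",
                                       "score", "n_contributing", "statistic",
                                       "p", "p_adj", "classification"])


def proliferation_test(selection: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Welch's t-test of per-mutant selection coefficients against wild type.

    ``selection`` has columns ``aa_change_key`` and ``s`` (replicate-level
    selection coefficients); the wild-type rows are ``aa_change_key ==
    "WT"``.  BH across mutants, decision at adjusted P < alpha.
    """
    wt = selection.loc[selection["aa_change_key"] == "WT", "s"].to_numpy()
    if len(wt) < 2:
        raise ValueError("need at least 2 wild-type replicates")
    tests = []
    for key, sub in selection[selection["aa_change_key"] != "WT"] \
            .groupby("aa_change_key", sort=True):
        vals = sub["s"].to_numpy()
        if len(vals) < 2:
            continue
        t, p = welch_t_test(vals, wt, "two-sided")
        tests.append((key, t, p))
    if not tests:
        return pd.DataFrame(columns=["aa_change_key", "test", "statistic",
                                     "p", "p_adj", "significant"])
    p_adj = bh_fdr([t[2] for t in tests])
    return pd.DataFrame(
        [{"aa_change_key": key, "test": "proliferation_welch", "statistic": t,
          "p": p, "p_adj": pa, "significant": pa < alpha}
         for (key, t, p), pa in zip(tests, p_adj)]
    )


# --------------------------------------------------------------------------
# Full cascade
# --------------------------------------------------------------------------


@dataclass
class CascadeResult:
    scores: pd.DataFrame            # surviving replicate-level Sho1 scores
    aa_scores: pd.DataFrame         # aggregated + classified per-aa scores
    outlier_flags: pd.DataFrame
    defect_flags: pd.DataFrame
    abundance_flags: pd.DataFrame
    classification: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_cascade(scores: pd.DataFrame, alpha: float = 0.05,
                control_condition: str | None = "noMTX",
                binding_bait: str = "Sho1", abundance_bait: str = "Hog1",
                wt_policy: str = "wt_and_silent",
                min_contrib: int = 3) -> CascadeResult:
    """Run the full filter/classification cascade on replicate score records.

    ``scores`` is the output of :func:`motifdms.scoring.score_counts`
    covering both baits and all conditions present.  Steps that lack their
    inputs (no control condition, no abundance bait) are skipped and noted
    in the summary.
    """
    work = scores.copy()
    summary: dict = {"n_records_in": int(len(work))}

    # 2. control outliers, then re-rescale without the flagged anchors
    flags = flag_control_outliers(work, alpha=alpha)
    flagged_controls = set(flags.loc[flags["flagged"], "variant_id"])
    summary["n_control_outliers"] = len(flagged_controls)
    if flagged_controls:
        work = scoring.rescale_scores(work, wt_policy=wt_policy,
                                      excluded_controls=flagged_controls)
        work = work[~work["variant_id"].isin(flagged_controls)]
    # 3. control-condition defects
    if control_condition is not None and \
            (work["condition"] == control_condition).any():
        defects = flag_control_condition_defects(
            work[work["bait"] == binding_bait], control_condition, alpha=alpha)
        bad_keys = set(defects.loc[defects["flagged"], "aa_change_key"])
    else:
        defects = pd.DataFrame(columns=["bait", "aa_change_key", "test",
                                        "statistic", "p", "p_adj", "flagged"])
        bad_keys = set()
        summary["control_condition_step"] = "skipped (condition absent)"
    summary["n_control_condition_defects"] = len(bad_keys)

    # 4. abundance exclusion via the Hog1 bait; the abundance readout is
    # the Hog1 PCA under MTX selection, so control conditions are not pooled
    hog1 = work[(work["bait"] == abundance_bait) &
                work["condition"].str.startswith("MTX")]
    if len(hog1):
        abundance = flag_abundance_mutants(hog1, alpha=alpha)
        abundance_keys = set(abundance.loc[abundance["flagged"], "aa_change_key"])
    else:
        abundance = pd.DataFrame(columns=["aa_change_key", "test", "statistic",
                                          "p", "p_adj", "flagged"])
        abundance_keys = set()
        summary["abundance_step"] = "skipped (no abundance-control bait)"
    summary["n_abundance_excluded"] = len(abundance_keys)

    removed = bad_keys | abundance_keys
    sho1 = work[(work["bait"] == binding_bait) &
                ~work["aa_change_key"].isin(removed)].reset_index(drop=True)
    summary["n_records_out"] = int(len(sho1))

    # 5. classification of the survivors (MTX conditions)
    mtx = sho1[sho1["condition"].str.startswith("MTX")]
    classification = classify_mutants(mtx, alpha=alpha)
    summary["n_classified"] = int(classification["aa_change_key"].nunique()) \
        if len(classification) else 0
    for cls in ("stronger", "weaker", "not_different"):
        summary[f"n_{cls}"] = int((classification["classification"] == cls).sum()) \
            if len(classification) else 0

    aa = scoring.aggregate_aa(sho1, min_contrib=min_contrib)
    if len(aa) and len(classification):
        aa = aa.merge(
            classification[["bait", "condition", "aa_change_key", "p_adj",
                            "classification"]],
            on=["bait", "condition", "aa_change_key"], how="left",
        )
    return CascadeResult(scores=sho1, aa_scores=aa, outlier_flags=flags,
                         defect_flags=defects, abundance_flags=abundance,
                         classification=classification, summary=summary)
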