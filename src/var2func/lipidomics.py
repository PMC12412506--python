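"""Differential-abundance analysis of targeted lipid concentration matrices.

The workflow mirrors common targeted-lipidomics practice:

* missing concentrations are imputed as one fifth of the lipid's minimum
  observed positive value, then log10-transformed and Pareto-scaled
  (centred, divided by the square root of the standard deviation) for
  multivariate analysis; univariate statistics and fold changes use the
  raw (imputed) concentrations;
* per lipid, the two groups are compared by Welch's t-test when both pass
  the D'Agostino-Pearson normality screen, by Mann-Whitney otherwise; the
  omnibus normality test needs n >= 8 per group, so smaller designs are
  routed to Welch's t with a note;
* the two-stage linear step-up procedure of Benjamini, Krieger and
  Yekutieli (BKY) controls the false discovery rate at level Q (1% by
  default);
* volcano significance combines p < 0.05 with |log2 fold change| > 0.58;
* per-class totals (sum of lipid concentrations within a class per
  sample) are compared by Welch's t-test;
* PLS-DA variable importance in projection (VIP) scores from a NIPALS
  PLS1 fit against the centred group indicator rank discriminant lipids;
  mean squared VIP is 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreprocessResult",
    "preprocess",
    "route_and_test",
    "bky_fdr",
    "differential",
    "class_totals",
    "plsda_vip",
]

# below this per-group n the D'Agostino-Pearson omnibus test is undefined
MIN_N_NORMALITY = 8
VOLCANO_P = 0.05
VOLCANO_LOG2FC = 0.58


@dataclass
class PreprocessResult:
    scaled: pd.DataFrame         # log10 + Pareto-scaled, for multivariate analysis
    imputed: pd.DataFrame        # raw concentrations after imputation
    dropped: list                # all-missing lipids removed
    constant: list               # zero-variance lipids (scaled to 0)


def preprocess(matrix: pd.DataFrame) -> PreprocessResult:
    """Impute, log10-transform, and Pareto-scale a samples x lipids matrix.

    Missing values (NaN) are replaced by 1/5 of the lipid's minimum
    observed positive value. Lipids with no observed positive value are
    dropped with a warning. Pareto scaling divides the centred log10
    values by the square root of the standard deviation; a constant lipid
    (sd = 0) is flagged and scaled to all zeros.
    """
    mat = matrix.astype(float).copy()
    observed_pos = (mat > 0) & mat.notna()
    dropped = [c for c in mat.columns if not observed_pos[c].any()]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} lipid(s) with no positive observation",
                      stacklevel=2)
        mat = mat.drop(columns=dropped)
    fill = mat[mat > 0].min(axis=0) / 5.0
    imputed = mat.fillna(fill)
    logged = np.log10(imputed)
    sd = logged.std(axis=0, ddof=1)
    constant = [c for c in logged.columns if sd[c] == 0 or not np.isfinite(sd[c])]
    centered = logged - logged.mean(axis=0)
    scaled = centered / np.sqrt(sd.replace(0, np.nan))
    scaled[constant] = 0.0
    return PreprocessResult(scaled=scaled, imputed=imputed, dropped=dropped,
                            constant=constant)


def route_and_test(treated, control, normality_alpha: float = 0.05) -> tuple:
    """Normality-routed two-sample test.

    Runs the D'Agostino-Pearson omnibus test on each group (needs
    n >= 8); if both look normal at ``normality_alpha``, compares the
    groups with Welch's t-test, otherwise with the two-sided Mann-Whitney
    test. Groups too small for the normality screen are routed to
    Welch's t.

    Returns
    -------
    (test_used, p) with test_used in {"welch_t", "mann_whitney"}.
    """
    x = np.asarray(treated, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if x.size < MIN_N_NORMALITY or y.size < MIN_N_NORMALITY:
        normal = True  # omnibus test undefined; default route
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (stats.normaltest(x).pvalue > normality_alpha
                      and stats.normaltest(y).pvalue > normality_alpha)
    if normal:
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            p = 1.0 if x.mean() == y.mean() else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        return "welch_t", p
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return "mann_whitney", float(res.pvalue)


def bky_fdr(pvals, q: float = 0.01) -> np.ndarray:
    """Benjamini-Krieger-Yekutieli two-stage linear step-up FDR procedure.

    Stage 1 runs Benjamini-Hochberg at level q' = q/(1+q), giving r1
    rejections. If r1 = 0 nothing is rejected; if r1 = m everything is.
    Otherwise stage 2 reruns BH at level q' * m/(m - r1) and its
    rejections are returned.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)

    def bh_reject(level: float) -> np.ndarray:
        order = np.argsort(p, kind="stable")
        thresh = level * np.arange(1, m + 1) / m
        passed = p[order] <= thresh
        out = np.zeros(m, dtype=bool)
        if passed.any():
            k = int(np.max(np.nonzero(passed)[0]))
            out[order[: k + 1]] = True
        return out

    stage1 = bh_reject(q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return bh_reject(q1 * m / (m - r1))


def differential(matrix: pd.DataFrame, groups, class_map, q: float = 0.01,
                 volcano_p: float = VOLCANO_P,
                 volcano_log2fc: float = VOLCANO_LOG2FC) -> pd.DataFrame:
    """Per-lipid differential abundance between two groups.

    Parameters
    ----------
    matrix : samples x lipids raw concentrations (missing allowed).
    groups : sample -> group label mapping/Series with exactly two levels;
        the first level in sorted order is treated as control, the other
        as treated, unless the labels are ("treated", "control")-like —
        pass an ordered pd.Categorical to control direction explicitly.
    class_map : lipid -> class mapping/Series.

    Fold changes are log2(mean treated / mean control) on raw imputed
    concentrations; p-values come from the normality-routed test; BKY
    rejection flags are at level ``q`` and volcano significance combines
    the raw p and fold-change thresholds.
    """
    groups = pd.Series(groups)
    levels = _two_levels(groups)
    control_label, treated_label = levels
    class_map = pd.Series(class_map)
    missing = [c for c in matrix.columns if c not in class_map.index]
    if missing:
        raise ValueError(f"{len(missing)} lipid(s) missing from the class map, "
                         f"e.g. {missing[0]!r}")
    prep = preprocess(matrix)
    imputed = prep.imputed
    t_idx = groups.index[groups == treated_label]
    c_idx = groups.index[groups == control_label]
    rows = []
    for lipid in imputed.columns:
        treated = imputed.loc[t_idx, lipid].to_numpy()
        control = imputed.loc[c_idx, lipid].to_numpy()
        log2fc = float(np.log2(treated.mean() / control.mean()))
        test_used, p = route_and_test(treated, control)
        rows.append({"lipid": lipid, "class": class_map[lipid],
                     "log2fc": log2fc, "test_used": test_used, "p": p})
    out = pd.DataFrame(rows)
    out["bky_reject"] = bky_fdr(out["p"].to_numpy(), q=q)
    out["volcano_sig"] = (out["p"] < volcano_p) & (out["log2fc"].abs() > volcano_log2fc)
    return out


def _two_levels(groups: pd.Series) -> tuple:
    """(control, treated) labels; categorical order wins, else sorted order."""
    if isinstance(groups.dtype, pd.CategoricalDtype):
        levels = list(groups.cat.categories)
    else:
        levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if (groups == levels[0]).sum() < 2 or (groups == levels[1]).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    return levels[0], levels[1]


def class_totals(matrix: pd.DataFrame, groups, class_map) -> pd.DataFrame:
    """Per-class concentration totals compared between groups.

    Sums the (imputed) concentrations of each class's lipids per sample
    and compares the per-sample class totals between the two groups with
    a two-tailed Welch t-test; reports mean and SD per group. A class
    holding a single lipid is still summed (the sum is the value itself).
    """
    groups = pd.Series(groups)
    control_label, treated_label = _two_levels(groups)
    class_map = pd.Series(class_map)
    imputed = preprocess(matrix).imputed
    rows = []
    for cls in sorted(class_map.unique()):
        lipids = [c for c in imputed.columns if class_map.get(c) == cls]
        if not lipids:
            continue
        sums = imputed[lipids].sum(axis=1)
        treated = sums[groups == treated_label].to_numpy()
        control = sums[groups == control_label].to_numpy()
        p = float(stats.ttest_ind(treated, control, equal_var=False).pvalue)
        rows.append({"class": cls, "n_lipids": len(lipids),
                     "mean_treated": treated.mean(), "sd_treated": treated.std(ddof=1),
                     "mean_control": control.mean(), "sd_control": control.std(ddof=1),
                     "p": p})
    return pd.DataFrame(rows)


def plsda_vip(preprocessed: pd.DataFrame, groups, n_components: int = 2) -> pd.DataFrame:
    """PLS-DA variable importance in projection via NIPALS PLS1.

    Fits a PLS1 model of the centred binary group indicator on the
    preprocessed matrix and computes per-lipid VIP scores

        VIP_j = sqrt( p * sum_a SSY_a * w_aj^2 / sum_a SSY_a )

    with unit-norm weight vectors w_a and SSY_a the y-variance explained
    by component a; mean(VIP^2) = 1 holds by construction. Requested
    components beyond the usable rank are reduced with a warning.
    """
    groups = pd.Series(groups)
    control_label, treated_label = _two_levels(groups)
    x = preprocessed.to_numpy(dtype=float).copy()
    y = (groups.loc[preprocessed.index] == treated_label).to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    y = y - y.mean()
    n, n_feat = x.shape
    max_rank = min(n - 1, n_feat)
    if n_components > max_rank:
        warnings.warn(f"n_components reduced from {n_components} to {max_rank}",
                      stacklevel=2)
        n_components = max_rank
    weights, ssy = [], []
    for _ in range(n_components):
        xy = x.T @ y
        norm = np.linalg.norm(xy)
        if norm < 1e-12:
            break
        w = xy / norm
        t = x @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p_load = x.T @ t / tt
        q_load = y @ t / tt
        x = x - np.outer(t, p_load)
        y = y - q_load * t
        weights.append(w)
        ssy.append(q_load**2 * tt)
    if not weights:
        raise ValueError("PLS found no usable component (constant input?)")
    w_mat = np.array(weights)            # (A, p), rows unit norm
    ssy_arr = np.array(ssy)
    vip = np.sqrt(n_feat * (ssy_arr[:, None] * w_mat**2).sum(axis=0) / ssy_arr.sum())
    return pd.DataFrame({"lipid": preprocessed.columns, "vip": vip,
                         "n_components": len(weights)})
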