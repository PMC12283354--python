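"""Differential metabolites per glucose-status subgroup, odds ratios, overlaps,
proportion tests, repeated-measures response tests and response clustering.

Differential calling uses two-sided Wilcoxon rank-sum tests per metabolite
(exact P for small tie-free samples, midrank normal approximation with
continuity correction otherwise) against the NGT controls, with Storey
q-values gated at q < 0.1.  A metabolite is a *consistent* signature when it
passes the gate with the same direction in both a discovery and a validation
cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .ev import compute_qvalues
from .synthgen import GLUCOSE_GROUPS, SampleMetadata

Q_GATE = 0.1  # adjusted-significance gate used throughout


# ---------------------------------------------------------------------------
# differential metabolites
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b) -> tuple[float, float, int]:
    """Two-sided rank-sum test; returns (W statistic, p, direction).

    Exact enumeration when the pooled sample is tie-free and n <= 25;
    otherwise the midrank normal approximation with tie-corrected variance
    and continuity correction.  Direction is the sign of the median
    difference of ``a`` relative to ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    direction = int(np.sign(np.median(a) - np.median(b)))
    # rank-sum W of the first sample = U + n_a(n_a+1)/2
    w = float(res.statistic + len(a) * (len(a) + 1) / 2)
    return w, float(res.pvalue), direction


@dataclass
class DifferentialResult:
    metabolite_id: str
    comparison: str
    statistic: float
    effect_direction: int
    p: float
    q: float = float("nan")


def differential_metabolites(
    metab: pd.DataFrame, meta: SampleMetadata, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Per-metabolite rank-sum tests for one group-vs-control contrast.

    ``contrast`` is (case group, control group), e.g. ("T2D", "NGT").
    Returns a tidy frame with statistic, direction, p and q (q over the
    metabolites of this contrast); significance gate is q < 0.1.
    """
    case, ctrl = contrast
    for g in contrast:
        if g not in GLUCOSE_GROUPS:
            raise ValueError(f"unknown group {g!r}")
    groups = meta.table["group"]
    idx_case = groups[groups == case].index
    idx_ctrl = groups[groups == ctrl].index
    if len(idx_case) < 3 or len(idx_ctrl) < 3:
        raise ValueError("both groups need at least 3 samples")
    rows = []
    for met in metab.columns:
        w, p, d = wilcoxon_rank_sum(metab.loc[idx_case, met], metab.loc[idx_ctrl, met])
        rows.append((met, f"{case}_vs_{ctrl}", w, d, p))
    df = pd.DataFrame(
        rows, columns=["metabolite_id", "comparison", "statistic", "effect_direction", "p"]
    )
    df["q"] = compute_qvalues(df["p"].to_numpy())[0]
    df["significant"] = df["q"] < Q_GATE
    return df


def consistent_signatures(discovery: pd.DataFrame, validation: pd.DataFrame) -> pd.DataFrame:
    """Metabolites significant with the same direction in both cohorts."""
    m = discovery.merge(
        validation, on=["metabolite_id", "comparison"], suffixes=("_disc", "_val")
    )
    keep = (
        m["significant_disc"]
        & m["significant_val"]
        & (m["effect_direction_disc"] == m["effect_direction_val"])
        & (m["effect_direction_disc"] != 0)
    )
    return m.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# adjusted odds ratios
# ---------------------------------------------------------------------------

@dataclass
class ORResult:
    metabolite_id: str
    outcome: str
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    separation: bool = False


def adjusted_odds_ratio(
    y, metabolite, age=None, sex=None, metabolite_id: str = "", outcome: str = ""
) -> ORResult:
    """Logistic OR per SD of metabolite, adjusted for age and sex.

    With ``age``/``sex`` omitted the fit is metabolite-only.  Perfect
    separation is flagged and the CI reported unbounded.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(y, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 5:
        raise ValueError("y must be binary with both classes >= 5")
    cols = [np.asarray(metabolite, dtype=float)]
    for cov in (age, sex):
        if cov is not None:
            cols.append(np.asarray(cov, dtype=float))
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (duplicated covariate?)")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y == classes[1], X).fit(disp=0, maxiter=200)
            beta = fit.params[1]
            se = fit.bse[1]
            p = fit.pvalues[1]
            if not np.isfinite(se) or se > 50:
                raise PerfectSeparationWarning("huge SE")
        except (PerfectSeparationWarning, np.linalg.LinAlgError, Exception) as exc:
            if isinstance(exc, ValueError):
                raise
            return ORResult(metabolite_id, outcome, float("nan"), 0.0, float("inf"), float("nan"), True)
    return ORResult(
        metabolite_id,
        outcome,
        float(np.exp(beta)),
        float(np.exp(beta - 1.959963984540054 * se)),
        float(np.exp(beta + 1.959963984540054 * se)),
        float(p),
    )


# ---------------------------------------------------------------------------
# overlaps and proportions
# ---------------------------------------------------------------------------

def overlap_summary(sets: dict[str, set]) -> pd.DataFrame:
    """Exact membership counts per intersection region of named sets.

    Regions are encoded by the subset of set names a member belongs to;
    every non-empty region is listed with its count and members.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], list] = {}
    for x in universe:
        key = tuple(n for n in names if x in sets[n])
        regions.setdefault(key, []).append(x)
    rows = [
        {"region": "&".join(key), "count": len(v), "members": sorted(map(str, v))}
        for key, v in sorted(regions.items())
    ]
    return pd.DataFrame(rows)


def proportion_test(counts) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) on an r x k table."""
    table = np.asarray(counts, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# repeated measures
# ---------------------------------------------------------------------------

def repeated_measures_anova(values) -> tuple[float, tuple[int, int], float]:
    """Within-subject one-way ANOVA on a subjects x timepoints matrix.

    F = MS_time / MS_error after removing subject effects;
    df = (t-1), (t-1)(s-1).  Rows with missing cells are dropped (complete-
    case) with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a subjects x timepoints matrix")
    if np.isnan(v).any():
        keep = ~np.isnan(v).any(axis=1)
        warnings.warn(
            f"dropping {int((~keep).sum())} subject(s) with missing cells", stacklevel=2
        )
        v = v[keep]
    s, t = v.shape
    if s < 3 or t < 2:
        raise ValueError("need >= 3 complete subjects and >= 2 timepoints")
    grand = v.mean()
    ss_time = s * ((v.mean(axis=0) - grand) ** 2).sum()
    ss_subj = t * ((v.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((v - grand) ** 2).sum()
    ss_err = ss_tot - ss_time - ss_subj
    df_time = t - 1
    df_err = (t - 1) * (s - 1)
    ms_time = ss_time / df_time
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return 0.0, (df_time, df_err), 1.0
    f = ms_time / ms_err
    p = float(stats.f.sf(f, df_time, df_err))
    return float(f), (df_time, df_err), p


# ---------------------------------------------------------------------------
# response clustering
# ---------------------------------------------------------------------------

def cluster_responses(effects: pd.DataFrame, k: int = 8) -> pd.Series:
    """Agglomerative (Ward, Euclidean) clustering of metabolite response codes.

    ``effects`` is a metabolite x descriptor matrix of signed significance
    codes and reversal flags; the tree is cut at ``k`` clusters (reduced
    with a warning if fewer distinct rows exist).  Deterministic and
    invariant to row order.
    """
    if effects.isna().any().any():
        raise ValueError("descriptor matrix may not contain missing values")
    x = effects.to_numpy(dtype=float)
    n_distinct = len(np.unique(x, axis=0))
    if k > n_distinct:
        warnings.warn(f"k reduced from {k} to {n_distinct} distinct rows", stacklevel=2)
        k = n_distinct
    # sort rows lexicographically so labels do not depend on input order
    order = np.lexsort(x.T[::-1])
    z = linkage(x[order], method="ward", metric="euclidean")
    labels_sorted = fcluster(z, t=k, criterion="maxclust")
    labels = np.empty(len(x), dtype=int)
    labels[order] = labels_sorted
    return pd.Series(labels, index=effects.index, name="cluster")
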