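"""Out-of-sample explained variance of metabolites from grouped feature sets.

For every (metabolite, feature group) pair a gradient-boosted decision-tree
(GBDT) model is evaluated with k-fold cross-validation; the explained
variance (EV) is the out-of-sample coefficient of determination
R2 = 1 - SSE/SST on the pooled out-of-fold predictions (it may be negative).
Inference combines two resampling devices:

* a pairs bootstrap (B iterations, whole samples resampled with
  replacement) gives the percentile 95% CI.  CV folds inside a resample
  partition *unique* sample ids, so a duplicated sample never sits in a
  training and a test fold at once -- without this the bootstrap R2
  distribution is optimistically shifted and its CI misses the point
  estimate almost surely.
* a Wald z-score against an empirical null: the same CV pipeline is run on
  M label permutations, and z = (R2_point - mean_perm) / sd_perm with a
  two-sided normal P.  Out-of-sample R2 has a strictly negative expectation
  under independence (the model's prediction variance is pure loss), so the
  naive z = R2/SD is not centred; permutation centring restores nominal
  type-I error while keeping the test a Wald-style z-ratio.

Storey q-values (smoother pi0 estimate, BH fallback at pi0 = 1) gate
significance at q < 0.1 throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .dataio import MetaboliteMatrix
from .synthgen import GROUPS, FeatureBundle


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GBDTSpec:
    """Hyperparameter search space for the per-fold random search.

    ``n_search`` random draws are evaluated on an inner 75/25 split of each
    training fold and the best (inner MSE) is refit on the full training
    fold.  ``fast()`` is a fixed single weak configuration used inside
    large resampling simulations where the search would dominate runtime.
    """

    n_search: int = 10
    num_boost_round: int = 100
    depth_range: tuple[int, int] = (3, 8)
    leaves_range: tuple[int, int] = (8, 64)
    lr_range: tuple[float, float] = (0.01, 0.2)
    feature_fraction_range: tuple[float, float] = (0.5, 1.0)
    min_child_samples: int = 20
    fixed_params: dict | None = None

    @staticmethod
    def fast() -> "GBDTSpec":
        return GBDTSpec(
            n_search=1,
            num_boost_round=12,
            fixed_params={
                "num_leaves": 4,
                "learning_rate": 0.25,
                "max_depth": 3,
                "max_bin": 15,
            },
        )

    def draw(self, rng: np.random.Generator) -> dict:
        if self.fixed_params is not None:
            return dict(self.fixed_params)
        depth = int(rng.integers(self.depth_range[0], self.depth_range[1] + 1))
        leaves = int(rng.integers(self.leaves_range[0], self.leaves_range[1] + 1))
        leaves = min(leaves, 2**depth)
        lr = float(np.exp(rng.uniform(np.log(self.lr_range[0]), np.log(self.lr_range[1]))))
        ff = float(rng.uniform(*self.feature_fraction_range))
        return {
            "max_depth": depth,
            "num_leaves": leaves,
            "learning_rate": lr,
            "feature_fraction": ff,
        }


def _train(X, y, params, rounds, seed):
    full = {
        "objective": "regression",
        "verbosity": -1,
        "num_threads": 1,
        "min_child_samples": 20,
        "seed": seed,
        **params,
    }
    ds = lgb.Dataset(np.asarray(X), label=np.asarray(y), free_raw_data=False,
                     params={"verbosity": -1})
    return lgb.train(full, ds, num_boost_round=rounds)


def fit_gbdt(X, y, spec: GBDTSpec | None = None, seed: int = 0):
    """Fit one GBDT on all rows (random search via an inner 75/25 split)."""
    spec = spec or GBDTSpec()
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    params = _search_params(X, y, spec, rng)
    return _train(X, y, params, spec.num_boost_round, int(rng.integers(2**31)))


def _search_params(X, y, spec: GBDTSpec, rng: np.random.Generator) -> dict:
    if spec.n_search <= 1:
        return spec.draw(rng)
    n = len(y)
    perm = rng.permutation(n)
    cut = max(int(n * 0.75), 1)
    tr, va = perm[:cut], perm[cut:]
    if len(va) == 0:
        return spec.draw(rng)
    best, best_mse = None, np.inf
    for _ in range(spec.n_search):
        cand = spec.draw(rng)
        booster = _train(X[tr], y[tr], cand, spec.num_boost_round, int(rng.integers(2**31)))
        mse = float(np.mean((y[va] - booster.predict(X[va])) ** 2))
        if mse < best_mse:
            best, best_mse = cand, mse
    return best


# ---------------------------------------------------------------------------
# out-of-fold prediction and EV
# ---------------------------------------------------------------------------

def _fold_assignment(groups: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per row such that folds partition the *unique* group labels."""
    uniq = np.unique(groups)
    if len(uniq) < k:
        raise ValueError(f"need at least {k} distinct samples for {k} folds")
    perm = rng.permutation(len(uniq))
    fold_of_uniq = np.empty(len(uniq), dtype=int)
    for fi, chunk in enumerate(np.array_split(perm, k)):
        fold_of_uniq[chunk] = fi
    return fold_of_uniq[np.searchsorted(uniq, groups)]


def oof_predict(
    X,
    y,
    k: int = 5,
    spec: GBDTSpec | None = None,
    seed: int = 0,
    groups: np.ndarray | None = None,
    n_repeats: int = 1,
) -> np.ndarray:
    """Out-of-fold GBDT predictions: every sample predicted exactly once
    per repeat by a model not trained on it.

    ``groups`` (default: row index) defines the unit the folds partition;
    bootstrap callers pass the resampled original indices so duplicates
    travel together.  With ``n_repeats`` > 1 the CV is repeated with fresh
    fold splits and the out-of-fold predictions averaged, shrinking the
    model-variance penalty of the downstream R2.  Deterministic given
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per element of y")
    n = len(y)
    if n < 2 * k and k != n:  # k == n is leave-one-out
        raise ValueError(f"need n >= 2k (= {2 * k}) samples, got {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed in X or y")
    spec = spec or GBDTSpec()
    rng = np.random.default_rng(seed)
    if np.ptp(y) == 0:
        warnings.warn("constant target: returning constant predictions", stacklevel=2)
        return np.full(n, y[0])
    if groups is None:
        groups = np.arange(n)
    total = np.zeros(n)
    for _ in range(n_repeats):
        fold = _fold_assignment(np.asarray(groups), k, rng)
        pred = np.empty(n)
        for fi in range(k):
            te = fold == fi
            tr = ~te
            params = _search_params(X[tr], y[tr], spec, rng)
            booster = _train(X[tr], y[tr], params, spec.num_boost_round, int(rng.integers(2**31)))
            pred[te] = booster.predict(X[te])
        total += pred
    return total / n_repeats


def explained_variance(y, yhat) -> float:
    """R2 = 1 - SSE/SST of predictions against observations (may be negative)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat) or len(y) < 3:
        raise ValueError("y and yhat must have equal length >= 3")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("entries must be finite")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


@dataclass
class EVResult:
    """Per-(metabolite, group) explained variance with bootstrap CI and Wald P."""

    metabolite_id: str
    feature_group: str
    r2: float
    ci_low: float
    ci_high: float
    p: float
    q: float | None = None
    n_boot: int = 0
    boot_r2: np.ndarray = field(default=None, repr=False)
    null_mean: float = float("nan")
    null_sd: float = float("nan")


def ev_bootstrap(
    X,
    y,
    B: int = 1000,
    k: int = 5,
    spec: GBDTSpec | None = None,
    seed: int = 0,
    n_perm: int = 10,
    metabolite_id: str = "",
    feature_group: str = "",
) -> EVResult:
    """Point EV with bootstrap percentile CI and permutation-centred Wald P."""
    if B < 50:
        warnings.warn(f"B = {B} bootstrap iterations give an unstable SE", stacklevel=2)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    spec = spec or GBDTSpec()
    rng = np.random.default_rng(seed)
    n = len(y)
    point = explained_variance(y, oof_predict(X, y, k, spec, int(rng.integers(2**31))))
    boot = np.empty(B)
    for b in range(B):
        s = rng.integers(0, n, n)
        pred = oof_predict(X[s], y[s], k, spec, int(rng.integers(2**31)), groups=s)
        boot[b] = explained_variance(y[s], pred)
    perm = np.empty(n_perm)
    for m in range(n_perm):
        yp = y[rng.permutation(n)]
        perm[m] = explained_variance(yp, oof_predict(X, yp, k, spec, int(rng.integers(2**31))))
    null_mean = float(perm.mean())
    null_sd = float(perm.std(ddof=1))
    if null_sd == 0:
        p = 1.0
    else:
        # under the null the point statistic and the M permutation statistics
        # are iid, so (point - mean)/sd follows sqrt(1 + 1/M) * t_{M-1}
        z = (point - null_mean) / (null_sd * np.sqrt(1 + 1 / n_perm))
        p = float(2 * stats.t.sf(abs(z), df=n_perm - 1))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return EVResult(
        metabolite_id,
        feature_group,
        float(point),
        float(lo),
        float(hi),
        p,
        n_boot=B,
        boot_r2=boot,
        null_mean=null_mean,
        null_sd=null_sd,
    )


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def compute_qvalues(p, pi0: float | None = None) -> tuple[np.ndarray, dict]:
    """Storey q-values with the smoother pi0 estimate.

    pi0 is estimated by fitting a cubic smoothing spline to
    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over lambda = 0.05..0.95
    and taking the value at the largest lambda; when the estimate falls
    outside (0, 1] the computation falls back to pi0 = 1 (then q-values
    equal Benjamini-Hochberg) and sets ``info['pi0_fallback']``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), {"pi0": 1.0, "pi0_fallback": False}
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    info = {"pi0_fallback": False}
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
        if m < 100 or pi0_lam.max() == 0:
            pi0 = 1.0
            info["pi0_fallback"] = True
        else:
            spl = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(spl(lam[-1]))
            if not 0 < pi0 <= 1:
                pi0 = 1.0
                info["pi0_fallback"] = True
    info["pi0"] = pi0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0, 1)
    out = np.empty(m)
    out[order] = q
    return out, info


# ---------------------------------------------------------------------------
# whole-metabolome relative predictive power
# ---------------------------------------------------------------------------

@dataclass
class RelativePowerResult:
    """Share of full-model explained variance per feature group."""

    shares: dict[str, float]
    raw_weighted_ev: dict[str, float]
    component_ev: pd.DataFrame
    n_components: int
    uninformative: bool = False


def assemble_design(bundle: FeatureBundle) -> dict[str, np.ndarray]:
    """Per-group predictor matrices the GBDT models consume.

    Clinical values are used as-is, microbiome abundances are
    log10(x + 1e-6), diet codes are mode-imputed.  'full' concatenates the
    three groups.
    """
    from .dataio import filter_diet, transform_microbiome

    mats = {
        "clinical": bundle.clinical.to_numpy(dtype=float),
        "microbiome": transform_microbiome(bundle.microbiome).to_numpy(),
        "diet": filter_diet(bundle.diet).to_numpy(dtype=float),
    }
    mats["full"] = np.hstack([mats[g] for g in GROUPS])
    return mats


def relative_power(
    bundle: FeatureBundle,
    metabolites: MetaboliteMatrix,
    n_components: int | None = None,
    k: int = 5,
    spec: GBDTSpec | None = None,
    seed: int = 0,
    variance_target: float = 0.8,
    max_components: int = 20,
) -> RelativePowerResult:
    """Relative predictive power of the three groups over the metabolome.

    Principal components of the (preprocessed) metabolite matrix are each
    predicted from every group and from all features; a group's share is the
    eigenvalue-weighted mean of max(EV, 0) divided by the full model's, then
    normalized so the three group shares sum to 1.  When the full model
    explains essentially nothing the result is flagged uninformative.
    """
    if metabolites.state != "preprocessed":
        raise ValueError("relative_power expects a preprocessed metabolite matrix")
    vals = metabolites.values.to_numpy()
    n, q = vals.shape
    rank = min(n - 1, q)
    if n_components is None:
        # smallest count explaining >= variance_target of metabolome variance
        u, s, vt = np.linalg.svd(vals - vals.mean(axis=0), full_matrices=False)
        frac = np.cumsum(s**2) / np.sum(s**2)
        n_components = int(np.searchsorted(frac, variance_target) + 1)
        n_components = min(n_components, max_components)
    if n_components > rank:
        warnings.warn(f"n_components reduced to rank {rank}", stacklevel=2)
        n_components = rank
    centered = vals - vals.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    eigvals = (s[:n_components] ** 2) / (n - 1)

    mats = assemble_design(bundle)
    rng = np.random.default_rng(seed)
    spec = spec or GBDTSpec()
    ev = {}
    for gname in (*GROUPS, "full"):
        evs = []
        for c in range(n_components):
            pred = oof_predict(mats[gname], scores[:, c], k, spec, int(rng.integers(2**31)))
            evs.append(explained_variance(scores[:, c], pred))
        ev[gname] = np.array(evs)
    component_ev = pd.DataFrame(ev, index=[f"PC{c + 1}" for c in range(n_components)])

    w = eigvals / eigvals.sum()
    weighted = {g: float(np.sum(w * np.maximum(ev[g], 0))) for g in (*GROUPS, "full")}
    if weighted["full"] < 1e-3:
        return RelativePowerResult(
            {g: float("nan") for g in GROUPS}, weighted, component_ev, n_components, True
        )
    raw_shares = {g: weighted[g] / weighted["full"] for g in GROUPS}
    tot = sum(raw_shares.values())
    shares = {g: raw_shares[g] / tot for g in GROUPS} if tot > 0 else raw_shares
    return RelativePowerResult(shares, weighted, component_ev, n_components, False)


# ---------------------------------------------------------------------------
# cross-cohort replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationComparison:
    """EV-vs-EV regression across two cohorts with Cook's-distance outliers."""

    slope: float
    intercept: float
    pearson_r: float
    pearson_p: float
    cooks_d: np.ndarray
    outliers: np.ndarray  # boolean flags
    factor: float


def replication_compare(ev_a, ev_b, factor: float = 3.0) -> ReplicationComparison:
    """OLS of cohort-B EV on cohort-A EV; flag points whose Cook's distance
    exceeds ``factor`` times the mean Cook's distance."""
    import statsmodels.api as sm

    a = np.asarray(ev_a, dtype=float)
    b = np.asarray(ev_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired EV vectors must have equal length")
    if len(a) < 10:
        raise ValueError("need at least 10 paired points")
    model = sm.OLS(b, sm.add_constant(a)).fit()
    if model.ssr < 1e-14 * max(np.sum(b**2), 1.0):  # exact fit: no influence
        cooks = np.zeros(len(a))
    else:
        cooks = model.get_influence().cooks_distance[0]
    mean_d = cooks.mean()
    if np.isinf(factor):
        flags = np.zeros(len(a), dtype=bool)
    else:
        flags = cooks > factor * mean_d
    r, rp = stats.pearsonr(a, b)
    return ReplicationComparison(
        float(model.params[1]),
        float(model.params[0]),
        float(r),
        float(rp),
        cooks,
        flags,
        factor,
    )


# ---------------------------------------------------------------------------
# convenience: EV table over many metabolites
# ---------------------------------------------------------------------------

def ev_table(
    bundle: FeatureBundle,
    metabolites: MetaboliteMatrix,
    groups=GROUPS,
    B: int = 1000,
    k: int = 5,
    spec: GBDTSpec | None = None,
    seed: int = 0,
    n_perm: int = 10,
) -> pd.DataFrame:
    """EV + CI + Wald P + q for every (metabolite, group); tidy dataframe."""
    mats = assemble_design(bundle)
    rng = np.random.default_rng(seed)
    rows = []
    for gname in groups:
        for met in metabolites.metabolite_ids:
            res = ev_bootstrap(
                mats[gname],
                metabolites.values[met].to_numpy(),
                B=B,
                k=k,
                spec=spec,
                seed=int(rng.integers(2**31)),
                n_perm=n_perm,
                metabolite_id=met,
                feature_group=gname,
            )
            rows.append(res)
    df = pd.DataFrame(
        {
            "metabolite_id": [r.metabolite_id for r in rows],
            "group": [r.feature_group for r in rows],
            "r2": [r.r2 for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p": [r.p for r in rows],
        }
    )
    df["q"] = np.nan
    for gname in groups:
        mask = df["group"] == gname
        df.loc[mask, "q"] = compute_qvalues(df.loc[mask, "p"].to_numpy())[0]
    return df
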