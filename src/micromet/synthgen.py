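"""Synthetic cohorts with the statistical structure of a microbiome-metabolome study.

Real studies of this kind pair zero-inflated compositional metagenomic-species
(MGS) abundance tables with continuous clinical biomarkers, ordinal
food-frequency-questionnaire (FFQ) items and a plasma metabolite matrix.
Those data are controlled-access, so every downstream stage in this package is
exercised on cohorts drawn here, which carry a machine-readable ground-truth
sidecar: planted per-group explained-variance fractions for each metabolite,
planted mediation triplets with their analytic proportion mediated, and
planted group-wise metabolite shifts.

The generator is deterministic under its seed, and the ground truth is written
as a separate JSON sidecar that analysis stages never read (only tests do).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("clinical", "microbiome", "diet")
#: Glucose-status strata: normal tolerance, impaired fasting glucose, impaired
#: glucose tolerance, combined glucose intolerance, type 2 diabetes.
GLUCOSE_GROUPS = ("NGT", "IFG", "IGT", "CGI", "T2D")
#: Default stratum proportions mirroring a discovery cohort of 697
#: (220/185/173/74/45).
DEFAULT_GROUP_PROPS = (220 / 697, 185 / 697, 173 / 697, 74 / 697, 45 / 697)

DIET_CODE_MAX = 8  # ordinal FFQ frequency codes 0..8


@dataclass
class FeatureBundle:
    """The three grouped design matrices sharing one sample index.

    ``clinical`` is continuous (first columns are age / sex / BMI copies),
    ``microbiome`` holds relative abundances (rows sum to 1, zero-inflated)
    and ``diet`` holds ordinal frequency codes with missing cells (NaN).
    """

    sample_ids: list[str]
    clinical: pd.DataFrame
    microbiome: pd.DataFrame
    diet: pd.DataFrame
    diet_missing_frac: pd.Series = field(default=None)

    def __post_init__(self):
        for tab in (self.clinical, self.microbiome, self.diet):
            if list(tab.index) != list(self.sample_ids):
                raise ValueError("feature tables must share sample_ids and row order")
        row_sums = self.microbiome.to_numpy().sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("microbiome rows must sum to 1")
        if (self.microbiome.to_numpy() < 0).any():
            raise ValueError("microbiome entries must be non-negative")
        if self.diet_missing_frac is None:
            self.diet_missing_frac = self.diet.isna().mean()

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def group(self, name: str) -> pd.DataFrame:
        if name not in GROUPS:
            raise KeyError(f"unknown feature group {name!r}")
        return getattr(self, name)


@dataclass
class SampleMetadata:
    """Per-sample covariates: age (years), sex (0/1), BMI (kg/m2), glucose group."""

    table: pd.DataFrame  # columns: age, sex, bmi, group (and optional risk_score)

    def __post_init__(self):
        t = self.table
        bad = set(t["group"]) - set(GLUCOSE_GROUPS)
        if bad:
            raise ValueError(f"unknown glucose-status labels: {sorted(bad)}")
        if not (np.isfinite(t["age"]).all() and (t["age"] > 0).all()):
            raise ValueError("age must be finite and positive")
        if not (np.isfinite(t["bmi"]).all() and (t["bmi"] > 0).all()):
            raise ValueError("bmi must be finite and positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class MetaboliteSignal:
    """Planted target explained-variance fraction per feature group for one metabolite."""

    clinical: float = 0.0
    microbiome: float = 0.0
    diet: float = 0.0
    linear: bool = True
    n_active: int = 5
    #: optional group -> explicit active feature indices (e.g. to plant a
    #: keystone MGS driving many metabolites)
    active: dict | None = None

    def targets(self) -> dict[str, float]:
        return {"clinical": self.clinical, "microbiome": self.microbiome, "diet": self.diet}


@dataclass
class GroundTruth:
    """Machine-readable truth channel for parameter-recovery tests.

    ``signal_fractions`` maps metabolite -> group -> target EV in [0, 1];
    ``generators`` stores the frozen generating predictors (feature indices,
    weights and the standardization constants of the generating bundle) so an
    oracle prediction can be evaluated on fresh draws; ``mediation`` stores
    (a, b, c_prime, proportion) per planted triplet; ``differential`` stores
    planted group-wise shifts on the standardized scale.
    """

    seed: int
    signal_fractions: dict = field(default_factory=dict)
    generators: dict = field(default_factory=dict)
    mediation: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)

    def __post_init__(self):
        for met, fr in self.signal_fractions.items():
            if sum(fr.values()) > 1 + 1e-9:
                raise ValueError(f"planted fractions for {met} sum above 1")

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=_default, indent=1, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# feature bundle
# ---------------------------------------------------------------------------

def gen_feature_bundle(
    n: int,
    p_c: int = 20,
    p_m: int = 50,
    p_d: int = 30,
    zero_inflation: float = 0.3,
    diet_missing: float = 0.05,
    n_latent: int = 5,
    seed: int = 0,
) -> FeatureBundle:
    """Draw a cohort's clinical / microbiome / diet design matrices.

    The microbiome table is generated as exponentiated correlated Gaussians
    (log-normal marginals with a rank-``n_latent`` correlation structure),
    multiplicative zero-inflation applied *before* closure to the simplex.
    Diet columns are ordinal codes 0..8 with missing-completely-at-random
    cells; clinical columns are continuous with age/sex/BMI as the first
    three columns.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    if min(p_c, p_m, p_d) < 1:
        raise ValueError("group sizes must be positive")
    if not 0 <= zero_inflation < 1:
        raise ValueError("zero_inflation must lie in [0, 1); 1 is degenerate")
    rng = _rng(seed)
    ids = [f"S{i:05d}" for i in range(n)]

    # clinical: age/sex/bmi plus correlated lab values
    age = rng.uniform(50, 64, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(27.0, 4.0, n).clip(16, 55)
    latent_c = rng.normal(size=(n, 3))
    labs = latent_c @ rng.normal(size=(3, max(p_c - 3, 1))) * 0.6 + rng.normal(
        size=(n, max(p_c - 3, 1))
    )
    clin = np.column_stack([age, sex, bmi, labs])[:, :p_c]
    clin_cols = (["age", "sex", "bmi"] + [f"clin_{j:03d}" for j in range(max(p_c - 3, 0))])[:p_c]
    clinical = pd.DataFrame(clin, index=ids, columns=clin_cols)

    # microbiome: low-rank log-normal, zero-inflation, closure
    load = rng.normal(size=(n_latent, p_m)) * 0.8
    z = rng.normal(size=(n, n_latent)) @ load + rng.normal(size=(n, p_m))
    scale = rng.normal(0.0, 1.5, p_m)  # heterogeneous mean log-abundance
    raw = np.exp(z + scale)
    keep = rng.random(size=(n, p_m)) >= zero_inflation
    # never zero out a whole row: the most abundant taxon always survives
    keep[np.arange(n), raw.argmax(axis=1)] = True
    raw = raw * keep
    micro = raw / raw.sum(axis=1, keepdims=True)
    microbiome = pd.DataFrame(micro, index=ids, columns=[f"mgs_{j:04d}" for j in range(p_m)])

    # diet: ordinal codes via thresholded latent Gaussian, MCAR missingness
    lat = rng.normal(size=(n, 2)) @ rng.normal(size=(2, p_d)) * 0.5 + rng.normal(size=(n, p_d))
    # column-specific cut points give skewed frequency distributions
    codes = np.empty((n, p_d))
    for j in range(p_d):
        cuts = np.sort(rng.normal(0, 1.2, DIET_CODE_MAX))
        codes[:, j] = np.searchsorted(cuts, lat[:, j])
    miss = rng.random(size=(n, p_d)) < diet_missing
    codes[miss] = np.nan
    diet = pd.DataFrame(codes, index=ids, columns=[f"ffq_{j:03d}" for j in range(p_d)])

    return FeatureBundle(ids, clinical, microbiome, diet)


# ---------------------------------------------------------------------------
# design-matrix transforms shared by the generator and its oracle
# ---------------------------------------------------------------------------

def _raw_group_matrix(bundle: FeatureBundle, group: str) -> np.ndarray:
    if group == "microbiome":
        return np.log10(bundle.microbiome.to_numpy() + 1e-6)
    if group == "diet":
        x = bundle.diet.to_numpy().copy()
        for j in range(x.shape[1]):
            col = x[:, j]
            if np.isnan(col).any():
                vals = col[~np.isnan(col)]
                if vals.size == 0:
                    fill = 0.0
                else:
                    uniq, cnt = np.unique(vals, return_counts=True)
                    fill = uniq[cnt.argmax()]
                col[np.isnan(col)] = fill
        return x
    return bundle.clinical.to_numpy()


def design_matrix(bundle: FeatureBundle, group: str, params: dict | None = None):
    """Standardized design matrix for one group; returns (X, params).

    ``params`` (means/SDs of the generating bundle) lets the metabolite
    oracle be evaluated as a *fixed* predictor on fresh cohort draws.
    """
    x = _raw_group_matrix(bundle, group)
    if params is None:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        params = {"mu": mu, "sd": sd}
    return (x - params["mu"]) / params["sd"], params


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------

def _group_signal(xg: np.ndarray, spec: MetaboliteSignal, rng: np.random.Generator, group: str):
    """One group's raw signal component; returns (values, generator record)."""
    p = xg.shape[1]
    if spec.active and group in spec.active:
        idx = np.sort(np.asarray(spec.active[group], dtype=int))
        k = len(idx)
    else:
        k = min(spec.n_active, p)
        idx = np.sort(rng.choice(p, size=k, replace=False))
    w = rng.normal(size=k)
    s = xg[:, idx] @ w
    rec = {"idx": idx, "w": w, "pairs": np.empty((0, 2), dtype=int), "w_pairs": np.empty(0)}
    if not spec.linear and k >= 2:
        # sparse nonlinear terms: variance-normalized pairwise products of
        # two randomly chosen in-group features, mixed 50/50 with the
        # linear part -- gives tree models an edge a linear fit lacks
        n_pairs = max(1, k // 2)
        pairs = rng.choice(idx, size=(n_pairs, 2))
        wp = rng.normal(size=n_pairs)
        prod = xg[:, pairs[:, 0]] * xg[:, pairs[:, 1]]
        prod_sd = prod.std(axis=0, ddof=1)
        prod_sd[prod_sd == 0] = 1.0
        nl = (prod / prod_sd) @ wp
        s_sd = max(s.std(ddof=1), 1e-12)
        nl_sd = max(nl.std(ddof=1), 1e-12)
        s = s / s_sd + nl / nl_sd
        rec["w"] = w / s_sd
        rec["pairs"] = pairs
        rec["w_pairs"] = wp / nl_sd
        rec["pair_sd"] = prod_sd
        rec["nl_scale"] = nl_sd
    return s, rec


def gen_metabolite_matrix(
    bundle: FeatureBundle,
    signal_spec: dict[str, MetaboliteSignal],
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Metabolites as noisy group-wise functions of the bundle.

    Each metabolite is ``y = sum_g s_g(X_g) + eps`` with every component
    rescaled so that Var(s_g)/Var(y) equals the target fraction for group g
    (targets must sum to at most 0.95, leaving irreducible noise).
    Returns the samples x metabolites matrix and the ground truth carrying
    the frozen generating predictors.
    """
    rng = _rng(seed)
    truth = GroundTruth(seed=seed)
    xg = {}
    std_params = {}
    for g in GROUPS:
        xg[g], std_params[g] = design_matrix(bundle, g)
    cols = {}
    for met, spec in signal_spec.items():
        targets = spec.targets()
        tot = sum(targets.values())
        if tot > 0.95 + 1e-12:
            raise ValueError(f"signal fractions for {met} sum to {tot:.3f} > 0.95")
        y = np.zeros(bundle.n)
        gens = {}
        for g, frac in targets.items():
            if frac <= 0:
                continue
            s, rec = _group_signal(xg[g], spec, rng, g)
            sd = s.std(ddof=1)
            if sd == 0:
                continue
            coef = np.sqrt(frac) / sd
            y = y + coef * s
            rec["scale"] = coef
            gens[g] = rec
        noise_sd = np.sqrt(max(1.0 - tot, 0.0))
        y = y + rng.normal(0.0, noise_sd, bundle.n)
        cols[met] = y
        truth.signal_fractions[met] = targets
        truth.generators[met] = {
            "groups": gens,
            "noise_sd": noise_sd,
            "linear": spec.linear,
            "std_params": {g: std_params[g] for g in gens},
        }
    mat = pd.DataFrame(cols, index=bundle.sample_ids)
    return mat, truth


def oracle_predict(truth: GroundTruth, metabolite: str, bundle: FeatureBundle) -> np.ndarray:
    """Evaluate the frozen generating predictor of one metabolite on a bundle.

    Uses the standardization constants recorded at generation time, so this
    is a fixed predictor; on fresh draws its R-squared estimates the planted
    signal fraction sum.
    """
    gen = truth.generators[metabolite]
    yhat = np.zeros(bundle.n)
    for g, rec in gen["groups"].items():
        params = {k: np.asarray(v) for k, v in gen["std_params"][g].items()}
        x, _ = design_matrix(bundle, g, params=params)
        idx = np.asarray(rec["idx"], dtype=int)
        s = x[:, idx] @ np.asarray(rec["w"])
        pairs = np.asarray(rec["pairs"], dtype=int)
        if pairs.size:
            prod = x[:, pairs[:, 0]] * x[:, pairs[:, 1]]
            prod = prod / np.asarray(rec["pair_sd"])
            s = s + prod @ np.asarray(rec["w_pairs"])
        yhat = yhat + np.asarray(rec["scale"]) * s
    return yhat


# ---------------------------------------------------------------------------
# mediation triplets
# ---------------------------------------------------------------------------

def gen_mediation_triplet(
    n: int,
    a: float,
    b: float,
    c_prime: float,
    covar_effects: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """A planted MGS1 -> metabolite -> MGS2 mediation triplet.

    Structural model (covariates z = standardized age, sex, BMI):
        mediator = a * MGS1 + gamma' z + eps1
        MGS2     = c' * MGS1 + b * mediator + gamma' z + eps2
    The analytic proportion mediated a*b / (a*b + c') is stored in the truth
    (flagged undefined when the total effect is zero, not raised).

    Returns ``(table, meta, truth)`` where table has columns mgs1,
    mediator, mgs2.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = _rng(seed)
    ids = [f"S{i:05d}" for i in range(n)]
    age = rng.uniform(50, 64, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(27.0, 4.0, n).clip(16, 55)
    z = np.column_stack([(age - age.mean()) / age.std(), sex - sex.mean(), (bmi - bmi.mean()) / bmi.std()])
    ce = covar_effects or {}
    gamma = np.array([ce.get("age", 0.0), ce.get("sex", 0.0), ce.get("bmi", 0.0)])
    mgs1 = rng.normal(size=n)
    mediator = a * mgs1 + z @ gamma + rng.normal(0, noise_sd, n)
    mgs2 = c_prime * mgs1 + b * mediator + z @ gamma + rng.normal(0, noise_sd, n)
    total = a * b + c_prime
    prop = float("nan") if total == 0 else a * b / total
    truth = GroundTruth(seed=seed)
    truth.mediation["triplet"] = {
        "a": a,
        "b": b,
        "c_prime": c_prime,
        "proportion": prop,
        "proportion_defined": total != 0,
    }
    table = pd.DataFrame({"mgs1": mgs1, "mediator": mediator, "mgs2": mgs2}, index=ids)
    meta = SampleMetadata(
        pd.DataFrame({"age": age, "sex": sex, "bmi": bmi, "group": "NGT"}, index=ids)
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# glucose-status labels and planted differential shifts
# ---------------------------------------------------------------------------

def gen_cohort_labels(
    n: int,
    metabolites: pd.DataFrame,
    group_props: tuple[float, ...] = DEFAULT_GROUP_PROPS,
    planted_shifts: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
):
    """Assign NGT/IFG/IGT/CGI/T2D labels and plant standardized group shifts.

    ``planted_shifts`` maps metabolite -> group -> additive effect on the
    standardized scale; the planted set and effects go into the truth.
    Returns ``(meta, shifted_metabolites, truth)``.
    """
    if abs(sum(group_props) - 1.0) > 1e-6:
        raise ValueError("group proportions must sum to 1")
    if len(metabolites) != n:
        raise ValueError("metabolite matrix row count must equal n")
    rng = _rng(seed)
    labels = rng.choice(len(GLUCOSE_GROUPS), size=n, p=np.asarray(group_props))
    groups = np.asarray(GLUCOSE_GROUPS)[labels]
    age = rng.uniform(50, 64, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(27.0, 4.0, n).clip(16, 55)
    meta = SampleMetadata(
        pd.DataFrame({"age": age, "sex": sex, "bmi": bmi, "group": groups}, index=metabolites.index)
    )
    shifted = metabolites.copy()
    planted_shifts = planted_shifts or {}
    truth = GroundTruth(seed=seed)
    for met, shifts in planted_shifts.items():
        if met not in shifted.columns:
            raise KeyError(f"unknown metabolite {met!r}")
        sd = shifted[met].std(ddof=1)
        for grp, eff in shifts.items():
            if grp not in GLUCOSE_GROUPS:
                raise ValueError(f"unknown group {grp!r}")
            mask = groups == grp
            shifted.loc[mask, met] += eff * sd
        truth.differential[met] = dict(shifts)
    return meta, shifted, truth


def to_raw_abundance_scale(
    std_matrix: pd.DataFrame, seed: int = 0, missing_frac: float = 0.02
) -> pd.DataFrame:
    """Map standardized metabolite values onto a positive raw-intensity scale
    (exponentiate) and hide a small fraction of cells, so the preprocessing
    chain (log10, min-imputation, standardization) has real work to do."""
    rng = _rng(seed)
    vals = np.power(10.0, std_matrix.to_numpy() * 0.5 + 3.0)
    mask = rng.random(vals.shape) < missing_frac
    vals[mask] = np.nan
    return pd.DataFrame(vals, index=std_matrix.index, columns=std_matrix.columns)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_cohort(
    out_dir: str | Path,
    bundle: FeatureBundle,
    metabolites: pd.DataFrame | None = None,
    meta: SampleMetadata | None = None,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write a cohort as TSV tables (+ JSON truth sidecar); returns file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, tab in (
        ("clinical", bundle.clinical),
        ("microbiome", bundle.microbiome),
        ("diet", bundle.diet),
    ):
        p = out / f"{name}.tsv"
        tab.to_csv(p, sep="\t", index_label="sample_id", na_rep="NA")
        files[name] = p
    if metabolites is not None:
        p = out / "metabolites.tsv"
        metabolites.to_csv(p, sep="\t", index_label="sample_id", na_rep="NA")
        files["metabolites"] = p
    if meta is not None:
        p = out / "metadata.tsv"
        meta.table.to_csv(p, sep="\t", index_label="sample_id", na_rep="NA")
        files["metadata"] = p
    if truth is not None:
        p = out / "truth.json"
        truth.write(p)
        files["truth"] = p
    return files
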