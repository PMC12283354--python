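"""Bidirectional covariate-adjusted linear mediation with bootstrap inference.

Two ordinary-least-squares models define the estimator (covariates: age,
BMI, sex):

    mediator model:  metabolite = a * MGS1 + covariates
    outcome model:   MGS2 = c' * MGS1 + b * metabolite + covariates

Under these linear no-interaction models the average causal mediation
effect (ACME, the indirect effect) is the product of coefficients a*b, the
average direct effect (ADE) is c', the total effect is their sum exactly,
and the proportion mediated is ACME / total.  Confidence intervals and the
P value come from a nonparametric pairs bootstrap (resample rows, refit
both models).  Variables are standardized before fitting; the proportion is
scale-invariant, so this only stabilizes the numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: |total effect| below this (on standardized variables) flags the
#: proportion mediated as undefined.
TOTAL_EPS = 1e-8


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    a: float
    b: float
    c_prime: float
    acme: float
    ade: float
    total: float
    prop_mediated: float
    prop_defined: bool
    ci_acme: tuple[float, float]
    ci_prop: tuple[float, float]
    p: float
    n_boot: int
    boot_acme: np.ndarray = field(default=None, repr=False)

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "a": self.a,
            "b": self.b,
            "c_prime": self.c_prime,
            "acme": self.acme,
            "ade": self.ade,
            "total": self.total,
            "prop_mediated": self.prop_mediated,
            "prop_defined": self.prop_defined,
            "acme_ci_low": self.ci_acme[0],
            "acme_ci_high": self.ci_acme[1],
            "prop_ci_low": self.ci_prop[0],
            "prop_ci_high": self.ci_prop[1],
            "p": self.p,
            "n_boot": self.n_boot,
        }


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # name the collinear columns by checking pairwise rank loss
        raise np.linalg.LinAlgError(
            f"rank-deficient design: rank {rank} < {X.shape[1]} columns"
        )
    return coef


def _paths(exposure, mediator, outcome, Z):
    """(a, b, c') from the two OLS fits on standardized variables."""
    Xm = np.column_stack([np.ones(len(exposure)), exposure, Z])
    a = _ols(mediator, Xm)[1]
    Xo = np.column_stack([np.ones(len(exposure)), exposure, mediator, Z])
    co = _ols(outcome, Xo)
    return a, co[2], co[1]  # a, b, c_prime


def fit_mediation(
    exposure,
    mediator,
    outcome,
    covariates,
    B: int = 1000,
    seed: int = 0,
    names: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
    standardize: bool = True,
) -> MediationResult:
    """Product-of-coefficients mediation with pairs-bootstrap CI and P.

    With ``standardize=False`` the variables are only centred, so a, b and
    c' stay on the structural scale of the inputs (useful when comparing
    against known generating coefficients).

    The P value is the fraction of bootstrap ACME draws crossing zero,
    doubled and capped at 1.  When |total| < 1e-8 the proportion mediated is
    flagged undefined but the effects are still reported.
    """
    exposure = np.asarray(exposure, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = len(exposure)
    if not (len(mediator) == len(outcome) == len(Z) == n):
        raise ValueError("all variables must have equal length")
    if n < 20:
        raise ValueError("need at least 20 samples")
    if standardize:
        x = _standardize(exposure)
        m = _standardize(mediator)
        y = _standardize(outcome)
    else:
        x = exposure - exposure.mean()
        m = mediator - mediator.mean()
        y = outcome - outcome.mean()
    Zs = np.column_stack([_standardize(Z[:, j]) for j in range(Z.shape[1])])

    a, b, c_prime = _paths(x, m, y, Zs)
    acme = a * b
    ade = c_prime
    total = acme + ade
    defined = abs(total) >= TOTAL_EPS
    prop = acme / total if defined else float("nan")

    rng = np.random.default_rng(seed)
    boot_acme = np.empty(B)
    boot_prop = np.full(B, np.nan)
    for i in range(B):
        s = rng.integers(0, n, n)
        try:
            ab, bb, cb = _paths(x[s], m[s], y[s], Zs[s])
        except np.linalg.LinAlgError:
            boot_acme[i] = np.nan
            continue
        boot_acme[i] = ab * bb
        tb = ab * bb + cb
        if abs(tb) >= TOTAL_EPS:
            boot_prop[i] = ab * bb / tb
    ok = ~np.isnan(boot_acme)
    ci_acme = tuple(np.percentile(boot_acme[ok], [2.5, 97.5])) if ok.any() else (np.nan, np.nan)
    okp = ~np.isnan(boot_prop)
    ci_prop = tuple(np.percentile(boot_prop[okp], [2.5, 97.5])) if okp.any() else (np.nan, np.nan)
    if ok.any():
        frac = min((boot_acme[ok] <= 0).mean(), (boot_acme[ok] >= 0).mean())
        p = min(1.0, 2 * frac)
    else:
        p = float("nan")
    return MediationResult(
        names[0],
        names[1],
        names[2],
        float(a),
        float(b),
        float(c_prime),
        float(acme),
        float(ade),
        float(total),
        float(prop),
        bool(defined),
        (float(ci_acme[0]), float(ci_acme[1])),
        (float(ci_prop[0]), float(ci_prop[1])),
        float(p),
        B,
        boot_acme,
    )


def bidirectional_mediation(
    mgs1,
    mgs2,
    metabolite,
    covariates,
    B: int = 1000,
    seed: int = 0,
    names: tuple[str, str, str] = ("mgs1", "metabolite", "mgs2"),
) -> tuple[MediationResult, MediationResult]:
    """Mediation in both directions: mgs1 -> metabolite -> mgs2 and the reverse."""
    fwd = fit_mediation(
        mgs1, metabolite, mgs2, covariates, B=B, seed=seed,
        names=(names[0], names[1], names[2]),
    )
    rev = fit_mediation(
        mgs2, metabolite, mgs1, covariates, B=B, seed=seed + 1,
        names=(names[2], names[1], names[0]),
    )
    return fwd, rev


def mediation_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
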