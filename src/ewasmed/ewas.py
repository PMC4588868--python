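"""Per-CpG linear modelling of methylation on exposure plus covariates.

Each probe's beta values are regressed on exposure status adjusted for
sex, gestational age, maternal age, pre-pregnancy BMI, education, plate
and the six estimated cell-type proportions; the exposure coefficient is
tested two-sided against a Student t reference with n - k degrees of
freedom.  Multiplicity is handled by Benjamini-Hochberg FDR over all
tested probes, with the conventional genome-wide Bonferroni threshold
p < 1e-7 (and the exact 0.05/m bound) reported alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CohortDataset

DEFAULT_COVARIATES = (
    "sex",
    "gestational_age",
    "maternal_age",
    "maternal_bmi",
    "education",
    "plate",
)
GENOME_WIDE_P = 1e-7


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending sort, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_design(
    samples: pd.DataFrame,
    proportions: pd.DataFrame | None = None,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Design matrix: intercept + exposure + covariates (+ cell proportions).

    ``plate`` expands to treatment-coded dummies (first plate as
    reference); all other covariates enter numerically.  Cell proportions,
    when given, are joined on sample id and must cover every sample.
    """
    cols = {"intercept": np.ones(len(samples)), "exposure": samples["exposure"].astype(float)}
    X = pd.DataFrame(cols, index=samples.index)
    for cov in covariates:
        if cov == "plate":
            dummies = pd.get_dummies(
                samples["plate"], prefix="plate", drop_first=True, dtype=float
            )
            X = pd.concat([X, dummies], axis=1)
        else:
            if cov not in samples.columns:
                raise KeyError(f"covariate {cov!r} not in sample sheet")
            X[cov] = samples[cov].astype(float)
    if proportions is not None:
        missing = samples.index.difference(proportions.index)
        if len(missing):
            raise ValueError(
                f"cell proportions missing for samples: {list(missing[:5])}"
            )
        props = proportions.loc[samples.index]
        X = pd.concat([X, props.add_prefix("prop_")], axis=1)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        kept = np.empty((A.shape[0], 0))
        aliased = []
        for j, name in enumerate(X.columns):
            cand = np.hstack([kept, A[:, [j]]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                aliased.append(name)
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")


def _ols_term(Y: np.ndarray, X: np.ndarray, j: int):
    """Vectorised OLS of each column of Y on X; inference for coefficient j.

    Returns (coef, se, t, p, dof) arrays over the columns of Y.
    """
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > parameters ({n} samples, {k} columns)")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)  # k x m
    resid = Y - X @ B
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[j, j], 0.0))
    coef = B[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
    t = np.where((se == 0) & (coef == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return coef, se, t, p, dof


def fit_probe_model(y, design: pd.DataFrame, term: str = "exposure"):
    """OLS of one probe's betas on the design; returns (coef, se, t, p).

    With no covariates the exposure coefficient equals the difference of
    group means exactly.  A zero-residual fit yields se = 0 and p -> 0.
    """
    y = np.asarray(y, dtype=float)
    _check_full_rank(design)
    j = list(design.columns).index(term)
    coef, se, t, p, _ = _ols_term(y[:, None], design.to_numpy(dtype=float), j)
    return float(coef[0]), float(se[0]), float(t[0]), float(p[0])


def run_ewas(
    dataset: CohortDataset,
    proportions: pd.DataFrame | None = None,
    covariates=DEFAULT_COVARIATES,
    bonferroni: str = "fixed",
) -> pd.DataFrame:
    """Covariate-adjusted EWAS of every probe; one row per probe.

    Assumes QC and covariate imputation have already been applied.
    ``bonferroni`` selects the flag convention: ``"fixed"`` uses the
    genome-wide p < 1e-7 cutoff, ``"exact"`` uses p < 0.05 / m.  Both
    thresholds are returned as columns regardless.

    Output columns: probe_id (index), coefficient, se, t, p, q,
    bonferroni_significant, bonferroni_exact, mean_methylation,
    raw_difference, n_used.
    """
    if bonferroni not in ("fixed", "exact"):
        raise ValueError("bonferroni must be 'fixed' or 'exact'")
    X = build_design(dataset.samples, proportions, covariates)
    _check_full_rank(X)
    Y = dataset.beta.to_numpy(dtype=float).T  # samples x probes
    j = list(X.columns).index("exposure")
    coef, se, t, p, _ = _ols_term(Y, X.to_numpy(dtype=float), j)
    q = bh_fdr(p)
    m = Y.shape[1]
    exact = p < 0.05 / m
    fixed = p < GENOME_WIDE_P
    exposed = dataset.samples["exposure"].to_numpy() == 1
    raw_diff = Y[exposed].mean(axis=0) - Y[~exposed].mean(axis=0)
    out = pd.DataFrame(
        {
            "coefficient": coef,
            "se": se,
            "t": t,
            "p": p,
            "q": q,
            "bonferroni_significant": fixed if bonferroni == "fixed" else exact,
            "bonferroni_exact": exact,
            "mean_methylation": Y.mean(axis=0),
            "raw_difference": raw_diff,
            "n_used": Y.shape[0],
        },
        index=dataset.beta.index.rename("probe_id"),
    )
    return out


def dose_response_test(
    dataset: CohortDataset,
    probe_ids,
    proportions: pd.DataFrame | None = None,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Within-exposed regression of methylation on cigarettes/day.

    Tests, per probe, whether methylation scales with smoking intensity
    among exposed samples only.  Returns slope, se, t, p and a ``low_n``
    flag (set, with a warning, below 10 exposed samples).
    """
    exposed_ids = dataset.samples.index[dataset.samples["exposure"] == 1]
    sub = dataset.subset(samples=list(exposed_ids))
    cigs = sub.samples["cigarettes_per_day"]
    if cigs.isna().any():
        raise ValueError("cigarettes_per_day missing for some exposed samples")
    if cigs.nunique() <= 1:
        raise ValueError("cigarettes_per_day has zero variance among exposed")
    low_n = len(exposed_ids) < 10
    if low_n:
        warnings.warn(
            f"dose-response test on only {len(exposed_ids)} exposed samples",
            stacklevel=2,
        )
    X = build_design(sub.samples, proportions, covariates)
    X = X.drop(columns="exposure")
    X.insert(1, "cigarettes_per_day", cigs.astype(float))
    _check_full_rank(X)
    Y = sub.beta.loc[list(probe_ids)].to_numpy(dtype=float).T
    coef, se, t, p, _ = _ols_term(Y, X.to_numpy(dtype=float), 1)
    return pd.DataFrame(
        {"slope": coef, "se": se, "t": t, "p": p, "low_n": low_n},
        index=pd.Index(list(probe_ids), name="probe_id"),
    )


CONTINUOUS_DESCRIPTIVES = (
    "birthweight",
    "gestational_age",
    "maternal_age",
    "maternal_bmi",
)
CATEGORICAL_DESCRIPTIVES = ("sex", "education")


def descriptive_table(dataset: CohortDataset) -> pd.DataFrame:
    """Group summaries with difference tests, one row per characteristic.

    Continuous variables get mean +/- SD per group, the difference of
    means (exposed - unexposed) and an independent-samples t-test p;
    binary variables get counts (%) and a Pearson chi-square p.
    """
    sheet = dataset.samples
    groups = {g: sheet[sheet["exposure"] == g] for g in (0, 1)}
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("both exposure groups must be non-empty")
    rows = []
    for var in CONTINUOUS_DESCRIPTIVES:
        if var not in sheet.columns:
            continue
        a, b = groups[0][var].dropna(), groups[1][var].dropna()
        t, p = stats.ttest_ind(b, a, equal_var=True)
        rows.append(
            {
                "characteristic": var,
                "kind": "continuous",
                "unexposed_mean": a.mean(),
                "unexposed_sd": a.std(ddof=1),
                "exposed_mean": b.mean(),
                "exposed_sd": b.std(ddof=1),
                "difference": b.mean() - a.mean(),
                "p": p,
            }
        )
    for var in CATEGORICAL_DESCRIPTIVES:
        if var not in sheet.columns:
            continue
        a, b = groups[0][var].dropna(), groups[1][var].dropna()
        table = np.array(
            [[(a == 1).sum(), (a == 0).sum()], [(b == 1).sum(), (b == 0).sum()]]
        )
        if table.min() == 0 and (table.sum(axis=0) == 0).any():
            p = np.nan
        else:
            p = stats.chi2_contingency(table, correction=False)[1]
        rows.append(
            {
                "characteristic": var,
                "kind": "categorical",
                "unexposed_mean": (a == 1).mean(),
                "unexposed_sd": np.nan,
                "exposed_mean": (b == 1).mean(),
                "exposed_sd": np.nan,
                "difference": (b == 1).mean() - (a == 1).mean(),
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("characteristic")
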