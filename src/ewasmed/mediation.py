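"""Baron-Kenny mediation of an exposure -> outcome effect through one CpG.

Three nested OLS models are fitted on the identical complete-case sample
set:

* model a:    CpG = exposure + covariates          -> beta_a, SE_a
* model c:    BW  = exposure + covariates          -> beta_c, SE_c (total effect)
* full model: BW  = exposure + CpG + covariates    -> beta_c', beta_b, SE_b

In linear models the indirect effect satisfies the exact identity
beta_a * beta_b = beta_c - beta_c' (product of coefficients equals
difference of coefficients); the identity is asserted on every run as a
guard against accidental sample-set mismatch.  Inference on the indirect
effect uses the Sobel normal-theory test with
SE = sqrt(beta_a^2 SE_b^2 + beta_b^2 SE_a^2), and the proportion mediated
is (beta_a*beta_b) / ((beta_a*beta_b) + beta_c'), identically
(beta_c - beta_c') / beta_c.

Methylation enters as a proportion in [0, 1], so beta_b is "grams per
100% methylation".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ewas import DEFAULT_COVARIATES, build_design, _check_full_rank
from .simulate import CohortDataset

_IDENTITY_RTOL = 1e-8


@dataclass
class MediationRecord:
    probe_id: str
    beta_a: float
    se_a: float
    p_a: float
    beta_c: float
    se_c: float
    p_c: float
    beta_c_prime: float
    beta_b: float
    se_b: float
    p_b: float
    delta: float                 # beta_c - beta_c' (grams)
    mediation_pct: float         # delta / beta_c, as a proportion
    sobel_z: float
    sobel_p: float
    r_square_c: float
    n_used: int
    condition_i: bool            # exposure associated with mediator
    condition_ii: bool           # exposure associated with outcome
    condition_iii: bool          # mediator associated with outcome (full model)
    condition_iv: bool           # |beta_c'| < |beta_c|
    condition_v: bool            # Sobel p < 0.05

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def sobel_test(beta_a: float, se_a: float, beta_b: float, se_b: float):
    """Normal-theory test of the indirect effect beta_a * beta_b.

    z = (beta_a * beta_b) / sqrt(beta_a^2 se_b^2 + beta_b^2 se_a^2), with a
    two-sided p from the standard normal.  Negating either coefficient
    negates z and leaves p unchanged.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    if se_a == 0 and se_b == 0:
        raise ValueError("at least one standard error must be positive")
    indirect = beta_a * beta_b
    denom = np.sqrt(beta_a**2 * se_b**2 + beta_b**2 * se_a**2)
    if denom == 0:
        if indirect == 0:
            return 0.0, 1.0
        raise ValueError("zero Sobel SE with nonzero indirect effect")
    z = indirect / denom
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return float(z), p


def mediation_percentage(
    beta_a: float, beta_b: float, beta_c_prime: float, tol: float = 1e-12
) -> float:
    """Proportion of the total effect carried by the mediator.

    Product form (beta_a*beta_b) / ((beta_a*beta_b) + beta_c_prime); under
    the OLS identity the denominator equals beta_c, so this also equals
    (beta_c - beta_c') / beta_c.  Near-zero total effects are flagged
    unstable (NaN with a warning).
    """
    indirect = beta_a * beta_b
    total = indirect + beta_c_prime
    if abs(total) < tol:
        warnings.warn("near-zero total effect; proportion mediated is unstable",
                      stacklevel=2)
        return float("nan")
    return indirect / total


def indirect_effect(beta_c: float, beta_c_prime: float) -> tuple[float, float]:
    """Difference-of-coefficients form: (delta, proportion mediated).

    delta = beta_c - beta_c' and proportion = delta / beta_c.
    """
    if beta_c == 0:
        raise ValueError("total effect beta_c is zero")
    delta = beta_c - beta_c_prime
    return delta, delta / beta_c


def _complete_cases(
    dataset: CohortDataset,
    proportions: pd.DataFrame | None,
    probe_id: str,
    covariates,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """(design, mediator, outcome) restricted to the shared complete rows."""
    if probe_id not in dataset.beta.index:
        raise KeyError(f"probe {probe_id} not in beta matrix")
    X = build_design(dataset.samples, proportions, covariates)
    m = dataset.beta.loc[probe_id]
    y = dataset.samples["birthweight"]
    frame = pd.concat([X, m.rename("_m"), y.rename("_y")], axis=1)
    frame = frame.dropna()
    if len(frame) == 0:
        raise ValueError("no complete-case samples")
    return (
        frame[X.columns],
        frame["_m"].to_numpy(float),
        frame["_y"].to_numpy(float),
    )


def run_mediation(
    dataset: CohortDataset,
    proportions: pd.DataFrame | None,
    probe_id: str,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> MediationRecord:
    """Fit the three mediation models for one CpG and fill a full record.

    All models share the identical complete-case rows; the product /
    difference identity for the indirect effect is asserted to relative
    tolerance 1e-8.  Condition booleans i-v are reported alongside the
    estimates rather than gating them.
    """
    X, m, y = _complete_cases(dataset, proportions, probe_id, covariates)
    if np.ptp(m) == 0:
        raise ValueError(f"mediator {probe_id} has zero variance")
    _check_full_rank(X)
    A = X.to_numpy(float)
    j = list(X.columns).index("exposure")

    fit_a = sm.OLS(m, A).fit()
    fit_c = sm.OLS(y, A).fit()
    A_full = np.hstack([A, m[:, None]])
    fit_full = sm.OLS(y, A_full).fit()

    beta_a, se_a, p_a = fit_a.params[j], fit_a.bse[j], fit_a.pvalues[j]
    beta_c, se_c, p_c = fit_c.params[j], fit_c.bse[j], fit_c.pvalues[j]
    beta_c_prime = fit_full.params[j]
    beta_b, se_b, p_b = (
        fit_full.params[-1],
        fit_full.bse[-1],
        fit_full.pvalues[-1],
    )

    delta = beta_c - beta_c_prime
    product = beta_a * beta_b
    scale = max(1.0, abs(beta_c))
    if abs(product - delta) > _IDENTITY_RTOL * scale:
        raise RuntimeError(
            f"mediation identity violated for {probe_id}: "
            f"beta_a*beta_b={product:.6g} vs beta_c-beta_c'={delta:.6g}; "
            "the three models were not fitted on identical samples"
        )
    sobel_z, sobel_p = sobel_test(beta_a, se_a, beta_b, se_b)
    pct = delta / beta_c if beta_c != 0 else float("nan")
    return MediationRecord(
        probe_id=probe_id,
        beta_a=float(beta_a),
        se_a=float(se_a),
        p_a=float(p_a),
        beta_c=float(beta_c),
        se_c=float(se_c),
        p_c=float(p_c),
        beta_c_prime=float(beta_c_prime),
        beta_b=float(beta_b),
        se_b=float(se_b),
        p_b=float(p_b),
        delta=float(delta),
        mediation_pct=float(pct),
        sobel_z=sobel_z,
        sobel_p=sobel_p,
        r_square_c=float(fit_c.rsquared),
        n_used=len(X),
        condition_i=bool(p_a < alpha),
        condition_ii=bool(p_c < alpha),
        condition_iii=bool(p_b < alpha),
        condition_iv=bool(abs(beta_c_prime) < abs(beta_c)),
        condition_v=bool(sobel_p < alpha),
    )


def mediation_table(
    dataset: CohortDataset,
    proportions: pd.DataFrame | None,
    probe_ids,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Run :func:`run_mediation` for several probes; one row per probe."""
    records = [
        run_mediation(dataset, proportions, p, covariates).to_dict()
        for p in probe_ids
    ]
    return pd.DataFrame(records).set_index("probe_id")


def interaction_check(
    dataset: CohortDataset,
    proportions: pd.DataFrame | None,
    probe_id: str,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Exposure x mediator and covariate x mediator interaction tests.

    The full outcome model is augmented with one interaction term at a
    time; each row reports that term's coefficient, SE and two-sided p.
    Uniform p-values here support the no-interaction assumption of the
    mediation decomposition.
    """
    X, m, y = _complete_cases(dataset, proportions, probe_id, covariates)
    if np.ptp(m) == 0:
        raise ValueError(f"mediator {probe_id} has zero variance")
    _check_full_rank(X)
    A = X.to_numpy(float)
    base = np.hstack([A, m[:, None]])
    mc = m - m.mean()  # centred to tame collinearity with main effects
    rows = []
    for name in X.columns:
        if name == "intercept":
            continue
        term = X[name].to_numpy(float)
        if np.ptp(term) == 0:
            continue
        inter = (term - term.mean()) * mc
        fit = sm.OLS(y, np.hstack([base, inter[:, None]])).fit()
        rows.append(
            {
                "term": f"{name}:{probe_id}",
                "coefficient": float(fit.params[-1]),
                "se": float(fit.bse[-1]),
                "p": float(fit.pvalues[-1]),
            }
        )
    return pd.DataFrame(rows).set_index("term")
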