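"""Reference-based cell-type deconvolution (constrained projection).

Per-sample leukocyte proportions are estimated by projecting each
methylation profile onto a signature matrix of cell-type mean betas,
solving a nonnegative least-squares problem over a set of discriminating
probes.  No sum-to-one equality is imposed — the estimated proportions
may sum slightly off 1 — which keeps all cell types usable together as
regression covariates without exact collinearity with the intercept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .simulate import CellTypeReferencePanel


def select_discriminating_probes(
    reference: CellTypeReferencePanel, k: int
) -> list[str]:
    """The ``k`` probes with largest between-cell-type variance.

    Variance is taken across the reference columns (one mean beta per
    type, so the one-way between-group statistic reduces to the row
    variance); ties are broken by input probe order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    sig = reference.signature
    if k > sig.shape[0]:
        raise ValueError(f"k={k} exceeds probe count {sig.shape[0]}")
    var = sig.to_numpy().var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")
    return [sig.index[i] for i in order[:k]]


def _collinear_types(sub: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns not adding rank (reported on error)."""
    bad, kept = [], np.empty((sub.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.hstack([kept, sub[:, [j]]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(name)
    return bad


def estimate_cell_proportions(
    beta: pd.DataFrame,
    reference: CellTypeReferencePanel,
    probes: list[str] | None = None,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions by nonnegative least squares.

    Parameters
    ----------
    beta : probes x samples matrix of beta values.
    reference : signature panel; its probe index must cover ``probes``.
    probes : discriminating probes to fit on; defaults to the 100
        most type-variable reference probes present in ``beta``.
    renormalize : if True, rescale each sample's estimate to sum to 1.

    Returns a samples x cell-types DataFrame with nonnegative entries.
    """
    sig = reference.signature
    if probes is None:
        avail = CellTypeReferencePanel(sig.loc[sig.index.intersection(beta.index)])
        probes = select_discriminating_probes(avail, min(100, avail.signature.shape[0]))
    missing = [p for p in probes if p not in beta.index or p not in sig.index]
    if missing:
        raise KeyError(f"selected probes absent from beta or reference: {missing[:5]}")

    A = sig.loc[probes].to_numpy()
    if np.linalg.matrix_rank(A) < A.shape[1]:
        bad = _collinear_types(A, list(sig.columns))
        raise ValueError(
            f"reference is rank deficient on selected probes; collinear "
            f"cell types: {bad}"
        )
    Y = beta.loc[probes].to_numpy()
    est = np.empty((Y.shape[1], A.shape[1]))
    for j in range(Y.shape[1]):
        est[j], _ = nnls(A, Y[:, j])
    if renormalize:
        totals = est.sum(axis=1, keepdims=True)
        np.divide(est, totals, out=est, where=totals > 0)
    return pd.DataFrame(est, index=beta.columns, columns=sig.columns)
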