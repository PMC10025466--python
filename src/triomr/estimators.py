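"""Two-stage Mendelian-randomization estimators for trio data.

Three estimators of the causal effect of an exposure X on an outcome Y, all
using the offspring's genotype at the instrument locus G (additive and
dominance codings) as instruments and differing in what they condition on:

* ``fit_conventional_mr`` — no family information: regress X on the offspring
  genotype codings, then Y on the fitted exposure.
* ``fit_parental_genotype_mr`` — add the additive and dominance codings of
  both parents' genotypes to both stages (the parental-allele-score
  adjustment).
* ``fit_mating_type_mr`` — add reference-coded indicators of the parental
  *mating type* (the unordered pair of parental genotypes, six categories) to
  both stages.  Because the mating type is a saturated encoding of the
  parental genotype pair, this conditioning remains valid when parental
  genotype effects are non-additive, where the allele-score adjustment is not.

Only the offspring's X and Y enter the regressions; parents contribute
genotypes alone.  The second-stage covariate coefficients are re-estimated
jointly with the coefficient on the fitted exposure, and inference on that
coefficient uses plain OLS standard errors treating the fitted exposure as a
fixed regressor (a 2SLS-style corrected standard error is available via
``se_method="2sls"``).

The OLS core detects rank deficiency with a column-pivoted QR decomposition
and drops aliased columns by name, so silent model changes (e.g. a mating
type absent from the sample) are always visible in the fit diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .genetics import (
    additive_code,
    dominance_code,
    mating_type_code,
    mating_type_indicator_matrix,
    MatingType,
)
from .simulate import TrioDataset

__all__ = [
    "OLSResult",
    "MRFitResult",
    "ols",
    "fit_conventional_mr",
    "fit_parental_genotype_mr",
    "fit_mating_type_mr",
    "fit_all",
    "EstimationError",
    "DegenerateInstrumentError",
]

MIN_SAMPLE = 10
RANK_RTOL = 1e-8

METHODS = ("conventional", "parental_genotype", "mating_type")


class EstimationError(RuntimeError):
    """An estimator could not be fit on the supplied data."""


class DegenerateInstrumentError(EstimationError):
    """The instrument carries no usable variation (e.g. monomorphic locus, or
    no mating type within which the offspring genotype segregates)."""


@dataclass
class OLSResult:
    """Least-squares fit with pivoted-QR rank handling.

    ``coefs`` maps retained column names to estimates; aliased columns are in
    ``dropped`` and excluded from inference.  ``cov`` is the coefficient
    covariance on the retained columns (residual variance times the inverse
    normal matrix).
    """

    coefs: dict[str, float]
    cov: np.ndarray
    sigma2: float
    rank: int
    df_resid: int
    dropped: list[str]
    fitted: np.ndarray
    resid: np.ndarray
    degenerate: bool = False

    def se(self, name: str) -> float:
        i = list(self.coefs).index(name)
        return float(np.sqrt(self.cov[i, i]))


def ols(y, design: np.ndarray, names: list[str], rtol: float = RANK_RTOL) -> OLSResult:
    """OLS of ``y`` on a named design matrix, dropping aliased columns.

    Rank is determined from a column-pivoted QR decomposition: columns whose
    pivot magnitude falls below ``rtol`` times the largest pivot are dropped
    (reported by name) and excluded from the fit and from inference.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response and design have different numbers of rows")
    if len(names) != p:
        raise ValueError("one name per design column is required")

    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > rtol * diag[0])) if diag.size and diag[0] > 0 else 0
    if rank == 0:
        raise EstimationError("design matrix has rank zero")
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in sorted(piv[rank:])]
    if n <= rank:
        raise EstimationError(
            f"need more rows ({n}) than retained columns ({rank})")

    Xk = X[:, keep]
    q1, r1 = np.linalg.qr(Xk)
    beta = scipy.linalg.solve_triangular(r1, q1.T @ y)
    fitted = Xk @ beta
    resid = y - fitted
    df_resid = n - rank
    rss = float(resid @ resid)
    sigma2 = rss / df_resid
    r1_inv = scipy.linalg.solve_triangular(r1, np.eye(rank))
    cov = sigma2 * (r1_inv @ r1_inv.T)

    degenerate = np.var(y) == 0.0 and rank == 1
    return OLSResult(
        coefs={names[j]: float(b) for j, b in zip(keep, beta)},
        cov=cov, sigma2=sigma2, rank=rank, df_resid=df_resid,
        dropped=dropped, fitted=fitted, resid=resid, degenerate=degenerate,
    )


@dataclass
class MRFitResult:
    """Point estimate and inference for the causal X→Y effect.

    ``beta_xy_hat`` is the second-stage coefficient on the fitted exposure;
    ``p_value`` is two-sided from the t distribution with
    n − (retained stage-2 columns) degrees of freedom.
    """

    method: str
    beta_xy_hat: float
    se: float
    t_stat: float
    p_value: float
    stage1_coefs: dict[str, float] = field(default_factory=dict)
    stage2_coefs: dict[str, float] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)
    n_used: int = 0
    se_method: str = "naive"

    def to_record(self) -> dict:
        """Flat record for tabular output."""
        return {
            "method": self.method,
            "beta_xy_hat": self.beta_xy_hat,
            "se": self.se,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "dropped_columns": ";".join(self.dropped_columns),
        }


def _design_columns(data: TrioDataset):
    df = data.df
    for col in ("G", "Gm", "Gf", "X", "Y"):
        if df[col].isna().any():
            raise EstimationError(f"column {col} contains missing values")
    g = df["G"].to_numpy(dtype=np.int64)
    gm = df["Gm"].to_numpy(dtype=np.int64)
    gf = df["Gf"].to_numpy(dtype=np.int64)
    x = df["X"].to_numpy(dtype=float)
    y = df["Y"].to_numpy(dtype=float)
    return g, gm, gf, x, y


def _two_stage(data: TrioDataset, method: str, stage1_extra: np.ndarray,
               extra_names: list[str], se_method: str) -> MRFitResult:
    """Shared two-stage machinery.

    Stage 1 regresses X on [1, fA(G), fD(G)] plus the method's covariates;
    stage 2 regresses Y on [1, X̂] plus the same covariates with freely
    re-estimated coefficients.
    """
    g, _, _, x, y = _design_columns(data)
    n = len(x)
    if n < MIN_SAMPLE:
        raise EstimationError(f"need at least {MIN_SAMPLE} families, got {n}")
    if se_method not in ("naive", "2sls"):
        raise ValueError("se_method must be 'naive' or '2sls'")

    ones = np.ones(n)
    fa = additive_code(g).astype(float)
    fd = dominance_code(g).astype(float)
    s1_design = np.column_stack([ones, fa, fd, stage1_extra])
    s1_names = ["const", "fA(G)", "fD(G)"] + extra_names
    s1 = ols(y=x, design=s1_design, names=s1_names)
    if "fA(G)" in s1.dropped and "fD(G)" in s1.dropped:
        raise DegenerateInstrumentError(
            "offspring genotype at locus G carries no variation beyond the "
            "conditioning covariates (no segregating families); the instrument "
            "is unidentified")
    xhat = s1.fitted

    s2_design = np.column_stack([ones, xhat, stage1_extra])
    s2_names = ["const", "xhat"] + extra_names
    s2 = ols(y=y, design=s2_design, names=s2_names)
    if "xhat" not in s2.coefs:
        raise DegenerateInstrumentError(
            "fitted exposure is collinear with the conditioning covariates")

    beta = s2.coefs["xhat"]
    if se_method == "naive":
        se = s2.se("xhat")
    else:
        # 2SLS residuals: evaluate the structural equation at the observed X.
        keep = list(s2.coefs)
        cols = {"const": ones, "xhat": x}
        for nm, col in zip(extra_names, stage1_extra.T):
            cols[nm] = col
        resid = y - np.column_stack([cols[nm] for nm in keep]) @ np.array(
            [s2.coefs[nm] for nm in keep])
        sigma2 = float(resid @ resid) / s2.df_resid
        se = s2.se("xhat") * np.sqrt(sigma2 / s2.sigma2) if s2.sigma2 > 0 else 0.0

    if se > 0:
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), s2.df_resid))
    else:  # exact fit: the estimate is deterministic, no sampling variability
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0

    dropped = [f"stage1:{c}" for c in s1.dropped] + [f"stage2:{c}" for c in s2.dropped]
    return MRFitResult(
        method=method, beta_xy_hat=float(beta), se=float(se), t_stat=float(t),
        p_value=p, stage1_coefs=dict(s1.coefs), stage2_coefs=dict(s2.coefs),
        dropped_columns=dropped, n_used=n, se_method=se_method,
    )


def fit_conventional_mr(data: TrioDataset, se_method: str = "naive") -> MRFitResult:
    """Conventional two-stage MR using the offspring genotype only."""
    n = len(data.df)
    empty = np.empty((n, 0))
    return _two_stage(data, "conventional", empty, [], se_method)


def fit_parental_genotype_mr(data: TrioDataset, se_method: str = "naive") -> MRFitResult:
    """Two-stage MR conditioning on both parents' genotype codings."""
    _, gm, gf, _, _ = _design_columns(data)
    extra = np.column_stack([
        additive_code(gm), dominance_code(gm),
        additive_code(gf), dominance_code(gf),
    ]).astype(float)
    names = ["fA(Gm)", "fD(Gm)", "fA(Gf)", "fD(Gf)"]
    return _two_stage(data, "parental_genotype", extra, names, se_method)


def fit_mating_type_mr(data: TrioDataset, se_method: str = "naive") -> MRFitResult:
    """Two-stage MR conditioning on the parental mating type.

    Indicator columns for mating types absent from the sample are aliased with
    the intercept block and reported in ``dropped_columns``.
    """
    _, gm, gf, _, _ = _design_columns(data)
    codes = mating_type_code(gm, gf)
    extra = mating_type_indicator_matrix(codes).astype(float)
    names = [f"I[{MatingType(k).label}]" for k in range(5)]
    return _two_stage(data, "mating_type", extra, names, se_method)


_FITTERS = {
    "conventional": fit_conventional_mr,
    "parental_genotype": fit_parental_genotype_mr,
    "mating_type": fit_mating_type_mr,
}


def fit_all(data: TrioDataset, se_method: str = "naive") -> dict[str, MRFitResult]:
    """Fit all three estimators on the same dataset."""
    return {m: _FITTERS[m](data, se_method=se_method) for m in METHODS}
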