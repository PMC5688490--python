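"""Translog cost-function estimation of factor cost shares.

The model
---------

For facility i with total cost :math:`C_i`, factor prices
:math:`p_{1..4}` (personnel, consumables, other-direct, indirect) and output
volume :math:`y_i`, the translog cost function is the second-order log
approximation

.. math::

    \\ln C = \\beta_0 + \\sum_i \\beta_i \\ln p_i
             + \\tfrac12 \\sum_{i,j} \\gamma_{ij} \\ln p_i \\ln p_j
             + \\delta_y \\ln y, \\qquad \\gamma_{ij} = \\gamma_{ji}.

Linear homogeneity in prices is imposed by normalizing by the indirect-cost
price (the numeraire): the regression is of :math:`\\ln (C/p_4)` on the three
normalized log prices :math:`\\ln \\tilde p_i = \\ln(p_i/p_4)`, their squares
and cross-products, and :math:`\\ln y`. By Shephard's lemma the cost share of
factor i is the log-price derivative

.. math::

    s_i = \\beta_i + \\sum_j \\gamma_{ij} \\ln \\tilde p_j,

evaluated by default at the sample mean of the log normalized prices; the
numeraire share is the complement :math:`s_4 = 1 - s_1 - s_2 - s_3`, so the
four shares sum to one by construction. Standard errors for coefficients use
the heteroskedasticity-robust Huber/White sandwich with HC1 small-sample
scaling; share standard errors follow by the delta method (the shares are
linear in the coefficients).

Two estimators are provided: the cost-function regression above (default)
and a stacked share-system regression of observed expenditure shares on log
normalized prices with cross-equation symmetry imposed, for sensitivity
analysis.

Usage follows the Model/Results convention::

    model = TranslogCostModel.from_records(records, level="hospital")
    res = model.fit()            # TranslogResults
    est = res.shares()           # ShareEstimates with delta-method SEs
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import DEFAULT_FACTOR_SHARES
from .errors import EstimationError
from .types import FacilityCostRecord, FactorShares

#: Factor order; the last factor is the numeraire used to impose homogeneity.
FACTORS: Tuple[str, ...] = ("personnel", "consumables", "odc", "indirect")

_PRICE_COLS = tuple(f"price_{f}" for f in FACTORS)
_REQUIRED_COLS = ("total_cost", "output_volume") + _PRICE_COLS


def _param_names(interaction: bool) -> Tuple[str, ...]:
    non_num = FACTORS[:3]
    names = ["const"]
    names += [f"beta_{f}" for f in non_num]
    names += [f"gamma_{f}_{f}" for f in non_num]
    names += [
        f"gamma_{non_num[i]}_{non_num[j]}"
        for i in range(3)
        for j in range(i + 1, 3)
    ]
    names.append("delta_y")
    if interaction:
        names += [f"theta_{f}" for f in non_num]
    return tuple(names)


def _design_matrix(
    z: np.ndarray, lny: np.ndarray, interaction: bool
) -> np.ndarray:
    """Regressor matrix for the normalized translog.

    ``z`` holds the three log normalized prices. Diagonal quadratic terms
    enter as 0.5*z_i^2 (their coefficient is gamma_ii); cross terms enter as
    z_i*z_j once for i<j (their coefficient is the common gamma_ij, since the
    symmetric pair contributes gamma_ij*z_i*z_j to the double sum).
    """
    n = z.shape[0]
    cols = [np.ones(n)]
    cols += [z[:, i] for i in range(3)]
    cols += [0.5 * z[:, i] ** 2 for i in range(3)]
    cols += [z[:, i] * z[:, j] for i in range(3) for j in range(i + 1, 3)]
    cols.append(lny)
    if interaction:
        cols += [z[:, i] * lny for i in range(3)]
    return np.column_stack(cols)


def sandwich_covariance(X: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Huber/White sandwich covariance of OLS coefficients, HC1 scaling.

    ``(X'X)^{-1} X' diag(e^2) X (X'X)^{-1}`` scaled by ``n/(n-k)``. Requires a
    full-rank design.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(resid, dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise EstimationError("design matrix is rank deficient")
    if n <= k:
        raise EstimationError(f"need more than k={k} rows, got {n}")
    xtx_inv = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * (e**2)[:, None])
    return xtx_inv @ meat @ xtx_inv * (n / (n - k))


@dataclass(frozen=True)
class ShareEstimates:
    """Point estimates and robust SEs for the four factor shares.

    Shares sum to one exactly: the numeraire share is the complement of the
    other three.
    """

    level: Optional[str]
    shares: Dict[str, float]
    se: Dict[str, float]
    n_obs: int
    eval_point: Dict[str, float]

    def conf_int(self, alpha: float = 0.05) -> Dict[str, Tuple[float, float]]:
        zcrit = stats.norm.ppf(1 - alpha / 2)
        return {
            f: (self.shares[f] - zcrit * self.se[f], self.shares[f] + zcrit * self.se[f])
            for f in FACTORS
        }

    def to_factor_shares(self) -> FactorShares:
        if self.level is None:
            raise EstimationError("cannot build FactorShares without a level")
        return FactorShares(
            level=self.level,
            s_personnel=self.shares["personnel"],
            s_consumables=self.shares["consumables"],
            s_odc=self.shares["odc"],
            s_indirect=self.shares["indirect"],
        )


class TranslogResults:
    """Fitted translog cost function with robust covariance.

    Attributes
    ----------
    params : pd.Series
        Coefficients: intercept, first-order ``beta_*`` (three non-numeraire
        factors), second-order ``gamma_*_*`` (symmetric, numeraire terms
        recovered implicitly by homogeneity), and the output elasticity
        ``delta_y``.
    cov_params : pd.DataFrame
        HC1 sandwich covariance of the coefficients.
    bse : pd.Series
        Robust standard errors.
    rsquared_adj : float
        Adjusted R^2 of the transformed regression.
    eval_point : pd.Series
        Sample mean of the log normalized prices; default evaluation point
        for the shares.
    """

    def __init__(
        self,
        model: "TranslogCostModel",
        params: np.ndarray,
        cov: np.ndarray,
        resid: np.ndarray,
        rsquared: float,
        rsquared_adj: float,
        eval_point: np.ndarray,
    ):
        self.model = model
        names = list(_param_names(model.price_output_interaction))
        self.params = pd.Series(params, index=names)
        self.cov_params = pd.DataFrame(cov, index=names, columns=names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self.resid = resid
        self.rsquared = rsquared
        self.rsquared_adj = rsquared_adj
        self.nobs = len(resid)
        self.df_resid = self.nobs - len(names)
        self.level = model.level
        self.eval_point = pd.Series(
            eval_point, index=[f"lp_{f}" for f in FACTORS[:3]]
        )

    @property
    def gamma(self) -> pd.DataFrame:
        """Symmetric 3x3 matrix of second-order coefficients (non-numeraire)."""
        non_num = FACTORS[:3]
        G = np.zeros((3, 3))
        for i in range(3):
            G[i, i] = self.params[f"gamma_{non_num[i]}_{non_num[i]}"]
            for j in range(i + 1, 3):
                G[i, j] = G[j, i] = self.params[f"gamma_{non_num[i]}_{non_num[j]}"]
        return pd.DataFrame(G, index=non_num, columns=non_num)

    def _share_gradients(self, z: np.ndarray) -> np.ndarray:
        """Rows i=0..3: gradient of share i w.r.t. the full parameter vector."""
        names = list(self.params.index)
        non_num = FACTORS[:3]
        A = np.zeros((4, len(names)))
        for i in range(3):
            A[i, names.index(f"beta_{non_num[i]}")] = 1.0
            A[i, names.index(f"gamma_{non_num[i]}_{non_num[i]}")] = z[i]
            for j in range(3):
                if j == i:
                    continue
                lo, hi = min(i, j), max(i, j)
                A[i, names.index(f"gamma_{non_num[lo]}_{non_num[hi]}")] += z[j]
            if self.model.price_output_interaction:
                A[i, names.index(f"theta_{non_num[i]}")] = self.model._lny_mean
        A[3] = -A[:3].sum(axis=0)
        return A

    def shares(
        self, eval_point: Optional[Sequence[float]] = None
    ) -> ShareEstimates:
        """Factor shares by differentiation, with delta-method robust SEs.

        ``eval_point`` is a length-3 vector of log normalized prices; defaults
        to the sample mean. The numeraire share is the complement of the other
        three so the four sum to one exactly.
        """
        z = (
            np.asarray(self.eval_point, dtype=float)
            if eval_point is None
            else np.asarray(eval_point, dtype=float)
        )
        if z.shape != (3,):
            raise EstimationError(
                f"eval_point must have length 3, got shape {z.shape}"
            )
        non_num = FACTORS[:3]
        G = self.gamma.to_numpy()
        s = np.empty(4)
        for i in range(3):
            s[i] = self.params[f"beta_{non_num[i]}"] + G[i] @ z
            if self.model.price_output_interaction:
                s[i] += self.params[f"theta_{non_num[i]}"] * self.model._lny_mean
        s[3] = 1.0 - s[:3].sum()
        A = self._share_gradients(z)
        cov_s = A @ self.cov_params.to_numpy() @ A.T
        se = np.sqrt(np.clip(np.diag(cov_s), 0.0, None))
        return ShareEstimates(
            level=self.level,
            shares=dict(zip(FACTORS, s)),
            se=dict(zip(FACTORS, se)),
            n_obs=self.nobs,
            eval_point=dict(zip(non_num, z)),
        )

    def summary(self) -> str:
        """Plain-text summary: fit statistics, robust coefficient table, shares."""
        lines = []
        title = "Translog cost function"
        if self.level:
            lines.append(f"{title} — level: {self.level}")
        else:
            lines.append(title)
        lines.append(
            f"n = {self.nobs}, adj. R^2 = {self.rsquared_adj:.4f}, "
            "cov: HC1 (Huber/White sandwich)"
        )
        lines.append("-" * 62)
        lines.append(f"{'coef':<28}{'estimate':>12}{'rob. SE':>12}{'z':>9}")
        for name in self.params.index:
            b, se = self.params[name], self.bse[name]
            zval = b / se if se > 0 else np.inf
            lines.append(f"{name:<28}{b:>12.5f}{se:>12.5f}{zval:>9.2f}")
        lines.append("-" * 62)
        est = self.shares()
        lines.append("Factor shares at mean log normalized prices:")
        for f in FACTORS:
            lines.append(
                f"  {f:<14}{est.shares[f] * 100:>7.1f}%   (SE {est.se[f] * 100:.2f} pp)"
            )
        return "\n".join(lines)


class TranslogCostModel:
    """Translog cost-function model for one facility level.

    Parameters
    ----------
    data : pd.DataFrame
        Columns ``total_cost``, ``price_personnel``, ``price_consumables``,
        ``price_odc``, ``price_indirect``, ``output_volume``; optionally
        ``level`` (filtered when ``level`` is given) and observed ``share_*``
        columns for the share-system estimator.
    level : str, optional
        Facility level ("hospital" or "health_centre") to select and record.
    price_output_interaction : bool
        Include price-output interaction terms (non-homothetic technology).
        Off by default.
    """

    #: minimum observations beyond the regressor count
    MIN_EXTRA_OBS = 5

    def __init__(
        self,
        data: pd.DataFrame,
        level: Optional[str] = None,
        *,
        price_output_interaction: bool = False,
    ):
        df = data
        if level is not None and "level" in df.columns:
            df = df[df["level"] == level]
        missing = [c for c in _REQUIRED_COLS if c not in df.columns]
        if missing:
            raise EstimationError(f"facility data missing columns {missing}")
        df = df.reset_index(drop=True)
        if (df[list(_PRICE_COLS)] <= 0).to_numpy().any():
            raise EstimationError("factor prices must be strictly positive")
        if (df["total_cost"] <= 0).any() or (df["output_volume"] <= 0).any():
            raise EstimationError("total_cost and output_volume must be positive")
        self.data = df
        self.level = level
        self.price_output_interaction = price_output_interaction

        lnp = np.log(df[list(_PRICE_COLS)].to_numpy(dtype=float))
        self._z = lnp[:, :3] - lnp[:, 3:4]  # log prices normalized by numeraire
        self._lny = np.log(df["output_volume"].to_numpy(dtype=float))
        self._lny_mean = float(self._lny.mean())
        self._y = np.log(df["total_cost"].to_numpy(dtype=float)) - lnp[:, 3]
        self.exog = _design_matrix(self._z, self._lny, price_output_interaction)
        self.endog = self._y
        self.k_params = self.exog.shape[1]

    @classmethod
    def from_records(
        cls,
        records: Iterable[Union[FacilityCostRecord, Mapping]],
        level: Optional[str] = None,
        **kwargs,
    ) -> "TranslogCostModel":
        rows = [
            r.model_dump() if isinstance(r, FacilityCostRecord) else dict(r)
            for r in records
        ]
        return cls(pd.DataFrame(rows), level=level, **kwargs)

    def fit(self) -> TranslogResults:
        """Ordinary least squares with HC1 sandwich covariance."""
        X, y = self.exog, self.endog
        n, k = X.shape
        if n < k + self.MIN_EXTRA_OBS:
            raise EstimationError(
                f"insufficient observations: need at least {k + self.MIN_EXTRA_OBS} "
                f"({k} regressors + {self.MIN_EXTRA_OBS}), got {n}"
            )
        if np.linalg.matrix_rank(X) < k:
            raise EstimationError(
                "singular design matrix (degenerate prices or output)"
            )
        params, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ params
        cov = sandwich_covariance(X, resid)
        sst = float(((y - y.mean()) ** 2).sum())
        ssr = float((resid**2).sum())
        rsq = 1.0 if sst == 0 else 1.0 - ssr / sst
        rsq_adj = 1.0 - (1.0 - rsq) * (n - 1) / (n - k)
        return TranslogResults(
            model=self,
            params=params,
            cov=cov,
            resid=resid,
            rsquared=rsq,
            rsquared_adj=rsq_adj,
            eval_point=self._z.mean(axis=0),
        )


def fit_translog(
    records: Union[pd.DataFrame, Iterable[Union[FacilityCostRecord, Mapping]]],
    level: Optional[str] = None,
    **kwargs,
) -> TranslogResults:
    """Convenience wrapper: build a :class:`TranslogCostModel` and fit it."""
    if isinstance(records, pd.DataFrame):
        return TranslogCostModel(records, level=level, **kwargs).fit()
    return TranslogCostModel.from_records(records, level=level, **kwargs).fit()


def derive_shares(
    fit: TranslogResults, eval_point: Optional[Sequence[float]] = None
) -> ShareEstimates:
    """Factor shares from a fitted translog (Shephard's lemma), with SEs."""
    return fit.shares(eval_point=eval_point)


# ---------------------------------------------------------------------------
# share-system estimator (sensitivity alternative)
# ---------------------------------------------------------------------------

_SHARE_COLS = ("share_personnel", "share_consumables", "share_odc")


class ShareSystemResults:
    """Stacked share-system fit: observed expenditure shares regressed on log
    normalized prices with cross-equation symmetry imposed.

    Exposes ``params``, ``cov_params`` (HC1 on the stacked system) and
    :meth:`shares` with the same semantics as :class:`TranslogResults`.
    """

    def __init__(self, params, cov, names, eval_point, n_obs, level):
        self.params = pd.Series(params, index=names)
        self.cov_params = pd.DataFrame(cov, index=names, columns=names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self.eval_point = pd.Series(eval_point, index=[f"lp_{f}" for f in FACTORS[:3]])
        self.nobs = n_obs
        self.level = level

    def shares(self, eval_point: Optional[Sequence[float]] = None) -> ShareEstimates:
        z = (
            np.asarray(self.eval_point, dtype=float)
            if eval_point is None
            else np.asarray(eval_point, dtype=float)
        )
        if z.shape != (3,):
            raise EstimationError(f"eval_point must have length 3, got {z.shape}")
        non_num = FACTORS[:3]
        names = list(self.params.index)
        A = np.zeros((4, len(names)))
        s = np.empty(4)
        for i in range(3):
            A[i, names.index(f"beta_{non_num[i]}")] = 1.0
            for j in range(3):
                lo, hi = min(i, j), max(i, j)
                A[i, names.index(f"gamma_{non_num[lo]}_{non_num[hi]}")] += z[j]
            s[i] = A[i] @ self.params.to_numpy()
        s[3] = 1.0 - s[:3].sum()
        A[3] = -A[:3].sum(axis=0)
        cov_s = A @ self.cov_params.to_numpy() @ A.T
        se = np.sqrt(np.clip(np.diag(cov_s), 0.0, None))
        return ShareEstimates(
            level=self.level,
            shares=dict(zip(FACTORS, s)),
            se=dict(zip(FACTORS, se)),
            n_obs=self.nobs,
            eval_point=dict(zip(non_num, z)),
        )


def fit_share_system(
    data: pd.DataFrame, level: Optional[str] = None
) -> ShareSystemResults:
    """Estimate the three non-numeraire share equations jointly.

    Each observed share ``w_i = beta_i + sum_j gamma_ij ln(p_j/p_4)`` is
    stacked into one regression with symmetry (``gamma_ij = gamma_ji``)
    imposed through shared coefficients; the numeraire equation is dropped
    (adding-up). Requires observed ``share_*`` columns.
    """
    df = data
    if level is not None and "level" in df.columns:
        df = df[df["level"] == level]
    df = df.reset_index(drop=True)
    missing = [c for c in _PRICE_COLS + _SHARE_COLS if c not in df.columns]
    if missing:
        raise EstimationError(f"share-system estimator needs columns {missing}")
    if df[list(_SHARE_COLS)].isna().to_numpy().any():
        raise EstimationError("share-system estimator: missing observed shares")
    n = len(df)
    lnp = np.log(df[list(_PRICE_COLS)].to_numpy(dtype=float))
    z = lnp[:, :3] - lnp[:, 3:4]
    non_num = FACTORS[:3]
    names = [f"beta_{f}" for f in non_num] + [
        f"gamma_{non_num[i]}_{non_num[j]}"
        for i in range(3)
        for j in range(i, 3)
    ]
    k = len(names)
    X = np.zeros((3 * n, k))
    y = np.empty(3 * n)
    for i in range(3):
        rows = slice(i * n, (i + 1) * n)
        y[rows] = df[_SHARE_COLS[i]].to_numpy(dtype=float)
        X[rows, names.index(f"beta_{non_num[i]}")] = 1.0
        for j in range(3):
            lo, hi = min(i, j), max(i, j)
            X[rows, names.index(f"gamma_{non_num[lo]}_{non_num[hi]}")] += z[:, j]
    if n < k + TranslogCostModel.MIN_EXTRA_OBS:
        raise EstimationError(
            f"insufficient observations for share system: got {n}"
        )
    if np.linalg.matrix_rank(X) < k:
        raise EstimationError("singular design in share system")
    params, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ params
    cov = sandwich_covariance(X, resid)
    return ShareSystemResults(
        params=params,
        cov=cov,
        names=names,
        eval_point=z.mean(axis=0),
        n_obs=n,
        level=level,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def shares_report(
    fits: Optional[Mapping[str, Union[ShareEstimates, FactorShares]]] = None,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Factor-share table by facility level, in percent at one decimal.

    With no argument, reports the packaged default proportions (the published
    estimates applied by the costing engine). Pass fitted
    :class:`ShareEstimates` (or :class:`FactorShares`) per level to report an
    estimation run instead; robust SEs and n are included when available.
    ``renormalize`` rescales each row to sum to exactly 100%.
    """
    if fits is None:
        fits = DEFAULT_FACTOR_SHARES
    missing = [lvl for lvl in ("hospital", "health_centre") if lvl not in fits]
    if missing:
        raise EstimationError(f"shares_report: missing level(s) {missing}")
    rows = []
    for lvl in ("hospital", "health_centre"):
        est = fits[lvl]
        if isinstance(est, FactorShares):
            shares = dict(zip(FACTORS, est.as_tuple()))
            se = {f: np.nan for f in FACTORS}
            n_obs = np.nan
        else:
            shares = dict(est.shares)
            se = dict(est.se)
            n_obs = est.n_obs
        total = sum(shares.values())
        scale = 1.0 / total if renormalize and total > 0 else 1.0
        row = {"level": lvl}
        for f in FACTORS:
            row[f"{f}_pct"] = round(shares[f] * scale * 100.0, 1)
        for f in FACTORS:
            row[f"se_{f}_pct"] = (
                round(se[f] * scale * 100.0, 2) if np.isfinite(se[f]) else np.nan
            )
        row["n_obs"] = n_obs
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")
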