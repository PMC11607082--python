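"""Partial least squares regression of the end-point BG ratio.

The model regresses one response — the population-level B-cell to
granulocyte ratio at the end time point — on five per-mouse predictors:

1. clonal-sum B-cell abundance at the pre-divergent time point,
2. clonal-sum granulocyte abundance at the pre-divergent time point,
3. the population BG ratio at the pre-divergent time point (FACS),
4. net clonal change in B-cell abundance (pre-divergent to end),
5. net clonal change in granulocyte abundance (pre-divergent to end).

Fitting uses the classical NIPALS algorithm on column-centered,
unit-variance-scaled data, deflating both predictor and response blocks,
with two components by default.  Variable importance of projection (VIP)
scores follow the standard weights-and-explained-variance formula

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

with SSY_a the response variance explained by component a; the mean of the
squared VIPs over the p predictors is 1 by construction, and predictors
with VIP > 1 are flagged as highly influential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CellType, TimePoint

PREDICTOR_NAMES = (
    "b_clonal_sum_pre",
    "gr_clonal_sum_pre",
    "bg_ratio_pre",
    "delta_b_clonal",
    "delta_gr_clonal",
)


def build_plsr_dataset(
    abundance: pd.DataFrame, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """One row per mouse with the five predictors and the response.

    ``abundance`` is a (filtered) clone-abundance table; ``phenotypes`` the
    per-(mouse, time point) population table with ``bg_ratio``.  Mice
    missing any required cell are dropped.
    """
    blood = abundance[abundance["cell_type"].isin((CellType.GR.value, CellType.B.value))]
    sums = blood.pivot_table(
        index="mouse_id",
        columns=["cell_type", "time_point"],
        values="abundance",
        aggfunc="sum",
        fill_value=0.0,
    )
    ratios = phenotypes.pivot_table(
        index="mouse_id", columns="time_point", values="bg_ratio", aggfunc="first"
    )
    rows = []
    for mouse in sums.index:
        try:
            b_pre = sums.loc[mouse, (CellType.B.value, TimePoint.PRE_DIVERGENT.value)]
            gr_pre = sums.loc[mouse, (CellType.GR.value, TimePoint.PRE_DIVERGENT.value)]
            b_end = sums.loc[mouse, (CellType.B.value, TimePoint.END.value)]
            gr_end = sums.loc[mouse, (CellType.GR.value, TimePoint.END.value)]
            ratio_pre = ratios.loc[mouse, TimePoint.PRE_DIVERGENT.value]
            ratio_end = ratios.loc[mouse, TimePoint.END.value]
        except KeyError:
            continue
        if np.isnan([b_pre, gr_pre, b_end, gr_end, ratio_pre, ratio_end]).any():
            continue
        rows.append(
            {
                "mouse_id": mouse,
                "b_clonal_sum_pre": float(b_pre),
                "gr_clonal_sum_pre": float(gr_pre),
                "bg_ratio_pre": float(ratio_pre),
                "delta_b_clonal": float(b_end - b_pre),
                "delta_gr_clonal": float(gr_end - gr_pre),
                "bg_ratio_end": float(ratio_end),
            }
        )
    return pd.DataFrame(rows)


class PLSRegressionNipals:
    """NIPALS partial least squares regression with a single response.

    Parameters
    ----------
    X : (n, p) array or DataFrame of predictors
    y : (n,) array or Series response
    n_components : int, default 2
    scale : bool, default True
        Center and scale columns to unit variance before fitting (VIP
        conventions assume it).
    """

    def __init__(self, X, y, n_components: int = 2, scale: bool = True,
                 tol: float = 1e-10, max_iter: int = 500):
        if isinstance(X, pd.DataFrame):
            self.predictor_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.predictor_names = [f"x{j + 1}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, p) with y of length n")
        n, p = X.shape
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if n_components > rank:
            raise ValueError(
                f"n_components={n_components} exceeds predictor rank {rank}"
            )
        x_sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(x_sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance predictor column: {self.predictor_names[zero[0]]}"
            )
        if y.std(ddof=1) == 0:
            raise ValueError("response has zero variance; PLSR undefined")
        self.X, self.y = X, y
        self.n_components = n_components
        self.scale = scale
        self.tol, self.max_iter = tol, max_iter

    def fit(self) -> "PLSResults":
        X, y = self.X, self.y
        n, p = X.shape
        A = self.n_components
        x_mean, y_mean = X.mean(axis=0), y.mean()
        x_sd = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        y_sd = y.std(ddof=1) if self.scale else 1.0
        Xc = (X - x_mean) / x_sd
        yc = (y - y_mean) / y_sd

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        Q = np.zeros(A)
        T = np.zeros((n, A))
        Xa, ya = Xc.copy(), yc.copy()
        for a in range(A):
            u = ya.copy()
            w = np.zeros(p)
            for _ in range(self.max_iter):
                w_new = Xa.T @ u
                norm = np.linalg.norm(w_new)
                if norm == 0:
                    raise RuntimeError(f"NIPALS collapsed at component {a + 1}")
                w_new /= norm
                t = Xa @ w_new
                q = (ya @ t) / (t @ t)
                u_new = ya * q
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w, u = w_new, u_new
            t = Xa @ w
            q = (ya @ t) / (t @ t)
            pvec = (Xa.T @ t) / (t @ t)
            Xa = Xa - np.outer(t, pvec)
            ya = ya - t * q
            W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, q, t

        # regression coefficients on the standardized scale
        R = W @ np.linalg.inv(P.T @ W)  # X-rotations
        beta_std = R @ Q
        fitted_std = Xc @ beta_std
        fitted = fitted_std * y_sd + y_mean
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y_mean) ** 2))
        r2 = 1.0 - ss_res / ss_tot

        ssy = Q**2 * np.einsum("ij,ij->j", T, T)  # response variance per component
        wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
        vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())

        return PLSResults(
            model=self,
            weights=W,
            x_loadings=P,
            y_loadings=Q,
            scores=T,
            x_rotations=R,
            coef_std=beta_std,
            x_mean=x_mean,
            x_sd=x_sd,
            y_mean=y_mean,
            y_sd=y_sd,
            fitted=fitted,
            r2=r2,
            vip=vip,
        )


@dataclass
class PLSResults:
    """Fitted PLSR: loadings, scores, VIP scores and goodness of fit."""

    model: PLSRegressionNipals
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    x_rotations: np.ndarray
    coef_std: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    fitted: np.ndarray
    r2: float
    vip: np.ndarray

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean) / self.x_sd
        return Xs @ self.coef_std * self.y_sd + self.y_mean

    @property
    def influential(self) -> list[str]:
        """Predictors with VIP > 1 (highly influential on the response)."""
        return [n for n, v in zip(self.model.predictor_names, self.vip) if v > 1.0]

    def vip_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.model.predictor_names,
                "vip": self.vip,
                "influential": self.vip > 1.0,
                "coef_std": self.coef_std,
            }
        )

    def summary(self) -> str:
        lines = [
            "PLSR of end-point BG ratio",
            "==========================",
            f"mice: {self.model.X.shape[0]}   predictors: {self.model.X.shape[1]}   "
            f"components: {self.model.n_components}",
            f"R^2: {self.r2:.4f}",
            "",
            "predictor             VIP     std. coef",
        ]
        for name, v, c in zip(self.model.predictor_names, self.vip, self.coef_std):
            mark = " *" if v > 1 else ""
            lines.append(f"{name:<20} {v:6.3f}  {c:10.4f}{mark}")
        lines.append("(* VIP > 1: highly influential)")
        return "\n".join(lines)
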