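"""Maximum-likelihood covariance-structure (SEM) engine with mean structure.

Models are path models over observed and latent variables, held in the
usual three-matrix parameterization: a directed-coefficient matrix ``A``
(entry ``A[target, source]``), a symmetric residual/exogenous
(co)variance matrix ``Psi``, and an intercept/mean vector ``m``.  With
``B = (I − A)⁻¹`` the model-implied moments of the observed subset are

    Σ(θ) = F B Psi Bᵀ Fᵀ,        μ(θ) = F B m,

where ``F`` filters the observed rows.  Estimation minimizes the ML
discrepancy

    F_ML = ln|Σ| + tr(S Σ⁻¹) − ln|S| − p + (x̄ − μ)ᵀ Σ⁻¹ (x̄ − μ)

between sample moments (S, x̄; covariance with the n−1 denominator) and
implied moments; the model chi-square is (n − 1)·F_min, matching the
convention of the commercial SEM packages this work parallels.

Free parameters are labeled entries; entries sharing a label are
constrained equal.  Variances are optimized on the log scale so the
implied covariance stays positive definite along the search path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .data_model import MomentData
from .exceptions import (
    DegenerateVarianceError,
    IdentificationError,
    StructuralError,
)

__all__ = [
    "SemModel", "FitOptions", "FitResult", "FitIndices",
    "implied_moments", "implied_moments_full", "ml_discrepancy",
    "fit_model", "standard_errors", "baseline_model", "fit_indices",
    "explained_variance", "growth_explained_variance",
]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

class SemModel:
    """Path-model specification with fixed, free and equality-constrained entries.

    Entries are set with :meth:`set_path`, :meth:`set_variance`,
    :meth:`set_covariance` and :meth:`set_mean`; passing ``label=`` makes
    an entry free (entries sharing a label share one parameter), omitting
    it fixes the entry at ``value``.
    """

    def __init__(self, names: Sequence[str], observed: Sequence[str]):
        self.names = list(names)
        if len(set(self.names)) != len(self.names):
            raise StructuralError("duplicate variable names")
        unknown = [v for v in observed if v not in self.names]
        if unknown:
            raise StructuralError(f"observed variables not declared: {unknown}")
        self.observed = list(observed)
        k = len(self.names)
        self._idx = {v: i for i, v in enumerate(self.names)}
        self.A = np.zeros((k, k))
        self.A_label = np.full((k, k), None, dtype=object)
        self.Psi = np.zeros((k, k))
        self.Psi_label = np.full((k, k), None, dtype=object)
        self.m = np.zeros(k)
        self.m_label = np.full(k, None, dtype=object)

    # -- construction -------------------------------------------------------

    def idx(self, name: str) -> int:
        try:
            return self._idx[name]
        except KeyError as exc:
            raise StructuralError(f"unknown variable {name!r}") from exc

    def set_path(self, source: str, target: str, *, value: float = 0.0,
                 label: str | None = None) -> None:
        i, j = self.idx(target), self.idx(source)
        if i == j:
            raise StructuralError(f"{target!r} cannot be its own parent")
        self.A[i, j] = value
        self.A_label[i, j] = label

    def set_variance(self, name: str, *, value: float = 0.0,
                     label: str | None = None) -> None:
        i = self.idx(name)
        self.Psi[i, i] = value
        self.Psi_label[i, i] = label

    def set_covariance(self, a: str, b: str, *, value: float = 0.0,
                       label: str | None = None) -> None:
        i, j = self.idx(a), self.idx(b)
        if i == j:
            raise StructuralError("use set_variance for diagonal entries")
        self.Psi[i, j] = self.Psi[j, i] = value
        self.Psi_label[i, j] = self.Psi_label[j, i] = label

    def set_mean(self, name: str, *, value: float = 0.0,
                 label: str | None = None) -> None:
        i = self.idx(name)
        self.m[i] = value
        self.m_label[i] = label

    # -- parameter bookkeeping ---------------------------------------------

    @property
    def latent_names(self) -> list[str]:
        return [v for v in self.names if v not in self.observed]

    @property
    def free_labels(self) -> list[str]:
        """Distinct free-parameter labels, in order of first appearance
        (A row-major, then lower triangle of Psi, then means)."""
        seen: dict[str, None] = {}
        k = len(self.names)
        for i in range(k):
            for j in range(k):
                lab = self.A_label[i, j]
                if lab is not None:
                    seen.setdefault(lab)
        for i in range(k):
            for j in range(i + 1):
                lab = self.Psi_label[i, j]
                if lab is not None:
                    seen.setdefault(lab)
        for i in range(k):
            lab = self.m_label[i]
            if lab is not None:
                seen.setdefault(lab)
        return list(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    @property
    def variance_labels(self) -> set[str]:
        """Labels that sit (only) on the Psi diagonal — kept positive during
        optimization via a log transform."""
        diag = {self.Psi_label[i, i] for i in range(len(self.names))
                if self.Psi_label[i, i] is not None}
        offdiag = set()
        k = len(self.names)
        for i in range(k):
            for j in range(k):
                if i != j and self.Psi_label[i, j] is not None:
                    offdiag.add(self.Psi_label[i, j])
                if self.A_label[i, j] is not None:
                    offdiag.add(self.A_label[i, j])
        for i in range(k):
            if self.m_label[i] is not None:
                offdiag.add(self.m_label[i])
        mixed = diag & offdiag
        if mixed:
            raise StructuralError(
                f"label(s) {sorted(mixed)} constrain a variance equal to a "
                "non-variance entry; use distinct labels"
            )
        return diag

    def validate(self) -> None:
        if np.any(np.diag(self.A) != 0) or any(
                self.A_label[i, i] is not None for i in range(len(self.names))):
            raise StructuralError("diag(A) must be zero (no self-loops)")
        self.variance_labels  # raises on mixed labels

    def degrees_of_freedom(self) -> int:
        """Moments minus free parameters, counting p(p+1)/2 covariance
        moments plus p means for the observed variables."""
        p = len(self.observed)
        return p * (p + 1) // 2 + p - self.n_free

    # -- evaluation ---------------------------------------------------------

    def materialize(self, theta: Mapping[str, float]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Numeric (A, Psi, m) at the parameter assignment ``theta``."""
        missing = [lab for lab in self.free_labels if lab not in theta]
        if missing:
            raise StructuralError(f"theta missing labels: {missing}")
        A = self.A.copy()
        Psi = self.Psi.copy()
        m = self.m.copy()
        k = len(self.names)
        for i in range(k):
            for j in range(k):
                if self.A_label[i, j] is not None:
                    A[i, j] = theta[self.A_label[i, j]]
                if self.Psi_label[i, j] is not None:
                    Psi[i, j] = theta[self.Psi_label[i, j]]
            if self.m_label[i] is not None:
                m[i] = theta[self.m_label[i]]
        return A, Psi, m

    def observed_index(self) -> np.ndarray:
        return np.array([self.idx(v) for v in self.observed])

    def compile(self):
        """Vectorized materializer: theta-vector -> (A, Psi, m).

        Precomputes index arrays for the free entries so repeated
        evaluation inside the optimizer avoids Python loops.
        """
        labels = self.free_labels
        pos = {lab: i for i, lab in enumerate(labels)}
        k = len(self.names)

        def entries(label_arr):
            ii, jj, pp = [], [], []
            it = np.ndindex(label_arr.shape)
            for index in it:
                lab = label_arr[index]
                if lab is not None:
                    ii.append(index[0])
                    jj.append(index[1] if len(index) > 1 else 0)
                    pp.append(pos[lab])
            return (np.array(ii, dtype=int), np.array(jj, dtype=int),
                    np.array(pp, dtype=int))

        A_i, A_j, A_p = entries(self.A_label)
        S_i, S_j, S_p = entries(self.Psi_label)
        m_i, _, m_p = entries(self.m_label.reshape(-1, 1))
        A0, S0, m0 = self.A.copy(), self.Psi.copy(), self.m.copy()

        def materialize_vec(theta: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            A = A0.copy(); Psi = S0.copy(); m = m0.copy()
            if len(A_p):
                A[A_i, A_j] = theta[A_p]
            if len(S_p):
                Psi[S_i, S_j] = theta[S_p]
            if len(m_p):
                m[m_i] = theta[m_p]
            return A, Psi, m

        index_arrays = ((A_i, A_j, A_p), (S_i, S_j, S_p), (m_i, m_p))
        return labels, materialize_vec, index_arrays


# ---------------------------------------------------------------------------
# Implied moments and discrepancy
# ---------------------------------------------------------------------------

def implied_moments_full(model: SemModel, theta: Mapping[str, float]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Implied covariance and means over *all* (observed + latent) variables."""
    A, Psi, m = model.materialize(theta)
    k = len(model.names)
    try:
        B = np.linalg.solve(np.eye(k) - A, np.eye(k))
    except np.linalg.LinAlgError as exc:
        raise StructuralError(
            "(I − A) is singular: the path matrix contains a cycle with "
            "unit loop product"
        ) from exc
    sigma = B @ Psi @ B.T
    mu = B @ m
    return (sigma + sigma.T) / 2.0, mu


def implied_moments(model: SemModel, theta: Mapping[str, float]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Implied covariance matrix and mean vector of the observed variables."""
    sigma, mu = implied_moments_full(model, theta)
    idx = model.observed_index()
    return sigma[np.ix_(idx, idx)], mu[idx]


def ml_discrepancy(sigma: np.ndarray, mu: np.ndarray,
                   S: np.ndarray, xbar: np.ndarray) -> float:
    """ML discrepancy between implied (sigma, mu) and sample (S, xbar).

    Nonnegative, and zero exactly when the moments are reproduced.
    Raises :class:`DegenerateVarianceError` when ``sigma`` is not positive
    definite (the optimizer treats that as a rejected step — never a
    silent NaN).
    """
    p = S.shape[0]
    try:
        c, low = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DegenerateVarianceError(
            "implied covariance is not positive definite"
        ) from exc
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegenerateVarianceError("sample covariance is not positive definite")
    d = xbar - mu
    return float(
        logdet_sigma + np.trace(cho_solve((c, low), S)) - logdet_s - p
        + d @ cho_solve((c, low), d)
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimizer controls for :func:`fit_model`."""

    start: dict[str, float] | None = None
    max_iter: int = 2000
    g_tol: float = 1e-9
    compute_se: bool = True
    #: Newton polish steps (numerical Hessian) after quasi-Newton search.
    polish_steps: int = 3


@dataclass
class FitIndices:
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    pclose: float


@dataclass
class FitResult:
    """Converged (or flagged) ML fit: parameter table and fit statistics."""

    model: SemModel = field(repr=False)
    params: pd.DataFrame = field(repr=False)
    theta: dict[str, float] = field(repr=False)
    f_min: float
    chi2: float
    df: int
    p_value: float
    n: int
    baseline_chi2: float
    baseline_df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    pclose: float
    r2: dict[str, float]
    converged: bool
    iterations: int
    warnings: list[str] = field(default_factory=list)

    def parameter(self, label: str) -> pd.Series:
        row = self.params.loc[self.params["label"] == label]
        if row.empty:
            raise KeyError(f"no parameter labeled {label!r}")
        return row.iloc[0]

    def cr(self, label: str) -> float:
        return float(self.parameter(label)["cr"])

    def to_dict(self) -> dict:
        def _clean(x):
            return None if x is None or (isinstance(x, float) and not np.isfinite(x)) else x
        return {
            "parameters": [
                {"label": r["label"], "estimate": _clean(r["estimate"]),
                 "se": _clean(r["se"]), "cr": _clean(r["cr"]),
                 "p": _clean(r["p"])}
                for _, r in self.params.iterrows()
            ],
            "fit": {
                "chi2": _clean(self.chi2), "df": int(self.df),
                "p": _clean(self.p_value), "cfi": _clean(self.cfi),
                "tli": _clean(self.tli), "rmsea": _clean(self.rmsea),
                "rmsea_ci": [_clean(self.rmsea_ci[0]), _clean(self.rmsea_ci[1])],
                "pclose": _clean(self.pclose),
            },
            "r2": {k: _clean(v) for k, v in self.r2.items()},
            "converged": bool(self.converged),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _start_values(model: SemModel, data: MomentData) -> dict[str, float]:
    """Default starts: sample variances/means for observed moments, a
    least-squares fit of observed means on fixed loadings for latent
    means (for linear-growth factors this is the day-1 mean and the OLS
    slope of means over days), zero for paths and covariances."""
    s = dict(zip(data.variables, np.diag(data.covariance)))
    xbar = dict(zip(data.variables, data.means))
    start: dict[str, float] = {}
    k = len(model.names)
    endog = {model.names[i] for i in range(k)
             if np.any(model.A[i, :] != 0)
             or any(lab is not None for lab in model.A_label[i, :])}

    # latent means via least squares on fixed loadings
    lat_mean_labels = [(i, model.m_label[i]) for i in range(k)
                       if model.m_label[i] is not None
                       and model.names[i] not in model.observed]
    if lat_mean_labels:
        obs_rows = [model.idx(v) for v in model.observed if v in endog]
        if obs_rows:
            L = np.array([[model.A[r, i] for i, _ in lat_mean_labels]
                          for r in obs_rows])
            y = np.array([xbar.get(model.names[r], 0.0) for r in obs_rows])
            if np.linalg.matrix_rank(L) == len(lat_mean_labels):
                sol, *_ = np.linalg.lstsq(L, y, rcond=None)
            else:
                sol = np.zeros(len(lat_mean_labels))
            for (idx_, lab), v in zip(lat_mean_labels, sol):
                start.setdefault(lab, float(v))

    for i in range(k):
        name = model.names[i]
        lab = model.Psi_label[i, i]
        if lab is not None and lab not in start:
            if name in model.observed:
                v = s.get(name, 1.0)
                start[lab] = 0.5 * v if name in endog else v
            else:
                # latent variance: scale from the variables it loads on
                loads = [(model.A[model.idx(o), i], s.get(o, 1.0))
                         for o in model.observed
                         if model.A[model.idx(o), i] != 0]
                if loads:
                    lam2 = np.mean([l * l for l, _ in loads])
                    start[lab] = 0.5 * np.mean([v for _, v in loads]) / max(lam2, 1.0)
                else:
                    start[lab] = 1.0
        mlab = model.m_label[i]
        if mlab is not None and mlab not in start:
            start[mlab] = xbar.get(name, 0.0) if name in model.observed else 0.0
    for lab in model.free_labels:
        start.setdefault(lab, 0.0)
    return start


def _num_gradient(fun, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(len(x)):
        h = rel_step * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2 * h)
    return g


def _hessian_from_grad(f_and_grad, x: np.ndarray,
                       rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient (then
    symmetrized), step ``rel_step`` relative per axis."""
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        H[:, i] = (f_and_grad(xp)[1] - f_and_grad(xm)[1]) / (2 * h)
    return (H + H.T) / 2.0


def _num_hessian(fun, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian (step ``rel_step`` relative per axis)."""
    n = len(x)
    h = np.array([rel_step * max(1.0, abs(xi)) for xi in x])
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / (h[i] ** 2)
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4 * h[i] * h[j])
    return H


_PENALTY = 1e10


def _fast_objective(model: SemModel, S: np.ndarray, xbar: np.ndarray):
    """Discrepancy (and its analytic gradient) as functions of the raw
    theta vector.

    The gradient uses the standard path-model matrix calculus: with
    B = (I−A)⁻¹, M = B Psi Bᵀ, P = Σ⁻¹, d = x̄ − μ and

        G_Σ = P − P (S + d dᵀ) P,   ḡ = F̃ᵀ(−2 P d),

    the derivatives are ∂F/∂Psi = Bᵀ Ḡ B, ∂F/∂A = 2 Bᵀ Ḡ M + Bᵀ ḡ (B m)ᵀ
    and ∂F/∂m = Bᵀ ḡ, where Ḡ embeds G_Σ in the observed block.
    Returns ``(f, f_and_grad)``; non-PD implied covariance yields the
    penalty value (with a zero gradient) rather than a NaN.
    """
    labels, materialize_vec, index_arrays = model.compile()
    (A_i, A_j, A_p), (S_i, S_j, S_p), (m_i, m_p) = index_arrays
    n_free = len(labels)
    idx = model.observed_index()
    k = len(model.names)
    eye = np.eye(k)
    ix = np.ix_(idx, idx)
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise DegenerateVarianceError("sample covariance is not positive definite")

    def core(th: np.ndarray, with_grad: bool):
        A, Psi, m = materialize_vec(th)
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(Psi))
                and np.all(np.isfinite(m))):
            return _PENALTY, np.zeros(n_free)
        try:
            B = np.linalg.solve(eye - A, eye)
        except np.linalg.LinAlgError:
            return _PENALTY, np.zeros(n_free)
        M = B @ Psi @ B.T
        sigma = M[ix]
        mu = (B @ m)[idx]
        try:
            c, low = cho_factor((sigma + sigma.T) / 2.0, lower=True)
        except (np.linalg.LinAlgError, ValueError):
            return _PENALTY, np.zeros(n_free)
        d = xbar - mu
        Pinv_S = cho_solve((c, low), S)
        Pinv_d = cho_solve((c, low), d)
        val = (2.0 * np.sum(np.log(np.diag(c)))
               + np.trace(Pinv_S) - logdet_s - p + d @ Pinv_d)
        if not np.isfinite(val):
            return _PENALTY, np.zeros(n_free)
        if not with_grad:
            return float(val), None
        P = cho_solve((c, low), np.eye(p))
        G_sigma = P - P @ (S + np.outer(d, d)) @ P
        Gbar = np.zeros((k, k))
        Gbar[ix] = G_sigma
        gbar = np.zeros(k)
        gbar[idx] = -2.0 * Pinv_d
        Bt_G = B.T @ Gbar
        H_psi = Bt_G @ B
        Bm = B @ m
        Bt_g = B.T @ gbar
        grad_A = 2.0 * Bt_G @ M + np.outer(Bt_g, Bm)
        g = np.zeros(n_free)
        if len(A_p):
            np.add.at(g, A_p, grad_A[A_i, A_j])
        if len(S_p):
            np.add.at(g, S_p, H_psi[S_i, S_j])
        if len(m_p):
            np.add.at(g, m_p, Bt_g[m_i])
        return float(val), g

    def f(th: np.ndarray) -> float:
        return core(th, False)[0]

    def f_and_grad(th: np.ndarray) -> tuple[float, np.ndarray]:
        return core(th, True)

    return f, f_and_grad


def fit_model(model: SemModel, data: MomentData,
              options: FitOptions | None = None) -> FitResult:
    """Fit ``model`` to sample moments by maximum likelihood.

    Minimizes the ML discrepancy with a quasi-Newton (L-BFGS) search on a
    transformed parameterization (variances on the log scale) followed by
    damped Newton polish steps on the natural scale; deterministic given
    identical inputs and options.
    """
    options = options or FitOptions()
    model.validate()
    labels = model.free_labels
    df = model.degrees_of_freedom()
    if df < 0:
        raise IdentificationError(
            f"model has {model.n_free} free parameters but only "
            f"{model.n_free + df} sample moments (df = {df})"
        )
    md = data.subset(model.observed)
    p = md.p
    if md.n < p + 1:
        raise IdentificationError(
            f"n = {md.n} is too small for ML fitting of p = {p} variables"
        )
    S, xbar, n = md.covariance, md.means, md.n
    var_labels = model.variance_labels
    is_var = np.array([lab in var_labels for lab in labels])

    start = _start_values(model, md)
    if options.start:
        start.update(options.start)
    theta0 = np.array([start[lab] for lab in labels])
    theta0[is_var] = np.maximum(theta0[is_var], 1e-3)

    def to_theta(z: np.ndarray) -> np.ndarray:
        th = z.copy()
        th[is_var] = np.exp(np.clip(z[is_var], -60.0, 60.0))
        return th

    def to_z(th: np.ndarray) -> np.ndarray:
        z = th.copy()
        z[is_var] = np.log(np.maximum(th[is_var], 1e-12))
        return z

    f_theta, fg_theta = _fast_objective(model, S, xbar)

    def fg_z(z: np.ndarray) -> tuple[float, np.ndarray]:
        th = to_theta(z)
        val, g = fg_theta(th)
        gz = g.copy()
        gz[is_var] *= th[is_var]  # chain rule through the log transform
        return val, gz

    iterations = 0
    if labels:
        res = optimize.minimize(
            fg_z, to_z(theta0), method="L-BFGS-B", jac=True,
            options={"maxiter": options.max_iter, "ftol": 1e-15,
                     "gtol": options.g_tol, "maxcor": 40,
                     "maxfun": 10 * options.max_iter * max(1, len(labels))},
        )
        iterations = int(res.nit)
        theta_hat = to_theta(res.x)

        # damped Newton polish on the natural scale: drives the gradient to
        # machine noise so self-consistency recovery is exact to ~1e-8
        for _ in range(max(0, options.polish_steps)):
            g = fg_theta(theta_hat)[1]
            if np.max(np.abs(g)) < 1e-12:
                break
            H = _hessian_from_grad(fg_theta, theta_hat, rel_step=1e-5)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=1e-10)[0]
            if not np.all(np.isfinite(step)):
                break
            f_cur = f_theta(theta_hat)
            for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
                cand = theta_hat - damp * step
                if np.all(cand[is_var] > 0) and f_theta(cand) <= f_cur + 1e-14:
                    theta_hat = cand
                    break
            else:
                break
    else:
        theta_hat = theta0

    f_min = f_theta(theta_hat)
    grad = fg_theta(theta_hat)[1] if labels else np.zeros(0)
    # convergence is judged on the optimized (log-variance) scale: a
    # variance estimate at the zero boundary is a converged boundary
    # solution even though the natural-scale gradient cannot vanish there
    grad_opt = grad.copy()
    if labels:
        grad_opt[is_var] *= theta_hat[is_var]
    converged = bool(f_min < _PENALTY and
                     (not labels or np.max(np.abs(grad_opt)) < 1e-5))
    warnings_: list[str] = []
    if labels and converged and np.any(theta_hat[is_var] < 1e-8):
        warnings_.append(
            "one or more variance estimates are at the zero boundary; "
            "their standard errors are unreliable"
        )
    if not converged:
        warnings_.append(
            "optimizer did not meet the gradient tolerance; estimates and "
            "fit indices should not be interpreted"
        )

    theta_dict = dict(zip(labels, theta_hat))
    chi2_val = max((n - 1) * f_min, 0.0)
    p_chi2 = float(stats.chi2.sf(chi2_val, df)) if df > 0 else float("nan")

    # independence baseline (free variances and means): closed-form optimum
    # at sigma_ii = s_ii, mu = xbar, so chi2_b = -(n-1) ln|R|
    R = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
    sign, logdetR = np.linalg.slogdet(R)
    baseline_chi2 = float(max(-(n - 1) * logdetR, 0.0)) if sign > 0 else float("inf")
    baseline_df = p * (p - 1) // 2

    if converged and df >= 0:
        fi = fit_indices(chi2_val, df, baseline_chi2, baseline_df, n)
    else:
        fi = FitIndices(float("nan"), float("nan"), float("nan"),
                        (float("nan"), float("nan")), float("nan"))
        if not converged:
            warnings_.append("fit indices suppressed (non-convergence)")

    if options.compute_se and labels and converged:
        table, se_warn = standard_errors(model, md, theta_dict)
        warnings_.extend(se_warn)
    else:
        table = pd.DataFrame({
            "label": labels,
            "estimate": theta_hat,
            "se": np.full(len(labels), np.nan),
            "cr": np.full(len(labels), np.nan),
            "p": np.full(len(labels), np.nan),
        })

    r2 = explained_variance(theta_dict, model) if converged else {}

    return FitResult(
        model=model, params=table, theta=theta_dict, f_min=f_min,
        chi2=chi2_val, df=df, p_value=p_chi2, n=n,
        baseline_chi2=baseline_chi2, baseline_df=baseline_df,
        cfi=fi.cfi, tli=fi.tli, rmsea=fi.rmsea, rmsea_ci=fi.rmsea_ci,
        pclose=fi.pclose, r2=r2, converged=converged,
        iterations=iterations, warnings=warnings_,
    )


def standard_errors(model: SemModel, data: MomentData,
                    theta: Mapping[str, float]
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Wald standard errors from the numerically differentiated Hessian of
    ((n−1)/2)·F_ML at the optimum (central differences, relative step 1e-5).

    CR = estimate/SE; two-sided p from the standard normal.  A
    non-invertible Hessian yields missing SEs plus a boundary/
    identification warning.
    """
    labels = model.free_labels
    md = data.subset(model.observed)
    S, xbar, n = md.covariance, md.means, md.n

    _, fg_raw = _fast_objective(model, S, xbar)

    def fg_obj(th: np.ndarray) -> tuple[float, np.ndarray]:
        val, g = fg_raw(th)
        return 0.5 * (n - 1) * val, 0.5 * (n - 1) * g

    th = np.array([theta[lab] for lab in labels])
    H = _hessian_from_grad(fg_obj, th, rel_step=1e-5)
    warn: list[str] = []
    se = np.full(len(labels), np.nan)
    try:
        Hc = cho_factor((H + H.T) / 2.0)
        cov = cho_solve(Hc, np.eye(len(labels)))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        warn.append(
            "information matrix is singular (boundary or under-identified "
            "parameter); standard errors reported missing"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cr = np.where(se > 0, th / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(cr))
    return pd.DataFrame({"label": labels, "estimate": th, "se": se,
                         "cr": cr, "p": pvals}), warn


def baseline_model(data: MomentData) -> SemModel:
    """Independence baseline: free variances and free means, zero
    covariances.  Used as the reference model for CFI/TLI."""
    model = SemModel(data.variables, data.variables)
    for v in data.variables:
        model.set_variance(v, value=1.0, label=f"var_{v}")
        model.set_mean(v, label=f"mean_{v}")
    return model


def fit_indices(chi2: float, df: int, chi2_baseline: float,
                df_baseline: int, n: int) -> FitIndices:
    """CFI, TLI and RMSEA (point, 90% CI, close-fit p) from chi-squares.

    RMSEA and its CI invert the noncentral chi-square at the 5%/95%
    points; the close-fit p ("PCLOSE") is evaluated at the RMSEA = 0.05
    reference.  With df = 0 the RMSEA is undefined and reported as NaN.
    """
    d = max(chi2 - df, 0.0)
    d_b = max(chi2_baseline - df_baseline, 0.0)
    denom = max(d_b, d)
    cfi = 1.0 if denom == 0 else 1.0 - d / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df > 0 and df_baseline > 0 and chi2_baseline / df_baseline > 1.0:
        ratio_b = chi2_baseline / df_baseline
        tli = (ratio_b - chi2 / df) / (ratio_b - 1.0)
        tli = float(min(tli, 1.0))
    else:
        tli = float("nan") if df == 0 else 1.0

    if df == 0:
        return FitIndices(cfi, tli, float("nan"),
                          (float("nan"), float("nan")), float("nan"))

    scale = df * (n - 1)
    rmsea = float(np.sqrt(d / scale))

    def ncp_for(prob: float) -> float:
        # largest lambda with P(X_{df,lambda} <= chi2) >= prob
        if stats.chi2.cdf(chi2, df) < prob:
            return 0.0
        lo, hi = 0.0, max(10.0, 2 * chi2)
        while stats.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2
            if hi > 1e8:
                break
        return float(optimize.brentq(
            lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob, lo, hi,
            xtol=1e-10))

    lam_lo = ncp_for(0.95)
    lam_hi = ncp_for(0.05)
    ci = (float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale)))
    lam_close = 0.05 ** 2 * scale
    pclose = float(stats.ncx2.sf(chi2, df, lam_close))
    return FitIndices(cfi, tli, rmsea, ci, pclose)


def explained_variance(theta: Mapping[str, float] | "FitResult",
                       model: SemModel | None = None) -> dict[str, float]:
    """Squared multiple correlations for endogenous variables.

    R² = 1 − (residual/disturbance variance)/(model-implied variance),
    for every variable — latent growth factors included — that receives
    at least one path.  Entries with non-positive implied variance are
    flagged as NaN.
    """
    if isinstance(theta, FitResult):
        model = theta.model
        theta = theta.theta
    assert model is not None
    sigma_full, _ = implied_moments_full(model, theta)
    _, Psi, _ = model.materialize(theta)
    out: dict[str, float] = {}
    k = len(model.names)
    for i in range(k):
        has_path = np.any(model.A[i, :] != 0) or any(
            lab is not None for lab in model.A_label[i, :])
        if not has_path:
            continue
        total = sigma_full[i, i]
        out[model.names[i]] = (
            float(1.0 - Psi[i, i] / total) if total > 0 else float("nan")
        )
    return out


def growth_explained_variance(fit: FitResult,
                              latents: Sequence[str] = ("ICEPT", "SLOPE")
                              ) -> float:
    """Combined R² of the growth factors: one minus the ratio of summed
    disturbance variances to summed implied factor variances."""
    sigma_full, _ = implied_moments_full(fit.model, fit.theta)
    _, Psi, _ = fit.model.materialize(fit.theta)
    idx = [fit.model.idx(v) for v in latents]
    resid = sum(Psi[i, i] for i in idx)
    total = sum(sigma_full[i, i] for i in idx)
    if total <= 0:
        return float("nan")
    return float(1.0 - resid / total)
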