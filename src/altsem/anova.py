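"""Mixed-design factorial ANOVA with sphericity diagnostics.

Between-subject factors (binary, full factorial with all interactions)
crossed with one within-subject factor — the T acquisition days.  Sums
of squares are Type III, computed from an effect-coded (deviation)
design matrix, matching the point-and-click GLM workflow this package
is compared against.  The within-subject block is analyzed on an
orthonormal contrast basis; sphericity is assessed with Mauchly's W and
within-subject tests are reported uncorrected and with Greenhouse–
Geisser and Huynh–Feldt corrected degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LongitudinalDataset, MomentData
from .exceptions import DegenerateVarianceError, DesignError

__all__ = [
    "AnovaResult", "MauchlyResult", "EpsilonResult",
    "mixed_anova", "mauchly_test", "mauchly_from_covariance",
    "epsilon_corrections", "epsilons_from_covariance",
    "partial_eta_squared", "sphericity_from_moments", "helmert_contrasts",
]


def helmert_contrasts(T: int) -> np.ndarray:
    """Orthonormal T×(T−1) contrast basis orthogonal to the unit vector."""
    C = np.zeros((T, T - 1))
    for k in range(T - 1):
        C[: k + 1, k] = 1.0
        C[k + 1, k] = -(k + 1)
        C[:, k] /= np.linalg.norm(C[:, k])
    return C


@dataclass
class MauchlyResult:
    W: float
    chi2: float
    df: int
    p: float
    approximate: bool = False


@dataclass
class EpsilonResult:
    gg: float
    hf: float
    hf_uncapped: float
    lower_bound: float
    approximate: bool = False


@dataclass
class AnovaResult:
    """Between- and within-subject tables plus sphericity diagnostics."""

    between: pd.DataFrame
    within: pd.DataFrame
    mauchly: MauchlyResult
    epsilons: EpsilonResult
    n: int
    T: int
    n_cells: int
    factors: tuple[str, ...] = ()

    @property
    def n_error(self) -> int:
        return self.n - self.n_cells

    def effect(self, name: str, table: str = "between") -> pd.Series:
        tab = self.between if table == "between" else self.within
        row = tab.loc[tab["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect {name!r} in {table} table")
        return row.iloc[0]

    def to_dict(self) -> dict:
        return {
            "between": self.between.to_dict(orient="records"),
            "within": self.within.to_dict(orient="records"),
            "mauchly": {"W": self.mauchly.W, "chi2": self.mauchly.chi2,
                        "df": self.mauchly.df, "p": self.mauchly.p},
            "epsilons": {"gg": self.epsilons.gg, "hf": self.epsilons.hf,
                         "lower_bound": self.epsilons.lower_bound},
            "n": self.n, "T": self.T, "cells": self.n_cells,
        }

    def to_text(self) -> str:
        eps = self.epsilons
        lines = [
            "Between-subjects effects",
            self.between.to_string(index=False, float_format="%.4f"),
            "",
            "Within-subjects effects",
            self.within.to_string(index=False, float_format="%.4f"),
            "",
            f"Mauchly W = {self.mauchly.W:.4f}, "
            f"chi2({self.mauchly.df}) = {self.mauchly.chi2:.2f}, "
            f"p = {self.mauchly.p:.4g}",
            f"epsilon: GG = {eps.gg:.3f}, HF = {eps.hf:.3f} "
            f"(lower bound {eps.lower_bound:.3f})",
        ]
        return "\n".join(lines)


def _effect_terms(factors: tuple[str, ...]) -> list[tuple[str, ...]]:
    terms: list[tuple[str, ...]] = []
    for order in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, order))
    return terms


def _term_name(term: tuple[str, ...]) -> str:
    return " * ".join(term)


def _design_matrix(data: LongitudinalDataset, factors: tuple[str, ...]
                   ) -> tuple[np.ndarray, list[tuple[str, ...]]]:
    """Intercept + effect-coded (0 → +1, 1 → −1) columns, one per term."""
    n = data.n
    codes = {f: 1.0 - 2.0 * data.data[f].to_numpy(dtype=float)
             for f in factors}
    terms = _effect_terms(factors)
    X = np.ones((n, 1 + len(terms)))
    for j, term in enumerate(terms, start=1):
        col = np.ones(n)
        for f in term:
            col = col * codes[f]
        X[:, j] = col
    return X, terms


def _check_cells(data: LongitudinalDataset, factors: tuple[str, ...]) -> int:
    if not factors:
        return 1
    counts = data.data.groupby(list(factors)).size()
    for combo in itertools.product((0, 1), repeat=len(factors)):
        key = combo[0] if len(combo) == 1 else combo
        cnt = int(counts.get(key, 0))
        if cnt == 0:
            cell = ", ".join(f"{f}={v}" for f, v in zip(factors, combo))
            raise DesignError(f"empty design cell: {cell}")
        if cnt < 2:
            cell = ", ".join(f"{f}={v}" for f, v in zip(factors, combo))
            raise DesignError(
                f"design cell {cell} has fewer than 2 subjects"
            )
    return 2 ** len(factors)


def _type3_ss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-column hypothesis SS (Type III under effect coding) and residual SS.

    For a full-rank effect-coded design, the Type III SS of the term in
    column j is beta_j^2 / [(X'X)^{-1}]_{jj} summed over the responses.
    ``y`` may be a matrix (responses in columns); SS are summed across
    columns, which is the trace of the hypothesis SSCP.
    """
    y2 = y if y.ndim == 2 else y[:, None]
    XtX = X.T @ X
    G = np.linalg.inv(XtX)
    beta = G @ (X.T @ y2)
    resid = y2 - X @ beta
    ss_resid = float(np.sum(resid ** 2))
    ss_terms = np.array([
        float(np.sum(beta[j, :] ** 2) / G[j, j]) for j in range(X.shape[1])
    ])
    return ss_terms, ss_resid


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise DesignError("sums of squares must be nonnegative")
    if ss_effect == 0 and ss_error == 0:
        raise DesignError("partial eta squared undefined: both SS are zero")
    return float(ss_effect / (ss_effect + ss_error))


def epsilon_corrections(contrast_covariance: np.ndarray, n_e: int,
                        T: int | None = None,
                        n_groups: int = 1) -> EpsilonResult:
    """Greenhouse–Geisser and Huynh–Feldt epsilons from a (T−1)×(T−1)
    contrast covariance.

    ε_GG = (Σλ)² / (q Σλ²) over the eigenvalues λ (q = T−1).  The
    Huynh–Feldt correction follows the GLM convention of the software
    family this package parallels, using the total sample size
    N = n_e + n_groups and the between-design rank:

        ε_HF = (N·q·ε_GG − 2) / (q·n_e − q²·ε_GG),

    reported capped at 1 (uncapped value retained).
    """
    G = np.asarray(contrast_covariance, dtype=float)
    q = G.shape[0]
    if T is not None and q != T - 1:
        raise DesignError(f"contrast covariance is {q}x{q}, expected {T - 1}")
    lam = np.linalg.eigvalsh((G + G.T) / 2.0)
    if np.sum(lam ** 2) == 0:
        raise DegenerateVarianceError("contrast covariance is zero")
    gg = float(lam.sum() ** 2 / (q * np.sum(lam ** 2)))
    N = n_e + n_groups
    denom = q * n_e - q * q * gg
    if denom <= 0:
        raise DesignError(f"n_e = {n_e} too small for the Huynh–Feldt correction")
    hf_unc = float((N * q * gg - 2.0) / denom)
    return EpsilonResult(gg=gg, hf=min(1.0, hf_unc), hf_uncapped=hf_unc,
                         lower_bound=1.0 / q)


def mauchly_from_covariance(day_covariance: np.ndarray, n_e: int,
                            approximate: bool = False) -> MauchlyResult:
    """Mauchly's sphericity test from a T×T within-subject covariance.

    W = det(C'ΣC) / (tr(C'ΣC)/q)^q with C an orthonormal contrast basis;
    χ² ≈ −(n_e − (2q² + q + 2)/(6q))·ln W on q(q+1)/2 − 1 df.
    """
    S = np.asarray(day_covariance, dtype=float)
    T = S.shape[0]
    q = T - 1
    if n_e < q:
        raise DesignError(f"error df {n_e} below T−1 = {q}")
    C = helmert_contrasts(T)
    G = C.T @ S @ C
    sign, logdet = np.linalg.slogdet(G)
    if sign <= 0:
        raise DegenerateVarianceError("contrast covariance is singular")
    trace = float(np.trace(G))
    lnW = logdet - q * np.log(trace / q)
    W = float(np.exp(lnW))
    f = n_e - (2.0 * q * q + q + 2.0) / (6.0 * q)
    chi2 = float(-f * lnW)
    df = q * (q + 1) // 2 - 1
    return MauchlyResult(W=W, chi2=chi2, df=df,
                         p=float(stats.chi2.sf(chi2, df)),
                         approximate=approximate)


def epsilons_from_covariance(day_covariance: np.ndarray, n_e: int,
                             n_groups: int = 1,
                             approximate: bool = False) -> EpsilonResult:
    """Epsilon corrections computed from a T×T within-subject covariance."""
    S = np.asarray(day_covariance, dtype=float)
    C = helmert_contrasts(S.shape[0])
    res = epsilon_corrections(C.T @ S @ C, n_e, n_groups=n_groups)
    res.approximate = approximate
    return res


def _pooled_contrast_covariance(data: LongitudinalDataset,
                                between: tuple[str, ...]
                                ) -> tuple[np.ndarray, int]:
    Y = data.outcomes.to_numpy(dtype=float)
    X, _ = _design_matrix(data, between)
    C = helmert_contrasts(data.T)
    Z = Y @ C
    beta = np.linalg.lstsq(X, Z, rcond=None)[0]
    E = Z - X @ beta
    n_e = data.n - X.shape[1]
    return (E.T @ E) / n_e, n_e


def mauchly_test(data: LongitudinalDataset,
                 between: tuple[str, ...] = ()) -> MauchlyResult:
    """Mauchly's test on the pooled within-cells contrast covariance."""
    between = tuple(between)
    _check_cells(data, between)
    G, n_e = _pooled_contrast_covariance(data, between)
    sign, logdet = np.linalg.slogdet(G)
    if sign <= 0:
        raise DegenerateVarianceError("contrast covariance is singular")
    q = data.T - 1
    if n_e < q:
        raise DesignError(f"error df {n_e} below T−1 = {q}")
    lnW = logdet - q * np.log(np.trace(G) / q)
    f = n_e - (2.0 * q * q + q + 2.0) / (6.0 * q)
    chi2 = float(-f * lnW)
    df = q * (q + 1) // 2 - 1
    return MauchlyResult(W=float(np.exp(lnW)), chi2=chi2, df=df,
                         p=float(stats.chi2.sf(chi2, df)))


def sphericity_from_moments(moments: MomentData,
                            day_names: tuple[str, ...],
                            covariate_names: tuple[str, ...] = (),
                            n_groups: int | None = None
                            ) -> tuple[MauchlyResult, EpsilonResult]:
    """Approximate sphericity diagnostics from moment-level input.

    Raw per-cell data are unavailable in moment form, so the pooled
    within-cells day covariance is approximated by partialling the
    binary covariates out of the day block (Σ_dd − Σ_dc Σ_cc⁻¹ Σ_cd); the
    error sample size is n minus the number of between cells (2^k for k
    binary factors).  Results are flagged ``approximate``.
    """
    if n_groups is None:
        n_groups = 2 ** len(covariate_names) if covariate_names else 1
    md = moments.subset(tuple(day_names) + tuple(covariate_names))
    Td = len(day_names)
    Sdd = md.covariance[:Td, :Td]
    if covariate_names:
        Sdc = md.covariance[:Td, Td:]
        Scc = md.covariance[Td:, Td:]
        Sw = Sdd - Sdc @ np.linalg.solve(Scc, Sdc.T)
    else:
        Sw = Sdd
    n_e = moments.n - n_groups
    return (mauchly_from_covariance(Sw, n_e, approximate=True),
            epsilons_from_covariance(Sw, n_e, n_groups=n_groups,
                                     approximate=True))


def mixed_anova(data: LongitudinalDataset,
                between: tuple[str, ...]) -> AnovaResult:
    """Full-factorial mixed-design ANOVA: ``between`` factors × day.

    Between-subject effects are tested on the subject means (scaled by
    √T so sums of squares match the standard GLM decomposition); the
    within-subject block is tested on orthonormal day contrasts.  Within
    effects are reported uncorrected and with GG/HF-corrected df
    (corrected df rounded to 1 decimal in the table, SPSS-style).
    """
    between = tuple(between)
    if data.T < 2:
        raise DesignError("no within factor: T must be ≥ 2")
    for f in between:
        if f not in data.covariate_names:
            raise DesignError(f"between factor {f!r} is not a covariate column")
    n_cells = _check_cells(data, between)
    Y = data.outcomes.to_numpy(dtype=float)
    n, T = Y.shape
    X, terms = _design_matrix(data, between)
    r = X.shape[1]
    if n <= r:
        raise DesignError("not enough subjects for the between design")

    # ---- between-subjects table (on sqrt(T) * subject means)
    b = np.sqrt(T) * Y.mean(axis=1)
    ss_terms, ss_err_b = _type3_ss(X, b)
    df_err_b = n - r
    rows_b = []
    for j, term in enumerate(terms, start=1):
        ss = ss_terms[j]
        F = (ss / 1.0) / (ss_err_b / df_err_b) if ss_err_b > 0 else np.inf
        rows_b.append({
            "effect": _term_name(term), "ss": ss, "df": 1,
            "ms": ss, "F": F,
            "p": float(stats.f.sf(F, 1, df_err_b)),
            "partial_eta_sq": partial_eta_squared(ss, ss_err_b),
        })
    rows_b.append({"effect": "Error", "ss": ss_err_b, "df": df_err_b,
                   "ms": ss_err_b / df_err_b, "F": np.nan, "p": np.nan,
                   "partial_eta_sq": np.nan})
    between_tab = pd.DataFrame(rows_b)

    # ---- within-subjects table (on orthonormal day contrasts)
    q = T - 1
    C = helmert_contrasts(T)
    Z = Y @ C
    ss_terms_w, ss_err_w = _type3_ss(X, Z)
    df_err_w = (n - r) * q
    # numerically-zero within variation (identical values across days)
    tiny = 1e-12 * (float(np.sum(Y ** 2)) + 1.0)
    if ss_err_w <= tiny:
        ss_err_w = 0.0
        ss_terms_w = np.where(ss_terms_w <= tiny, 0.0, ss_terms_w)
    ms_err_w = ss_err_w / df_err_w

    G_pooled, n_e_pool = _pooled_contrast_covariance(data, between)
    try:
        eps = epsilon_corrections(G_pooled, n_e_pool, n_groups=r)
        mauchly = mauchly_test(data, between)
    except (DegenerateVarianceError, FloatingPointError, ZeroDivisionError):
        # no within-subject variation left: sphericity is undefined
        eps = EpsilonResult(np.nan, np.nan, np.nan, 1.0 / q)
        mauchly = MauchlyResult(np.nan, np.nan, q * (q + 1) // 2 - 1, np.nan)

    rows_w = []
    within_effects = [("day", 0)] + [
        (f"{_term_name(term)} * day", j)
        for j, term in enumerate(terms, start=1)
    ]
    for name, j in within_effects:
        ss = ss_terms_w[j]
        df1 = q
        F = (ss / df1) / ms_err_w if ms_err_w > 0 else (
            0.0 if ss == 0 else np.inf)
        row = {
            "effect": name, "ss": ss, "df": df1, "ms": ss / df1,
            "F": F, "p": float(stats.f.sf(F, df1, df_err_w)),
            "partial_eta_sq": partial_eta_squared(ss, ss_err_w)
            if (ss > 0 or ss_err_w > 0) else np.nan,
        }
        for tag, e in (("gg", eps.gg), ("hf", eps.hf)):
            row[f"df_{tag}"] = round(df1 * e, 1)
            row[f"df_err_{tag}"] = round(df_err_w * e, 1)
            row[f"p_{tag}"] = float(stats.f.sf(F, df1 * e, df_err_w * e))
        rows_w.append(row)
    rows_w.append({"effect": "Error (day)", "ss": ss_err_w, "df": df_err_w,
                   "ms": ms_err_w, "F": np.nan, "p": np.nan,
                   "partial_eta_sq": np.nan,
                   "df_gg": round(df_err_w * eps.gg, 1),
                   "df_err_gg": np.nan, "p_gg": np.nan,
                   "df_hf": round(df_err_w * eps.hf, 1),
                   "df_err_hf": np.nan, "p_hf": np.nan})
    within_tab = pd.DataFrame(rows_w)

    return AnovaResult(between=between_tab, within=within_tab,
                       mauchly=mauchly, epsilons=eps, n=n, T=T,
                       n_cells=n_cells, factors=between)
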