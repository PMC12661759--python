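"""Per-protein variance decomposition under crossed random intercepts.

The model for one protein's log2 intensities is

    y_mp = mu + a_m + b_p + e_mp,   a ~ N(0, s2_method),
                                    b ~ N(0, s2_patient),
                                    e ~ N(0, s2_residual),

with method and patient intercepts crossed. Components are estimated by
EM-REML, which keeps every component non-negative by construction;
convergence is declared when the restricted log-likelihood changes by
less than 1e-8 (at most 500 iterations). Missing cells are simply
omitted observations. Reported quantities are the variance fractions
s2_i / (s2_method + s2_patient + s2_residual).

For complete balanced designs the method and patient incidence Gram
matrices commute, so the whole iteration runs in a fixed eigenbasis at
O(n) per step; unbalanced designs fall back to dense Cholesky algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VarianceFractions",
    "fit_variance_components",
    "partition_variance",
    "summarize_fractions",
]

REML_TOL = 1e-8
REML_MAX_ITER = 500
MIN_OBSERVATIONS = 6


@dataclass
class VarianceFractions:
    protein: str
    fraction_method: float
    fraction_patient: float
    fraction_residual: float
    n_observations: int
    converged: bool
    note: str = ""
    sigma2_method: float = float("nan")
    sigma2_patient: float = float("nan")
    sigma2_residual: float = float("nan")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fraction_method, self.fraction_patient, self.fraction_residual)


def _incidence(labels: list[str]) -> np.ndarray:
    levels = sorted(set(labels))
    index = {lab: i for i, lab in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for row, lab in enumerate(labels):
        Z[row, index[lab]] = 1.0
    return Z


def _em_reml_dense(y, Z1, Z2, s2, tol=REML_TOL, max_iter=REML_MAX_ITER):
    """General EM-REML; returns (s2, converged, n_iter)."""
    n = len(y)
    A = Z1 @ Z1.T
    B = Z2 @ Z2.T
    q1, q2 = Z1.shape[1], Z2.shape[1]
    ones = np.ones(n)
    last_ll = -np.inf
    converged = False
    for iteration in range(max_iter):
        V = s2[0] * A + s2[1] * B + s2[2] * np.eye(n)
        chol = cho_factor(V, lower=True)
        Vinv = cho_solve(chol, np.eye(n))
        w = Vinv @ ones
        s = float(ones @ w)
        Py = Vinv @ y - w * (float(w @ y) / s)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        ll = -0.5 * (logdet_v + math.log(s) + float(y @ Py))
        quad = [float(Py @ A @ Py), float(Py @ B @ Py), float(Py @ Py)]
        tr = [
            float(np.sum(Vinv * A)) - float(w @ A @ w) / s,
            float(np.sum(Vinv * B)) - float(w @ B @ w) / s,
            float(np.trace(Vinv)) - float(w @ w) / s,
        ]
        qs = [q1, q2, n - 1]
        new = np.array(
            [s2[i] + s2[i] ** 2 / qs[i] * (quad[i] - tr[i]) for i in range(3)]
        )
        new = np.maximum(new, 1e-12)
        if abs(ll - last_ll) < tol:
            converged = True
            s2 = new
            break
        last_ll = ll
        s2 = new
    return s2, converged, iteration + 1


def _em_reml_balanced(y, Z1, Z2, s2, tol=REML_TOL, max_iter=REML_MAX_ITER):
    """O(n)-per-iteration EM-REML in the common eigenbasis (balanced case).

    Returns None when the incidence Gram matrices do not commute.
    """
    A = Z1 @ Z1.T
    B = Z2 @ Z2.T
    if not np.allclose(A @ B, B @ A, atol=1e-10):
        return None
    n = len(y)
    # a generic irrational combination separates the joint eigenspaces
    _, U = np.linalg.eigh(A + math.sqrt(2.0) * B)
    alpha = np.einsum("ij,jk,ki->i", U.T, A, U)
    beta = np.einsum("ij,jk,ki->i", U.T, B, U)
    if not (
        np.allclose(U.T @ A @ U, np.diag(alpha), atol=1e-8)
        and np.allclose(U.T @ B @ U, np.diag(beta), atol=1e-8)
    ):
        return None
    alpha = np.maximum(alpha, 0.0)
    beta = np.maximum(beta, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    Z1t = U.T @ Z1
    Z2t = U.T @ Z2
    q1, q2 = Z1.shape[1], Z2.shape[1]
    last_ll = -np.inf
    converged = False
    for iteration in range(max_iter):
        lam = s2[0] * alpha + s2[1] * beta + s2[2]
        inv = 1.0 / lam
        s = float(np.sum(xt**2 * inv))
        py = yt * inv - xt * inv * (float(np.sum(xt * inv * yt)) / s)
        ll = -0.5 * (
            float(np.sum(np.log(lam))) + math.log(s) + float(yt @ py)
        )
        quad = [
            float(np.sum((Z1t.T @ py) ** 2)),
            float(np.sum((Z2t.T @ py) ** 2)),
            float(py @ py),
        ]
        w2 = xt * inv
        tr = [
            float(np.sum(alpha * inv)) - float(np.sum(alpha * w2**2)) / s,
            float(np.sum(beta * inv)) - float(np.sum(beta * w2**2)) / s,
            float(np.sum(inv)) - float(np.sum(w2**2)) / s,
        ]
        qs = [q1, q2, n - 1]
        new = np.array(
            [s2[i] + s2[i] ** 2 / qs[i] * (quad[i] - tr[i]) for i in range(3)]
        )
        new = np.maximum(new, 1e-12)
        if abs(ll - last_ll) < tol:
            converged = True
            s2 = new
            break
        last_ll = ll
        s2 = new
    return s2, converged, iteration + 1


def fit_variance_components(
    observations: pd.DataFrame, protein: str = ""
) -> VarianceFractions:
    """Fit the crossed random-intercepts model to one protein's data.

    ``observations`` needs columns ``method``, ``patient``, ``value``.
    Raises ValueError when the design cannot identify the components
    (single method or patient, or fewer than 6 observations); constant
    responses return the all-residual convention with a flag.
    """
    df = observations.dropna(subset=["value"])
    methods = df["method"].tolist()
    patients = df["patient"].tolist()
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    if n < MIN_OBSERVATIONS:
        raise ValueError(f"{protein}: only {n} observations (need >= {MIN_OBSERVATIONS})")
    if len(set(methods)) < 2 or len(set(patients)) < 2:
        raise ValueError(f"{protein}: need >= 2 methods and >= 2 patients")

    total_var = float(np.var(y, ddof=1))
    if total_var <= 1e-12:
        return VarianceFractions(protein, 0.0, 0.0, 1.0, n, True, "degenerate: constant response")

    Z1 = _incidence(methods)
    Z2 = _incidence(patients)
    s2 = np.full(3, total_var / 3.0)
    fast = _em_reml_balanced(y, Z1, Z2, s2)
    if fast is not None:
        s2, converged, _ = fast
    else:
        s2, converged, _ = _em_reml_dense(y, Z1, Z2, s2)
    total = float(np.sum(s2))
    fractions = s2 / total
    return VarianceFractions(
        protein,
        float(fractions[0]),
        float(fractions[1]),
        float(fractions[2]),
        n,
        converged,
        sigma2_method=float(s2[0]),
        sigma2_patient=float(s2[1]),
        sigma2_residual=float(s2[2]),
    )


def partition_variance(long_table: pd.DataFrame) -> pd.DataFrame:
    """Fit every protein in a long table (protein, method, patient, value).

    Proteins with insufficient design are skipped with a reason column
    rather than raising. Returns one row per protein.
    """
    rows = []
    for protein, group in long_table.groupby("protein", sort=True):
        try:
            fit = fit_variance_components(group, str(protein))
        except ValueError as exc:
            rows.append(
                {
                    "protein": protein,
                    "fraction_method": np.nan,
                    "fraction_patient": np.nan,
                    "fraction_residual": np.nan,
                    "n_observations": int(group["value"].notna().sum()),
                    "converged": False,
                    "note": f"skipped: {exc}",
                }
            )
            continue
        rows.append(
            {
                "protein": protein,
                "fraction_method": fit.fraction_method,
                "fraction_patient": fit.fraction_patient,
                "fraction_residual": fit.fraction_residual,
                "sigma2_method": fit.sigma2_method,
                "sigma2_patient": fit.sigma2_patient,
                "sigma2_residual": fit.sigma2_residual,
                "n_observations": fit.n_observations,
                "converged": fit.converged,
                "note": fit.note,
            }
        )
    return pd.DataFrame(rows)


def pooled_fractions(fits: pd.DataFrame) -> tuple[float, float, float]:
    """Dataset-level variance fractions: components summed across proteins.

    Summing the per-protein component estimates before taking the ratio
    avoids the Jensen bias of averaging per-protein fractions, so this is
    the quantity to compare against a generative truth shared by all
    proteins.
    """
    ok = fits[fits["converged"] & fits["sigma2_method"].notna()]
    if not len(ok):
        raise ValueError("no converged fits")
    sums = np.array(
        [
            ok["sigma2_method"].sum(),
            ok["sigma2_patient"].sum(),
            ok["sigma2_residual"].sum(),
        ]
    )
    fractions = sums / sums.sum()
    return (float(fractions[0]), float(fractions[1]), float(fractions[2]))


def matrix_to_long(matrix) -> pd.DataFrame:
    """Flatten a QuantMatrix into (protein, method, patient, value) rows."""
    rows = []
    for sample in matrix.samples:
        method = matrix.method_of(sample)
        patient = matrix.patient_of(sample)
        col = matrix.values[sample]
        for protein, value in col.items():
            if not np.isnan(value):
                rows.append(
                    {
                        "protein": protein,
                        "method": method,
                        "patient": patient,
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows)


def summarize_fractions(fits: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary (percent) of each component across proteins."""
    ok = fits[fits["converged"] & fits["fraction_method"].notna()]
    if not len(ok):
        raise ValueError("no converged variance fits to summarize")
    rows = []
    for component in ("method", "patient", "residual"):
        values = ok[f"fraction_{component}"].to_numpy() * 100.0
        rows.append(
            {
                "component": component,
                "n_proteins": len(values),
                "mean_pct": float(np.mean(values)),
                "median_pct": float(np.median(values)),
                "q1_pct": float(np.percentile(values, 25)),
                "q3_pct": float(np.percentile(values, 75)),
            }
        )
    return pd.DataFrame(rows)
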