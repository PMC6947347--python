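"""Single-trait animal model: y = Xb + Za + e, a ~ N(0, K sigma_a^2).

The kernel K is any dense relationship matrix (pedigree A, genomic G, or
weighted G*).  Henderson's mixed-model equations give BLUE fixed effects and
BLUP breeding values; variance components come from an exact restricted
maximum likelihood that eigendecomposes the record-space kernel Z K Z' and
profiles the residual variance, so the search is one-dimensional in the
variance ratio.  Corrected phenotypes Yc = y - X b_hat (fixed effects from a
pedigree-based fit) are the response used by the genomic models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .relmat import RelationshipMatrix


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Which phenotype columns enter the model and on which kernel."""

    response: str = "y"
    fixed_factors: list[str] = field(default_factory=lambda: ["herd", "sex"])
    covariates: list[str] = field(default_factory=lambda: ["age"])
    random_kernel: str = "A"


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    se_sigma_a2: float = np.nan
    se_sigma_e2: float = np.nan
    se_h2: float = np.nan
    loglik: float = np.nan
    boundary: bool = False

    @property
    def h2(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else np.nan

    @property
    def ratio(self) -> float:
        """sigma_e^2 / sigma_a^2, the MME shrinkage parameter."""
        return self.sigma_e2 / self.sigma_a2


@dataclass
class Design:
    """Design matrices plus the encoding needed to rebuild X on new rows."""

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    record_animals: list[str]
    kernel_ids: list[str]
    x_labels: list[str]
    factor_levels: dict[str, list[str]]
    covariates: list[str]
    n_dropped: int = 0


@dataclass
class EvaluationResult:
    b_hat: pd.Series
    ebv: pd.Series
    vc: VarianceComponents
    model: ModelSpec
    design: Design
    diagnostics: dict = field(default_factory=dict)

    def write_csv(self, path) -> None:
        self.ebv.rename("ebv").to_csv(path, index_label="animal")


def build_design(
    phenos: pd.DataFrame,
    model: ModelSpec,
    kernel_ids: list[str],
    factor_levels: dict[str, list[str]] | None = None,
) -> Design:
    """Full-rank fixed-effect matrix (reference level dropped per factor) and
    the record-to-animal incidence matrix Z.

    Rows with a missing response are dropped (counted in the design).  Factors
    with a single observed level are dropped with a warning.  ``factor_levels``
    pins the dummy coding (used when re-encoding validation rows).
    """
    import warnings

    df = phenos.copy()
    needed = [model.response, "animal", *model.fixed_factors, *model.covariates]
    for col in needed:
        if col not in df.columns:
            raise ModelError(f"phenotype table lacks column '{col}'")
    n_total = len(df)
    df = df.dropna(subset=[model.response])
    n_dropped = n_total - len(df)

    kernel_set = set(kernel_ids)
    bad = [a for a in df["animal"].astype(str) if a not in kernel_set]
    if bad:
        raise ModelError(f"records for animals absent from the kernel: {bad[:5]}...")

    cols = [np.ones(len(df))]
    labels = ["intercept"]
    levels_used: dict[str, list[str]] = {}
    for fac in model.fixed_factors:
        vals = df[fac].astype(str)
        if factor_levels is not None and fac in factor_levels:
            lv = factor_levels[fac]
            unknown = set(vals) - set(lv)
            if unknown:
                raise ModelError(f"factor '{fac}' has unseen levels {sorted(unknown)}")
        else:
            lv = sorted(vals.unique())
        if len(lv) < 2:
            warnings.warn(f"factor '{fac}' has a single level; dropped", stacklevel=2)
            levels_used[fac] = lv
            continue
        levels_used[fac] = list(lv)
        for level in lv[1:]:  # reference = first level
            cols.append((vals == level).to_numpy(float))
            labels.append(f"{fac}[{level}]")
    for cov in model.covariates:
        cols.append(df[cov].to_numpy(float))
        labels.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed-effect design is rank deficient")

    kern_pos = {a: i for i, a in enumerate(kernel_ids)}
    Z = np.zeros((len(df), len(kernel_ids)))
    animals = df["animal"].astype(str).tolist()
    for r, a in enumerate(animals):
        Z[r, kern_pos[a]] = 1.0
    return Design(
        X=X,
        Z=Z,
        y=df[model.response].to_numpy(float),
        record_animals=animals,
        kernel_ids=list(kernel_ids),
        x_labels=labels,
        factor_levels=levels_used,
        covariates=list(model.covariates),
        n_dropped=n_dropped,
    )


def _kernel_values(K) -> np.ndarray:
    return K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)


def solve_mme(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    K,
    vc: VarianceComponents,
    K_inv: np.ndarray | None = None,
    method: str = "direct",
    tol: float = 1e-15,
    max_iter: int = 20000,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Solve Henderson's MME; returns (b_hat, a_hat, diagnostics).

    [X'X  X'Z          ] [b]   [X'y]
    [Z'X  Z'Z + K^-1 k ] [a] = [Z'y],   k = sigma_e^2 / sigma_a^2.

    ``method='direct'`` uses a dense symmetric solve; ``method='pcg'`` runs a
    Jacobi-preconditioned conjugate gradient to a relative residual of ``tol``
    (the convergence criterion used for the iterative path).
    """
    Kv = _kernel_values(K)
    if vc.sigma_a2 <= 0 or vc.sigma_e2 < 0:
        raise ModelError("variance components must be positive")
    k = vc.ratio
    if K_inv is None:
        try:
            c, low = linalg.cho_factor(Kv)
            K_inv = linalg.cho_solve((c, low), np.eye(Kv.shape[0]))
        except linalg.LinAlgError as exc:
            raise ModelError("kernel is not invertible; condition it first") from exc
    p, q = X.shape[1], Z.shape[1]
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z + K_inv * k
    rhs = np.concatenate([X.T @ y, Z.T @ y])

    diagnostics: dict = {"method": method}
    if method == "direct":
        try:
            sol = linalg.solve(C, rhs, assume_a="sym")
        except linalg.LinAlgError as exc:
            raise ModelError("singular MME coefficient matrix") from exc
        diagnostics["iterations"] = 1
    elif method == "pcg":
        sol, info = _pcg(C, rhs, tol=tol, max_iter=max_iter)
        if info["relative_residual"] > tol:
            raise ModelError(
                f"PCG failed to reach tolerance {tol:g} "
                f"(reached {info['relative_residual']:.2e})"
            )
        diagnostics.update(info)
    else:
        raise ModelError(f"unknown solver '{method}'")
    resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    diagnostics["final_residual"] = resid
    return sol[:p], sol[p:], diagnostics


def _pcg(C, rhs, tol, max_iter):
    """Jacobi-preconditioned conjugate gradient for the (SPD) MME."""
    d = np.diag(C).copy()
    d[d <= 0] = 1.0
    x = np.zeros_like(rhs)
    r = rhs - C @ x
    z = r / d
    p = z.copy()
    rz = r @ z
    norm_rhs = np.linalg.norm(rhs)
    it = 0
    for it in range(1, max_iter + 1):
        Cp = C @ p
        alpha = rz / (p @ Cp)
        x += alpha * p
        r -= alpha * Cp
        rel = np.linalg.norm(r) / norm_rhs
        if rel <= tol:
            break
        z = r / d
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    rel = float(np.linalg.norm(rhs - C @ x) / norm_rhs)
    return x, {"iterations": it, "relative_residual": rel}


def fit_blup(
    phenos: pd.DataFrame,
    model: ModelSpec,
    kernel: RelationshipMatrix,
    vc: VarianceComponents | None = None,
    design: Design | None = None,
    K_inv: np.ndarray | None = None,
    method: str = "direct",
) -> EvaluationResult:
    """Convenience wrapper: design + (optional) REML + MME solve."""
    if design is None:
        design = build_design(phenos, model, kernel.ids)
    if vc is None:
        vc = reml_variance(design.X, design.Z, design.y, kernel)
    b, a, diag = solve_mme(design.X, design.Z, design.y, kernel, vc, K_inv=K_inv, method=method)
    return EvaluationResult(
        b_hat=pd.Series(b, index=design.x_labels, name="estimate"),
        ebv=pd.Series(a, index=design.kernel_ids, name="ebv"),
        vc=vc,
        model=model,
        design=design,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def reml_variance(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    K,
    log_gamma_bounds: tuple[float, float] = (-14.0, 14.0),
    compute_se: bool = True,
) -> VarianceComponents:
    """Exact REML for the one-kernel model via eigendecomposition.

    With H = Z K Z' = U S U' and gamma = sigma_a^2 / sigma_e^2, the rotated
    data have diagonal covariance sigma_e^2 (gamma S + I); the restricted
    likelihood is maximized over log(gamma) by bounded scalar search with
    sigma_e^2 profiled out in closed form.  Standard errors come from the
    numerical Hessian of the REML log-likelihood at the optimum.
    """
    n, p = X.shape
    if n <= p + 1:
        raise ModelError("too few records to estimate two variance components")
    Kv = _kernel_values(K)
    H = Z @ Kv @ Z.T
    s, U = np.linalg.eigh(0.5 * (H + H.T))
    s = np.clip(s, 0.0, None)
    if s.max() <= 0:
        raise ModelError("kernel is zero on the record space")
    yt = U.T @ y
    Xt = U.T @ X

    def neg2_reml(log_gamma: float) -> float:
        return _neg2_reml_profiled(log_gamma, s, yt, Xt, n, p)[0]

    res = optimize.minimize_scalar(
        neg2_reml, bounds=log_gamma_bounds, method="bounded",
        options={"xatol": 1e-10},
    )
    lg = float(res.x)
    n2, sigma_e2 = _neg2_reml_profiled(lg, s, yt, Xt, n, p)
    gamma = np.exp(lg)
    sigma_a2 = gamma * sigma_e2
    boundary = bool(
        lg <= log_gamma_bounds[0] + 1e-6 or lg >= log_gamma_bounds[1] - 1e-6
    )
    loglik = -0.5 * (n2 + (n - p) * np.log(2 * np.pi))

    se_a = se_e = se_h2 = np.nan
    if compute_se and not boundary:
        se_a, se_e, se_h2 = _reml_se(sigma_a2, sigma_e2, s, yt, Xt, n, p)
    return VarianceComponents(
        sigma_a2=float(sigma_a2),
        sigma_e2=float(sigma_e2),
        se_sigma_a2=se_a,
        se_sigma_e2=se_e,
        se_h2=se_h2,
        loglik=float(loglik),
        boundary=boundary,
    )


def _neg2_reml_profiled(log_gamma, s, yt, Xt, n, p):
    """-2 l_R(gamma) with sigma_e^2 profiled; returns (-2l, sigma_e2_hat)."""
    gamma = np.exp(log_gamma)
    v = gamma * s + 1.0
    vinv = 1.0 / v
    XtV = Xt * vinv[:, None]
    XVX = Xt.T @ XtV
    XVy = XtV.T @ yt
    try:
        cf = linalg.cho_factor(XVX)
    except linalg.LinAlgError:
        return np.inf, np.nan
    beta = linalg.cho_solve(cf, XVy)
    r = yt - Xt @ beta
    ss = float(np.sum(r * r * vinv))
    sigma_e2 = ss / (n - p)
    logdet_v = float(np.sum(np.log(v)))
    logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    n2 = (n - p) * np.log(sigma_e2) + logdet_v + logdet_xvx + (n - p)
    return n2, sigma_e2


def reml_loglik(sigma_a2, sigma_e2, X, Z, y, K) -> float:
    """Restricted log-likelihood at a given variance pair (for checks)."""
    Kv = _kernel_values(K)
    H = Z @ Kv @ Z.T
    s, U = np.linalg.eigh(0.5 * (H + H.T))
    s = np.clip(s, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X
    n, p = X.shape
    return _reml_loglik_rotated(sigma_a2, sigma_e2, s, yt, Xt, n, p)


def _reml_loglik_rotated(sigma_a2, sigma_e2, s, yt, Xt, n, p):
    v = sigma_a2 * s + sigma_e2
    if (v <= 0).any():
        return -np.inf
    vinv = 1.0 / v
    XtV = Xt * vinv[:, None]
    XVX = Xt.T @ XtV
    try:
        cf = linalg.cho_factor(XVX)
    except linalg.LinAlgError:
        return -np.inf
    beta = linalg.cho_solve(cf, XtV.T @ yt)
    r = yt - Xt @ beta
    ss = float(np.sum(r * r * vinv))
    logdet_v = float(np.sum(np.log(v)))
    logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_xvx + ss)


def _reml_se(sigma_a2, sigma_e2, s, yt, Xt, n, p):
    """Asymptotic SEs from the numerical Hessian of l_R(sigma_a2, sigma_e2)."""
    theta0 = np.array([sigma_a2, sigma_e2])
    h = np.maximum(1e-5 * theta0, 1e-10)

    def f(th):
        return _reml_loglik_rotated(th[0], th[1], s, yt, Xt, n, p)

    Hm = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i], ej[j] = h[i], h[j]
            Hm[i, j] = Hm[j, i] = (
                f(theta0 + ei + ej) - f(theta0 + ei - ej)
                - f(theta0 - ei + ej) + f(theta0 - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-Hm)
        if (np.diag(cov) < 0).any():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    se_a, se_e = np.sqrt(np.diag(cov))
    tot = sigma_a2 + sigma_e2
    grad = np.array([sigma_e2 / tot**2, -sigma_a2 / tot**2])
    se_h2 = float(np.sqrt(grad @ cov @ grad))
    return float(se_a), float(se_e), se_h2


def correct_phenotypes(
    result: EvaluationResult, phenos: pd.DataFrame
) -> pd.DataFrame:
    """Yc = y - X b_hat for every phenotyped animal (validation included).

    The fixed-effect design is re-encoded with the factor levels of the
    original fit, so solutions transfer exactly.
    """
    model = result.model
    design = result.design
    df = phenos.dropna(subset=[model.response]).copy()
    cols = [np.ones(len(df))]
    for fac, lv in design.factor_levels.items():
        if len(lv) < 2:
            continue
        vals = df[fac].astype(str)
        unknown = set(vals) - set(lv)
        if unknown:
            raise ModelError(f"factor '{fac}' has levels unseen in the fit: {sorted(unknown)}")
        for level in lv[1:]:
            cols.append((vals == level).to_numpy(float))
    for cov in design.covariates:
        cols.append(df[cov].to_numpy(float))
    X = np.column_stack(cols)
    if X.shape[1] != len(result.b_hat):
        raise ModelError("design mismatch between fit and correction table")
    yc = df[model.response].to_numpy(float) - X @ result.b_hat.to_numpy()
    return pd.DataFrame(
        {"animal": df["animal"].astype(str).to_numpy(), "yc": yc}
    )
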