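"""Iterative SNP weighting for weighted GBLUP.

One weighting round: build G* from the current weights (all ones at iteration
1, so the first round IS plain GBLUP), solve the GBLUP system for direct
genomic values, backsolve per-SNP effects

    u_hat = lambda D M' G*^-1 g_hat,

update the weights — linear: d_i = u_i^2; nonlinearA: d_i = CT^min(|u_i|/sd(u)
- 2, limit) — and renormalize so the weights sum to the SNP count (total
genetic variance held constant).  Ten rounds are the conventional schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .lmm import Design, ModelSpec, VarianceComponents, build_design, solve_mme
from .relmat import CenteredGenotypes, RelationshipMatrix, build_weighted_G, condition_G


class WeightingError(ValueError):
    pass


@dataclass
class WeightScheme:
    """SNP-weight update rule: 'linear' (d = u^2) or 'nonlinearA'
    (d = CT^(|u|/sd - 2) with the exponent capped above at ``exponent_limit``)."""

    kind: str = "nonlinearA"
    ct: float = 1.25
    exponent_limit: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "nonlinearA"):
            raise WeightingError(f"unknown weighting kind '{self.kind}'")
        if self.kind == "nonlinearA":
            if self.ct <= 1:
                raise WeightingError("CT must exceed 1 for nonlinearA weights")
            if self.exponent_limit <= 0:
                raise WeightingError("exponent limit must be positive")

    @property
    def label(self) -> str:
        if self.kind == "linear":
            return "WGBLUP_linear"
        return f"WGBLUP_nonlinearA_CT{self.ct:g}_lim{self.exponent_limit:g}"


@dataclass
class SNPWeights:
    d: np.ndarray
    iteration: int = 1

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise WeightingError("weights must be finite and non-negative")


@dataclass
class IterationRecord:
    t: int
    weights: np.ndarray  # weights used to build G* at this iteration
    snp_effects: np.ndarray
    gebv: pd.Series


@dataclass
class IterationTrace:
    scheme: WeightScheme
    snp_ids: list[str]
    iterations: list[IterationRecord] = field(default_factory=list)
    truncated: bool = False

    def gebv(self, t: int) -> pd.Series:
        return self.iterations[t - 1].gebv

    def snp_effects(self, t: int) -> np.ndarray:
        return self.iterations[t - 1].snp_effects

    def to_frame(self, freqs: np.ndarray | None = None) -> pd.DataFrame:
        """Tidy per-iteration SNP table: effect, weight, % variance."""
        from .evalmod import snp_variance_share

        frames = []
        for rec in self.iterations:
            df = pd.DataFrame(
                {
                    "iteration": rec.t,
                    "snp_id": self.snp_ids,
                    "effect": rec.snp_effects,
                    "weight": rec.weights,
                }
            )
            if freqs is not None:
                df["pct_variance"] = snp_variance_share(rec.snp_effects, freqs)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def gebv_frame(self) -> pd.DataFrame:
        out = {f"iter{rec.t}": rec.gebv for rec in self.iterations}
        return pd.DataFrame(out)


def linear_weight(u: np.ndarray) -> np.ndarray:
    """Raw linear weights d_i = u_i^2 (normalize separately)."""
    u = np.asarray(u, dtype=float)
    if not np.isfinite(u).all():
        raise WeightingError("SNP effects must be finite")
    return u**2


def nonlinearA_weight(u: np.ndarray, scheme: WeightScheme) -> np.ndarray:
    """Raw nonlinearA weights d_i = CT^min(|u_i|/sd(u) - 2, limit).

    sd is the sample standard deviation (m-1 denominator) of the current
    effect vector; the exponent is capped above only — its natural floor is
    -2 at u_i = 0.
    """
    if scheme.kind != "nonlinearA":
        raise WeightingError("scheme is not nonlinearA")
    u = np.asarray(u, dtype=float)
    sd = float(np.std(u, ddof=1))
    if sd == 0 or np.all(u == u.flat[0]):
        raise WeightingError(
            "sd of SNP effects is zero (all effects identical); "
            "nonlinearA weights are undefined — check that the model was fit"
        )
    expo = np.minimum(np.abs(u) / sd - 2.0, scheme.exponent_limit)
    return scheme.ct**expo


def normalize_weights(d_raw: np.ndarray, m: int | None = None, iteration: int = 1) -> SNPWeights:
    """Scale weights so their sum (trace of D) equals the SNP count m."""
    d_raw = np.asarray(d_raw, dtype=float)
    m = len(d_raw) if m is None else m
    total = d_raw.sum()
    if total <= 0:
        raise WeightingError("all-zero raw weights cannot be normalized")
    return SNPWeights(d_raw * (m / total), iteration=iteration)


def backsolve_snp_effects(
    cg: CenteredGenotypes,
    weights,
    G_star_inv: np.ndarray,
    gebv: np.ndarray,
) -> np.ndarray:
    """SNP effects from genomic values: u = lambda diag(d) M' G*^-1 g."""
    d = np.asarray(getattr(weights, "d", weights), dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if d.shape != (cg.n_snps,):
        raise WeightingError("one weight per SNP required")
    if gebv.shape != (cg.n_animals,):
        raise WeightingError("one genomic value per genotyped animal required")
    return cg.scale * d * (cg.M.T @ (G_star_inv @ gebv))


def run_wgblup(
    cg: CenteredGenotypes,
    yc_train: pd.Series,
    vc: VarianceComponents,
    scheme: WeightScheme,
    n_iterations: int = 10,
    blend: float = 0.05,
    A22: RelationshipMatrix | None = None,
    model: ModelSpec | None = None,
    phenos_train: pd.DataFrame | None = None,
) -> IterationTrace:
    """Run the weighted-GBLUP loop and record the full per-iteration trace.

    ``yc_train`` holds corrected phenotypes indexed by training-animal id (a
    subset of ``cg.animal_ids``); validation animals contribute genotypes
    only.  Variance components stay fixed across iterations.  By default the
    response is modelled with an intercept only (the fixed effects having been
    removed in Yc); pass ``model`` + ``phenos_train`` to refit fixed effects.

    Iteration 1 uses unit weights, so its output is exactly plain GBLUP.
    """
    train_ids = [str(a) for a in yc_train.index]
    missing = set(train_ids) - set(cg.animal_ids)
    if missing:
        raise WeightingError(f"training animals without genotypes: {sorted(missing)[:5]}")

    if model is None:
        design = _intercept_design(cg, train_ids, yc_train.to_numpy(float))
    else:
        if phenos_train is None:
            raise WeightingError("phenos_train is required when a model is given")
        design = build_design(phenos_train, model, cg.animal_ids)
        design.y = yc_train.loc[design.record_animals].to_numpy(float)

    trace = IterationTrace(scheme=scheme, snp_ids=list(cg.snp_ids))
    d = SNPWeights(np.ones(cg.n_snps), iteration=1)
    for t in range(1, n_iterations + 1):
        try:
            Gs = build_weighted_G(cg, d)
            Gc = condition_G(Gs, A22=A22, blend=blend)
            c, low = linalg.cho_factor(Gc.values)
            G_inv = linalg.cho_solve((c, low), np.eye(Gc.n))
            _, a_hat, _ = solve_mme(design.X, design.Z, design.y, Gc, vc, K_inv=G_inv)
            u = backsolve_snp_effects(cg, d, G_inv, a_hat)
        except (linalg.LinAlgError, np.linalg.LinAlgError, ValueError) as exc:
            if not trace.iterations:
                raise
            import warnings

            warnings.warn(
                f"weighted-GBLUP iteration {t} failed numerically ({exc}); "
                "trace truncated",
                stacklevel=2,
            )
            trace.truncated = True
            break
        trace.iterations.append(
            IterationRecord(
                t=t,
                weights=d.d.copy(),
                snp_effects=u,
                gebv=pd.Series(a_hat, index=cg.animal_ids, name=f"iter{t}"),
            )
        )
        if t == n_iterations:
            break
        raw = linear_weight(u) if scheme.kind == "linear" else nonlinearA_weight(u, scheme)
        d = normalize_weights(raw, cg.n_snps, iteration=t + 1)
    return trace


def run_gblup(
    cg: CenteredGenotypes,
    yc_train: pd.Series,
    vc: VarianceComponents,
    blend: float = 0.05,
    A22: RelationshipMatrix | None = None,
) -> IterationTrace:
    """Plain GBLUP = a single unit-weight round of the weighting loop."""
    return run_wgblup(
        cg, yc_train, vc, WeightScheme(kind="nonlinearA"), n_iterations=1,
        blend=blend, A22=A22,
    )


def _intercept_design(cg: CenteredGenotypes, train_ids: list[str], y: np.ndarray) -> Design:
    pos = {a: i for i, a in enumerate(cg.animal_ids)}
    Z = np.zeros((len(train_ids), cg.n_animals))
    for r, a in enumerate(train_ids):
        Z[r, pos[a]] = 1.0
    return Design(
        X=np.ones((len(train_ids), 1)),
        Z=Z,
        y=np.asarray(y, float),
        record_animals=list(train_ids),
        kernel_ids=list(cg.animal_ids),
        x_labels=["intercept"],
        factor_levels={},
        covariates=[],
    )
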