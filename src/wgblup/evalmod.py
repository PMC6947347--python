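"""Forward-validation metrics: accuracy, dispersion bias, per-SNP variance.

Validation animals are those born strictly after the cut-off date; accuracy is
the correlation between predictions and corrected phenotypes divided by the
square root of the trait heritability, and bias is the slope of corrected
phenotypes regressed on predictions (1 = no dispersion bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    pass


@dataclass
class ValidationSplit:
    cutoff_date: pd.Timestamp
    training_ids: list[str]
    validation_ids: list[str]


@dataclass
class ValidationReport:
    """Tidy accuracy/bias table: one row per method x iteration."""

    rows: pd.DataFrame  # columns: method, iteration, accuracy, bias, n_validation
    h2: float
    cutoff_date: pd.Timestamp | None = None
    extra: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        import json

        payload = {
            "h2": self.h2,
            "cutoff_date": str(self.cutoff_date),
            "rows": self.rows.to_dict(orient="records"),
            **self.extra,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def split_by_date(phenos: pd.DataFrame, cutoff) -> ValidationSplit:
    """Validation = animals born strictly after the cut-off; ties train."""
    if "birth_date" not in phenos.columns:
        raise ValidationError("phenotype table lacks a birth_date column")
    dates = pd.to_datetime(phenos["birth_date"])
    if dates.isna().any():
        raise ValidationError("missing birth dates")
    cutoff = pd.Timestamp(cutoff)
    is_valid = dates > cutoff
    training = phenos.loc[~is_valid, "animal"].astype(str).tolist()
    validation = phenos.loc[is_valid, "animal"].astype(str).tolist()
    if not validation:
        raise ValidationError(f"no animals born after {cutoff.date()}: empty validation set")
    if not training:
        raise ValidationError(f"all animals born after {cutoff.date()}: empty training set")
    return ValidationSplit(cutoff, training, validation)


def accuracy(gebv: np.ndarray, yc: np.ndarray, h2: float) -> float:
    """cor(predictions, corrected phenotypes) / sqrt(h2)."""
    gebv = np.asarray(gebv, float)
    yc = np.asarray(yc, float)
    if not 0 < h2 <= 1:
        raise ValidationError("h2 must lie in (0, 1]")
    if gebv.size < 3 or gebv.size != yc.size:
        raise ValidationError("need >= 3 paired validation values")
    if np.std(gebv) == 0 or np.std(yc) == 0:
        raise ValidationError("zero variance in predictions or phenotypes")
    r = float(np.corrcoef(gebv, yc)[0, 1])
    return r / float(np.sqrt(h2))


def bias(gebv: np.ndarray, yc: np.ndarray) -> float:
    """OLS slope of corrected phenotypes on predictions (target 1)."""
    gebv = np.asarray(gebv, float)
    yc = np.asarray(yc, float)
    v = np.var(gebv)
    if v == 0:
        raise ValidationError("zero variance in predictions")
    return float(np.cov(yc, gebv, ddof=1)[0, 1] / np.var(gebv, ddof=1))


def snp_variance_share(u: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Percent of additive variance per SNP: 100 * 2p(1-p)u^2 / total."""
    u = np.asarray(u, float)
    p = np.asarray(freqs, float)
    if u.shape != p.shape:
        raise ValidationError("effects and frequencies must align")
    v = 2.0 * p * (1.0 - p) * u**2
    tot = v.sum()
    if tot <= 0:
        raise ValidationError("zero total SNP variance")
    return 100.0 * v / tot


def evaluate_trace(
    trace,
    yc: pd.Series,
    validation_ids: list[str],
    h2: float,
    method: str | None = None,
) -> pd.DataFrame:
    """Per-iteration accuracy/bias rows for one weighting trace."""
    vids = [str(a) for a in validation_ids]
    yv = yc.loc[vids].to_numpy(float)
    label = method if method is not None else trace.scheme.label
    rows = []
    for rec in trace.iterations:
        gv = rec.gebv.loc[vids].to_numpy(float)
        rows.append(
            {
                "method": label,
                "iteration": rec.t,
                "accuracy": accuracy(gv, yv, h2),
                "bias": bias(gv, yv),
                "n_validation": len(vids),
            }
        )
    return pd.DataFrame(rows)
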