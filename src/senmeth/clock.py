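"""Epigenetic senescence signature: per-CpG linear clocks averaged.

The signature predicts the passage number (or cumulative population
doublings, cPD) of a cultured cell preparation from methylation levels at a
small panel of senescence-associated CpGs. Each CpG carries its own
ordinary-least-squares model ``target = alpha + beta_coef * DNAm`` fitted on
training samples; a sample's prediction is the unweighted mean of the
per-CpG estimates over the CpGs with an available methylation level.
Predictions are deliberately not clipped: strongly negative or large
estimates are meaningful signals of heterogeneity (clonal populations can
predict far outside the trained passage range).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClockCpG",
    "ClockModel",
    "ClockPrediction",
    "fit_clock",
    "predict",
    "deviation_profile",
    "evaluate",
]


@dataclass(frozen=True)
class ClockCpG:
    """One signature CpG's linear model: ``target = intercept + slope * beta``."""

    cpg_id: str
    gene: str
    intercept: float
    slope: float
    r2: float

    def estimate(self, beta: float) -> float:
        return self.intercept + self.slope * beta


@dataclass
class ClockModel:
    """The full signature: one linear model per CpG, predictions averaged."""

    target: str  # "passage" or "cpd"
    cpgs: list[ClockCpG]

    def __post_init__(self) -> None:
        if not self.cpgs:
            raise ValueError("clock model needs at least one usable CpG")
        for c in self.cpgs:
            if not (np.isfinite(c.intercept) and np.isfinite(c.slope)):
                raise ValueError(f"{c.cpg_id}: non-finite coefficients")

    @property
    def cpg_ids(self) -> list[str]:
        return [c.cpg_id for c in self.cpgs]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "target": self.target,
            "cpgs": [
                {"id": c.cpg_id, "gene": c.gene, "intercept": c.intercept,
                 "slope": c.slope, "r2": c.r2}
                for c in self.cpgs
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClockModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            target=payload["target"],
            cpgs=[
                ClockCpG(d["id"], d["gene"], d["intercept"], d["slope"], d["r2"])
                for d in payload["cpgs"]
            ],
        )


@dataclass
class ClockPrediction:
    """Per-CpG passage estimates and their unweighted mean for one sample."""

    estimates: dict[str, float]
    combined: float
    n_cpgs_used: int
    sample: str | None = None


def fit_clock(
    training_table: pd.DataFrame,
    target: str = "passage",
    cpg_columns: Sequence[str] | None = None,
    genes: Mapping[str, str] | None = None,
) -> ClockModel:
    """Fit one OLS model per signature CpG: ``target ~ beta``.

    Parameters
    ----------
    training_table : one row per sample; a column named ``target`` plus one
        beta column per signature CpG (values in [0, 1], NaN allowed).
    target : name of the target column ("passage" or "cpd").
    cpg_columns : beta columns to use; default: every column other than the
        target and ``sample``.
    genes : optional map CpG column -> gene symbol.

    Missing betas are dropped pairwise per CpG. A CpG with fewer than 3
    complete pairs or zero beta variance is excluded with a warning; if no
    CpG survives, a ValueError is raised.
    """
    if target not in training_table.columns:
        raise ValueError(f"training table has no {target!r} column")
    if cpg_columns is None:
        cpg_columns = [
            c for c in training_table.columns if c not in (target, "sample", "sample_id")
        ]
    y_all = pd.to_numeric(training_table[target], errors="coerce")
    if y_all.notna().sum() < 3:
        raise ValueError("need at least 3 samples with a non-missing target")

    cpgs: list[ClockCpG] = []
    for col in cpg_columns:
        x = pd.to_numeric(training_table[col], errors="coerce")
        ok = x.notna() & y_all.notna()
        if ok.sum() < 3:
            logger.warning("clock CpG %s: <3 complete observations, excluded", col)
            continue
        xv, yv = x[ok].to_numpy(float), y_all[ok].to_numpy(float)
        if np.ptp(xv) == 0:
            logger.warning("clock CpG %s: zero beta variance, excluded", col)
            continue
        fit = stats.linregress(xv, yv)
        cpgs.append(
            ClockCpG(
                cpg_id=col,
                gene=(genes or {}).get(col, col),
                intercept=float(fit.intercept),
                slope=float(fit.slope),
                r2=float(fit.rvalue**2),
            )
        )
    if not cpgs:
        raise ValueError("no usable signature CpG (all excluded)")
    return ClockModel(target=target, cpgs=cpgs)


def predict(
    model: ClockModel, beta_profile: Mapping[str, float], sample: str | None = None
) -> ClockPrediction:
    """Predict the target for one sample from its signature-CpG betas.

    ``beta_profile`` maps CpG id to methylation level; CpGs missing from the
    profile (or NaN) are skipped and ``n_cpgs_used`` reduced. Estimates are
    not clipped. Raises if no signature CpG overlaps the profile.
    """
    estimates: dict[str, float] = {}
    for c in model.cpgs:
        beta = beta_profile.get(c.cpg_id)
        if beta is None or not np.isfinite(beta):
            continue
        estimates[c.cpg_id] = c.estimate(float(beta))
    if not estimates:
        raise ValueError(
            f"no overlap between profile and signature CpGs (expected {model.cpg_ids})"
        )
    combined = float(np.mean(list(estimates.values())))
    return ClockPrediction(estimates, combined, len(estimates), sample=sample)


def deviation_profile(
    predictions: Sequence[ClockPrediction], true_values: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG and combined prediction deviations from the true targets.

    Returns ``(per_sample, summary)``: ``per_sample`` holds one row per
    sample with ``<cpg> - true`` for every CpG (NaN if unused) plus
    ``combined``; ``summary`` gives mean, SD (n-1) and range of each
    deviation column across samples. The bulk-versus-subclone contrast lives
    here: bulk deviations hug zero at every CpG while single-cell-derived
    clones scatter widely and discordantly across CpGs.
    """
    if len(predictions) != len(true_values):
        raise ValueError("predictions and true_values differ in length")
    rows = []
    for pred, true in zip(predictions, true_values):
        row = {"sample": pred.sample, "true": true,
               "combined": pred.combined - true}
        for cid, est in pred.estimates.items():
            row[cid] = est - true
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    dev_cols = [c for c in per_sample.columns if c not in ("sample", "true")]
    summary = pd.DataFrame(
        {
            "mean": per_sample[dev_cols].mean(),
            "sd": per_sample[dev_cols].std(ddof=1),
            "min": per_sample[dev_cols].min(),
            "max": per_sample[dev_cols].max(),
        }
    )
    return per_sample, summary


def evaluate(
    predictions: Sequence[ClockPrediction] | Sequence[float],
    true_values: Sequence[float],
) -> dict[str, float]:
    """Prediction accuracy: R² (squared Pearson correlation), RMSE, n.

    R² follows the predicted-versus-real scatterplot convention (squared
    correlation), so a constant offset does not reduce it; RMSE is on the
    target scale and does.
    """
    pred = np.array(
        [p.combined if isinstance(p, ClockPrediction) else float(p) for p in predictions],
        dtype=float,
    )
    true = np.asarray(true_values, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("predictions and true_values differ in length")
    if len(pred) < 3:
        raise ValueError("need at least 3 samples to evaluate")
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        r2 = float("nan")
    else:
        r2 = float(stats.pearsonr(pred, true).statistic ** 2)
    rmse = float(np.sqrt(np.mean((pred - true) ** 2)))
    return {"r2": r2, "rmse": rmse, "n": int(len(pred))}
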