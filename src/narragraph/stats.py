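"""Rank-based correlation stage.

Spearman correlations between windowed graph attributes and symptom
scores, covariate-controlled partial Spearman correlations, and
Bonferroni thresholds, emitted as attribute x symptom-scale tables.

Partial Spearman is realized as Pearson correlation of rank residuals:
every variable is midrank-transformed, the x- and y-ranks are each
residualized by least squares on the covariate ranks (plus intercept),
and the residuals are correlated; the two-sided p-value comes from a
t distribution with n - 2 - k degrees of freedom.  With no covariates
this reduces exactly to plain Spearman.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ConstantInputError",
    "RankDeficiencyError",
    "ATTRIBUTE_COLUMNS",
    "SYMPTOM_COLUMNS",
    "DEFAULT_COVARIATES",
    "spearman",
    "partial_spearman",
    "bonferroni_threshold",
    "build_cohort_table",
    "correlation_table",
]

ATTRIBUTE_COLUMNS = ("TNW", "RE", "L1", "LSC", "ASP")
SYMPTOM_COLUMNS = (
    "symptoms_total",
    "symptoms_inattention",
    "symptoms_hyperactivity",
)
DEFAULT_COVARIATES = (
    "age",
    "iq",
    "education_years",
    "bdi",
    "stai_state",
    "stai_trait",
    "upps_total",
)

# attributes entering the Bonferroni family; TNW is reported alongside
# but flagged at the nominal level
BONFERRONI_FAMILY = ("RE", "L1", "LSC", "ASP")


class ConstantInputError(ValueError):
    """A correlation input has zero rank variance."""


class RankDeficiencyError(ValueError):
    """Covariate ranks are collinear."""


@dataclass(frozen=True)
class CorrelationResult:
    attribute: str
    scale: str
    r: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()
    significant_bonferroni: bool = False
    threshold: float = 0.05


def _check_finite(name: str, a: np.ndarray) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite values in {name}")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    r is the Pearson correlation of midranks; the two-sided p-value uses
    ``t = r * sqrt((n-2)/(1-r^2))`` with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    _check_finite("x", x)
    _check_finite("y", y)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0:
        raise ConstantInputError("x is constant (zero rank variance)")
    if np.ptp(ry) == 0:
        raise ConstantInputError("y is constant (zero rank variance)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    p = _t_pvalue(r, df=n - 2)
    return r, p


def _t_pvalue(r: float, df: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Sequence[Sequence[float]] | np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Spearman correlation of x and y controlling for covariates.

    ``covariates`` is an (n, k) matrix (or None/empty for plain
    Spearman).  Returns (r, p, n) with the p-value on n - 2 - k degrees
    of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z.reshape(n, -1) if z.size else z.reshape(n, 0)
    if z.shape[0] != n:
        raise ValueError("covariate rows must match observation count")
    k = z.shape[1]
    if k == 0:
        r, p = spearman(x, y)
        return r, p, n
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    _check_finite("covariates", z)

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0:
        raise ConstantInputError("x is constant (zero rank variance)")
    if np.ptp(ry) == 0:
        raise ConstantInputError("y is constant (zero rank variance)")
    rz = np.column_stack([sps.rankdata(col) for col in z.T])

    design = np.column_stack([np.ones(n), rz])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise RankDeficiencyError("covariate ranks are collinear")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    res_x = rx - design @ beta_x
    res_y = ry - design @ beta_y
    if np.allclose(res_x, 0) or np.allclose(res_y, 0):
        raise ConstantInputError(
            "residuals are constant after covariate control"
        )
    r = float(np.corrcoef(res_x, res_y)[0, 1])
    r = max(-1.0, min(1.0, r))
    p = _t_pvalue(r, df=n - 2 - k)
    return r, p, n


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold ``alpha / m`` for m comparisons."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError("m must be an integer >= 1")
    return alpha / m


def build_cohort_table(
    profiles: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Merge narrative profiles with subject metadata into one table.

    ``profiles`` carries subject_id, TNW and the windowed attribute
    means; ``metadata`` carries asrs_01..asrs_18 plus covariates.  ASRS
    items are scored into the three symptom counts.
    """
    from .scales import AsrsResponse, score_asrs

    item_cols = [f"asrs_{i:02d}" for i in range(1, 19)]
    missing = [c for c in item_cols if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing ASRS columns: {missing}")

    scored = []
    for _, row in metadata.iterrows():
        resp = AsrsResponse(
            subject_id=str(row["subject_id"]),
            items=tuple(int(row[c]) for c in item_cols),
        )
        rec = {"subject_id": resp.subject_id}
        rec.update(score_asrs(resp).as_dict())
        scored.append(rec)
    scores = pd.DataFrame(scored)

    meta = metadata.copy()
    meta["subject_id"] = meta["subject_id"].astype(str)
    prof = profiles.copy()
    prof["subject_id"] = prof["subject_id"].astype(str)
    out = prof.merge(scores, on="subject_id").merge(
        meta.drop(columns=item_cols), on="subject_id"
    )
    return out


def correlation_table(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
    threshold_family_size: int = 4,
    alpha: float = 0.05,
    attributes: Sequence[str] = ATTRIBUTE_COLUMNS,
    scales: Sequence[str] = SYMPTOM_COLUMNS,
) -> list[CorrelationResult]:
    """Attribute x symptom-scale correlation grid.

    Plain Spearman when ``covariates`` is empty, partial Spearman
    otherwise.  Cells for the four graph attributes are flagged against
    ``bonferroni_threshold(alpha, threshold_family_size)``; TNW is
    flagged at the nominal alpha.
    """
    covariates = tuple(covariates)
    for col in (*attributes, *scales, *covariates):
        if col not in cohort.columns:
            raise ValueError(f"cohort table missing column {col!r}")
        if cohort[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")
    corrected = bonferroni_threshold(alpha, threshold_family_size)
    z = cohort[list(covariates)].to_numpy(dtype=float) if covariates else None

    results = []
    for attr in attributes:
        for scale in scales:
            x = cohort[attr].to_numpy(dtype=float)
            y = cohort[scale].to_numpy(dtype=float)
            try:
                r, p, n = partial_spearman(x, y, z)
            except ConstantInputError as err:
                raise ConstantInputError(
                    f"({attr}, {scale}): {err}"
                ) from err
            thr = corrected if attr in BONFERRONI_FAMILY else alpha
            results.append(
                CorrelationResult(
                    attribute=attr,
                    scale=scale,
                    r=r,
                    p=p,
                    n=n,
                    covariates=covariates,
                    significant_bonferroni=p < thr,
                    threshold=thr,
                )
            )
    return results


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Long-format DataFrame of correlation results."""
    return pd.DataFrame(
        {
            "attribute": [r.attribute for r in results],
            "scale": [r.scale for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "covariates": [",".join(r.covariates) for r in results],
            "threshold": [r.threshold for r in results],
            "significant": [r.significant_bonferroni for r in results],
        }
    )
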