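"""Inter-rater agreement and error statistics for grade comparisons.

Implements linear-weighted Cohen's kappa with the standard interpretation
bands, exact Clopper-Pearson binomial confidence intervals, conditional
grade-assignment tables and residual-error summaries.

Note on confidence intervals: Clopper-Pearson applies to proportions (e.g.
45/50 graded in agreement), not to kappa itself; kappa intervals here come
from a seeded nonparametric bootstrap over cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

# lower bound (inclusive) -> label; kappa < 0 is "none"
KAPPA_BANDS: list[tuple[float, str]] = [
    (0.0, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "near perfect"),
]


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float | None
    ci_high: float | None
    confidence: float
    band: str


def _encode(a: Sequence, b: Sequence) -> tuple[np.ndarray, np.ndarray, list]:
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) == 0:
        raise ValueError("empty rating table")
    cats = sorted(set(a) | set(b))
    idx = {c: i for i, c in enumerate(cats)}
    return (
        np.array([idx[x] for x in a]),
        np.array([idx[x] for x in b]),
        cats,
    )


def linear_weighted_kappa(
    rater_a: Sequence,
    rater_b: Sequence,
    confidence: float | None = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> KappaResult:
    """Linear-weighted Cohen's kappa between two raters over ordinal categories.

    kappa = 1 - sum(w_ij O_ij) / sum(w_ij E_ij) with weights
    w_ij = |i - j| / (k - 1), O the observed joint proportions and E the
    chance-expected (outer product of marginals). Categories are ordered by
    their sorted union. A bootstrap CI over cases is attached when
    ``confidence`` is given.
    """
    ai, bi, cats = _encode(rater_a, rater_b)
    k = len(cats)
    if k < 2:
        raise ValueError("kappa undefined: a single shared constant rating")
    kappa = _weighted_kappa_from_codes(ai, bi, k)
    ci_low = ci_high = None
    if confidence is not None and len(ai) >= 2:
        rng = np.random.default_rng(seed)
        n = len(ai)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            ra, rb = ai[idx], bi[idx]
            if len(np.unique(np.concatenate([ra, rb]))) < 2:
                continue
            boots.append(_weighted_kappa_from_codes(ra, rb, k))
        if boots:
            lo = (1 - confidence) / 2
            ci_low = float(np.quantile(boots, lo))
            ci_high = float(np.quantile(boots, 1 - lo))
    return KappaResult(
        kappa=kappa,
        ci_low=ci_low,
        ci_high=ci_high,
        confidence=confidence if confidence is not None else float("nan"),
        band=interpretation_band(kappa),
    )


def _weighted_kappa_from_codes(ai: np.ndarray, bi: np.ndarray, k: int) -> float:
    n = len(ai)
    observed = np.zeros((k, k))
    np.add.at(observed, (ai, bi), 1.0 / n)
    marg_a = observed.sum(axis=1)
    marg_b = observed.sum(axis=0)
    expected = np.outer(marg_a, marg_b)
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(i - j) / (k - 1)
    denom = float((w * expected).sum())
    if denom == 0:
        raise ValueError("kappa undefined: no chance disagreement (constant ratings)")
    return float(1.0 - (w * observed).sum() / denom)


def interpretation_band(kappa: float) -> str:
    """Agreement label for a kappa value; < 0 is 'none', band boundaries
    belong to the upper band (0.21 -> 'fair')."""
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError(f"kappa out of range: {kappa}")
    if kappa < 0:
        return "none"
    label = KAPPA_BANDS[0][1]
    for lo, name in KAPPA_BANDS:
        if kappa >= lo:
            label = name
    return label


def clopper_pearson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for a proportion,
    via the beta-quantile characterisation of the binomial tails."""
    if n < 1 or not (0 <= successes <= n):
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    low = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def conditional_grade_table(reference: Sequence, predicted: Sequence) -> pd.DataFrame:
    """P(predicted grade | reference grade): row-normalised contingency table.

    Rows are reference (gold standard) grades, columns predicted grades;
    every row over a represented reference grade sums to 1.
    """
    if len(reference) != len(predicted):
        raise ValueError("rating vectors must have equal length")
    if len(reference) == 0:
        raise ValueError("empty rating table")
    cats = sorted(set(reference) | set(predicted))
    table = pd.crosstab(pd.Series(reference, name="reference"), pd.Series(predicted, name="predicted"))
    table = table.reindex(index=cats, columns=cats, fill_value=0)
    sums = table.sum(axis=1)
    out = table.div(sums.replace(0, np.nan), axis=0)
    return out


def residual_errors(estimates: Sequence[float], reference: Sequence[float]) -> dict:
    """Per-case signed residuals (estimate - reference) with mean +- SD of the
    absolute error, as used for index-error boxplots."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("length mismatch between estimates and reference")
    resid = est - ref
    return {
        "residuals": resid,
        "mean_abs_error": float(np.mean(np.abs(resid))) if resid.size else float("nan"),
        "sd_abs_error": float(np.std(np.abs(resid), ddof=0)) if resid.size else float("nan"),
        "mean_signed": float(np.mean(resid)) if resid.size else float("nan"),
    }
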