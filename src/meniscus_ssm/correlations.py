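"""Pearson correlation of shape-mode scores against anthropometric covariates.

All tests are two-tailed Pearson tests: the p-value comes from the exact
t-distribution with n - 2 degrees of freedom, and the 95% confidence
interval for r from the Fisher z-transform, z +/- z_{0.975} / sqrt(n - 3).
No multiple-testing correction is applied by default, matching common
practice in morphometric correlation screens; Benjamini-Hochberg
adjustment is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

COVARIATES = ("height", "weight", "bmi", "condyle_width", "axial_rotation")
ALPHA = 0.05


@dataclass
class AnthropometricRecord:
    """One subject's anthropometric covariates.

    height cm, weight kg, bmi kg/m^2, condyle_width mm, axial_rotation
    degrees, sex 'male'/'female'.  When height, weight and bmi are all
    present, bmi must agree with weight / (height/100)^2 within 5%.
    """

    subject_id: str
    height: float | None = None
    weight: float | None = None
    bmi: float | None = None
    condyle_width: float | None = None
    axial_rotation: float | None = None
    sex: str | None = None

    def validate(self) -> "AnthropometricRecord":
        for name in ("height", "weight", "bmi", "condyle_width"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if None not in (self.height, self.weight, self.bmi):
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(self.bmi - implied) > 0.05 * implied:
                raise ValueError(
                    f"bmi {self.bmi:.2f} inconsistent with weight/height^2 "
                    f"({implied:.2f}) beyond 5%")
        return self


@dataclass
class CorrelationResult:
    """Pearson r with two-tailed p and Fisher 95% CI for one pair."""

    r: float
    p: float
    ci_low: float | None
    ci_high: float | None
    n: int
    group: str = "mixed"
    pair: tuple[str, str] | None = None

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def fisher_ci(r: float, n: int, confidence: float = 0.95
              ) -> tuple[float, float] | None:
    """Fisher z confidence interval for a Pearson coefficient; None for n <= 3."""
    if n <= 3:
        return None
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(0.5 + confidence / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_test(x, y, group: str = "mixed",
                 pair: tuple[str, str] | None = None) -> CorrelationResult:
    """Two-tailed Pearson test with Fisher 95% CI.

    Requires equal-length vectors with n >= 3 and non-zero variance in
    both; at n = 3 the CI is undefined and reported as missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    ci = fisher_ci(res.statistic, n)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue),
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
        n=n, group=group, pair=pair)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up false-discovery-rate control)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.clip(adj, 0, 1)
    return out


def _results_frame(results: list[CorrelationResult],
                   adjust: bool) -> pd.DataFrame:
    rows = []
    for res in results:
        cov, mode = res.pair if res.pair else (None, None)
        rows.append({"group": res.group, "covariate": cov, "mode": mode,
                     "n": res.n, "r": res.r, "p": res.p,
                     "ci_low": res.ci_low, "ci_high": res.ci_high})
    frame = pd.DataFrame(rows)
    if adjust and len(frame):
        frame["p_adjusted"] = benjamini_hochberg(frame["p"].to_numpy())
        frame["significant"] = frame["p_adjusted"] < ALPHA
    elif len(frame):
        frame["significant"] = frame["p"] < ALPHA
    return frame


def records_to_frame(records: list[AnthropometricRecord]) -> pd.DataFrame:
    for rec in records:
        rec.validate()
    return pd.DataFrame(
        [{"subject_id": rec.subject_id, "sex": rec.sex,
          **{c: getattr(rec, c) for c in COVARIATES}} for rec in records]
    ).set_index("subject_id")


def anthro_correlation_table(records: list[AnthropometricRecord],
                             covariates=("height", "weight", "bmi",
                                         "condyle_width"),
                             adjust: bool = False) -> pd.DataFrame:
    """All pairwise covariate correlations (the cohort-description table)."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    frame = records_to_frame(records)
    results = []
    for i, a in enumerate(covariates):
        for b in covariates[i + 1:]:
            sub = frame[[a, b]].dropna()
            if len(sub) < 3:
                continue
            results.append(pearson_test(sub[a], sub[b], pair=(a, b)))
    return _results_frame(results, adjust)


def pmv_correlation_table(scores: pd.DataFrame,
                          records: list[AnthropometricRecord],
                          modes=(1, 2, 3, 4, 5, 6),
                          covariates=("height", "weight", "bmi",
                                      "condyle_width", "axial_rotation"),
                          groups=("mixed", "male", "female"),
                          adjust: bool = False) -> pd.DataFrame:
    """Mode-score vs covariate correlations in mixed and per-sex groups.

    ``scores`` is indexed by subject_id with one column per mode (int or
    'pmv1'-style labels are both accepted).  Subject ids must match the
    anthropometric records exactly.
    """
    frame = records_to_frame(records)
    unmatched = sorted(set(scores.index).symmetric_difference(frame.index))
    if unmatched:
        raise ValueError(f"subject ids do not match: {unmatched[:10]}")
    scores = scores.loc[frame.index]

    def mode_column(k):
        if k in scores.columns:
            return scores[k]
        name = f"pmv{k}"
        if name in scores.columns:
            return scores[name]
        raise KeyError(f"no score column for mode {k}")

    results = []
    for group in groups:
        mask = (np.ones(len(frame), dtype=bool) if group == "mixed"
                else (frame["sex"] == group).to_numpy())
        if mask.sum() < 3:
            warnings.warn(f"group {group!r} has fewer than 3 subjects; "
                          "skipped", stacklevel=2)
            continue
        for k in modes:
            score = mode_column(k).to_numpy()[mask]
            for cov in covariates:
                vals = frame[cov].to_numpy(dtype=float)[mask]
                ok = np.isfinite(vals)
                if ok.sum() < 3:
                    continue
                results.append(pearson_test(score[ok], vals[ok], group=group,
                                            pair=(cov, k)))
    return _results_frame(results, adjust)
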