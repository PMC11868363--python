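"""Clinical evaluation statistics for paired image-quality studies.

Implements the duct-to-periductal relative contrast ratio
RC = (SI_duct - SI_periduct) / (SI_duct + SI_periduct), paired two-sided
confidence intervals, non-inferiority assessment against prespecified
margins (non-inferior when the whole CI lies above minus the margin) and
superiority assessment (CI entirely above zero), weighted kappa agreement
with the conventional interpretation bands, and a synthetic generator for
paired per-patient RC values and three-reader 5-point Likert scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .errors import (
    DegenerateMarginalsError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedRatioError,
)

DUCTS = ("MPD", "CBD", "LHD", "RHD")
SCORE_ITEMS = DUCTS + ("overall",)

#: Prespecified per-duct non-inferiority margins for the RC difference
#: (the standard deviation of the reference-arm RC values).
DEFAULT_MARGINS = {"MPD": 0.07, "CBD": 0.06, "LHD": 0.07, "RHD": 0.11}

#: Reference per-duct RC central values used by the synthetic generator.
DEFAULT_RC_MEANS = {"MPD": 0.80, "CBD": 0.89, "LHD": 0.88, "RHD": 0.86}


def compute_rc(si_duct: float, si_periduct: float) -> float:
    """Relative duct-to-periductal contrast ratio, in [-1, 1]."""
    if si_duct < 0 or si_periduct < 0:
        raise InvalidParameterError("signal intensities must be >= 0")
    if si_duct + si_periduct == 0:
        raise UndefinedRatioError("both signal intensities are zero")
    return (si_duct - si_periduct) / (si_duct + si_periduct)


def paired_ci(differences, alpha: float = 0.05, method: str = "t",
              n_boot: int = 10000, seed: int | None = None):
    """Two-sided (1 - alpha) CI for the mean of paired differences.

    ``method='t'`` gives the Student-t interval; ``'bootstrap'`` the
    seeded percentile bootstrap.  Constant differences yield the
    degenerate interval (d, d).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InsufficientDataError("need at least 2 paired differences")
    if not (0 < alpha < 1):
        raise InvalidParameterError("alpha must be in (0, 1)")
    if method == "t":
        m = d.mean()
        se = d.std(ddof=1) / np.sqrt(d.size)
        if se == 0:
            return (float(m), float(m))
        tcrit = stats.t.ppf(1 - alpha / 2, d.size - 1)
        return (float(m - tcrit * se), float(m + tcrit * se))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, d.size, size=(n_boot, d.size))
        means = d[idx].mean(axis=1)
        lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi))
    raise InvalidParameterError(f"unknown CI method {method!r}")


@dataclass
class PairedComparison:
    """Verdict of a paired superiority or non-inferiority assessment."""

    duct: str | None
    differences: np.ndarray
    ci_low: float
    ci_high: float
    margin: float
    verdict: str  # superior | non_inferior | inconclusive
    alpha: float = 0.05
    metadata: dict = field(default_factory=dict)


def assess_noninferiority(differences, margin: float,
                          duct: str | None = None, alpha: float = 0.05,
                          **ci_kwargs) -> PairedComparison:
    """Non-inferior iff the whole two-sided CI lies strictly above -margin."""
    if margin < 0:
        raise InvalidParameterError("margin must be >= 0")
    lo, hi = paired_ci(differences, alpha=alpha, **ci_kwargs)
    verdict = "non_inferior" if lo > -margin else "inconclusive"
    return PairedComparison(duct, np.asarray(differences, float), lo, hi,
                            margin, verdict, alpha)


def assess_superiority(differences, duct: str | None = None,
                       alpha: float = 0.05, **ci_kwargs) -> PairedComparison:
    """Superior iff the whole two-sided CI lies strictly above zero."""
    lo, hi = paired_ci(differences, alpha=alpha, **ci_kwargs)
    verdict = "superior" if lo > 0 else "inconclusive"
    return PairedComparison(duct, np.asarray(differences, float), lo, hi,
                            0.0, verdict, alpha)


def weighted_kappa(ratings_a, ratings_b, scheme: str = "quadratic") -> float:
    """Weighted Cohen's kappa for ordinal 1-5 ratings."""
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.size != b.size or a.size < 2:
        raise InvalidParameterError("need two equal-length vectors, n >= 2")
    for v in (a, b):
        if v.min() < 1 or v.max() > 5:
            raise InvalidParameterError("ratings must lie in 1..5")
    if scheme not in ("linear", "quadratic"):
        raise InvalidParameterError("scheme must be linear or quadratic")
    if np.all(a == a[0]) and np.all(b == a[0]):
        raise DegenerateMarginalsError(
            "kappa undefined: both raters constant in one category"
        )
    k = cohen_kappa_score(a, b, weights=scheme, labels=list(range(1, 6)))
    if np.isnan(k):
        raise DegenerateMarginalsError("kappa undefined for these marginals")
    return float(k)


def kappa_interpretation(kappa: float) -> str:
    """Conventional agreement band for a kappa value.

    The value is rounded to two decimals (half up) before banding:
    0.81-1.00 excellent, 0.61-0.80 substantial, 0.41-0.60 moderate,
    0.21-0.40 fair, 0.00-0.20 poor; negative values are below chance.
    """
    if not (-1 <= kappa <= 1):
        raise InvalidParameterError("kappa must be in [-1, 1]")
    k = float(Decimal(repr(float(kappa))).quantize(Decimal("0.01"),
                                                   rounding=ROUND_HALF_UP))
    if k < 0:
        return "poor (below chance)"
    if k <= 0.20:
        return "poor"
    if k <= 0.40:
        return "fair"
    if k <= 0.60:
        return "moderate"
    if k <= 0.80:
        return "substantial"
    return "excellent"


def wilcoxon_signed_rank(a, b):
    """Off-the-shelf two-sided Wilcoxon signed-rank test (scipy-backed)."""
    return stats.wilcoxon(np.asarray(a, float), np.asarray(b, float),
                          alternative="two-sided")


# ---------------------------------------------------------------------------
# Synthetic clinical-data generator
# ---------------------------------------------------------------------------

def generate_clinical_dataset(
    n_patients: int = 41,
    rc_means: dict | None = None,
    rc_sds: dict | None = None,
    paired_correlation: float = 0.9,
    score_shift: float = 0.3,
    score_base_mean: float = 3.3,
    score_patient_sd: float = 0.8,
    score_reader_sd: float = 0.5,
    n_readers: int = 3,
    seed: int = 0,
):
    """Paired per-patient RC values and multi-reader Likert scores.

    RC values per duct are drawn from a correlated bivariate normal across
    the two arms (``U_plus``/``U_minus``), truncated to [-1, 1]; signal
    intensities consistent with each RC are emitted alongside.  Likert
    scores come from a discretized latent-normal model: a shared patient
    latent per item, an arm shift of ``score_shift`` for ``U_plus``, and
    per-reader noise, rounded and clipped to 1..5.  Fully reproducible
    given ``seed``.

    Returns ``(rc_table, score_table)`` as DataFrames; the rc table has
    columns (patient_id, duct, arm, si_duct, si_periduct, rc) and the
    score table (patient_id, reader, item, arm, score).
    """
    if n_patients < 2:
        raise InvalidParameterError("n_patients must be >= 2")
    if not (-1 < paired_correlation < 1):
        raise InvalidParameterError("paired_correlation must be in (-1, 1)")
    rc_means = dict(DEFAULT_RC_MEANS if rc_means is None else rc_means)
    rc_sds = dict(DEFAULT_MARGINS if rc_sds is None else rc_sds)
    for d, m in rc_means.items():
        if not (-1 <= m <= 1):
            raise InvalidParameterError(f"rc mean for {d} outside [-1, 1]")
    rng = np.random.default_rng(seed)

    rc_rows = []
    rho = paired_correlation
    for duct in rc_means:
        mu, sd = rc_means[duct], rc_sds[duct]
        cov = sd ** 2 * np.array([[1.0, rho], [rho, 1.0]])
        draws = rng.multivariate_normal([mu, mu], cov, size=n_patients)
        draws = np.clip(draws, -0.995, 0.995)
        si_peri = rng.uniform(40.0, 120.0, size=n_patients)
        for p in range(n_patients):
            for arm, rc in (("U_plus", draws[p, 0]),
                            ("U_minus", draws[p, 1])):
                si_duct = si_peri[p] * (1 + rc) / (1 - rc)
                rc_rows.append({
                    "patient_id": p, "duct": duct, "arm": arm,
                    "si_duct": si_duct, "si_periduct": si_peri[p],
                    "rc": compute_rc(si_duct, si_peri[p]),
                })

    score_rows = []
    for item in SCORE_ITEMS:
        latent = score_base_mean + rng.normal(0, score_patient_sd,
                                              size=n_patients)
        for arm, shift in (("U_plus", score_shift), ("U_minus", 0.0)):
            for reader in range(n_readers):
                noisy = latent + shift + rng.normal(0, score_reader_sd,
                                                    size=n_patients)
                scores = np.clip(np.rint(noisy), 1, 5).astype(int)
                for p in range(n_patients):
                    score_rows.append({
                        "patient_id": p, "reader": reader, "item": item,
                        "arm": arm, "score": int(scores[p]),
                    })
    return pd.DataFrame(rc_rows), pd.DataFrame(score_rows)


def rc_differences(rc_table: pd.DataFrame, duct: str) -> np.ndarray:
    """Per-patient U_plus - U_minus RC differences for one duct."""
    sub = rc_table[rc_table["duct"] == duct]
    wide = sub.pivot(index="patient_id", columns="arm", values="rc")
    return (wide["U_plus"] - wide["U_minus"]).to_numpy()


def score_differences(score_table: pd.DataFrame, item: str) -> np.ndarray:
    """Per-patient U_plus - U_minus differences of reader-mean scores."""
    sub = score_table[score_table["item"] == item]
    mean = sub.groupby(["patient_id", "arm"])["score"].mean().unstack()
    return (mean["U_plus"] - mean["U_minus"]).to_numpy()


def noninferiority_report(rc_table: pd.DataFrame,
                          margins: dict | None = None,
                          alpha: float = 0.05) -> dict:
    """Per-duct non-inferiority comparisons of the RC values."""
    margins = dict(DEFAULT_MARGINS if margins is None else margins)
    return {
        duct: assess_noninferiority(rc_differences(rc_table, duct),
                                    margins[duct], duct=duct, alpha=alpha)
        for duct in margins
    }


def superiority_report(score_table: pd.DataFrame,
                       alpha: float = 0.05) -> dict:
    """Per-item superiority comparisons of reader-mean Likert scores."""
    items = score_table["item"].unique()
    return {
        item: assess_superiority(score_differences(score_table, item),
                                 duct=item, alpha=alpha)
        for item in items
    }


def kappa_range(score_table: pd.DataFrame, arm: str = "U_plus",
                scheme: str = "quadratic"):
    """Pairwise weighted kappas across readers; returns (min, max, dict)."""
    sub = score_table[score_table["arm"] == arm]
    wide = sub.pivot_table(index=["patient_id", "item"], columns="reader",
                           values="score", aggfunc="first")
    readers = list(wide.columns)
    kappas = {}
    for i, ra in enumerate(readers):
        for rb in readers[i + 1:]:
            kappas[(ra, rb)] = weighted_kappa(wide[ra], wide[rb],
                                              scheme=scheme)
    vals = list(kappas.values())
    return min(vals), max(vals), kappas
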