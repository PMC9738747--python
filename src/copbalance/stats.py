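"""Class-pair screening on approximate-entropy features.

Before modelling, the analysis searches for the pair of diagnosis classes
most likely to be separable: patients are restricted to the older stratum
(age strictly above 47 years, where age-associated balance decline is
established), and every unordered class pair is compared feature-by-feature
with the two-sample Kolmogorov-Smirnov test.  A pair qualifies when the
distributions differ significantly on every feature; qualifying pairs are
ranked by mean KS distance D and the top pair is selected.  Shapiro-Wilk
normality testing is provided for the same exploratory step (the ApEn
features are typically non-normal, which is what motivates the
distribution-free KS comparison).

Both elementary tests delegate to scipy.stats; the screening logic —
stratification, pair enumeration, the all-features significance rule and the
ranking — is this module's own.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .classify import FEATURE_COLUMNS
from .synthetic import CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "ScreeningReport",
    "shapiro_wilk",
    "ks_two_sample",
    "screen_pairs",
]

DEFAULT_AGE_CUT = 47.0
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    sample_sizes: tuple[int, ...]
    feature: str | None = None


@dataclass
class ScreeningReport:
    """Outcome of the exhaustive class-pair search.

    ``pair_results`` maps each unordered class pair to its 12 per-feature KS
    results; ``ranking`` orders pairs by mean D descending with their
    qualification flag; ``selected_pair`` is the top qualifying pair or None.
    """

    age_cut: float
    alpha: float
    mode: str
    pair_results: dict[tuple[str, str], list[TestResult]] = field(default_factory=dict)
    ranking: list[tuple[tuple[str, str], float, bool]] = field(default_factory=list)
    selected_pair: tuple[str, str] | None = None
    excluded_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "age_cut": self.age_cut,
            "alpha": self.alpha,
            "mode": self.mode,
            "selected_pair": list(self.selected_pair) if self.selected_pair else None,
            "excluded_classes": self.excluded_classes,
            "ranking": [
                {"pair": list(pair), "mean_D": d, "qualifies": q}
                for pair, d, q in self.ranking
            ],
            "pair_results": {
                f"{a}|{b}": [
                    {
                        "feature": r.feature,
                        "D": r.statistic,
                        "p_value": r.p_value,
                        "sample_sizes": list(r.sample_sizes),
                    }
                    for r in results
                ]
                for (a, b), results in self.pair_results.items()
            },
        }


def shapiro_wilk(sample) -> TestResult:
    """Shapiro-Wilk W test for the null of normality (3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk unreliable above n = 5000")
    if np.ptp(x) == 0.0:
        logger.warning("constant sample: Shapiro-Wilk is degenerate, returning W=1, p=1")
        return TestResult(1.0, 1.0, "shapiro-wilk", (int(x.size),))
    w, p = sstats.shapiro(x)
    return TestResult(float(w), float(p), "shapiro-wilk", (int(x.size),))


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum of |F(x) - G(x)| over the pooled sample points;
    the p-value comes from the asymptotic two-sample Kolmogorov distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sstats.ks_2samp(a, b, method="asymp")
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        "ks-2sample",
        (int(a.size), int(b.size)),
    )


def _pair_qualifies(results: list[TestResult], alpha: float, mode: str) -> bool:
    if mode == "all_features":
        return all(r.p_value < alpha for r in results)
    if mode == "per_condition":
        # weaker reading: each condition significant on at least one axis
        for cond in CONDITIONS:
            cond_results = [r for r in results if r.feature.startswith(f"c{cond}_")]
            if not any(r.p_value < alpha for r in cond_results):
                return False
        return True
    raise ValueError(f"unknown screening mode {mode!r}")


def screen_pairs(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    age_cut: float = DEFAULT_AGE_CUT,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "all_features",
    min_class_size: int = 3,
) -> ScreeningReport:
    """Exhaustive KS screening of diagnosis-class pairs in the older stratum.

    Parameters
    ----------
    features
        One row per patient (index = patient_id), the 12 ApEn columns of
        :data:`copbalance.classify.FEATURE_COLUMNS`.
    metadata
        Columns ``patient_id``, ``diagnosis``, ``age``.
    age_cut
        Older stratum is age strictly greater than this (years).
    alpha
        Per-test significance level; no multiplicity correction is applied.
    mode
        ``"all_features"`` (default): all 12 comparisons must have p < alpha.
        ``"per_condition"``: each of the 6 conditions significant on at
        least one axis.
    """
    report = ScreeningReport(age_cut=age_cut, alpha=alpha, mode=mode)
    meta = metadata.set_index("patient_id") if "patient_id" in metadata.columns else metadata
    meta = meta.loc[meta.index.intersection(features.index)]
    older = meta[meta["age"] > age_cut]
    classes = []
    for label, group in older.groupby("diagnosis", observed=True):
        if len(group) < min_class_size:
            logger.warning(
                "class %s has %d patients above age %.0f (< %d); excluded",
                label, len(group), age_cut, min_class_size,
            )
            report.excluded_classes.append(str(label))
        else:
            classes.append(str(label))
    classes.sort()
    if len(classes) < 2:
        logger.warning("fewer than two classes above the age cut: empty report")
        return report

    ranking = []
    for a, b in itertools.combinations(classes, 2):
        ids_a = older.index[older["diagnosis"].astype(str) == a]
        ids_b = older.index[older["diagnosis"].astype(str) == b]
        results = []
        for col in FEATURE_COLUMNS:
            r = ks_two_sample(features.loc[ids_a, col], features.loc[ids_b, col])
            results.append(
                TestResult(r.statistic, r.p_value, r.test_name, r.sample_sizes, col)
            )
        report.pair_results[(a, b)] = results
        mean_d = float(np.mean([r.statistic for r in results]))
        ranking.append(((a, b), mean_d, _pair_qualifies(results, alpha, mode)))

    ranking.sort(key=lambda item: item[1], reverse=True)
    report.ranking = ranking
    qualifying = [pair for pair, _, ok in ranking if ok]
    report.selected_pair = qualifying[0] if qualifying else None
    return report
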