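"""Statistical significance of the cross-validated classifier.

Two complementary arguments:

* A label-permutation test: shuffle the label vector, re-run the entire
  LOOCV pipeline, and record the statistic (AUC or accuracy); the p-value
  is the plain fraction of permuted statistics at least as large as the
  observed one (no +1 smoothing; an observed zero count is reported as a
  bound "< 1/n_perm").

* A closed-form binomial argument: the probability that a coin-flip
  classifier gets strictly more than a given fraction of n cases right,
  computed by exact integer summation of the binomial tail.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List

import numpy as np

from .classify import ClassifierConfig, accuracy_at, loocv_scores, roc_auc
from .features import FeatureMatrix


class SignificanceError(ValueError):
    """Raised for invalid significance-test inputs."""


@dataclass
class PermutationResult:
    """Observed statistic, permutation null sample, and the resulting p-value."""

    statistic: str
    observed: float
    null_values: List[float]
    n_perm: int
    p_value: float
    seed: int

    @property
    def p_display(self) -> str:
        """The p-value, with an exact zero shown as the bound it implies."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_value:g}"

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.with_suffix(".json").write_text(json.dumps({
            "statistic": self.statistic,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "p_display": self.p_display,
            "seed": self.seed,
        }, indent=2))
        np.savetxt(prefix.with_suffix(".null.tsv"), self.null_values, fmt="%.10g")


def _statistic(X: np.ndarray, y: np.ndarray, which: str, cfg: ClassifierConfig) -> float:
    scores = loocv_scores(X, y, cfg)
    if which == "auc":
        return roc_auc(scores, y)[1]
    return accuracy_at(scores, y, 0.5)


def permutation_test(
    features: FeatureMatrix,
    statistic: str = "auc",
    n_perm: int = 2000,
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
    fast: bool = False,
) -> PermutationResult:
    """Label-permutation p-value for the LOOCV AUC or accuracy.

    Each permutation uniformly shuffles the label vector and re-runs the
    entire LOOCV pipeline (standardization, SVM fit and calibration per
    fold).  ``fast=True`` switches the config to rank calibration, which
    leaves the score order — hence the AUC — unchanged while skipping the
    per-fold sigmoid fit; it is off by default and not recommended for the
    accuracy statistic, whose 0.5 threshold lives on the calibrated scale.
    """
    if statistic not in ("auc", "accuracy"):
        raise SignificanceError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise SignificanceError("n_perm must be >= 1")
    cfg = cfg or ClassifierConfig()
    if fast:
        from dataclasses import replace
        cfg = replace(cfg, calibration="rank")
    X, y = features.values, features.y
    observed = _statistic(X, y, statistic, cfg)
    rng = np.random.default_rng(seed)
    null_values = []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        null_values.append(_statistic(X, y_perm, statistic, cfg))
    p = float(np.sum(np.asarray(null_values) >= observed)) / n_perm
    return PermutationResult(
        statistic=statistic,
        observed=float(observed),
        null_values=[float(v) for v in null_values],
        n_perm=n_perm,
        p_value=p,
        seed=seed,
    )


def binomial_significance(
    n_cases: int, fraction_correct: float, null_success_prob: float = 0.5
) -> float:
    """Exact upper-tail probability of beating a chance classifier.

    P(X > fraction_correct * n_cases) with X ~ Binomial(n_cases, p0), i.e.
    P(X >= floor(fraction_correct * n_cases) + 1), by exact summation over
    binomial coefficients (no normal approximation).
    """
    if n_cases < 1:
        raise SignificanceError("n_cases must be >= 1")
    if not 0.0 < fraction_correct < 1.0:
        raise SignificanceError("fraction_correct must lie strictly in (0, 1)")
    if not 0.0 < null_success_prob < 1.0:
        raise SignificanceError("null_success_prob must lie strictly in (0, 1)")
    k_min = math.floor(fraction_correct * n_cases) + 1
    if k_min > n_cases:
        return 0.0
    p, q = null_success_prob, 1.0 - null_success_prob
    total = 0.0
    for k in range(k_min, n_cases + 1):
        total += math.comb(n_cases, k) * (p ** k) * (q ** (n_cases - k))
    return min(total, 1.0)
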