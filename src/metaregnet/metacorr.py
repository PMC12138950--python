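"""Random-effects meta-analysis of TF-target Pearson correlations.

Each cohort x subtype correlation r with sample size n enters on the Fisher-z
scale, z = atanh(r) with sampling variance v = 1/(n - 3).  Cohorts are pooled
per TF and subtype with the DerSimonian-Laird estimator of the between-study
variance tau^2:

    Q    = sum w_i (z_i - z_fixed)^2,          w_i = 1/v_i
    tau2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))
    z*   = sum z_i/(v_i + tau2) / sum 1/(v_i + tau2)

The pooled correlation, its normal-theory confidence interval and the
two-sided p-value are reported on the correlation scale via tanh.  A TF is
retained as a regulator when its pooled |r| exceeds the cutoff with p below
threshold in every required subtype (the dual-subtype filter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class MetaError(ValueError):
    pass


@dataclass
class CorrelationRecord:
    """One cohort-level correlation on the Fisher-z scale."""

    tf: str
    target: str
    cohort: str
    subtype: str
    r: float
    n: int

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise MetaError(f"|r| must be < 1, got {self.r}")
        if self.n < 4:
            raise MetaError("n must be >= 4 for Fisher-z variance 1/(n-3)")

    @property
    def z(self) -> float:
        return float(np.arctanh(self.r))

    @property
    def v(self) -> float:
        return 1.0 / (self.n - 3)


def fisher_z_record(r: float, n: int, tf: str = "", target: str = "",
                    cohort: str = "", subtype: str = "") -> CorrelationRecord:
    return CorrelationRecord(tf, target, cohort, subtype, float(r), int(n))


@dataclass
class MetaResult:
    tf: str
    subtype: str
    pooled_r: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    Q: float
    k: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.pooled_r <= self.ci_high):
            raise MetaError("CI must bracket the pooled estimate")
        if self.tau2 < 0:
            raise MetaError("tau2 must be >= 0")


@dataclass
class MetaParams:
    abs_r_cutoff: float = 0.4
    p_cutoff: float = 0.05
    require_both_subtypes: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.abs_r_cutoff < 1):
            raise MetaError("abs_r_cutoff must lie in [0, 1)")
        if not (0 < self.p_cutoff <= 1):
            raise MetaError("p_cutoff must lie in (0, 1]")


def pool_random_effects(records: list[CorrelationRecord], ci_level: float = 0.95) -> MetaResult:
    """DerSimonian-Laird pooling of one TF x subtype group of correlations.

    With zero heterogeneity (Q <= k - 1) the estimate reduces exactly to the
    fixed-effect inverse-variance mean; k = 1 returns that study's r with a
    CI from its own variance.
    """
    if not records:
        raise MetaError("no records to pool")
    tfs = {r.tf for r in records}
    subtypes = {r.subtype for r in records}
    if len(tfs) > 1 or len(subtypes) > 1:
        raise MetaError("records must share tf and subtype")
    z = np.array([r.z for r in records])
    v = np.array([r.v for r in records])
    k = len(records)
    w = 1.0 / v
    z_fixed = (w * z).sum() / w.sum()
    Q = float((w * (z - z_fixed) ** 2).sum())
    if k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom)
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    z_pooled = float((w_star * z).sum() / w_star.sum())
    se = float(np.sqrt(1.0 / w_star.sum()))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    p = float(2 * stats.norm.sf(abs(z_pooled) / se))
    return MetaResult(
        tf=records[0].tf,
        subtype=records[0].subtype,
        pooled_r=float(np.tanh(z_pooled)),
        ci_low=float(np.tanh(z_pooled - zcrit * se)),
        ci_high=float(np.tanh(z_pooled + zcrit * se)),
        p=p,
        tau2=float(tau2),
        Q=Q,
        k=k,
    )


def select_regulators(meta: dict[tuple[str, str], MetaResult],
                      params: MetaParams | None = None,
                      subtypes: tuple[str, ...] | None = None) -> list[str]:
    """TFs whose pooled |r| > cutoff with p < threshold in every required subtype."""
    params = params or MetaParams()
    tfs = sorted({tf for tf, _ in meta})
    if subtypes is None:
        subtypes = tuple(sorted({s for _, s in meta}))
    retained = []
    for tf in tfs:
        results = []
        complete = True
        for s in subtypes:
            res = meta.get((tf, s))
            if res is None:
                complete = False
            else:
                results.append(res)
        if params.require_both_subtypes and not complete:
            warnings.warn(f"TF {tf} lacks results for some subtypes; excluded")
            continue
        if results and all(
            abs(r.pooled_r) > params.abs_r_cutoff and r.p < params.p_cutoff
            for r in results
        ):
            retained.append(tf)
    return retained


def forest_json(records: list[CorrelationRecord], result: MetaResult) -> dict:
    """Forest-plot-ready structure: one row per study plus the pooled row."""
    zcrit = 1.959963984540054
    return {
        "tf": result.tf,
        "subtype": result.subtype,
        "studies": [
            {
                "cohort": r.cohort,
                "r": r.r,
                "n": r.n,
                "ci_low": float(np.tanh(r.z - zcrit * np.sqrt(r.v))),
                "ci_high": float(np.tanh(r.z + zcrit * np.sqrt(r.v))),
            }
            for r in records
        ],
        "pooled": {
            "r": result.pooled_r,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "p": result.p,
            "tau2": result.tau2,
            "Q": result.Q,
            "k": result.k,
        },
    }


def meta_table(results: list[MetaResult]) -> pd.DataFrame:
    """Forest-plot-ready table: one pooled row per TF x subtype."""
    return pd.DataFrame(
        [
            {
                "tf": r.tf,
                "subtype": r.subtype,
                "pooled_r": r.pooled_r,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "tau2": r.tau2,
                "Q": r.Q,
                "k": r.k,
            }
            for r in results
        ]
    )
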