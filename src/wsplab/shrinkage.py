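"""IVW combination of per-variant estimates and shrinkage with delta-method SEs.

Per-variant effect estimates (beta, SE) from a within-pair model are
combined against discovery-GWAS effect sizes ("weights") by the
inverse-variance weighted (IVW) estimator

    beta_IVW = sum_j w_j b_j / s_j^2  /  sum_j w_j^2 / s_j^2
    se_IVW   = 1 / sqrt( sum_j w_j^2 / s_j^2 ),

which is the slope of the no-intercept weighted regression of betas on
weights with weights 1/SE^2 — the effect of the discovery polygenic score
on the phenotype in that model. Shrinkage between two models is the
percentage attenuation of the comparison IVW estimate relative to the
reference, with a first-order delta-method standard error assuming zero
covariance between the two estimators. Heterogeneity between estimates is
assessed by the normal difference-of-two-means test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IVWResult",
    "ShrinkageResult",
    "ivw_combine",
    "compute_shrinkage",
    "difference_of_means_test",
]


@dataclass(frozen=True)
class IVWResult:
    beta_ivw: float
    se_ivw: float
    n_variants: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.se_ivw) and self.se_ivw > 0):
            raise ValueError(f"se_ivw must be positive, got {self.se_ivw}")


@dataclass(frozen=True)
class ShrinkageResult:
    """Percentage attenuation of the comparison model relative to the
    reference, positive when the comparison estimate is closer to zero."""

    shrinkage_pct: float
    se_pct: float
    ci_low_pct: float
    ci_high_pct: float
    reference_label: str
    comparison_label: str
    het_z: Optional[float] = None
    het_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ci_low_pct <= self.shrinkage_pct <= self.ci_high_pct:
            raise ValueError("confidence interval must bracket the estimate")
        if self.het_p is not None and not 0.0 <= self.het_p <= 1.0:
            raise ValueError(f"het_p must be a probability, got {self.het_p}")


def ivw_combine(table: pd.DataFrame) -> IVWResult:
    """Inverse-variance weighted estimate from a (variant, weight, beta, se) table.

    ``weight`` is the discovery-GWAS effect size for the variant; ``beta``
    and ``se`` come from the within-pair model being summarised.
    """
    required = {"weight", "beta", "se"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"association table lacks columns: {sorted(missing)}")
    if len(table) < 1:
        raise ValueError("need at least one variant")
    if "variant" in table.columns and table["variant"].duplicated().any():
        dupes = table.loc[table["variant"].duplicated(), "variant"].tolist()
        raise ValueError(f"duplicate variants in association table: {dupes}")
    w = table["weight"].to_numpy(dtype=float)
    b = table["beta"].to_numpy(dtype=float)
    s = table["se"].to_numpy(dtype=float)
    if not np.all(np.isfinite(w)) or not np.all(np.isfinite(b)):
        raise ValueError("weights and betas must be finite")
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all SEs must be positive and finite")
    info = np.sum(w**2 / s**2)
    if info == 0.0:
        raise ValueError("all weights are zero: no information to combine")
    beta = float(np.sum(w * b / s**2) / info)
    return IVWResult(beta_ivw=beta, se_ivw=float(1.0 / np.sqrt(info)), n_variants=len(table))


def compute_shrinkage(
    reference: IVWResult,
    comparison: IVWResult,
    reference_label: str = "reference",
    comparison_label: str = "comparison",
) -> ShrinkageResult:
    """Percentage attenuation of comparison relative to reference.

        shrinkage% = 100 * (1 - beta_comparison / beta_reference)

    The SE is first-order delta method on the ratio with zero covariance:
    100 * sqrt( se_c^2/b_r^2 + b_c^2 se_r^2 / b_r^4 ); the 95% CI is
    estimate +/- 1.96 SE. A weakly identified reference (|beta| < 10 SE)
    triggers a warning — the ratio CI is then unreliable; an exactly zero
    reference beta is an error.
    """
    b_r, s_r = reference.beta_ivw, reference.se_ivw
    b_c, s_c = comparison.beta_ivw, comparison.se_ivw
    if b_r == 0.0:
        raise ValueError("reference beta is exactly zero: shrinkage undefined")
    if abs(b_r) < 10.0 * s_r:
        warnings.warn(
            "reference estimate is weakly identified (|beta| < 10 SE); "
            "the delta-method interval may be unreliable",
            stacklevel=2,
        )
    pct = 100.0 * (1.0 - b_c / b_r)
    se = 100.0 * np.sqrt(s_c**2 / b_r**2 + (b_c**2) * s_r**2 / b_r**4)
    half = 1.96 * se
    return ShrinkageResult(
        shrinkage_pct=float(pct),
        se_pct=float(se),
        ci_low_pct=float(pct - half),
        ci_high_pct=float(pct + half),
        reference_label=reference_label,
        comparison_label=comparison_label,
    )


def difference_of_means_test(
    est1: Tuple[float, float], est2: Tuple[float, float]
) -> Tuple[float, float]:
    """Normal test for a difference between two independent estimates.

    ``z = (v1 - v2) / sqrt(se1^2 + se2^2)`` with a two-sided p-value;
    assumes zero covariance between the estimators.
    """
    v1, s1 = est1
    v2, s2 = est2
    for value in (v1, s1, v2, s2):
        if not np.isfinite(value):
            raise ValueError("estimates and SEs must be finite")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("both SEs must be positive")
    z = (v1 - v2) / np.hypot(s1, s2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def shrinkage_with_heterogeneity(
    result_a: ShrinkageResult, result_b: ShrinkageResult
) -> ShrinkageResult:
    """Attach a heterogeneity z / p comparing two shrinkage estimates to the
    first of them (computed on the shrinkage scale)."""
    z, p = difference_of_means_test(
        (result_a.shrinkage_pct, result_a.se_pct),
        (result_b.shrinkage_pct, result_b.se_pct),
    )
    return ShrinkageResult(
        shrinkage_pct=result_a.shrinkage_pct,
        se_pct=result_a.se_pct,
        ci_low_pct=result_a.ci_low_pct,
        ci_high_pct=result_a.ci_high_pct,
        reference_label=result_a.reference_label,
        comparison_label=result_a.comparison_label,
        het_z=z,
        het_p=p,
    )


def join_weights(
    estimates_frame: pd.DataFrame, weights_frame: pd.DataFrame
) -> pd.DataFrame:
    """Join a summary-statistics table (variant, beta, se) with a discovery
    weights table (variant, weight) into the IVW input schema."""
    merged = estimates_frame.merge(weights_frame[["variant", "weight"]], on="variant")
    if len(merged) < len(estimates_frame):
        lost = set(estimates_frame["variant"]) - set(merged["variant"])
        raise ValueError(f"variants missing discovery weights: {sorted(lost)}")
    return merged


__all__ += ["shrinkage_with_heterogeneity", "join_weights"]
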