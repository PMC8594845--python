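"""Spouse-pair construction and within-pair correlation estimation.

Spouses are formed by the rank-matching procedure: males and females are
each sorted in descending order of a compatibility score and matched by
rank. Matching on a score correlated with a trait induces a spousal
correlation for that trait (the large-sample limit under quantile
matching is the squared trait-score correlation). Random-pair null
replicates re-pair the same individuals uniformly at random, keeping
every pair male-female, which destroys assortment while preserving the
marginal distributions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import SimulationSeed

__all__ = [
    "CorrelationEstimate",
    "rank_match_pairs",
    "generate_random_pairs",
    "pairwise_correlation",
    "write_pairs",
    "read_pairs",
]

PAIR_COLUMNS = ["index_id", "partner_id", "pair_type", "replicate"]

#: replicate count used throughout for the random-pair null
DEFAULT_N_REPLICATES = 100


@dataclass(frozen=True)
class CorrelationEstimate:
    """Within-pair association of one variable, estimated by regressing the
    partner's value on the index member's value (slope convention); the
    Pearson correlation is carried alongside for reference."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_pairs: int
    pearson_r: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")


def _descending_stable(values: np.ndarray) -> np.ndarray:
    """Indices sorting values descending, ties broken by original order."""
    return np.argsort(-values, kind="stable")


def rank_match_pairs(cohort: pd.DataFrame, score_field: str) -> pd.DataFrame:
    """Pair the i-th highest-scoring male with the i-th highest-scoring female.

    The male is always the index member. Requires equal sex counts; unequal
    counts raise rather than silently dropping individuals.
    """
    if score_field not in cohort.columns:
        raise ValueError(f"score field {score_field!r} not found in cohort")
    scores = cohort[score_field].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError(f"score field {score_field!r} contains non-finite values")
    males = cohort[cohort["sex"] == 1]
    females = cohort[cohort["sex"] == 0]
    if len(males) != len(females):
        raise ValueError(
            f"rank matching requires equal sex counts, got {len(males)} males "
            f"and {len(females)} females"
        )
    m_order = _descending_stable(males[score_field].to_numpy(dtype=float))
    f_order = _descending_stable(females[score_field].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "index_id": males["id"].to_numpy()[m_order],
            "partner_id": females["id"].to_numpy()[f_order],
            "pair_type": "spouse",
            "replicate": pd.array([pd.NA] * len(males), dtype="Int64"),
        }
    )


def generate_random_pairs(
    spouse_pairs: pd.DataFrame,
    cohort: pd.DataFrame,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: SimulationSeed = SimulationSeed(0, "random-pairs"),
) -> pd.DataFrame:
    """Uniformly random male-female re-pairings of a paired sample.

    Each replicate permutes the female partners against the fixed males;
    a random pair may coincide with a true couple (no derangement is
    enforced). Replicates are indexed 0..n_replicates-1.
    """
    if n_replicates < 0:
        raise ValueError(f"n_replicates must be >= 0, got {n_replicates}")
    if n_replicates == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    sex = cohort.set_index("id")["sex"]
    males = spouse_pairs["index_id"].to_numpy()
    females = spouse_pairs["partner_id"].to_numpy()
    if not (sex.loc[males] == 1).all() or not (sex.loc[females] == 0).all():
        raise ValueError("spouse_pairs must index males against female partners")
    rng = seed.rng()
    frames = []
    for r in range(n_replicates):
        frames.append(
            pd.DataFrame(
                {
                    "index_id": males,
                    "partner_id": rng.permutation(females),
                    "pair_type": "random",
                    "replicate": r,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["replicate"] = out["replicate"].astype("Int64")
    return out


def pairwise_correlation(
    cohort: pd.DataFrame, pairs: pd.DataFrame, field: str
) -> CorrelationEstimate:
    """Within-pair association of ``field`` for one set of pairs.

    Regresses the partner's value on the index member's value; when the two
    marginal variances are equal the slope is numerically close to the
    Pearson correlation, which is why pair studies report regression slopes
    as correlations.
    """
    col = field if field in cohort.columns else f"pheno_{field}"
    if col not in cohort.columns:
        raise ValueError(f"field {field!r} not found in cohort")
    values = cohort.set_index("id")[col]
    x = values.loc[pairs["index_id"]].to_numpy(dtype=float)
    y = values.loc[pairs["partner_id"]].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(x)}")
    fit = stats.linregress(x, y)
    half = 1.96 * fit.stderr
    return CorrelationEstimate(
        estimate=float(fit.slope),
        se=float(fit.stderr),
        ci_low=float(fit.slope - half),
        ci_high=float(fit.slope + half),
        n_pairs=int(len(x)),
        pearson_r=float(fit.rvalue),
    )


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="")


def read_pairs(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"index_id": str, "partner_id": str})
    frame["replicate"] = frame["replicate"].astype("Int64")
    return frame
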