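"""Within-pair difference tables and difference regressions.

A pair contributes one observation: the index-minus-partner difference of
the outcome regressed on the difference of a predictor, with difference
covariates (age, sex, ancestry covariates) and the sex of the index
member. Any environmental term shared by the two members of a pair is
identical in both and cancels exactly from every difference, which is the
design's claim to deconfounding.

Linear difference models whose regressors are all antisymmetric (they
negate when the pair order is reversed) are fit without an intercept, so
the fitted slope is exactly invariant to reversing the order of any
subset of pairs. Designs containing ``index_sex`` — which swaps rather
than negates — and all logistic fits include an intercept.

For binary outcomes, pairs are reoriented so the outcome difference is 0
or 1 (discordant pairs always index the case; concordant pairs are kept
with outcome 0) and the oriented difference is modelled by unconditional
logistic regression.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AssociationEstimate",
    "compute_pair_differences",
    "orient_binary_pairs",
    "fit_pair_regression",
    "summarize_random_pair_fits",
    "estimates_to_frame",
    "write_estimates",
    "read_estimates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationEstimate:
    """One model's effect estimate for one variant or exposure."""

    variant_or_exposure: str
    beta: float
    se: float
    n_pairs: int
    model_label: str = "wsp"
    family: str = "linear"

    def __post_init__(self) -> None:
        # zero allowed for noiseless designs; IVW requires strictly positive
        if not (np.isfinite(self.se) and self.se >= 0):
            raise ValueError(f"se must be nonnegative and finite, got {self.se}")
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")


def _resolve(cohort: pd.DataFrame, name: str) -> str:
    if name in cohort.columns:
        return name
    pheno = f"pheno_{name}"
    if pheno in cohort.columns:
        return pheno
    raise ValueError(f"field {name!r} not found in cohort")


def compute_pair_differences(
    cohort: pd.DataFrame,
    pairs: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Index-minus-partner differences for one set of pairs.

    Returns one row per pair with ``outcome_diff``, a ``<name>_diff``
    column per predictor and covariate, ``index_sex``, ``pair_type`` and
    ``replicate``. Pairs with any missing value among the used fields are
    dropped with a logged count; zero surviving pairs is an error.
    """
    out_col = _resolve(cohort, outcome)
    pred_cols = {p: _resolve(cohort, p) for p in predictors}
    cov_cols = {c: _resolve(cohort, c) for c in covariates}
    used = [out_col, *pred_cols.values(), *cov_cols.values(), "sex"]
    indexed = cohort.set_index("id")[list(dict.fromkeys(used))]

    idx = indexed.loc[pairs["index_id"]].reset_index(drop=True)
    par = indexed.loc[pairs["partner_id"]].reset_index(drop=True)

    diffs = pd.DataFrame(
        {
            "pair_id": pairs["index_id"].to_numpy()
            + "|"
            + pairs["partner_id"].to_numpy(),
            "index_id": pairs["index_id"].to_numpy(),
            "partner_id": pairs["partner_id"].to_numpy(),
            "outcome_diff": idx[out_col].to_numpy(dtype=float)
            - par[out_col].to_numpy(dtype=float),
        }
    )
    for name, col in {**pred_cols, **cov_cols}.items():
        diffs[f"{name}_diff"] = idx[col].to_numpy(dtype=float) - par[col].to_numpy(
            dtype=float
        )
    diffs["index_sex"] = idx["sex"].to_numpy(dtype=float)
    diffs["partner_sex"] = par["sex"].to_numpy(dtype=float)
    diffs["pair_type"] = pairs["pair_type"].to_numpy()
    diffs["replicate"] = (
        pairs["replicate"].to_numpy()
        if "replicate" in pairs.columns
        else pd.array([pd.NA] * len(pairs), dtype="Int64")
    )

    numeric = [c for c in diffs.columns if c.endswith("_diff")] + ["index_sex"]
    complete = np.all(np.isfinite(diffs[numeric].to_numpy(dtype=float)), axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d pairs with missing values", n_dropped)
    diffs = diffs.loc[complete].reset_index(drop=True)
    if len(diffs) == 0:
        raise ValueError("no complete pairs remain after dropping missing values")
    return diffs


def _canonical_bit(index_id: str, partner_id: str) -> int:
    """Order-invariant pseudo-random bit for one unordered pair of ids."""
    a, b = sorted((str(index_id), str(partner_id)))
    digest = hashlib.sha256(f"{a}|{b}".encode("utf-8")).digest()
    return digest[0] & 1


def orient_binary_pairs(diffs: pd.DataFrame) -> pd.DataFrame:
    """Reorient pairs with a binary outcome so outcome_diff is 0 or 1.

    Rows with outcome difference -1 (partner is the case) are flipped: all
    difference columns are negated and the index/partner roles (and sexes)
    are swapped. Concordant pairs (case-case and control-control) are
    retained with outcome 0 and put into a canonical orientation keyed to
    the unordered id pair (a deterministic, order-invariant coin flip), so
    the oriented table — and every downstream estimate — is identical
    whichever member was initially the index, and the index-sex covariate
    is not structurally confounded with discordance when the input pairs
    are all male-indexed. Idempotent on already-oriented tables.
    """
    values = diffs["outcome_diff"].to_numpy(dtype=float)
    if not np.all(np.isin(values, (-1.0, 0.0, 1.0))):
        raise ValueError("outcome is not binary: outcome_diff must lie in {-1, 0, 1}")
    out = diffs.copy()
    flip = values == -1.0
    if "index_id" in out.columns and "partner_id" in out.columns:
        idx_ids = out["index_id"].astype(str).to_numpy()
        par_ids = out["partner_id"].astype(str).to_numpy()
        for i in np.flatnonzero(values == 0.0):
            lo, hi = sorted((idx_ids[i], par_ids[i]))
            want_index = (lo, hi)[_canonical_bit(idx_ids[i], par_ids[i])]
            if idx_ids[i] != want_index:
                flip[i] = True
    else:
        logger.info(
            "no id columns: concordant pairs keep their input orientation"
        )
    diff_cols = [c for c in out.columns if c.endswith("_diff")]
    out.loc[flip, diff_cols] = -out.loc[flip, diff_cols]
    idx_sex = out["index_sex"].to_numpy().copy()
    par_sex = out["partner_sex"].to_numpy().copy()
    out.loc[flip, "index_sex"] = par_sex[flip]
    out.loc[flip, "partner_sex"] = idx_sex[flip]
    if "index_id" in out.columns:
        idx_id = out["index_id"].to_numpy().copy()
        out.loc[flip, "index_id"] = out.loc[flip, "partner_id"].to_numpy()
        out.loc[flip, "partner_id"] = idx_id[flip]
    return out


def _auto_covariates(diffs: pd.DataFrame, exclude: set) -> list:
    cols = []
    if "age_diff" in diffs.columns and "age_diff" not in exclude:
        cols.append("age_diff")
    # sibling-style designs carry sex_diff; male-indexed spouse designs use
    # the index member's sex instead
    if "sex_diff" in diffs.columns:
        cols.append("sex_diff")
    else:
        cols.append("index_sex")
    cols += [
        c
        for c in diffs.columns
        if c.startswith("pc") and c.endswith("_diff") and c not in exclude
    ]
    return cols


def fit_pair_regression(
    diffs: pd.DataFrame,
    predictors: Sequence[str],
    covariates: Optional[Sequence[str]] = None,
    family: str = "linear",
    model_label: str = "wsp",
    min_pairs: int = 10,
) -> list:
    """Marginal difference regressions, one fitted model per predictor.

    Each predictor of interest is fit separately with the shared covariate
    set, mirroring per-variant association testing. ``covariates=None``
    selects ``age_diff`` (if present), ``sex_diff`` if present else
    ``index_sex``, and any ancestry-difference columns in the table;
    constant columns are pruned with a logged note.
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    if len(diffs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs, got {len(diffs)}")
    y = diffs["outcome_diff"].to_numpy(dtype=float)
    if family == "logistic" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError(
            "logistic family requires an oriented {0,1} outcome; "
            "run orient_binary_pairs first"
        )

    pred_cols = [p if p.endswith("_diff") else f"{p}_diff" for p in predictors]
    if covariates is None:
        cov_cols = _auto_covariates(diffs, exclude=set(pred_cols))
    else:
        cov_cols = [
            c if (c.endswith("_diff") or c == "index_sex") else f"{c}_diff"
            for c in covariates
        ]
    missing = [c for c in pred_cols + cov_cols if c not in diffs.columns]
    if missing:
        raise ValueError(f"columns not found in difference table: {missing}")

    kept_cov = []
    for c in cov_cols:
        if np.ptp(diffs[c].to_numpy(dtype=float)) == 0.0:
            logger.info("dropping constant covariate column %r", c)
        else:
            kept_cov.append(c)

    estimates = []
    for pred_name, pred_col in zip(predictors, pred_cols):
        cols = [pred_col] + kept_cov
        X = diffs[cols].to_numpy(dtype=float)
        add_intercept = family == "logistic" or "index_sex" in cols
        if add_intercept:
            X = sm.add_constant(X, prepend=False)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient for predictor {pred_name!r}; "
                f"columns {cols} are collinear"
            )
        if family == "linear":
            res = sm.OLS(y, X).fit()
        else:
            try:
                res = sm.Logit(y, X).fit(disp=0)
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                raise ValueError(
                    f"logistic fit failed for predictor {pred_name!r}: {exc}"
                ) from exc
            if not res.mle_retvals.get("converged", True) or not np.isfinite(
                res.bse[0]
            ):
                raise ValueError(
                    f"separation or non-convergence in logistic fit for "
                    f"predictor {pred_name!r}"
                )
        base = pred_name[:-5] if pred_name.endswith("_diff") else pred_name
        estimates.append(
            AssociationEstimate(
                variant_or_exposure=base,
                beta=float(res.params[0]),
                se=float(res.bse[0]),
                n_pairs=int(len(diffs)),
                model_label=model_label,
                family=family,
            )
        )
    return estimates


def summarize_random_pair_fits(
    replicate_estimates: Sequence[Sequence[AssociationEstimate]],
) -> list:
    """Median beta and median SE per variant across random-pair replicates.

    A single replicate passes through unchanged apart from the model label.
    """
    if len(replicate_estimates) == 0:
        raise ValueError("need at least one replicate of estimates")
    variant_sets = [
        tuple(e.variant_or_exposure for e in rep) for rep in replicate_estimates
    ]
    if len(set(variant_sets)) != 1:
        raise ValueError("variant sets differ across replicates")
    families = {e.family for rep in replicate_estimates for e in rep}
    if len(families) != 1:
        raise ValueError("mixed model families across replicates")
    (family,) = families
    out = []
    for j, variant in enumerate(variant_sets[0]):
        betas = np.array([rep[j].beta for rep in replicate_estimates])
        ses = np.array([rep[j].se for rep in replicate_estimates])
        n = int(np.median([rep[j].n_pairs for rep in replicate_estimates]))
        out.append(
            AssociationEstimate(
                variant_or_exposure=variant,
                beta=float(np.median(betas)),
                se=float(np.median(ses)),
                n_pairs=n,
                model_label="random_pair_median",
                family=family,
            )
        )
    return out


def estimates_to_frame(estimates: Sequence[AssociationEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant": [e.variant_or_exposure for e in estimates],
            "model_label": [e.model_label for e in estimates],
            "family": [e.family for e in estimates],
            "beta": [e.beta for e in estimates],
            "se": [e.se for e in estimates],
            "n_pairs": [e.n_pairs for e in estimates],
        }
    )


def write_estimates(estimates: Sequence[AssociationEstimate], path) -> None:
    estimates_to_frame(estimates).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_estimates(path) -> list:
    frame = pd.read_csv(path, sep="\t", dtype={"variant": str})
    return [
        AssociationEstimate(
            variant_or_exposure=row.variant,
            beta=float(row.beta),
            se=float(row.se),
            n_pairs=int(row.n_pairs),
            model_label=row.model_label,
            family=row.family,
        )
        for row in frame.itertuples()
    ]
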