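"""Synthetic cohorts with the structure assumed by within-pair analyses.

The generator produces individual-level tables under an additive phenotype
model

    P = G + c*E + a*Age + s*Sex + offset*subpop + eps,

where ``G`` is the sum of per-variant dosage effects, ``E`` is an
unmeasured environmental confounder, and ``eps`` is i.i.d. noise. A latent
assortment score ``A`` (a weighted combination of standardised cohort
columns plus noise) drives spouse formation downstream; ancestry
covariates ``pc1..pc10`` stand in for genetic principal components, with
``pc1`` tracking subpopulation membership when two-way stratification is
enabled. Sibling cohorts are generated by explicit Mendelian segregation
from simulated parental genomes.

Cohort tables are plain :class:`pandas.DataFrame` objects with columns
``id, sex, age, family_id, E, A, pc1..pc10, pheno_<name>..., g_<j>...``
and round-trip losslessly through tab-separated files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import SimulationSeed

__all__ = [
    "StratificationParams",
    "PhenotypeModelParams",
    "simulate_individuals",
    "simulate_sibling_cohort",
    "apply_shared_environment",
    "add_binary_phenotype",
    "genetic_score",
    "write_cohort",
    "read_cohort",
    "N_ANCESTRY_COVARIATES",
]

logger = logging.getLogger(__name__)

#: number of ancestry covariates emitted, mirroring "first 10 PCs" usage
N_ANCESTRY_COVARIATES = 10

#: SD of the pure-noise ancestry covariates when stratification is off
_DEFAULT_ANCESTRY_SD = 1.0


@dataclass(frozen=True)
class StratificationParams:
    """Two-subpopulation structure making ancestry a genuine confounder.

    Per-variant frequencies are ``f +/- freq_divergence * f(1-f)`` in the
    two subpopulations, clipped to (0.01, 0.99); the phenotype receives a
    fixed offset in subpopulation 1, so any variant whose frequency
    diverges acquires a spurious marginal association.
    """

    freq_divergence: float = 0.5
    subpop_phenotype_offset: float = 0.0
    ancestry_noise_sd: float = 0.1
    n_subpops: int = 2

    def validate(self) -> None:
        if self.n_subpops != 2:
            raise ValueError("stratification.n_subpops: only 2 subpopulations supported")
        if not 0.0 <= self.freq_divergence <= 1.0:
            raise ValueError(
                f"stratification.freq_divergence must be in [0, 1], got {self.freq_divergence}"
            )
        if not np.isfinite(self.subpop_phenotype_offset):
            raise ValueError("stratification.subpop_phenotype_offset must be finite")
        if not (np.isfinite(self.ancestry_noise_sd) and self.ancestry_noise_sd >= 0):
            raise ValueError("stratification.ancestry_noise_sd must be >= 0")


@dataclass(frozen=True)
class PhenotypeModelParams:
    """Parameters of the additive phenotype model and its genetic scores.

    ``assortment_weights`` maps cohort column names (``"E"``, ``"age"``,
    ``"pc1"``, ``"pheno_<name>"``...) to weights; the assortment score is
    the weighted sum of the standardised columns plus
    ``N(0, assortment_noise_sd^2)`` noise.
    """

    variant_count: int = 0
    allele_freqs: tuple = ()
    variant_effects: tuple = ()
    confounder_effect: float = 0.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    noise_sd: float = 1.0
    shared_env_sd: float = 0.0
    stratification: Optional[StratificationParams] = None
    phenotype_name: str = "y"
    age_range: tuple = (40.0, 70.0)
    assortment_weights: dict = field(default_factory=dict)
    assortment_noise_sd: float = 1.0

    def validate(self) -> None:
        if self.variant_count < 0:
            raise ValueError(f"variant_count must be >= 0, got {self.variant_count}")
        freqs = np.asarray(self.allele_freqs, dtype=float)
        effects = np.asarray(self.variant_effects, dtype=float)
        if freqs.size != self.variant_count:
            raise ValueError(
                f"allele_freqs length {freqs.size} != variant_count {self.variant_count}"
            )
        if effects.size != self.variant_count:
            raise ValueError(
                f"variant_effects length {effects.size} != variant_count {self.variant_count}"
            )
        if freqs.size and not np.all((freqs > 0.0) & (freqs < 1.0)):
            raise ValueError("allele_freqs must lie strictly in (0, 1)")
        if effects.size and not np.all(np.isfinite(effects)):
            raise ValueError("variant_effects must be finite")
        for name in ("confounder_effect", "age_effect", "sex_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("noise_sd", "shared_env_sd", "assortment_noise_sd"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0.0):
                raise ValueError(f"{name} must be a nonnegative real, got {value}")
        lo, hi = self.age_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"age_range must be an ordered finite pair, got {self.age_range}")
        for key, w in self.assortment_weights.items():
            if not np.isfinite(w):
                raise ValueError(f"assortment_weights[{key!r}] must be finite")
        if self.stratification is not None:
            self.stratification.validate()

    @property
    def phenotype_column(self) -> str:
        return f"pheno_{self.phenotype_name}"


def _ancestry_columns() -> list:
    return [f"pc{i}" for i in range(1, N_ANCESTRY_COVARIATES + 1)]


def _genotype_columns(m: int) -> list:
    return [f"g_{j}" for j in range(1, m + 1)]


def _subpop_freqs(params: PhenotypeModelParams) -> np.ndarray:
    """Per-subpopulation allele frequencies, shape (2, m)."""
    f = np.asarray(params.allele_freqs, dtype=float)
    strat = params.stratification
    shift = strat.freq_divergence * f * (1.0 - f)
    # subpopulation 1 (the one receiving the phenotype offset) gets the
    # higher frequencies, so a positive offset confounds upward
    return np.clip(np.vstack([f - shift, f + shift]), 0.01, 0.99)


def _draw_ancestry(
    rng: np.random.Generator, n: int, subpop: Optional[np.ndarray], noise_sd: float
) -> np.ndarray:
    pcs = rng.normal(0.0, noise_sd, size=(n, N_ANCESTRY_COVARIATES))
    if subpop is not None:
        # centred one-hot membership indicator on pc1; pc2..pc10 pure noise
        pcs[:, 0] += subpop - 0.5
    return pcs


def _assemble_phenotype(
    params: PhenotypeModelParams,
    rng: np.random.Generator,
    dosages: np.ndarray,
    E: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    subpop: Optional[np.ndarray],
    extra: Optional[np.ndarray] = None,
) -> np.ndarray:
    n = E.shape[0]
    effects = np.asarray(params.variant_effects, dtype=float)
    G = dosages @ effects if effects.size else np.zeros(n)
    P = (
        G
        + params.confounder_effect * E
        + params.age_effect * age
        + params.sex_effect * sex
        + rng.normal(0.0, params.noise_sd, n)
    )
    if subpop is not None and params.stratification is not None:
        P = P + params.stratification.subpop_phenotype_offset * subpop
    if extra is not None:
        P = P + extra
    return P


def _assortment_score(
    params: PhenotypeModelParams, rng: np.random.Generator, frame: pd.DataFrame
) -> np.ndarray:
    n = len(frame)
    A = rng.normal(0.0, params.assortment_noise_sd, n)
    for key, w in params.assortment_weights.items():
        col = f"pheno_{key}" if key not in frame.columns and f"pheno_{key}" in frame.columns else key
        if col not in frame.columns:
            raise ValueError(f"assortment_weights refers to unknown column {key!r}")
        values = frame[col].to_numpy(dtype=float)
        sd = values.std()
        if sd > 0:
            values = (values - values.mean()) / sd
        A = A + w * values
    return A


def _finalise(frame: pd.DataFrame, params: PhenotypeModelParams, rng: np.random.Generator) -> pd.DataFrame:
    frame["A"] = _assortment_score(params, rng, frame)
    ordered = (
        ["id", "sex", "age", "family_id", "E", "A"]
        + _ancestry_columns()
        + [c for c in frame.columns if c.startswith("pheno_")]
        + [c for c in frame.columns if c.startswith("g_")]
    )
    return frame[ordered].reset_index(drop=True)


def simulate_individuals(
    params: PhenotypeModelParams, n_per_sex: int, seed: SimulationSeed
) -> pd.DataFrame:
    """Draw ``2 * n_per_sex`` unrelated individuals from the population model.

    Dosages are sums of two Bernoulli(allele frequency) draws, so they take
    exact values in {0, 1, 2}; with stratification enabled each individual's
    frequencies come from their (equiprobable) subpopulation.
    """
    params.validate()
    if n_per_sex < 1:
        raise ValueError(f"n_per_sex must be >= 1, got {n_per_sex}")
    rng = seed.rng()
    n = 2 * n_per_sex
    m = params.variant_count

    sex = np.concatenate([np.ones(n_per_sex, dtype=int), np.zeros(n_per_sex, dtype=int)])
    age = rng.uniform(params.age_range[0], params.age_range[1], n)
    E = rng.standard_normal(n)

    subpop = None
    if params.stratification is not None:
        subpop = rng.integers(0, 2, n)
        p = _subpop_freqs(params)[subpop, :]  # (n, m)
    else:
        p = np.broadcast_to(np.asarray(params.allele_freqs, dtype=float), (n, m))
    dosages = rng.binomial(2, p) if m else np.zeros((n, 0), dtype=int)

    pcs = _draw_ancestry(
        rng,
        n,
        subpop,
        params.stratification.ancestry_noise_sd
        if params.stratification is not None
        else _DEFAULT_ANCESTRY_SD,
    )
    P = _assemble_phenotype(params, rng, dosages, E, age, sex, subpop)

    frame = pd.DataFrame({"id": [f"I{i:06d}" for i in range(n)], "sex": sex, "age": age})
    frame["family_id"] = pd.array([pd.NA] * n, dtype="string")
    frame["E"] = E
    for i, col in enumerate(_ancestry_columns()):
        frame[col] = pcs[:, i]
    frame[params.phenotype_column] = P
    for j, col in enumerate(_genotype_columns(m)):
        frame[col] = dosages[:, j]
    return _finalise(frame, params, rng)


def simulate_sibling_cohort(
    params: PhenotypeModelParams, n_families: int, seed: SimulationSeed
) -> tuple:
    """Families of two full siblings via Mendelian segregation.

    For each family two parental genomes (pairs of alleles per variant) are
    drawn from the population model; each offspring independently inherits
    one allele per variant from each parent. Siblings share ``family_id``
    and a family-level environment component of SD ``shared_env_sd`` added
    to the phenotype.

    Returns ``(cohort, pair_table)``; ``n_families = 0`` yields empty
    tables, not an error.
    """
    params.validate()
    if n_families < 0:
        raise ValueError(f"n_families must be >= 0, got {n_families}")
    m = params.variant_count
    if n_families == 0:
        empty = pd.DataFrame(
            columns=["id", "sex", "age", "family_id", "E", "A"]
            + _ancestry_columns()
            + [params.phenotype_column]
            + _genotype_columns(m)
        )
        pairs = pd.DataFrame(columns=["index_id", "partner_id", "pair_type", "replicate"])
        return empty, pairs

    rng = seed.rng()
    subpop_fam = None
    if params.stratification is not None:
        subpop_fam = rng.integers(0, 2, n_families)
        p_fam = _subpop_freqs(params)[subpop_fam, :]  # (F, m)
    else:
        p_fam = np.broadcast_to(np.asarray(params.allele_freqs, dtype=float), (n_families, m))

    # parental genomes: (F, m, 2) alleles per parent
    father = rng.binomial(1, p_fam[:, :, None], size=(n_families, m, 2)) if m else None
    mother = rng.binomial(1, p_fam[:, :, None], size=(n_families, m, 2)) if m else None

    def _offspring_dosage() -> np.ndarray:
        if not m:
            return np.zeros((n_families, 0), dtype=int)
        pick_f = rng.integers(0, 2, size=(n_families, m, 1))
        pick_m = rng.integers(0, 2, size=(n_families, m, 1))
        a = np.take_along_axis(father, pick_f, axis=2)[:, :, 0]
        b = np.take_along_axis(mother, pick_m, axis=2)[:, :, 0]
        return a + b

    fam_env = rng.normal(0.0, params.shared_env_sd, n_families)
    rows = []
    sib_ids = []
    for k in range(2):
        dosages = _offspring_dosage()
        n = n_families
        sex = rng.integers(0, 2, n)
        age = rng.uniform(params.age_range[0], params.age_range[1], n)
        E = rng.standard_normal(n)
        pcs = _draw_ancestry(
            rng,
            n,
            subpop_fam,
            params.stratification.ancestry_noise_sd
            if params.stratification is not None
            else _DEFAULT_ANCESTRY_SD,
        )
        P = _assemble_phenotype(params, rng, dosages, E, age, sex, subpop_fam, extra=fam_env)
        ids = [f"F{i:06d}_S{k + 1}" for i in range(n)]
        sib_ids.append(ids)
        frame = pd.DataFrame({"id": ids, "sex": sex, "age": age})
        frame["family_id"] = pd.array([f"F{i:06d}" for i in range(n)], dtype="string")
        frame["E"] = E
        for i, col in enumerate(_ancestry_columns()):
            frame[col] = pcs[:, i]
        frame[params.phenotype_column] = P
        for j, col in enumerate(_genotype_columns(m)):
            frame[col] = dosages[:, j]
        rows.append(frame)

    cohort = pd.concat(rows, ignore_index=True)
    cohort = _finalise(cohort, params, rng)
    pairs = pd.DataFrame(
        {
            "index_id": sib_ids[0],
            "partner_id": sib_ids[1],
            "pair_type": "sibling",
            "replicate": pd.array([pd.NA] * n_families, dtype="Int64"),
        }
    )
    return cohort, pairs


def apply_shared_environment(
    cohort: pd.DataFrame,
    pairs: pd.DataFrame,
    shared_env_sd: float,
    target_phenotype: str,
    seed: SimulationSeed,
) -> pd.DataFrame:
    """Add one N(0, sd^2) draw identically to both members of each pair.

    Because the draw is common to the pair it cancels exactly from every
    within-pair difference — the shared-environment terms drop out of the
    difference model by construction. Unpaired individuals are unchanged.
    """
    if not (np.isfinite(shared_env_sd) and shared_env_sd >= 0):
        raise ValueError(f"shared_env_sd must be nonnegative, got {shared_env_sd}")
    col = target_phenotype if target_phenotype in cohort.columns else f"pheno_{target_phenotype}"
    if col not in cohort.columns:
        raise ValueError(f"target phenotype {target_phenotype!r} not found in cohort")
    known = set(cohort["id"])
    bad = pairs[
        ~pairs["index_id"].isin(known) | ~pairs["partner_id"].isin(known)
    ]
    if len(bad):
        raise ValueError(
            "pairs reference ids missing from cohort: "
            + ", ".join(f"({r.index_id}, {r.partner_id})" for r in bad.itertuples())
        )
    out = cohort.copy()
    if shared_env_sd == 0 or len(pairs) == 0:
        return out
    rng = seed.rng()
    draws = rng.normal(0.0, shared_env_sd, len(pairs))
    add = pd.Series(0.0, index=cohort["id"])
    add.loc[pairs["index_id"].to_numpy()] += draws
    add.loc[pairs["partner_id"].to_numpy()] += draws
    out[col] = out[col].to_numpy() + add.loc[out["id"]].to_numpy()
    return out


def add_binary_phenotype(
    cohort: pd.DataFrame, source: str, name: str, prevalence: float
) -> pd.DataFrame:
    """Dichotomise a continuous phenotype by a liability threshold.

    Cases are the top ``prevalence`` fraction of the source (liability)
    distribution; deterministic given the cohort.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    src = source if source in cohort.columns else f"pheno_{source}"
    if src not in cohort.columns:
        raise ValueError(f"source phenotype {source!r} not found in cohort")
    out = cohort.copy()
    liability = out[src].to_numpy(dtype=float)
    threshold = np.quantile(liability, 1.0 - prevalence)
    out[f"pheno_{name}"] = (liability > threshold).astype(int)
    return out


def genetic_score(cohort: pd.DataFrame, effects: Sequence[float]) -> np.ndarray:
    """Weighted sum of dosage columns g_1..g_m."""
    effects = np.asarray(effects, dtype=float)
    cols = _genotype_columns(effects.size)
    return cohort[cols].to_numpy(dtype=float) @ effects


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Tab-separated, UTF-8, LF line endings; missing family_id empty."""
    cohort.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="")


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "family_id" in frame.columns:
        frame["family_id"] = frame["family_id"].astype("string")
    return frame
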