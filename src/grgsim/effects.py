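"""Causal-effect simulation: site selection and effect-size distributions.

This is the first pipeline stage: choose ``M_causal`` polymorphic sites
uniformly at random, then draw one effect size per causal site per trait
from a built-in family (normal, exponential, fixed, gamma, Student-t) or
accept user-supplied effects.  In standardized mode the effects are drawn
from ``N(0, h^2 / M_causal)`` so the genetic variance on the standardized
scale targets the requested narrow-sense heritability directly.

Effect tables use the pipeline's schema: ``mutation_id``,
``causal_mutation_id`` and ``effect_size``, where ``causal_mutation_id`` is
the 0-based trait index grouping the rows of a multi-trait simulation.
Effect draws depend only on the causal id set — never on genotype values —
so swapping graphs with identical mutation ids yields identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import Grg, allele_frequencies

__all__ = [
    "DistributionSpec",
    "EffectTable",
    "SimConfig",
    "sample_causal_mutations",
    "draw_effects",
    "draw_effects_standardized",
    "load_custom_effects",
    "stage_rng",
]

_FAMILIES = ("normal", "exponential", "fixed", "gamma", "t")

# stage codes for deriving independent substreams from one root seed
_STAGE_CODES = {"causal": 1, "effects": 2, "noise": 3}


def stage_rng(seed: int, stage: str, trait_id: int = 0) -> np.random.Generator:
    """Independent random stream keyed by (root seed, stage, trait).

    Each pipeline stage and trait draws from its own substream, so adding a
    trait or re-running a later stage never perturbs earlier draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGE_CODES[stage], int(trait_id)])
    )


@dataclass(frozen=True)
class DistributionSpec:
    """Effect-size distribution for one or more traits.

    Family parameters: normal (mean, sd, optional covariance across traits),
    exponential (scale), fixed (value), gamma (shape, scale), t (df, mean,
    sd; location-scale Student-t).  Multivariate draws (row-wise over traits
    with ``covariance``) are supported for the normal family only; other
    families draw independently per trait.  ``negative_sign_prob`` randomly
    flips the sign of exponential/gamma draws (default 0: drawn as-is,
    positive).
    """

    family: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    scale: float = 1.0
    value: float = 1.0
    shape: float = 1.0
    df: float = 10.0
    num_traits: int = 1
    covariance: np.ndarray | None = None
    negative_sign_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if self.num_traits < 1:
            raise ValueError("num_traits must be >= 1")
        if self.family == "normal" and self.sd <= 0:
            raise ValueError("normal family requires sd > 0")
        if self.family == "exponential" and self.scale <= 0:
            raise ValueError("exponential family requires scale > 0")
        if self.family == "gamma" and (self.shape <= 0 or self.scale <= 0):
            raise ValueError("gamma family requires shape > 0 and scale > 0")
        if self.family == "t" and (self.df <= 0 or self.sd <= 0):
            raise ValueError("t family requires df > 0 and sd > 0")
        if not (0.0 <= self.negative_sign_prob <= 1.0):
            raise ValueError("negative_sign_prob must lie in [0, 1]")
        if self.covariance is not None:
            if self.family != "normal":
                raise ValueError(
                    "covariance is supported for the normal family only"
                )
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (self.num_traits, self.num_traits):
                raise ValueError(
                    f"covariance must be {self.num_traits}x{self.num_traits}, got {cov.shape}"
                )
            if not np.allclose(cov, cov.T):
                raise ValueError("covariance must be symmetric")
            eigvals = np.linalg.eigvalsh(cov)
            if eigvals.min() < -1e-10:
                raise ValueError("covariance must be positive semi-definite")
            object.__setattr__(self, "covariance", cov)
        if self.family == "t" and self.df <= 2:
            warnings.warn(
                f"t family with df={self.df} <= 2 has infinite variance",
                stacklevel=2,
            )


class EffectTable:
    """Per-(mutation, trait) causal effect sizes ``beta``.

    Wraps a dataframe with columns ``mutation_id``, ``causal_mutation_id``
    (the 0-based trait index) and ``effect_size``.  Every length-M beta
    vector is zero off the causal set.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        required = {"mutation_id", "causal_mutation_id", "effect_size"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"effect table missing columns {sorted(missing)}")
        df = df[["mutation_id", "causal_mutation_id", "effect_size"]].copy()
        df["mutation_id"] = df["mutation_id"].astype(int)
        df["causal_mutation_id"] = df["causal_mutation_id"].astype(int)
        df["effect_size"] = df["effect_size"].astype(float)
        if df.duplicated(["mutation_id", "causal_mutation_id"]).any():
            dup = df[df.duplicated(["mutation_id", "causal_mutation_id"])].iloc[0]
            raise ValueError(
                f"duplicate effect for mutation {int(dup.mutation_id)}, "
                f"trait {int(dup.causal_mutation_id)}"
            )
        if not np.isfinite(df["effect_size"]).all():
            raise ValueError("effect sizes must be finite")
        self.df = df.reset_index(drop=True)

    @property
    def trait_ids(self) -> list[int]:
        return sorted(self.df["causal_mutation_id"].unique())

    @property
    def num_traits(self) -> int:
        return len(self.trait_ids)

    def causal_ids(self, trait_id: int) -> np.ndarray:
        sub = self.df[self.df["causal_mutation_id"] == trait_id]
        return np.sort(sub["mutation_id"].to_numpy())

    def beta_vector(self, num_mutations: int, trait_id: int) -> np.ndarray:
        """Scatter this trait's effects into a dense length-M vector."""
        sub = self.df[self.df["causal_mutation_id"] == trait_id]
        ids = sub["mutation_id"].to_numpy()
        if ids.size and (ids.min() < 0 or ids.max() >= num_mutations):
            bad = ids[(ids < 0) | (ids >= num_mutations)][0]
            raise ValueError(f"effect refers to unknown mutation id {int(bad)}")
        beta = np.zeros(num_mutations)
        beta[ids] = sub["effect_size"].to_numpy()
        return beta

    def validate_against(self, grg: Grg) -> None:
        ids = self.df["mutation_id"].to_numpy()
        if ids.size and (ids.min() < 0 or ids.max() >= grg.num_mutations):
            bad = ids[(ids < 0) | (ids >= grg.num_mutations)][0]
            raise ValueError(
                f"effect refers to mutation id {int(bad)} absent from the graph"
            )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EffectTable) and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SimConfig:
    """All simulation knobs for the end-to-end pipeline.

    ``m_causal=None`` means every eligible (polymorphic) site is causal.
    ``standardized`` switches genetic values to the standardized genotype
    matrix and, when no distribution is given, draws effects from
    ``N(0, h^2 / M_causal)``.  ``prevalence`` turns the continuous phenotype
    into a binary case/control trait by liability thresholding and requires
    standardized mode.
    """

    m_causal: int | None = None
    heritability: float = 0.5
    standardized: bool = True
    distribution: DistributionSpec | None = None
    prevalence: float | None = None
    normalize: str | None = None  # None | "standard" | "quantile"
    normalize_target: str = "phenotype"  # "phenotype" | "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.heritability <= 1.0):
            raise ValueError(
                f"heritability must lie in (0, 1], got {self.heritability}"
            )
        if self.m_causal is not None and self.m_causal < 1:
            raise ValueError("m_causal must be >= 1")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ValueError(
                f"population prevalence must lie in (0, 1), got {self.prevalence}"
            )
        if self.prevalence is not None and not self.standardized:
            raise ValueError("binary traits require standardized mode")
        if self.normalize not in (None, "standard", "quantile"):
            raise ValueError(f"unknown normalization mode {self.normalize!r}")
        if self.normalize_target not in ("phenotype", "both"):
            raise ValueError(f"unknown normalize target {self.normalize_target!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sample_causal_mutations(
    grg: Grg, m_causal: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of causal sites among polymorphic mutations.

    Monomorphic sites (f in {0, 1}) are never eligible: they carry no
    genotypic variance and have an undefined standardized scale.  The
    returned ids are sorted ascending for determinism.
    """
    fv = allele_frequencies(grg)
    eligible = np.flatnonzero(fv.polymorphic)
    if m_causal > eligible.size:
        raise ValueError(
            f"m_causal={m_causal} exceeds the {eligible.size} eligible "
            "(polymorphic) sites"
        )
    chosen = rng.choice(eligible, size=m_causal, replace=False)
    return np.sort(chosen)


def draw_effects(
    spec: DistributionSpec,
    causal_ids: np.ndarray,
    rng: np.random.Generator,
) -> EffectTable:
    """Draw one effect per causal mutation per trait from the spec's family."""
    causal_ids = np.asarray(causal_ids, dtype=int)
    m = causal_ids.size
    t = spec.num_traits
    if spec.family == "normal" and spec.covariance is not None:
        mean = np.full(t, spec.mean)
        draws = rng.multivariate_normal(mean, spec.covariance, size=m)
    else:
        draws = np.empty((m, t))
        for trait in range(t):
            draws[:, trait] = _draw_univariate(spec, m, rng)
    records = []
    for trait in range(t):
        records.append(
            pd.DataFrame(
                {
                    "mutation_id": causal_ids,
                    "causal_mutation_id": trait,
                    "effect_size": draws[:, trait],
                }
            )
        )
    return EffectTable(pd.concat(records, ignore_index=True))


def _draw_univariate(
    spec: DistributionSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.family == "normal":
        return rng.normal(spec.mean, spec.sd, size=size)
    if spec.family == "fixed":
        return np.full(size, float(spec.value))
    if spec.family == "t":
        return spec.mean + spec.sd * rng.standard_t(spec.df, size=size)
    if spec.family == "exponential":
        draws = rng.exponential(spec.scale, size=size)
    else:  # gamma
        draws = rng.gamma(spec.shape, spec.scale, size=size)
    if spec.negative_sign_prob > 0.0:
        flips = rng.random(size) < spec.negative_sign_prob
        draws = np.where(flips, -draws, draws)
    return draws


def draw_effects_standardized(
    h2: float,
    causal_ids: np.ndarray,
    rng: np.random.Generator,
    num_traits: int = 1,
) -> EffectTable:
    """Standardized-mode effects: ``beta ~ N(0, h^2 / M_causal)`` iid.

    On the standardized genotype scale every column has unit variance, so
    this prior gives the genetic values an expected variance of ``h^2``.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"heritability must lie in (0, 1], got {h2}")
    causal_ids = np.asarray(causal_ids, dtype=int)
    if causal_ids.size < 1:
        raise ValueError("at least one causal mutation is required")
    sd = float(np.sqrt(h2 / causal_ids.size))
    spec = DistributionSpec(family="normal", mean=0.0, sd=sd, num_traits=num_traits)
    return draw_effects(spec, causal_ids, rng)


def load_custom_effects(
    table: pd.DataFrame | str | Path, grg: Grg | None = None
) -> EffectTable:
    """Validate user-supplied effects (dataframe or TSV path) into an EffectTable.

    The TSV needs columns ``mutation_id`` and ``effect_size``; an optional
    ``causal_mutation_id`` column assigns traits (default: trait 0).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    df = table.copy()
    if "causal_mutation_id" not in df.columns:
        df["causal_mutation_id"] = 0
    et = EffectTable(df)
    if grg is not None:
        et.validate_against(grg)
    return et
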