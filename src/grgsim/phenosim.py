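"""Phenotype simulation pipeline on genotype representation graphs.

Stages 2-4 of the simulator: genetic values via the graph dot product (raw
or standardized genotype scale), environmental noise calibrated to a target
narrow-sense heritability, phenotype assembly ``y = Xb + e``, optional
normalization, liability thresholding for binary traits, and additive
combination of genetic values across multiple graphs (chromosomes).

The model
---------
With ``X`` the N-by-M diploid genotype matrix (``X[i, j] = G[2i, j] +
G[2i+1, j]``), the continuous phenotype is ``y = X beta + e``.  In
standardized mode the genotype matrix is column-standardized, ``X~ = (X - U)
Sigma`` with ``U[:, i] = 2 f_i`` and ``Sigma = diag(1 / sigma_i)``,
``sigma_i = sqrt(2 f_i (1 - f_i))``; the product ``X~ beta`` is computed
without materializing ``X~`` as ``X (Sigma beta) - sum_i 2 f_i beta_i /
sigma_i`` (the subtraction is one scalar per trait since ``U Sigma beta`` is
constant over individuals).  Environmental noise is ``e ~ N(0, Var(X beta)
(1/h^2 - 1))`` with the sample variance (denominator N-1) of the simulated
genetic values, so the realized heritability targets ``h^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from . import io as grg_io
from .effects import (
    DistributionSpec,
    EffectTable,
    SimConfig,
    _draw_univariate,
    draw_effects,
    draw_effects_standardized,
    sample_causal_mutations,
    stage_rng,
)
from .graph import Grg, allele_frequencies, dot_product_down

__all__ = [
    "GeneticValueTable",
    "PhenotypeTable",
    "genetic_values",
    "genetic_values_standardized",
    "environmental_noise",
    "assemble_phenotypes",
    "normalize",
    "binarize",
    "combine_genetic_values",
    "sim_phenotypes",
]


@dataclass
class GeneticValueTable:
    """Genetic values at the haploid-sample and the individual level.

    ``samples`` has columns (sample_node_id, causal_mutation_id,
    genetic_value); ``individuals`` has (individual_id, causal_mutation_id,
    genetic_value), where ``causal_mutation_id`` is the trait index.  In raw
    mode an individual's value is exactly the sum of its two sample values;
    in standardized mode the per-trait centering constant is subtracted at
    the individual level only.
    """

    samples: pd.DataFrame
    individuals: pd.DataFrame

    @property
    def trait_ids(self) -> list[int]:
        return sorted(self.individuals["causal_mutation_id"].unique())

    def individual_values(self, trait_id: int) -> np.ndarray:
        sub = self.individuals[self.individuals["causal_mutation_id"] == trait_id]
        return sub["genetic_value"].to_numpy()

    def individual_id_sequence(self) -> list:
        first = self.trait_ids[0]
        sub = self.individuals[self.individuals["causal_mutation_id"] == first]
        return sub["individual_id"].tolist()


@dataclass
class PhenotypeTable:
    """Final per-individual table: genetic value, noise, phenotype.

    Columns: individual_id, causal_mutation_id (trait index), genetic_value,
    environmental_noise, phenotype, plus normalized_phenotype (and
    normalized_genetic_value) after quantile normalization.  Before any
    normalization or binarization, phenotype = genetic_value +
    environmental_noise exactly.
    """

    df: pd.DataFrame

    @property
    def trait_ids(self) -> list[int]:
        return sorted(self.df["causal_mutation_id"].unique())

    def trait(self, trait_id: int) -> pd.DataFrame:
        return self.df[self.df["causal_mutation_id"] == trait_id]

    def realized_heritability(self, trait_id: int = 0) -> float:
        """Sample-variance ratio Var(genetic) / Var(phenotype) for one trait."""
        sub = self.trait(trait_id)
        return float(
            np.var(sub["genetic_value"], ddof=1) / np.var(sub["phenotype"], ddof=1)
        )


# ---------------------------------------------------------------------------
# stage 2: genetic values
# ---------------------------------------------------------------------------


def _tables_from_haploid(
    grg: Grg, per_trait_hap: dict[int, np.ndarray], offsets: dict[int, float]
) -> GeneticValueTable:
    two_n = grg.num_haploid_samples
    sample_frames, indiv_frames = [], []
    for trait, hap in per_trait_hap.items():
        sample_frames.append(
            pd.DataFrame(
                {
                    "sample_node_id": np.arange(two_n),
                    "causal_mutation_id": trait,
                    "genetic_value": hap,
                }
            )
        )
        indiv = hap[0::2] + hap[1::2] - offsets.get(trait, 0.0)
        indiv_frames.append(
            pd.DataFrame(
                {
                    "individual_id": grg.individual_ids,
                    "causal_mutation_id": trait,
                    "genetic_value": indiv,
                }
            )
        )
    return GeneticValueTable(
        pd.concat(sample_frames, ignore_index=True),
        pd.concat(indiv_frames, ignore_index=True),
    )


def genetic_values(grg: Grg, effects: EffectTable) -> GeneticValueTable:
    """Raw-scale genetic values ``X beta`` via one downward dot product per trait.

    Haploid values are ``G beta``; individual ``i``'s value is the sum over
    its two haploid samples ``2i`` and ``2i + 1``.
    """
    effects.validate_against(grg)
    per_trait = {
        trait: dot_product_down(grg, effects.beta_vector(grg.num_mutations, trait))
        for trait in effects.trait_ids
    }
    return _tables_from_haploid(grg, per_trait, {})


def genetic_values_standardized(grg: Grg, effects: EffectTable) -> GeneticValueTable:
    """Standardized-scale genetic values ``(X - U) Sigma beta``.

    Computed as ``X (Sigma beta)`` via the graph minus the scalar
    ``sum_i 2 f_i beta_i / sigma_i`` per trait.  Every causal site must be
    polymorphic (``sigma_i > 0``); the resulting values have mean zero over
    individuals by construction.
    """
    effects.validate_against(grg)
    fv = allele_frequencies(grg)
    sigmas = fv.sigmas
    per_trait: dict[int, np.ndarray] = {}
    offsets: dict[int, float] = {}
    for trait in effects.trait_ids:
        beta = effects.beta_vector(grg.num_mutations, trait)
        causal = np.flatnonzero(beta)
        mono = causal[sigmas[causal] == 0.0]
        if mono.size:
            raise ValueError(
                f"causal mutation {int(mono[0])} is monomorphic "
                f"(f={fv.frequencies[int(mono[0])]}); standardized scale undefined"
            )
        w = np.zeros_like(beta)
        w[causal] = beta[causal] / sigmas[causal]
        per_trait[trait] = dot_product_down(grg, w)
        offsets[trait] = float(np.sum(2.0 * fv.frequencies[causal] * w[causal]))
    return _tables_from_haploid(grg, per_trait, offsets)


# ---------------------------------------------------------------------------
# stage 3: environmental noise
# ---------------------------------------------------------------------------


def environmental_noise(
    gvalues: GeneticValueTable,
    h2: float | None = None,
    noise_spec: DistributionSpec | None = None,
    rng: np.random.Generator | Mapping[int, np.random.Generator] | None = None,
) -> pd.DataFrame:
    """Per-individual environmental noise, one independent draw per trait.

    With a heritability, ``e ~ N(0, V (1/h^2 - 1))`` where ``V`` is the
    sample variance (denominator N-1) of that trait's individual genetic
    values; ``h2 = 1`` gives exactly zero noise.  Alternatively a
    user-defined distribution draws iid noise directly.  ``rng`` may be a
    single generator or a per-trait mapping.
    """
    if (h2 is None) == (noise_spec is None):
        raise ValueError("provide exactly one of h2 or noise_spec")
    if h2 is not None and not (0.0 < h2 <= 1.0):
        raise ValueError(f"heritability must lie in (0, 1], got {h2}")
    frames = []
    for trait in gvalues.trait_ids:
        sub = gvalues.individuals[gvalues.individuals["causal_mutation_id"] == trait]
        g = sub["genetic_value"].to_numpy()
        n = g.size
        rng_t = rng[trait] if isinstance(rng, Mapping) else rng
        if rng_t is None:
            rng_t = np.random.default_rng()
        if h2 is not None:
            if h2 == 1.0:
                eps = np.zeros(n)
            else:
                v = float(np.var(g, ddof=1)) if n > 1 else 0.0
                if v == 0.0:
                    raise ValueError(
                        f"trait {trait}: genetic values are degenerate (variance 0); "
                        "noise scaling for h2 < 1 is undefined"
                    )
                eps = rng_t.normal(0.0, np.sqrt(v * (1.0 / h2 - 1.0)), size=n)
        else:
            eps = _draw_univariate(noise_spec, n, rng_t)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": sub["individual_id"].to_numpy(),
                    "causal_mutation_id": trait,
                    "environmental_noise": eps,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def assemble_phenotypes(
    gvalues: GeneticValueTable, noise: pd.DataFrame
) -> PhenotypeTable:
    """Combine genetic values and noise into ``phenotype = genetic + noise``."""
    merged = gvalues.individuals.merge(
        noise, on=["individual_id", "causal_mutation_id"], validate="one_to_one"
    )
    merged["phenotype"] = merged["genetic_value"] + merged["environmental_noise"]
    return PhenotypeTable(merged)


# ---------------------------------------------------------------------------
# stage 4: normalization and binarization
# ---------------------------------------------------------------------------


def _standard_normalize(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        raise ValueError("cannot normalize an empty table")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("standard deviation is zero; normalization undefined")
    return (x - float(np.mean(x))) / sd


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        raise ValueError("cannot normalize an empty table")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 0.5) / x.size)


def normalize(
    pheno: PhenotypeTable, mode: str = "standard", target: str = "phenotype"
) -> PhenotypeTable:
    """Normalize phenotypes (and optionally genetic values), per trait.

    ``standard`` rescales in place to mean 0 / sd 1 (denominator N-1).
    ``quantile`` is a rank-based inverse-normal transform, ``Phi^{-1}((r -
    0.5) / N)`` with average ranks for ties; it appends
    ``normalized_phenotype`` (and ``normalized_genetic_value`` when target is
    ``both``) and preserves the raw columns.  Both modes preserve ranks.
    """
    if mode not in ("standard", "quantile"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if target not in ("phenotype", "both"):
        raise ValueError(f"unknown normalization target {target!r}")
    df = pheno.df.copy()
    cols = ["phenotype"] if target == "phenotype" else ["phenotype", "genetic_value"]
    for trait in pheno.trait_ids:
        mask = df["causal_mutation_id"] == trait
        for col in cols:
            x = df.loc[mask, col].to_numpy(dtype=float)
            if mode == "standard":
                df.loc[mask, col] = _standard_normalize(x)
            else:
                df.loc[mask, f"normalized_{col}"] = _quantile_normalize(x)
    return PhenotypeTable(df)


def binarize(pheno: PhenotypeTable, prevalence: float) -> PhenotypeTable:
    """Liability-threshold conversion to a binary case/control trait.

    The continuous phenotype is standard-normalized, then individuals whose
    liability exceeds the theoretical Gaussian quantile ``Phi^{-1}(1 - K)``
    become cases (1), everyone else controls (0); the phenotype column is
    overwritten.  ``K`` is the population prevalence.  Already-binary input
    is rejected.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"population prevalence must lie in (0, 1), got {prevalence}")
    df = pheno.df.copy()
    threshold = ndtri(1.0 - prevalence)
    for trait in pheno.trait_ids:
        mask = df["causal_mutation_id"] == trait
        x = df.loc[mask, "phenotype"].to_numpy(dtype=float)
        if x.size > 1 and set(np.unique(x)) <= {0.0, 1.0}:
            raise ValueError(
                f"trait {trait}: phenotype is already binary; refusing to re-threshold"
            )
        liability = _standard_normalize(x)
        df.loc[mask, "phenotype"] = (liability > threshold).astype(float)
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# multi-graph combination
# ---------------------------------------------------------------------------


def combine_genetic_values(tables: Sequence[GeneticValueTable]) -> GeneticValueTable:
    """Sum genetic values across graphs (additive across chromosomes).

    All tables must cover identical individual id sequences and trait sets;
    sample-level values are summed too when the sample id sequences agree.
    """
    if not tables:
        raise ValueError("no genetic value tables to combine")
    first = tables[0]
    ref_ids = first.individual_id_sequence()
    ref_traits = first.trait_ids
    for k, tab in enumerate(tables[1:], start=1):
        if tab.trait_ids != ref_traits:
            raise ValueError(
                f"table {k}: trait set {tab.trait_ids} != {ref_traits}"
            )
        ids = tab.individual_id_sequence()
        if ids != ref_ids:
            n = min(len(ids), len(ref_ids))
            for j in range(n):
                if ids[j] != ref_ids[j]:
                    raise ValueError(
                        f"table {k}: individual order mismatch at position {j}: "
                        f"{ids[j]!r} != {ref_ids[j]!r}"
                    )
            raise ValueError(
                f"table {k}: {len(ids)} individuals != {len(ref_ids)}"
            )
    indiv = first.individuals.copy()
    samples = first.samples.copy()
    for tab in tables[1:]:
        indiv["genetic_value"] = (
            indiv["genetic_value"].to_numpy() + tab.individuals["genetic_value"].to_numpy()
        )
        if len(tab.samples) == len(samples):
            samples["genetic_value"] = (
                samples["genetic_value"].to_numpy()
                + tab.samples["genetic_value"].to_numpy()
            )
    return GeneticValueTable(samples, indiv)


# ---------------------------------------------------------------------------
# end-to-end wrapper
# ---------------------------------------------------------------------------


def sim_phenotypes(
    grg: Grg | Sequence[Grg],
    config: SimConfig | None = None,
    output_prefix: str | None = None,
    **kwargs,
) -> PhenotypeTable:
    """End-to-end simulation: causal sampling -> effects -> genetic values ->
    [combine] -> noise -> phenotypes -> [normalize] -> [binarize].

    Accepts either a :class:`SimConfig` or its fields as keyword arguments,
    so ``sim_phenotypes(grg, heritability=0.3)`` runs a standardized
    simulation with every polymorphic site causal.  With several graphs
    (e.g. one per chromosome; identical individual orders required) causal
    sites are sampled from the pooled eligible sites and genetic values are
    combined additively before noise.  ``output_prefix`` additionally writes
    the stage tables (TSV) and the final ``.par``/``.phen`` files.
    """
    if config is None:
        config = SimConfig(**kwargs)
    elif kwargs:
        raise ValueError("pass either a SimConfig or keyword arguments, not both")
    grgs: list[Grg] = [grg] if isinstance(grg, Grg) else list(grg)
    if not grgs:
        raise ValueError("at least one graph is required")

    # stage 1: pooled causal sampling and effect draws
    freqs = [allele_frequencies(g) for g in grgs]
    eligible = [
        (gi, int(m)) for gi, fv in enumerate(freqs) for m in np.flatnonzero(fv.polymorphic)
    ]
    m_causal = config.m_causal if config.m_causal is not None else len(eligible)
    if m_causal > len(eligible):
        raise ValueError(
            f"causal sampling failed: m_causal={m_causal} exceeds the "
            f"{len(eligible)} eligible (polymorphic) sites"
        )
    rng_causal = stage_rng(config.seed, "causal")
    idx = np.sort(rng_causal.choice(len(eligible), size=m_causal, replace=False))
    pooled_causal = [eligible[i] for i in idx]

    num_traits = config.distribution.num_traits if config.distribution else 1
    rng_eff = stage_rng(config.seed, "effects")
    if config.distribution is not None:
        pooled_effects = draw_effects(
            config.distribution, np.arange(m_causal), rng_eff
        )
    else:
        if not config.standardized:
            raise ValueError(
                "raw mode requires an explicit effect-size distribution"
            )
        pooled_effects = draw_effects_standardized(
            config.heritability, np.arange(m_causal), rng_eff, num_traits=num_traits
        )
    # split pooled rows back into per-graph effect tables
    per_graph_effects: list[EffectTable | None] = []
    pdf = pooled_effects.df
    for gi in range(len(grgs)):
        rows = [k for k, (g, _m) in enumerate(pooled_causal) if g == gi]
        if not rows:
            per_graph_effects.append(None)
            continue
        sub = pdf[pdf["mutation_id"].isin(rows)].copy()
        sub["mutation_id"] = sub["mutation_id"].map(
            {k: pooled_causal[k][1] for k in rows}
        )
        per_graph_effects.append(EffectTable(sub))

    # stage 2: genetic values per graph, then combine
    compute = genetic_values_standardized if config.standardized else genetic_values
    gtables = [
        compute(g, eff)
        for g, eff in zip(grgs, per_graph_effects)
        if eff is not None
    ]
    gvalues = combine_genetic_values(gtables)

    # stage 3: noise and phenotype assembly
    noise_rngs = {
        trait: stage_rng(config.seed, "noise", trait) for trait in gvalues.trait_ids
    }
    noise = environmental_noise(gvalues, h2=config.heritability, rng=noise_rngs)
    pheno = assemble_phenotypes(gvalues, noise)

    # stage 4: optional normalization and binarization
    if config.normalize is not None:
        pheno = normalize(pheno, mode=config.normalize, target=config.normalize_target)
    if config.prevalence is not None:
        pheno = binarize(pheno, config.prevalence)

    if output_prefix is not None:
        _write_outputs(
            output_prefix, grgs, freqs, per_graph_effects, gvalues, pheno
        )
    return pheno


def _write_outputs(prefix, grgs, freqs, per_graph_effects, gvalues, pheno) -> None:
    """Write stage TSVs plus GCTA .par (per graph x trait) and .phen (per trait)."""
    eff_frames = [e.df for e in per_graph_effects if e is not None]
    grg_io.write_table(pd.concat(eff_frames, ignore_index=True), f"{prefix}.effects.tsv")
    grg_io.write_table(gvalues.samples, f"{prefix}.genetic_values.samples.tsv")
    grg_io.write_table(gvalues.individuals, f"{prefix}.genetic_values.individuals.tsv")
    grg_io.write_table(pheno.df, f"{prefix}.phenotypes.tsv")
    traits = pheno.trait_ids
    multi_graph = len(grgs) > 1
    for gi, (g, fv, eff) in enumerate(zip(grgs, freqs, per_graph_effects)):
        if eff is None:
            continue
        gtag = f".chr{gi}" if multi_graph else ""
        for trait in traits:
            ttag = f".trait{trait}" if len(traits) > 1 else ""
            grg_io.write_par(
                eff, g.mutations, fv, f"{prefix}{gtag}{ttag}.par", trait_id=trait
            )
    for trait in traits:
        ttag = f".trait{trait}" if len(traits) > 1 else ""
        grg_io.write_phen(pheno, f"{prefix}{ttag}.phen", trait_id=trait)
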