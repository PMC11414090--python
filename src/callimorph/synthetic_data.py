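"""Synthetic trait tables and sequence alignments with known ground truth.

Parental individuals are drawn from a multivariate normal with declared
per-trait means/SDs and an exchangeable between-trait correlation. Hybrid
group means follow a chosen regime relative to the parental means:

* additive       -> mid-parent value
* heterotic      -> MPV + effect_size * pooled SD
* dysgenetic     -> MPV - effect_size * pooled SD
* transgressive  -> max(parental means) + effect_size * pooled SD
* parent1_like / parent2_like -> that parent's mean

Sequence alignments are evolved site-independently under the TN93 model on
a star tree, so expected between-group distance is the sum of the two
branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .genetic_distance import (
    BASES,
    GroupedAlignment,
    SubstitutionModelParams,
    tn93_transition_matrix,
)
from .hybrid_classification import mid_parent_value
from .reference_data import DEFAULT_PLAN, GROUP_SIZES, HYBRID_SUMMARIES, PARENT_SUMMARIES
from .schema import BILATERAL_TRAITS, TRAIT_NAMES, UNILATERAL_TRAITS
from .trait_io import MISSING, TraitRecord, TraitTable

REGIMES = (
    "additive",
    "heterotic",
    "dysgenetic",
    "transgressive",
    "parent1_like",
    "parent2_like",
)


@dataclass(frozen=True)
class HybridSpec:
    parents: tuple[str, str]
    regime: str = "additive"
    effect_size: float = 1.0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")


@dataclass
class SyntheticScenario:
    """Generative parameters for a trait-table simulation."""

    parental_specs: Mapping[str, Mapping[str, tuple[float, float]]]
    hybrid_specs: Mapping[str, HybridSpec] = field(default_factory=dict)
    group_sizes: Mapping[str, int] = field(default_factory=dict)
    missing_rate: float = 0.0
    trait_correlation: float = 0.5
    adult_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        p = len(TRAIT_NAMES)
        if not (-1.0 / (p - 1) < self.trait_correlation < 1.0):
            raise ValidationError("trait_correlation yields an invalid correlation matrix")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValidationError(f"group size for {g} must be >= 2")


@dataclass
class SyntheticTraits:
    """Generated table plus the bookkeeping needed to use it as an oracle."""

    table: TraitTable
    true_means: dict[str, dict[str, float]]
    regimes: dict[str, str]
    adult_counts: dict[str, int]


def default_scenario(seed: int = 0, missing_rate: float = 0.0) -> SyntheticScenario:
    """Study-scale scenario: published species means/SDs, published group
    sizes (209 individuals over 8 taxa), additive hybrids by default."""
    parental = {
        taxon: {t: (mean, sd) for t, (_, mean, sd) in traits.items()}
        for taxon, traits in PARENT_SUMMARIES.items()
    }
    # hybrid groups keep their published trait dispersion
    hybrid_sds = {
        taxon: {t: sd for t, (_, _, sd) in traits.items()}
        for taxon, traits in HYBRID_SUMMARIES.items()
    }
    hybrids = {
        "PJ": HybridSpec(parents=("J", "P")),
        "PG": HybridSpec(parents=("G", "P")),
        "AH": HybridSpec(parents=("A", "J")),
        "CC": HybridSpec(parents=("G", "P")),
    }
    scenario = SyntheticScenario(
        parental_specs=parental,
        hybrid_specs=hybrids,
        group_sizes=dict(GROUP_SIZES),
        missing_rate=missing_rate,
        seed=seed,
    )
    scenario._hybrid_sds = hybrid_sds  # type: ignore[attr-defined]
    return scenario


def _exchangeable_cov(sds: np.ndarray, rho: float) -> np.ndarray:
    p = len(sds)
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sds, sds)


def _hybrid_mean(spec: HybridSpec, m1: float, m2: float, s1: float, s2: float) -> float:
    mpv = mid_parent_value(m1, m2)
    pooled = 0.5 * (s1 + s2)
    if spec.regime == "additive":
        return mpv
    if spec.regime == "heterotic":
        return mpv + spec.effect_size * pooled
    if spec.regime == "dysgenetic":
        return mpv - spec.effect_size * pooled
    if spec.regime == "transgressive":
        return max(m1, m2) + spec.effect_size * pooled
    if spec.regime == "parent1_like":
        return m1
    return m2


def generate_traits(scenario: SyntheticScenario) -> SyntheticTraits:
    """Draw a reproducible trait table under the scenario."""
    rng = np.random.default_rng(scenario.seed)
    hybrid_sds = getattr(scenario, "_hybrid_sds", {})

    true_means: dict[str, dict[str, float]] = {}
    group_sds: dict[str, dict[str, float]] = {}
    for taxon, spec in scenario.parental_specs.items():
        true_means[taxon] = {t: spec[t][0] for t in TRAIT_NAMES}
        group_sds[taxon] = {t: spec[t][1] for t in TRAIT_NAMES}
    for taxon, hspec in scenario.hybrid_specs.items():
        p1, p2 = hspec.parents
        means, sds = {}, {}
        for t in TRAIT_NAMES:
            m1, s1 = scenario.parental_specs[p1][t]
            m2, s2 = scenario.parental_specs[p2][t]
            means[t] = _hybrid_mean(hspec, m1, m2, s1, s2)
            sds[t] = hybrid_sds.get(taxon, {}).get(t, 0.5 * (s1 + s2))
        true_means[taxon] = means
        group_sds[taxon] = sds

    records: list[TraitRecord] = []
    adult_counts: dict[str, int] = {}
    idx = 0
    for taxon in scenario.group_sizes:
        if taxon not in true_means:
            raise ValidationError(f"no spec for group {taxon!r}")
        n = scenario.group_sizes[taxon]
        mu = np.array([true_means[taxon][t] for t in TRAIT_NAMES])
        sds = np.array([group_sds[taxon][t] for t in TRAIT_NAMES])
        cov = _exchangeable_cov(sds, scenario.trait_correlation)
        draws = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
        draws = np.abs(draws)  # trait measurements are strictly positive
        n_adult = 0
        for row in draws:
            vals = dict(zip(TRAIT_NAMES, row))
            is_adult = rng.random() < scenario.adult_fraction
            n_adult += is_adult
            uni = {}
            for t in UNILATERAL_TRAITS:
                if t == "WEIGHT":
                    continue
                v = vals[t]
                uni[t] = MISSING if rng.random() < scenario.missing_rate else v
            bi = {}
            for t in BILATERAL_TRAITS:
                v = vals[t]
                jitter = 0.01 * v * rng.standard_normal()
                left, right = v + jitter, v - jitter
                if rng.random() < scenario.missing_rate:
                    left = MISSING
                if rng.random() < scenario.missing_rate:
                    right = MISSING
                bi[t] = (left, right)
            weight = vals["WEIGHT"]
            if rng.random() < scenario.missing_rate:
                weight = MISSING
            records.append(
                TraitRecord(
                    individual_id=f"SYN{idx:04d}",
                    taxon=taxon,
                    sex="F" if rng.random() < 0.5 else "M",
                    age_class="adult" if is_adult else "juvenile",
                    site="synthetic",
                    weight_g=weight,
                    unilateral_traits=uni,
                    bilateral_traits=bi,
                )
            )
            idx += 1
        adult_counts[taxon] = int(n_adult)

    table = TraitTable(
        records=records,
        provenance={"source": "synthetic", "seed": scenario.seed, "row_count": len(records)},
    )
    regimes = {h: s.regime for h, s in scenario.hybrid_specs.items()}
    return SyntheticTraits(
        table=table, true_means=true_means, regimes=regimes, adult_counts=adult_counts
    )


def default_plan() -> dict[str, list[tuple[str, str]]]:
    return {h: list(pairs) for h, pairs in DEFAULT_PLAN.items()}


# ---------------------------------------------------------------------------
# sequences


def generate_sequences(
    branch_lengths: Mapping[str, float],
    params: SubstitutionModelParams,
    length: int,
    n_per_group: int = 1,
    seed: int = 0,
) -> tuple[GroupedAlignment, dict[tuple[str, str], float]]:
    """Evolve sequences on a star tree under TN93.

    Each sequence descends independently from the shared root along its
    group's branch, so the expected distance between groups g and h is
    ``branch_lengths[g] + branch_lengths[h]``. Returns the alignment plus
    the true between-group distances as bookkeeping.
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    if any(b < 0 for b in branch_lengths.values()):
        raise ValidationError("branch lengths must be >= 0")
    rng = np.random.default_rng(seed)
    pi = np.asarray(params.base_freqs)
    root = rng.choice(4, size=length, p=pi)

    sequences: dict[str, str] = {}
    groups: dict[str, str] = {}
    for group in sorted(branch_lengths):
        P = tn93_transition_matrix(params, branch_lengths[group])
        # row-normalize against clipping drift
        P = P / P.sum(axis=1, keepdims=True)
        cum = np.cumsum(P, axis=1)
        for rep in range(n_per_group):
            u = rng.random(length)
            child = (u[:, None] > cum[root]).sum(axis=1)
            seq_id = f"{group}_{rep}"
            sequences[seq_id] = "".join(BASES[b] for b in child)
            groups[seq_id] = group
    truth = {
        (g, h): branch_lengths[g] + branch_lengths[h]
        for i, g in enumerate(sorted(branch_lengths))
        for h in sorted(branch_lengths)[i + 1:]
    }
    return GroupedAlignment(sequences=sequences, groups=groups), truth
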