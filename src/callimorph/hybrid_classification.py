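"""Mid-parent-value classification of hybrid traits.

Each (hybrid group, parental pair, trait) cell is labelled transgressive,
heterotic, dysgenetic, intermediate, parental-like, or outside-range
nonsignificant, from a one-sample t-test of the hybrid mean against the
mid-parent value and Welch t-tests against each parent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ValidationError
from .schema import TRAIT_NAMES, significance_code
from .stats_core import GroupSummary, one_sample_t, summarize, welch_t

__all__ = [
    "ParentalPair",
    "ClassificationResult",
    "mid_parent_value",
    "classify_trait",
    "classify_all",
    "summary_mode_classify",
    "results_to_frame",
    "results_to_wide",
]

LABELS = (
    "heterotic",
    "dysgenetic",
    "transgressive",
    "intermediate",
    "parent1_like",
    "parent2_like",
    "above_both_ns",
    "below_both_ns",
)


@dataclass(frozen=True)
class ParentalPair:
    """Unordered pair of putative parental taxa; label canonical alphabetical."""

    parent1: str
    parent2: str

    def __post_init__(self):
        if self.parent1 == self.parent2:
            raise ValidationError("parental pair must name two distinct taxa")

    @property
    def label(self) -> str:
        return "_".join(sorted((self.parent1, self.parent2)))


@dataclass(frozen=True)
class ClassificationResult:
    hybrid_group: str
    pair: ParentalPair
    trait: str
    label: str
    mpv: float
    hybrid_n: int
    hybrid_mean: float
    hybrid_sd: float
    p_mpv: float
    p_vs_parent1: float
    p_vs_parent2: float
    direction: int  # sign of (hybrid mean - mpv)


def mid_parent_value(mean1: float, mean2: float) -> float:
    """Half the sum of the two parental means (symmetric)."""
    if not (math.isfinite(mean1) and math.isfinite(mean2)):
        raise ValueError("parental means must be finite")
    return 0.5 * (mean1 + mean2)


def classify_trait(
    hybrid: GroupSummary,
    parent1: GroupSummary,
    parent2: GroupSummary,
    alpha: float = 0.05,
    low_transgression: bool = False,
) -> ClassificationResult:
    """Label one hybrid trait relative to a parental pair.

    Decision order:

    1. transgressive — hybrid mean above both parental means and both
       hybrid-vs-parent Welch tests significant (with ``low_transgression``,
       symmetrically below both as well);
    2. heterotic / dysgenetic — MPV t-test significant, hybrid mean
       above / below the MPV;
    3. otherwise, by position: strictly inside the parental range ->
       intermediate; equal to a parental mean -> that parent-like; outside
       the range -> nearer-parent-like when indistinguishable from the
       nearer parent but distinct from the farther one, else
       above_both_ns / below_both_ns.
    """
    if not (hybrid.trait == parent1.trait == parent2.trait):
        raise ValidationError("summaries must all describe the same trait")
    pair = ParentalPair(parent1.group, parent2.group)
    mpv = mid_parent_value(parent1.mean, parent2.mean)

    p_mpv = one_sample_t(hybrid, mpv).p_value
    p1 = welch_t(hybrid, parent1).p_value
    p2 = welch_t(hybrid, parent2).p_value

    h = hybrid.mean
    lo, hi = min(parent1.mean, parent2.mean), max(parent1.mean, parent2.mean)
    both_sig = p1 < alpha and p2 < alpha

    label = None
    if h > hi and both_sig:
        label = "transgressive"
    elif low_transgression and h < lo and both_sig:
        label = "transgressive"
    elif p_mpv < alpha:
        label = "heterotic" if h > mpv else "dysgenetic"
    else:
        d1, d2 = abs(h - parent1.mean), abs(h - parent2.mean)
        if lo < h < hi:
            label = "intermediate"
        elif d1 == d2:
            label = "intermediate"
        elif h == parent1.mean:
            label = "parent1_like"
        elif h == parent2.mean:
            label = "parent2_like"
        else:
            # outside the parental range
            near_is_p1 = d1 < d2
            p_near, p_far = (p1, p2) if near_is_p1 else (p2, p1)
            if p_near >= alpha and p_far < alpha:
                label = "parent1_like" if near_is_p1 else "parent2_like"
            else:
                label = "above_both_ns" if h > hi else "below_both_ns"

    return ClassificationResult(
        hybrid_group=hybrid.group,
        pair=pair,
        trait=hybrid.trait,
        label=label,
        mpv=mpv,
        hybrid_n=hybrid.n,
        hybrid_mean=hybrid.mean,
        hybrid_sd=hybrid.sd,
        p_mpv=p_mpv,
        p_vs_parent1=p1,
        p_vs_parent2=p2,
        direction=(h > mpv) - (h < mpv),
    )


Plan = Mapping[str, Sequence[tuple[str, str] | Sequence[str]]]


def _classify_from_summaries(
    summaries: Iterable[GroupSummary],
    plan: Plan,
    alpha: float,
    require_all: bool,
) -> list[ClassificationResult]:
    pool: dict[tuple[str, str], GroupSummary] = {
        (s.group, s.trait): s for s in summaries
    }
    seen_traits = {t for _, t in pool}
    traits = [t for t in TRAIT_NAMES if t in seen_traits]
    traits += sorted(seen_traits.difference(TRAIT_NAMES))
    results: list[ClassificationResult] = []
    for hybrid_group, pairs in plan.items():
        if not any(g == hybrid_group for g, _ in pool):
            raise ValidationError(f"hybrid group {hybrid_group!r} absent from data")
        for parents in pairs:
            p1_code, p2_code = parents
            for trait in traits:
                keys = [(hybrid_group, trait), (p1_code, trait), (p2_code, trait)]
                missing = [k for k in keys if k not in pool]
                usable = not missing and all(
                    pool[k].n >= 2 and pool[k].sd for k in keys
                )
                if not usable:
                    if require_all:
                        raise ValidationError(
                            f"missing or degenerate summary for {missing or keys}"
                        )
                    continue  # skipped cell, warning left to caller's report
                results.append(
                    classify_trait(
                        pool[(hybrid_group, trait)],
                        pool[(p1_code, trait)],
                        pool[(p2_code, trait)],
                        alpha=alpha,
                    )
                )
    return results


def classify_all(
    flat: pd.DataFrame, plan: Plan, alpha: float = 0.05
) -> list[ClassificationResult]:
    """Classify every (hybrid group, configured parental pair, trait) cell.

    ``plan`` maps hybrid taxon codes to parental pairs, e.g.
    ``{"AH": [("A", "J"), ("A", "P"), ("A", "G")]}``.
    """
    if not plan:
        return []
    return _classify_from_summaries(summarize(flat), plan, alpha, require_all=False)


def summary_mode_classify(
    summaries: Sequence[GroupSummary], plan: Plan, alpha: float = 0.05
) -> list[ClassificationResult]:
    """Same decision logic as :func:`classify_all`, fed from externally
    supplied (n, mean, sd) summaries — e.g. typed in from a published table.
    Missing summaries are an error naming the gap."""
    if not plan:
        return []
    return _classify_from_summaries(summaries, plan, alpha, require_all=True)


# ---------------------------------------------------------------------------
# renderings


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Long-format table, one row per classified cell."""
    rows = [
        {
            "hybrid_group": r.hybrid_group,
            "pair": r.pair.label,
            "trait": r.trait,
            "n": r.hybrid_n,
            "mean": r.hybrid_mean,
            "sd": r.hybrid_sd,
            "mpv": r.mpv,
            "p_mpv": r.p_mpv,
            "p_vs_p1": r.p_vs_parent1,
            "p_vs_p2": r.p_vs_parent2,
            "direction": r.direction,
            "label": r.label,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def results_to_wide(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Rounded rendering mimicking the published per-hybrid tables:
    means/SD/MPV to 1 decimal, p-values to 3 decimals with star codes."""
    rows = []
    for r in results:
        rows.append(
            {
                "hybrid_group": r.hybrid_group,
                "pair": r.pair.label,
                "trait": r.trait,
                "N": r.hybrid_n,
                "Mean": round(r.hybrid_mean, 1),
                "SD": round(r.hybrid_sd, 1),
                "MPV": round(r.mpv, 1),
                "p(MPV)": f"{r.p_mpv:.3f} {significance_code(r.p_mpv)}",
                "p(vs P1)": f"{r.p_vs_parent1:.3f} {significance_code(r.p_vs_parent1)}",
                "p(vs P2)": f"{r.p_vs_parent2:.3f} {significance_code(r.p_vs_parent2)}",
                "classification": r.label,
            }
        )
    return pd.DataFrame(rows)
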