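"""End-to-end pipeline orchestration: ingest -> filter -> tests -> tables."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .exceptions import CallimorphError
from .genetic_distance import between_group_means, estimate_mcl_params, read_group_map, read_grouped_fasta
from .hybrid_classification import classify_all, results_to_frame, results_to_wide
from .morphospace import pca_report, run_pca
from .reference_data import DEFAULT_PLAN
from .stats_core import games_howell_table, levene_test, manova_pillai, summarize, welch_anova_table
from .schema import TRAIT_NAMES
from .trait_io import filter_adults, read_trait_table, write_flat_table

logger = logging.getLogger("callimorph")


@dataclass
class RunConfig:
    traits_path: str
    out_dir: str
    fasta_path: str | None = None
    groups_path: str | None = None
    plan: Mapping[str, Sequence[tuple[str, str]]] = field(
        default_factory=lambda: {h: list(p) for h, p in DEFAULT_PLAN.items()}
    )
    alpha: float = 0.05
    pca_subsets: Sequence[Sequence[str]] = (
        ("J", "P", "PJ"),
        ("G", "P", "PG"),
        ("A", "G", "J", "P", "AH"),
    )
    pca_scaling: str = "correlation"
    adults_only: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise CallimorphError("alpha must be in (0, 1)")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write stage CSVs plus a run manifest.

    Deterministic given (inputs, config, seed); any stage error aborts with
    the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": [],
        "warnings": [],
        "skipped": [],
    }

    stage = "ingest"
    try:
        table = read_trait_table(config.traits_path)
        manifest["warnings"] += table.provenance.get("warnings", [])
        if config.adults_only:
            table = filter_adults(table)
        write_flat_table(table, out / "traits_clean.csv")
        flat = table.to_flat_frame()
        manifest["stages"].append({"stage": stage, "rows": len(flat)})

        stage = "summaries"
        summaries = summarize(flat)
        pd.DataFrame(
            [
                {"taxon": s.group, "trait": s.trait, "n": s.n, "mean": s.mean, "sd": s.sd}
                for s in summaries
            ]
        ).to_csv(out / "group_summaries.csv", index=False)
        manifest["stages"].append({"stage": stage, "n_summaries": len(summaries)})

        stage = "univariate_tests"
        lev_rows = []
        for trait in TRAIT_NAMES:
            groups, names = [], []
            for taxon, subg in flat.groupby("taxon"):
                vals = pd.to_numeric(subg[trait], errors="coerce").dropna()
                if len(vals) >= 2:
                    groups.append(vals.to_numpy())
                    names.append(str(taxon))
            if len(groups) >= 2:
                res = levene_test(groups, group_names=names)
                lev_rows.append(
                    {"trait": trait, "statistic": res.statistic, "df1": res.df1,
                     "df2": res.df2, "p_value": res.p_value}
                )
        pd.DataFrame(lev_rows).to_csv(out / "levene.csv", index=False)
        welch_anova_table(flat).to_csv(out / "welch_anova.csv", index=False)
        games_howell_table(flat, alpha=config.alpha).to_csv(
            out / "games_howell.csv", index=False
        )
        manifest["stages"].append({"stage": stage})

        stage = "manova"
        complete = flat.dropna(subset=list(TRAIT_NAMES))
        if len(complete) > len(TRAIT_NAMES) and complete["taxon"].nunique() >= 2:
            res = manova_pillai(
                complete[list(TRAIT_NAMES)].to_numpy(), complete["taxon"].to_numpy()
            )
            with open(out / "manova.json", "w") as fh:
                json.dump(
                    {"pillai": res.statistic, "df1": res.df1, "df2": res.df2,
                     "p_value": res.p_value}, fh, indent=2
                )
            manifest["stages"].append({"stage": stage, "pillai": res.statistic})
        else:
            manifest["skipped"].append(stage)

        stage = "classification"
        results = classify_all(flat, config.plan, alpha=config.alpha)
        results_to_frame(results).to_csv(out / "classification_long.csv", index=False)
        results_to_wide(results).to_csv(out / "classification_wide.csv", index=False)
        manifest["stages"].append({"stage": stage, "n_cells": len(results)})

        stage = "pca"
        for subset in config.pca_subsets:
            subset = tuple(subset)
            try:
                res = run_pca(flat, subset=subset, scaling=config.pca_scaling)
            except CallimorphError as exc:
                manifest["warnings"].append(f"pca {subset}: {exc}")
                continue
            pca_report(res, outdir=out)
        manifest["stages"].append({"stage": stage})

        stage = "genetic_distance"
        if config.fasta_path and config.groups_path:
            alignment = read_grouped_fasta(
                config.fasta_path, read_group_map(config.groups_path)
            )
            params = estimate_mcl_params(alignment)
            matrix = between_group_means(alignment, params)
            matrix.to_frame().to_csv(out / "distance_matrix.csv")
            matrix.to_long().to_csv(out / "distance_pairs.csv", index=False)
            manifest["warnings"] += matrix.warnings
            manifest["stages"].append({"stage": stage})
        else:
            manifest["skipped"].append(stage)
    except CallimorphError as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
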