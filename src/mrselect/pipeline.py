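"""End-to-end workflow: instruments -> univariable MR -> MVMR model selection.

`run_pipeline` executes the full analysis the package is built around:
per-exposure instrument selection and harmonization, the univariable
estimator suite with Bonferroni-flagged significance, pairwise conditional-F
enumeration, forward selection of the MVMR model, and the final MVMR fit
with its adjusted Q-statistic. All outputs are tab-delimited files plus a
machine-readable YAML manifest recording inputs, thresholds and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import MRSelectError
from .mvmr import adjusted_q, conditional_f, mvmr_ivw
from .selection import enumerate_pairs, forward_select
from .summary_data import (
    AssociationTable,
    assemble_mvmr_set,
    read_association_table,
)
from .univariable import UnivariableConfig, bonferroni_threshold, run_univariable_suite

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and options shared by every pipeline stage."""

    p_threshold: float = 5e-8
    window_kb: float = 10_000.0
    palindrome_band: float = 0.08
    f_threshold: float = 10.0
    alpha: float = 0.05
    seed: int = 0
    n_boot: int = 1000
    ivw_model: str = "fixed"
    remove_outliers: bool = False
    methods: tuple[str, ...] = ("ivw", "egger", "median", "mode")

    @classmethod
    def from_yaml(cls, path: str | Path, **flag_overrides) -> "RunConfig":
        """Config file values override defaults; explicit flags override both."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in flag_overrides.items() if v is not None})
        return cls(**data)


def load_tables(
    exposure_paths: list[str | Path],
    outcome_path: str | Path,
) -> tuple[list[AssociationTable], AssociationTable]:
    exposures = [
        read_association_table(p, trait_type="continuous") for p in exposure_paths
    ]
    outcome = read_association_table(outcome_path, trait_type="binary")
    return exposures, outcome


def univariable_stage(
    exposures: list[AssociationTable],
    outcome: AssociationTable,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariable suite per exposure; returns (estimates, heterogeneity)."""
    m = len(exposures)
    sig = bonferroni_threshold(config.alpha, m)
    est_rows, het_rows = [], []
    ucfg = UnivariableConfig(
        methods=config.methods,
        ivw_model=config.ivw_model,
        n_boot=config.n_boot,
        seed=config.seed,
        remove_outliers=config.remove_outliers,
        outlier_alpha=config.alpha,
    )
    for table in exposures:
        hset = assemble_mvmr_set(
            [table], outcome, config.p_threshold, config.window_kb,
            config.palindrome_band,
        )
        res = run_univariable_suite(hset, ucfg)
        for est in res.estimates:
            row = asdict(est)
            row["exposure"] = res.exposure
            row["outcome"] = res.outcome
            row["mean_f"] = res.mean_f
            row["significant_bonferroni"] = (
                bool(est.pvalue < sig) if est.status == "ok" else False
            )
            est_rows.append(row)
        het_rows.append(
            {
                "exposure": res.exposure,
                "outcome": res.outcome,
                "Q": res.heterogeneity.Q,
                "df": res.heterogeneity.df,
                "pvalue": res.heterogeneity.pvalue,
                "n_outliers_removed": res.n_outliers_removed,
                "outlier_ids": ",".join(res.heterogeneity.outlier_ids),
            }
        )
    cols = ["exposure", "outcome", "method", "beta", "se", "ci_low", "ci_high",
            "pvalue", "odds_ratio", "or_ci_low", "or_ci_high", "n_snps",
            "mean_f", "significant_bonferroni", "status", "message"]
    return pd.DataFrame(est_rows)[cols], pd.DataFrame(het_rows)


def run_pipeline(
    exposures: list[AssociationTable],
    outcome: AssociationTable,
    config: RunConfig,
    out_dir: str | Path,
) -> dict:
    """Run every stage and write artifacts under ``out_dir``.

    Returns the manifest dictionary. Raises on the first failing stage with
    partial outputs retained on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mrselect",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "instrument_pvalue": config.p_threshold,
            "window_kb": config.window_kb,
            "conditional_f": config.f_threshold,
            "alpha": config.alpha,
            "bonferroni_m": len(exposures),
        },
        "exposures": [t.trait_name for t in exposures],
        "outcome": outcome.trait_name,
        "stages": {},
    }

    stage = "univariable"
    try:
        estimates, heterogeneity = univariable_stage(exposures, outcome, config)
        estimates.to_csv(out_dir / "univariable_estimates.tsv", sep="\t", index=False)
        heterogeneity.to_csv(out_dir / "heterogeneity.tsv", sep="\t", index=False)
        manifest["stages"][stage] = "ok"

        if len(exposures) >= 2:
            stage = "pair_enumeration"
            pairs = enumerate_pairs(
                exposures, outcome, config.f_threshold,
                p_threshold=config.p_threshold, window_kb=config.window_kb,
                palindrome_band=config.palindrome_band,
            )
            pairs.to_frame().to_csv(out_dir / "pair_scores.tsv", sep="\t", index=False)
            pairs.f_matrix.to_csv(out_dir / "conditional_f_matrix.tsv", sep="\t")
            manifest["stages"][stage] = "ok"

            stage = "forward_selection"
            trace = forward_select(
                exposures, outcome, config.f_threshold,
                p_threshold=config.p_threshold, window_kb=config.window_kb,
                palindrome_band=config.palindrome_band,
            )
            (out_dir / "selection_trace.txt").write_text(trace.to_text() + "\n")
            manifest["stages"][stage] = "ok"
            manifest["final_model"] = trace.final_model

            if trace.final_model:
                stage = "mvmr"
                hset = assemble_mvmr_set(
                    [t for t in exposures if t.trait_name in trace.final_model],
                    outcome, config.p_threshold, config.window_kb,
                    config.palindrome_band,
                )
                est = mvmr_ivw(hset)
                strength = (
                    conditional_f(hset, threshold=config.f_threshold)
                    if hset.n_exposures >= 2 else None
                )
                q = adjusted_q(hset, est)
                rows = []
                for k, name in enumerate(est.exposure_names):
                    rows.append({
                        "exposure": name,
                        "beta": est.betas[k],
                        "se": est.ses[k],
                        "ci_low": est.ci_lows[k],
                        "ci_high": est.ci_highs[k],
                        "pvalue": est.pvalues[k],
                        "odds_ratio": est.odds_ratios[k],
                        "conditional_f": (
                            strength.conditional_f[k] if strength else float("nan")
                        ),
                        "n_snps": est.n_snps,
                    })
                pd.DataFrame(rows).to_csv(
                    out_dir / "mvmr_estimates.tsv", sep="\t", index=False
                )
                manifest["stages"][stage] = "ok"
                manifest["adjusted_q"] = {"Q_a": q.Q_a, "df": q.df, "pvalue": q.pvalue}
    except MRSelectError as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        raise

    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
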