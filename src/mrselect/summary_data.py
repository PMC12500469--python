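"""Reading, validation, pruning and harmonization of GWAS summary statistics.

The module turns per-trait association tables (one row per variant: alleles,
effect-allele frequency, beta, SE, p-value, sample size) into an
analysis-ready :class:`HarmonizedSet` holding the instrument-exposure matrix
``gamma`` and the instrument-outcome vector ``Gamma`` on a common effect
allele orientation.

Variant independence is enforced by greedy distance pruning (keep the
smallest-p variant, discard neighbours within a window) rather than
LD-based clumping, which would require a genotype reference panel. For
data without local LD this is exact; for real data it is a documented
approximation of the r^2-based procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInstrumentError,
    HarmonizationError,
    InputError,
)

logger = logging.getLogger(__name__)

#: Canonical column order of an association table.
COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Default mapping from file headers to canonical columns.
DEFAULT_DIALECT: Mapping[str, str] = {
    "SNP": "variant_id",
    "chr": "chromosome",
    "pos": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pvalue",
    "n": "n",
}

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Provenance flags recorded per variant during harmonization.
FLAG_UNCHANGED = "unchanged"
FLAG_FLIPPED = "allele_flipped"
FLAG_DROPPED_PALINDROMIC = "dropped_palindromic"
FLAG_DROPPED_MISSING = "dropped_missing"


@dataclass
class AssociationTable:
    """Per-trait GWAS summary statistics keyed by variant.

    Parameters
    ----------
    trait_name
        Label of the trait the associations refer to.
    trait_type
        ``"continuous"`` (betas in SD units of a z-standardized trait) or
        ``"binary"`` (betas on the log-odds scale).
    df
        DataFrame with the canonical :data:`COLUMNS`.
    """

    trait_name: str
    trait_type: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"association table missing columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            dup = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise InputError(f"duplicate variant_id in table {self.trait_name!r}: {dup}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> pd.Series:
        return self.df["variant_id"]

    def subset(self, variant_ids: Sequence[str]) -> "AssociationTable":
        """Return a copy restricted to ``variant_ids`` (in table order)."""
        keep = self.df[self.df["variant_id"].isin(set(variant_ids))]
        return replace(self, df=keep.reset_index(drop=True))

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("variant_id")


def _validate_rows(df: pd.DataFrame, trait_name: str) -> pd.DataFrame:
    """Drop rows violating the per-variant invariants, logging counts."""
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    for col in ("eaf", "beta", "se", "pvalue", "n", "position"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chromosome"] = df["chromosome"].astype(str)
    df["variant_id"] = df["variant_id"].astype(str)

    reasons = {
        "non_finite": ~np.isfinite(df[["eaf", "beta", "se", "pvalue"]]).all(axis=1),
        "se_nonpositive": ~(df["se"] > 0),
        "eaf_out_of_range": ~df["eaf"].between(0.0, 1.0),
        "pvalue_out_of_range": ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        "bad_alleles": ~(
            df["effect_allele"].isin(_NUCLEOTIDES)
            & df["other_allele"].isin(_NUCLEOTIDES)
            & (df["effect_allele"] != df["other_allele"])
        ),
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in reasons.items():
        mask = mask.fillna(True) & ~bad
        if mask.any():
            logger.warning(
                "%s: dropping %d row(s): %s", trait_name, int(mask.sum()), reason
            )
        bad |= mask
    df = df[~bad].reset_index(drop=True)
    df["position"] = df["position"].astype(np.int64)
    return df


def read_association_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
) -> AssociationTable:
    """Read a tab- or comma-delimited summary-statistics file.

    ``dialect`` maps file headers to canonical field names; the default
    expects ``SNP chr pos effect_allele other_allele eaf beta se pval n``.
    Rows violating the record invariants (se <= 0, alleles outside ACGT,
    p outside (0,1], ...) are dropped with a logged count.
    """
    path = Path(path)
    dialect = dict(dialect or DEFAULT_DIALECT)
    raw = pd.read_csv(path, sep=None, engine="python")
    rename = {src: dst for src, dst in dialect.items() if src in raw.columns}
    missing = set(dialect.values()) - set(rename.values()) - (
        set(raw.columns) & set(COLUMNS)
    )
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing mandatory column(s) {sorted(missing)} "
            f"(dialect: {dialect})"
        )
    df = raw.rename(columns=rename)[COLUMNS]
    df = _validate_rows(df, trait_name or path.stem)
    if df.empty:
        raise InputError(f"{path.name}: no valid rows after validation")
    return AssociationTable(trait_name or path.stem, trait_type, df)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    """Write a table in the default tab-delimited dialect (round-trippable)."""
    inverse = {v: k for k, v in DEFAULT_DIALECT.items()}
    out = table.df[COLUMNS].rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False)


def select_instruments(
    table: AssociationTable,
    p_threshold: float = 5e-8,
    window_kb: float = 10_000.0,
) -> AssociationTable:
    """Select genome-wide-significant, distance-pruned instruments.

    Keeps variants with ``pvalue < p_threshold`` and then, per chromosome,
    greedily retains the smallest-p remaining variant while discarding all
    others within ``window_kb`` of it.
    """
    if not (0 < p_threshold < 1):
        raise ConfigurationError("p_threshold must lie in (0, 1)")
    if window_kb <= 0:
        raise ConfigurationError("window_kb must be positive")
    hits = table.df[table.df["pvalue"] < p_threshold]
    if hits.empty:
        raise EmptyInstrumentError(
            f"{table.trait_name}: no variant passes p < {p_threshold:g}"
        )
    window_bp = window_kb * 1_000.0
    kept: list[int] = []
    for _, chrom_df in hits.groupby("chromosome", sort=True):
        remaining = chrom_df.sort_values(
            ["pvalue", "position", "variant_id"]
        ).copy()
        while not remaining.empty:
            best = remaining.iloc[0]
            kept.append(best.name)
            remaining = remaining[
                (remaining["position"] - best["position"]).abs() > window_bp
            ]
    out = table.df.loc[sorted(kept)].reset_index(drop=True)
    return replace(table, df=out)


@dataclass
class HarmonizedSet:
    """Allele-aligned instrument set for one outcome and >= 1 exposures.

    ``gamma``/``gamma_se`` are L x K instrument-exposure association
    matrices; ``Gamma``/``Gamma_se`` the length-L instrument-outcome vector.
    ``provenance`` records, for every candidate variant (kept or dropped),
    the harmonization action taken.
    """

    outcome_name: str
    exposure_names: list[str]
    variant_ids: np.ndarray
    gamma: np.ndarray
    gamma_se: np.ndarray
    Gamma: np.ndarray
    Gamma_se: np.ndarray
    provenance: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.gamma_se = np.atleast_2d(np.asarray(self.gamma_se, dtype=float))
        if self.gamma.shape[0] == 1 and len(self.variant_ids) > 1:
            self.gamma = self.gamma.T
            self.gamma_se = self.gamma_se.T
        self.Gamma = np.asarray(self.Gamma, dtype=float).ravel()
        self.Gamma_se = np.asarray(self.Gamma_se, dtype=float).ravel()
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        L, K = self.gamma.shape
        if self.gamma_se.shape != (L, K) or len(self.Gamma) != L or len(self.Gamma_se) != L:
            raise InputError("inconsistent harmonized array shapes")
        if len(self.exposure_names) != K:
            raise InputError("exposure_names length does not match gamma columns")
        if len(set(self.variant_ids)) != L:
            raise InputError("duplicate variants in harmonized set")
        if np.any(self.gamma_se <= 0) or np.any(self.Gamma_se <= 0):
            raise InputError("all standard errors must be positive")

    @property
    def n_variants(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.gamma.shape[1]

    def single(self, exposure: str | int = 0) -> "HarmonizedSet":
        """Return the K=1 view for one exposure (for univariable estimators)."""
        k = (
            exposure
            if isinstance(exposure, int)
            else self.exposure_names.index(exposure)
        )
        return HarmonizedSet(
            outcome_name=self.outcome_name,
            exposure_names=[self.exposure_names[k]],
            variant_ids=self.variant_ids.copy(),
            gamma=self.gamma[:, [k]].copy(),
            gamma_se=self.gamma_se[:, [k]].copy(),
            Gamma=self.Gamma.copy(),
            Gamma_se=self.Gamma_se.copy(),
            provenance=self.provenance,
        )

    def subset(self, keep: np.ndarray) -> "HarmonizedSet":
        """Return a copy restricted to a boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return HarmonizedSet(
            outcome_name=self.outcome_name,
            exposure_names=list(self.exposure_names),
            variant_ids=self.variant_ids[idx],
            gamma=self.gamma[idx],
            gamma_se=self.gamma_se[idx],
            Gamma=self.Gamma[idx],
            Gamma_se=self.Gamma_se[idx],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per variant with per-exposure beta/se columns."""
        data: dict[str, np.ndarray] = {"variant_id": self.variant_ids}
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.gamma[:, k]
            data[f"se_{name}"] = self.gamma_se[:, k]
        data[f"beta_{self.outcome_name}"] = self.Gamma
        data[f"se_{self.outcome_name}"] = self.Gamma_se
        return pd.DataFrame(data)

    def to_file(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def flip_orientation(beta: float, eaf: float) -> tuple[float, float]:
    """Swap effect/other allele orientation: beta -> -beta, eaf -> 1-eaf."""
    return -beta, 1.0 - eaf


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    palindrome_band: float = 0.08,
) -> HarmonizedSet:
    """Align effect alleles across exposure and outcome tables.

    The instrument set is the union of the exposure tables' variants,
    restricted to variants present in every exposure table and in the
    outcome table. Orientation follows the first exposure table; swapped
    alleles flip the sign of beta and complement the frequency. Palindromic
    variants (A/T, C/G) whose frequency lies within ``palindrome_band`` of
    0.5 in any table are dropped; palindromic variants outside the band are
    aligned by frequency.
    """
    if not exposures:
        raise ConfigurationError("at least one exposure table is required")
    if not (0 <= palindrome_band < 0.5):
        raise ConfigurationError("palindrome_band must lie in [0, 0.5)")

    tables = list(exposures) + [outcome]
    indexed = [t.indexed() for t in tables]
    names = [t.trait_name for t in tables]

    union = pd.concat(
        [t.df[["variant_id", "chromosome", "position"]] for t in exposures]
    ).drop_duplicates("variant_id")
    union = union.sort_values(["chromosome", "position", "variant_id"])

    rows = []
    prov = []
    for vid in union["variant_id"]:
        present = [vid in idx.index for idx in indexed]
        if not all(present):
            absent = [n for n, p in zip(names, present) if not p]
            prov.append((vid, FLAG_DROPPED_MISSING, f"absent in {','.join(absent)}"))
            continue
        recs = [idx.loc[vid] for idx in indexed]
        ea0, oa0 = recs[0]["effect_allele"], recs[0]["other_allele"]
        eaf0 = float(recs[0]["eaf"])
        palindromic = _is_palindromic(ea0, oa0)

        if palindromic and any(
            abs(float(r["eaf"]) - 0.5) <= palindrome_band
            or abs((1.0 - float(r["eaf"])) - 0.5) <= palindrome_band
            for r in recs
        ):
            prov.append((vid, FLAG_DROPPED_PALINDROMIC, "eaf near 0.5"))
            continue

        betas, ses, flipped, mismatch = [], [], False, False
        for r in recs:
            ea, oa = r["effect_allele"], r["other_allele"]
            beta, eaf = float(r["beta"]), float(r["eaf"])
            if palindromic:
                # allele letters cannot distinguish strand; align by frequency
                factor = 1.0 if (eaf - 0.5) * (eaf0 - 0.5) > 0 else -1.0
            elif (ea, oa) == (ea0, oa0):
                factor = 1.0
            elif (ea, oa) == (oa0, ea0):
                factor = -1.0
            elif (_COMPLEMENT[ea], _COMPLEMENT[oa]) == (ea0, oa0):
                factor = 1.0
            elif (_COMPLEMENT[ea], _COMPLEMENT[oa]) == (oa0, ea0):
                factor = -1.0
            else:
                mismatch = True
                break
            if factor < 0:
                flipped = True
            betas.append(factor * beta)
            ses.append(float(r["se"]))
        if mismatch:
            prov.append((vid, FLAG_DROPPED_MISSING, "allele mismatch"))
            continue
        prov.append((vid, FLAG_FLIPPED if flipped else FLAG_UNCHANGED, ""))
        rows.append((vid, betas, ses))

    provenance = pd.DataFrame(prov, columns=["variant_id", "flag", "detail"])
    if len(rows) < 2:
        raise HarmonizationError(
            f"only {len(rows)} variant(s) survive harmonization (need >= 2)"
        )

    K = len(exposures)
    variant_ids = np.array([r[0] for r in rows], dtype=object)
    betas = np.array([r[1] for r in rows], dtype=float)
    ses = np.array([r[2] for r in rows], dtype=float)
    return HarmonizedSet(
        outcome_name=outcome.trait_name,
        exposure_names=[t.trait_name for t in exposures],
        variant_ids=variant_ids,
        gamma=betas[:, :K],
        gamma_se=ses[:, :K],
        Gamma=betas[:, K],
        Gamma_se=ses[:, K],
        provenance=provenance,
    )


def assemble_mvmr_set(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    p_threshold: float = 5e-8,
    window_kb: float = 10_000.0,
    palindrome_band: float = 0.08,
) -> HarmonizedSet:
    """Instrument-select each exposure, pool the union, and harmonize.

    This reproduces the usual multivariable-MR assembly: the instrument set
    is the union of per-exposure genome-wide-significant pruned variants,
    with each full exposure table subset to that union so every exposure
    contributes an association at every pooled instrument (complete-case
    restriction across tables happens inside :func:`harmonize`).
    """
    selected = [select_instruments(t, p_threshold, window_kb) for t in exposures]
    union_ids: list[str] = []
    seen: set[str] = set()
    for sel in selected:
        for vid in sel.df["variant_id"]:
            if vid not in seen:
                seen.add(vid)
                union_ids.append(vid)
    pooled = [t.subset(union_ids) for t in exposures]
    return harmonize(pooled, outcome, palindrome_band=palindrome_band)
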