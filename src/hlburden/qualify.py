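"""Genotype QC and rare-variant qualification filters.

A variant qualifies for burden analysis when it is rare both in reference
populations (gnomAD African and Non-Finnish European AF <= 0.001) and in the
cohort itself (AF < 0.01), and is predicted deleterious: a loss-of-function
class (frameshift, stop-gain, canonical splice) or a missense with REVEL
score > 0.6.  Genotype-level QC precedes frequency filtering: calls with
fewer than 7 supporting reads are set missing, and variants are kept only if
at least one homozygous-alt call, or one heterozygous call supported by at
least 15% of reads, survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet

import numpy as np
import pandas as pd

MISSING = -1

CONSEQUENCE_CLASSES = frozenset(
    {"frameshift", "stop_gain", "canonical_splice", "missense", "synonymous"}
)

DEFAULT_PLOF_CLASSES = frozenset({"frameshift", "stop_gain", "canonical_splice"})

DEFAULT_CLINVAR_PATHOGENIC = frozenset(
    {"Pathogenic", "Likely pathogenic", "Pathogenic/Likely pathogenic"}
)


@dataclass(frozen=True)
class QualificationConfig:
    """Thresholds for variant qualification.

    ``gnomad_af_max`` is inclusive (a reference AF strictly greater than the
    threshold removes the variant); ``cohort_af_max`` is exclusive (the
    cohort AF must be strictly below it).  Both conventions are configurable
    through ``gnomad_inclusive`` / ``cohort_strict``.
    """

    gnomad_af_max: float = 0.001
    cohort_af_max: float = 0.01
    revel_min: float = 0.6
    plof_classes: FrozenSet[str] = DEFAULT_PLOF_CLASSES
    clinvar_pathogenic_labels: FrozenSet[str] = DEFAULT_CLINVAR_PATHOGENIC
    gnomad_inclusive: bool = True
    cohort_strict: bool = True
    min_depth: int = 7
    min_het_alt_fraction: float = 0.15

    def __post_init__(self):
        if not (0 <= self.gnomad_af_max <= 1 and 0 <= self.cohort_af_max <= 1):
            raise ValueError("allele-frequency thresholds must lie in [0,1]")
        if not self.plof_classes <= CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown pLoF classes: {self.plof_classes - CONSEQUENCE_CLASSES}")


def apply_genotype_qc(
    genotypes: np.ndarray,
    depth: np.ndarray,
    alt_fraction: np.ndarray,
    min_depth: int = 7,
    min_het_alt_fraction: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Read-support QC on an individuals x variants genotype matrix.

    Genotypes covered by fewer than ``min_depth`` reads are set to missing.
    A variant is then retained only if it keeps at least one homozygous-alt
    call or at least one heterozygous call whose alternate-read fraction is
    >= ``min_het_alt_fraction``.

    Returns ``(qc_genotypes, variant_keep_mask)``; dropped variants stay as
    columns so the mask can be applied by the caller together with the
    annotation table.
    """
    genotypes = np.asarray(genotypes)
    if depth.shape != genotypes.shape or alt_fraction.shape != genotypes.shape:
        raise ValueError("depth/alt-fraction matrices must align with genotypes")
    g = genotypes.copy()
    g[depth < min_depth] = MISSING
    hom_alt = (g == 2).any(axis=0)
    supported_het = ((g == 1) & (alt_fraction >= min_het_alt_fraction)).any(axis=0)
    keep = hom_alt | supported_het
    return g, keep


def cohort_allele_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per variant, missing-aware.

    AF = alt allele count / (2 x number of non-missing genotypes); variants
    with every genotype missing get ``NaN``.
    """
    g = np.asarray(genotypes, dtype=np.int64)
    obs = g != MISSING
    alt = np.where(obs, g, 0).sum(axis=0)
    denom = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)
    return af


def qualify_variants(
    annotations: pd.DataFrame,
    cohort_af: np.ndarray | pd.Series,
    config: QualificationConfig = QualificationConfig(),
) -> pd.DataFrame:
    """Select qualifying deleterious rare variants.

    ``annotations`` needs columns ``variant_id, gene_id, consequence, revel,
    gnomad_afr_af, gnomad_nfe_af, clinvar``; ``cohort_af`` aligns with its
    rows.  Missing gnomAD AFs are treated as 0 (novel variants are kept).

    Returns the qualifying subset with a ``reason`` column ("plof" or
    "missense_revel") and a ``clinvar_pathogenic`` flag.
    """
    ann = annotations.reset_index(drop=True)
    unknown = set(ann["consequence"].unique()) - CONSEQUENCE_CLASSES
    if unknown:
        raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
    af = np.asarray(cohort_af, dtype=float)
    if len(af) != len(ann):
        raise ValueError("cohort AF vector must align with annotation rows")

    gnomad_afr = ann["gnomad_afr_af"].fillna(0.0).to_numpy(float)
    gnomad_nfe = ann["gnomad_nfe_af"].fillna(0.0).to_numpy(float)
    if config.gnomad_inclusive:
        gnomad_ok = (gnomad_afr <= config.gnomad_af_max) & (gnomad_nfe <= config.gnomad_af_max)
    else:
        gnomad_ok = (gnomad_afr < config.gnomad_af_max) & (gnomad_nfe < config.gnomad_af_max)
    if config.cohort_strict:
        cohort_ok = af < config.cohort_af_max
    else:
        cohort_ok = af <= config.cohort_af_max
    cohort_ok &= ~np.isnan(af)

    is_plof = ann["consequence"].isin(config.plof_classes).to_numpy()
    revel = ann["revel"].to_numpy(float) if "revel" in ann else np.full(len(ann), np.nan)
    is_damaging_missense = (
        (ann["consequence"] == "missense").to_numpy()
        & ~np.isnan(revel)
        & (revel > config.revel_min)
    )

    qual = gnomad_ok & cohort_ok & (is_plof | is_damaging_missense)
    out = ann.loc[qual].copy()
    out["cohort_af"] = af[qual]
    out["reason"] = np.where(is_plof[qual], "plof", "missense_revel")
    clinvar = out.get("clinvar", pd.Series("", index=out.index)).fillna("")
    out["clinvar_pathogenic"] = clinvar.isin(config.clinvar_pathogenic_labels)
    return out.reset_index(drop=True)


def clinvar_partition(qualified: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a qualified set into ClinVar-pathogenic variants and the rest."""
    flag = qualified["clinvar_pathogenic"].astype(bool)
    return qualified[flag].copy(), qualified[~flag].copy()
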