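"""Per-gene and aggregate burden scores from qualifying variants.

The burden of a gene for an individual is the sum of alternate-allele counts
over that gene's qualifying variants (a homozygote contributes 2); a
variant-counting mode (homozygote contributes 1) is available.  Missing
genotypes contribute 0 — no imputation is attempted for rare variants.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INHERITANCE_CLASSES = ("DFNA", "DFNB", "DFNA+B")


def load_known_genes(path=None) -> pd.DataFrame:
    """Load the known hearing-loss gene list (gene_id, inheritance_class).

    The packaged default is a synthetic stand-in list with the canonical
    composition of the curated congenital-HL gene set: 173 autosomal genes,
    66 autosomal-dominant (DFNA), 97 autosomal-recessive (DFNB) and 10 with
    both inheritance patterns.  Supply ``path`` to use a real curated list.
    """
    if path is None:
        ref = resources.files("hlburden.data") / "known_hl_genes_synthetic.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "inheritance_class"} - set(df.columns)
    if missing:
        raise ValueError(f"gene list missing columns: {sorted(missing)}")
    return df


def gene_burden(
    genotypes: np.ndarray,
    variant_ids: Sequence[str],
    qualified: pd.DataFrame,
    individual_ids: Sequence[str],
    mode: str = "alleles",
) -> pd.DataFrame:
    """Individuals x genes burden matrix from qualifying variants.

    ``genotypes`` is individuals x variants with missing encoded as -1;
    ``qualified`` maps qualifying ``variant_id`` to ``gene_id``.  With
    ``mode="alleles"`` (default) a homozygous-alt genotype counts 2; with
    ``mode="variants"`` it counts 1.  Qualifying variants without a gene are
    skipped.  Genes with no qualifying variants are absent from the columns.
    """
    if mode not in ("alleles", "variants"):
        raise ValueError("mode must be 'alleles' or 'variants'")
    g = np.asarray(genotypes)
    pos = {v: i for i, v in enumerate(variant_ids)}
    qual = qualified.dropna(subset=["gene_id"])
    qual = qual[qual["variant_id"].isin(pos)]
    counts = np.maximum(g, 0)  # missing -> 0
    if mode == "variants":
        counts = np.minimum(counts, 1)
    cols = {}
    for gene, grp in qual.groupby("gene_id"):
        idx = [pos[v] for v in grp["variant_id"]]
        cols[gene] = counts[:, idx].sum(axis=1)
    out = pd.DataFrame(cols, index=pd.Index(individual_ids, name="individual_id"))
    return out.sort_index(axis=1)


def total_burden(burdens: pd.DataFrame, genes: Iterable[str] | None = None) -> pd.Series:
    """Total burden over a gene subset (row sum of the selected columns).

    ``genes`` defaults to every column.  Genes in the subset that never
    acquired qualifying variants (hence have no column) contribute zero;
    asking for a gene id that is neither a column nor in the declared
    universe is the caller's responsibility to validate via ``strict`` use
    of :func:`gene_burden` inputs.
    """
    if genes is None:
        sel = burdens
    else:
        genes = list(genes)
        present = [g for g in genes if g in burdens.columns]
        sel = burdens[present]
    if sel.shape[1] == 0:
        return pd.Series(0, index=burdens.index, name="total_burden")
    return sel.sum(axis=1).rename("total_burden")


def carrier_summary(burdens: pd.DataFrame, case_labels: pd.Series) -> pd.DataFrame:
    """Carrier counts per gene: carriers (burden >= 1), case carriers, frequencies.

    ``case_labels`` is a nullable-boolean Series (True = case) indexed by
    individual id, as produced by ``binarize_case_control``; individuals with
    NA labels count toward carriers but not case carriers.
    """
    labels = case_labels.reindex(burdens.index)
    is_case = (labels == True).fillna(False).to_numpy(bool)  # noqa: E712  (nullable boolean)
    mat = burdens.to_numpy() >= 1
    carriers = mat.sum(axis=0)
    case_carriers = mat[is_case].sum(axis=0)
    n = len(burdens)
    return pd.DataFrame(
        {
            "gene_id": burdens.columns,
            "carriers": carriers.astype(int),
            "case_carriers": case_carriers.astype(int),
            "carrier_freq": carriers / n if n else np.nan,
        }
    )


def filter_genes_by_case_carriers(summary: pd.DataFrame, threshold: int) -> list[str]:
    """Genes with strictly more than ``threshold`` case carriers.

    The known-gene scan uses threshold 0 (any case carrier); the exome-wide
    scan uses the permutation-calibrated threshold (25 in the study design).
    """
    if threshold < 0:
        raise ValueError("case-carrier threshold must be nonnegative")
    keep = summary["case_carriers"] > threshold
    return summary.loc[keep, "gene_id"].tolist()
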