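"""Readers and writers for the pipeline's standard formats.

Rare genotypes travel as VCF v4.2 (GT, with optional DP/AD read-support
fields for genotype QC); everything else is tab-separated text with
documented headers.  Coordinates are 1-based inclusive and variant ids are
``chrom:pos:ref:alt``.  Multiallelic VCF records must be pre-split into
biallelic records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

TABLE_SCHEMAS = {
    "audiograms": ["individual_id", "date", "ear", "conduction", "frequency_hz", "threshold_db"],
    "phecodes": ["individual_id", "phecode", "date"],
    "covariates": ["individual_id", "sex", "age", "ancestry"],
    "annotations": [
        "variant_id",
        "gene_id",
        "consequence",
        "revel",
        "gnomad_afr_af",
        "gnomad_nfe_af",
        "clinvar",
    ],
    "weights": ["variant_id", "effect_allele", "other_allele", "weight"],
    "gene_set": ["gene_id", "inheritance_class"],
    "common_variants": ["variant_id", "ref", "alt", "rsq"],
    "gene_map": ["variant_id", "gene_id"],
}


class SchemaError(ValueError):
    pass


class VCFParseError(ValueError):
    pass


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a tab-separated table and validate its required columns.

    Unknown columns are preserved (downstream code ignores them); a missing
    required column raises :class:`SchemaError` naming it.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind '{kind}'")
    df = pd.read_csv(
        path, sep="\t", dtype={"individual_id": str, "phecode": str, "date": str},
        float_precision="round_trip",
    )
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for '{kind}' table")
    return df


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", index=False, float_format=float_format)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, genotypes, variants: pd.DataFrame, individual_ids, depth=None, alt_reads=None) -> None:
    """Write an individuals x variants genotype matrix as VCF v4.2.

    ``variants`` needs ``chrom, pos, ref, alt`` (and optionally
    ``variant_id`` for the ID column).  When ``depth``/``alt_reads`` are
    given, per-genotype DP and AD (ref,alt) fields are emitted.
    """
    G = np.asarray(genotypes)
    n, V = G.shape
    if len(variants) != V:
        raise ValueError("variant table must align with genotype columns")
    with_support = depth is not None and alt_reads is not None
    fmt = "GT:DP:AD" if with_support else "GT"
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_support:
            f.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            f.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for c in sorted(set(variants["chrom"])):
            f.write(f"##contig=<ID={c}>\n")
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, individual_ids)) + "\n")
        vid = variants["variant_id"] if "variant_id" in variants else pd.Series(["."] * V)
        chrom = variants["chrom"].to_numpy()
        pos = variants["pos"].to_numpy()
        ref = variants["ref"].to_numpy()
        alt = variants["alt"].to_numpy()
        for j in range(V):
            cells = []
            for i in range(n):
                gt = _GT_CODE[int(G[i, j])]
                if with_support:
                    dp = int(depth[i, j])
                    ar = int(alt_reads[i, j])
                    cells.append(f"{gt}:{dp}:{max(dp - ar, 0)},{ar}")
                else:
                    cells.append(gt)
            f.write(
                f"{chrom[j]}\t{pos[j]}\t{vid.iloc[j]}\t{ref[j]}\t{alt[j]}\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path):
    """Read a biallelic VCF into a genotype matrix plus QC metrics.

    Returns ``(genotypes, variants, individual_ids, depth, alt_reads)``;
    ``genotypes`` is individuals x variants in {0,1,2,-1} (missing = -1),
    ``depth``/``alt_reads`` are None when the file has no DP/AD fields.
    A multiallelic record raises :class:`VCFParseError` directing the user
    to pre-split it.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    gts, rows, dps, ads = [], [], [], []
    for k, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise VCFParseError(
                f"{path}: record {k + 1} ({rec.CHROM}:{rec.POS}) is multiallelic; pre-split to biallelic records"
            )
        g = rec.gt_types.astype(np.int16)  # gts012: 0/1/2 and 3=unknown
        g[g == 3] = MISSING
        gts.append(g.astype(np.int8))
        vid = rec.ID if rec.ID not in (None, ".") else f"chr{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        rows.append(
            {
                "variant_id": vid,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        dps.append(None if dp is None else dp.reshape(-1).astype(np.int32))
        ads.append(None if ad is None else ad[:, 1].astype(np.int32))
    vcf.close()
    if not rows:
        return (
            np.empty((len(samples), 0), dtype=np.int8),
            pd.DataFrame(columns=["variant_id", "chrom", "pos", "ref", "alt"]),
            samples,
            None,
            None,
        )
    G = np.stack(gts, axis=1)
    variants = pd.DataFrame(rows)
    have_support = all(d is not None for d in dps) and all(a is not None for a in ads)
    depth = np.stack(dps, axis=1) if have_support else None
    alt_reads = np.stack(ads, axis=1) if have_support else None
    if alt_reads is not None:
        alt_reads = np.clip(alt_reads, 0, None)
    return G, variants, samples, depth, alt_reads


def read_cohort(directory):
    """Read back a cohort written by :func:`hlburden.synthetic.write_cohort`.

    Returns a dict of the component tables and matrices keyed like the file
    names (without extensions).
    """
    directory = Path(directory)
    G, variants, samples, depth, alt_reads = read_vcf(directory / "rare.vcf")
    covariates = read_table(directory / "covariates.tsv", "covariates")
    annotations = read_table(directory / "annotations.tsv", "annotations")
    common_variants = read_table(directory / "common_variants.tsv", "common_variants")
    dosage_df = pd.read_csv(
        directory / "common_dosages.tsv", sep="\t", dtype={"individual_id": str}, float_precision="round_trip"
    )
    dosages = dosage_df.drop(columns=["individual_id"]).to_numpy(np.float32)
    audiograms = read_table(directory / "audiograms.tsv", "audiograms")
    phecodes = (
        read_table(directory / "phecodes.tsv", "phecodes")
        if (directory / "phecodes.tsv").stat().st_size > 0
        else pd.DataFrame(columns=TABLE_SCHEMAS["phecodes"])
    )
    weights = read_table(directory / "prs_weights.tsv", "weights")
    truth_individuals = pd.read_csv(
        directory / "truth_individuals.tsv", sep="\t", dtype={"individual_id": str}, float_precision="round_trip"
    )
    truth_genes = pd.read_csv(directory / "truth_genes.tsv", sep="\t", float_precision="round_trip")
    return {
        "rare_genotypes": G,
        "rare_variants": variants,
        "rare_depth": depth,
        "rare_alt_reads": alt_reads,
        "vcf_samples": samples,
        "covariates": covariates,
        "annotations": annotations,
        "common_variants": common_variants,
        "common_dosages": dosages,
        "audiograms": audiograms,
        "phecodes": phecodes,
        "prs_weights": weights,
        "truth_individuals": truth_individuals,
        "truth_genes": truth_genes,
    }
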