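"""Synthetic biobank generator with known ground truth.

Emulates the data structure of an EHR-linked, exome-sequenced cohort used to
study adult-onset hearing loss: demographics and genetic PCs for a
two-component (European / African-American) ancestry mixture, rare exonic
variants with population-specific frequencies and deleteriousness
annotations (consequence class, REVEL, gnomAD reference frequencies,
ClinVar labels, per-genotype read support), imputed common-variant dosages
with imputation quality, per-frequency per-ear audiograms available for a
small liability-biased subset, and hearing-loss phecode billing records
whose case/control labels misclassify audiometric truth at configurable
rates.

The phenotype follows a liability model on the degree-HL scale:

    L = b_age * (age-58)/15 + b_sex * male + PC terms
        + beta_B * (truth-deleterious burden in known HL genes)
        + sum_g beta_g * burden_g + PRS + N(0, noise_sd)

Liability is mapped monotonically through its empirical quantile to a
worse-ear pure-tone average on [-10, 110] dB, from which per-ear,
per-frequency thresholds are emitted.  Phecode status is drawn conditionally
on audiogram positivity (PTA > 25 dB) so that the configured
misclassification structure — by default 65% of phecode cases and 27% of
phecode controls audiogram-positive among audiogram holders — is reproduced.

All randomness derives from one root seed through named substreams, so each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from hlburden.burden import load_known_genes

_STREAMS = {"individuals": 0, "rare": 1, "common": 2, "phenotype": 3, "prs": 4}

AUDIOGRAM_FREQUENCIES = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)
_FREQ_OFFSETS = {250.0: -6.0, 500.0: -4.0, 1000.0: 0.0, 2000.0: 4.0, 4000.0: 10.0, 8000.0: 16.0}
_PTA_FREQS = (500.0, 1000.0, 2000.0)
_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the source study's structure: n = 20,000, 51% male,
    ages uniform on 25-90 (median ~58), 75/25 European / African-American
    ancestry mixture, audiograms for 5.3% of the cohort enriched for hearing
    loss, and phecode labels calibrated so that 65% of phecode cases and 27%
    of phecode controls with audiograms are audiogram-positive.
    """

    n_individuals: int = 20_000
    seed: int = 0

    # demographics / ancestry mixture
    male_fraction: float = 0.51
    age_range: tuple = (25.0, 90.0)
    ancestry_labels: tuple = ("EUR", "AFR")
    ancestry_weights: tuple = (0.75, 0.25)
    pc1_means: tuple = (-0.012, 0.036)
    pc_sd: float = 0.01
    n_pcs: int = 20

    # rare variants
    n_extra_genes: int = 30
    variants_per_gene_mean: float = 12.0
    rare_af_log10_range: tuple = (-4.7, -2.3)
    ancestry_af_sigma: float = 0.5
    consequence_probs: dict = field(
        default_factory=lambda: {
            "frameshift": 0.06,
            "stop_gain": 0.06,
            "canonical_splice": 0.03,
            "missense": 0.55,
            "synonymous": 0.30,
        }
    )
    gnomad_af_sigma: float = 0.35
    gnomad_missing_prob: float = 0.15
    clinvar_pathogenic_prob: float = 0.05
    clinvar_benign_prob: float = 0.10
    depth_mean: float = 30.0
    low_depth_prob: float = 0.01
    low_depth_mean: float = 4.0
    low_support_het_prob: float = 0.03

    # common variants
    n_common_variants: int = 200
    common_maf_range: tuple = (0.05, 0.5)
    rsq_range: tuple = (0.2, 1.0)
    dosage_noise_sd: float = 0.08
    prs_causal_fraction: float = 0.5

    # liability effects (degree-HL scale)
    beta_total_burden: float = 0.05
    gene_betas: dict = field(default_factory=dict)
    beta_age: float = 0.65
    beta_sex: float = 0.15
    beta_pcs: tuple = ()
    prs_variance_share: float = 0.05
    noise_sd: float = 0.96

    # audiograms
    audiogram_fraction: float = 0.053
    audiogram_bias: float = 4.8
    population_positive_rate: float = 0.18
    pta_range: tuple = (-10.0, 110.0)
    ear_asymmetry_sd: float = 2.5
    threshold_noise_sd: float = 1.5
    exam_date: str = "2020-06-15"

    # phecodes (code 389, Hearing Loss)
    phecode: str = "389"
    audiopos_frac_cases: float = 0.65
    audiopos_frac_controls: float = 0.27
    case_rate_audiogram: float = 0.30
    control_rate_audiogram: float = 0.35
    pop_case_given_pos: float = 0.30
    pop_na_given_pos: float = 0.15
    pop_case_given_neg: float = 0.04
    pop_na_given_neg: float = 0.05

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ConfigurationError("n_individuals must be nonnegative")
        if abs(sum(self.ancestry_weights) - 1.0) > 1e-9:
            raise ConfigurationError("ancestry mixture weights must sum to 1")
        probs = [
            self.male_fraction,
            self.audiogram_fraction,
            self.population_positive_rate,
            self.audiopos_frac_cases,
            self.audiopos_frac_controls,
            self.case_rate_audiogram,
            self.control_rate_audiogram,
            self.pop_case_given_pos,
            self.pop_na_given_pos,
            self.pop_case_given_neg,
            self.pop_na_given_neg,
            self.prs_variance_share,
            *self.ancestry_weights,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if abs(sum(self.consequence_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("consequence probabilities must sum to 1")
        if not (0 < self.population_positive_rate < 1):
            raise ConfigurationError("population_positive_rate must lie in (0, 1)")

    @property
    def pta_shape(self) -> float:
        """Exponent of the quantile -> PTA map giving the configured positivity."""
        lo, hi = self.pta_range
        frac = (25.0 - lo) / (hi - lo)
        return float(np.log(frac) / np.log(1.0 - self.population_positive_rate))

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator derived from the root seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, _STREAMS[stream])))


@dataclass
class TruthRecord:
    """Ground truth retained by the generator for parameter-recovery tests."""

    gene_betas: pd.Series
    beta_total_burden: float
    prs_weights: pd.DataFrame
    liability: np.ndarray
    total_burden: pd.Series
    deleterious_variants: list
    prs_term: np.ndarray
    worse_pta: np.ndarray
    audiogram_positive: np.ndarray
    has_audiogram: np.ndarray
    phecode_status: np.ndarray


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    covariates: pd.DataFrame
    rare_genotypes: np.ndarray
    rare_variants: pd.DataFrame
    rare_depth: np.ndarray
    rare_alt_reads: np.ndarray
    common_dosages: np.ndarray
    common_variants: pd.DataFrame
    audiograms: pd.DataFrame
    phecodes: pd.DataFrame
    truth: TruthRecord

    @property
    def individual_ids(self) -> pd.Index:
        return pd.Index(self.covariates["individual_id"])

    def alt_fraction(self) -> np.ndarray:
        """Per-genotype alternate-read fraction (0 where depth is 0)."""
        depth = self.rare_depth.astype(np.float32)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, self.rare_alt_reads / np.maximum(depth, 1), 0.0)
        return frac.astype(np.float32)


def simulate_individuals(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Covariate table: sex, age, ancestry label, genetic PCs 1-20."""
    rng = rng or config.rng("individuals")
    n = config.n_individuals
    cols = ["individual_id", "sex", "age", "ancestry"] + [f"PC{i}" for i in range(1, config.n_pcs + 1)]
    if n == 0:
        return pd.DataFrame(columns=cols)
    ids = [f"IND{i:06d}" for i in range(1, n + 1)]
    sex = (rng.random(n) < config.male_fraction).astype(int)
    age = rng.uniform(*config.age_range, size=n)
    anc_idx = rng.choice(len(config.ancestry_labels), size=n, p=list(config.ancestry_weights))
    ancestry = np.array(config.ancestry_labels)[anc_idx]
    pcs = rng.normal(0.0, config.pc_sd, size=(n, config.n_pcs))
    pcs[:, 0] += np.array(config.pc1_means)[anc_idx]
    out = pd.DataFrame({"individual_id": ids, "sex": sex, "age": age, "ancestry": ancestry})
    for i in range(config.n_pcs):
        out[f"PC{i + 1}"] = pcs[:, i]
    return out


def _gene_table(config: GeneratorConfig) -> pd.DataFrame:
    genes = load_known_genes()
    if config.n_extra_genes:
        extra = pd.DataFrame(
            {
                "gene_id": [f"NOVG{i + 1:03d}" for i in range(config.n_extra_genes)],
                "inheritance_class": "novel",
            }
        )
        genes = pd.concat([genes, extra], ignore_index=True)
    return genes


def simulate_rare_genotypes(config: GeneratorConfig, covariates: pd.DataFrame, rng=None):
    """Rare genotype matrix, annotation table and per-genotype read support.

    Per gene a variant count is drawn (1 + Poisson), each variant gets a
    log-uniform base allele frequency with lognormal ancestry-specific
    shifts, and genotypes are Binomial(2, AF) within ancestry.  Annotations
    carry consequence class, REVEL (missense only), gnomAD AFR/NFE AFs
    correlated with the simulated frequencies, and sparse ClinVar labels.

    Returns ``(genotypes int8, annotations, depth int16, alt_reads int16)``.
    """
    if not len(covariates):
        raise ConfigurationError("covariates table is empty")
    rng = rng or config.rng("rare")
    n = len(covariates)
    genes = _gene_table(config)
    n_var_per_gene = 1 + rng.poisson(max(config.variants_per_gene_mean - 1.0, 0.0), size=len(genes))
    gene_ids = np.repeat(genes["gene_id"].to_numpy(), n_var_per_gene)
    V = int(n_var_per_gene.sum())

    lo, hi = config.rare_af_log10_range
    base_af = 10 ** rng.uniform(lo, hi, size=V)
    sig = config.ancestry_af_sigma
    af_by_pop = {}
    for pop in config.ancestry_labels:
        mult = rng.lognormal(-0.5 * sig**2, sig, size=V)
        af_by_pop[pop] = np.clip(base_af * mult, 1e-6, 0.05)

    chrom = (np.arange(V) % 22) + 1
    pos = 1_000_000 + np.arange(V) * 137
    ref_idx = rng.integers(0, 4, size=V)
    alt_idx = (ref_idx + rng.integers(1, 4, size=V)) % 4
    ref, alt = _BASES[ref_idx], _BASES[alt_idx]
    variant_id = np.array([f"chr{c}:{p}:{r}:{a}" for c, p, r, a in zip(chrom, pos, ref, alt)])

    cons_names = list(config.consequence_probs)
    cons = rng.choice(cons_names, size=V, p=[config.consequence_probs[c] for c in cons_names])
    revel = np.where(cons == "missense", rng.uniform(0.0, 1.0, size=V), np.nan)

    gsig = config.gnomad_af_sigma
    gnomad_afr = np.clip(af_by_pop[config.ancestry_labels[-1]] * rng.lognormal(-0.5 * gsig**2, gsig, V), 0, 1)
    gnomad_nfe = np.clip(af_by_pop[config.ancestry_labels[0]] * rng.lognormal(-0.5 * gsig**2, gsig, V), 0, 1)
    # variants absent from the reference database (novel); downstream filters treat them as AF 0
    absent = rng.random(V) < config.gnomad_missing_prob
    gnomad_afr[absent] = np.nan
    gnomad_nfe[absent] = np.nan

    deleterious = np.isin(cons, ("frameshift", "stop_gain", "canonical_splice")) | (
        (cons == "missense") & (np.nan_to_num(revel) > 0.6)
    )
    clinvar = np.full(V, "", dtype=object)
    u = rng.random(V)
    path_lbl = rng.choice(["Pathogenic", "Likely pathogenic"], size=V)
    clinvar[deleterious & (u < config.clinvar_pathogenic_prob)] = path_lbl[
        deleterious & (u < config.clinvar_pathogenic_prob)
    ]
    benign = (u >= config.clinvar_pathogenic_prob) & (
        u < config.clinvar_pathogenic_prob + config.clinvar_benign_prob
    )
    clinvar[benign] = "Benign"

    anc = covariates["ancestry"].to_numpy()
    G = np.empty((n, V), dtype=np.int8)
    depth = np.empty((n, V), dtype=np.int16)
    alt_reads = np.empty((n, V), dtype=np.int16)
    for start in range(0, V, 512):
        end = min(start + 512, V)
        block = np.empty((n, end - start), dtype=np.int8)
        for pop in config.ancestry_labels:
            idx = np.flatnonzero(anc == pop)
            if idx.size:
                block[idx] = rng.binomial(2, af_by_pop[pop][start:end], size=(idx.size, end - start)).astype(np.int8)
        G[:, start:end] = block
        low = rng.random((n, end - start)) < config.low_depth_prob
        d = np.where(
            low,
            rng.poisson(config.low_depth_mean, size=(n, end - start)),
            rng.poisson(config.depth_mean, size=(n, end - start)),
        ).astype(np.int16)
        depth[:, start:end] = d
        p = np.full((n, end - start), 0.005, dtype=np.float32)  # sequencing-error floor
        het = block == 1
        if het.any():
            p_het = np.where(
                rng.random(int(het.sum())) < config.low_support_het_prob,
                rng.beta(2.0, 30.0, size=int(het.sum())),
                rng.beta(20.0, 20.0, size=int(het.sum())),
            )
            p[het] = p_het
        hom = block == 2
        if hom.any():
            p[hom] = rng.beta(40.0, 2.0, size=int(hom.sum()))
        alt_reads[:, start:end] = rng.binomial(d.astype(np.int64), p).astype(np.int16)

    annotations = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene_id": gene_ids,
            "consequence": cons,
            "revel": revel,
            "gnomad_afr_af": gnomad_afr,
            "gnomad_nfe_af": gnomad_nfe,
            "clinvar": clinvar,
        }
    )
    for pop in config.ancestry_labels:
        annotations[f"true_af_{pop}"] = af_by_pop[pop]
    return G, annotations, depth, alt_reads


def simulate_common_genotypes(config: GeneratorConfig, covariates: pd.DataFrame, rng=None):
    """Common-variant dosage matrix in [0,2] with per-variant imputation quality."""
    if not len(covariates):
        raise ConfigurationError("covariates table is empty")
    rng = rng or config.rng("common")
    n, m = len(covariates), config.n_common_variants
    maf = rng.uniform(*config.common_maf_range, size=m)
    g = rng.binomial(2, maf, size=(n, m))
    dosage = np.clip(g + rng.normal(0.0, config.dosage_noise_sd, size=(n, m)), 0.0, 2.0).astype(np.float32)
    rsq = rng.uniform(*config.rsq_range, size=m)
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref, alt = _BASES[ref_idx], _BASES[alt_idx]
    chrom = (np.arange(m) % 22) + 1
    pos = 50_000_000 + np.arange(m) * 9973
    variants = pd.DataFrame(
        {
            "variant_id": [f"chr{c}:{p}:{r}:{a}" for c, p, r, a in zip(chrom, pos, ref, alt)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "af": maf,
            "rsq": rsq,
        }
    )
    return dosage, variants


def _truth_burden(G: np.ndarray, annotations: pd.DataFrame, known_genes: set) -> tuple[pd.Series, np.ndarray, pd.DataFrame]:
    """Truth-deleterious per-gene burdens and the known-gene total."""
    revel = annotations["revel"].to_numpy(float)
    cons = annotations["consequence"].to_numpy()
    deleterious = np.isin(cons, ("frameshift", "stop_gain", "canonical_splice")) | (
        (cons == "missense") & (np.nan_to_num(revel) > 0.6)
    )
    counts = np.maximum(G, 0)
    in_known = annotations["gene_id"].isin(known_genes).to_numpy()
    total = counts[:, deleterious & in_known].sum(axis=1)
    per_gene = {}
    for gene, grp in annotations.loc[deleterious].groupby("gene_id"):
        per_gene[gene] = counts[:, grp.index.to_numpy()].sum(axis=1)
    return pd.Series(total, name="total_burden"), deleterious, pd.DataFrame(per_gene)


def _solve_status_probs(pi: float, frac_pos_case: float, frac_pos_ctrl: float, case_rate: float, ctrl_rate: float):
    """Conditional P(case|A), P(control|A) reproducing the target positivity fractions.

    Solves Bayes' rule within the audiogram subset given its realised
    positivity ``pi``; probabilities are clipped to the simplex (scaled down
    proportionally if case+control exceed 1 in a stratum, NA absorbing the
    remainder).
    """
    pi = min(max(pi, 1e-9), 1 - 1e-9)
    q1 = frac_pos_case * case_rate / pi
    q0 = (1 - frac_pos_case) * case_rate / (1 - pi)
    g1 = frac_pos_ctrl * ctrl_rate / pi
    g0 = (1 - frac_pos_ctrl) * ctrl_rate / (1 - pi)
    out = []
    for q, g in ((q1, g1), (q0, g0)):
        q, g = max(q, 0.0), max(g, 0.0)
        if q + g > 1.0:
            s = 1.0 / (q + g)
            q, g = q * s, g * s
        out.append((q, g))
    return out  # [(case|pos, control|pos), (case|neg, control|neg)]


def _quota_statuses(n: int, p_case: float, p_ctrl: float, rng) -> np.ndarray:
    """Largest-remainder allocation of case/control/NA statuses, shuffled."""
    probs = np.array([p_case, p_ctrl, max(1.0 - p_case - p_ctrl, 0.0)])
    raw = probs * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i % 3]] += 1
    statuses = np.repeat(np.array(["case", "control", "NA"]), base)
    rng.shuffle(statuses)
    return statuses


def simulate_phenotypes(
    config: GeneratorConfig,
    covariates: pd.DataFrame,
    total_burden: np.ndarray,
    gene_burdens: pd.DataFrame,
    prs_term: np.ndarray,
    rng=None,
):
    """Liability, audiograms for a biased subset, and calibrated phecode records.

    Returns ``(audiograms, phecodes, extras)`` where ``extras`` carries the
    latent liability, the internal worse-ear PTA for every individual,
    audiogram positivity, the audiogram-subset indicator and phecode status.
    """
    rng = rng or config.rng("phenotype")
    n = len(covariates)
    if len(total_burden) != n or len(prs_term) != n:
        raise ValueError("burden/PRS vectors must align with covariates")

    age_c = (covariates["age"].to_numpy(float) - 58.0) / 15.0
    sex = covariates["sex"].to_numpy(float)
    liability = config.beta_age * age_c + config.beta_sex * sex
    if config.beta_pcs:
        for i, b in enumerate(config.beta_pcs):
            liability = liability + b * covariates[f"PC{i + 1}"].to_numpy(float)
    liability = liability + config.beta_total_burden * np.asarray(total_burden, float)
    for gene, beta in config.gene_betas.items():
        if gene in gene_burdens.columns:
            liability = liability + beta * gene_burdens[gene].to_numpy(float)
    liability = liability + np.asarray(prs_term, float)
    liability = liability + rng.normal(0.0, config.noise_sd, size=n)

    # monotone liability-quantile -> PTA map, calibrated population positivity
    u = (np.argsort(np.argsort(liability)) + 0.5) / n
    lo, hi = config.pta_range
    base_pta = lo + (hi - lo) * u**config.pta_shape

    ear_pta = {}
    thresholds = {}
    for ear in ("left", "right"):
        shift = rng.normal(0.0, config.ear_asymmetry_sd, size=n)
        t_ear = {}
        for f in AUDIOGRAM_FREQUENCIES:
            t = base_pta + shift + _FREQ_OFFSETS[f] + rng.normal(0.0, config.threshold_noise_sd, size=n)
            t_ear[f] = np.clip(np.round(t), -10, 120)
        thresholds[ear] = t_ear
        ear_pta[ear] = np.mean([t_ear[f] for f in _PTA_FREQS], axis=0)
    worse_pta = np.maximum(ear_pta["left"], ear_pta["right"])
    positive = worse_pta > 25.0

    # liability-biased audiogram availability
    w = np.exp(config.audiogram_bias * u)
    p_sel = np.clip(config.audiogram_fraction * w / w.mean(), 0.0, 1.0)
    has_aud = rng.random(n) < p_sel

    # phecode status: quota-calibrated inside the audiogram subset
    status = np.full(n, "", dtype=object)
    sub = np.flatnonzero(has_aud)
    if sub.size:
        pi = float(positive[sub].mean())
        (c_pos, g_pos), (c_neg, g_neg) = _solve_status_probs(
            pi,
            config.audiopos_frac_cases,
            config.audiopos_frac_controls,
            config.case_rate_audiogram,
            config.control_rate_audiogram,
        )
        for mask, (pc, pg) in (
            (sub[positive[sub]], (c_pos, g_pos)),
            (sub[~positive[sub]], (c_neg, g_neg)),
        ):
            status[mask] = _quota_statuses(len(mask), pc, pg, rng)
    out = np.flatnonzero(~has_aud)
    if out.size:
        r = rng.random(out.size)
        pos_out = positive[out]
        pc = np.where(pos_out, config.pop_case_given_pos, config.pop_case_given_neg)
        pna = np.where(pos_out, config.pop_na_given_pos, config.pop_na_given_neg)
        status[out] = np.where(r < pc, "case", np.where(r < pc + pna, "NA", "control"))

    # emit tables
    ids = covariates["individual_id"].to_numpy()
    aud_rows = []
    gap = np.clip(rng.normal(5.0, 3.0, size=n), 0.0, None)
    for ear in ("left", "right"):
        for f in AUDIOGRAM_FREQUENCIES:
            aud_rows.append(
                pd.DataFrame(
                    {
                        "individual_id": ids[sub],
                        "date": config.exam_date,
                        "ear": ear,
                        "conduction": "air",
                        "frequency_hz": f,
                        "threshold_db": thresholds[ear][f][sub],
                    }
                )
            )
        for f in _PTA_FREQS:
            aud_rows.append(
                pd.DataFrame(
                    {
                        "individual_id": ids[sub],
                        "date": config.exam_date,
                        "ear": ear,
                        "conduction": "bone",
                        "frequency_hz": f,
                        "threshold_db": np.clip(np.round(thresholds[ear][f][sub] - gap[sub]), -10, 120),
                    }
                )
            )
    audiograms = (
        pd.concat(aud_rows, ignore_index=True)
        if aud_rows
        else pd.DataFrame(columns=["individual_id", "date", "ear", "conduction", "frequency_hz", "threshold_db"])
    )

    counts = np.where(status == "case", 2 + rng.poisson(1.5, size=n), np.where(status == "NA", 1, 0))
    rep = np.repeat(np.arange(n), counts)
    phecodes = pd.DataFrame(
        {"individual_id": ids[rep], "phecode": config.phecode, "date": config.exam_date}
    )

    extras = {
        "liability": liability,
        "worse_pta": worse_pta,
        "audiogram_positive": positive,
        "has_audiogram": has_aud,
        "phecode_status": status,
    }
    return audiograms, phecodes, extras


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort with ground truth."""
    covariates = simulate_individuals(config)
    if not len(covariates):
        raise ConfigurationError("cannot generate a cohort with zero individuals")
    G, annotations, depth, alt_reads = simulate_rare_genotypes(config, covariates)
    dosages, common = simulate_common_genotypes(config, covariates)

    known = set(load_known_genes()["gene_id"])
    total, deleterious_mask, per_gene = _truth_burden(G, annotations, known)
    per_gene.index = covariates.index

    # PRS term scaled to the configured liability variance share
    rng = config.rng("prs")
    m = config.n_common_variants
    n_causal = max(int(round(config.prs_causal_fraction * m)), 1)
    causal = rng.choice(m, size=n_causal, replace=False)
    w = np.zeros(m)
    w[causal] = rng.normal(0.0, 1.0, size=n_causal)
    centered = dosages - dosages.mean(axis=0, keepdims=True)
    prs_raw = centered @ w
    age_c = (covariates["age"].to_numpy(float) - 58.0) / 15.0
    base = config.beta_age * age_c + config.beta_sex * covariates["sex"].to_numpy(float)
    if config.beta_pcs:
        for i, b in enumerate(config.beta_pcs):
            base = base + b * covariates[f"PC{i + 1}"].to_numpy(float)
    base = base + config.beta_total_burden * total.to_numpy(float)
    for gene, beta in config.gene_betas.items():
        if gene in per_gene.columns:
            base = base + beta * per_gene[gene].to_numpy(float)
    var_other = float(np.var(base)) + config.noise_sd**2
    share = config.prs_variance_share
    if share > 0 and np.var(prs_raw) > 0:
        target = share / (1.0 - share) * var_other
        w *= np.sqrt(target / np.var(prs_raw))
        prs_term = centered @ w
    else:
        w[:] = 0.0
        prs_term = np.zeros(len(covariates))

    audiograms, phecodes, extras = simulate_phenotypes(
        config, covariates, total.to_numpy(), per_gene, prs_term
    )

    weights = pd.DataFrame(
        {
            "variant_id": common["variant_id"],
            "effect_allele": common["alt"],
            "other_allele": common["ref"],
            "weight": w,
        }
    )
    truth = TruthRecord(
        gene_betas=pd.Series(config.gene_betas, dtype=float),
        beta_total_burden=config.beta_total_burden,
        prs_weights=weights,
        liability=extras["liability"],
        total_burden=pd.Series(total.to_numpy(), index=covariates["individual_id"], name="total_burden"),
        deleterious_variants=annotations.loc[deleterious_mask, "variant_id"].tolist(),
        prs_term=prs_term,
        worse_pta=extras["worse_pta"],
        audiogram_positive=extras["audiogram_positive"],
        has_audiogram=extras["has_audiogram"],
        phecode_status=extras["phecode_status"],
    )
    return SyntheticCohort(
        config=config,
        covariates=covariates,
        rare_genotypes=G,
        rare_variants=annotations,
        rare_depth=depth,
        rare_alt_reads=alt_reads,
        common_dosages=dosages,
        common_variants=common,
        audiograms=audiograms,
        phecodes=phecodes,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as plain-text files (VCF + TSV) with a checksum manifest."""
    from hlburden.io import write_vcf  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = list(cohort.covariates["individual_id"])
    files = {}

    write_vcf(
        directory / "rare.vcf",
        cohort.rare_genotypes,
        cohort.rare_variants,
        ids,
        depth=cohort.rare_depth,
        alt_reads=cohort.rare_alt_reads,
    )
    files["rare.vcf"] = None

    def _tsv(name, df, float_format="%.10g"):
        df.to_csv(directory / name, sep="\t", index=False, float_format=float_format)
        files[name] = None

    _tsv("covariates.tsv", cohort.covariates, "%.17g")
    _tsv("annotations.tsv", cohort.rare_variants, "%.17g")
    _tsv("common_variants.tsv", cohort.common_variants, "%.17g")
    dosage_df = pd.DataFrame(
        cohort.common_dosages, columns=cohort.common_variants["variant_id"]
    )
    dosage_df.insert(0, "individual_id", ids)
    _tsv("common_dosages.tsv", dosage_df, "%.9g")
    _tsv("audiograms.tsv", cohort.audiograms, "%.10g")
    _tsv("phecodes.tsv", cohort.phecodes)
    _tsv("prs_weights.tsv", cohort.truth.prs_weights, "%.17g")
    truth_ind = pd.DataFrame(
        {
            "individual_id": ids,
            "liability": cohort.truth.liability,
            "total_burden": cohort.truth.total_burden.to_numpy(),
            "worse_pta": cohort.truth.worse_pta,
            "has_audiogram": cohort.truth.has_audiogram.astype(int),
            "phecode_status": cohort.truth.phecode_status,
        }
    )
    _tsv("truth_individuals.tsv", truth_ind, "%.17g")
    truth_genes = cohort.truth.gene_betas.rename_axis("gene_id").rename("beta").reset_index()
    _tsv("truth_genes.tsv", truth_genes, "%.17g")

    manifest = {"n_individuals": len(ids), "seed": cohort.config.seed, "files": {}}
    for name in files:
        digest = hashlib.sha256((directory / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
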