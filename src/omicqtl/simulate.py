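"""Synthetic cohort generator with known ground truth.

Genotypes come from a founder-mosaic model: a small pool of founder
haplotypes is copied block-wise into sample haplotypes, with a fixed
switch probability between adjacent blocks. Haplotype sharing inside a
block produces strong local LD; switching between blocks makes LD decay
with block distance. Offspring haplotypes are block-level transmissions
from in-family parents, which induces realistic kinship. This is a
deliberate simplification of a coalescent: it gives tunable block LD and
family structure, which is all the pipeline's statistics consume.

Phenotypes follow the same generative structure the mapping model
assumes: planted cis effects on a latent trait, hidden confounders,
a kinship-correlated polygenic term, independent noise, and a
Poisson-log-normal observation layer with per-sample library sizes.
"""
from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ConfigurationError,
    GenotypePanel,
    GroundTruth,
    GwasSummary,
    PhenotypeSet,
)

logger = logging.getLogger(__name__)

#: cis-window half-width in bp by phenotype type (genes 1 Mb, peaks 100 kb)
CIS_WINDOW = {"expression": 1_000_000, "accessibility": 100_000, "acetylation": 100_000}


def _sample_paths(rng, n_hap: int, n_blocks: int, n_founders: int, recomb: float):
    """Markov-chain founder indices, one per (haplotype, block)."""
    paths = np.empty((n_hap, n_blocks), dtype=np.int64)
    paths[:, 0] = rng.integers(0, n_founders, size=n_hap)
    for b in range(1, n_blocks):
        switch = rng.random(n_hap) < recomb
        paths[:, b] = np.where(switch, rng.integers(0, n_founders, size=n_hap), paths[:, b - 1])
    return paths


def simulate_genotype_panel(
    n_founder_haplotypes: int,
    n_samples: int,
    family_spec: list[int] | None = None,
    n_blocks: int = 10,
    variants_per_block: int = 20,
    recomb_between_blocks: float = 0.1,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: str = "chr1",
    within_block_spacing: int = 500,
    between_block_gap: int = 50_000,
) -> GenotypePanel:
    """Simulate a family-structured genotype panel with block LD.

    Parameters
    ----------
    n_founder_haplotypes
        Size of the founder haplotype pool. Smaller pools give stronger
        within-block LD (two haplotypes give |r| = 1 at all polymorphic
        pairs).
    family_spec
        Sizes of nuclear families; each family contributes two founder
        parents and ``size - 2`` offspring. Remaining samples are
        unrelated founders.
    recomb_between_blocks
        Probability of switching founder haplotype between adjacent
        blocks; 0.5 makes blocks independent.
    """
    if min(n_founder_haplotypes, n_samples, n_blocks, variants_per_block) < 1:
        raise ConfigurationError("all counts must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ConfigurationError("maf_range must be within (0, 0.5]")
    family_spec = list(family_spec or [])
    if sum(family_spec) > n_samples:
        raise ConfigurationError(
            f"family sizes sum to {sum(family_spec)} > n_samples {n_samples}"
        )
    if any(s < 2 for s in family_spec):
        raise ConfigurationError("family sizes must be >= 2")

    rng = np.random.default_rng(seed)
    n_variants = n_blocks * variants_per_block
    block_of_variant = np.repeat(np.arange(n_blocks), variants_per_block)

    # founder pool alleles: Bernoulli(f_v) with f_v uniform in maf_range
    freqs = rng.uniform(lo, hi, size=n_variants)
    founders = (rng.random((n_founder_haplotypes, n_variants)) < freqs).astype(np.int8)

    samples = []
    # population haplotype paths for founder individuals
    n_offspring = sum(max(s - 2, 0) for s in family_spec)
    n_founder_ind = n_samples - n_offspring
    founder_paths = _sample_paths(
        rng, 2 * n_founder_ind, n_blocks, n_founder_haplotypes, recomb_between_blocks
    )

    paths = np.empty((2 * n_samples, n_blocks), dtype=np.int64)
    fi = 0  # founder-individual cursor
    si = 0  # sample cursor
    for fam_id, size in enumerate(family_spec):
        parents = []
        for p in range(2):
            paths[2 * si] = founder_paths[2 * fi]
            paths[2 * si + 1] = founder_paths[2 * fi + 1]
            samples.append((f"fam{fam_id}_p{p}", f"fam{fam_id}", "founder"))
            parents.append(si)
            fi += 1
            si += 1
        for o in range(size - 2):
            for h, parent in enumerate(parents):
                # block-level meiosis: walk over the parent's two haplotypes
                which = np.empty(n_blocks, dtype=np.int64)
                which[0] = rng.integers(0, 2)
                for b in range(1, n_blocks):
                    if rng.random() < recomb_between_blocks:
                        which[b] = rng.integers(0, 2)
                    else:
                        which[b] = which[b - 1]
                paths[2 * si + h] = paths[2 * parent + which, np.arange(n_blocks)]
            samples.append((f"fam{fam_id}_o{o}", f"fam{fam_id}", "offspring"))
            si += 1
    while si < n_samples:
        paths[2 * si] = founder_paths[2 * fi]
        paths[2 * si + 1] = founder_paths[2 * fi + 1]
        samples.append((f"ind{si}", f"solo{si}", "founder"))
        fi += 1
        si += 1

    def realize(founder_alleles: np.ndarray) -> np.ndarray:
        hap = founder_alleles[paths[:, block_of_variant], np.arange(n_variants)]
        return (hap[0::2] + hap[1::2]).astype(np.int8)

    dosages = realize(founders)
    # redraw columns that came out monomorphic so the AF invariant holds
    for _ in range(100):
        mono = (dosages.min(axis=0) == dosages.max(axis=0)).nonzero()[0]
        if mono.size == 0:
            break
        freqs[mono] = rng.uniform(lo, hi, size=mono.size)
        founders[:, mono] = (
            rng.random((n_founder_haplotypes, mono.size)) < freqs[mono]
        ).astype(np.int8)
        dosages = realize(founders)
    else:  # pragma: no cover - pathological configs only
        raise ConfigurationError("could not realize polymorphic variants")

    pos = np.empty(n_variants, dtype=np.int64)
    block_span = variants_per_block * within_block_spacing
    for b in range(n_blocks):
        start = 1 + b * (block_span + between_block_gap)
        pos[block_of_variant == b] = start + np.arange(variants_per_block) * within_block_spacing

    variants = pd.DataFrame(
        {
            "id": [f"var{i}" for i in range(n_variants)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "af": dosages.mean(axis=0) / 2.0,
        }
    )
    sample_df = pd.DataFrame(samples, columns=["id", "family", "role"])
    return GenotypePanel(dosages, variants, sample_df)


@dataclass
class EffectSpec:
    """One planted cis effect on one element (latent-SD units)."""

    element: str
    variant: str
    beta: float
    temporal_class: str = "shared"
    shared_group: str | None = None


SimulatedPhenotypes = namedtuple("SimulatedPhenotypes", "phenotypes truth latent")


def realized_kinship(panel: GenotypePanel) -> np.ndarray:
    """GRM Z Z'/m from standardized dosages (no pruning; simulator-side)."""
    d = panel.dosages.astype(float)
    p = d.mean(axis=0) / 2.0
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    return z @ z.T / z.shape[1]


def simulate_phenotypes(
    panel: GenotypePanel,
    elements: pd.DataFrame,
    design: list[EffectSpec],
    n_hidden_factors: int = 0,
    factor_sd: float = 0.0,
    polygenic_sd: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    base_log_mean: float = np.log(100.0),
    count_scale: float = 0.25,
    library_size_sd: float = 0.3,
) -> SimulatedPhenotypes:
    """Simulate count phenotypes with planted cis effects.

    The latent trait per element is the sum of planted standardized-
    genotype effects, hidden-factor contributions (factor values are
    standard normal per sample; element loadings are N(0, factor_sd^2)),
    a polygenic term MVN(0, polygenic_sd^2 K) with K the realized GRM,
    and N(0, noise_sd^2) noise. Counts are Poisson with rate
    ``lib_i * exp(base + count_scale * latent)`` and log-normal library
    sizes, an overdispersed model adequate for a pipeline that consumes
    only TMM + inverse-normal values.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    n_el = len(elements)
    el_index = {e: i for i, e in enumerate(elements["id"])}
    var_meta = panel.variants.set_index("id")

    for spec in design:
        el = elements.loc[elements["id"] == spec.element]
        if el.empty:
            raise ConfigurationError(f"unknown element {spec.element!r}")
        el = el.iloc[0]
        w = CIS_WINDOW[el["phenotype_type"]]
        vpos = var_meta.loc[spec.variant, "pos"]
        if not (el["start"] - w <= vpos <= el["end"] + w):
            raise ConfigurationError(
                f"causal variant {spec.variant} outside cis window of {spec.element}"
            )

    latent = np.zeros((n_el, n))
    for spec in design:
        g = panel.genotypes(spec.variant)
        gz = (g - g.mean()) / g.std()
        latent[el_index[spec.element]] += spec.beta * gz

    if n_hidden_factors > 0 and factor_sd > 0:
        factors = rng.standard_normal((n_hidden_factors, n))
        loadings = rng.normal(0.0, factor_sd, size=(n_el, n_hidden_factors))
        latent += loadings @ factors
    else:
        factors = np.zeros((0, n))

    if polygenic_sd > 0:
        K = realized_kinship(panel)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        latent += polygenic_sd * (rng.standard_normal((n_el, n)) @ L.T)

    if noise_sd > 0:
        latent += rng.normal(0.0, noise_sd, size=(n_el, n))

    lib = np.exp(rng.normal(0.0, library_size_sd, size=n))
    rate = lib[None, :] * np.exp(base_log_mean + count_scale * latent)
    counts = rng.poisson(rate).astype(np.int64)

    pheno = PhenotypeSet(
        counts=counts,
        elements=elements.reset_index(drop=True),
        sample_ids=list(panel.samples["id"]),
        library_sizes=counts.sum(axis=0).astype(float) + 1.0,
    )
    shared_groups: dict[str, list[str]] = {}
    for spec in design:
        if spec.shared_group is not None:
            shared_groups.setdefault(spec.shared_group, []).append(spec.element)
    truth = GroundTruth(
        causal_effects=[
            {
                "element": s.element,
                "variant": s.variant,
                "beta": s.beta,
                "temporal_class": s.temporal_class,
                "shared_group": s.shared_group,
            }
            for s in design
        ],
        shared_groups=shared_groups,
        temporal_classes={s.element: s.temporal_class for s in design},
    )
    return SimulatedPhenotypes(pheno, truth, latent)


def simulate_gwas_summary(
    panel: GenotypePanel,
    region: list[str],
    joint_effects: dict[str, float],
    n_gwas: int,
    seed: int = 0,
    trait: str = "trait",
    ridge_eps: float = 1e-6,
) -> GwasSummary:
    """Simulate GWAS summary statistics from the region's LD structure.

    z ~ MVN(sqrt(N) R b, R) with R the dosage correlation matrix of the
    reference panel and b the standardized joint effects; betas are
    recovered via se = 1 / sqrt(2 N p (1 - p)).
    """
    idx = panel.variant_index(region)
    if (idx < 0).any():
        missing = [v for v, i in zip(region, idx) if i < 0]
        raise ConfigurationError(f"region variants absent from panel: {missing}")
    rng = np.random.default_rng(seed)
    d = panel.dosages[:, idx].astype(float)
    R = np.corrcoef(d, rowvar=False)
    R = np.atleast_2d(R)
    b = np.array([joint_effects.get(v, 0.0) for v in region])
    mean = np.sqrt(n_gwas) * R @ b
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        logger.warning("ill-conditioned LD matrix; ridge-regularizing with eps=%g", ridge_eps)
        R_reg = R + ridge_eps * np.eye(len(region))
        R_reg /= np.sqrt(np.outer(np.diag(R_reg), np.diag(R_reg)))
        L = np.linalg.cholesky(R_reg)
    z = mean + L @ rng.standard_normal(len(region))
    p_allele = panel.variants["af"].to_numpy()[idx]
    se = 1.0 / np.sqrt(2.0 * n_gwas * p_allele * (1.0 - p_allele))
    beta = z * se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"variant": region, "beta": beta, "se": se, "p": pvals, "n": n_gwas}
    )
    return GwasSummary(table=table, trait=trait)


AnnotationSet = namedtuple("AnnotationSet", "peaks motifs states genes fixtures")


def simulate_annotations(
    panel: GenotypePanel,
    mopcv_fixtures: list[str],
    seed: int = 0,
    peak_halfwidth: int = 150,
    motif_halfwidth: int = 8,
) -> AnnotationSet:
    """Build interval annotations whose correct MOPCV rank is known.

    For each requested label the generator picks a distinct panel variant
    and constructs the peak/motif/credible-set geometry that defines that
    label: High = the variant sits in its own caQTL's caPeak; Moderate =
    it sits in the caPeak of a *different* caQTL signal; Low = it only
    overlaps an accessibility peak carrying no caQTL. All intervals are
    0-based half-open (BED); variants are 1-based.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(panel.n_variants)
    peaks, motifs, states, fixtures = [], [], [], []
    chrom = panel.variants["chrom"].iloc[0]
    cursor = 0

    def interval(pos: int, half: int) -> tuple[int, int]:
        return max(pos - 1 - half, 0), pos - 1 + half + 1

    for k, label in enumerate(mopcv_fixtures):
        if label not in ("High", "Moderate", "Low"):
            raise ConfigurationError(f"unknown MOPCV rank label {label!r}")
        vrow = panel.variants.iloc[order[cursor]]
        cursor += 1
        vid, pos = vrow["id"], int(vrow["pos"])
        s, e = interval(pos, peak_halfwidth)
        signal = f"caqtl_sig{k}"
        own_peak = f"capeak{k}"
        credible = {signal: [vid]}
        if label == "High":
            peaks.append((chrom, s, e, own_peak, signal))
            capeak_of = {signal: own_peak}
        elif label == "Moderate":
            other = f"caqtl_sig{k}_other"
            other_peak = f"capeak{k}_other"
            # variant lies in the OTHER signal's caPeak; its own caPeak is elsewhere
            peaks.append((chrom, s, e, other_peak, other))
            far = pos + 10 * peak_halfwidth
            peaks.append((chrom, far, far + 2 * peak_halfwidth, own_peak, signal))
            capeak_of = {signal: own_peak, other: other_peak}
            credible[other] = []
        else:  # Low: plain accessibility peak with no caQTL behind it
            peaks.append((chrom, s, e, f"atac_peak{k}", ""))
            far = pos + 10 * peak_halfwidth
            peaks.append((chrom, far, far + 2 * peak_halfwidth, own_peak, signal))
            capeak_of = {signal: own_peak}
        ms, me = interval(pos, motif_halfwidth)
        motifs.append((chrom, ms, me, f"motif{k}", 1))
        states.append((chrom, s, e, "EnhA1"))
        fixtures.append(
            {
                "variant": vid,
                "expected_rank": label,
                "credible_sets": credible,
                "capeak_of_signal": capeak_of,
            }
        )

    peaks_df = pd.DataFrame(peaks, columns=["chrom", "start", "end", "name", "signal"])
    motifs_df = pd.DataFrame(motifs, columns=["chrom", "start", "end", "name", "bound"])
    states_df = pd.DataFrame(states, columns=["chrom", "start", "end", "state"])
    genes_df = pd.DataFrame(columns=["chrom", "start", "end", "name", "strand", "tss"])
    return AnnotationSet(peaks_df, motifs_df, states_df, genes_df, fixtures)


def simulate_lfsr_matrix(
    pairs: list[str],
    classes: dict[str, str],
    edev_tissues: list[str],
    adult_tissues: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """LFSR matrix from planted temporal classes.

    Active (pair significant in a tissue group) draws LFSR ~ U(0, 0.02);
    inactive draws U(0.2, 1). The classification contract, not an
    empirical-Bayes fit, is what downstream code consumes.
    """
    rng = np.random.default_rng(seed)
    cols = list(edev_tissues) + list(adult_tissues)
    rows = []
    for pair in pairs:
        cls = classes[pair]
        edev_active = cls in ("EDev-specific", "shared")
        adult_active = cls in ("adult-specific", "shared")
        row = {}
        for t in edev_tissues:
            row[t] = rng.uniform(0.0, 0.02) if edev_active else rng.uniform(0.2, 1.0)
        for t in adult_tissues:
            row[t] = rng.uniform(0.0, 0.02) if adult_active else rng.uniform(0.2, 1.0)
        rows.append(row)
    return pd.DataFrame(rows, index=pairs, columns=cols)
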