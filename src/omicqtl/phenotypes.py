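"""Phenotype normalization, filtering and covariate estimation.

The normalization contract mirrors the standard bulk-QTL recipe: TMM
(trimmed mean of M-values) between-sample factors, abundance filters,
then a per-element rank-based inverse normal transform so each retained
element is exactly standard-normal-distributed across samples. Hidden
confounders are estimated as principal components of the normalized
matrix (a deterministic surrogate for factor models such as PEER, which
in practice track sequencing depth and sample heterogeneity); the factor
interface is pluggable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypePanel, PhenotypeSet

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def tmm_normalize(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """TMM normalization factors and CPM matrix on effective library sizes.

    The reference sample is the one whose 75th percentile of
    library-size-scaled counts is closest to the mean 75th percentile.
    Each sample's factor is the weighted mean of log2 ratios (M-values)
    against the reference after trimming ``trim_m`` of the most extreme
    M-values and ``trim_a`` of the most extreme A-values on each side,
    with inverse-asymptotic-variance weights. Zero-count genes are
    excluded pairwise. Factors are rescaled to geometric mean 1.

    Returns ``(factors, cpm)`` where ``cpm[g, s] = counts[g, s] /
    (lib_s * factor_s) * 1e6``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    zero_lib = np.flatnonzero(lib == 0)
    if zero_lib.size:
        raise ValueError(f"sample {zero_lib[0]} has all-zero counts")

    f75 = np.quantile(counts / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.empty(counts.shape[1])
    for s in range(counts.shape[1]):
        factors[s] = _tmm_pair_factor(
            counts[:, s], counts[:, ref], lib[s], lib[ref], trim_m, trim_a
        )
    factors /= np.exp(np.mean(np.log(factors)))
    cpm = counts / (lib * factors) * 1e6
    return factors, cpm


def _tmm_pair_factor(obs, ref, lib_obs, lib_ref, trim_m, trim_a) -> float:
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    if np.max(np.abs(m), initial=0.0) < 1e-6:
        return 1.0
    n = m.size
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    lo_m = np.floor(n * trim_m) + 1
    lo_a = np.floor(n * trim_a) + 1
    sel = (
        (rm >= lo_m)
        & (rm <= n + 1 - lo_m)
        & (ra >= lo_a)
        & (ra <= n + 1 - lo_a)
    )
    if not sel.any():
        return 1.0
    # inverse asymptotic (binomial) variance of each M-value
    w = 1.0 / ((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
    f = np.sum(w[sel] * m[sel]) / np.sum(w[sel])
    return float(2.0**f)


def filter_expression_elements(
    tpm: np.ndarray,
    counts: np.ndarray,
    element_meta: pd.DataFrame,
    tpm_min: float = 0.1,
    count_min: float = 6,
    sample_frac: float = 0.2,
) -> np.ndarray:
    """Expression filter: autosomal, TPM and raw-count thresholds.

    Retained iff autosomal AND TPM >= 0.1 in >= 20% of samples AND raw
    count >= 6 in >= 20% of samples (all inclusive).
    """
    tpm = np.asarray(tpm, dtype=float)
    counts = np.asarray(counts, dtype=float)
    autosomal = ~element_meta["chrom"].isin(SEX_CHROMS).to_numpy()
    tpm_ok = (tpm >= tpm_min).mean(axis=1) >= sample_frac
    count_ok = (counts >= count_min).mean(axis=1) >= sample_frac
    return autosomal & tpm_ok & count_ok


def filter_peak_elements(
    tmm_values: np.ndarray,
    element_meta: pd.DataFrame,
    low_tmm: float = 1.0,
    sample_frac: float = 0.2,
) -> np.ndarray:
    """Peak filter: removed iff on a sex chromosome OR TMM < 1 in >= 20%."""
    tmm_values = np.asarray(tmm_values, dtype=float)
    sex = element_meta["chrom"].isin(SEX_CHROMS).to_numpy()
    low = (tmm_values < low_tmm).mean(axis=1) >= sample_frac
    return ~(sex | low)


def inverse_normal_transform(row: np.ndarray) -> np.ndarray:
    """Rank-based INT: Phi^-1((rank - 0.5) / n), average ranks on ties."""
    row = np.asarray(row, dtype=float)
    n = row.size
    if n < 3:
        raise ValueError("inverse normal transform needs n >= 3")
    if np.ptp(row) == 0:
        raise ValueError("constant row cannot be inverse normal transformed")
    ranks = stats.rankdata(row)
    return stats.norm.ppf((ranks - 0.5) / n)


@dataclass
class NormalizedPhenotypes:
    """Final per-element INT values plus the filtering audit trail."""

    values: np.ndarray  # kept elements x samples
    elements: pd.DataFrame  # metadata for kept elements
    sample_ids: list[str]
    norm_factors: np.ndarray
    mask: pd.DataFrame  # all elements: id, kept, reason


def normalize_phenotypes(
    pheno: PhenotypeSet,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizedPhenotypes:
    """TMM -> abundance filter -> inverse normal transform.

    Expression elements use the TPM/raw-count filter (TPM computed as
    counts-per-million over a unit-length model, since synthetic elements
    have no transcript structure); peak elements use the TMM < 1 filter.
    """
    counts = pheno.counts
    factors, tmm = tmm_normalize(counts, trim_m=trim_m, trim_a=trim_a)
    meta = pheno.elements

    is_expr = (meta["phenotype_type"] == "expression").to_numpy()
    kept = np.zeros(len(meta), dtype=bool)
    reason = np.array(["kept"] * len(meta), dtype=object)
    if is_expr.any():
        sub = filter_expression_elements(tmm[is_expr], counts[is_expr], meta.loc[is_expr])
        kept[is_expr] = sub
        reason[np.flatnonzero(is_expr)[~sub]] = "expression_filter"
    if (~is_expr).any():
        sub = filter_peak_elements(tmm[~is_expr], meta.loc[~is_expr])
        kept[~is_expr] = sub
        reason[np.flatnonzero(~is_expr)[~sub]] = "peak_filter"
    sex = meta["chrom"].isin(SEX_CHROMS).to_numpy()
    reason[sex & ~kept] = "sex_chromosome"

    values = np.vstack(
        [inverse_normal_transform(tmm[i]) for i in np.flatnonzero(kept)]
    ) if kept.any() else np.empty((0, counts.shape[1]))
    mask = pd.DataFrame({"id": meta["id"], "kept": kept, "reason": reason})
    return NormalizedPhenotypes(
        values=values,
        elements=meta.loc[kept].reset_index(drop=True),
        sample_ids=list(pheno.sample_ids),
        norm_factors=factors,
        mask=mask,
    )


def genotype_pcs(
    panel: GenotypePanel,
    prune_r2: float = 0.2,
    n_pcs: int = 5,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Top principal-component scores of LD-pruned standardized dosages."""
    from .ld import indep_pairwise

    if n_pcs == 0:
        return np.empty((panel.n_samples, 0))
    keep = indep_pairwise(panel, window=window, step=step, r2_max=prune_r2)
    d = panel.dosages[:, keep].astype(float)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    z = (d[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    z -= z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum())
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds genotype matrix rank {rank}")
    return u[:, :n_pcs] * s[:n_pcs]


def hidden_factors(
    normalized: NormalizedPhenotypes, k: int, n_top: int = 2000
) -> np.ndarray:
    """Top-k PCs of the element-centered matrix (2,000 most variable rows)."""
    if k == 0:
        return np.empty((len(normalized.sample_ids), 0))
    vals = normalized.values
    if k >= len(normalized.sample_ids):
        raise ValueError("k must be smaller than the number of samples")
    var = vals.var(axis=1)
    top = np.argsort(var)[::-1][: min(n_top, vals.shape[0])]
    x = vals[top] - vals[top].mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(k, len(s))
    return vt[:k].T * s[:k]


def optimize_factor_count(
    panel: GenotypePanel,
    normalized: NormalizedPhenotypes,
    candidate_ks: list[int],
    pilot_elements: int = 1000,
    seed: int = 0,
    fixed_covariates: np.ndarray | None = None,
    kinship: np.ndarray | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the hidden-factor count by pilot QTL discovery.

    Runs the primary scan on a random pilot subset of elements for each
    candidate k and returns the smallest k achieving the maximum
    significant-element count (ties break to the smallest k).
    """
    from . import qtl as qtl_mod

    if not candidate_ks:
        raise ValueError("candidate_ks must be non-empty")
    rng = np.random.default_rng(seed)
    n_el = normalized.values.shape[0]
    pilot = np.sort(rng.choice(n_el, size=min(pilot_elements, n_el), replace=False))
    sub = NormalizedPhenotypes(
        values=normalized.values[pilot],
        elements=normalized.elements.iloc[pilot].reset_index(drop=True),
        sample_ids=normalized.sample_ids,
        norm_factors=normalized.norm_factors,
        mask=normalized.mask,
    )
    if kinship is None:
        kinship = qtl_mod.build_kinship(panel)
    counts = []
    for k in candidate_ks:
        factors = hidden_factors(normalized, k)
        cov = factors if fixed_covariates is None else np.hstack([fixed_covariates, factors])
        res = qtl_mod.map_primary_qtls(panel, sub, covariates=cov, kinship=kinship)
        counts.append(int(sum(1 for r in res if r.q < 0.05)))
    curve = pd.DataFrame({"k": candidate_ks, "n_significant": counts})
    best = curve.loc[curve["n_significant"] == curve["n_significant"].max(), "k"].min()
    return int(best), curve
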