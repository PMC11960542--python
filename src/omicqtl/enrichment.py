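"""Fisher-exact enrichment analyses with BH correction.

Covers the pipeline's four enrichment designs: chromatin-state
enrichment of lead variants (significant vs non-significant element
leads as background), TFBS enrichment in peak classes, caPeak-upstream-
of-eGene enrichment, and complex-vs-singleton GWAS-colocalization
enrichment (the last at raw p < 0.05 by design, without BH).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: 18-state chromatin vocabulary collapsed to 5 categories; the "EnG2"
#: spelling is accepted alongside "EnhG2" (both occur in published tables)
STATE_COLLAPSE = {
    "TssA": "Promoter",
    "TssBiv": "Promoter",
    "TssFlnkU": "Promoter",
    "TssFlnkD": "Promoter",
    "TssFlnk": "Promoter",
    "EnhA1": "Enhancer",
    "EnhA2": "Enhancer",
    "EnhG1": "Enhancer",
    "EnG2": "Enhancer",
    "EnhG2": "Enhancer",
    "EnhWk": "Enhancer",
    "EnhBiv": "Enhancer",
    "ReprPC": "Repressed",
    "ReprPCWk": "Repressed",
    "Het": "Repressed",
    "ZNF/Rpts": "Repressed",
    "Tx": "Transcribed",
    "TxWk": "Transcribed",
    "Quies": "Quiescent",
}


@dataclass
class EnrichmentResult:
    category: str
    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    p: float
    p_adjusted: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    continuity_corrected: bool = False


def fisher_enrichment(
    a: int, b: int, c: int, d: int, category: str = ""
) -> EnrichmentResult:
    """Two-sided Fisher exact test with sample OR and Woolf logit 95% CI.

    0.5 is added to every cell for the CI only when some cell is zero
    (flagged). A zero row or column makes the OR undefined and p = 1.
    """
    table = np.array([[a, b], [c, d]])
    if min(a + b, c + d, a + c, b + d) == 0:
        return EnrichmentResult(category, (a, b, c, d), np.nan, 1.0)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        corrected = True
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
        corrected = False
    or_sample = (a * d) / (b * c) if min(b, c) > 0 else (aa * dd) / (bb * cc)
    log_or = np.log((aa * dd) / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    zcrit = stats.norm.ppf(0.975)
    return EnrichmentResult(
        category,
        (a, b, c, d),
        float(or_sample),
        float(p),
        ci_low=float(np.exp(log_or - zcrit * se)),
        ci_high=float(np.exp(log_or + zcrit * se)),
        continuity_corrected=corrected,
    )


def bh_adjust(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    if not results:
        return results
    ps = np.array([r.p for r in results])
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    for r, qv in zip(results, q):
        r.p_adjusted = float(qv)
    return results


def collapse_chromatin_states(states: pd.Series | list[str]) -> pd.Series:
    """Map 18-state labels to the 5 collapsed categories; unknown -> error."""
    s = pd.Series(states)
    unknown = sorted(set(s) - set(STATE_COLLAPSE))
    if unknown:
        raise ValueError(f"unknown chromatin state labels: {unknown}")
    return s.map(STATE_COLLAPSE)


def lead_variant_state_enrichment(
    significant_states: pd.DataFrame,
    background_states: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Per-state, per-phenotype Fisher tests of lead-variant overlap.

    Inputs have columns ``variant, phenotype_type, state`` (collapsed
    categories); each test contrasts significant leads overlapping a
    state vs background leads, BH-adjusted across states x phenotypes.
    """
    results = []
    for ptype in sorted(significant_states["phenotype_type"].unique()):
        fg = significant_states.loc[significant_states["phenotype_type"] == ptype]
        bg = background_states.loc[background_states["phenotype_type"] == ptype]
        if bg.empty:
            bg = background_states
        for state in sorted(set(fg["state"]) | set(bg["state"])):
            a = int((fg["state"] == state).sum())
            b = len(fg) - a
            c = int((bg["state"] == state).sum())
            d = len(bg) - c
            res = fisher_enrichment(a, b, c, d, category=f"{ptype}:{state}")
            results.append(res)
    return bh_adjust(results)


def capeak_upstream_enrichment(
    genes: pd.DataFrame,
    capeaks: pd.DataFrame,
    window: int = 100_000,
) -> EnrichmentResult:
    """Fisher test: gene has >= 1 caPeak in its strand-aware upstream window
    x gene is an eGene.

    ``genes`` columns: ``id, chrom, tss, strand, is_egene``; ``capeaks``
    columns: ``chrom, start, end`` (0-based half-open).
    """
    has_peak = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            lo, hi = g["tss"] - window, g["tss"]
        else:
            lo, hi = g["tss"], g["tss"] + window
        sub = capeaks.loc[capeaks["chrom"] == g["chrom"]]
        hit = ((sub["start"] < hi) & (sub["end"] > lo)).any()
        has_peak.append(bool(hit))
    genes = genes.assign(has_peak=has_peak)
    a = int((genes["is_egene"] & genes["has_peak"]).sum())
    b = int((genes["is_egene"] & ~genes["has_peak"]).sum())
    c = int((~genes["is_egene"] & genes["has_peak"]).sum())
    d = int((~genes["is_egene"] & ~genes["has_peak"]).sum())
    return fisher_enrichment(a, b, c, d, category="capeak_upstream_of_egene")


def complex_vs_singleton_gwas_enrichment(
    qtl_categories: pd.Series,
    colocalized: pd.Series,
) -> list[EnrichmentResult]:
    """Per-category Fisher test of GWAS colocalization vs all others.

    ``qtl_categories`` maps QTL id -> one of the ten complex/singleton
    composition categories; ``colocalized`` maps QTL id -> bool.
    Significance is assessed at raw p < 0.05 (no BH, by design).
    """
    cats = qtl_categories.astype(str)
    coloc = colocalized.reindex(cats.index).fillna(False).astype(bool)
    results = []
    for cat in sorted(cats.unique()):
        in_cat = cats == cat
        a = int((in_cat & coloc).sum())
        b = int((in_cat & ~coloc).sum())
        c = int((~in_cat & coloc).sum())
        d = int((~in_cat & ~coloc).sum())
        results.append(fisher_enrichment(a, b, c, d, category=cat))
    return results
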