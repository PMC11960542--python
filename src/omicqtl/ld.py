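"""Linkage disequilibrium statistics and complex-QTL module detection.

r^2 is the squared Pearson correlation of dosages; D' uses two-locus
haplotype frequencies estimated by EM over unphased genotype pairs
(double heterozygotes are the only ambiguous class). Same-tissue QTLs
whose lead variants are in high LD and nearby are treated as one genetic
signal; communities of the resulting graph (Louvain modularity
maximization with a fixed node order and seed, so runs are reproducible)
are the complex-QTL modules.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ComplexQtlModule, GenotypePanel, QtlRecord

logger = logging.getLogger(__name__)


def ld_r2(g1: np.ndarray, g2: np.ndarray, min_samples: int = 10) -> float:
    """Squared dosage correlation over shared non-missing samples.

    Returns NaN (with a log message) if either variant has zero variance
    among the shared samples.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 >= 0) & (g2 >= 0) & np.isfinite(g1) & np.isfinite(g2)
    if ok.sum() < min_samples:
        raise ValueError(f"need >= {min_samples} shared non-missing samples")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        logger.info("ld_r2 undefined: zero-variance genotype vector")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _unambiguous_counts(table: np.ndarray) -> np.ndarray:
    """Haplotype counts (AB, Ab, aB, ab) from all unambiguous genotype cells.

    A genotype pair with at most one heterozygous locus resolves into two
    haplotypes uniquely; only the double heterozygote (1, 1) is ambiguous.
    """
    c = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            nij = table[i, j]
            if nij == 0:
                continue
            a_alleles = [1] * i + [0] * (2 - i)
            b_alleles = [1] * j + [0] * (2 - j)
            for a, b in zip(a_alleles, b_alleles):
                c[0 if (a and b) else 1 if a else 2 if b else 3] += nij
    return c


def _em_haplotype_freqs(
    g1: np.ndarray, g2: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """EM haplotype frequencies (AB, Ab, aB, ab) from unphased genotypes."""
    table = np.zeros((3, 3))
    for a, b in zip(g1.astype(int), g2.astype(int)):
        table[a, b] += 1
    n_hap = 2.0 * table.sum()
    base = _unambiguous_counts(table)
    n11 = table[1, 1]

    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        p_ab_cis = freqs[0] * freqs[3]  # AB/ab phase
        p_ab_trans = freqs[1] * freqs[2]  # Ab/aB phase
        c = base.copy()
        if n11 > 0:
            den = p_ab_cis + p_ab_trans
            w = p_ab_cis / den if den > 0 else 0.5
            c[0] += n11 * w
            c[3] += n11 * w
            c[1] += n11 * (1 - w)
            c[2] += n11 * (1 - w)
        new = c / n_hap
        if np.max(np.abs(new - freqs)) < tol:
            return new
        freqs = new
    raise RuntimeError(
        f"EM for haplotype frequencies did not converge in {max_iter} iterations "
        f"(last freqs {freqs})"
    )


def ld_dprime(
    g1: np.ndarray, g2: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> float:
    """|D'| from EM haplotype frequencies of two unphased variants."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 >= 0) & (g2 >= 0)
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("both variants must be polymorphic")
    pAB, pAb, paB, pab = _em_haplotype_freqs(a, b, tol=tol, max_iter=max_iter)
    pA = pAB + pAb
    pB = pAB + paB
    d = pAB - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return 0.0
    return float(min(abs(d) / dmax, 1.0))


def shared_qtl_pairs(
    records: list[QtlRecord],
    panel: GenotypePanel,
    r2_min: float = 0.8,
    max_dist: int = 100_000,
) -> list[tuple[QtlRecord, QtlRecord, float]]:
    """Same-tissue primary-QTL pairs sharing a genetic signal.

    A pair is shared iff the lead variants are on the same chromosome,
    within ``max_dist`` bp, and r^2 strictly greater than ``r2_min``.
    Records whose lead variant is absent from the reference panel are
    skipped (logged), mirroring LD computation in a reference population.
    """
    known = set(panel.variants["id"])
    usable = []
    for r in records:
        if r.lead_variant in known:
            usable.append(r)
        else:
            logger.info("lead variant %s absent from reference panel; skipped", r.lead_variant)
    pairs = []
    by_tissue: dict[str, list[QtlRecord]] = {}
    for r in usable:
        by_tissue.setdefault(r.tissue, []).append(r)
    for tissue_records in by_tissue.values():
        for i in range(len(tissue_records)):
            for j in range(i + 1, len(tissue_records)):
                a, b = tissue_records[i], tissue_records[j]
                if a.chrom != b.chrom or abs(a.pos - b.pos) > max_dist:
                    continue
                if a.lead_variant == b.lead_variant:
                    pairs.append((a, b, 1.0))
                    continue
                r2 = ld_r2(panel.genotypes(a.lead_variant), panel.genotypes(b.lead_variant))
                if np.isfinite(r2) and r2 > r2_min:
                    pairs.append((a, b, r2))
    return pairs


def _composition_category(members: list[QtlRecord]) -> str:
    label = {"accessibility": "caQTL", "acetylation": "haQTL", "expression": "eQTL"}
    present = [
        lab
        for typ, lab in (
            ("accessibility", "caQTL"),
            ("acetylation", "haQTL"),
            ("expression", "eQTL"),
        )
        if any(m.phenotype_type == typ for m in members)
    ]
    return "-".join(present)


def detect_complex_modules(
    pairs: list[tuple[QtlRecord, QtlRecord, float]],
    records: list[QtlRecord],
    seed: int = 0,
) -> tuple[list[ComplexQtlModule], list[QtlRecord]]:
    """Louvain communities of the shared-signal graph, per tissue.

    Modules of size >= 2 become complex QTLs; edge-less QTLs are
    singletons. Nodes are inserted in sorted order and the community
    seed is fixed so the partition is reproducible.
    """
    key = {(r.tissue, r.element, r.rank): r for r in records}
    by_tissue_edges: dict[str, list[tuple]] = {}
    for a, b, r2 in pairs:
        by_tissue_edges.setdefault(a.tissue, []).append((a, b, r2))

    modules: list[ComplexQtlModule] = []
    in_module: set[tuple] = set()
    counter = 0
    for tissue in sorted(by_tissue_edges):
        g = nx.Graph()
        edges = by_tissue_edges[tissue]
        nodes = sorted(
            {(a.tissue, a.element, a.rank) for a, b, _ in edges}
            | {(b.tissue, b.element, b.rank) for a, b, _ in edges}
        )
        g.add_nodes_from(nodes)
        for a, b, r2 in edges:
            g.add_edge((a.tissue, a.element, a.rank), (b.tissue, b.element, b.rank), weight=1.0)
        communities = nx.community.louvain_communities(g, seed=seed)
        for comm in sorted(communities, key=lambda c: sorted(c)[0]):
            if len(comm) < 2:
                continue
            members = [key[n] for n in sorted(comm)]
            modules.append(
                ComplexQtlModule(
                    module_id=f"module{counter}",
                    tissue=tissue,
                    members=members,
                    category=_composition_category(members),
                )
            )
            in_module.update(comm)
            counter += 1
    singletons = [r for r in records if (r.tissue, r.element, r.rank) not in in_module]
    return modules, singletons


def min_distance_to_tss(qtl: QtlRecord, gene_models: pd.DataFrame) -> float:
    """Minimum |lead position - TSS| over expressed genes on the chromosome."""
    sub = gene_models.loc[gene_models["chrom"] == qtl.chrom]
    if sub.empty:
        return float("nan")
    return float(np.min(np.abs(sub["tss"].to_numpy(dtype=float) - qtl.pos)))


def indep_pairwise(
    panel: GenotypePanel,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
    variant_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy sliding-window LD pruning (plink --indep-pairwise dialect).

    Within each ``window``-variant window, one member of every pair with
    r^2 > ``r2_max`` is removed — the member with the smaller MAF, ties
    to the later position — then the window slides by ``step``. Returns
    indices of surviving variants in position order.
    """
    if variant_mask is None:
        idx_all = np.arange(panel.n_variants)
    else:
        idx_all = np.flatnonzero(variant_mask)
    d = panel.dosages[:, idx_all].astype(float)
    af = d.mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    m = d.shape[1]
    keep = np.ones(m, dtype=bool)
    for start in range(0, max(m - 1, 1), step):
        win = [i for i in range(start, min(start + window, m)) if keep[i]]
        changed = True
        while changed:
            changed = False
            for ii in range(len(win)):
                i = win[ii]
                if not keep[i]:
                    continue
                for jj in range(ii + 1, len(win)):
                    j = win[jj]
                    if not keep[j]:
                        continue
                    gi, gj = d[:, i], d[:, j]
                    if gi.std() == 0 or gj.std() == 0:
                        continue
                    r = np.corrcoef(gi, gj)[0, 1]
                    if r * r > r2_max:
                        if maf[i] < maf[j]:
                            drop = i
                        elif maf[j] < maf[i]:
                            drop = j
                        else:
                            drop = j  # tie -> later position
                        keep[drop] = False
                        changed = True
        if start + window >= m:
            break
    return idx_all[keep]
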