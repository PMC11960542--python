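"""Two-step cis-QTL mapping with a kinship linear mixed model.

Step 1 (discovery): for each element, the response is regressed on each
cis variant with fixed covariates (genotype PCs, hidden factors, other
covariates) and a random effect u ~ N(0, sigma_u^2 K) with K the genetic
relatedness matrix. Variance components are estimated once per element
under the null and held fixed across cis variants (the standard
fast-LMM approximation), so each variant test is a GLS Wald test in the
eigen-rotated coordinates of K. Per-element multiple testing uses an
effective-number-of-tests correction from chunked eigendecomposition of
the local LD matrix; genome-wide control is Benjamini-Hochberg over the
per-element lead variants.

Step 2 (filtering): conditional signals discovered by stepwise
regression are removed when their lead variants are in high LD
(r^2 >= 0.8 and/or D' >= 0.8) with the primary lead in a reference
panel, with an explicit removal ledger, sequential renumbering of the
survivors, and re-estimation ("regression") of primary summary
statistics conditioned on the surviving secondary leads.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypePanel, QtlRecord
from .ld import indep_pairwise, ld_dprime, ld_r2
from .phenotypes import NormalizedPhenotypes

logger = logging.getLogger(__name__)

#: the hg38 MHC interval excluded from mapping on real data (configurable;
#: synthetic chromosomes pass an empty exclusion list)
MHC_INTERVAL = ("chr6", 28_510_120, 33_480_577)


def hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test on heterozygote counts.

    Two-sided p: the sum of probabilities of all heterozygote counts
    (given the allele counts) no more probable than the observed one.
    """
    n = n_het + n_hom_ref + n_hom_alt
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    if n == 0 or n_rare == 0:
        return 1.0
    # heterozygote count has the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.empty(hets.size)
    lgam = math.lgamma
    for k, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[k] = (
            lgam(n + 1)
            - lgam(h + 1)
            - lgam(rare_hom + 1)
            - lgam(common_hom + 1)
            + h * math.log(2)
            + lgam(n_rare + 1)
            + lgam(2 * n - n_rare + 1)
            - lgam(2 * n + 1)
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def variant_qc(
    panel: GenotypePanel,
    hwe_p_min: float = 1e-6,
    call_rate_min: float = 0.99,
    maf_min: float = 0.05,
) -> np.ndarray:
    """QC mask: HWE exact p > 1e-6, call rate >= 0.99, MAF > 0.05."""
    d = panel.dosages
    keep = np.zeros(panel.n_variants, dtype=bool)
    for j in range(panel.n_variants):
        g = d[:, j]
        called = g[g >= 0]
        if called.size / g.size < call_rate_min:
            continue
        af = called.mean() / 2.0
        maf = min(af, 1 - af)
        if maf <= maf_min:
            continue
        n_het = int((called == 1).sum())
        n_ref = int((called == 0).sum())
        n_alt = int((called == 2).sum())
        if hwe_exact_p(n_het, n_ref, n_alt) <= hwe_p_min:
            continue
        keep[j] = True
    return keep


def build_kinship(
    panel: GenotypePanel,
    prune_window: int = 50,
    prune_step: int = 5,
    prune_r2: float = 0.2,
) -> np.ndarray:
    """GRM K = Z Z' / m over LD-pruned standardized dosages, clipped PSD."""
    keep = indep_pairwise(panel, window=prune_window, step=prune_step, r2_max=prune_r2)
    if keep.size < 2:
        raise ValueError("kinship needs >= 2 pruned variants")
    d = panel.dosages[:, keep].astype(float)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    z = (d[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    k = z @ z.T / z.shape[1]
    k = (k + k.T) / 2.0
    w, v = np.linalg.eigh(k)
    if w.min() < 0:
        logger.info("clipping %d negative kinship eigenvalues at 0", int((w < 0).sum()))
        w = np.clip(w, 0, None)
        k = (v * w) @ v.T
    return k


@dataclass
class RotatedData:
    """Null-model fit in the eigenbasis of the kinship matrix."""

    delta: float  # sigma_e^2 / sigma_u^2 at the REML optimum
    eigenvalues: np.ndarray
    y_rot: np.ndarray
    cov_rot: np.ndarray  # includes the intercept column
    rotation: np.ndarray  # U' (apply to genotypes before scanning)
    loglik: float


def _reml_loglik(log10_delta: float, lam: np.ndarray, y: np.ndarray, c: np.ndarray) -> float:
    delta = 10.0**log10_delta
    w = 1.0 / (lam + delta)
    sw = np.sqrt(w)
    cw = c * sw[:, None]
    yw = y * sw
    beta, res, rank, _ = np.linalg.lstsq(cw, yw, rcond=None)
    r = yw - cw @ beta
    rss = float(r @ r)
    n, p = c.shape
    if rss <= 0:
        return -np.inf
    sigma2 = rss / (n - p)
    _, logdet_ctc = np.linalg.slogdet(cw.T @ cw)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma2)
        + np.sum(np.log(lam + delta))
        + logdet_ctc
        + (n - p)
    )
    return ll


def null_variance_components(
    y: np.ndarray,
    covariates: np.ndarray,
    kinship_eig: tuple[np.ndarray, np.ndarray],
    grid: tuple[float, float, int] = (-5.0, 5.0, 100),
    tol: float = 1e-6,
    element_id: str = "",
) -> RotatedData:
    """REML fit of the variance ratio delta on a log grid + golden section.

    ``kinship_eig`` is ``(eigenvalues, eigenvectors)`` of K, computed once
    per tissue. Returns the rotated (decorrelated) response and covariates
    for fast per-variant GLS.
    """
    lam, u = kinship_eig
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite response for element {element_id!r}")
    c = np.column_stack([np.ones_like(y), covariates]) if covariates.size else np.ones((y.size, 1))
    y_rot = u.T @ y
    c_rot = u.T @ c

    lo, hi, npts = grid
    xs = np.linspace(lo, hi, npts)
    lls = np.array([_reml_loglik(x, lam, y_rot, c_rot) for x in xs])
    if not np.any(np.isfinite(lls)):
        raise ValueError(f"non-finite likelihood for element {element_id!r}")
    i = int(np.nanargmax(lls))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, npts - 1)]
    res = optimize.minimize_scalar(
        lambda x: -_reml_loglik(x, lam, y_rot, c_rot),
        bracket=None,
        bounds=(a, b),
        method="bounded",
        options={"xatol": tol},
    )
    best = res.x if -res.fun >= lls[i] else xs[i]
    ll = max(-res.fun, lls[i])
    return RotatedData(
        delta=float(10.0**best),
        eigenvalues=lam,
        y_rot=y_rot,
        cov_rot=c_rot,
        rotation=u.T,
        loglik=float(ll),
    )


def association_scan(
    rotated: RotatedData,
    genotypes: np.ndarray,
    extra_covariate_genotypes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant GLS Wald tests with the null variance ratio fixed.

    ``genotypes`` is samples x variants on the original scale; columns
    collinear with the covariates get beta = NaN and are excluded from
    the effective-tests correction downstream.
    """
    w = 1.0 / (rotated.eigenvalues + rotated.delta)
    sw = np.sqrt(w)
    c_rot = rotated.cov_rot
    if extra_covariate_genotypes is not None and extra_covariate_genotypes.size:
        extra_rot = rotated.rotation @ extra_covariate_genotypes
        c_rot = np.column_stack([c_rot, extra_rot])
    cw = c_rot * sw[:, None]
    yw = rotated.y_rot * sw
    gw = (rotated.rotation @ genotypes) * sw[:, None]

    q, _ = np.linalg.qr(cw)
    y_r = yw - q @ (q.T @ yw)
    g_r = gw - q @ (q.T @ gw)

    gg = np.einsum("ij,ij->j", g_r, g_r)
    gy = y_r @ g_r
    n, p = cw.shape
    df = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = y_r @ y_r - beta**2 * gg
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    scale = np.median(np.abs(gw)) if gw.size else 1.0
    collinear = gg <= (1e-10 * max(scale, 1.0)) ** 2 * n
    beta[collinear] = np.nan
    se[collinear] = np.nan
    pvals[collinear] = np.nan
    if collinear.any():
        logger.warning("%d collinear genotype columns dropped from scan", int(collinear.sum()))
    return pd.DataFrame({"beta": beta, "se": se, "p": pvals})


def effective_tests(
    genotypes: np.ndarray,
    var_threshold: float = 0.99,
    chunk: int = 200,
) -> int:
    """Effective number of tests from chunked LD eigendecomposition.

    Variants are processed in consecutive chunks of <= ``chunk``; each
    chunk contributes the smallest number of eigenvalues of its dosage
    correlation matrix whose cumulative fraction reaches
    ``var_threshold``; the element total is the sum over chunks.
    """
    m = genotypes.shape[1]
    if m == 0:
        return 0
    total = 0
    for start in range(0, m, chunk):
        g = genotypes[:, start : start + chunk].astype(float)
        sd = g.std(axis=0)
        g = g[:, sd > 0]
        if g.shape[1] == 0:
            continue
        if g.shape[1] == 1:
            total += 1
            continue
        r = np.corrcoef(g, rowvar=False)
        w = np.linalg.eigvalsh(r)[::-1]
        w = np.clip(w, 0, None)
        frac = np.cumsum(w) / w.sum()
        total += int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
    return total


def corrected_p(p_min: float, m_eff: int) -> float:
    return float(min(1.0, p_min * m_eff))


def pick_lead(scan: pd.DataFrame) -> int:
    """Index of the lead variant: min p, ties to largest |beta|."""
    p = scan["p"].to_numpy()
    ok = np.isfinite(p)
    if not ok.any():
        raise ValueError("no testable variants")
    pmin = np.nanmin(p)
    tied = np.flatnonzero(ok & (p == pmin))
    if tied.size == 1:
        return int(tied[0])
    betas = np.abs(scan["beta"].to_numpy()[tied])
    return int(tied[np.argmax(betas)])


def genomewide_fdr(records: list[QtlRecord], alpha: float = 0.05) -> list[QtlRecord]:
    """BH q-values over the element-corrected p of lead variants."""
    if not records:
        return records
    ps = np.array([r.corrected_p for r in records])
    _, q, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    for r, qv in zip(records, q):
        r.q = float(qv)
    return records


@dataclass
class CisWindow:
    """Candidate variants for one element."""

    element: str
    chrom: str
    start: int
    end: int
    variant_idx: np.ndarray  # columns of the panel dosage matrix


def build_cis_windows(
    panel: GenotypePanel,
    elements: pd.DataFrame,
    qc_mask: np.ndarray | None = None,
    window_gene: int = 1_000_000,
    window_peak: int = 100_000,
    mhc_exclude: list[tuple[str, int, int]] | None = None,
    tss_anchored: bool = False,
) -> list[CisWindow]:
    """Cis windows: element body (or TSS) +/- 1 Mb for genes, 100 kb for peaks.

    Elements within the window width of an excluded interval (the MHC by
    default on real data) are dropped; synthetic scenarios pass
    ``mhc_exclude=[]``.
    """
    mhc_exclude = [] if mhc_exclude is None else mhc_exclude
    out = []
    var_chrom = panel.variants["chrom"].to_numpy()
    var_pos = panel.variants["pos"].to_numpy()
    base = np.ones(panel.n_variants, dtype=bool) if qc_mask is None else qc_mask
    for _, el in elements.iterrows():
        w = window_gene if el["phenotype_type"] == "expression" else window_peak
        if tss_anchored and el["phenotype_type"] == "expression":
            anchor_start = anchor_end = int(el["tss"])
        else:
            anchor_start, anchor_end = int(el["start"]), int(el["end"])
        lo, hi = anchor_start - w, anchor_end + w
        excluded = any(
            el["chrom"] == c and anchor_start - w <= e and anchor_end + w >= s
            for c, s, e in mhc_exclude
        )
        if excluded:
            continue
        mask = base & (var_chrom == el["chrom"]) & (var_pos >= lo) & (var_pos <= hi)
        out.append(
            CisWindow(
                element=el["id"],
                chrom=el["chrom"],
                start=lo,
                end=hi,
                variant_idx=np.flatnonzero(mask),
            )
        )
    return out


@dataclass
class ElementScan:
    """Scan output for one element at one conditioning level."""

    window: CisWindow
    scan: pd.DataFrame
    rotated: RotatedData
    m_eff: int
    lead_idx: int

    def lead_record(
        self, panel: GenotypePanel, meta: pd.Series, rank: str
    ) -> QtlRecord:
        i = self.window.variant_idx[self.lead_idx]
        row = self.scan.iloc[self.lead_idx]
        return QtlRecord(
            element=self.window.element,
            tissue=meta["tissue"],
            phenotype_type=meta["phenotype_type"],
            rank=rank,
            lead_variant=panel.variants["id"].iloc[i],
            chrom=panel.variants["chrom"].iloc[i],
            pos=int(panel.variants["pos"].iloc[i]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            p=float(row["p"]),
            corrected_p=corrected_p(float(row["p"]), self.m_eff),
        )


def scan_element(
    panel: GenotypePanel,
    y: np.ndarray,
    covariates: np.ndarray,
    window: CisWindow,
    kinship_eig: tuple[np.ndarray, np.ndarray],
    extra_genotypes: np.ndarray | None = None,
    rotated: RotatedData | None = None,
) -> ElementScan | None:
    """Null fit + cis scan + effective-tests correction for one element.

    Conditioning genotypes (previously discovered leads) join the fixed
    covariates of the null fit, so the variance ratio is re-estimated
    under the conditional null.
    """
    if window.variant_idx.size == 0:
        return None
    if rotated is None:
        cov_eff = covariates
        if extra_genotypes is not None and extra_genotypes.size:
            cov_eff = np.column_stack([covariates, extra_genotypes]) if covariates.size else extra_genotypes
        rotated = null_variance_components(
            y, cov_eff, kinship_eig, element_id=window.element
        )
        extra_genotypes = None  # already absorbed into the covariate block
    geno = panel.dosages[:, window.variant_idx].astype(float)
    scan = association_scan(rotated, geno, extra_covariate_genotypes=extra_genotypes)
    tested = scan["p"].notna().to_numpy()
    if not tested.any():
        return None
    m_eff = effective_tests(geno[:, tested])
    lead = pick_lead(scan)
    return ElementScan(window=window, scan=scan, rotated=rotated, m_eff=m_eff, lead_idx=lead)


def map_primary_qtls(
    panel: GenotypePanel,
    normalized: NormalizedPhenotypes,
    covariates: np.ndarray | None = None,
    kinship: np.ndarray | None = None,
    windows: list[CisWindow] | None = None,
    qc_mask: np.ndarray | None = None,
    alpha: float = 0.05,
) -> list[QtlRecord]:
    """Primary scan for every retained element, with genome-wide BH."""
    if kinship is None:
        kinship = build_kinship(panel)
    eig = np.linalg.eigh(kinship)
    kinship_eig = (eig[0], eig[1])
    if covariates is None:
        covariates = np.empty((panel.n_samples, 0))
    if windows is None:
        windows = build_cis_windows(panel, normalized.elements, qc_mask=qc_mask, mhc_exclude=[])
    win_by_el = {w.element: w for w in windows}
    records = []
    for i, el in normalized.elements.iterrows():
        w = win_by_el.get(el["id"])
        if w is None:
            continue
        es = scan_element(panel, normalized.values[i], covariates, w, kinship_eig)
        if es is None:
            continue
        records.append(es.lead_record(panel, el, "primary"))
    return genomewide_fdr(records, alpha=alpha)


def conditional_scan(
    panel: GenotypePanel,
    y: np.ndarray,
    covariates: np.ndarray,
    window: CisWindow,
    kinship_eig: tuple[np.ndarray, np.ndarray],
    meta: pd.Series,
    primary: QtlRecord,
    max_conditional: int = 3,
    alpha: float = 0.05,
) -> list[QtlRecord]:
    """Stepwise conditional discovery: <= 3 rounds, each conditioning on
    all previously found leads; stops at the first non-significant round.

    Significance here is at the element-corrected level (corrected p <
    alpha); the genome-wide BH pass over conditional leads is applied by
    the caller across elements.
    """
    leads = [primary.lead_variant]
    out: list[QtlRecord] = []
    for k in range(1, max_conditional + 1):
        extra = np.column_stack([panel.genotypes(v) for v in leads])
        es = scan_element(
            panel, y, covariates, window, kinship_eig, extra_genotypes=extra
        )
        if es is None:
            break
        rec = es.lead_record(panel, meta, f"conditional{k}")
        if rec.corrected_p >= alpha or not np.isfinite(rec.corrected_p):
            break
        out.append(rec)
        leads.append(rec.lead_variant)
    return out


@dataclass
class FilterLedger:
    """Removal bookkeeping for conditional-QTL filtering."""

    removed: list[tuple[QtlRecord, str]] = field(default_factory=list)

    def drop(self, rec: QtlRecord, reason: str) -> None:
        rec.status = f"removed:{reason}"
        self.removed.append((rec, reason))

    def reasons(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"element": r.element, "rank": r.rank, "lead": r.lead_variant, "reason": why}
                for r, why in self.removed
            ]
        )


def filter_conditional_qtls(
    primary: QtlRecord,
    conditionals: list[QtlRecord],
    reference_panel: GenotypePanel,
    r2_max: float = 0.8,
    dprime_max: float = 0.8,
    ledger: FilterLedger | None = None,
) -> tuple[list[QtlRecord], FilterLedger]:
    """Apply the conditional-filtering ledger for one element.

    (a) conditional lead absent from the reference panel -> removed;
    (b) primary lead absent -> primary kept, all conditionals removed;
    (c) conditional lead with r^2 >= 0.8 OR D' >= 0.8 to the primary
        lead -> removed;
    (d) monomorphic primary lead -> its conditionals removed; monomorphic
        conditional lead -> removed;
    (e) survivors renumbered sequentially.
    """
    ledger = ledger or FilterLedger()
    known = set(reference_panel.variants["id"])

    stage1 = []
    for rec in conditionals:
        if rec.lead_variant not in known:
            ledger.drop(rec, "absent_from_panel")
        else:
            stage1.append(rec)

    if primary.lead_variant not in known:
        for rec in stage1:
            ledger.drop(rec, "primary_absent")
        return [], ledger

    g_primary = reference_panel.genotypes(primary.lead_variant)
    if g_primary.std() == 0:
        for rec in stage1:
            ledger.drop(rec, "monomorphic_primary")
        return [], ledger

    survivors = []
    for rec in stage1:
        g = reference_panel.genotypes(rec.lead_variant)
        if g.std() == 0:
            ledger.drop(rec, "monomorphic_conditional")
            continue
        r2 = ld_r2(g, g_primary)
        dp = ld_dprime(g, g_primary)
        if (np.isfinite(r2) and r2 >= r2_max) or dp >= dprime_max:
            ledger.drop(rec, "ld_with_primary")
            continue
        survivors.append(rec)

    for k, rec in enumerate(survivors, start=1):
        rec.rank = f"conditional{k}"
    return survivors, ledger


def regress_primary_signal(
    panel: GenotypePanel,
    y: np.ndarray,
    covariates: np.ndarray,
    window: CisWindow,
    kinship_eig: tuple[np.ndarray, np.ndarray],
    meta: pd.Series,
    primary: QtlRecord,
    surviving_conditionals: list[QtlRecord],
) -> QtlRecord:
    """Re-estimate the primary signal conditioning on surviving leads.

    Elements with no surviving conditionals pass through unregressed.
    """
    if not surviving_conditionals:
        return primary
    extra = np.column_stack(
        [panel.genotypes(r.lead_variant) for r in surviving_conditionals]
    )
    es = scan_element(panel, y, covariates, window, kinship_eig, extra_genotypes=extra)
    rec = es.lead_record(panel, meta, "primary")
    rec.q = primary.q
    rec.regressed = True
    return rec


@dataclass
class QtlMappingResult:
    """Full two-step output for one tissue/phenotype dataset."""

    primaries: list[QtlRecord]
    conditionals: list[QtlRecord]
    ledger: FilterLedger
    scans: dict[str, pd.DataFrame] = field(default_factory=dict)


def map_qtls(
    panel: GenotypePanel,
    normalized: NormalizedPhenotypes,
    covariates: np.ndarray | None = None,
    reference_panel: GenotypePanel | None = None,
    kinship: np.ndarray | None = None,
    max_conditional: int = 3,
    alpha: float = 0.05,
    qc_mask: np.ndarray | None = None,
    keep_scans: bool = False,
) -> QtlMappingResult:
    """End-to-end two-step mapping: discovery, conditionals, filtering,
    renumbering and primary regression."""
    if reference_panel is None:
        reference_panel = panel
    if kinship is None:
        kinship = build_kinship(panel)
    lam, u = np.linalg.eigh(kinship)
    kinship_eig = (lam, u)
    if covariates is None:
        covariates = np.empty((panel.n_samples, 0))
    windows = build_cis_windows(panel, normalized.elements, qc_mask=qc_mask, mhc_exclude=[])
    win_by_el = {w.element: w for w in windows}

    primary_records: list[QtlRecord] = []
    row_of_element: dict[str, int] = {}
    for i, el in normalized.elements.iterrows():
        w = win_by_el.get(el["id"])
        if w is None:
            continue
        es = scan_element(panel, normalized.values[i], covariates, w, kinship_eig)
        if es is None:
            continue
        row_of_element[el["id"]] = i
        primary_records.append(es.lead_record(panel, el, "primary"))
    genomewide_fdr(primary_records, alpha=alpha)

    significant = [r for r in primary_records if r.q < alpha]
    ledger = FilterLedger()
    all_conditionals: list[QtlRecord] = []
    regressed: list[QtlRecord] = []
    scans: dict[str, pd.DataFrame] = {}
    for prim in significant:
        i = row_of_element[prim.element]
        el = normalized.elements.iloc[i]
        w = win_by_el[prim.element]
        conds = conditional_scan(
            panel,
            normalized.values[i],
            covariates,
            w,
            kinship_eig,
            el,
            prim,
            max_conditional=max_conditional,
            alpha=alpha,
        )
        kept, ledger = filter_conditional_qtls(prim, conds, reference_panel, ledger=ledger)
        all_conditionals.extend(kept)
        final_primary = regress_primary_signal(
            panel, normalized.values[i], covariates, w, kinship_eig, el, prim, kept
        )
        regressed.append(final_primary)
        if keep_scans:
            es = scan_element(panel, normalized.values[i], covariates, w, kinship_eig)
            df = es.scan.copy()
            df["variant"] = panel.variants["id"].to_numpy()[w.variant_idx]
            scans[prim.element] = df

    non_significant = [r for r in primary_records if r.q >= alpha]
    return QtlMappingResult(
        primaries=regressed + non_significant,
        conditionals=all_conditionals,
        ledger=ledger,
        scans=scans,
    )
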