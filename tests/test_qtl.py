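"""LMM scan, corrections, conditional machinery and the filtering ledger."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicqtl.datatypes import QtlRecord
from omicqtl import qtl as Q
from omicqtl.phenotypes import NormalizedPhenotypes
from omicqtl.simulate import EffectSpec, simulate_genotype_panel, simulate_phenotypes
from tests.conftest import make_elements


def hwe_enumeration_oracle(n_het, n_hom_ref, n_hom_alt):
    """Full enumeration of the conditional heterozygote distribution,
    written independently (direct factorial products, no log trick)."""
    n = n_het + n_hom_ref + n_hom_alt
    n_a = n_het + 2 * min(n_hom_ref, n_hom_alt)
    probs = {}
    for h in range(n_a % 2, n_a + 1, 2):
        rare_hom = (n_a - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            continue
        num = (
            math.factorial(n) * math.factorial(n_a) * math.factorial(2 * n - n_a) * 2**h
        )
        den = (
            math.factorial(h)
            * math.factorial(rare_hom)
            * math.factorial(common_hom)
            * math.factorial(2 * n)
        )
        probs[h] = num / den
    total = sum(probs.values())
    obs = probs[n_het] / total
    return sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12))


class TestHweAndQc:
    @pytest.mark.parametrize(
        "het,ref,alt",
        [(50, 25, 25), (10, 80, 10), (57, 21, 22), (0, 50, 50), (100, 0, 0), (3, 90, 7)],
    )
    def test_exact_p_matches_enumeration(self, het, ref, alt):
        assert Q.hwe_exact_p(het, ref, alt) == pytest.approx(
            hwe_enumeration_oracle(het, ref, alt), rel=1e-10
        )

    def test_balanced_hwe_retained(self):
        # (AA, Aa, aa) = (25, 50, 25) is the HWE expectation at p = 0.5
        assert Q.hwe_exact_p(50, 25, 25) > 1e-6

    def test_all_heterozygote_removed(self):
        assert Q.hwe_exact_p(100, 0, 0) < 1e-6

    def test_variant_qc_filters(self, small_panel):
        dos = small_panel.dosages.copy()
        dos[:, 0] = 0  # monomorphic
        dos[:, 1] = 1  # all-het, HWE violation
        dos[2:, 2] = -1  # call rate failure
        panel = small_panel.subset_samples(np.ones(small_panel.n_samples, dtype=bool))
        panel.dosages = dos
        d = np.ma.masked_equal(dos, -1)
        panel.variants["af"] = np.asarray(d.mean(axis=0) / 2.0)
        keep = Q.variant_qc(panel)
        assert not keep[0] and not keep[1] and not keep[2]
        assert keep.sum() > 0


class TestKinship:
    def test_duplicate_sample_symmetry(self, small_panel):
        from omicqtl.datatypes import GenotypePanel

        dos = np.vstack([small_panel.dosages, small_panel.dosages[:1]])
        variants = small_panel.variants.copy()
        variants["af"] = dos.mean(axis=0) / 2.0
        samples = pd.concat(
            [small_panel.samples,
             pd.DataFrame([{"id": "dup", "family": "solo", "role": "founder"}])],
            ignore_index=True,
        )
        panel = GenotypePanel(dos, variants, samples)
        k = Q.build_kinship(panel)
        assert k[0, 0] == pytest.approx(k[-1, -1], abs=1e-10)
        assert k[0, -1] == pytest.approx(k[0, 0], abs=1e-10)

    def test_symmetric_psd(self, small_panel):
        k = Q.build_kinship(small_panel)
        assert np.allclose(k, k.T, atol=1e-12)
        assert np.linalg.eigvalsh(k).min() > -1e-10


class TestNullVarianceComponents:
    def test_identity_kinship_matches_ols(self, small_panel):
        rng = np.random.default_rng(0)
        n = small_panel.n_samples
        y = rng.standard_normal(n)
        eye = np.eye(n)
        eig = np.linalg.eigh(eye)
        rot = Q.null_variance_components(y, np.empty((n, 0)), (eig[0], eig[1]))
        geno = small_panel.dosages[:, :20].astype(float)
        scan = Q.association_scan(rot, geno)
        for j in range(20):
            g = geno[:, j]
            res = stats.linregress(g, y)
            assert scan["beta"][j] == pytest.approx(res.slope, abs=1e-8)
            assert scan["p"][j] == pytest.approx(res.pvalue, abs=1e-8)

    def test_variance_ratio_recovery(self):
        # sigma_u^2 / sigma_e^2 = 1 planted: delta_hat in [0.5, 2] for
        # most replicates at n = 300
        panel = simulate_genotype_panel(40, 300, [6] * 10, n_blocks=20,
                                        variants_per_block=5, seed=13)
        k = Q.build_kinship(panel)
        lam, u = np.linalg.eigh(k)
        L = np.linalg.cholesky(k + 1e-8 * np.eye(300))
        hits = 0
        n_rep = 10
        for s in range(n_rep):
            rng = np.random.default_rng(100 + s)
            y = L @ rng.standard_normal(300) + rng.standard_normal(300)
            rot = Q.null_variance_components(y, np.empty((300, 0)), (lam, u))
            if 0.5 <= rot.delta <= 2.0:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_scale_equivariance(self, small_panel):
        rng = np.random.default_rng(3)
        n = small_panel.n_samples
        k = Q.build_kinship(small_panel)
        lam, u = np.linalg.eigh(k)
        y = rng.standard_normal(n)
        geno = small_panel.dosages[:, :10].astype(float)
        r1 = Q.null_variance_components(y, np.empty((n, 0)), (lam, u))
        r2 = Q.null_variance_components(2 * y, np.empty((n, 0)), (lam, u))
        assert r1.delta == pytest.approx(r2.delta, rel=1e-4)
        s1 = Q.association_scan(r1, geno)
        s2 = Q.association_scan(r2, geno)
        assert np.allclose(s1["p"], s2["p"], atol=1e-10)

    def test_nonfinite_response_rejected(self, small_panel):
        n = small_panel.n_samples
        k = np.eye(n)
        eig = np.linalg.eigh(k)
        y = np.full(n, np.nan)
        with pytest.raises(ValueError, match="gX"):
            Q.null_variance_components(y, np.empty((n, 0)), (eig[0], eig[1]),
                                       element_id="gX")


class TestAssociationScan:
    def test_null_p_uniform(self):
        # 2,000 null variants against an independent response: KS vs U(0,1)
        panel = simulate_genotype_panel(60, 150, [], n_blocks=400,
                                        variants_per_block=5,
                                        recomb_between_blocks=0.5, seed=21)
        rng = np.random.default_rng(0)
        n = panel.n_samples
        y = rng.standard_normal(n)
        eig = np.linalg.eigh(np.eye(n))
        rot = Q.null_variance_components(y, np.empty((n, 0)), (eig[0], eig[1]))
        scan = Q.association_scan(rot, panel.dosages.astype(float))
        ps = scan["p"].dropna().to_numpy()
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_conditioning_on_causal_kills_signal(self, cohort_panel):
        af = cohort_panel.variants["af"].to_numpy()
        maf = np.minimum(af, 1 - af)
        causal = cohort_panel.variants["id"].iloc[int(np.argmin(np.abs(maf - 0.3)))]
        elements = make_elements(1)
        hits = 0
        n_rep = 10
        k = Q.build_kinship(cohort_panel)
        lam, u = np.linalg.eigh(k)
        ci = cohort_panel.variant_index([causal])[0]
        for s in range(n_rep):
            res = simulate_phenotypes(
                cohort_panel, elements, [EffectSpec("g0", causal, 1.0)],
                noise_sd=1.0, seed=900 + s,
            )
            y = res.latent[0]
            rot = Q.null_variance_components(
                y, cohort_panel.genotypes(causal)[:, None], (lam, u)
            )
            scan = Q.association_scan(rot, cohort_panel.dosages[:, [ci]].astype(float))
            # the causal variant itself is collinear with the covariate
            assert np.isnan(scan["p"][0])
            near = [i for i in range(max(ci - 3, 0), min(ci + 4, cohort_panel.n_variants))
                    if i != ci]
            scan2 = Q.association_scan(rot, cohort_panel.dosages[:, near].astype(float))
            if (scan2["p"].dropna() > 0.05).all():
                hits += 1
        assert hits >= 0.7 * n_rep


class TestEffectiveTests:
    def test_identity_correlation_bonferroni(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(5000, 50)).astype(float)
        m_eff = Q.effective_tests(g)
        assert m_eff == 50
        assert Q.corrected_p(1e-4, m_eff) == pytest.approx(50e-4)

    def test_perfect_block_single_test(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=200).astype(float)
        g = np.column_stack([base] * 30)
        assert Q.effective_tests(g) == 1

    def test_two_block_toy_matches_full_eigen_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, size=300).astype(float)
        b = rng.integers(0, 3, size=300).astype(float)
        g = np.column_stack(
            [a + 0.1 * rng.standard_normal(300) for _ in range(60)]
            + [b + 0.1 * rng.standard_normal(300) for _ in range(60)]
        )
        # independent oracle: single full eigendecomposition (m=120 < chunk)
        r = np.corrcoef(g, rowvar=False)
        w = np.sort(np.linalg.eigvalsh(r))[::-1]
        frac = np.cumsum(w) / w.sum()
        expected = int(np.argmax(frac >= 0.99 - 1e-12)) + 1
        assert Q.effective_tests(g) == expected

    def test_corrected_p_bounds(self):
        assert Q.corrected_p(0.5, 10) == 1.0
        assert Q.corrected_p(1e-3, 7) == pytest.approx(7e-3)


def _record(element, p, beta=1.0, rank="primary", lead="v1"):
    return QtlRecord(
        element=element, tissue="t", phenotype_type="expression", rank=rank,
        lead_variant=lead, chrom="chr1", pos=100, beta=beta, se=0.1,
        p=p, corrected_p=p,
    )


class TestFdrAndLeads:
    def test_all_p_one(self):
        recs = [_record(f"g{i}", 1.0) for i in range(4)]
        Q.genomewide_fdr(recs)
        assert all(r.q == 1.0 for r in recs)

    def test_hand_computed_bh(self):
        ps = [0.01, 0.02, 0.03, 0.5, 0.04]
        recs = [_record(f"g{i}", p) for i, p in enumerate(ps)]
        Q.genomewide_fdr(recs)
        # hand BH: sorted p (0.01,0.02,0.03,0.04,0.5); q_i = min over
        # j >= i of p_j * n / j -> (0.05, 0.05, 0.05, 0.05, 0.5)
        expected = {"g0": 0.05, "g1": 0.05, "g2": 0.05, "g3": 0.5, "g4": 0.05}
        for r in recs:
            assert r.q == pytest.approx(expected[r.element], abs=1e-12)

    def test_lead_tiebreak_largest_beta(self):
        scan = pd.DataFrame({"beta": [0.4, -0.6], "se": [0.1, 0.1], "p": [0.001, 0.001]})
        assert Q.pick_lead(scan) == 1

    def test_q_monotone_in_corrected_p(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(size=30)
        recs = [_record(f"g{i}", p) for i, p in enumerate(ps)]
        Q.genomewide_fdr(recs)
        order = np.argsort(ps)
        qs = np.array([recs[i].q for i in order])
        assert (np.diff(qs) >= -1e-12).all()


class TestConditionalFiltering:
    def _panel_with_ld(self):
        return simulate_genotype_panel(6, 200, [], n_blocks=4,
                                       variants_per_block=10, seed=31)

    def test_high_r2_removed(self):
        panel = self._panel_with_ld()
        # plant a near-copy so the pair is unambiguously in high LD
        dos = panel.dosages.copy()
        dos[:, 1] = dos[:, 0]
        dos[:3, 1] = np.clip(dos[:3, 1] + 1, 0, 2)
        panel.dosages = dos
        panel.variants["af"] = dos.mean(axis=0) / 2.0
        d = panel.dosages.astype(float)
        r2 = np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2
        assert r2 > 0.9
        prim = _record("g0", 1e-8, lead=panel.variants["id"].iloc[0])
        cond = _record("g0", 1e-4, rank="conditional1", lead=panel.variants["id"].iloc[1])
        kept, ledger = Q.filter_conditional_qtls(prim, [cond], panel)
        assert kept == []
        assert ledger.reasons()["reason"].tolist() == ["ld_with_primary"]

    def test_dprime_alone_suffices(self):
        # construct genotypes with low r^2 but D' = 1 (rare allele always on
        # the common-allele background of the other locus)
        g1 = np.array([0] * 90 + [1] * 10 + [0] * 100)
        g2 = np.array([0] * 90 + [0] * 10 + [1] * 60 + [0] * 40)
        from omicqtl.ld import ld_r2, ld_dprime

        assert ld_r2(g1, g2) < 0.8
        assert ld_dprime(g1, g2) >= 0.8
        panel = self._panel_with_ld()
        dos = panel.dosages.copy()
        dos[:, 5] = g1
        dos[:, 6] = g2
        panel.dosages = dos
        panel.variants["af"] = dos.mean(axis=0) / 2.0
        prim = _record("g0", 1e-8, lead=panel.variants["id"].iloc[5])
        cond = _record("g0", 1e-4, rank="conditional1", lead=panel.variants["id"].iloc[6])
        kept, ledger = Q.filter_conditional_qtls(prim, [cond], panel)
        assert kept == []
        assert ledger.reasons()["reason"].tolist() == ["ld_with_primary"]

    def test_absent_conditional_removed_absent_primary_keeps_primary(self):
        panel = self._panel_with_ld()
        prim = _record("g0", 1e-8, lead="not_in_panel")
        cond1 = _record("g0", 1e-4, rank="conditional1",
                        lead=panel.variants["id"].iloc[35])
        cond2 = _record("g0", 1e-3, rank="conditional2", lead="also_absent")
        kept, ledger = Q.filter_conditional_qtls(prim, [cond1, cond2], panel)
        assert kept == []
        reasons = ledger.reasons()["reason"].tolist()
        assert reasons == ["absent_from_panel", "primary_absent"]

    def test_renumbering_after_removal(self):
        panel = self._panel_with_ld()
        # primary in block 0; conditional1 in same block (high LD, removed);
        # conditional2 in the last block (independent, kept, renumbered)
        prim = _record("g0", 1e-8, lead=panel.variants["id"].iloc[0])
        c1 = _record("g0", 1e-5, rank="conditional1", lead=panel.variants["id"].iloc[1])
        c2 = _record("g0", 1e-4, rank="conditional2", lead=panel.variants["id"].iloc[35])
        kept, _ = Q.filter_conditional_qtls(prim, [c1, c2], panel)
        assert [r.rank for r in kept] == ["conditional1"]
        assert kept[0].lead_variant == panel.variants["id"].iloc[35]

    def test_monomorphic_rules(self):
        panel = self._panel_with_ld()
        dos = panel.dosages.copy()
        dos[:, 20] = 1  # monomorphic-in-panel but present
        panel.dosages = dos
        prim_mono = _record("g0", 1e-8, lead=panel.variants["id"].iloc[20])
        cond = _record("g0", 1e-4, rank="conditional1", lead=panel.variants["id"].iloc[35])
        kept, ledger = Q.filter_conditional_qtls(prim_mono, [cond], panel)
        assert kept == [] and ledger.reasons()["reason"].tolist() == ["monomorphic_primary"]

        prim = _record("g1", 1e-8, lead=panel.variants["id"].iloc[0])
        cond_mono = _record("g1", 1e-4, rank="conditional1", lead=panel.variants["id"].iloc[20])
        kept, ledger2 = Q.filter_conditional_qtls(prim, [cond_mono], panel)
        assert kept == []
        assert ledger2.reasons()["reason"].tolist() == ["monomorphic_conditional"]


class TestRegressionAndBookkeeping:
    def test_passthrough_without_conditionals(self, cohort_panel, planted_dataset):
        res, causal = planted_dataset
        from omicqtl.phenotypes import normalize_phenotypes

        norm = normalize_phenotypes(res.phenotypes)
        out = Q.map_qtls(cohort_panel, norm)
        sig = [r for r in out.primaries if r.q < 0.05]
        assert sig and all(not r.regressed for r in sig if not out.conditionals)

    def test_count_conservation(self, cohort_panel, planted_dataset):
        res, _ = planted_dataset
        from omicqtl.phenotypes import normalize_phenotypes

        norm = normalize_phenotypes(res.phenotypes)
        out = Q.map_qtls(cohort_panel, norm)
        assert len(out.primaries) == len(norm.elements)
        # removal reasons partition removed conditionals
        n_removed = len(out.ledger.removed)
        assert len(out.ledger.reasons()) == n_removed
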