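import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from archintro import introgression as intro
from archintro.io_formats import (MISSING, ArchaicGenotypes, HaplotypePanel,
                                  RecombinationMap, Variant)
from archintro.synthetic_data import DemographyParams, sample_ils_lengths

PARAMS = intro.TractCallerParams()


def _emission_oracle(archaic_gt, modern_gt, p, eps):
    """Brute-force enumeration of the IBD emission: sum over which archaic
    allele is copied, whether the copy flips, and the partner draw."""
    archaic_alleles = {0: [0, 0], 1: [0, 1], 2: [1, 1]}[archaic_gt]
    total = 0.0
    for a in archaic_alleles:                    # uniformly chosen allele
        for flip, w_f in ((0, 1 - eps), (1, eps)):
            copied = a ^ flip
            for partner, w_p in ((1, p), (0, 1 - p)):
                if copied + partner == modern_gt:
                    total += 0.5 * w_f * w_p
    return total


class TestSiteLod:
    def test_missing_archaic_uninformative(self):
        assert intro.site_lod(MISSING, 1, 0.3, PARAMS) == 0.0

    def test_fixed_site_uninformative(self):
        assert intro.site_lod(2, 2, 0.0, PARAMS) == 0.0
        assert intro.site_lod(2, 2, 1.0, PARAMS) == 0.0

    def test_hom_alt_archaic_het_modern_rare_allele(self):
        # log10[((1-eps)(1-p) + eps p) / (2p(1-p))] at p=0.01, eps=0.002
        got = intro.site_lod(2, 1, 0.01, PARAMS)
        assert got == pytest.approx(np.log10(0.98804 / 0.0198), abs=1e-6)
        assert got == pytest.approx(1.698, abs=1e-3)

    def test_hom_ref_archaic_hom_ref_modern(self):
        got = intro.site_lod(0, 0, 0.5, PARAMS)
        assert got == pytest.approx(0.300, abs=5e-3)

    @pytest.mark.parametrize("archaic_gt", [0, 1, 2])
    @pytest.mark.parametrize("modern_gt", [0, 1, 2])
    @pytest.mark.parametrize("p", [0.01, 0.3, 0.77])
    def test_matches_enumeration_oracle(self, archaic_gt, modern_gt, p):
        eps = PARAMS.modern_error
        num = _emission_oracle(archaic_gt, modern_gt, p, eps)
        den = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2][modern_gt]
        assert intro.site_lod(archaic_gt, modern_gt, p, PARAMS) == \
            pytest.approx(np.log10(num / den), abs=1e-12)


def brute_force_segments(x):
    """Independent oracle: recursive maximum-subarray decomposition."""
    x = list(x)

    def best(lo, hi):
        top = None
        for i in range(lo, hi):
            s = 0.0
            for j in range(i, hi):
                s += x[j]
                if top is None or s > top[2]:
                    top = (i, j, s)
        return top

    out = []

    def rec(lo, hi):
        if lo >= hi:
            return
        b = best(lo, hi)
        if b is None or b[2] <= 0:
            return
        rec(lo, b[0])
        out.append(b)
        rec(b[1] + 1, hi)

    rec(0, len(x))
    return sorted(out)


class TestMaximalScoringSegments:
    def test_spec_example_merges_through_dip(self):
        segs = intro.maximal_scoring_segments([2.0, -0.5, 3.0])
        assert len(segs) == 1
        s, e, score = segs[0]
        assert (s, e) == (0, 2)
        assert score == pytest.approx(4.5)

    def test_all_negative_empty(self):
        assert intro.maximal_scoring_segments([-1.0, -0.1, -3.0]) == []

    def test_two_separated_peaks(self):
        segs = intro.maximal_scoring_segments([3.0, -5.0, 2.0])
        assert [(s, e) for s, e, _ in segs] == [(0, 0), (2, 2)]

    @given(st.integers(0, 10**6), st.integers(1, 25))
    def test_equals_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1.0, 1.2, size=n)  # continuous: ties have measure 0
        got = sorted(intro.maximal_scoring_segments(x))
        want = brute_force_segments(x)
        assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in want]
        np.testing.assert_allclose([v for *_, v in got],
                                   [v for *_, v in want], atol=1e-9)


def _toy_panel(site_signs):
    """A 1-sample panel whose per-site LOD sign for sample S0 follows
    ``site_signs``: +1 -> S0 het with archaic hom-alt (positive LOD),
    0 -> archaic missing (LOD exactly 0), -1 -> S0 hom-ref against an
    archaic hom-alt call (negative LOD)."""
    n_pad = 60  # padding samples fix the allele frequency
    sites = [Variant("chr1", 1000 * (k + 1), "A", "G")
             for k in range(len(site_signs))]
    panel_alleles = np.zeros((2 * (n_pad + 1), len(sites)), np.int8)
    arch_gt = np.full(len(sites), 2, np.int8)
    for j, sign in enumerate(site_signs):
        if sign > 0:
            panel_alleles[0, j] = 1       # S0 carries the archaic allele
        elif sign == 0:
            arch_gt[j] = MISSING
        # one distinct pad carrier per site keeps 0 < p < 1 without any
        # pad sample accumulating LOD across sites
        panel_alleles[2 * (1 + j % n_pad), j] = 1
    samples = ["S0"] + [f"P{i}" for i in range(n_pad)]
    panel = HaplotypePanel(samples, sites, panel_alleles, phased=True)
    archaic = ArchaicGenotypes(sites, arch_gt)
    return panel, archaic


class TestCallTracts:
    def test_threshold_is_inclusive_boundary(self):
        rmap = RecombinationMap.uniform("chr1", 100_000)
        panel, archaic = _toy_panel([1, 1, 1])
        lods = intro._site_lod_matrix(panel, archaic, PARAMS)[0]
        total = lods.sum()
        below = intro.call_tracts(panel, archaic, rmap,
                                  intro.TractCallerParams(
                                      lod_threshold=total + 0.1))
        at = intro.call_tracts(panel, archaic, rmap,
                               intro.TractCallerParams(lod_threshold=total))
        assert [t.sample for t in below] == []
        assert [t.sample for t in at] == ["S0"]

    def test_no_tract_when_all_sites_negative(self):
        rmap = RecombinationMap.uniform("chr1", 100_000)
        panel, archaic = _toy_panel([-1, -1, -1])
        assert intro.call_tracts(panel, archaic, rmap, PARAMS) == []

    def test_span_covers_contributing_sites(self):
        rmap = RecombinationMap.uniform("chr1", 100_000)
        panel, archaic = _toy_panel([1, 0, 1, 1])
        tracts = [t for t in intro.call_tracts(
            panel, archaic, rmap,
            intro.TractCallerParams(lod_threshold=3.0)) if t.sample == "S0"]
        assert len(tracts) == 1
        assert (tracts[0].start_bp, tracts[0].end_bp) == (1000, 4000)
        assert tracts[0].length_cM == pytest.approx(0.003)

    def test_sensitivity_and_fdr_on_simulated_panel(self, study,
                                                    called_tracts):
        panel, rmap = study.panel, study.rec_map
        truth = []
        for t in panel.truth_tracts:
            length = (rmap.genetic_position(t.end_bp)
                      - rmap.genetic_position(t.start_bp))
            truth.append((t.sample, t.start_bp, t.end_bp, t.origin, length))

        def overlaps(t, sample, s, e):
            return t.sample == sample and t.start_bp <= e and t.end_bp >= s

        long_introgressed = [t for t in truth
                             if t[3] == "introgressed" and t[4] >= 0.05]
        hit = sum(any(overlaps(c, s, a, b) for c in called_tracts)
                  for s, a, b, _, _ in long_introgressed)
        sensitivity = hit / len(long_introgressed)
        false = sum(1 for c in called_tracts
                    if not any(overlaps(c, s, a, b)
                               for s, a, b, _, _ in truth))
        fdr = false / max(len(called_tracts), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.1


class TestRunsOfHomozygosity:
    def _panel(self, dosages):
        sites = [Variant("chr1", 100 * (j + 1), "A", "G")
                 for j in range(len(dosages))]
        alleles = np.zeros((2, len(dosages)), np.int8)
        for j, d in enumerate(dosages):
            alleles[0, j] = 1 if d >= 1 else 0
            alleles[1, j] = 1 if d == 2 else 0
        return HaplotypePanel(["S0"], sites, alleles, phased=True)

    def test_all_hom_sites(self):
        panel = self._panel([2] * 12)
        assert intro.runs_of_homozygosity(panel, "S0", 1, 10_000) == \
            ("hom", True)

    def test_half_het_sites(self):
        panel = self._panel([1, 0] * 6)
        assert intro.runs_of_homozygosity(panel, "S0", 1, 10_000) == \
            ("het", True)

    def test_99_percent_rule(self):
        panel = self._panel([2] * 99 + [1])
        assert intro.runs_of_homozygosity(panel, "S0", 1, 100_000)[0] == "hom"
        panel = self._panel([2] * 97 + [1, 1, 1])
        assert intro.runs_of_homozygosity(panel, "S0", 1, 100_000)[0] == "het"

    def test_too_few_sites_low_confidence(self):
        panel = self._panel([2] * 5)
        assert intro.runs_of_homozygosity(panel, "S0", 1, 10_000) == \
            ("het", False)


class TestExpectedSharedLength:
    def test_published_demography(self):
        L = intro.expected_shared_length(21_500, 2_000)
        assert L == pytest.approx(1 / 410, rel=1e-12)

    def test_no_admixture_case(self):
        assert intro.expected_shared_length(10_000, 0) == pytest.approx(0.005)

    def test_time_scaling(self):
        L1 = intro.expected_shared_length(21_500, 2_000)
        L2 = intro.expected_shared_length(43_000, 4_000)
        assert L2 == pytest.approx(L1 / 2)

    def test_invalid_times(self):
        with pytest.raises(ValueError):
            intro.expected_shared_length(1_000, 2_000)


class TestIlsLengthThreshold:
    def test_matches_survival_equation_bisection_oracle(self):
        # independent oracle: solve (1+m/L)exp(-m/L) = q by pure bisection
        L = 1 / 410
        q = 0.05 / 61
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if (1 + mid / L) * np.exp(-mid / L) > q:
                lo = mid
            else:
                hi = mid
        assert intro.ils_length_threshold(0.05, 61, L) == \
            pytest.approx(0.5 * (lo + hi), rel=1e-9)

    def test_degenerate_target_probability(self):
        # survival at 0 is 1, so a target probability of 1 gives m = 0
        assert intro.ils_length_threshold(1.0, 1, 1.0) == 0.0
        assert intro.ils_length_threshold(0.999999, 1, 1.0) > 0

    def test_survival_at_L_closed_form(self):
        # (1 + 1) e^-1 = 0.73576: threshold equals L exactly
        q = 2 * np.exp(-1.0)
        L = 0.37
        m = intro.ils_length_threshold(q, 1, L)
        assert m == pytest.approx(L, rel=1e-9)

    @given(st.floats(0.001, 0.2), st.integers(1, 200),
           st.floats(1e-4, 0.1))
    def test_monotonicity(self, alpha, n_tests, L):
        m = intro.ils_length_threshold(alpha, n_tests, L)
        assert m > 0
        assert intro.ils_length_threshold(alpha, n_tests + 1, L) > m
        assert intro.ils_length_threshold(alpha, n_tests, L * 1.1) > m
        assert intro.ils_length_threshold(min(alpha * 1.5, 0.9), n_tests,
                                          L) < m


class TestFilterSignificantTracts:
    def _tracts(self, lengths):
        return [intro.ArchaicTract("S", "chr1", 1, 2, 5.0, length_cM=l)
                for l in lengths]

    def test_strict_inequality(self):
        kept = intro.filter_significant_tracts(
            self._tracts([0.022, 0.023, 0.024]), 0.023)
        assert [t.length_cM for t in kept] == [0.024]

    def test_zero_threshold_keeps_all(self):
        assert len(intro.filter_significant_tracts(
            self._tracts([0.001, 0.5]), 0.0)) == 2

    def test_ils_null_calibration(self):
        demo = DemographyParams(seed=0)
        L = intro.expected_shared_length(demo.t_div_gen, demo.t_admix_gen)
        m = intro.ils_length_threshold(0.05, 61, L)
        rng = np.random.default_rng(123)
        lengths = sample_ils_lengths(rng, 200_000, demo)
        frac = np.mean(lengths > m)
        q = 0.05 / 61
        se = np.sqrt(q * (1 - q) / lengths.size)
        assert abs(frac - q) <= 3 * se


class TestTractDosage:
    def _tracts(self):
        return [
            intro.ArchaicTract("S0", "chr1", 100, 200, 5, 0.1, "het"),
            intro.ArchaicTract("S0", "chr1", 150, 300, 5, 0.1, "het"),
            intro.ArchaicTract("S1", "chr1", 100, 200, 5, 0.1, "hom"),
        ]

    def test_uncovered_position(self):
        assert intro.tract_dosage(self._tracts(), "S0", 999) == 0

    def test_het_and_hom_coverage(self):
        assert intro.tract_dosage(self._tracts(), "S0", 150) == 1
        assert intro.tract_dosage(self._tracts(), "S1", 150) == 2

    def test_overlapping_tracts_merged(self):
        merged = intro.merge_sample_tracts(self._tracts())
        assert merged["S0"] == [(100, 300, "het")]
        assert intro.tract_dosage(self._tracts(), "S0", 250) == 1

    def test_vector_matches_scalar(self):
        tr = self._tracts()
        vec = intro.tract_dosage_vector(tr, ["S0", "S1", "S2"], 150)
        assert vec.tolist() == [1, 2, 0]


class TestCosegregation:
    def test_identical_vectors(self):
        r = intro.cosegregation_r2([0, 1, 2, 0], [0, 1, 2, 0])
        assert r.r2 == pytest.approx(1.0)

    def test_hand_computed_r2(self):
        r = intro.cosegregation_r2([0, 1, 2, 0], [0, 1, 1, 0])
        assert r.r2 == pytest.approx(9 / 11, abs=1e-12)

    def test_constant_vector_flagged_undefined(self):
        r = intro.cosegregation_r2([1, 1, 1, 1], [0, 1, 1, 0])
        assert not r.defined and np.isnan(r.r2)

    def test_carrier_haplotype_count(self):
        r = intro.cosegregation_r2([0, 1, 2], [0, 1, 2])
        assert r.n_carrier_haplotypes == 3


class TestClassifyLocus:
    def _cls(self, r2):
        res = intro.CosegregationResult(r2=r2, n_carrier_haplotypes=10)
        return intro.classify_locus({"src": res})

    def test_published_denisova_value_is_none(self):
        assert self._cls(0.029)["label"] == "none"

    def test_high_r2_cosegregating(self):
        assert self._cls(0.95)["label"] == "cosegregating"

    def test_boundaries_fall_to_lower_class(self):
        assert self._cls(0.2)["label"] == "none"
        assert self._cls(0.5)["label"] == "candidate"

    def test_undefined_result_none(self):
        res = intro.CosegregationResult(r2=float("nan"),
                                        n_carrier_haplotypes=0, defined=False)
        assert intro.classify_locus({"src": res})["label"] == "none"

    def test_fixture_recovers_planted_origins(self, study, called_tracts):
        panel, rmap = study.panel, study.rec_map
        L = intro.expected_shared_length(21_500, 2_000)
        m = intro.ils_length_threshold(0.05, 61, L)
        sig = intro.filter_significant_tracts(called_tracts, m)
        dosages = panel.dosages()
        for _, row in study.causal_table.iterrows():
            v = Variant(row.chrom, int(row.pos), row.ref, row.alt)
            j = panel.site_index(v)
            tdos = intro.tract_dosage_vector(sig, panel.samples, v.pos)
            res = intro.cosegregation_r2(dosages[:, j], tdos)
            label = intro.classify_locus({"arch": res})["label"]
            if row.archaic:
                assert label == "cosegregating", str(v)
            else:
                assert label == "none", str(v)
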