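"""PSI, Bayesian dPSI with the mv95 rule, event typing, ORF impact, qPCR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vmtools import splicing as sp
from vmtools.models import Interval, TranscriptModel
from vmtools.synth import PlantedEvent, gen_junction_counts
from conftest import SAFE_CODONS, build_toy_locus, mirror_locus


# ------------------------------------------------------ numeric oracle

def mv95_by_integration(a1, b1, a2, b2, grid=8001):
    """5th percentile of s*(X2 - X1), X_i ~ Beta, by numeric convolution.

    Independent of the Monte-Carlo path in diff_splice: the density of the
    difference of two independent Betas is computed on a grid by discrete
    convolution, then the median fixes the sign s and the quantile is read
    off the CDF.
    """
    x = np.linspace(0, 1, grid)
    dx = x[1] - x[0]
    f1 = stats.beta.pdf(x, a1, b1)
    f2 = stats.beta.pdf(x, a2, b2)
    # density of D = X2 - X1 on [-1, 1]
    conv = np.convolve(f2, f1[::-1]) * dx
    d = np.linspace(-1, 1, conv.size)
    cdf = np.cumsum(conv) * dx
    cdf /= cdf[-1]
    median = np.interp(0.5, cdf, d)
    s = 1.0 if median >= 0 else -1.0
    if s > 0:
        q = np.interp(0.05, cdf, d)
    else:
        q = -np.interp(0.95, cdf, d)
    return max(0.0, q)


class TestComputePsi:
    @pytest.mark.parametrize("inc,exc,ni,ne,expected", [
        (20, 10, 2, 1, 0.5),   # junction normalization forces 10/(10+10)
        (0, 7, 1, 1, 0.0),
        (13, 0, 1, 1, 1.0),
    ])
    def test_formula(self, inc, exc, ni, ne, expected):
        assert sp.compute_psi(inc, exc, ni, ne).psi == pytest.approx(expected)

    def test_zero_reads_flags_undefined(self):
        est = sp.compute_psi(0, 0)
        assert not est.defined

    def test_zero_junction_count_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_psi(1, 1, n_inc_junc=0)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 500), st.integers(1, 500), st.integers(1, 200))
    def test_monotone_in_inclusion_reads(self, inc, exc, step):
        lo = sp.compute_psi(inc, exc).psi
        hi = sp.compute_psi(inc + step, exc).psi
        assert 0.0 <= lo <= hi <= 1.0


class TestDiffSplice:
    def test_strong_switch_passes(self):
        res = sp.diff_splice([(100, 900)], [(900, 100)], seed=0)
        assert res.dpsi_point == pytest.approx(0.8)
        assert res.passes
        oracle = mv95_by_integration(101, 901, 901, 101)
        assert res.mv95 == pytest.approx(oracle, abs=0.01)

    def test_identical_counts_do_not_pass(self):
        res = sp.diff_splice([(50, 50)], [(50, 50)], seed=0)
        assert res.dpsi_point == 0.0
        assert not res.passes

    def test_nine_total_reads_fails_coverage(self):
        res = sp.diff_splice([(5, 4)], [(200, 10)], seed=0)
        assert not res.coverage_ok and not res.passes

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            sp.diff_splice([], [(10, 10)])

    def test_same_seed_reproduces_mv95(self):
        a = sp.diff_splice([(30, 70)], [(80, 20)], seed=5)
        b = sp.diff_splice([(30, 70)], [(80, 20)], seed=5)
        assert a.mv95 == b.mv95

    def test_mv95_matches_integration_on_random_configurations(self):
        """Monte-Carlo mv95 vs numeric beta-difference integration on 20
        random count configurations, within 0.01."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            inc_c, exc_c = rng.integers(5, 300, size=2)
            inc_t, exc_t = rng.integers(5, 300, size=2)
            res = sp.diff_splice([(inc_c, exc_c)], [(inc_t, exc_t)],
                                 n_draws=100_000, seed=int(rng.integers(1e6)),
                                 min_effect=0.0)
            oracle = mv95_by_integration(inc_c + 1, exc_c + 1,
                                         inc_t + 1, exc_t + 1)
            assert res.mv95 == pytest.approx(oracle, abs=0.01)

    def test_mv95_bounded_by_point_estimate(self):
        res = sp.diff_splice([(200, 800)], [(600, 400)], seed=1)
        assert res.mv95 <= abs(res.dpsi_point) + 0.02

    def test_mv95_approaches_dpsi_at_extreme_coverage(self):
        n = 100_000
        res = sp.diff_splice([(int(0.2 * n), int(0.8 * n))],
                             [(int(0.7 * n), int(0.3 * n))], seed=2)
        assert res.mv95 == pytest.approx(abs(res.dpsi_point), abs=0.02)

    def test_null_events_pass_fraction_below_005(self):
        """Type-I control: equal planted PSI, coverage 50."""
        events = [PlantedEvent(
            event=sp.SpliceEvent(event_id=f"E{i}", gene_id=f"G{i}",
                                 transcript_id=f"T{i}", chrom="chr1",
                                 strand="+", segment=Interval(100, 200),
                                 event_type="EX"),
            psi_control=0.5, psi_treated=0.5) for i in range(1000)]
        counts = gen_junction_counts(33, events, coverage=50, replicates=3)
        rng = np.random.default_rng(34)
        n_pass = 0
        for row in counts.itertuples():
            control = [(getattr(row, f"ctrl_{i}_inc"), getattr(row, f"ctrl_{i}_exc"))
                       for i in (1, 2, 3)]
            treated = [(getattr(row, f"trt_{i}_inc"), getattr(row, f"trt_{i}_exc"))
                       for i in (1, 2, 3)]
            res = sp.diff_splice(control, treated, n_draws=2000, rng=rng)
            n_pass += res.passes
        assert n_pass / 1000 <= 0.05

    def test_planted_effects_recovered_with_power(self):
        """>=90% of 30 planted |dPSI| = 0.5 events recovered at coverage 200."""
        events = [PlantedEvent(
            event=sp.SpliceEvent(event_id=f"E{i}", gene_id=f"G{i}",
                                 transcript_id=f"T{i}", chrom="chr1",
                                 strand="+", segment=Interval(100, 200),
                                 event_type="IR"),
            psi_control=0.2, psi_treated=0.7) for i in range(30)]
        counts = gen_junction_counts(35, events, coverage=200, replicates=3)
        rng = np.random.default_rng(36)
        n_pass = 0
        for row in counts.itertuples():
            control = [(getattr(row, f"ctrl_{i}_inc"), getattr(row, f"ctrl_{i}_exc"))
                       for i in (1, 2, 3)]
            treated = [(getattr(row, f"trt_{i}_inc"), getattr(row, f"trt_{i}_exc"))
                       for i in (1, 2, 3)]
            res = sp.diff_splice(control, treated, n_draws=2000, rng=rng)
            n_pass += res.passes
        assert n_pass >= 27


class TestClassifyEventType:
    @pytest.fixture
    def tx(self):
        return TranscriptModel(transcript_id="T", gene_id="G", chrom="c",
                               strand="+",
                               exons=[Interval(100, 160), Interval(280, 340),
                                      Interval(460, 520)])

    def test_full_intron_is_ir(self, tx):
        assert sp.classify_event_type(Interval(160, 280), tx) == "IR"

    def test_middle_exon_is_ex(self, tx):
        assert sp.classify_event_type(Interval(280, 340), tx) == "EX"

    def test_left_shift_is_a5ss_on_plus(self, tx):
        assert sp.classify_event_type(Interval(160, 200), tx) == "A5SS"

    def test_right_shift_is_a3ss_on_plus(self, tx):
        assert sp.classify_event_type(Interval(250, 280), tx) == "A3SS"

    def test_minus_strand_genomic_left_shift_is_a3ss(self, tx):
        """Mirror of a plus-strand A5SS: on the minus strand a shifted
        genomic-left intron boundary is the transcript 3' splice site."""
        minus = TranscriptModel(transcript_id="T", gene_id="G", chrom="c",
                                strand="-", exons=tx.exons)
        assert sp.classify_event_type(Interval(160, 200), minus) == "A3SS"

    def test_unclassifiable_segment_warns_other(self, tx):
        with pytest.warns(UserWarning):
            assert sp.classify_event_type(Interval(150, 300), tx) == "other"

    def test_strand_mirror_preserves_event_type(self, tx):
        seq = "A" * 600
        for seg, expected in [(Interval(160, 280), "IR"),
                              (Interval(280, 340), "EX"),
                              (Interval(160, 200), "A5SS")]:
            _, m_tx, m_seg = mirror_locus(seq, _with_cds(tx), seg)
            assert sp.classify_event_type(m_seg, m_tx) == expected


def _with_cds(tx):
    return TranscriptModel(transcript_id=tx.transcript_id, gene_id=tx.gene_id,
                           chrom=tx.chrom, strand=tx.strand, exons=tx.exons,
                           cds_start=100, cds_end=520)


class TestClassifyOrfImpact:
    def _event(self, seg, etype):
        return sp.SpliceEvent(event_id="e", gene_id="g", transcript_id="TOY",
                              chrom="chrT", strand="+", segment=seg,
                              event_type=etype)

    def test_retained_intron_with_inframe_stop_is_deleterious(self):
        codons = [SAFE_CODONS[0]] * 10 + ["TAA"] + [SAFE_CODONS[0]] * 29
        seq, tx = build_toy_locus(intron1_codons=codons)
        lab = sp.classify_orf_impact(self._event(Interval(160, 280), "IR"), tx, seq)
        assert lab.label == "deleterious"
        assert lab.ptc_found

    def test_framepreserving_stopfree_intron_is_neutral(self):
        seq, tx = build_toy_locus()  # intron 1 is stop-free, 120 nt (mod 3 = 0)
        lab = sp.classify_orf_impact(self._event(Interval(160, 280), "IR"), tx, seq)
        assert lab.label == "neutral"
        assert lab.frame_preserved and not lab.ptc_found

    def test_skipping_ptc_exon_is_protective(self):
        codons = ["TAA"] + [SAFE_CODONS[1]] * 19  # PTC at the start of exon 2
        seq, tx = build_toy_locus(exon2_codons=codons)
        lab = sp.classify_orf_impact(self._event(Interval(280, 340), "EX"), tx, seq)
        assert lab.label == "protective"

    def test_strand_mirror_preserves_orf_labels(self):
        cases = []
        codons = [SAFE_CODONS[0]] * 10 + ["TAA"] + [SAFE_CODONS[0]] * 29
        cases.append((build_toy_locus(intron1_codons=codons),
                      Interval(160, 280), "deleterious"))
        cases.append((build_toy_locus(), Interval(160, 280), "neutral"))
        cases.append((build_toy_locus(exon2_codons=["TAA"] + [SAFE_CODONS[1]] * 19),
                      Interval(280, 340), "protective"))
        for (seq, tx), seg, expected in cases:
            m_seq, m_tx, m_seg = mirror_locus(seq, tx, seg)
            ev = sp.SpliceEvent(event_id="e", gene_id="g", transcript_id="TOY",
                                chrom="chrT", strand="-", segment=m_seg,
                                event_type=None)
            assert sp.classify_orf_impact(ev, m_tx, m_seq).label == expected

    def test_missing_cds_is_an_error(self):
        seq, tx = build_toy_locus()
        bare = TranscriptModel(transcript_id="T", gene_id="G", chrom="chrT",
                               strand="+", exons=tx.exons)
        with pytest.raises(ValueError, match="CDS"):
            sp.classify_orf_impact(self._event(Interval(160, 280), "IR"),
                                   bare, seq)


class TestSummarizeEvents:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["event_id", "gene_id", "event_type",
                                           "chrom", "strand", "start", "end",
                                           "dpsi_point", "passes"])

    def test_no_passing_events_all_zero(self):
        out = sp.summarize_events(self._frame(
            [("e1", "g1", "IR", "c", "+", 0, 10, 0.0, False)]))
        assert out["n_events_passing"] == 0
        assert all(v == 0 for v in out["counts_by_type"].values())

    def test_gene_with_three_events_counts_once(self):
        rows = [(f"e{i}", "g1", "EX", "c", "+", 0, 10, 0.5, True)
                for i in range(3)]
        out = sp.summarize_events(self._frame(rows))
        assert out["n_events_passing"] == 3
        assert out["n_genes_passing"] == 1

    def test_retained_intron_export(self):
        rows = [("e1", "g1", "IR", "c", "+", 5, 50, 0.4, True),
                ("e2", "g2", "EX", "c", "+", 60, 80, 0.4, True)]
        out = sp.summarize_events(self._frame(rows))
        assert [d["event_id"] for d in out["retained_introns"]] == ["e1"]


class TestQpcrRetentionRatio:
    @pytest.mark.parametrize("ct_i,ct_s,expected", [
        (20.0, 20.0, 1.0),
        (21.0, 20.0, 0.5),
        (18.0, 20.0, 4.0),
    ])
    def test_two_to_the_minus_delta_ct(self, ct_i, ct_s, expected):
        assert sp.qpcr_retention_ratio(ct_i, ct_s) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            sp.qpcr_retention_ratio(float("nan"), 20.0)
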