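"""Heteroplasmy caller thresholds, summaries, VCF filtering and batch
concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitohet import calling


def counts_row(ref="A", depth=100, A=0, C=0, G=0, T=0, pos=1):
    if ref == "A" and A == 0:
        A = depth - C - G - T
    return {
        "chrom": "mt",
        "pos": pos,
        "ref": ref,
        "depth": depth,
        "count_A": A,
        "count_C": C,
        "count_G": G,
        "count_T": T,
    }


def make_table(rows):
    return pd.DataFrame(rows)


class TestCallThresholds:
    @pytest.mark.parametrize(
        "alt_count,min_freq,called",
        [
            (1, 0.02, False),  # 1% below the 2% filter
            (2, 0.02, True),  # exactly 2% is retained
            (2, 0.05, False),  # stricter 5% check drops it
            (5, 0.05, True),  # 5% passes the strict filter
        ],
    )
    def test_frequency_threshold(self, alt_count, min_freq, called):
        table = make_table([counts_row(depth=100, G=alt_count)])
        out = calling.call_het_sites(table, min_freq=min_freq, individual="x")
        assert (len(out) == 1) == called
        if called:
            assert out.iloc[0]["alt"] == "G"
            assert out.iloc[0]["alt_freq"] == alt_count / 100

    def test_min_depth(self):
        table = make_table([counts_row(depth=9, G=3)])
        assert len(calling.call_het_sites(table, min_depth=10)) == 0
        assert len(calling.call_het_sites(table, min_depth=5)) == 1

    def test_multiallelic_collapses_to_top_alt(self):
        table = make_table([counts_row(depth=100, C=3, G=7, T=5)])
        out = calling.call_het_sites(table, individual="x")
        assert out.iloc[0]["alt"] == "G"

    def test_tie_broken_by_base_order(self):
        table = make_table([counts_row(depth=100, C=5, G=5)])
        out = calling.call_het_sites(table, individual="x")
        assert out.iloc[0]["alt"] == "C"

    def test_frequency_uses_stated_depth_not_count_sum(self):
        # depth 200 but only 120 counted reads (N/other dropped upstream)
        row = counts_row(depth=200, A=110, G=10)
        out = calling.call_het_sites(make_table([row]), individual="x")
        assert out.iloc[0]["alt_freq"] == 10 / 200

    def test_zero_depth_rows_skipped(self):
        table = make_table(
            [counts_row(depth=0, pos=1), counts_row(depth=100, G=10, pos=2)]
        )
        out = calling.call_het_sites(table, individual="x")
        assert list(out["pos"]) == [2]

    def test_malformed_base_rejected(self):
        table = make_table([counts_row(ref="N", depth=100)])
        with pytest.raises(ValueError, match="reference"):
            calling.call_het_sites(table)

    def test_bad_min_freq_rejected(self):
        with pytest.raises(ValueError):
            calling.call_het_sites(make_table([counts_row()]), min_freq=0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        rows=st.lists(
            st.tuples(
                st.integers(10, 300),  # depth
                st.integers(0, 30),  # alt count bound
            ),
            min_size=1,
            max_size=20,
        ),
        f1=st.floats(0.01, 0.2),
        f2=st.floats(0.01, 0.2),
    )
    def test_raising_min_freq_never_adds_calls(self, rows, f1, f2):
        table = make_table(
            [
                counts_row(depth=d, G=min(a, d), pos=i + 1)
                for i, (d, a) in enumerate(rows)
            ]
        )
        lo, hi = sorted((f1, f2))
        n_lo = len(calling.call_het_sites(table, min_freq=lo))
        n_hi = len(calling.call_het_sites(table, min_freq=hi))
        assert n_hi <= n_lo


class TestSummaries:
    def test_reported_percentage_for_most_variable_snail(self):
        sites = pd.DataFrame(
            {
                "individual": "C854",
                "pos": range(1, 1889),
                "alt_freq": 0.011,
            }
        )
        s = calling.summarize_individual(sites, L_mt=14202)
        assert s.n_variable == 1888
        assert s.pct_sites_variable == pytest.approx(13.29, abs=0.01)
        assert round(s.pct_sites_variable) == 13

    def test_no_called_sites_undefined_mean(self):
        empty = pd.DataFrame(columns=["individual", "pos", "alt_freq"])
        s = calling.summarize_individual(empty, L_mt=100, individual="x")
        assert s.n_variable == 0
        assert s.pct_sites_variable == 0
        assert np.isnan(s.mean_freq_excl_zero)

    def test_incl_vs_excl_zero_means(self):
        sites = pd.DataFrame(
            {"individual": "x", "pos": [1, 2], "alt_freq": [0.10, 0.30]}
        )
        s = calling.summarize_individual(sites, L_mt=10, n_assayed=10)
        assert s.mean_freq_excl_zero == pytest.approx(20.0)
        assert s.mean_freq_incl_zero == pytest.approx(4.0)
        assert s.mean_freq_incl_zero <= s.mean_freq_excl_zero

    def test_round_trip_recovers_true_counts_noiselessly(
        self, small_genome, small_nonsyn_table
    ):
        """With no sequencing error and all true frequencies >= the filter,
        calling recovers exactly the true variable sites."""
        from conftest import small_config
        from mitohet import simulate as sim

        genome, ann = small_genome
        cfg = small_config(error_rate=0.0, mean_depth=4000.0, mu=0.0)
        state = sim.simulate_matriline(cfg, genome, ann, small_nonsyn_table)
        # push every true frequency comfortably above the 2% threshold
        state.freqs[state.freqs > 0] = np.clip(
            state.freqs[state.freqs > 0] + 0.05, None, 0.9
        )
        tables, _ = sim.simulate_readcounts(state, genome, cfg)
        sites = calling.call_many(tables)
        for i, ind in enumerate(state.individuals):
            truth = set(np.flatnonzero(state.freqs[i] > 0) + 1)
            called = set(sites[sites["individual"] == ind]["pos"])
            assert called == truth


class TestBamReadcountReader:
    def test_native_lines(self, tmp_path):
        path = tmp_path / "brc.tsv"
        path.write_text(
            "mt\t1\tA\t100\t=:0:...\tA:90:x:y\tC:4:x\tG:6:x\tT:0:x\tN:0:x\n"
            "mt\t2\tC\t50\t=:0:...\tA:0:x\tC:50:x\tG:0:x\tT:0:x\n"
        )
        df = calling.read_bam_readcount(path)
        assert list(df["pos"]) == [1, 2]
        assert df.iloc[0]["count_G"] == 6
        out = calling.call_het_sites(df, individual="x")
        assert out.iloc[0]["alt"] == "G" and out.iloc[0]["alt_freq"] == 0.06


def vcf_record(pos, qual=50.0, n=10, missing=0, bad_depth=0, alts=("G",)):
    depths = np.full(n, 100)
    depths[:bad_depth] = 5
    miss = np.zeros(n, dtype=bool)
    miss[n - missing :] = missing > 0
    return calling.VcfSiteRecord(
        pos=pos, ref="A", alts=tuple(alts), qual=qual, depths=depths, missing=miss
    )


class TestVcfFilter:
    def test_quality_boundary(self):
        records = [vcf_record(1, qual=29.0), vcf_record(2, qual=30.0)]
        kept, _ = calling.filter_vcf(records, 10, min_qual=30)
        assert [r.pos for r in kept] == [2]

    def test_exactly_ten_percent_missing_removed(self):
        records = [vcf_record(1, n=10, missing=1)]
        kept, log = calling.filter_vcf(records, 10)
        assert not kept and log["missingness"] == 1

    def test_just_under_ten_percent_kept(self):
        records = [vcf_record(1, n=11, missing=1)]
        kept, _ = calling.filter_vcf(records, 11)
        assert len(kept) == 1

    def test_out_of_range_depth_counts_as_missing(self):
        records = [vcf_record(1, n=10, bad_depth=1)]
        kept, _ = calling.filter_vcf(records, 10)
        assert not kept

    def test_multiallelic_excluded_and_logged(self):
        records = [vcf_record(1, alts=("G", "T"))]
        kept, log = calling.filter_vcf(records, 10)
        assert not kept and log["multiallelic"] == 1

    def test_toy_file_against_per_rule_oracle(self):
        """20 sites, 6 violating exactly one rule each; survivors equal the
        intersection of single-rule applications."""
        records = [vcf_record(i) for i in range(1, 15)]
        records += [
            vcf_record(15, qual=10.0),
            vcf_record(16, qual=29.9),
            vcf_record(17, n=10, missing=2),
            vcf_record(18, n=10, missing=5),
            vcf_record(19, bad_depth=2),
            vcf_record(20, alts=("G", "T")),
        ]
        kept, _ = calling.filter_vcf(records, 10)
        assert [r.pos for r in kept] == list(range(1, 15))

        # independent per-rule oracle: apply each rule alone, intersect
        rule_bi = {r.pos for r in records if len(r.alts) == 1}
        rule_q = {r.pos for r in records if r.qual >= 30}
        rule_m = {
            r.pos
            for r in records
            if (r.missing | (r.depths < 10) | (r.depths > 500)).sum() / 10 < 0.10
        }
        assert {r.pos for r in kept} == rule_bi & rule_q & rule_m

    def test_raising_qual_never_adds_sites(self):
        rng = np.random.default_rng(3)
        records = [
            vcf_record(i, qual=float(q)) for i, q in enumerate(rng.uniform(0, 120, 50))
        ]
        n30 = len(calling.filter_vcf(records, 10, min_qual=30)[0])
        n90 = len(calling.filter_vcf(records, 10, min_qual=90)[0])
        assert n90 <= n30


class TestConcordance:
    def test_identical_tables_perfect(self):
        f = {i: 0.01 * i for i in range(1, 11)}
        rep = calling.concordance(f, f)
        assert rep.r2 == pytest.approx(1.0)

    def test_negated_tables_anticorrelated(self):
        f = {i: 0.01 * i for i in range(1, 11)}
        g = {i: -v for i, v in f.items()}
        rep = calling.concordance(f, g)
        assert rep.r == pytest.approx(-1.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(8)
        a = {i: float(v) for i, v in enumerate(rng.uniform(0, 0.2, 10))}
        b = {i: float(v) for i, v in enumerate(rng.uniform(0, 0.2, 10))}
        rep = calling.concordance(a, b)
        x = np.array(list(a.values()))
        y = np.array(list(b.values()))
        r_direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert rep.r == pytest.approx(r_direct, abs=1e-12)

    def test_absent_keys_imputed_as_zero(self):
        a = {1: 0.1, 2: 0.2, 3: 0.3}
        b = {1: 0.1, 2: 0.2, 4: 0.4}
        rep = calling.concordance(a, b)
        assert rep.n == 4  # union of keys

    def test_zero_variance_undefined(self):
        a = {1: 0.1, 2: 0.1, 3: 0.1}
        b = {1: 0.1, 2: 0.2, 3: 0.3}
        rep = calling.concordance(a, b)
        assert not rep.defined

    def test_too_few_keys_rejected(self):
        with pytest.raises(ValueError):
            calling.concordance({1: 0.1}, {1: 0.2})

    def test_batches_of_same_matriline_agree(self, small_genome, small_nonsyn_table):
        """Two independent sequencing replicates of the same individuals
        (same truth, fresh noise) show strong per-individual concordance."""
        from conftest import small_config
        from mitohet import simulate as sim

        genome, ann = small_genome
        state = sim.simulate_matriline(
            small_config(), genome, ann, small_nonsyn_table
        )
        maps = []
        for seed in (101, 202):
            cfg = small_config(seed=seed, mean_depth=300.0)
            tables, _ = sim.simulate_readcounts(state, genome, cfg)
            sites = calling.call_many(tables)
            maps.append(
                {
                    (i, p): f
                    for i, p, f in zip(
                        sites["individual"], sites["pos"], sites["alt_freq"]
                    )
                }
            )
        rep = calling.concordance(maps[0], maps[1])
        assert rep.r2 > 0.7 and rep.p < 1e-10


class TestFalsePositiveCalibration:
    def test_error_only_call_rate_matches_analytic_tail(self, fp_calibration):
        """Error-only sequencing: the observed per-site call rate at the 2%
        filter sits within 3 SE of the exact multinomial tail probability."""
        c = fp_calibration
        assert abs(c["observed"] - c["analytic"]) <= 3 * c["se"]
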