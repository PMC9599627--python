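import numpy as np
import pandas as pd
import pytest

from bloomshift.config import SampleSheet, SampleSpec, SimConfig
from bloomshift.formats import AlignmentRecord
from bloomshift.simulate import generate_references, generate_reads, to_alignment_records
from bloomshift.snv import (
    SnvCall,
    SnvError,
    allele_trajectories,
    build_pileup,
    call_snvs,
    call_snvs_per_sample,
    classify_effect,
    snv_density,
)

REF = {"o": "ATGAAACCCGGGTTTAAACCCGGGTTTTAA"}  # 30 nt


def _aln(seq, pos=0, cigar=None, read_id="r"):
    cigar = cigar or [("M", len(seq))]
    return AlignmentRecord(read_id, "o", pos, cigar, nm=0, seq=seq)


class TestPileup:
    def test_single_matching_read(self):
        pile = build_pileup([_aln(REF["o"][:10])], REF)
        depth = pile.depth("o")
        assert (depth[:10] == 1).all() and (depth[10:] == 0).all()

    def test_deletion_emits_no_base(self):
        seq = REF["o"][:5] + REF["o"][7:12]  # 5M2D5M
        pile = build_pileup([_aln(seq, cigar=[("M", 5), ("D", 2), ("M", 5)])], REF)
        depth = pile.depth("o")
        assert (depth[:5] == 1).all()
        assert depth[5] == 0 and depth[6] == 0
        assert (depth[7:12] == 1).all()

    def test_insertion_consumes_read_only(self):
        seq = REF["o"][:5] + "AA" + REF["o"][5:10]
        pile = build_pileup([_aln(seq, cigar=[("M", 5), ("I", 2), ("M", 5)])], REF)
        assert (pile.depth("o")[:10] == 1).all()

    def test_overrun_names_record(self):
        with pytest.raises(SnvError, match="r9"):
            build_pileup([_aln("A" * 20, pos=15, read_id="r9")], REF)

    def test_secondary_ignored(self):
        rec = _aln(REF["o"][:10])
        rec.is_primary = False
        assert build_pileup([rec], REF).depth("o").sum() == 0

    def test_base_counts_sum_to_depth(self):
        rng = np.random.default_rng(0)
        alns = []
        for i in range(50):
            start = int(rng.integers(0, 20))
            seq = "".join(rng.choice(list("ACGT"), 10))
            alns.append(_aln(seq, pos=start, read_id=f"r{i}"))
        pile = build_pileup(alns, REF)
        assert (pile.counts["o"].sum(axis=0) == pile.depth("o")).all()


class TestCallThresholds:
    def _pileup_with(self, depth, alt):
        counts = {"o": np.zeros((4, 30), dtype=np.int64)}
        # site 10 is "G"; plant alt "T" (index 3)
        counts["o"][2, 10] = depth - alt
        counts["o"][3, 10] = alt
        from bloomshift.snv import Pileup

        return Pileup(counts)

    def test_depth_below_floor_never_called(self):
        assert call_snvs(self._pileup_with(3, 3), REF) == []

    def test_call_with_frequency(self):
        (call,) = call_snvs(self._pileup_with(20, 6), REF)
        assert call.pos == 11 and call.ref_allele == "G" and call.alt_allele == "T"

    def test_min_alt_count(self):
        assert call_snvs(self._pileup_with(20, 1), REF) == []

    def test_min_af(self):
        assert call_snvs(self._pileup_with(100, 4), REF) == []  # af 0.04 < 0.05

    def test_multiallelic_site_emits_multiple_calls(self):
        from bloomshift.snv import Pileup

        counts = {"o": np.zeros((4, 30), dtype=np.int64)}
        counts["o"][2, 10] = 10
        counts["o"][0, 10] = 5
        counts["o"][3, 10] = 5
        calls = call_snvs(Pileup(counts), REF)
        assert sorted(c.alt_allele for c in calls) == ["A", "T"]


STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TestClassifyEffect:
    def test_synonymous_third_position(self):
        call = SnvCall("x", 3, "T", "C")  # GAT -> GAC, Asp -> Asp
        assert classify_effect(call, "GAT") == "SYN"
        assert call.codon_index == 0 and call.codon_pos == 3

    def test_nonsynonymous_first_position(self):
        call = SnvCall("x", 1, "G", "T")  # GAT -> TAT, Asp -> Tyr
        assert classify_effect(call, "GAT") == "NONSYN"

    def test_stop_gain_is_nonsyn(self):
        call = SnvCall("x", 3, "G", "A")  # TGG -> TGA, Trp -> stop
        assert classify_effect(call, "TGG") == "NONSYN"

    def test_incomplete_trailing_codon_is_na(self):
        call = SnvCall("x", 4, "A", "C")
        assert classify_effect(call, "GATA") == "NA"

    def test_all_576_single_base_substitutions_match_table_oracle(self):
        bases = "ACGT"
        n = 0
        for codon, aa in STANDARD_CODE.items():
            for pos in range(3):
                for alt in bases:
                    if alt == codon[pos]:
                        continue
                    mutated = codon[:pos] + alt + codon[pos + 1 :]
                    expected = "SYN" if STANDARD_CODE[mutated] == aa else "NONSYN"
                    call = SnvCall("x", pos + 1, codon[pos], alt)
                    assert classify_effect(call, codon) == expected, f"{codon}->{mutated}"
                    n += 1
        assert n == 576


class TestOnSimulatedReads:
    def test_clean_data_zero_calls(self):
        cfg = SimConfig(
            seed=5, n_taxon_groups=1, orfs_per_group=10, error_rate=0.0,
            samples=[SampleSpec("S1", "N", "B1", "mid", 10_000)],
        )
        bundle = generate_references(cfg)
        alns = to_alignment_records(generate_reads(bundle, "S1"))
        pileups = {"S1": build_pileup(alns, bundle.references)}
        assert call_snvs_per_sample(pileups, bundle.references) == []

    def test_planted_snv_allele_fraction_within_binomial_ci(self):
        from scipy.stats import binom

        from conftest import plant_snvs

        cfg = SimConfig(
            seed=6, n_taxon_groups=1, orfs_per_group=5, error_rate=0.0,
            expr_log_sd=0.2, samples=[SampleSpec("S1", "N", "B1", "mid", 3_000)],
        )
        bundle = generate_references(cfg)
        cfg.snv_spec = plant_snvs(bundle, per_orf=1, freqs=(0.5, 0.5))
        bundle = generate_references(cfg)
        alns = to_alignment_records(generate_reads(bundle, "S1"))
        pileups = {"S1": build_pileup(alns, bundle.references)}
        calls = call_snvs_per_sample(pileups, bundle.references)
        assert len(calls) == len(cfg.snv_spec)
        for c in calls:
            depth, alt = c.samples["S1"]
            lo, hi = binom.ppf(0.005, depth, 0.5), binom.ppf(0.995, depth, 0.5)
            assert lo <= alt <= hi

    def test_error_driven_false_calls_bounded_by_binomial_tail(self):
        from scipy.stats import binom

        cfg = SimConfig(
            seed=7, n_taxon_groups=1, orfs_per_group=20, error_rate=0.001,
            expr_log_sd=0.2, samples=[SampleSpec("S1", "N", "B1", "mid", 30_000)],
        )
        bundle = generate_references(cfg)
        alns = to_alignment_records(generate_reads(bundle, "S1"))
        pileups = {"S1": build_pileup(alns, bundle.references)}
        calls = call_snvs_per_sample(pileups, bundle.references)
        # analytic bound: per site, P(specific alt base count >= max(min_alt, 0.05*depth))
        pile = pileups["S1"]
        expected = 0.0
        for orf in bundle.orf_ids:
            for d in pile.depth(orf):
                if d >= 4:
                    thresh = max(2, int(np.ceil(0.05 * d)))
                    expected += 3 * binom.sf(thresh - 1, int(d), 0.001 / 3)
        assert len(calls) <= max(5.0, 3 * expected)


class TestDensityAndTrajectories:
    def test_density_ratio(self):
        stats = snv_density(
            calls=[
                SnvCall("a", 5, "A", "C", called_in={"S1"}),
                SnvCall("b", 7, "A", "C", called_in={"S1"}),
            ],
            pileups={"S1": _dense_pileup(["a", "b", "c", "d"])},
            annotation=pd.DataFrame(
                {"orf_id": ["a", "b", "c", "d"], "taxon_group": ["g"] * 4}
            ),
        )
        (stat,) = stats
        assert stat.n_snvs == 2 and stat.n_orfs == 4 and stat.density == 0.5

    def test_zero_snvs_gives_zero_density(self):
        (stat,) = snv_density(
            [], {"S1": _dense_pileup(["a"])},
            pd.DataFrame({"orf_id": ["a"], "taxon_group": ["g"]}),
        )
        assert stat.density == 0.0

    def test_no_eligible_orfs_gives_missing_density(self):
        from bloomshift.snv import Pileup

        empty = Pileup({"a": np.zeros((4, 30), dtype=np.int64)})
        (stat,) = snv_density(
            [], {"S1": empty}, pd.DataFrame({"orf_id": ["a"], "taxon_group": ["g"]})
        )
        assert stat.density is None

    def _sheet(self):
        return SampleSheet.from_samples(
            [SampleSpec("M", "N", "B1", "mid", 100), SampleSpec("L", "N", "B1", "late", 100)]
        )

    def _call(self, af_mid, af_late, depth=100):
        return SnvCall(
            "a", 5, "A", "C",
            samples={"M": (depth, int(af_mid * depth)), "L": (depth, int(af_late * depth))},
            called_in={"M", "L"},
        )

    def test_sweep_flagged(self):
        (rec,) = allele_trajectories([self._call(0.3, 0.95)], self._sheet())
        assert rec.sweep and rec.delta_af == pytest.approx(0.65)

    def test_high_start_not_a_sweep(self):
        (rec,) = allele_trajectories([self._call(0.6, 0.95)], self._sheet())
        assert not rec.sweep

    def test_low_end_not_a_sweep(self):
        (rec,) = allele_trajectories([self._call(0.3, 0.7)], self._sheet())
        assert not rec.sweep

    def test_uncovered_stage_gives_missing_af(self):
        call = SnvCall("a", 5, "A", "C", samples={"M": (0, 0), "L": (50, 48)}, called_in={"L"})
        (rec,) = allele_trajectories([call], self._sheet())
        assert rec.af_mid is None and rec.delta_af is None and not rec.sweep


def _dense_pileup(orfs, depth=10, length=30):
    from bloomshift.snv import Pileup

    counts = {}
    for o in orfs:
        mat = np.zeros((4, length), dtype=np.int64)
        mat[0, :] = depth
        counts[o] = mat
    return Pileup(counts)
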