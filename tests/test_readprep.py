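import numpy as np
import pytest

from annotaudit import readprep as rp
from annotaudit import synthetic_data as syn

from oracles import brute_adapter_match, brute_polya_3prime

TSO = "CAATGAAGTCGCAGGGTTGGG"


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLocateTso:
    def test_exact_adapter_at_five_prime(self, adapter_spec, rng):
        read = rp.RawRead("r1", TSO + random_seq(rng, 100))
        m = rp.locate_tso(read, adapter_spec)
        assert m.orientation == "sense"
        assert m.edit_distance == 0
        assert m.span == (0, 21)

    def test_revcomp_adapter_at_three_prime(self, adapter_spec, rng):
        # the 3' adapter sequence from the trimming step
        assert rp.revcomp(TSO) == "CCCAACCCTGCGACTTCATTG"
        read = rp.RawRead("r2", random_seq(rng, 100) + "CCCAACCCTGCGACTTCATTG")
        m = rp.locate_tso(read, adapter_spec)
        assert m.orientation == "antisense"
        assert m.edit_distance == 0
        assert m.span == (100, 121)

    def test_two_substitutions_match_three_do_not(self, adapter_spec, rng):
        body = random_seq(rng, 179)
        # floor(0.1 * 21) = 2 errors allowed for the full adapter
        mutated2 = "CTATGAAGTCGCAGGGTTGGC"  # subs at positions 1 and 20
        read2 = rp.RawRead("m2", mutated2 + body)
        assert rp.locate_tso(read2, adapter_spec).orientation == "sense"
        mutated3 = "CTATGATGTCGCAGGGTTGGC"  # subs at positions 1, 6, 20
        read3 = rp.RawRead("m3", mutated3 + body)
        m = rp.locate_tso(read3, adapter_spec)
        # a full-adapter hit is ruled out; only a spurious truncated overlap
        # could remain, and the oracle agrees either way
        assert (m.orientation, m.span, m.edit_distance) == _oracle_tso(
            read3.sequence, adapter_spec
        )

    def test_absence_is_none(self, adapter_spec, rng):
        read = rp.RawRead("r3", random_seq(rng, 150))
        assert rp.locate_tso(read, adapter_spec).orientation == "none"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, adapter_spec, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            seq = _random_adapter_read(rng)
            read = rp.RawRead("x", seq)
            m = rp.locate_tso(read, adapter_spec)
            assert (m.orientation, m.span, m.edit_distance) == _oracle_tso(
                seq, adapter_spec
            )


def _random_adapter_read(rng, length=60):
    """Random read, frequently with a (mutated) adapter at either end."""
    seq = "".join(rng.choice(list("ACGT"), size=length))
    mode = rng.integers(0, 4)
    adapter = list(TSO)
    for _ in range(rng.integers(0, 4)):  # 0-3 random substitutions
        adapter[rng.integers(0, len(adapter))] = rng.choice(list("ACGT"))
    adapter = "".join(adapter)
    if mode == 1:
        seq = adapter + seq[len(adapter):]
    elif mode == 2:
        seq = seq[: -len(adapter)] + rp.revcomp(adapter)
    elif mode == 3:
        k = int(rng.integers(1, 7))
        seq = adapter[k:] + seq[len(adapter) - k:]
    return seq


def _oracle_tso(seq, spec):
    """Orientation decision replicated around the brute-force matcher."""
    sense = brute_adapter_match(seq.upper(), spec)
    anti = brute_adapter_match(rp.revcomp(seq.upper()), spec)
    if sense is None and anti is None:
        return ("none", None, None)
    if anti is None or (sense is not None and sense[0] <= anti[0]):
        d, s, e, _ = sense
        return ("sense", (s, e), d)
    d, s, e, _ = anti
    n = len(seq)
    return ("antisense", (n - e, n - s), d)


class TestDetectPolya:
    def test_simple_tail(self, adapter_spec):
        run = rp.detect_polya("ACGT" + "A" * 12, adapter_spec)
        assert run is not None
        assert (run.start, run.length) == (4, 12)

    def test_short_run_absent(self, adapter_spec):
        assert rp.detect_polya("A" * 5 + "CGCGCG", adapter_spec) is None

    def test_one_mismatch_tolerated(self, adapter_spec):
        run = rp.detect_polya("ACG" + "AAAAGAAAA", adapter_spec)
        assert run is not None
        assert (run.start, run.length, run.n_mismatches) == (3, 9, 1)

    def test_five_prime_polyt(self, adapter_spec):
        run = rp.detect_polya(
            "T" * 10 + "ACGTACGT" * 10, adapter_spec, end="5prime", base="T"
        )
        assert run is not None
        assert run.start == 0
        assert run.length == 10

    def test_empty_sequence_rejected(self, adapter_spec):
        with pytest.raises(ValueError):
            rp.detect_polya("", adapter_spec)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, adapter_spec, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ACGT"), p=[0.5, 0.2, 0.2, 0.1], size=80))
        got = rp.detect_polya(seq, adapter_spec)
        expected = brute_polya_3prime(
            seq, adapter_spec.polya_min_run, adapter_spec.polya_max_mismatches
        )
        if expected is None:
            assert got is None
        else:
            assert (got.start, got.length) == expected


class TestSelectFullLength:
    def test_constructed_triple(self, adapter_spec, rng):
        body = random_seq(rng, 80)
        r1 = TSO + body + "A" * 12
        reads = [
            rp.RawRead("a", r1),
            rp.RawRead("b", rp.revcomp(r1)),
            rp.RawRead("c", body),
        ]
        kept, report = rp.select_full_length(reads, adapter_spec)
        assert [r.id for r in kept] == ["a", "b"]
        assert kept[0].sense_sequence == kept[1].sense_sequence == body + "A" * 12
        assert not kept[0].was_reverse_complemented
        assert kept[1].was_reverse_complemented
        assert (
            report.n_input, report.n_kept, report.n_discarded_no_tso,
            report.n_reverse_complemented, report.n_polya_detected,
        ) == (3, 2, 1, 1, 2)

    def test_empty_input(self, adapter_spec):
        kept, report = rp.select_full_length([], adapter_spec)
        assert kept == []
        assert report.n_input == report.n_kept == report.n_discarded_no_tso == 0

    def test_simulated_batch_recovery(self, small_transcriptome, adapter_spec):
        genome, profiles, _, _ = small_transcriptome
        cfg = syn.ReadSimConfig(
            n_reads=400, antisense_fraction=0.3, adapterless_fraction=0.2, seed=21
        )
        reads, truth = syn.simulate_reads(profiles, genome, cfg)
        kept, report = rp.select_full_length(
            (rp.RawRead(i, s) for i, s in reads), adapter_spec
        )
        truth = truth.set_index("read_id")
        se = np.sqrt(0.8 * 0.2 / cfg.n_reads)
        assert abs(report.n_kept / report.n_input - 0.8) <= 3 * se
        n_correct = sum(
            1 for r in kept
            if bool(truth.loc[r.id, "antisense"]) == r.was_reverse_complemented
        )
        assert n_correct / len(kept) >= 0.99
        # no adapterless read survives
        assert not any(truth.loc[r.id, "adapterless"] for r in kept)

    def test_report_conservation(self, small_transcriptome, adapter_spec):
        genome, profiles, _, _ = small_transcriptome
        cfg = syn.ReadSimConfig(n_reads=100, adapterless_fraction=0.5, seed=2)
        reads, _ = syn.simulate_reads(profiles, genome, cfg)
        _, report = rp.select_full_length(
            (rp.RawRead(i, s) for i, s in reads), adapter_spec
        )
        assert report.n_input == (
            report.n_kept + report.n_discarded_no_tso + report.n_discarded_chimera
        )

    def test_orientation_idempotence(self, small_transcriptome, adapter_spec):
        genome, profiles, _, _ = small_transcriptome
        cfg = syn.ReadSimConfig(n_reads=30, antisense_fraction=0.5, seed=17)
        reads, _ = syn.simulate_reads(profiles, genome, cfg)
        kept, _ = rp.select_full_length(
            (rp.RawRead(i, s) for i, s in reads), adapter_spec
        )
        reprepped = [
            rp.RawRead(r.id, adapter_spec.tso_sequence + r.sense_sequence)
            for r in kept
        ]
        kept2, _ = rp.select_full_length(reprepped, adapter_spec)
        assert [r.sense_sequence for r in kept2] == [
            r.sense_sequence for r in kept
        ]

    def test_revcomp_symmetry(self, small_transcriptome, adapter_spec):
        genome, profiles, _, _ = small_transcriptome
        cfg = syn.ReadSimConfig(n_reads=30, seed=19)
        reads, _ = syn.simulate_reads(profiles, genome, cfg)
        for i, s in reads:
            fwd, _ = rp.select_full_length([rp.RawRead(i, s)], adapter_spec)
            rev, _ = rp.select_full_length(
                [rp.RawRead(i, rp.revcomp(s))], adapter_spec
            )
            assert len(fwd) == len(rev) == 1
            assert fwd[0].sense_sequence == rev[0].sense_sequence
            assert fwd[0].was_reverse_complemented != rev[0].was_reverse_complemented


class TestFastxIO:
    def test_fastq_roundtrip(self, tmp_path, adapter_spec, rng):
        body = random_seq(rng, 50)
        path = tmp_path / "in.fastq"
        path.write_text(f"@r1\n{TSO + body}\n+\n{'I' * (21 + 50)}\n")
        reads = list(rp.read_fastx(str(path)))
        assert len(reads) == 1
        kept, _ = rp.select_full_length(reads, adapter_spec)
        out = tmp_path / "out.fastq"
        rp.write_fastq(kept, str(out))
        back = list(rp.read_fastx(str(out)))
        assert back[0].sequence == body

    def test_fasta_and_gzip(self, tmp_path, rng):
        import gzip

        seq = random_seq(rng, 30)
        path = tmp_path / "in.fasta.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(f">r1\n{seq}\n")
        reads = list(rp.read_fastx(str(path)))
        assert reads[0].sequence == seq
        assert reads[0].qualities is None


class TestAdapterSpecValidation:
    def test_short_tso_rejected(self):
        with pytest.raises(ValueError):
            rp.AdapterSpec(tso_sequence="ACGT")

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            rp.AdapterSpec(max_error_rate=0.6)
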