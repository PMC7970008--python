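"""Quality filtering, contaminant screening and the filtering report."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_seq
from hypomre.qc import (
    CLASS_ORDER,
    ContaminantIndex,
    MalformedReadError,
    QCStats,
    ReadPair,
    Rejection,
    qc_report,
    quality_filter,
    run_qc,
)
from hypomre._io import quals_to_str, write_fastq
from hypomre._kmer import revcomp


def _pair(seq1, q1, seq2=None, q2=None, rid="r1"):
    seq2 = seq2 if seq2 is not None else seq1
    q2 = q2 if q2 is not None else q1
    return ReadPair(rid, seq1, q1, seq2, q2)


def _q(score, n):
    return quals_to_str(np.full(n, score))


class TestQualityFilter:
    def test_clean_pair_unchanged(self, rng):
        seq = random_seq(rng, 300)
        pair = _pair(seq, _q(40, 300))
        out = quality_filter(pair)
        assert isinstance(out, ReadPair)
        assert out.seq1 == seq and out.qual1 == pair.qual1

    def test_low_quality_tail_trims_to_short(self, rng):
        # 300 bp whose last 260 bases are Q2: trimmed to 40 < 50 -> "short"
        seq = random_seq(rng, 300)
        qual = _q(40, 40) + _q(2, 260)
        out = quality_filter(_pair(seq, qual))
        assert isinstance(out, Rejection)
        assert out.reason == "short"

    def test_boundary_exactly_min_len_survives(self, rng):
        seq = random_seq(rng, 300)
        qual = _q(40, 50) + _q(2, 250)
        out = quality_filter(_pair(seq, qual))
        assert isinstance(out, ReadPair)
        assert len(out.seq1) == 50

    def test_ambiguous_read_rejected(self, rng):
        half_n = "".join(
            "N" if i % 2 == 0 else c for i, c in enumerate(random_seq(rng, 200))
        )
        out = quality_filter(_pair(half_n, _q(40, 200)))
        assert isinstance(out, Rejection)
        assert out.reason == "ambiguous"

    def test_n_ends_trimmed(self, rng):
        core = random_seq(rng, 100)
        seq = "NNNN" + core + "NN"
        out = quality_filter(_pair(seq, _q(40, len(seq))))
        assert isinstance(out, ReadPair)
        assert out.seq1 == core

    def test_malformed_pair_names_read(self):
        with pytest.raises(MalformedReadError, match="badread"):
            ReadPair("badread", "ACGT", "III", "ACGT", "IIII")

    @given(st.data())
    def test_idempotent(self, data):
        """quality_filter(quality_filter(p)) == quality_filter(p)."""
        n = data.draw(st.integers(60, 120))
        seq = data.draw(st.text(alphabet="ACGTN", min_size=n, max_size=n))
        qual = quals_to_str(
            np.array(data.draw(st.lists(st.integers(2, 41), min_size=n, max_size=n)))
        )
        out = quality_filter(_pair(seq, qual))
        if isinstance(out, ReadPair):
            again = quality_filter(out)
            assert isinstance(again, ReadPair)
            assert (again.seq1, again.qual1, again.seq2, again.qual2) == (
                out.seq1, out.qual1, out.seq2, out.qual2,
            )


@pytest.fixture(scope="module")
def index():
    rng = np.random.default_rng(7)
    return (
        ContaminantIndex.from_sequences(
            {c: random_seq(rng, 4000) for c in CLASS_ORDER}, k=31
        ),
        rng,
    )


class TestContaminantScreen:

    def test_exact_substring_classified(self, index):
        idx, _ = index
        src = "phix"
        rng = np.random.default_rng(7)
        ref = random_seq(rng, 4000)  # same draw order as the fixture: phix first
        read = ref[1000:1200]
        assert idx.classify(read) == "phix"

    def test_random_read_is_clean(self, index, rng):
        idx, _ = index
        assert idx.classify(random_seq(rng, 200)) == "clean"

    def test_short_read_is_clean(self, index):
        idx, _ = index
        assert idx.classify("ACGTACGT") == "clean"

    def test_chimeric_read_majority_class(self, rng):
        chloro = random_seq(rng, 4000)
        idx = ContaminantIndex.from_sequences({"chloroplast": chloro}, k=31)
        read = chloro[100:220] + random_seq(rng, 80)  # 120 bp chloroplast + 80 random
        # oracle: direct canonical k-mer set intersection
        k = 31
        ref_kmers = set()
        for i in range(len(chloro) - k + 1):
            s = chloro[i : i + k]
            ref_kmers.add(min(s, revcomp(s)))
        hits = sum(
            1
            for i in range(len(read) - k + 1)
            if min(read[i : i + k], revcomp(read[i : i + k])) in ref_kmers
        )
        frac = hits / (len(read) - k + 1)
        assert frac >= 0.5
        assert idx.classify(read) == "chloroplast"

    def test_reverse_complement_still_classified(self, rng):
        mito = random_seq(rng, 4000)
        idx = ContaminantIndex.from_sequences({"mitochondrion": mito}, k=31)
        assert idx.classify(revcomp(mito[500:700])) == "mitochondrion"


class TestRunQC:
    def _write_pairs(self, tmp_path, pairs):
        write_fastq(tmp_path / "R1.fastq", [(p.id, p.seq1, p.qual1) for p in pairs])
        write_fastq(tmp_path / "R2.fastq", [(p.id, p.seq2, p.qual2) for p in pairs])
        return tmp_path / "R1.fastq", tmp_path / "R2.fastq"

    def test_partition_invariant_and_labels(self, tmp_path, rng):
        """clean + contaminant classes == hq per direction; >=99% label accuracy."""
        from hypomre.simulate import SimConfig, simulate
        from hypomre.qc import ContaminantIndex

        cfg = SimConfig(seed=31, genome_length=40_000, n_accessions=2, n_pairs=2000)
        out = simulate(cfg, tmp_path / "sim")
        idx = ContaminantIndex.from_fasta(out.contaminants_fasta, 31)
        s1, s2 = run_qc(
            *out.fastq["acc01"], idx,
            tmp_path / "o1.fastq", tmp_path / "o2.fastq", accession="acc01",
        )
        kept = sum(1 for _ in open(tmp_path / "o1.fastq")) // 4
        for s in (s1, s2):
            assert s.filtered_hq == s.hq - sum(s.contaminants.values())
            assert 0 < s.filtered_hq <= s.hq <= s.total
        # compare against planted truth labels
        truth = pd.read_csv(out.truth_reads, sep="\t")
        truth = truth[truth["read_id"].str.startswith("acc01:")]
        n_contam_true = len(truth)
        n_contam_called = sum(s1.contaminants.values())
        # per-direction R1 classification should recover nearly all spiked pairs
        assert abs(n_contam_called - n_contam_true) <= 0.01 * n_contam_true + 2
        assert kept <= s1.filtered_hq  # pair-level drop can only lose more

    def test_read_level_precision_and_recall(self, tmp_path):
        """Per-read labels against planted truth: >=99% precision and recall."""
        from hypomre.simulate import SimConfig, simulate
        from hypomre._io import iter_fastq

        # default error rate: at k=31 a read keeps >'min_frac' intact k-mers
        # with overwhelming probability only when errors are this rare
        cfg = SimConfig(seed=41, genome_length=50_000, n_accessions=1,
                        n_pairs=3000)
        out = simulate(cfg, tmp_path / "sim")
        idx = ContaminantIndex.from_fasta(out.contaminants_fasta, 31)
        truth = pd.read_csv(out.truth_reads, sep="\t")
        truth_label = dict(zip(truth["read_id"], truth["source"]))
        reads = list(iter_fastq(out.fastq["acc01"][0]))
        called = idx.classify_batch([s for _, s, _ in reads])
        tp = fp = fn = 0
        for (rid, _, _), lab in zip(reads, called):
            want = truth_label.get(rid, "clean")
            if lab != "clean" and lab == want:
                tp += 1
            elif lab != "clean" and lab != want:
                fp += 1
            elif lab == "clean" and want != "clean":
                fn += 1
        assert tp / (tp + fp) >= 0.99
        assert tp / (tp + fn) >= 0.99

    def test_report_no_contaminants(self):
        s = QCStats("a", "R1", total=100, hq=100, contaminants={})
        row = qc_report([s]).iloc[0]
        assert row["filtered_hq"] == 100
        assert row["filtered_hq_pct"] == 100.0

    def test_phix_spike_binomial(self, tmp_path, rng):
        """1% phiX spike over 1000 pairs: called count within 3 sigma of 10."""
        from hypomre.simulate import SimConfig, simulate

        cfg = SimConfig(
            seed=33, genome_length=40_000, n_accessions=1, n_pairs=1000,
            contaminant_fractions={"phix": 0.01},
        )
        out = simulate(cfg, tmp_path / "sim")
        idx = ContaminantIndex.from_fasta(out.contaminants_fasta, 31)
        s1, _ = run_qc(
            *out.fastq["acc01"], idx, tmp_path / "o1.fastq", tmp_path / "o2.fastq"
        )
        sd = np.sqrt(1000 * 0.01 * 0.99)
        assert abs(s1.contaminants.get("phix", 0) - 10) <= 3 * sd

    def test_empty_input_zero_row(self, tmp_path):
        (tmp_path / "e1.fastq").write_text("")
        (tmp_path / "e2.fastq").write_text("")
        s1, s2 = run_qc(
            tmp_path / "e1.fastq", tmp_path / "e2.fastq", None,
            tmp_path / "o1.fastq", tmp_path / "o2.fastq",
        )
        row = qc_report([s1, s2]).iloc[0]
        assert row["total"] == 0 and row["filtered_hq_pct"] == 0.0
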