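"""Unitig assembly, gapless mapping, retention and pileups."""
import numpy as np
import pytest

from conftest import random_seq
from hypomre import assembly
from hypomre.assembly import (
    Alignment,
    Contig,
    IntegrityError,
    assemble,
    auto_kmer_threshold,
    build_reference_hypomethylome,
    map_read,
    map_reads,
    pileup,
    pileup_to_frame,
    frame_to_pileup,
    retain_contigs,
)
from hypomre._kmer import revcomp


def _norm(s):
    return min(s, revcomp(s))


class TestAssemble:
    def test_single_fragment_single_contig(self, rng):
        frag = random_seq(rng, 300)
        contigs = assemble([frag] * 50)
        assert len(contigs) == 1
        assert _norm(contigs[0].seq) == _norm(frag)

    def test_two_families_two_contigs(self, rng):
        f1, f2 = random_seq(rng, 250), random_seq(rng, 400)
        contigs = assemble([f1] * 20 + [f2] * 20)
        assert {_norm(c.seq) for c in contigs} == {_norm(f1), _norm(f2)}

    def test_short_unitig_excluded(self, rng):
        short = random_seq(rng, 90)
        keep = random_seq(rng, 200)
        contigs = assemble([short] * 20 + [keep] * 20, min_contig_len=100)
        assert {_norm(c.seq) for c in contigs} == {_norm(keep)}

    def test_multiset_oracle_on_separated_fragments(self, rng):
        """Contigs == fragments as sets up to reverse complement."""
        frags = [random_seq(rng, int(rng.integers(150, 500))) for _ in range(15)]
        reads = [f for f in frags for _ in range(10)]
        contigs = assemble(reads)
        assert sorted(_norm(c.seq) for c in contigs) == sorted(_norm(f) for f in frags)

    def test_deterministic_order_and_ids(self, rng):
        frags = [random_seq(rng, 200) for _ in range(5)]
        reads = [f for f in frags for _ in range(10)]
        a = assemble(list(reads))
        b = assemble(list(reversed(reads)))
        assert [(c.contig_id, c.seq) for c in a] == [(c.contig_id, c.seq) for c in b]

    def test_below_count_threshold_empty(self, rng):
        contigs = assemble([random_seq(rng, 200)], min_kmer_count=2)
        assert contigs == []

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            assemble(["ACGT" * 50], k=30)

    def test_auto_threshold_separates_error_peak(self):
        # 1000 error k-mers at counts 1-3, signal at ~60
        counts = np.concatenate(
            [
                np.ones(800, dtype=np.int64),
                np.full(150, 2),
                np.full(50, 3),
                np.full(3000, 60),
                np.full(1000, 59),
            ]
        )
        thr = auto_kmer_threshold(counts)
        assert 2 <= thr <= 15
        assert thr > 3  # the count-3 error tail must fall below the cutoff

    def test_auto_threshold_low_depth_fallback(self):
        assert auto_kmer_threshold(np.full(100, 5)) == 2


class TestMapping:
    def test_exact_substring_full_length(self, rng):
        ctg = Contig("c0", random_seq(rng, 500))
        read = ctg.seq[100:350]
        (aln,), unmapped = map_reads([("r", read)], [ctg])
        assert not unmapped
        assert (aln.start, aln.strand, aln.matches, aln.length) == (100, "+", 250, 250)

    def test_reverse_complement_read(self, rng):
        ctg = Contig("c0", random_seq(rng, 500))
        read = revcomp(ctg.seq[100:350])
        (aln,), _ = map_reads([("r", read)], [ctg])
        assert (aln.start, aln.strand, aln.matches) == (100, "-", 250)

    def test_no_seed_unmapped(self, rng):
        ctg = Contig("c0", random_seq(rng, 500))
        alns, unmapped = map_reads([("r", random_seq(rng, 300))], [ctg])
        assert alns == [] and unmapped == ["r"]

    def test_two_mismatches_identity(self, rng):
        """Hamming-distance oracle: 2 mismatches in 300 bp -> matches 298."""
        ctg = Contig("c0", random_seq(rng, 600))
        read = list(ctg.seq[100:400])
        for p in (150, 200):
            read[p - 100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p - 100]]
        read = "".join(read)
        hamming = sum(a != b for a, b in zip(read, ctg.seq[100:400]))
        (aln,), _ = map_reads([("r", read)], [ctg])
        assert aln.matches == 300 - hamming == 298
        assert aln.identity >= 0.9

    def test_low_identity_rejected(self, rng):
        base = random_seq(rng, 300)
        ctg = Contig("c0", base)
        # keep one seed k-mer, scramble the rest
        read = base[:40] + random_seq(rng, 260)
        alns, unmapped = map_reads([("r", read)], [ctg], min_identity=0.9)
        assert unmapped == ["r"]

    def test_end_clipped_placement(self, rng):
        ctg = Contig("c0", random_seq(rng, 300))
        tail = random_seq(rng, 60)
        read = ctg.seq[200:] + tail  # 100 bp inside + 60 bp overhang
        (aln,), _ = map_reads([("r", read)], [ctg])
        assert (aln.start, aln.length, aln.read_start) == (200, 100, 0)
        assert aln.matches == 100


class TestRetention:
    def _contig_with_reads(self, rng, n_reads):
        ctg = Contig("c0", random_seq(rng, 300))
        alns = [
            Alignment(f"r{i}", "c0", 0, "+", 300, 300) for i in range(n_reads)
        ]
        return ctg, alns

    @pytest.mark.parametrize("n,kept", [(5, True), (4, False), (0, False)])
    def test_five_read_rule(self, rng, n, kept):
        ctg, alns = self._contig_with_reads(rng, n)
        retained = retain_contigs([ctg], alns, min_reads=5)
        assert bool(retained) == kept

    def test_distinct_reads_counted_once(self, rng):
        ctg = Contig("c0", random_seq(rng, 300))
        alns = [Alignment("same", "c0", 0, "+", 300, 300)] * 6
        assert retain_contigs([ctg], alns, min_reads=5) == []


class TestReferenceHypomethylome:
    def test_identical_genomes_match_single_assembly(self, rng):
        frags = [random_seq(rng, 300) for _ in range(8)]
        reads = [(f"r{i}_{j}", f) for i, f in enumerate(frags) for j in range(10)]
        per_acc = {"a1": reads, "a2": [(f"b{rid}", s) for rid, s in reads]}
        contigs, alns, stats = build_reference_hypomethylome(per_acc)
        single = assemble([s for _, s in reads])
        single = retain_contigs(single, map_reads(reads, single)[0])
        assert {_norm(c.seq) for c in contigs} == {_norm(c.seq) for c in single}

    def test_accession_specific_fragment_isolated(self, rng):
        shared = [random_seq(rng, 300) for _ in range(5)]
        only_a = random_seq(rng, 300)
        ra = [(f"a{i}_{j}", f) for i, f in enumerate(shared + [only_a]) for j in range(10)]
        rb = [(f"b{i}_{j}", f) for i, f in enumerate(shared) for j in range(10)]
        contigs, alns, _ = build_reference_hypomethylome({"A": ra, "B": rb})
        assert any(_norm(c.seq) == _norm(only_a) for c in contigs)
        target = next(c for c in contigs if _norm(c.seq) == _norm(only_a))
        b_on_target = [x for x in alns["B"] if x.contig_id == target.contig_id]
        assert b_on_target == []

    def test_requires_two_accessions(self, rng):
        with pytest.raises(ValueError):
            build_reference_hypomethylome({"a": [("r", random_seq(rng, 200))]})


class TestPileup:
    def test_uniform_coverage(self, rng):
        ctg = Contig("c0", random_seq(rng, 300))
        reads = {f"r{i}": ctg.seq[50:250] for i in range(10)}
        alns = [Alignment(rid, "c0", 50, "+", 200, 200) for rid in reads]
        arrays = pileup(alns, [ctg], reads)
        arr = arrays["c0"]
        base = "ACGT".index(ctg.seq[100])
        assert arr[100, base] == 10 and arr[100].sum() == 10
        assert arr[0].sum() == 0  # uncovered positions are present with depth 0

    def test_mixed_bases_counted(self, rng):
        ctg = Contig("c0", random_seq(rng, 100))
        pos = 50
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ctg.seq[pos]]
        reads = {}
        alns = []
        for i in range(10):
            s = ctg.seq if i < 8 else ctg.seq[:pos] + alt + ctg.seq[pos + 1 :]
            reads[f"r{i}"] = s
            alns.append(Alignment(f"r{i}", "c0", 0, "+", 99, 100))
        arr = pileup(alns, [ctg], reads)["c0"]
        assert arr[pos, "ACGT".index(ctg.seq[pos])] == 8
        assert arr[pos, "ACGT".index(alt)] == 2

    def test_depth_equals_alignment_length_sum(self, rng):
        ctg = Contig("c0", random_seq(rng, 400))
        reads = {f"r{i}": ctg.seq[i * 10 : i * 10 + 150] for i in range(20)}
        alns = [Alignment(f"r{i}", "c0", i * 10, "+", 150, 150) for i in range(20)]
        arr = pileup(alns, [ctg], reads)["c0"]
        assert arr.sum() == sum(a.length for a in alns)

    def test_out_of_bounds_alignment_rejected(self, rng):
        ctg = Contig("c0", random_seq(rng, 100))
        bad = Alignment("r", "c0", 50, "+", 100, 100)
        with pytest.raises(IntegrityError):
            pileup([bad], [ctg], {"r": random_seq(rng, 100)})

    def test_frame_roundtrip(self, rng):
        ctg = Contig("c0", random_seq(rng, 120))
        reads = {"r": ctg.seq[10:110]}
        alns = [Alignment("r", "c0", 10, "+", 100, 100)]
        arrays = pileup(alns, [ctg], reads)
        df = pileup_to_frame(arrays)
        back = frame_to_pileup(df, {"c0": 120})
        assert (back["c0"] == arrays["c0"]).all()
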