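import numpy as np
import pytest

from mpratile._seq import revcomp, seq_to_array
from mpratile.design import DesignParams, tile_oligos
from mpratile.quantify import (
    AssignmentRecord,
    CountMatrix,
    OligoAssigner,
    QuantifyError,
    Sample,
    TrimSpec,
    _banded_edit,
    assign_reads,
    count_umis,
    external_aligner_available,
    parse_sam_assignments,
    read_fastq_pairs,
    trim_adapters,
)
from mpratile.simulate import CountSimParams, ReadSimParams, simulate_reads, simulate_utrs

FWD_ADAPTER = "GGCGGAAAGATCGCCGTGTAAGTTTGCTTCGATATCCGCATGCTA"
REV_ADAPTER = "CTGATCAGCGGGTTTCACTAGTGCGACCGCAAGAG"


def write_fastq(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


@pytest.fixture(scope="module")
def pool2nt():
    """Three UTRs tiled at a 2-nt step (the hardest assignment geometry)."""
    params = CountSimParams(n_genes=3, utr_len_range=(500, 900), seed=31, flank_len=0)
    metas, _ = simulate_utrs(params)
    pool = []
    for m in metas:
        pool.extend(tile_oligos(m, DesignParams(step=2, flank_extension=0)))
    return pool


class TestTrimAdapters:
    def test_exact_adapter_removed(self, tmp_path):
        insert1, insert2 = "ACGT" * 24, "TGCA" * 22
        write_fastq(tmp_path / "r1.fq", [("r1", FWD_ADAPTER + insert1)])
        write_fastq(tmp_path / "r2.fq", [("r1", REV_ADAPTER + insert2)])
        spec = TrimSpec(FWD_ADAPTER, REV_ADAPTER)
        report = trim_adapters(
            tmp_path / "r1.fq", tmp_path / "r2.fq",
            tmp_path / "o1.fq", tmp_path / "o2.fq", spec,
        )
        assert report.total == 1 and report.retained == 1
        pairs = list(read_fastq_pairs(tmp_path / "o1.fq", tmp_path / "o2.fq"))
        assert pairs[0][1] == insert1 and pairs[0][3] == insert2

    def test_read_without_adapter_dropped_and_counted(self, tmp_path):
        write_fastq(tmp_path / "r1.fq", [("a", FWD_ADAPTER + "A" * 50), ("b", "T" * 90)])
        write_fastq(tmp_path / "r2.fq", [("a", REV_ADAPTER + "C" * 50), ("b", REV_ADAPTER + "C" * 50)])
        report = trim_adapters(
            tmp_path / "r1.fq", tmp_path / "r2.fq",
            tmp_path / "o1.fq", tmp_path / "o2.fq",
            TrimSpec(FWD_ADAPTER, REV_ADAPTER),
        )
        assert report.total == 2 and report.retained == 1 and report.dropped == 1

    def test_mismatch_tolerance(self, tmp_path):
        mutated = "T" + FWD_ADAPTER[1:]  # 1 mismatch in 45 nt < 10%
        write_fastq(tmp_path / "r1.fq", [("a", mutated + "A" * 50)])
        write_fastq(tmp_path / "r2.fq", [("a", REV_ADAPTER + "C" * 50)])
        report = trim_adapters(
            tmp_path / "r1.fq", tmp_path / "r2.fq",
            tmp_path / "o1.fq", tmp_path / "o2.fq",
            TrimSpec(FWD_ADAPTER, REV_ADAPTER),
        )
        assert report.retained == 1

    def test_retention_near_one_on_clean_simulation(self, pool2nt, tmp_path):
        params = ReadSimParams(
            n_reads=300, seed=32, fwd_adapter=FWD_ADAPTER, rev_adapter=REV_ADAPTER
        )
        simulate_reads(pool2nt, None, params, tmp_path / "r1.fq", tmp_path / "r2.fq")
        report = trim_adapters(
            tmp_path / "r1.fq", tmp_path / "r2.fq",
            tmp_path / "o1.fq", tmp_path / "o2.fq",
            TrimSpec(FWD_ADAPTER, REV_ADAPTER),
        )
        assert report.fraction_retained >= 0.99

    def test_truncated_fastq_errors(self, tmp_path):
        write_fastq(tmp_path / "r1.fq", [("a", "A" * 10), ("b", "A" * 10)])
        write_fastq(tmp_path / "r2.fq", [("a", "C" * 10)])
        with pytest.raises(QuantifyError, match="record 1"):
            list(read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))

    def test_empty_adapter_rejected(self):
        with pytest.raises(QuantifyError):
            TrimSpec("", REV_ADAPTER)


class TestBandedEdit:
    def test_exact_match(self):
        a = seq_to_array("ACGTACGT")
        assert _banded_edit(a, a, 3) == 0

    def test_substitution(self):
        assert _banded_edit(seq_to_array("ACGTACGT"), seq_to_array("ACGAACGT"), 3) == 1

    def test_deletion_in_read(self):
        # read lost one template base; template end free
        read = seq_to_array("ACGTCGT")
        template = seq_to_array("ACGTACGTAA")
        assert _banded_edit(read, template, 3) == 1

    def test_free_template_end(self):
        assert _banded_edit(seq_to_array("ACGT"), seq_to_array("ACGTGGGG"), 3) == 0


class TestAssignment:
    def test_error_free_pair_assigned(self, pool2nt, tmp_path):
        params = ReadSimParams(n_reads=50, seed=33, mutation_rate=0.0, deletion_rate=0.0)
        truth = simulate_reads(pool2nt, None, params, tmp_path / "r1.fq", tmp_path / "r2.fq")
        recs = assign_reads(tmp_path / "r1.fq", tmp_path / "r2.fq", pool2nt)
        assert all(r.oligo_id == truth.read_to_oligo[r.read_name] for r in recs)

    def test_umi_is_first_8nt_of_reverse_read(self, pool2nt, tmp_path):
        params = ReadSimParams(n_reads=20, seed=34, mutation_rate=0.0, deletion_rate=0.0)
        simulate_reads(pool2nt, None, params, tmp_path / "r1.fq", tmp_path / "r2.fq")
        rev_reads = {
            name: s2 for name, _, _, s2, _ in
            read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")
        }
        recs = assign_reads(tmp_path / "r1.fq", tmp_path / "r2.fq", pool2nt)
        for r in recs:
            assert r.umi == rev_reads[r.read_name][:8]

    def test_high_effort_rescues_deletion_reads(self, pool2nt, tmp_path):
        params = ReadSimParams(n_reads=2000, seed=35, deletion_rate=0.01)
        truth = simulate_reads(pool2nt, None, params, tmp_path / "r1.fq", tmp_path / "r2.fq")

        def rate(effort):
            recs = assign_reads(tmp_path / "r1.fq", tmp_path / "r2.fq", pool2nt, effort=effort)
            return sum(r.oligo_id == truth.read_to_oligo[r.read_name] for r in recs) / len(recs)

        assert rate("default") < rate("high")

    def test_no_wrong_assignments(self, pool2nt, tmp_path):
        params = ReadSimParams(n_reads=2000, seed=36)
        truth = simulate_reads(pool2nt, None, params, tmp_path / "r1.fq", tmp_path / "r2.fq")
        for effort in ("default", "high"):
            recs = assign_reads(tmp_path / "r1.fq", tmp_path / "r2.fq", pool2nt, effort=effort)
            wrong = [
                r for r in recs
                if r.oligo_id is not None and r.oligo_id != truth.read_to_oligo[r.read_name]
            ]
            assert wrong == []

    def test_conservation_invariant(self, pool2nt, tmp_path):
        params = ReadSimParams(n_reads=500, seed=37)
        simulate_reads(pool2nt, None, params, tmp_path / "r1.fq", tmp_path / "r2.fq")
        recs = assign_reads(tmp_path / "r1.fq", tmp_path / "r2.fq", pool2nt, effort="default")
        assigned = sum(r.oligo_id is not None for r in recs)
        unassigned = sum(r.oligo_id is None for r in recs)
        assert assigned + unassigned == 500 == len(recs)

    def test_unknown_effort_rejected(self, pool2nt):
        with pytest.raises(QuantifyError):
            OligoAssigner(pool2nt, effort="turbo")


class TestSamParsing:
    SAM = """\
@HD\tVN:1.6\tSO:unsorted
@SQ\tSN:oligoA\tLN:260
@SQ\tSN:oligoB\tLN:260
read1\t99\toligoA\t1\t42\t97M\t=\t170\t260\t{}\t{}
read1\t147\toligoA\t170\t42\t91M\t=\t1\t-260\t{}\t{}
read2\t77\t*\t0\t0\t*\t*\t0\t0\t{}\t{}
""".format("A" * 97, "I" * 97, "C" * 91, "I" * 91, "G" * 50, "I" * 50)

    def test_parse_proper_pairs(self, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(self.SAM)
        assigned = parse_sam_assignments(sam)
        assert assigned == {"read1": ("oligoA", 42)}


@pytest.mark.skipif(
    not external_aligner_available(), reason="bowtie2 not installed"
)
def test_external_matches_builtin_on_error_free_reads(pool2nt, tmp_path):
    params = ReadSimParams(n_reads=2000, seed=38, mutation_rate=0.0, deletion_rate=0.0)
    simulate_reads(pool2nt, None, params, tmp_path / "r1.fq", tmp_path / "r2.fq")
    builtin = assign_reads(tmp_path / "r1.fq", tmp_path / "r2.fq", pool2nt, aligner="builtin")
    external = assign_reads(tmp_path / "r1.fq", tmp_path / "r2.fq", pool2nt, aligner="external")
    b = {r.read_name: r.oligo_id for r in builtin}
    e = {r.read_name: r.oligo_id for r in external}
    assert b == e


class TestCountUmis:
    SAMPLES = [Sample("s1", "soma", 1), Sample("s2", "neurite", 1)]

    def test_set_cardinality(self):
        recs = [
            AssignmentRecord("r1", "A", 42, "AAAAAAAA"),
            AssignmentRecord("r2", "A", 42, "AAAAAAAA"),
            AssignmentRecord("r3", "A", 42, "CCCCCCCC"),
        ]
        cm = count_umis({"s1": recs}, self.SAMPLES, ["A", "B"])
        assert cm.counts[0, 0] == 2  # {u1, u1, u2} -> 2

    def test_zero_row_retained(self):
        cm = count_umis({"s1": []}, self.SAMPLES, ["A", "B"])
        assert cm.oligo_ids == ["A", "B"]
        assert (cm.counts == 0).all()

    def test_duplicate_free_equals_read_counts(self, rng):
        umis = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(40)]
        assert len(set(umis)) == len(umis), "fixture must be duplicate-free"
        recs = [AssignmentRecord(f"r{i}", "A", 42, u) for i, u in enumerate(umis)]
        cm = count_umis({"s1": recs}, self.SAMPLES, ["A"])
        assert cm.counts[0, 0] == len(recs)

    def test_order_invariance(self, rng):
        recs = [
            AssignmentRecord(f"r{i}", rng.choice(["A", "B"]), 42,
                             "".join(rng.choice(list("ACGT"), size=8)))
            for i in range(100)
        ]
        cm1 = count_umis({"s1": recs}, self.SAMPLES, ["A", "B"])
        cm2 = count_umis({"s1": recs[::-1]}, self.SAMPLES, ["A", "B"])
        assert (cm1.counts == cm2.counts).all()

    def test_unassigned_reads_ignored(self):
        recs = [AssignmentRecord("r1", None, 0, "AAAAAAAA")]
        cm = count_umis({"s1": recs}, self.SAMPLES, ["A"])
        assert cm.counts.sum() == 0

    def test_unknown_oligo_errors(self):
        recs = [AssignmentRecord("r1", "ghost", 42, "AAAAAAAA")]
        with pytest.raises(QuantifyError, match="unknown oligo"):
            count_umis({"s1": recs}, self.SAMPLES, ["A"])


def test_error_free_matrix_equals_truth(pool2nt, tmp_path):
    """On error-free data with unique UMIs the count matrix is exactly the
    truth read-count table."""
    params = ReadSimParams(n_reads=800, seed=39, mutation_rate=0.0, deletion_rate=0.0)
    truth = simulate_reads(pool2nt, None, params, tmp_path / "r1.fq", tmp_path / "r2.fq")
    recs = assign_reads(tmp_path / "r1.fq", tmp_path / "r2.fq", pool2nt)
    umi_sets: dict[str, set] = {}
    unique = all(
        rec.umi not in umi_sets.setdefault(rec.oligo_id, set())
        and not umi_sets[rec.oligo_id].add(rec.umi)
        for rec in recs
    )
    if not unique:
        pytest.skip("UMI collision in fixture; exact equality not expected")
    samples = [Sample("s1", "soma", 1)]
    cm = count_umis({"s1": recs}, samples, [r.oligo_id for r in pool2nt])
    expected = {oid: 0 for oid in cm.oligo_ids}
    for oid in truth.read_to_oligo.values():
        expected[oid] += 1
    assert list(cm.counts[:, 0]) == [expected[oid] for oid in cm.oligo_ids]


class TestCountMatrix:
    def test_shape_validation(self):
        with pytest.raises(QuantifyError, match="inconsistent"):
            CountMatrix(["a"], [Sample("s", "soma", 1)], np.zeros((2, 1), dtype=int))

    def test_duplicate_sample_labels(self):
        with pytest.raises(QuantifyError, match="duplicate"):
            CountMatrix(
                ["a"], [Sample("s", "soma", 1), Sample("s", "neurite", 1)],
                np.zeros((1, 2), dtype=int),
            )

    def test_tsv_roundtrip(self, tmp_path):
        samples = [Sample("s1", "soma", 1), Sample("n1", "neurite", 1)]
        cm = CountMatrix(["a", "b"], samples, np.array([[1, 2], [3, 4]]))
        cm.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert back.oligo_ids == cm.oligo_ids
        assert (back.counts == cm.counts).all()
        assert [s.compartment for s in back.samples] == ["soma", "neurite"]
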