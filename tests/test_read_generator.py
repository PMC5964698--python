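import numpy as np
import pytest

from npbss import (
    ConfigError,
    CountSpec,
    ErrorConfig,
    apply_errors,
    parse_read_id,
    sample_read_origin,
    simulate,
    write_fastq,
)
from npbss.error_model import EmpiricalErrorModel
from npbss.length_model import LengthParams
from npbss.qv_model import QVTable, load_qv_table
from npbss.read_generator import (
    KIND_DEL,
    KIND_INS,
    KIND_MATCH,
    KIND_SUB,
    events_from_steps,
)
from npbss.reference_io import ReferenceSet, reverse_complement
from npbss.synthetic import random_genome


def _template(n, seed=0):
    return random_genome(n, seed=seed).records[0][1]


class TestApplyErrors:
    def test_zero_error_is_identity(self, rng):
        # all-zero rates => p_error 0 everywhere => read == template
        template = _template(2000)
        cfg = ErrorConfig(sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        out = apply_errors(template, cfg, load_qv_table(), 2000, rng)
        assert out.sequence == template
        assert out.consumed == 2000
        assert np.all(out.step_kinds == KIND_MATCH)

    def test_forced_substitution(self, rng):
        # p_error pinned at the 0.999 clamp with a substitution-only split:
        # essentially every base substituted, length preserved exactly
        template = _template(5000)
        model = EmpiricalErrorModel(a=0.009, b=0.99)
        cfg = ErrorConfig(
            sub_rate=0.5, ins_rate=0.0, del_rate=0.0, model=model,
            calibration_scale=1.0,
        )
        out = apply_errors(template, cfg, QVTable((10,), (1.0,)), 5000, rng)
        assert len(out.sequence) == 5000
        hamming = sum(a != b for a, b in zip(out.sequence, template))
        n_sub = int((out.step_kinds == KIND_SUB).sum())
        assert hamming == n_sub  # substituted bases always differ
        assert n_sub / 5000 > 0.98

    def test_event_accounting_identities(self, default_run):
        for read in default_run[:50]:
            counts = read.event_counts()
            assert counts[KIND_MATCH] + counts[KIND_SUB] + counts[KIND_DEL] == len(
                read.template
            )
            assert counts[KIND_MATCH] + counts[KIND_SUB] + counts[KIND_INS] == len(
                read.sequence
            )
            assert len(read.sequence) == len(read.qvs)

    def test_rate_recovery_at_defaults(self, default_run):
        # genome-average event rates converge to the configured 6/3/6
        counts = sum(r.event_counts() for r in default_run)
        n_cols = counts.sum()
        for kind, target in ((KIND_SUB, 0.06), (KIND_INS, 0.03), (KIND_DEL, 0.06)):
            observed = counts[kind] / n_cols
            se = np.sqrt(target * (1 - target) / n_cols)
            assert abs(observed - target) < 3 * se

    def test_empty_template_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_errors("", ErrorConfig(), load_qv_table(), 10, rng)

    def test_n_template_bases_survive(self, rng):
        # N matches are emitted as N; substitutions at N re-draw from ACGT
        template = "N" * 3000
        cfg = ErrorConfig().calibrated_against(load_qv_table())
        out = apply_errors(template, cfg, load_qv_table(), 3000, rng)
        for ev in events_from_steps(
            template[: out.consumed], out.sequence, out.step_kinds, out.step_qvs
        ):
            if ev.kind == "match":
                assert ev.base_emitted == "N"
            if ev.kind == "substitution":
                assert ev.base_emitted in "ACGT"


class TestEventScripts:
    def test_events_are_a_faithful_edit_script(self, default_run):
        # replaying the recorded events reproduces both the read and the
        # template exactly
        for read in default_run[:10]:
            emitted = []
            consumed = []
            for ev in read.events:
                if ev.base_emitted is not None:
                    emitted.append(ev.base_emitted)
                    assert ev.read_pos == len(emitted) - 1
                if ev.base_template is not None:
                    consumed.append(ev.base_template)
                if ev.kind == "substitution":
                    assert ev.base_emitted != ev.base_template
                if ev.kind == "insertion":
                    assert ev.base_template is None
                if ev.kind == "deletion":
                    assert ev.base_emitted is None and ev.read_pos is None
            assert "".join(emitted) == read.sequence
            assert "".join(consumed) == read.template

    def test_template_matches_reference_coordinates(self, genome_1mb, default_run):
        for read in default_run[:10]:
            ref_slice = genome_1mb[read.ref_id][read.start : read.end]
            expected = ref_slice if read.strand == "+" else reverse_complement(ref_slice)
            assert read.template == expected
            origin = parse_read_id(read.id)
            assert (origin.start, origin.end, origin.strand) == (
                read.start,
                read.end,
                read.strand,
            )


class TestSampleReadOrigin:
    def test_single_valid_position(self, rng):
        refs = ReferenceSet((("r", "ACGTACGTAC"),))
        rid, start, strand = sample_read_origin(refs, 10, rng)
        assert (rid, start) == ("r", 0)

    def test_length_proportional_record_choice(self, rng):
        refs = ReferenceSet(
            (("big", _template(90_000, seed=1)), ("small", _template(10_000, seed=2)))
        )
        n = 20_000
        picks = sum(
            sample_read_origin(refs, 100, rng)[0] == "big" for _ in range(n)
        )
        assert abs(picks / n - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)

    def test_strand_balance(self, rng):
        refs = ReferenceSet((("r", _template(10_000)),))
        n = 20_000
        plus = sum(sample_read_origin(refs, 100, rng)[2] == "+" for _ in range(n))
        assert abs(plus / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_no_record_long_enough(self, rng):
        refs = ReferenceSet((("r", "ACGT"),))
        with pytest.raises(ConfigError):
            sample_read_origin(refs, 100, rng)


class TestSimulate:
    def test_exact_read_count(self, genome_small):
        reads = list(
            simulate(
                genome_small,
                CountSpec(mode="explicit_n", n=25, mean_len=2000),
                seed=5,
            )
        )
        assert len(reads) == 25

    def test_minimal_run(self, genome_small, tmp_path):
        reads = list(
            simulate(genome_small, CountSpec(mode="explicit_n", n=1, mean_len=2000), seed=5)
        )
        assert len(reads) == 1
        assert write_fastq(reads, tmp_path / "one.fq") == 1

    def test_same_seed_byte_identical_fastq(self, genome_small, tmp_path):
        for name in ("a.fq", "b.fq"):
            reads = simulate(
                genome_small,
                CountSpec(mode="explicit_n", n=30, mean_len=2000),
                seed=11,
            )
            write_fastq(reads, tmp_path / name)
        assert (tmp_path / "a.fq").read_bytes() == (tmp_path / "b.fq").read_bytes()

    def test_lengths_within_bounds(self, genome_small):
        params = LengthParams(mu=7.2, sigma=0.4, min_len=800, max_len=3000)
        reads = list(
            simulate(
                genome_small,
                CountSpec(mode="explicit_n", n=50, mean_len=2000),
                length_params=params,
                seed=2,
            )
        )
        lens = [len(r.sequence) for r in reads]
        assert min(lens) >= 800 and max(lens) <= 3000

    def test_depth_mode_read_count(self, genome_small):
        reads = list(
            simulate(
                genome_small,
                CountSpec(mode="depth", depth=2, mean_len=2000),
                seed=2,
            )
        )
        # ceil(2 * 100000 / 2000) = 100
        assert len(reads) == 100

    def test_resample_file_mode_fits_lognormal(self, genome_small):
        source = tuple(
            int(x)
            for x in np.rint(
                np.exp(np.random.default_rng(0).normal(7.3, 0.3, size=500))
            )
        )
        reads = list(
            simulate(
                genome_small,
                CountSpec(mode="resample_file", n=40, source_lengths=source),
                seed=2,
            )
        )
        assert len(reads) == 40
        lens = np.array([len(r.sequence) for r in reads])
        assert min(source) <= lens.min() and lens.max() <= max(source)

    def test_truncation_at_record_end_warns(self, caplog):
        # a read spanning the whole record: deletions exhaust the template
        # before the target length is reached
        refs = random_genome(1000, seed=9)
        params = LengthParams(
            mu=float(np.log(1000)) + 0.001, sigma=0.01, min_len=1000, max_len=1000
        )
        with caplog.at_level("WARNING"):
            reads = list(
                simulate(
                    refs,
                    CountSpec(mode="explicit_n", n=5, mean_len=1000),
                    length_params=params,
                    seed=3,
                )
            )
        assert any(len(r.sequence) < 1000 for r in reads)
        assert "truncated" in caplog.text
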