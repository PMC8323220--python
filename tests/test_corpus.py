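"""Corpus I/O, diagnostics, and the synthetic generator."""

import numpy as np
import pytest

from critens import (
    CategorySchema,
    LabeledText,
    SyntheticSpec,
    class_distribution,
    generate_synthetic_corpus,
    read_corpus,
    split_records,
    subsample_training_set,
    write_corpus,
)
from critens.corpus import CorpusFormatError, class_private_tokens, shared_tokens


class TestReadWrite:
    def test_tsv_reading_maps_labels_to_sorted_dense_indices(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("年龄 > 80岁\tAge\n男、女不限\tGender\n", encoding="utf-8")
        records, schema = read_corpus(p, format="tsv")
        assert schema.names == ("Age", "Gender")
        assert [(r.text, r.label, r.split) for r in records] == [
            ("年龄 > 80岁", 0, "train"),
            ("男、女不限", 1, "train"),
        ]

    def test_empty_file_yields_empty_corpus_and_schema(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        records, schema = read_corpus(p)
        assert records == [] and schema.n == 0

    def test_repeated_record_shares_label_index(self, tmp_path):
        p = tmp_path / "rep.tsv"
        p.write_text("入组标准\tInclusion\n" * 5, encoding="utf-8")
        records, _ = read_corpus(p, format="tsv")
        assert len(records) == 5 and {r.label for r in records} == {0}

    @pytest.mark.parametrize("fmt", ["tsv", "jsonl"])
    def test_round_trip_identity(self, tmp_path, fmt):
        schema = CategorySchema(("Age", "Diagnostic", "Therapy"))
        records = [
            LabeledText("年龄 > 80岁", 0, "train"),
            LabeledText("病理诊断明确", 1, "valid"),
            LabeledText("正在接受放疗", 2, "test"),
        ]
        path = tmp_path / f"c.{fmt}"
        write_corpus(records, schema, path, format=fmt)
        back, back_schema = read_corpus(path, format=fmt)
        assert back == records and back_schema == schema

    def test_tsv_escapes_tabs_and_newlines_inside_text(self, tmp_path):
        schema = CategorySchema(("X",))
        records = [LabeledText("a\tb\nc\\d", 0)]
        path = tmp_path / "esc.tsv"
        write_corpus(records, schema, path, format="tsv")
        back, _ = read_corpus(path, format="tsv")
        assert back == records

    def test_jsonl_preserves_non_ascii(self, tmp_path):
        schema = CategorySchema(("诊断",))
        records = [LabeledText("年龄 ≥ 18 岁且 ≤ 75 岁", 0)]
        path = tmp_path / "u.jsonl"
        write_corpus(records, schema, path)
        assert "年龄" in path.read_text(encoding="utf-8")
        back, back_schema = read_corpus(path)
        assert back == records and back_schema == schema

    def test_missing_text_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text('{"text": "ok", "label": "A"}\n{"label": "B"}\n')
        with pytest.raises(CorpusFormatError, match=":2:"):
            read_corpus(p)

    def test_unknown_format_is_a_usage_error(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            read_corpus(tmp_path / "x.csv", format="csv")

    def test_label_outside_schema_rejected_on_write(self, tmp_path):
        schema = CategorySchema(("A",))
        with pytest.raises(ValueError, match="outside schema"):
            write_corpus([LabeledText("t", 1)], schema, tmp_path / "x.jsonl")


class TestClassDistribution:
    def test_direct_count_includes_zero_classes(self):
        schema = CategorySchema(("A", "B", "C"))
        records = [LabeledText("x", 0), LabeledText("y", 0), LabeledText("z", 1)]
        assert class_distribution(records, schema).tolist() == [2, 1, 0]

    def test_empty_corpus_gives_zero_vector(self):
        schema = CategorySchema(("A", "B"))
        assert class_distribution([], schema).tolist() == [0, 0]

    def test_counts_sum_to_corpus_size(self):
        records, schema = generate_synthetic_corpus(SyntheticSpec(seed=3))
        assert class_distribution(records, schema).sum() == len(records)

    def test_imbalanced_generator_yields_spread_counts(self):
        spec = SyntheticSpec(imbalance_exponent=1.2, seed=0)
        records, schema = generate_synthetic_corpus(spec)
        counts = class_distribution(records, schema)
        assert counts.max() > counts.min()


class TestSyntheticGenerator:
    def test_balanced_no_noise_texts_use_only_private_tokens(self):
        spec = SyntheticSpec(
            n_classes=4, total_samples=400, imbalance_exponent=0.0,
            noise_rate=0.0, seed=0,
        )
        records, schema = generate_synthetic_corpus(spec)
        counts = class_distribution(records, schema)
        assert np.all(np.abs(counts - 100) < 40)
        vocabs = {k: set(class_private_tokens(spec, k)) for k in range(4)}
        for rec in records[:50]:
            toks = {rec.text[i : i + 3] for i in range(0, len(rec.text), 3)}
            assert toks <= vocabs[rec.label]

    def test_seed_determinism_is_byte_identical(self):
        spec = SyntheticSpec(imbalance_exponent=2.0, seed=0)
        a, sa = generate_synthetic_corpus(spec)
        b, sb = generate_synthetic_corpus(spec)
        assert a == b and sa == sb

    def test_class_counts_within_3_sigma_of_multinomial_expectation(self):
        spec = SyntheticSpec(n_classes=8, total_samples=2000, imbalance_exponent=1.5, seed=11)
        records, schema = generate_synthetic_corpus(spec)
        counts = class_distribution(records, schema)
        w = spec.zipf_weights()
        expect = spec.total_samples * w
        sigma = np.sqrt(spec.total_samples * w * (1 - w))
        assert np.all(np.abs(counts - expect) <= 3 * sigma)

    def test_private_vocabularies_are_disjoint(self):
        spec = SyntheticSpec(seed=0)
        pools = [set(class_private_tokens(spec, k)) for k in range(spec.n_classes)]
        pools.append(set(shared_tokens(spec)))
        for i in range(len(pools)):
            for j in range(i + 1, len(pools)):
                assert not pools[i] & pools[j]

    def test_noise_free_corpus_is_separable_by_nearest_centroid(self):
        """Upper-bound fixture: disjoint private vocabularies imply a
        bag-of-tokens nearest-centroid rule classifies test perfectly."""
        spec = SyntheticSpec(
            n_classes=6, total_samples=600, noise_rate=0.0, seed=5
        )
        records, schema = generate_synthetic_corpus(spec)
        tokens = sorted(
            {t for k in range(6) for t in class_private_tokens(spec, k)}
        )
        tok_ix = {t: i for i, t in enumerate(tokens)}

        def bag(text):
            v = np.zeros(len(tokens))
            for i in range(0, len(text), 3):
                v[tok_ix[text[i : i + 3]]] += 1
            return v

        train = split_records(records, "train")
        test = split_records(records, "test")
        centroids = np.stack([
            np.mean([bag(r.text) for r in train if r.label == k], axis=0)
            for k in range(schema.n)
        ])
        correct = sum(
            int(np.argmin(((centroids - bag(r.text)) ** 2).sum(axis=1)) == r.label)
            for r in test
        )
        assert correct == len(test)

    def test_every_class_reaches_the_training_split(self):
        records, schema = generate_synthetic_corpus(SyntheticSpec(seed=1))
        train_labels = {r.label for r in split_records(records, "train")}
        assert train_labels == set(range(schema.n))

    def test_total_below_classes_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            generate_synthetic_corpus(
                SyntheticSpec(n_classes=8, total_samples=4)
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_classes": 1},
            {"noise_rate": 1.5},
            {"length_range": (0, 4)},
            {"split_fractions": (0.5, 0.2, 0.2)},
            {"imbalance_exponent": -1.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticSpec(**kwargs)


class TestSubsample:
    def test_fraction_one_is_identity(self):
        records, _ = generate_synthetic_corpus(SyntheticSpec(seed=2))
        assert subsample_training_set(records, 1.0, seed=0) == list(records)

    def test_half_fraction_halves_training_split_only(self):
        records, _ = generate_synthetic_corpus(SyntheticSpec(seed=2))
        n_train = len(split_records(records, "train"))
        reduced = subsample_training_set(records, 0.5, seed=0)
        assert len(split_records(reduced, "train")) == round(n_train * 0.5)
        assert split_records(reduced, "test") == split_records(records, "test")
        assert split_records(reduced, "valid") == split_records(records, "valid")

    def test_different_seeds_draw_different_subsets_of_equal_size(self):
        records, _ = generate_synthetic_corpus(SyntheticSpec(seed=2))
        draws = [
            tuple(r.text for r in split_records(subsample_training_set(records, 0.5, seed=s), "train"))
            for s in range(5)
        ]
        assert len({len(d) for d in draws}) == 1
        assert len(set(draws)) > 1

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            subsample_training_set([], 0.0, seed=0)
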