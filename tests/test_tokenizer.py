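"""Vocabulary, separator dialects, padding, MLM corruption."""

import numpy as np
import pytest
from scipy.stats import chisquare

from abcurriculum.records import SequenceRecord
from abcurriculum.tokenizer import (VOCAB, Vocabulary, encode, decode, corrupt,
                                    BRANCH_MASK, BRANCH_RANDOM, BRANCH_KEEP)
from abcurriculum.synthdata import GeneratorConfig, generate


def make_paired(heavy="QLSS", light="DIIK"):
    return SequenceRecord(record_id="r0", heavy_chain=heavy, light_chain=light,
                          chain_type="paired")


class TestVocabulary:
    def test_size_and_special_tokens(self):
        assert len(VOCAB) == 33
        assert "<sep>" in VOCAB.tokens
        for tok in ("<cls>", "<pad>", "<eos>", "<unk>", "<mask>"):
            assert tok in VOCAB.tokens

    def test_bijection(self):
        assert len(VOCAB.index) == len(VOCAB.tokens)
        for tok, i in VOCAB.index.items():
            assert VOCAB.tokens[i] == tok

    def test_unknown_residue_maps_to_unk(self):
        ids = VOCAB.encode_residues("A7J")   # 7 and J are not tokens
        assert ids[0] == VOCAB.index["A"]
        assert ids[1] == VOCAB.unk_id and ids[2] == VOCAB.unk_id


class TestEncode:
    def test_paired_cls_dialect_layout(self):
        # mirrors the QL…SS<cls>DI…IK pattern, framed by start/end tokens
        ex = encode(make_paired(), dialect="cls", pad_to=16)
        ids = ex.token_ids
        expected = ([VOCAB.cls_id] + [VOCAB.index[c] for c in "QLSS"]
                    + [VOCAB.cls_id] + [VOCAB.index[c] for c in "DIIK"]
                    + [VOCAB.eos_id] + [VOCAB.pad_id] * 5)
        assert ids.tolist() == expected
        assert len(ex) == 16

    def test_sep_dialect_uses_sep_token(self):
        ex = encode(make_paired(), dialect="sep", pad_to=16)
        assert list(ex.token_ids).count(VOCAB.sep_id) == 1
        assert list(ex.token_ids).count(VOCAB.cls_id) == 1  # BOS only

    def test_unpaired_heavy_trailing_separator(self):
        rec = SequenceRecord(record_id="h", heavy_chain="QLSS", chain_type="heavy")
        ex = encode(rec, dialect="cls", pad_to=10)
        # cls QLSS cls eos
        assert ex.token_ids[5] == VOCAB.cls_id
        assert ex.token_ids[6] == VOCAB.eos_id

    def test_unpaired_light_leading_separator(self):
        rec = SequenceRecord(record_id="l", light_chain="DIIK", chain_type="light")
        ex = encode(rec, dialect="sep", pad_to=10)
        assert ex.token_ids[1] == VOCAB.sep_id
        assert ex.token_ids[2] == VOCAB.index["D"]

    def test_none_dialect_has_no_separator(self):
        rec = SequenceRecord(record_id="h", heavy_chain="QLSS", chain_type="heavy")
        ex = encode(rec, dialect="none", pad_to=10)
        ids = ex.token_ids.tolist()
        assert ids[:6] == [VOCAB.cls_id] + [VOCAB.index[c] for c in "QLSS"] \
            + [VOCAB.eos_id]
        assert VOCAB.sep_id not in ids
        assert ids.count(VOCAB.cls_id) == 1

    def test_light_first_is_mirror_of_heavy_first(self):
        rec = make_paired()
        lf = encode(rec, dialect="sep", chain_order="light_first", pad_to=16)
        expected = ([VOCAB.cls_id] + [VOCAB.index[c] for c in "DIIK"]
                    + [VOCAB.sep_id] + [VOCAB.index[c] for c in "QLSS"]
                    + [VOCAB.eos_id] + [VOCAB.pad_id] * 5)
        assert lf.token_ids.tolist() == expected

    def test_special_mask_covers_exactly_non_residues(self):
        ex = encode(make_paired(), dialect="cls", pad_to=16)
        residue_ids = set(VOCAB.residue_ids.tolist())
        for pos in range(len(ex)):
            is_residue_token = (int(ex.token_ids[pos]) in residue_ids
                                and ex.attention_mask[pos])
            assert ex.special_mask[pos] == (not is_residue_token)

    def test_length_error_names_record(self):
        with pytest.raises(ValueError, match="r0"):
            encode(make_paired("Q" * 200, "D" * 200), pad_to=320)

    @pytest.mark.parametrize("dialect", ["sep", "cls", "none"])
    @pytest.mark.parametrize("chain_type", ["paired", "heavy", "light"])
    def test_encode_decode_round_trip(self, dialect, chain_type):
        if chain_type == "paired":
            rec = make_paired("QVQLVQSG", "EIVLTQSP")
        elif chain_type == "heavy":
            rec = SequenceRecord(record_id="x", heavy_chain="QVQLVQSG",
                                 chain_type="heavy")
        else:
            rec = SequenceRecord(record_id="x", light_chain="EIVLTQSP",
                                 chain_type="light")
        ex = encode(rec, dialect=dialect, pad_to=32)
        back = decode(ex)
        assert back.chain_type == rec.chain_type
        assert back.heavy_chain == rec.heavy_chain
        assert back.light_chain == rec.light_chain

    def test_region_labels_aligned(self):
        recs = generate(GeneratorConfig(n_paired=1, seed=0))
        ex = encode(recs[0], dialect="cls")
        cdr3 = recs[0].region_span("heavy", "CDR3")
        labelled = [i for i, l in enumerate(ex.region_labels) if l == "H:CDR3"]
        assert len(labelled) == cdr3.end - cdr3.start
        # the labelled tokens spell the CDR3 sequence
        seq = "".join(VOCAB.tokens[ex.token_ids[i]] for i in labelled)
        assert seq == recs[0].heavy_chain[cdr3.start:cdr3.end]


class TestCorrupt:
    def test_zero_rate_is_identity(self):
        ex = encode(make_paired(), pad_to=16)
        ids, labels, branches = corrupt(ex, select_rate=0.0, rng=0)
        assert np.array_equal(ids, ex.token_ids)
        assert np.all(labels == -100)
        assert np.all(branches == 0)

    def test_fraction_validation(self):
        ex = encode(make_paired(), pad_to=16)
        with pytest.raises(ValueError):
            corrupt(ex, mask_frac=0.9, random_frac=0.2, keep_frac=0.1, rng=0)

    def test_special_positions_untouched(self):
        recs = generate(GeneratorConfig(n_paired=50, seed=1))
        rng = np.random.default_rng(0)
        for rec in recs:
            ex = encode(rec)
            ids, labels, branches = corrupt(ex, rng=rng)
            special = ex.special_mask
            assert np.all(labels[special] == -100)
            assert np.array_equal(ids[special], ex.token_ids[special])

    def test_corruption_statistics(self):
        # selection ~15%, mask ~80% / random ~10% / keep ~10% of selected
        recs = generate(GeneratorConfig(n_unpaired_heavy=2000, seed=0))
        rng = np.random.default_rng(0)
        n_residues = n_selected = n_masked = n_random = n_kept = 0
        changed_random = 0
        for rec in recs:
            ex = encode(rec, pad_to=160)
            ids, labels, branches = corrupt(ex, rng=rng)
            n_residues += int((~ex.special_mask).sum())
            sel = labels != -100
            n_selected += int(sel.sum())
            n_masked += int((branches == BRANCH_MASK).sum())
            n_random += int((branches == BRANCH_RANDOM).sum())
            n_kept += int((branches == BRANCH_KEEP).sum())
            changed_random += int((ids[branches == BRANCH_RANDOM]
                                   != ex.token_ids[branches == BRANCH_RANDOM]).sum())
        assert n_selected >= 10_000
        assert n_selected / n_residues == pytest.approx(0.15, abs=0.01)
        assert n_masked / n_selected == pytest.approx(0.80, abs=0.02)
        # replacement draws may coincide with the original residue by chance
        assert n_random / n_selected == pytest.approx(0.10, abs=0.02)
        chi, p = chisquare([n_masked, n_random, n_kept],
                           [0.8 * n_selected, 0.1 * n_selected, 0.1 * n_selected])
        assert p > 0.001

    def test_branch_split_chi_square_large(self):
        # ≥1e5 selected positions for the goodness-of-fit check
        recs = generate(GeneratorConfig(n_unpaired_heavy=6000, seed=2))
        rng = np.random.default_rng(1)
        counts = np.zeros(3, dtype=int)
        for rec in recs:
            ex = encode(rec, pad_to=160)
            _, _, branches = corrupt(ex, rng=rng)
            counts[0] += int((branches == BRANCH_MASK).sum())
            counts[1] += int((branches == BRANCH_RANDOM).sum())
            counts[2] += int((branches == BRANCH_KEEP).sum())
        total = counts.sum()
        assert total >= 100_000
        _, p = chisquare(counts, total * np.array([0.8, 0.1, 0.1]))
        assert p > 0.001

    def test_random_branch_draws_residue_tokens_only(self):
        recs = generate(GeneratorConfig(n_unpaired_heavy=200, seed=3))
        rng = np.random.default_rng(2)
        special = {VOCAB.cls_id, VOCAB.pad_id, VOCAB.eos_id, VOCAB.mask_id,
                   VOCAB.sep_id, VOCAB.unk_id}
        for rec in recs:
            ex = encode(rec, pad_to=160)
            ids, _, branches = corrupt(ex, rng=rng)
            replaced = ids[branches == BRANCH_RANDOM]
            assert not (set(replaced.tolist()) & special)
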