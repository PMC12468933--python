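"""Antibody tokenization: vocabulary, separator dialects, padding, corruption.

The vocabulary is the standard 33-token protein-LM token set with one unused
placeholder replaced by a dedicated ``<sep>`` chain-separator token, keeping
the size at exactly 33.

Separator *dialects* control how the boundary between heavy and light chains
is marked:

- ``sep``:  a dedicated ``<sep>`` token,
- ``cls``:  the start-of-string ``<cls>`` token reused as separator,
- ``none``: no separator at all.

Placement mirrors chain topology: between the chains of a paired sequence
(``QL…SS<cls>DI…IK``), after an unpaired heavy chain (``QL…SS<cls>``), and
before an unpaired light chain (``<cls>DI…IK``).  Independently of dialect,
every example is framed with a start token at position 0 and an end token
after the sequence, then right-padded to a fixed length (default 320, sized
to the longest paired input).

MLM corruption follows the standard recipe: 15% of residue positions are
selected i.i.d.; of these 80% become ``<mask>``, 10% a random residue token,
10% are kept unchanged.  Special positions (start/separator/end/pad) are
never selected and never replaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import SequenceRecord, Region, PAIRED, HEAVY, LIGHT

__all__ = ["Vocabulary", "TokenizedExample", "encode", "decode", "corrupt",
           "encode_batch", "PAD_TO_DEFAULT"]

PAD_TO_DEFAULT = 320

#: Corruption branch codes recorded per position by :func:`corrupt`.
BRANCH_NONE, BRANCH_MASK, BRANCH_RANDOM, BRANCH_KEEP = 0, 1, 2, 3

_TOKENS = (
    "<cls>", "<pad>", "<eos>", "<unk>",
    "L", "A", "G", "V", "S", "E", "R", "T", "I", "D", "P", "K",
    "Q", "N", "F", "Y", "M", "H", "W", "C",
    "X", "B", "U", "Z", "O", ".", "-",
    "<sep>", "<mask>",
)

_CANONICAL_AA = "LAGVSERTIDPKQNFYMHWC"


class Vocabulary:
    """Bijective token ↔ id mapping over the 33-token antibody vocabulary."""

    def __init__(self, tokens: Sequence[str] = _TOKENS):
        if len(tokens) != len(set(tokens)):
            raise ValueError("duplicate tokens")
        self.tokens = tuple(tokens)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        for required in ("<cls>", "<pad>", "<eos>", "<unk>", "<mask>", "<sep>"):
            if required not in self.index:
                raise ValueError(f"vocabulary missing {required}")
        self.cls_id = self.index["<cls>"]
        self.pad_id = self.index["<pad>"]
        self.eos_id = self.index["<eos>"]
        self.unk_id = self.index["<unk>"]
        self.mask_id = self.index["<mask>"]
        self.sep_id = self.index["<sep>"]
        #: ids a residue position may hold (single-character tokens)
        self.residue_ids = np.array(
            [i for i, t in enumerate(self.tokens) if len(t) == 1])
        #: ids used for the 10% random-replacement branch (canonical residues)
        self.canonical_ids = np.array([self.index[a] for a in _CANONICAL_AA])
        self.special_ids = frozenset(
            i for i, t in enumerate(self.tokens) if len(t) > 1)

    def __len__(self) -> int:
        return len(self.tokens)

    def encode_residues(self, seq: str) -> np.ndarray:
        return np.array([self.index.get(ch, self.unk_id) for ch in seq],
                        dtype=np.int64)

    def decode_residues(self, ids: Sequence[int]) -> str:
        return "".join(self.tokens[i] for i in ids)


VOCAB = Vocabulary()


@dataclass
class TokenizedExample:
    """A fixed-length encoded record plus alignment metadata.

    ``special_mask`` is True exactly at non-residue positions (start,
    separator, end, pad).  ``region_labels`` holds strings like ``"H:CDR3"``
    at residue positions and ``""`` elsewhere.
    """

    record_id: str
    token_ids: np.ndarray
    attention_mask: np.ndarray
    special_mask: np.ndarray
    region_labels: np.ndarray
    domain: str                     # "paired" or "unpaired"
    chain_type: str                 # paired / heavy / light
    dialect: str
    chain_order: str
    #: token index where the second chain starts (paired records only)
    chain_boundary: Optional[int] = None

    def __post_init__(self):
        n = len(self.token_ids)
        if not (len(self.attention_mask) == len(self.special_mask)
                == len(self.region_labels) == n):
            raise ValueError("mask/label arrays misaligned with token_ids")

    @property
    def residue_positions(self) -> np.ndarray:
        return np.flatnonzero(~self.special_mask)

    def __len__(self) -> int:
        return len(self.token_ids)


def _separator_id(dialect: str, vocab: Vocabulary) -> Optional[int]:
    if dialect == "sep":
        return vocab.sep_id
    if dialect == "cls":
        return vocab.cls_id
    if dialect == "none":
        return None
    raise ValueError(f"unknown dialect {dialect!r}")


def _chain_pieces(record: SequenceRecord, chain_order: str):
    if chain_order not in ("heavy_first", "light_first"):
        raise ValueError(f"unknown chain_order {chain_order!r}")
    pieces = []
    if record.heavy_chain:
        pieces.append((HEAVY, record.heavy_chain, record.heavy_regions))
    if record.light_chain:
        pieces.append((LIGHT, record.light_chain, record.light_regions))
    if chain_order == "light_first":
        pieces.reverse()
    return pieces


def encode(record: SequenceRecord, dialect: str = "cls",
           chain_order: str = "heavy_first", pad_to: int = PAD_TO_DEFAULT,
           vocab: Vocabulary = VOCAB) -> TokenizedExample:
    """Encode one record into a fixed-length :class:`TokenizedExample`.

    Layout (before padding): start token, then the chain(s) with the
    dialect's separator placed between paired chains, after an unpaired
    heavy chain, or before an unpaired light chain; then the end token.
    Residues outside the vocabulary map to ``<unk>``.
    """
    sep = _separator_id(dialect, vocab)
    ids = [vocab.cls_id]
    labels = [""]
    special = [True]
    chain_boundary: Optional[int] = None
    pieces = _chain_pieces(record, chain_order)
    for pos_in_record, (which, seq, regions) in enumerate(pieces):
        if pos_in_record == 1:
            chain_boundary = len(ids)
        leading_sep = (sep is not None and record.chain_type == LIGHT)
        if leading_sep:
            ids.append(sep); labels.append(""); special.append(True)
        chain_labels = [""] * len(seq)
        for r in regions:
            for i in range(r.start, r.end):
                chain_labels[i] = f"{'H' if which == HEAVY else 'L'}:{r.label}"
        ids.extend(int(i) for i in vocab.encode_residues(seq))
        labels.extend(chain_labels)
        special.extend([False] * len(seq))
        trailing_sep = sep is not None and (
            record.chain_type == HEAVY
            or (record.is_paired and pos_in_record == 0))
        if trailing_sep:
            ids.append(sep); labels.append(""); special.append(True)
    ids.append(vocab.eos_id); labels.append(""); special.append(True)
    if len(ids) > pad_to:
        raise ValueError(
            f"record {record.record_id!r} encodes to {len(ids)} tokens "
            f"> pad_to={pad_to}")
    n_pad = pad_to - len(ids)
    attention = np.array([True] * len(ids) + [False] * n_pad)
    ids = np.array(ids + [vocab.pad_id] * n_pad, dtype=np.int64)
    special = np.array(special + [True] * n_pad)
    labels = np.array(labels + [""] * n_pad, dtype=object)
    return TokenizedExample(
        record_id=record.record_id,
        token_ids=ids,
        attention_mask=attention,
        special_mask=special,
        region_labels=labels,
        domain="paired" if record.is_paired else "unpaired",
        chain_type=record.chain_type,
        dialect=dialect,
        chain_order=chain_order,
        chain_boundary=chain_boundary,
    )


def decode(example: TokenizedExample,
           vocab: Vocabulary = VOCAB) -> SequenceRecord:
    """Invert :func:`encode`: recover the chains and chain type.

    Region coordinates and mutation counts are reconstructed from the
    example's alignment metadata where present.
    """
    ids = example.token_ids
    residue_pos = example.residue_positions
    if example.chain_type == PAIRED:
        if example.chain_boundary is None:
            raise ValueError(
                f"{example.record_id}: paired example lacks a chain boundary")
        first = residue_pos[residue_pos < example.chain_boundary]
        second = residue_pos[residue_pos >= example.chain_boundary]
        seq1 = vocab.decode_residues(ids[first])
        seq2 = vocab.decode_residues(ids[second])
        heavy, light = ((seq1, seq2) if example.chain_order == "heavy_first"
                        else (seq2, seq1))
        return SequenceRecord(record_id=example.record_id, heavy_chain=heavy,
                              light_chain=light, chain_type=PAIRED,
                              pairing_id=example.record_id)
    seq = vocab.decode_residues(ids[residue_pos])
    if example.chain_type == HEAVY:
        return SequenceRecord(record_id=example.record_id, heavy_chain=seq,
                              chain_type=HEAVY)
    return SequenceRecord(record_id=example.record_id, light_chain=seq,
                          chain_type=LIGHT)


def encode_batch(records: Sequence[SequenceRecord], dialect: str = "cls",
                 chain_order: str = "heavy_first",
                 pad_to: int = PAD_TO_DEFAULT,
                 vocab: Vocabulary = VOCAB) -> list[TokenizedExample]:
    return [encode(r, dialect, chain_order, pad_to, vocab) for r in records]


def corrupt(example: TokenizedExample, select_rate: float = 0.15,
            mask_frac: float = 0.8, random_frac: float = 0.1,
            keep_frac: float = 0.1,
            rng: np.random.Generator | int | None = None,
            vocab: Vocabulary = VOCAB):
    """Apply MLM corruption to one example.

    Returns ``(corrupted_ids, labels, branches)`` where ``labels`` holds the
    original token id at selected positions and −100 elsewhere, and
    ``branches`` records which corruption branch each selected position took
    (1 = masked, 2 = random residue, 3 = kept).
    """
    if abs(mask_frac + random_frac + keep_frac - 1.0) > 1e-9:
        raise ValueError("mask_frac + random_frac + keep_frac must equal 1")
    if not 0.0 <= select_rate <= 1.0:
        raise ValueError("select_rate must lie in [0, 1]")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ids = example.token_ids.copy()
    labels = np.full(len(ids), -100, dtype=np.int64)
    branches = np.zeros(len(ids), dtype=np.int8)
    eligible = ~example.special_mask
    selected = eligible & (rng.random(len(ids)) < select_rate)
    sel_idx = np.flatnonzero(selected)
    if sel_idx.size:
        labels[sel_idx] = example.token_ids[sel_idx]
        u = rng.random(sel_idx.size)
        masked = u < mask_frac
        randomized = (~masked) & (u < mask_frac + random_frac)
        kept = ~(masked | randomized)
        ids[sel_idx[masked]] = vocab.mask_id
        ids[sel_idx[randomized]] = rng.choice(
            vocab.canonical_ids, size=int(randomized.sum()))
        branches[sel_idx[masked]] = BRANCH_MASK
        branches[sel_idx[randomized]] = BRANCH_RANDOM
        branches[sel_idx[kept]] = BRANCH_KEEP
    return ids, labels, branches
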