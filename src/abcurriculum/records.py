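"""Antibody sequence records and corpus I/O.

A :class:`SequenceRecord` holds one antibody observation: a natively paired
heavy+light pair, or a single unpaired chain.  Each chain carries region
coordinates tiling it into the canonical FR1–CDR1–FR2–CDR2–FR3–CDR3–FR4
layout (0-based half-open intervals) plus a somatic-mutation count, so that
downstream code can compute region-resolved metrics and mutation-status
subsets without re-annotating sequences.

Corpora round-trip through CSV/TSV (one row per record) and FASTA (one entry
per chain; the two chains of a paired record share a ``pairing_id`` and are
distinguished by a ``|H`` / ``|L`` suffix).  Region coordinates and mutation
counts ride in the FASTA description as a JSON payload, because plain FASTA
has nowhere else to put them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Region", "SequenceRecord", "REGION_ORDER",
    "read_csv", "write_csv", "read_fasta", "write_fasta",
]

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

PAIRED, HEAVY, LIGHT = "paired", "heavy", "light"


@dataclass(frozen=True)
class Region:
    """One region interval on a chain, 0-based half-open."""

    label: str
    start: int
    end: int

    def __post_init__(self):
        if self.label not in REGION_ORDER:
            raise ValueError(f"unknown region label {self.label!r}")
        if not 0 <= self.start <= self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")


def _check_tiling(regions: Sequence[Region], length: int, chain: str) -> None:
    if not regions:
        return
    labels = tuple(r.label for r in regions)
    if labels != REGION_ORDER[:len(regions)]:
        raise ValueError(f"{chain} regions out of order: {labels}")
    pos = 0
    for r in regions:
        if r.start != pos:
            raise ValueError(
                f"{chain} regions do not tile: gap/overlap at {r.label}")
        pos = r.end
    if pos != length:
        raise ValueError(
            f"{chain} regions cover {pos} residues but chain has {length}")


@dataclass
class SequenceRecord:
    """One antibody record: paired heavy+light, or one unpaired chain."""

    record_id: str
    heavy_chain: Optional[str] = None
    light_chain: Optional[str] = None
    chain_type: str = PAIRED
    heavy_regions: tuple[Region, ...] = ()
    light_regions: tuple[Region, ...] = ()
    mutation_count_heavy: int = 0
    mutation_count_light: int = 0
    pairing_id: Optional[str] = None

    def __post_init__(self):
        if self.chain_type not in (PAIRED, HEAVY, LIGHT):
            raise ValueError(f"unknown chain_type {self.chain_type!r}")
        if self.chain_type == PAIRED:
            if not (self.heavy_chain and self.light_chain):
                raise ValueError(f"{self.record_id}: paired record needs both chains")
        elif self.chain_type == HEAVY:
            if not self.heavy_chain or self.light_chain:
                raise ValueError(f"{self.record_id}: heavy record needs exactly the heavy chain")
        else:
            if not self.light_chain or self.heavy_chain:
                raise ValueError(f"{self.record_id}: light record needs exactly the light chain")
        self.heavy_regions = tuple(
            r if isinstance(r, Region) else Region(*r) for r in self.heavy_regions)
        self.light_regions = tuple(
            r if isinstance(r, Region) else Region(*r) for r in self.light_regions)
        if self.heavy_chain:
            _check_tiling(self.heavy_regions, len(self.heavy_chain), "heavy")
        if self.light_chain:
            _check_tiling(self.light_regions, len(self.light_chain), "light")
        if self.mutation_count_heavy < 0 or self.mutation_count_light < 0:
            raise ValueError("mutation counts must be non-negative")

    @property
    def is_paired(self) -> bool:
        return self.chain_type == PAIRED

    @property
    def total_mutations(self) -> int:
        return self.mutation_count_heavy + self.mutation_count_light

    def chain(self, which: str) -> str:
        seq = self.heavy_chain if which == HEAVY else self.light_chain
        if seq is None:
            raise ValueError(f"{self.record_id} has no {which} chain")
        return seq

    def regions(self, which: str) -> tuple[Region, ...]:
        return self.heavy_regions if which == HEAVY else self.light_regions

    def region_span(self, which: str, label: str) -> Optional[Region]:
        for r in self.regions(which):
            if r.label == label:
                return r
        return None


def _regions_to_json(regions: Sequence[Region]) -> str:
    return json.dumps([[r.label, r.start, r.end] for r in regions])


def _regions_from_json(s) -> tuple[Region, ...]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return ()
    return tuple(Region(*item) for item in json.loads(s))


CSV_COLUMNS = [
    "record_id", "heavy", "light", "chain_type",
    "heavy_regions", "light_regions",
    "mutation_count_heavy", "mutation_count_light", "pairing_id",
]


def write_csv(records: Iterable[SequenceRecord], path: str | Path,
              sep: str = ",") -> None:
    rows = []
    for rec in records:
        rows.append({
            "record_id": rec.record_id,
            "heavy": rec.heavy_chain or "",
            "light": rec.light_chain or "",
            "chain_type": rec.chain_type,
            "heavy_regions": _regions_to_json(rec.heavy_regions),
            "light_regions": _regions_to_json(rec.light_regions),
            "mutation_count_heavy": rec.mutation_count_heavy,
            "mutation_count_light": rec.mutation_count_light,
            "pairing_id": rec.pairing_id or "",
        })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, sep=sep, index=False)


def read_csv(path: str | Path, sep: str = ",") -> list[SequenceRecord]:
    df = pd.read_csv(path, sep=sep, keep_default_na=False)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(SequenceRecord(
            record_id=str(row.record_id),
            heavy_chain=row.heavy or None,
            light_chain=row.light or None,
            chain_type=row.chain_type,
            heavy_regions=_regions_from_json(row.heavy_regions),
            light_regions=_regions_from_json(row.light_regions),
            mutation_count_heavy=int(row.mutation_count_heavy),
            mutation_count_light=int(row.mutation_count_light),
            pairing_id=str(row.pairing_id) or None,
        ))
    return records


def _fasta_entry(rec: SequenceRecord, which: str) -> SeqRecord:
    chain = rec.chain(which)
    meta = {
        "chain_type": rec.chain_type,
        "regions": [[r.label, r.start, r.end] for r in rec.regions(which)],
        "mutations": (rec.mutation_count_heavy if which == HEAVY
                      else rec.mutation_count_light),
    }
    suffix = "H" if which == HEAVY else "L"
    name = f"{rec.pairing_id or rec.record_id}|{suffix}"
    return SeqRecord(Seq(chain), id=name, description=json.dumps(meta))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write one FASTA entry per chain; paired chains share the id stem.

    Header convention: ``>{pairing_id}|H json-metadata`` — the ``|H``/``|L``
    suffix marks the chain and the JSON payload carries chain_type, region
    coordinates and the mutation count.
    """
    entries = []
    for rec in records:
        if rec.heavy_chain:
            entries.append(_fasta_entry(rec, HEAVY))
        if rec.light_chain:
            entries.append(_fasta_entry(rec, LIGHT))
    SeqIO.write(entries, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a corpus written by :func:`write_fasta`, re-joining paired chains."""
    partial: dict[str, dict] = {}
    order: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        stem, _, suffix = entry.id.rpartition("|")
        if suffix not in ("H", "L") or not stem:
            raise ValueError(f"{path}: malformed header {entry.id!r}")
        meta = json.loads(entry.description.split(None, 1)[1])
        if stem not in partial:
            partial[stem] = {"chain_type": meta["chain_type"]}
            order.append(stem)
        slot = partial[stem]
        key = "heavy" if suffix == "H" else "light"
        slot[key] = str(entry.seq)
        slot[key + "_regions"] = tuple(Region(*r) for r in meta["regions"])
        slot[key + "_mutations"] = int(meta["mutations"])
    records = []
    for stem in order:
        slot = partial[stem]
        records.append(SequenceRecord(
            record_id=stem,
            heavy_chain=slot.get("heavy"),
            light_chain=slot.get("light"),
            chain_type=slot["chain_type"],
            heavy_regions=slot.get("heavy_regions", ()),
            light_regions=slot.get("light_regions", ()),
            mutation_count_heavy=slot.get("heavy_mutations", 0),
            mutation_count_light=slot.get("light_mutations", 0),
            pairing_id=stem,
        ))
    return records
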