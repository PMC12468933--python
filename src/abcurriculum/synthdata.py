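"""Seeded synthetic antibody repertoires.

The generator emulates the statistical structure of real immune-repertoire
corpora at desk scale: chains are built from a small bank of toy germline
templates (framework regions and CDR1/CDR2 fixed per template), a randomized
CDR3 junction of configurable length, and somatic hypermutation applied to a
"memory" subset of records as i.i.d. substitutions at a per-residue rate.
Region coordinates and exact per-chain mutation counts are recorded on every
record, standing in for the numbering/annotation step a real pipeline would
run.  Paired records draw a heavy and a light chain together and share a
``pairing_id``; unpaired records carry a single chain.

What it does *not* model: V(D)J recombination statistics, germline gene usage
frequencies, insertions/deletions, or allelic variation.  It is a test-bed
for training mechanics, not a biological simulator.

For classification experiments, a short class-specific motif can be planted
in the heavy-chain CDR3 (``planted_classes``), giving a downstream task with
a known recoverable signal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .records import (SequenceRecord, Region, REGION_ORDER,
                      write_csv, write_fasta, PAIRED, HEAVY, LIGHT)

__all__ = ["GeneratorConfig", "generate", "generate_classed", "write_corpus"]

_AA = "ACDEFGHIKLMNPQRSTVWY"

# Toy germline templates: framework regions and CDR1/CDR2 per template.
# Loosely modelled on human V-gene architecture (lengths and conserved
# anchors such as the FR3-terminal cysteine and the FR4 WGQG/FGGG motifs),
# but hand-written — not IMGT alleles.
_HEAVY_TEMPLATES = {
    "HV1": {
        "FR1": "QVQLVQSGAEVKKPGASVKVSCKAS", "CDR1": "GYTFTSYA",
        "FR2": "ISWVRQAPGQGLEWMGW", "CDR2": "INPNSGGT",
        "FR3": "NYAQKFQGRVTMTRDTSISTAYMELSRLRSDDTAVYYC",
        "FR4": "WGQGTLVTVSS",
    },
    "HV3": {
        "FR1": "EVQLVESGGGLVQPGGSLRLSCAAS", "CDR1": "GFTFSSYA",
        "FR2": "MSWVRQAPGKGLEWVSA", "CDR2": "ISGSGGST",
        "FR3": "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC",
        "FR4": "WGQGTMVTVSS",
    },
    "HV4": {
        "FR1": "QVQLQESGPGLVKPSETLSLTCTVS", "CDR1": "GGSISSYY",
        "FR2": "WSWIRQPPGKGLEWIGY", "CDR2": "IYYSGSTN",
        "FR3": "YNPSLKSRVTISVDTSKNQFSLKLSSVTAADTAVYYC",
        "FR4": "WGQGTLVTVSS",
    },
    "HV5": {
        "FR1": "EVQLVQSGAEVKKPGESLKISCKGS", "CDR1": "GYSFTSYW",
        "FR2": "IGWVRQMPGKGLEWMGI", "CDR2": "IYPGDSDT",
        "FR3": "RYSPSFQGQVTISADKSISTAYLQWSSLKASDTAMYYC",
        "FR4": "WGQGTLVTVSS",
    },
}

_LIGHT_TEMPLATES = {
    "KV1": {
        "FR1": "DIQMTQSPSSLSASVGDRVTITC", "CDR1": "QASQDIS",
        "FR2": "NYLNWYQQKPGKAPKLLIY", "CDR2": "DASNLET",
        "FR3": "GVPSRFSGSGSGTDFTFTISSLQPEDIATYYC",
        "FR4": "FGQGTKVEIK",
    },
    "KV3": {
        "FR1": "EIVLTQSPGTLSLSPGERATLSC", "CDR1": "RASQSVS",
        "FR2": "SYLAWYQQKPGQAPRLLIY", "CDR2": "GASSRAT",
        "FR3": "GIPDRFSGSGSGTDFTLTISRLEPEDFAVYYC",
        "FR4": "FGQGTKLEIK",
    },
    "LV1": {
        "FR1": "QSVLTQPPSVSGAPGQRVTISC", "CDR1": "TGSSSNI",
        "FR2": "GAGYDVHWYQQLPGTAPKLLIY", "CDR2": "GNSNRPS",
        "FR3": "GVPDRFSGSKSGTSASLAITGLQAEDEADYYC",
        "FR4": "FGGGTKLTVL",
    },
    "LV2": {
        "FR1": "QSALTQPASVSGSPGQSITISC", "CDR1": "TGTSSDV",
        "FR2": "GGYNYVSWYQQHPGKAPKLMIY", "CDR2": "DVSNRPS",
        "FR3": "GVSNRFSGSKSGNTASLTISGLQAEDEADYYC",
        "FR4": "FGGGTKVTVL",
    },
}


@dataclass
class GeneratorConfig:
    """Knobs of the repertoire generator.

    ``shm_rate`` is the per-residue substitution probability applied to
    memory records (default 0.05, a typical order for memory B cells);
    ``memory_fraction`` is the fraction of records that receive it.
    ``cdr3_length_range`` bounds the heavy CDR3 junction (inclusive);
    light CDR3s use ``light_cdr3_length_range``.
    """

    n_paired: int = 0
    n_unpaired_heavy: int = 0
    n_unpaired_light: int = 0
    shm_rate: float = 0.05
    memory_fraction: float = 0.5
    cdr3_length_range: tuple[int, int] = (8, 20)
    light_cdr3_length_range: tuple[int, int] = (8, 11)
    seed: int = 0
    planted_classes: Optional[dict[str, str]] = None
    pad_budget: int = 320

    def __post_init__(self):
        if not 0.0 <= self.shm_rate <= 0.2:
            raise ValueError("shm_rate must lie in [0, 0.2]")
        if not 0.0 <= self.memory_fraction <= 1.0:
            raise ValueError("memory_fraction must lie in [0, 1]")
        lo, hi = self.cdr3_length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad cdr3_length_range")
        # longest paired encoding: both chains + start/sep/end framing
        h_max = max(sum(len(v) for v in t.values()) for t in _HEAVY_TEMPLATES.values()) + hi
        l_max = max(sum(len(v) for v in t.values()) for t in _LIGHT_TEMPLATES.values()) \
            + self.light_cdr3_length_range[1]
        if h_max + l_max + 3 > self.pad_budget:
            raise ValueError(
                f"cdr3_length_range {self.cdr3_length_range} can exceed the "
                f"{self.pad_budget}-token pad budget ({h_max + l_max + 3})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cdr3_length_range"] = list(self.cdr3_length_range)
        d["light_cdr3_length_range"] = list(self.light_cdr3_length_range)
        return d


def _build_chain(template: dict, cdr3: str):
    """Assemble a chain from template regions + CDR3; return (seq, regions)."""
    parts = {**template, "CDR3": cdr3}
    seq, regions, pos = [], [], 0
    for label in REGION_ORDER:
        piece = parts[label]
        regions.append(Region(label, pos, pos + len(piece)))
        seq.append(piece)
        pos += len(piece)
    return "".join(seq), tuple(regions)


def _random_cdr3(rng: np.random.Generator, length_range, prefix: str = "") -> str:
    lo, hi = length_range
    n = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(list(_AA), size=max(n - len(prefix), 0)))
    return (prefix + body)[:max(n, len(prefix))]


def _mutate(seq: str, regions, rate: float, rng: np.random.Generator,
            protected: Optional[tuple[int, int]] = None):
    """Apply i.i.d. substitutions (always to a different residue); return
    (mutated sequence, exact substitution count)."""
    if rate == 0.0:
        return seq, 0
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    count = 0
    for i in hits:
        if protected is not None and protected[0] <= i < protected[1]:
            continue
        alternatives = _AA.replace(chars[i], "") if chars[i] in _AA else _AA
        chars[i] = str(rng.choice(list(alternatives)))
        count += 1
    return "".join(chars), count


def _make_heavy(rng, cfg: GeneratorConfig, memory: bool,
                motif: Optional[str] = None):
    name = list(_HEAVY_TEMPLATES)[int(rng.integers(len(_HEAVY_TEMPLATES)))]
    lo, hi = cfg.cdr3_length_range
    if motif is not None:
        lo = max(lo, len(motif) + 2)
        hi = max(hi, lo)
    cdr3 = _random_cdr3(rng, (lo, hi), prefix="AR")
    protected = None
    if motif is not None:
        # plant the class motif right after the AR anchor
        cdr3 = cdr3[:2] + motif + cdr3[2 + len(motif):]
    seq, regions = _build_chain(_HEAVY_TEMPLATES[name], cdr3)
    if motif is not None:
        cdr3_region = regions[5]
        protected = (cdr3_region.start + 2, cdr3_region.start + 2 + len(motif))
    rate = cfg.shm_rate if memory else 0.0
    seq, count = _mutate(seq, regions, rate, rng, protected)
    return seq, regions, count


def _make_light(rng, cfg: GeneratorConfig, memory: bool):
    name = list(_LIGHT_TEMPLATES)[int(rng.integers(len(_LIGHT_TEMPLATES)))]
    cdr3 = _random_cdr3(rng, cfg.light_cdr3_length_range, prefix="Q")
    seq, regions = _build_chain(_LIGHT_TEMPLATES[name], cdr3)
    rate = cfg.shm_rate if memory else 0.0
    seq, count = _mutate(seq, regions, rate, rng)
    return seq, regions, count


def generate(config: GeneratorConfig) -> list[SequenceRecord]:
    """Generate a repertoire; deterministic given ``config.seed``.

    Order: paired records, then unpaired heavy, then unpaired light.  When
    ``planted_classes`` is set, class labels cycle over the records and the
    class motif is embedded in each heavy-chain CDR3; the class is also
    recorded as a ``record_id`` suffix (``...#<label>``).
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.planted_classes) if config.planted_classes else None
    records: list[SequenceRecord] = []

    def class_for(i):
        if classes is None:
            return None, None
        label = classes[i % len(classes)]
        return label, config.planted_classes[label]

    for i in range(config.n_paired):
        memory = bool(rng.random() < config.memory_fraction)
        label, motif = class_for(i)
        h_seq, h_reg, h_mut = _make_heavy(rng, config, memory, motif)
        l_seq, l_reg, l_mut = _make_light(rng, config, memory)
        rid = f"P{i:06d}" + (f"#{label}" if label else "")
        records.append(SequenceRecord(
            record_id=rid, heavy_chain=h_seq, light_chain=l_seq,
            chain_type=PAIRED, heavy_regions=h_reg, light_regions=l_reg,
            mutation_count_heavy=h_mut, mutation_count_light=l_mut,
            pairing_id=rid))
    for i in range(config.n_unpaired_heavy):
        memory = bool(rng.random() < config.memory_fraction)
        label, motif = class_for(i)
        h_seq, h_reg, h_mut = _make_heavy(rng, config, memory, motif)
        rid = f"H{i:06d}" + (f"#{label}" if label else "")
        records.append(SequenceRecord(
            record_id=rid, heavy_chain=h_seq, chain_type=HEAVY,
            heavy_regions=h_reg, mutation_count_heavy=h_mut))
    for i in range(config.n_unpaired_light):
        memory = bool(rng.random() < config.memory_fraction)
        l_seq, l_reg, l_mut = _make_light(rng, config, memory)
        rid = f"L{i:06d}"
        records.append(SequenceRecord(
            record_id=rid, light_chain=l_seq, chain_type=LIGHT,
            light_regions=l_reg, mutation_count_light=l_mut))
    return records


def generate_classed(config: GeneratorConfig) -> dict[str, list[SequenceRecord]]:
    """Generate a planted-class repertoire grouped by class label."""
    if not config.planted_classes:
        raise ValueError("config.planted_classes must be set")
    grouped: dict[str, list[SequenceRecord]] = {c: [] for c in config.planted_classes}
    for rec in generate(config):
        label = rec.record_id.rpartition("#")[2]
        grouped[label].append(rec)
    return grouped


def write_corpus(records: list[SequenceRecord], out_dir: str | Path,
                 fmt: str = "csv", stem: str = "corpus",
                 config: Optional[GeneratorConfig] = None) -> dict:
    """Write a corpus plus a manifest JSON; returns the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        path = out_dir / f"{stem}.csv"
        write_csv(records, path)
    elif fmt == "fasta":
        path = out_dir / f"{stem}.fasta"
        write_fasta(records, path)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    counts = {
        "paired": sum(r.chain_type == PAIRED for r in records),
        "unpaired_heavy": sum(r.chain_type == HEAVY for r in records),
        "unpaired_light": sum(r.chain_type == LIGHT for r in records),
    }
    manifest = {"file": path.name, "format": fmt, "counts": counts}
    if config is not None:
        cfg = config.to_dict()
        manifest["seed"] = config.seed
        manifest["config"] = cfg
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    with open(out_dir / f"{stem}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
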