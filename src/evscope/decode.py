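"""PBA read decoding: FASTQ -> single-EV molecule-count matrices.

Reads are fixed-layout concatenations of EV tag | protein tag | molecular
tag (UMI). Decoding splits each read at the configured offsets, drops reads
whose quality falls below Q20, assigns the protein tag against the panel,
and counts distinct UMIs per (EV tag, protein) to deduplicate PCR copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd
import pysam
import yaml

from .matrix import SingleEVMatrix
from .panel import PanelSpec

logger = logging.getLogger(__name__)


class ReadRecord(NamedTuple):
    ev_tag: str
    protein_tag: str
    molecular_tag: str
    quality: int  # summary Phred quality per the layout's quality_mode
    protein: str | None = None


@dataclass
class LayoutConfig:
    """Fixed read layout and quality-filter settings."""

    ev_tag_length: int = 15
    protein_tag_length: int = 8
    umi_length: int = 8
    quality_threshold: int = 20
    #: "min": summary quality is the minimum per-base Phred (strict);
    #: "mean": the mean per-base Phred.
    quality_mode: str = "min"

    @property
    def read_length(self) -> int:
        return self.ev_tag_length + self.protein_tag_length + self.umi_length

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LayoutConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


@dataclass
class DecodeStats:
    """Counters of reads dropped at each decoding step."""

    n_reads: int = 0
    n_truncated: int = 0
    n_low_quality: int = 0
    n_unmatched_tag: int = 0
    n_ambiguous_tag: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _summary_quality(qual: str, mode: str) -> int:
    if mode == "min":
        return ord(min(qual)) - 33
    if mode == "mean":
        return int(sum(map(ord, qual)) / len(qual)) - 33
    raise ValueError(f"unknown quality_mode {mode!r}")


def parse_reads(fastq_path: str | Path, layout: LayoutConfig,
                stats: DecodeStats | None = None) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ file (gzip-aware via pysam).

    Reads shorter than the configured layout are skipped and counted;
    longer reads are truncated on the right (trailing bases past the UMI
    carry no information).
    """
    if stats is None:
        stats = DecodeStats()
    n_yield = 0
    L = layout.read_length
    e, p = layout.ev_tag_length, layout.protein_tag_length
    with pysam.FastxFile(str(fastq_path)) as fh:
        for entry in fh:
            stats.n_reads += 1
            seq = entry.sequence
            qual = entry.quality
            if seq is None or qual is None or len(seq) < L:
                stats.n_truncated += 1
                continue
            n_yield += 1
            yield ReadRecord(seq[:e], seq[e:e + p], seq[e + p:L],
                             _summary_quality(qual[:L], layout.quality_mode))
    if stats.n_truncated:
        logger.info("%s: skipped %d truncated reads", fastq_path,
                    stats.n_truncated)
    if n_yield == 0:
        logger.warning("%s: zero usable reads", fastq_path)


def quality_filter(records: Iterable[ReadRecord], threshold: int = 20,
                   stats: DecodeStats | None = None) -> Iterator[ReadRecord]:
    """Keep records whose summary quality is >= threshold (Q20 default)."""
    for rec in records:
        if rec.quality >= threshold:
            yield rec
        elif stats is not None:
            stats.n_low_quality += 1


def _exact_distance_neighbors(tag: str, d: int) -> Iterator[str]:
    """All sequences at Hamming distance exactly d from tag."""
    from itertools import combinations, product
    if d == 0:
        yield tag
        return
    for positions in combinations(range(len(tag)), d):
        alts = [[b for b in "ACGT" if b != tag[i]] for i in positions]
        for subst in product(*alts):
            out = list(tag)
            for i, b in zip(positions, subst):
                out[i] = b
            yield "".join(out)


def _mismatch_lookup(panel: PanelSpec, max_mismatch: int) -> dict[str, str | None]:
    """Map every tag within max_mismatch of a panel tag to its protein.

    The closest panel tag wins; a tie at equal distance between two
    proteins maps to None (ambiguous, dropped downstream).
    """
    lookup: dict[str, str | None] = {}
    for d in range(max_mismatch + 1):
        layer: dict[str, str | None] = {}
        for protein, tag in panel.tag_map.items():
            for nb in _exact_distance_neighbors(tag, d):
                if nb in layer and layer[nb] != protein:
                    layer[nb] = None
                else:
                    layer[nb] = protein
        for nb, val in layer.items():
            lookup.setdefault(nb, val)
    return lookup


def assign_tags(records: Iterable[ReadRecord], panel: PanelSpec,
                max_mismatch: int = 0,
                stats: DecodeStats | None = None) -> Iterator[ReadRecord]:
    """Assign each record's protein tag to a panel protein.

    Exact match by default; with max_mismatch > 0, a unique panel tag within
    that Hamming distance is accepted. Unmatched and ambiguous reads are
    dropped and counted.
    """
    lookup = _mismatch_lookup(panel, max_mismatch)
    _missing = object()
    for rec in records:
        protein = lookup.get(rec.protein_tag, _missing)
        if protein is None:
            if stats is not None:
                stats.n_ambiguous_tag += 1
        elif protein is _missing:
            if stats is not None:
                stats.n_unmatched_tag += 1
        else:
            yield rec._replace(protein=protein)


def build_matrix(records: Iterable[ReadRecord], sample_id: str,
                 panel: PanelSpec, min_proteins_per_ev: int = 1,
                 min_molecules_per_ev: int = 1) -> SingleEVMatrix:
    """Count distinct UMIs per (EV tag, protein) and assemble the matrix.

    UMIs are identical only if byte-identical. EVs with fewer distinct
    proteins than ``min_proteins_per_ev`` or fewer total molecules than
    ``min_molecules_per_ev`` are removed. Row order = first appearance of
    the EV tag in the record stream.
    """
    ev_tags, prots, umis = [], [], []
    for rec in records:
        ev_tags.append(rec.ev_tag)
        prots.append(rec.protein)
        umis.append(rec.molecular_tag)
    if not ev_tags:
        from scipy import sparse
        return SingleEVMatrix(sample_id, [], list(panel.proteins),
                              sparse.csr_matrix((0, panel.size), dtype=int))
    df = pd.DataFrame({"ev_id": ev_tags, "protein": prots, "umi": umis})
    counts = (df.drop_duplicates()
                .groupby(["ev_id", "protein"], sort=False)
                .size().rename("count").reset_index())
    per_ev = counts.groupby("ev_id", sort=False).agg(
        n_prot=("protein", "size"), n_mol=("count", "sum"))
    bad = per_ev[(per_ev.n_prot < min_proteins_per_ev)
                 | (per_ev.n_mol < min_molecules_per_ev)].index
    if len(bad):
        counts = counts[~counts.ev_id.isin(set(bad))]
    # restore first-appearance order of surviving EVs
    order = {e: i for i, e in enumerate(dict.fromkeys(ev_tags))}
    counts = counts.sort_values("ev_id", key=lambda s: s.map(order),
                                kind="stable")
    return SingleEVMatrix.from_long_df(counts, sample_id,
                                       list(panel.proteins))


def decode_sample(fastq_path: str | Path, panel: PanelSpec,
                  layout: LayoutConfig | None = None, max_mismatch: int = 0,
                  min_proteins_per_ev: int = 1, min_molecules_per_ev: int = 1,
                  sample_id: str | None = None,
                  ) -> tuple[SingleEVMatrix, DecodeStats]:
    """Full decoding pipeline for one sample's FASTQ."""
    if layout is None:
        layout = LayoutConfig(protein_tag_length=panel.tag_length)
    if sample_id is None:
        sample_id = Path(fastq_path).name.split(".")[0]
    stats = DecodeStats()
    records = parse_reads(fastq_path, layout, stats)
    records = quality_filter(records, layout.quality_threshold, stats)
    records = assign_tags(records, panel, max_mismatch, stats)
    mat = build_matrix(records, sample_id, panel,
                       min_proteins_per_ev, min_molecules_per_ev)
    return mat, stats
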