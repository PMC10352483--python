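"""Antibody panel: protein names and their DNA protein tags.

A proximity barcoding assay panel maps each antibody (surface protein) to a
unique DNA tag of fixed length. Reads carry this tag, so the panel is the
lookup table the decoder uses to assign reads to proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Surface markers named throughout the ovarian-ascites EV analysis; the
#: remainder of the default 113-protein panel is filled with placeholder
#: cancer-marker names.
NAMED_MARKERS = [
    "CDCP1", "TACSTD2", "EPCAM", "ERBB2", "ITGA3", "ITGA6", "ITGB1",
    "ITGB4", "EGFR", "LAMP1", "CD151", "CD9", "CD63", "CD81", "ITGAL",
]

DEFAULT_PANEL_SIZE = 113


@dataclass(frozen=True)
class PanelSpec:
    """Ordered protein panel with a protein -> tag-sequence map.

    Invariants: tag sequences are unique and share one length.
    """

    proteins: tuple[str, ...]
    tag_map: dict[str, str] = field(hash=False)

    def __post_init__(self):
        if set(self.proteins) != set(self.tag_map):
            raise ValueError("panel proteins and tag_map keys differ")
        tags = list(self.tag_map.values())
        if len(set(tags)) != len(tags):
            raise ValueError("protein tag sequences are not unique")
        if len({len(t) for t in tags}) > 1:
            raise ValueError("protein tags have differing lengths")

    @property
    def tag_length(self) -> int:
        return len(next(iter(self.tag_map.values())))

    @property
    def size(self) -> int:
        return len(self.proteins)

    def index_of(self, protein: str) -> int:
        return self.proteins.index(protein)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanelSpec":
        """Read a two-column TSV: protein_name <tab> tag_sequence."""
        proteins, tag_map = [], {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                name, tag = line.split("\t")
                if name == "protein_name":  # optional header
                    continue
                proteins.append(name)
                tag_map[name] = tag
        return cls(tuple(proteins), tag_map)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_name\ttag_sequence\n")
            for p in self.proteins:
                fh.write(f"{p}\t{self.tag_map[p]}\n")


def random_tags(n: int, length: int, rng: np.random.Generator,
                min_distance: int = 3) -> list[str]:
    """Draw *n* distinct DNA tags of *length* nt with pairwise Hamming
    distance >= *min_distance* (rejection sampling)."""
    chosen: list[np.ndarray] = []
    max_tries = 100_000
    for _ in range(max_tries):
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != t).sum()) >= min_distance for t in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                break
    else:
        raise RuntimeError("could not generate enough well-separated tags")
    return ["".join("ACGT"[b] for b in t) for t in chosen]


def default_panel(n_proteins: int = DEFAULT_PANEL_SIZE, tag_length: int = 8,
                  seed: int = 20230703) -> PanelSpec:
    """Build the default panel: the named ascites-EV markers first, then
    numbered placeholders up to *n_proteins*.

    Tags are drawn deterministically from *seed* with pairwise Hamming
    distance >= 3, so single-mismatch correction is always unambiguous.
    """
    if n_proteins < len(NAMED_MARKERS):
        names = NAMED_MARKERS[:n_proteins]
    else:
        names = NAMED_MARKERS + [
            f"MKR{i:03d}" for i in range(len(NAMED_MARKERS) + 1, n_proteins + 1)
        ]
    rng = np.random.default_rng(seed)
    tags = random_tags(n_proteins, tag_length, rng)
    return PanelSpec(tuple(names), dict(zip(names, tags)))
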