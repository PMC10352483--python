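"""Synthetic proximity-barcoding-assay (PBA) data generator.

Emulates the statistical structure of a single-EV surface-protein screen of
ovarian-cancer (OVCA) versus non-cancer ascites: two sample groups, each
sample a mixture of EV subpopulations; a background mixture shared by both
groups; and one disease-specific subcluster co-expressing an
adhesion/oncogene marker set (CDCP1, TACSTD2, EPCAM, ERBB2, integrins, ...)
present only in the case group.

Each simulated EV draws a subcluster from its group's mixture weights, then
carries each panel protein independently with that subcluster's detection
probability; present proteins get a zero-truncated Poisson molecule count.
``emit_reads`` turns ground-truth molecules into FASTQ reads laid out as
EV tag | protein tag | molecular tag, with optional substitution errors and
a configurable fraction of sub-Q20 reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .matrix import SingleEVMatrix
from .panel import PanelSpec, default_panel

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Marker set of the planted disease-specific subcluster (detection
#: probability per EV). Mirrors the leading constituents of the
#: case-enriched cluster in the source assay.
TUMOR_MARKER_PROBS = {
    "CDCP1": 0.90, "TACSTD2": 0.80, "EPCAM": 0.80, "ERBB2": 0.70,
    "ITGA6": 0.70, "ITGA3": 0.60, "ITGB1": 0.60, "CD9": 0.60,
    "ITGB4": 0.50, "EGFR": 0.50, "LAMP1": 0.50, "CD151": 0.50,
}


@dataclass(frozen=True)
class SubclusterSpec:
    """One EV subpopulation: per-protein detection probabilities and its
    mixture proportion within each sample group."""

    name: str
    marker_probs: dict[str, float] = field(hash=False)
    group_weights: dict[str, float] = field(hash=False)
    #: detection probability applied to every panel protein not listed in
    #: marker_probs (nonspecific background binding)
    baseline_prob: float = 0.01

    def __post_init__(self):
        for p, v in self.marker_probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"marker probability out of [0,1] for {p}")
        if not 0.0 <= self.baseline_prob <= 1.0:
            raise ValueError("baseline_prob out of [0,1]")

    def prob_vector(self, panel: PanelSpec) -> np.ndarray:
        unknown = set(self.marker_probs) - set(panel.proteins)
        if unknown:
            raise ValueError(
                f"subcluster {self.name!r} has markers not in panel: "
                f"{sorted(unknown)}")
        probs = np.full(panel.size, self.baseline_prob)
        for p, v in self.marker_probs.items():
            probs[panel.index_of(p)] = v
        return probs


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    ``reads_per_molecule`` is the mean of a shifted Poisson (every molecule
    yields at least one read). ``low_quality_fraction`` is the fraction of
    reads emitted with sub-Q20 base qualities, which the decoder's quality
    filter removes.
    """

    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"OVCA": 8, "Con": 18}, hash=False)
    evs_per_sample: int = 20_000
    molecules_per_protein_rate: float = 2.0  # zero-truncated Poisson rate
    umi_length: int = 8
    ev_tag_length: int = 15
    reads_per_molecule: float = 1.2
    base_error_rate: float = 0.001
    low_quality_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.samples_per_group.values()):
            raise ValueError("sample counts must be positive")
        if self.evs_per_sample <= 0:
            raise ValueError("evs_per_sample must be positive")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0,1)")
        if not 0.0 <= self.low_quality_fraction <= 1.0:
            raise ValueError("low_quality_fraction must be in [0,1]")
        if self.reads_per_molecule < 1.0:
            raise ValueError("reads_per_molecule must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    matrices: dict[str, SingleEVMatrix]        # sample_id -> truth counts
    sample_groups: pd.Series                   # sample_id -> group label
    ev_table: pd.DataFrame                     # ev_id, sample, group, subcluster
    panel: PanelSpec
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ev_table.to_csv(outdir / "truth_evs.tsv", sep="\t", index=False)
        self.sample_groups.rename("group").rename_axis("sample_id").to_csv(
            outdir / "samples.tsv", sep="\t")
        self.panel.to_tsv(outdir / "panel.tsv")
        for sid, mat in self.matrices.items():
            mat.to_long_tsv(outdir / f"{sid}.truth.tsv")


def default_scenario(panel: PanelSpec | None = None,
                     planted_weight: float = 0.3,
                     tumor_markers: dict[str, float] | None = None,
                     ) -> tuple[PanelSpec, list[SubclusterSpec]]:
    """Default study conditions: three background subclusters shared by both
    groups plus one case-only tumor subcluster.

    Background weights are renormalized so each group's mixture sums to 1
    given the planted weight in the case group.
    """
    if panel is None:
        panel = default_panel()
    if tumor_markers is None:
        tumor_markers = TUMOR_MARKER_PROBS
    bg = [
        ("tetraspanin_bg", {"CD9": 0.7, "CD63": 0.6, "CD81": 0.5,
                            "LAMP1": 0.2}, 0.5),
        ("integrin_bg", {"ITGB1": 0.5, "ITGA3": 0.3, "ITGA6": 0.3,
                         "CD9": 0.3, "ITGAL": 0.2}, 0.3),
        ("dim_bg", {"CD9": 0.5, "CD63": 0.3}, 0.2),
    ]
    subclusters = [
        SubclusterSpec(name, probs,
                       {"OVCA": w * (1.0 - planted_weight), "Con": w},
                       baseline_prob=0.01)
        for name, probs, w in bg
    ]
    subclusters.append(SubclusterSpec(
        "cdcp1_tumor", dict(tumor_markers),
        {"OVCA": planted_weight, "Con": 0.0}, baseline_prob=0.01))
    return panel, subclusters


def _check_mixture(subclusters: list[SubclusterSpec],
                   groups: list[str]) -> dict[str, np.ndarray]:
    weights = {}
    for g in groups:
        w = np.array([s.group_weights.get(g, 0.0) for s in subclusters])
        if (w < 0).any() or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights for group {g!r} must sum to 1")
        weights[g] = w
    return weights


def _random_tags(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct random DNA tags as a (n, length) uint8 base-index array."""
    tags = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    # resolve collisions (negligible probability for length >= 12, but the
    # round-trip guarantee requires distinctness)
    while True:
        _, idx, counts = np.unique(tags, axis=0, return_index=True,
                                   return_counts=True)
        if (counts == 1).all():
            break
        dup = np.setdiff1d(np.arange(n), idx[counts == 1])
        tags[dup] = rng.integers(0, 4, size=(dup.size, length), dtype=np.uint8)
    return tags


def _tags_to_str(tags: np.ndarray) -> list[str]:
    return [t.tobytes().decode() for t in np.take(_BASE_BYTES, tags)]


def _zero_truncated_poisson(rate: float, size: int,
                            rng: np.random.Generator) -> np.ndarray:
    out = rng.poisson(rate, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(rate, size=int(zero.sum()))
        zero = out == 0
    return out


def simulate_population(config: SimConfig, panel: PanelSpec,
                        subclusters: list[SubclusterSpec]) -> SimulationTruth:
    """Draw the ground-truth single-EV matrices for every sample.

    EVs on which no protein is detected are dropped (they are invisible to
    the assay), so realized EV counts can fall slightly below
    ``evs_per_sample``.
    """
    groups = list(config.samples_per_group)
    weights = _check_mixture(subclusters, groups)
    prob_vectors = np.stack([s.prob_vector(panel) for s in subclusters])
    rng = np.random.default_rng(config.seed)

    matrices: dict[str, SingleEVMatrix] = {}
    sample_groups = {}
    ev_rows = []
    for g in groups:
        for i in range(config.samples_per_group[g]):
            sid = f"{g}_{i + 1:02d}"
            sample_groups[sid] = g
            n = config.evs_per_sample
            sub_idx = rng.choice(len(subclusters), size=n, p=weights[g])
            present = rng.random((n, panel.size)) < prob_vectors[sub_idx]
            keep = present.any(axis=1)
            present = present[keep]
            sub_idx = sub_idx[keep]
            tags = _random_tags(int(keep.sum()), config.ev_tag_length, rng)
            ev_ids = _tags_to_str(tags)
            rows, cols = np.nonzero(present)
            counts = _zero_truncated_poisson(
                config.molecules_per_protein_rate, rows.size, rng)
            mat = sparse.coo_matrix(
                (counts, (rows, cols)),
                shape=(len(ev_ids), panel.size)).tocsr()
            matrices[sid] = SingleEVMatrix(sid, ev_ids, list(panel.proteins),
                                           mat)
            ev_rows.append(pd.DataFrame({
                "ev_id": ev_ids, "sample": sid, "group": g,
                "subcluster": [subclusters[j].name for j in sub_idx]}))
    return SimulationTruth(
        matrices=matrices,
        sample_groups=pd.Series(sample_groups, name="group"),
        ev_table=pd.concat(ev_rows, ignore_index=True),
        panel=panel, config=config)


def emit_reads(truth: SimulationTruth, outdir: str | Path,
               config: SimConfig | None = None) -> dict[str, Path]:
    """Write one FASTQ per sample; returns sample_id -> path.

    Read sequence = EV tag | protein tag | UMI. Molecules of one (EV,
    protein) get distinct UMIs, so at zero error rate and zero low-quality
    fraction decoding reproduces the truth matrix exactly. Qualities are
    two-valued: Q40 throughout for passing reads, Q12 for reads destined to
    fail the Q20 filter.
    """
    if config is None:
        config = truth.config
    panel = truth.panel
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EAD]))
    tag_len = panel.tag_length
    read_len = config.ev_tag_length + tag_len + config.umi_length
    protein_tag_arr = np.frombuffer(
        "".join(panel.tag_map[p] for p in panel.proteins).encode(),
        dtype=np.uint8).reshape(panel.size, tag_len)
    base_of = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_of[b] = i
    protein_tag_idx = base_of[protein_tag_arr]

    paths = {}
    for sid, mat in truth.matrices.items():
        coo = mat.counts.tocoo()
        ev_tag_idx = np.stack([
            base_of[np.frombuffer(e.encode(), dtype=np.uint8)]
            for e in mat.ev_ids]) if mat.ev_ids else np.zeros(
                (0, config.ev_tag_length), dtype=np.uint8)
        n_mol = int(coo.data.sum())
        # one row per molecule
        mol_ev = np.repeat(coo.row, coo.data)
        mol_prot = np.repeat(coo.col, coo.data)
        # distinct UMIs within each (ev, protein): draw, then redraw clashes
        umi_codes = rng.integers(0, 4 ** config.umi_length, size=n_mol,
                                 dtype=np.int64)
        pair_key = mol_ev.astype(np.int64) * panel.size + mol_prot
        while True:
            df = pd.DataFrame({"k": pair_key, "u": umi_codes})
            dup = df.duplicated()
            if not dup.any():
                break
            umi_codes[dup.to_numpy()] = rng.integers(
                0, 4 ** config.umi_length, size=int(dup.sum()))
        # reads per molecule: 1 + Poisson(rate - 1)
        n_reads_per_mol = 1 + rng.poisson(config.reads_per_molecule - 1.0,
                                          size=n_mol)
        read_mol = np.repeat(np.arange(n_mol), n_reads_per_mol)
        n_reads = read_mol.size

        umi_idx = np.zeros((n_mol, config.umi_length), dtype=np.uint8)
        rem = umi_codes.copy()
        for j in range(config.umi_length - 1, -1, -1):
            umi_idx[:, j] = rem % 4
            rem //= 4

        seqs = np.concatenate([
            ev_tag_idx[mol_ev[read_mol]],
            protein_tag_idx[mol_prot[read_mol]],
            umi_idx[read_mol],
        ], axis=1)
        if config.base_error_rate > 0:
            err = rng.random(seqs.shape) < config.base_error_rate
            # substitution: shift by 1..3 mod 4 so the base always changes
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            seqs[err] = (seqs[err] + shift) % 4
        seq_bytes = np.take(_BASE_BYTES, seqs)
        lowq = rng.random(n_reads) < config.low_quality_fraction
        q_pass = chr(33 + 40) * read_len
        q_fail = chr(33 + 12) * read_len

        path = outdir / f"{sid}.fastq"
        with open(path, "w") as fh:
            for r in range(n_reads):
                fh.write(f"@{sid}:r{r}\n")
                fh.write(seq_bytes[r].tobytes().decode())
                fh.write("\n+\n")
                fh.write(q_fail if lowq[r] else q_pass)
                fh.write("\n")
        paths[sid] = path
    return paths
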