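"""Sparse single-EV count matrices.

The central container: one matrix per sample, rows = individual vesicles
(identified by their EV tag), columns = panel proteins, values = number of
distinct molecular tags (UMIs) observed for that (EV, protein).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class SingleEVMatrix:
    """EV x protein molecule-count matrix for one sample.

    Rows are ordered by first appearance of the EV tag; columns follow the
    panel order. Every stored EV has at least one nonzero protein.
    """

    sample_id: str
    ev_ids: list[str]
    proteins: list[str]
    counts: sparse.csr_matrix  # shape (n_evs, n_proteins), nonnegative ints

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.ev_ids), len(self.proteins)):
            raise ValueError("counts shape does not match ev_ids/proteins")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    # ---------------------------------------------------------- properties
    @property
    def n_evs(self) -> int:
        return len(self.ev_ids)

    def protein_totals(self) -> pd.Series:
        """Summed molecule count per protein across all EVs (raw sample
        expression)."""
        tot = np.asarray(self.counts.sum(axis=0)).ravel()
        return pd.Series(tot, index=self.proteins, name=self.sample_id)

    def proteins_per_ev(self) -> np.ndarray:
        """Number of distinct detected proteins per EV."""
        return np.diff(self.counts.indptr)

    def detection(self) -> sparse.csr_matrix:
        """Binary detection matrix (count >= 1)."""
        out = self.counts.copy()
        out.data = np.ones_like(out.data)
        return out

    # ------------------------------------------------------------------ I/O
    def to_long_tsv(self, path: str | Path) -> None:
        """Triplet long format: ev_id, protein, count."""
        coo = self.counts.tocoo()
        df = pd.DataFrame({
            "ev_id": [self.ev_ids[i] for i in coo.row],
            "protein": [self.proteins[j] for j in coo.col],
            "count": coo.data.astype(int),
        })
        df.sort_values(["ev_id", "protein"], inplace=True)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path: str | Path, sample_id: str,
                      proteins: list[str]) -> "SingleEVMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"ev_id": str, "protein": str})
        return cls.from_long_df(df, sample_id, proteins)

    @classmethod
    def from_long_df(cls, df: pd.DataFrame, sample_id: str,
                     proteins: list[str]) -> "SingleEVMatrix":
        """Build from a long table with columns ev_id, protein, count.

        EV row order follows first appearance in the table.
        """
        ev_ids = list(dict.fromkeys(df["ev_id"]))
        ev_idx = {e: i for i, e in enumerate(ev_ids)}
        prot_idx = {p: j for j, p in enumerate(proteins)}
        unknown = set(df["protein"]) - set(proteins)
        if unknown:
            raise ValueError(f"proteins not in panel: {sorted(unknown)[:5]}")
        mat = sparse.coo_matrix(
            (df["count"].to_numpy(),
             (df["ev_id"].map(ev_idx).to_numpy(),
              df["protein"].map(prot_idx).to_numpy())),
            shape=(len(ev_ids), len(proteins)),
        ).tocsr()
        mat.sum_duplicates()
        return cls(sample_id, ev_ids, list(proteins), mat)

    def to_wide_tsv(self, path: str | Path) -> None:
        """Dense wide format: ev_id + one column per panel protein."""
        df = pd.DataFrame(self.counts.toarray(), columns=self.proteins)
        df.insert(0, "ev_id", self.ev_ids)
        df.to_csv(path, sep="\t", index=False)


def summarize_matrix(matrix: SingleEVMatrix) -> dict:
    """Per-sample summary: EV count, total molecules, proteins-per-EV stats."""
    ppe = matrix.proteins_per_ev()
    nonempty = ppe > 0
    ppe_nz = ppe[nonempty]
    return {
        "sample_id": matrix.sample_id,
        "n_evs": int(nonempty.sum()),
        "total_molecules": int(matrix.counts.sum()),
        "proteins_per_ev_median": float(np.median(ppe_nz)) if ppe_nz.size else 0.0,
        "proteins_per_ev_mean": float(ppe_nz.mean()) if ppe_nz.size else 0.0,
        "proteins_per_ev_max": int(ppe_nz.max()) if ppe_nz.size else 0,
    }
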