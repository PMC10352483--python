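"""FlowSOM-style EV subpopulation discovery.

Pooled single EVs are embedded as detection vectors, summarized by a
self-organizing map (SOM), and the SOM node prototypes are merged by
hierarchical average-linkage metaclustering into k subpopulations.
Each metacluster is profiled by its size, its sample-group composition
(e.g. the fraction of member EVs from the ovarian-cancer group) and the
per-protein detection frequency among its members; group enrichment is
scored with a binomial test against the pooled group proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import binomtest

from .expression import bh_adjust
from .matrix import SingleEVMatrix

logger = logging.getLogger(__name__)


def featurize(matrices: dict[str, SingleEVMatrix], groups: pd.Series,
              mode: str = "binary") -> tuple[np.ndarray, pd.DataFrame]:
    """Pool all samples' EVs into one feature matrix.

    mode "binary": protein detected (1) / absent (0) — the default, since
    single-EV counts are shallow and the cluster read-out is detection
    frequency. "counts": raw molecule counts. "log1p": log1p counts.
    """
    panels = {tuple(m.proteins) for m in matrices.values()}
    if len(panels) != 1:
        raise ValueError("samples use different panels")
    blocks, meta = [], []
    for sid, mat in matrices.items():
        if mode == "binary":
            blocks.append(mat.detection().toarray().astype(float))
        elif mode == "counts":
            blocks.append(mat.counts.toarray().astype(float))
        elif mode == "log1p":
            blocks.append(np.log1p(mat.counts.toarray().astype(float)))
        else:
            raise ValueError(f"unknown feature mode {mode!r}")
        meta.append(pd.DataFrame({"ev_id": mat.ev_ids, "sample": sid,
                                  "group": groups[sid]}))
    X = np.vstack(blocks)
    return X, pd.concat(meta, ignore_index=True)


def _grid_coords(grid_w: int, grid_h: int) -> np.ndarray:
    xx, yy = np.meshgrid(np.arange(grid_w), np.arange(grid_h),
                         indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)


def best_matching_units(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Index of the nearest prototype per row (Euclidean); exact distance
    ties go to the lowest node index."""
    d2 = ((X ** 2).sum(axis=1, keepdims=True)
          - 2.0 * X @ codebook.T
          + (codebook ** 2).sum(axis=1))
    return np.argmin(d2, axis=1)


@dataclass
class ClusterModel:
    """Trained SOM codebook plus node -> metacluster mapping."""

    codebook: np.ndarray            # (grid_w*grid_h, n_proteins)
    grid_w: int
    grid_h: int
    metacluster_of_node: np.ndarray  # (n_nodes,), labels 1..k
    k: int
    seed: int

    def assign(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(node, metacluster) per EV."""
        nodes = best_matching_units(X, self.codebook)
        return nodes, self.metacluster_of_node[nodes]


def train_som(X: np.ndarray, grid_w: int = 10, grid_h: int = 10,
              epochs: int = 10, sigma_start: float | None = None,
              sigma_end: float = 0.5, seed: int = 0) -> np.ndarray:
    """Batch SOM with a Gaussian neighborhood shrinking over epochs.

    Prototypes are initialized from distinct data rows drawn under the
    seed. Each epoch maps every EV to its best-matching unit and replaces
    each prototype by the neighborhood-weighted mean of the mapped data.
    Deterministic for a fixed seed.
    """
    n, d = X.shape
    n_nodes = grid_w * grid_h
    if n < n_nodes:
        raise ValueError(f"need at least {n_nodes} EVs, got {n}")
    if sigma_start is None:
        sigma_start = max(grid_w, grid_h) / 2.0
    rng = np.random.default_rng(seed)
    codebook = X[rng.choice(n, size=n_nodes, replace=False)].astype(float)
    if np.ptp(X, axis=0).max() == 0:
        logger.warning("all EV feature vectors identical; "
                       "codebook collapses to a single point")
        return codebook
    coords = _grid_coords(grid_w, grid_h)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    sigmas = np.geomspace(sigma_start, sigma_end, epochs)
    for sigma in sigmas:
        bmu = best_matching_units(X, codebook)
        H = np.exp(-grid_d2 / (2.0 * sigma ** 2))
        onehot = sparse.csr_matrix(
            (np.ones(n), (bmu, np.arange(n))), shape=(n_nodes, n))
        node_sums = onehot @ X            # (n_nodes, d)
        node_counts = np.asarray(onehot.sum(axis=1)).ravel()
        num = H @ node_sums
        den = H @ node_counts
        codebook = num / den[:, None]
    return codebook


def metacluster(codebook: np.ndarray, occupied: np.ndarray, k: int = 28,
                n_consensus_reps: int = 0, subsample: float = 0.9,
                seed: int = 0) -> np.ndarray:
    """Merge SOM nodes into k metaclusters.

    Occupied nodes (>= 1 mapped EV) are clustered by average-linkage
    hierarchical clustering of their prototypes (Euclidean), cut at k;
    with ``n_consensus_reps`` > 0 the linkage instead runs on a consensus
    co-clustering distance averaged over node-subsampled replicates.
    Unoccupied nodes inherit the label of the nearest occupied prototype.
    Returned labels are provisional (1..k, arbitrary order); sizes are
    ranked downstream where EV assignments are known.
    """
    occ_idx = np.flatnonzero(occupied)
    if k > occ_idx.size:
        raise ValueError(f"k={k} exceeds {occ_idx.size} occupied nodes")
    P = codebook[occ_idx]
    if n_consensus_reps > 0:
        rng = np.random.default_rng(seed)
        m = occ_idx.size
        together = np.zeros((m, m))
        counted = np.zeros((m, m))
        for _ in range(n_consensus_reps):
            sub = np.sort(rng.choice(m, size=max(k, int(subsample * m)),
                                     replace=False))
            Z = linkage(P[sub], method="average", metric="euclidean")
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            ix = np.ix_(sub, sub)
            together[ix] += same
            counted[ix] += 1.0
        with np.errstate(invalid="ignore"):
            dist = 1.0 - np.where(counted > 0, together / counted, 0.0)
        np.fill_diagonal(dist, 0.0)
        from scipy.spatial.distance import squareform
        Z = linkage(squareform(dist, checks=False), method="average")
    else:
        Z = linkage(P, method="average", metric="euclidean")
    occ_labels = fcluster(Z, t=k, criterion="maxclust")
    labels = np.zeros(codebook.shape[0], dtype=int)
    labels[occ_idx] = occ_labels
    if (~occupied).any():
        un_idx = np.flatnonzero(~occupied)
        nearest = best_matching_units(codebook[un_idx], P)
        labels[un_idx] = occ_labels[nearest]
    return labels


def _relabel_by_size(meta_labels: np.ndarray,
                     ev_meta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Renumber metaclusters 1..k by descending EV membership."""
    ids, counts = np.unique(ev_meta, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {old: new + 1 for new, old in enumerate(order)}
    # metaclusters with zero EVs keep their relative order after the rest
    leftover = sorted(set(meta_labels) - set(ids))
    for old in leftover:
        mapping[old] = len(mapping) + 1
    remap = np.vectorize(mapping.get)
    return remap(meta_labels), remap(ev_meta)


def cluster_evs(matrices: dict[str, SingleEVMatrix], groups: pd.Series,
                grid_w: int = 10, grid_h: int = 10, k: int = 28,
                epochs: int = 10, mode: str = "binary",
                n_consensus_reps: int = 0, seed: int = 0,
                ) -> tuple[ClusterModel, pd.DataFrame]:
    """Full clustering pipeline: featurize, train SOM, metacluster, assign.

    Returns the model and an assignment table (ev_id, sample, group, node,
    metacluster) with metacluster ids ordered by descending size.
    """
    X, meta = featurize(matrices, groups, mode=mode)
    codebook = train_som(X, grid_w, grid_h, epochs=epochs, seed=seed)
    nodes = best_matching_units(X, codebook)
    occupied = np.zeros(codebook.shape[0], dtype=bool)
    occupied[np.unique(nodes)] = True
    labels = metacluster(codebook, occupied, k=k,
                         n_consensus_reps=n_consensus_reps, seed=seed)
    ev_meta = labels[nodes]
    labels, ev_meta = _relabel_by_size(labels, ev_meta)
    model = ClusterModel(codebook, grid_w, grid_h, labels, k, seed)
    assignment = meta.assign(node=nodes, metacluster=ev_meta)
    return model, assignment


def profile_clusters(assignment: pd.DataFrame,
                     X_detect: np.ndarray,
                     proteins: list[str]) -> pd.DataFrame:
    """Per-metacluster size fraction, group composition, and per-protein
    detection frequency.

    ``X_detect`` must be the binary detection matrix aligned with
    ``assignment`` rows. Empty metaclusters are omitted.
    """
    n_total = len(assignment)
    group_names = sorted(assignment["group"].unique())
    rows = []
    for mc, idx in assignment.groupby("metacluster").groups.items():
        members = assignment.loc[idx]
        det = X_detect[np.asarray(idx)]
        row = {"metacluster": mc,
               "n_evs": len(members),
               "size_fraction": len(members) / n_total}
        for g in group_names:
            row[f"frac_{g}"] = float((members["group"] == g).mean())
        freq = det.mean(axis=0)
        for p, f in zip(proteins, freq):
            row[f"detfreq_{p}"] = float(f)
        rows.append(row)
    return (pd.DataFrame(rows)
            .sort_values("metacluster")
            .set_index("metacluster"))


def top_markers(profile_row: pd.Series, n: int = 10) -> list[str]:
    """Proteins ranked by detection frequency within one metacluster."""
    det = profile_row.filter(like="detfreq_")
    det.index = [c[len("detfreq_"):] for c in det.index]
    return det.sort_values(ascending=False).index[:n].tolist()


def enrichment_test(profile: pd.DataFrame, assignment: pd.DataFrame,
                    case_group: str) -> pd.DataFrame:
    """Two-sided binomial test per metacluster: member case-group count
    against the pooled case-group proportion, BH-corrected."""
    pooled = float((assignment["group"] == case_group).mean())
    rows = []
    for mc, row in profile.iterrows():
        n = int(row["n_evs"])
        x = int(round(row[f"frac_{case_group}"] * n))
        p = binomtest(x, n, pooled, alternative="two-sided").pvalue
        rows.append({"metacluster": mc, "n_evs": n,
                     f"frac_{case_group}": row[f"frac_{case_group}"],
                     "pooled_fraction": pooled, "p_value": p})
    out = pd.DataFrame(rows).set_index("metacluster")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
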