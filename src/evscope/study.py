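"""Reference synthetic study: the scaled-down OVCA-ascites cohort.

Assembles the full pipeline on generated data at a desk-scale version of
the study design: 8 case (OVCA-like) and 18 control samples, a shared
background EV mixture, and one case-specific subcluster (mixture weight
0.2) co-expressing CDCP1, TACSTD2, EPCAM, ITGA6 and ERBB2. Reads are
emitted and decoded at zero sequencing error so the decoder is part of the
loop, then the cohort is clustered, tested for differential expression,
and scored with single- and paired-marker ROC curves.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, combinations, decode, expression, roc, simulate
from .matrix import SingleEVMatrix
from .panel import PanelSpec, default_panel

#: Planted case-specific marker set (detection probabilities per EV).
PLANTED_MARKERS = {"CDCP1": 0.90, "TACSTD2": 0.80, "EPCAM": 0.80,
                   "ITGA6": 0.70, "ERBB2": 0.70}
PLANTED_WEIGHT = 0.2


def cohort_config(seed: int, evs_per_sample: int = 5000) -> simulate.SimConfig:
    """Error-free cohort configuration used by the recovery experiment."""
    return simulate.SimConfig(
        samples_per_group={"OVCA": 8, "Con": 18},
        evs_per_sample=evs_per_sample,
        base_error_rate=0.0, low_quality_fraction=0.0,
        reads_per_molecule=1.0, seed=seed)


def build_cohort(seed: int, evs_per_sample: int = 5000,
                 workdir: str | Path | None = None,
                 ) -> tuple[dict[str, SingleEVMatrix], pd.Series, PanelSpec]:
    """Simulate, emit FASTQ, and decode the reference cohort.

    Returns (decoded matrices, sample groups, panel).
    """
    panel = default_panel()
    _, subclusters = simulate.default_scenario(
        panel=panel, planted_weight=PLANTED_WEIGHT,
        tumor_markers=PLANTED_MARKERS)
    cfg = cohort_config(seed, evs_per_sample)
    truth = simulate.simulate_population(cfg, panel, subclusters)

    def _decode_all(outdir):
        paths = simulate.emit_reads(truth, outdir)
        return {sid: decode.decode_sample(p, panel)[0]
                for sid, p in paths.items()}

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            matrices = _decode_all(tmp)
    else:
        matrices = _decode_all(workdir)
    return matrices, truth.sample_groups, panel


def recovery_metrics(matrices: dict[str, SingleEVMatrix], groups: pd.Series,
                     panel: PanelSpec, k: int = 20, seed: int = 0,
                     top_n: int = 10) -> dict:
    """Cluster the cohort and measure planted-subcluster recovery.

    Returns the best metacluster's case-group fraction, its top detection
    markers, and whether all planted markers are within the top ``top_n``.
    """
    _, assignment = clustering.cluster_evs(matrices, groups,
                                           grid_w=10, grid_h=10, k=k,
                                           seed=seed)
    X, _ = clustering.featurize(matrices, groups, mode="binary")
    profiles = clustering.profile_clusters(assignment, X,
                                           list(panel.proteins))
    best = profiles["frac_OVCA"].idxmax()
    markers = clustering.top_markers(profiles.loc[best], n=top_n)
    return {
        "metacluster": int(best),
        "case_fraction": float(profiles.loc[best, "frac_OVCA"]),
        "size_fraction": float(profiles.loc[best, "size_fraction"]),
        "top_markers": markers,
        "recovered": (profiles.loc[best, "frac_OVCA"] >= 0.9
                      and set(PLANTED_MARKERS) <= set(markers)),
    }


def differential_expression(matrices: dict[str, SingleEVMatrix],
                            groups: pd.Series) -> pd.DataFrame:
    """TMM-normalized two-group differential expression of the cohort."""
    expr = expression.aggregate(matrices, groups)
    expression.tmm_normalize(expr)
    return expression.differential_test(expr, "OVCA")


def marker_aucs(matrices: dict[str, SingleEVMatrix], groups: pd.Series,
                single: str = "CDCP1",
                pair: tuple[str, str] = ("CDCP1", "ITGA6")) -> dict:
    """Single-marker AUC and co-expression pair AUC on the cohort."""
    expr = expression.aggregate(matrices, groups)
    expression.tmm_normalize(expr)
    tables = [combinations.cpm_normalize(combinations.count_combinations(m))
              for m in matrices.values()]
    res_single = roc.roc_single(expr, single, "OVCA")
    res_pair = roc.roc_pair(pair[0], pair[1], "OVCA", tables=tables,
                            groups=groups)
    return {"auc_single": res_single.auc, "auc_pair": res_pair.auc}


def null_discovery_fraction(n_reps: int = 500, panel_size: int = 20,
                            n_case: int = 8, n_ctrl: int = 18,
                            seed: int = 0) -> float:
    """Type-I error check: both groups drawn from one negative-binomial
    distribution; returns the fraction of protein tests declared
    significant at q < 0.05 over all replicates."""
    rng = np.random.default_rng(seed)
    n = n_case + n_ctrl
    discoveries = 0
    total = 0
    samples = [f"s{i}" for i in range(n)]
    groups = pd.Series(["case"] * n_case + ["ctrl"] * n_ctrl, index=samples)
    for _ in range(n_reps):
        mu = rng.gamma(3.0, 60.0, size=panel_size)
        counts = rng.negative_binomial(
            8, 8 / (8 + mu[:, None]), size=(panel_size, n)).astype(float)
        expr = expression.ExpressionSet(
            pd.DataFrame(counts, columns=samples), groups)
        res = expression.differential_test(expr, "case",
                                           use_normalized=False)
        valid = res.q_value.dropna()
        discoveries += int((valid < 0.05).sum())
        total += len(valid)
    return discoveries / total
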