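"""Clustering agreement metrics and the subsampling robustness harness."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .data_io import CountMatrix


def _check_lengths(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (permutation-model expectation correction)."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b, average_method: str = "arithmetic") -> float:
    """Normalized mutual information.

    Normalized by the arithmetic mean of the entropies by default;
    ``average_method="geometric"`` is available for comparability with other
    tools.
    """
    a, b = _check_lengths(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


@dataclass
class EvalReport:
    ari: float
    nmi: float
    k_true: int
    k_pred: int
    contingency: np.ndarray

    def __post_init__(self) -> None:
        self.contingency = np.asarray(self.contingency)


def evaluate(true_labels, pred_labels) -> EvalReport:
    t, p = _check_lengths(true_labels, pred_labels)
    return EvalReport(
        ari=ari(t, p),
        nmi=nmi(t, p),
        k_true=len(np.unique(t)),
        k_pred=len(np.unique(p)),
        contingency=contingency_matrix(t, p),
    )


def subsample_harness(
    counts: CountMatrix,
    true_labels: np.ndarray,
    fraction: float = 0.95,
    repeats: int = 10,
    seed: int = 0,
    config=None,
) -> list[EvalReport]:
    """Run the full pipeline on random cell subsets and score each run.

    Each repeat draws ``ceil(fraction * n)`` cells without replacement,
    reruns the de novo pipeline and reports ARI/NMI against the subset of
    the true labels.
    """
    from .adaptive_merge import ScaceConfig, run_scace

    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    true_labels = np.asarray(true_labels)
    n = counts.n_cells
    size = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    cfg = config or ScaceConfig()

    reports = []
    for _ in range(repeats):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        sub = CountMatrix(
            counts.counts[:, idx],
            gene_ids=list(counts.gene_ids),
            cell_ids=[counts.cell_ids[j] for j in idx],
        )
        result = run_scace(sub, mode="de_novo", config=cfg)
        reports.append(evaluate(true_labels[idx], result.labels))
    return reports
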