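"""Evaluation metrics and statistical procedures.

Overlap between an estimated source patch and ground truth (resection proxy or
simulated patch) is expressed as two normalized overlap ratios — overlap
divided by the estimated area (precision) and by the true area (recall) — with
geometric and harmonic means as single-number summaries.  Localization error is
the average, over seizure-onset-zone electrodes, of the minimum distance to the
boundary of the estimated epileptogenic zone (zero for covered electrodes).
Group comparisons use a label-shuffling permutation test; multi-spike-type
results are combined by occurrence-weighted averaging, with a resampling check
that conclusions do not hinge on the particular weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .mesh import CorticalMesh, SourcePatch

__all__ = [
    "EvaluationResult",
    "GroupComparison",
    "precision_recall",
    "mean_measures",
    "localization_error",
    "timecourse_correlation",
    "permutation_test",
    "weighted_spike_metrics",
    "weight_robustness",
]


@dataclass
class EvaluationResult:
    """Per-case bundle of overlap metrics."""

    precision: float
    recall: float
    geometric_mean: float = np.nan
    harmonic_mean: float = np.nan
    localization_error: float = np.nan
    estimated_area: float = np.nan
    true_area: float = np.nan
    timecourse_r: float = np.nan

    def __post_init__(self):
        if np.isnan(self.geometric_mean):
            self.geometric_mean, self.harmonic_mean = mean_measures(
                self.precision, self.recall
            )


@dataclass
class GroupComparison:
    """Permutation-test result for a difference of group means."""

    group_a: np.ndarray
    group_b: np.ndarray
    statistic: float
    p_value: float
    n_permutations: int
    sidedness: str


def precision_recall(estimate: SourcePatch, truth: SourcePatch,
                     mesh: CorticalMesh, area_weighted: bool = True):
    """Normalized overlap ratios between estimated and true patches.

    Overlap is the summed vertex area of the intersection (or the vertex count
    with ``area_weighted=False``); precision divides by the estimated patch's
    area, recall by the truth's.  An empty estimate scores (0, 0).
    """
    if len(truth) == 0:
        raise ValueError("truth patch is empty")
    if len(estimate) == 0:
        return 0.0, 0.0
    inter = np.intersect1d(estimate.vertex_ids, truth.vertex_ids)
    if area_weighted:
        overlap = mesh.vertex_areas[inter].sum()
        est_area = mesh.vertex_areas[estimate.vertex_ids].sum()
        true_area = mesh.vertex_areas[truth.vertex_ids].sum()
    else:
        overlap, est_area, true_area = len(inter), len(estimate), len(truth)
    return float(overlap / est_area), float(overlap / true_area)


def mean_measures(precision: float, recall: float):
    """Geometric mean sqrt(a*b) and harmonic mean 2ab/(a+b) of two ratios."""
    for v in (precision, recall):
        if not 0 <= v <= 1:
            raise ValueError("precision and recall must lie in [0, 1]")
    geometric = float(np.sqrt(precision * recall))
    harmonic = 0.0 if precision + recall == 0 else \
        float(2 * precision * recall / (precision + recall))
    return geometric, harmonic


def patch_boundary(patch: SourcePatch, mesh: CorticalMesh) -> np.ndarray:
    """Member vertices with at least one non-member neighbor."""
    members = set(patch.vertex_ids.tolist())
    return np.array(
        [v for v in patch.vertex_ids
         if any(nb not in members for nb in mesh.adjacency[v])],
        dtype=int,
    )


def localization_error(ez: SourcePatch, soz_electrodes: np.ndarray,
                       mesh: CorticalMesh) -> float:
    """Average minimum distance from SOZ electrodes to the EZ boundary (mm).

    An electrode whose nearest mesh vertex is an interior EZ vertex counts as
    zero error (it is covered by the estimate).
    """
    if len(ez) == 0:
        raise ValueError("empty EZ estimate")
    soz_electrodes = np.atleast_2d(np.asarray(soz_electrodes, dtype=float))
    if soz_electrodes.shape[0] < 1 or soz_electrodes.shape[1] != 3:
        raise ValueError("soz_electrodes must be P x 3")
    boundary = patch_boundary(ez, mesh)
    if boundary.size == 0:  # patch covers the whole (closed) mesh
        return 0.0
    members = set(ez.vertex_ids.tolist())
    boundary_set = set(boundary.tolist())
    interior = members - boundary_set
    dists = []
    for e in soz_electrodes:
        d_all = np.linalg.norm(mesh.vertices - e, axis=1)
        nearest = int(np.argmin(d_all))
        if nearest in interior:
            dists.append(0.0)
            continue
        dists.append(float(np.min(np.linalg.norm(mesh.vertices[boundary] - e, axis=1))))
    return float(np.mean(dists))


def timecourse_correlation(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between estimated and true time courses."""
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError("time courses must have equal length")
    if estimated.std() == 0 or truth.std() == 0:
        raise ValueError("zero-variance time course")
    return float(pearsonr(estimated, truth).statistic)


def permutation_test(a, b, n_perm: int = 10_000, side: str = "greater",
                     rng=None) -> GroupComparison:
    """Label-shuffling test for a difference of group means.

    The observed statistic mean(a) - mean(b) is compared to its distribution
    under ``n_perm`` random relabelings; the add-one estimator
    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` never returns exactly
    zero.  ``side`` is "greater", "less" or "two-sided".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    rng = np.random.default_rng(rng)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[:n_a].mean() - perm[n_a:].mean()
        if side == "greater":
            count += stat >= observed
        elif side == "less":
            count += stat <= observed
        elif side == "two-sided":
            count += abs(stat) >= abs(observed)
        else:
            raise ValueError("side must be greater, less or two-sided")
    p = (1 + count) / (n_perm + 1)
    return GroupComparison(group_a=a, group_b=b, statistic=float(observed),
                           p_value=float(p), n_permutations=n_perm, sidedness=side)


def weighted_spike_metrics(per_type, counts) -> EvaluationResult:
    """Combine per-spike-type metrics weighted by spike occurrence counts.

    With 30 of 100 spikes of type 1 and 70 of type 2, the combined metric is
    0.3 * m_1 + 0.7 * m_2, for each metric separately.
    """
    if len(per_type) != len(counts):
        raise ValueError("per_type and counts must have equal length")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    w = counts / counts.sum()
    fields = ["precision", "recall", "geometric_mean", "harmonic_mean",
              "localization_error", "estimated_area", "true_area", "timecourse_r"]
    combined = {f: float(np.sum(w * np.array([getattr(r, f) for r in per_type])))
                for f in fields}
    return EvaluationResult(**combined)


def _simplex_uniform(k: int, rng) -> np.ndarray:
    """Uniform draw from the probability simplex (normalized exponentials)."""
    e = rng.exponential(size=k)
    return e / e.sum()


def weight_robustness(spike_values_per_subject, seizure_values,
                      n_repeat: int = 10_000, n_perm: int = 1_000,
                      alpha: float = 0.05, side: str = "greater", rng=None):
    """Fraction of random-weight recombinations keeping the group test significant.

    ``spike_values_per_subject`` is one array of per-spike-type metric values
    per subject; each repeat draws simplex-uniform weights per subject,
    recombines the spike metrics, and reruns the seizure-versus-spike
    permutation test.  The permutation draws are shared across repeats (common
    random numbers), so only the weights vary.  Returns
    ``(fraction significant, p-value array)``.
    """
    rng = np.random.default_rng(rng)
    seizure_values = np.asarray(seizure_values, dtype=float)
    spike_values_per_subject = [np.asarray(v, dtype=float)
                                for v in spike_values_per_subject]
    if len(spike_values_per_subject) < 2:
        raise ValueError("need at least 2 subjects")
    perm_seed = int(rng.integers(2 ** 31))
    pvals = np.empty(n_repeat)
    for r in range(n_repeat):
        combined = np.array([
            v[0] if len(v) == 1 else float(_simplex_uniform(len(v), rng) @ v)
            for v in spike_values_per_subject
        ])
        pvals[r] = permutation_test(seizure_values, combined, n_perm=n_perm,
                                    side=side, rng=perm_seed).p_value
    return float(np.mean(pvals < alpha)), pvals
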