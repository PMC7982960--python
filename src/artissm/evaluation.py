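"""Model quality metrics: compactness, specificity, generalizability and
in-sample reconstruction error, each as a function of the number of modes.

Distances are root-mean-square corresponding-vertex distances over the
geometry block only (reported in mm); the skeleton entries of the shape
vector are excluded from the error metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ArticulatedShapeModel, ShapeModelResults


@dataclass
class EvaluationCurve:
    metric: str
    mode_counts: np.ndarray
    values: np.ndarray
    units: str
    per_subject: np.ndarray | None = None  # (n_subjects, n_mode_counts)

    def as_dict(self) -> dict:
        return {"metric": self.metric, "units": self.units,
                "mode_counts": self.mode_counts.tolist(),
                "values": self.values.tolist()}


def _geometry_rms(layout, a: np.ndarray, b: np.ndarray) -> float:
    """RMS distance between corresponding vertices of two shape vectors."""
    diff = (layout.geometry_block(a) - layout.geometry_block(b)).reshape(-1, 3)
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def compactness(results: ShapeModelResults) -> EvaluationCurve:
    """Cumulative percentage of variance explained by the first m modes."""
    vals = results.compactness()
    return EvaluationCurve("compactness", np.arange(1, len(vals) + 1), vals, "%")


def specificity(results: ShapeModelResults, training_vectors: np.ndarray,
                n_samples: int = 200, seed: int = 0,
                mode_counts=None) -> EvaluationCurve:
    """How close randomly generated instances are to the training set.

    For each mode count m, instances are drawn using modes 1..m with
    standard-normal weights; each instance is scored by the RMS
    corresponding-vertex distance to its nearest training shape, and the
    curve reports the mean over samples.
    """
    training_vectors = np.atleast_2d(training_vectors)
    layout = results.layout
    if mode_counts is None:
        mode_counts = np.arange(1, results.n_modes + 1)
    mode_counts = np.asarray(mode_counts, int)
    values = []
    for m in mode_counts:
        vectors, _ = results.sample(n_samples, seed=seed, n_modes=int(m))
        dists = []
        for v in vectors:
            best = min(_geometry_rms(layout, v, t) for t in training_vectors)
            dists.append(best)
        values.append(float(np.mean(dists)))
    return EvaluationCurve("specificity", mode_counts, np.asarray(values), "mm")


def reconstruction_error(results: ShapeModelResults, vectors: np.ndarray,
                         mode_counts=None) -> EvaluationCurve:
    """In-sample error: fit the full model to each training shape with m
    modes and measure the RMS corresponding-vertex residual."""
    vectors = np.atleast_2d(vectors)
    layout = results.layout
    if mode_counts is None:
        mode_counts = np.arange(1, results.n_modes + 1)
    mode_counts = np.asarray(mode_counts, int)
    per_subject = np.zeros((len(vectors), len(mode_counts)))
    for i, s in enumerate(vectors):
        for k, m in enumerate(mode_counts):
            b = results.project(s, n_modes=int(m))
            per_subject[i, k] = _geometry_rms(layout, s, results.synthesize(b))
    return EvaluationCurve("reconstruction_error", mode_counts,
                           per_subject.mean(axis=0), "mm", per_subject)


def generalizability(vectors: np.ndarray, layout, mus,
                     mode_counts=None) -> EvaluationCurve:
    """Leave-one-out fitting error.

    For every subject, the model is rebuilt from the L-1 remaining shapes
    and fitted to the held-out one with m modes; the curve is the mean RMS
    corresponding-vertex error across subjects.
    """
    vectors = np.atleast_2d(vectors)
    L = len(vectors)
    if L < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    max_modes = L - 2  # a model built on L-1 shapes has at most L-2 modes
    if mode_counts is None:
        mode_counts = np.arange(1, max_modes + 1)
    mode_counts = np.asarray(mode_counts, int)
    mode_counts = mode_counts[mode_counts <= max_modes]
    per_subject = np.zeros((L, len(mode_counts)))
    for i in range(L):
        rest = np.delete(vectors, i, axis=0)
        res = ArticulatedShapeModel(rest, layout, mus).fit()
        for k, m in enumerate(mode_counts):
            b = res.project(vectors[i], n_modes=int(m))
            per_subject[i, k] = _geometry_rms(layout, vectors[i], res.synthesize(b))
    return EvaluationCurve("generalizability", mode_counts,
                           per_subject.mean(axis=0), "mm", per_subject)


def evaluate_all(results: ShapeModelResults, training_vectors: np.ndarray,
                 n_samples: int = 200, seed: int = 0) -> dict[str, EvaluationCurve]:
    """Compactness, specificity, generalizability and reconstruction error
    in one call (the standard model scorecard)."""
    return {
        "compactness": compactness(results),
        "specificity": specificity(results, training_vectors, n_samples, seed),
        "generalizability": generalizability(training_vectors, results.layout,
                                             results.mus),
        "reconstruction_error": reconstruction_error(results, training_vectors),
    }
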