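"""Second-order distance tables and classical (Torgerson) MDS.

Regions and models are embedded together: every pairwise second-order
correlation is converted to a distance 1 − statistic and the resulting
table is double-centred and eigendecomposed. Because projection to 2-D
distorts distances, per-pair residuals (embedded minus true distance) are
reported alongside the coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ModelRDM
from .inference import InferenceError, _corr_rows, rdm_correlation
from .patterns import RDM

__all__ = [
    "DistanceTable",
    "model_region_distances",
    "classical_mds",
    "embedding_residuals",
]


@dataclass
class DistanceTable:
    entities: tuple[str, ...]
    dist: np.ndarray

    def __post_init__(self) -> None:
        self.entities = tuple(self.entities)
        self.dist = np.asarray(self.dist, float)
        n = len(self.entities)
        if self.dist.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.dist)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.dist, self.dist.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.dist), 0, atol=1e-10):
            raise ValueError("distance diagonal must be 0")
        self.dist = (self.dist + self.dist.T) / 2.0
        np.fill_diagonal(self.dist, 0.0)

    @property
    def n(self) -> int:
        return len(self.entities)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dist, index=self.entities, columns=self.entities
        )


#: Dissimilarity imputed on a model's unconstrained cells when two models
#: must be compared but are constant on their jointly constrained cells
#: (e.g. two detectors, which agree "1" on every shared cell). Matches the
#: neutral similarity the synthetic generator assigns those cells.
NEUTRAL_DISSIM = 0.5


def _model_pair_distance(
    a: ModelRDM, b: ModelRDM, method: str
) -> float:
    iu, ju = np.triu_indices(a.n_conditions, k=1)
    joint = (a.mask & b.mask)[iu, ju]
    if np.count_nonzero(joint) < 3:
        raise InferenceError(
            f"models {a.name!r} and {b.name!r} share "
            f"{int(np.count_nonzero(joint))} constrained cells; >= 3 required"
        )
    x = a.dissim[iu[joint], ju[joint]]
    y = b.dissim[iu[joint], ju[joint]]
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        # fall back to the union of constrained cells, imputing the neutral
        # value on each model's unconstrained cells
        union = (a.mask | b.mask)[iu, ju]
        xf = np.where(a.mask, a.dissim, NEUTRAL_DISSIM)[iu[union], ju[union]]
        yf = np.where(b.mask, b.dissim, NEUTRAL_DISSIM)[iu[union], ju[union]]
        if (
            np.count_nonzero(union) < 3
            or np.ptp(xf) < 1e-12
            or np.ptp(yf) < 1e-12
        ):
            raise InferenceError(
                f"models {a.name!r} vs {b.name!r}: constant vector on the "
                "jointly constrained cells and no usable union fallback"
            )
        x, y = xf, yf
    return 1.0 - float(_corr_rows(x[None, :], y, method)[0])


def model_region_distances(
    region_rdms: Mapping[str, RDM],
    models: Sequence[ModelRDM],
    method: str = "pearson",
) -> DistanceTable:
    """Distance table over regions and models: 1 − second-order correlation.

    Region–model cells use each model's constrained cells; model–model cells
    use the jointly constrained cells; region–region cells correlate full
    upper triangles.
    """
    regions = sorted(region_rdms)
    entities = list(regions) + [m.name for m in models]
    n = len(entities)
    if n < 2:
        raise InferenceError("need at least two entities to embed")
    dist = np.zeros((n, n))
    nr = len(regions)
    for a in range(nr):
        va = region_rdms[regions[a]].upper_vector()
        for b in range(a + 1, nr):
            vb = region_rdms[regions[b]].upper_vector()
            d = 1.0 - float(_corr_rows(va[None, :], vb, method)[0])
            dist[a, b] = dist[b, a] = d
    for a in range(nr):
        for mi, model in enumerate(models):
            d = 1.0 - rdm_correlation(
                region_rdms[regions[a]], model, method
            )
            dist[a, nr + mi] = dist[nr + mi, a] = d
    for mi in range(len(models)):
        for mj in range(mi + 1, len(models)):
            d = _model_pair_distance(models[mi], models[mj], method)
            dist[nr + mi, nr + mj] = dist[nr + mj, nr + mi] = d
    return DistanceTable(entities=tuple(entities), dist=np.clip(dist, 0, None))


def classical_mds(
    d: DistanceTable, dims: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Torgerson double-centring eigendecomposition.

    Returns a coordinates frame (entity × dims) and the full eigenvalue
    spectrum (descending). Axes are ordered by eigenvalue; the sign of each
    axis is fixed so that the lexicographically smallest entity with a
    nonzero coordinate on that axis is positive, making the embedding
    invariant to entity input order. Negative eigenvalues (non-Euclidean
    input) contribute zero coordinates.
    """
    n = d.n
    if not (1 <= dims < n):
        raise ValueError("dims must satisfy 1 <= dims < number of entities")
    D2 = d.dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if np.max(np.abs(w)) < 1e-12:
        warnings.warn(
            "degenerate embedding: all pairwise distances are equal to zero",
            RuntimeWarning,
        )
    coords = V[:, :dims] * np.sqrt(np.clip(w[:dims], 0.0, None))
    # canonical sign per axis, keyed on entity labels (order-invariant)
    label_order = np.argsort(np.asarray(d.entities))
    for k in range(dims):
        col = coords[:, k]
        for idx in label_order:
            if abs(col[idx]) > 1e-9:
                if col[idx] < 0:
                    coords[:, k] = -col
                break
    frame = pd.DataFrame(
        coords,
        index=list(d.entities),
        columns=[f"dim{k + 1}" for k in range(dims)],
    )
    frame.index.name = "entity"
    return frame, w


def embedding_residuals(
    d: DistanceTable, coords: pd.DataFrame
) -> pd.DataFrame:
    """Per-pair residuals: embedded Euclidean distance minus true distance."""
    X = coords.to_numpy(float)
    rows = []
    for a in range(d.n):
        for b in range(a + 1, d.n):
            emb = float(np.linalg.norm(X[a] - X[b]))
            rows.append(
                {
                    "entity_a": d.entities[a],
                    "entity_b": d.entities[b],
                    "true_distance": float(d.dist[a, b]),
                    "embedded_distance": emb,
                    "residual": emb - float(d.dist[a, b]),
                }
            )
    return pd.DataFrame(rows)
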