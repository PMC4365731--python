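"""First-order activation RDMs from multivoxel patterns.

Each region-of-interest pattern is a voxel × condition matrix of GLM
parameter estimates. The dissimilarity between two conditions is the
correlation distance 1 − r, with r the Pearson correlation of their voxel
patterns, so every RDM cell lies in [0, 2] and the diagonal is exactly 0.
Per-subject RDMs are averaged cell-wise across participants before being
compared with hypothesis models.

Zero-variance (flat) condition patterns make Pearson r undefined; they raise
:class:`DegeneratePatternError` naming the offending condition rather than
propagating NaN into averaged RDMs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gramrsa")

__all__ = [
    "DegeneratePatternError",
    "PatternMatrix",
    "RDM",
    "correlation_distance",
    "activation_rdm",
    "average_rdms",
    "write_rdm_tsv",
    "read_rdm_tsv",
    "write_pattern_tsv",
    "read_pattern_tsv",
    "write_pattern_set",
    "read_pattern_manifest",
]


class DegeneratePatternError(ValueError):
    """A voxel pattern has zero variance, so correlation is undefined."""


@dataclass
class PatternMatrix:
    """Voxel × condition activity estimates for one subject in one ROI."""

    values: np.ndarray
    conditions: tuple[str, ...]
    subject_id: str = ""
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.conditions = tuple(self.conditions)
        if self.values.ndim != 2:
            raise ValueError("pattern values must be 2-D (voxel x condition)")
        if self.values.shape[0] < 2:
            raise ValueError("pattern needs >= 2 voxels")
        if self.values.shape[1] != len(self.conditions):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.conditions)} condition labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"non-finite entries in pattern "
                f"(subject={self.subject_id!r}, roi={self.roi_id!r})"
            )

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass
class RDM:
    """Symmetric condition × condition matrix of correlation distances."""

    dissim: np.ndarray
    conditions: tuple[str, ...]
    n_subjects: int = 1

    def __post_init__(self) -> None:
        self.dissim = np.asarray(self.dissim, float)
        self.conditions = tuple(self.conditions)
        n = len(self.conditions)
        if self.dissim.shape != (n, n):
            raise ValueError("RDM shape does not match condition labels")
        if not np.all(np.isfinite(self.dissim)):
            raise ValueError("RDM contains non-finite entries")
        if not np.allclose(self.dissim, self.dissim.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(self.dissim), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be 0")
        if self.dissim.min() < -1e-10 or self.dissim.max() > 2 + 1e-10:
            raise ValueError("RDM entries must lie in [0, 2]")
        # exact symmetry / zero diagonal after numerical tolerance checks
        self.dissim = np.clip((self.dissim + self.dissim.T) / 2.0, 0.0, 2.0)
        np.fill_diagonal(self.dissim, 0.0)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def upper_vector(self) -> np.ndarray:
        i, j = np.triu_indices(self.n_conditions, k=1)
        return self.dissim[i, j]


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 − Pearson r between two voxel vectors (range [0, 2])."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    sx = x - x.mean()
    sy = y - y.mean()
    vx = float(sx @ sx)
    vy = float(sy @ sy)
    if vx == 0.0 or vy == 0.0:
        raise DegeneratePatternError("zero-variance pattern vector")
    r = float(sx @ sy) / np.sqrt(vx * vy)
    return float(np.clip(1.0 - r, 0.0, 2.0))


def activation_rdm(p: PatternMatrix) -> RDM:
    """All pairwise correlation distances between condition patterns."""
    variances = p.values.var(axis=0)
    flat = np.flatnonzero(variances == 0.0)
    if flat.size:
        names = [p.conditions[k] for k in flat]
        raise DegeneratePatternError(
            f"zero-variance condition pattern(s) {names} "
            f"(subject={p.subject_id!r}, roi={p.roi_id!r})"
        )
    r = np.corrcoef(p.values.T)
    dissim = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dissim, 0.0)
    return RDM(dissim=dissim, conditions=p.conditions, n_subjects=1)


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Cell-wise arithmetic mean of RDMs; ``n_subjects`` accumulates."""
    if len(rdms) == 0:
        raise ValueError("need at least one RDM to average")
    first = rdms[0]
    for r in rdms[1:]:
        if r.dissim.shape != first.dissim.shape:
            raise ValueError("RDM shape mismatch in average")
        if r.conditions != first.conditions:
            raise ValueError("RDM condition-label mismatch in average")
    mean = np.mean([r.dissim for r in rdms], axis=0)
    return RDM(
        dissim=mean,
        conditions=first.conditions,
        n_subjects=sum(r.n_subjects for r in rdms),
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def write_rdm_tsv(rdm: RDM, path: str | Path) -> None:
    df = pd.DataFrame(rdm.dissim, index=rdm.conditions, columns=rdm.conditions)
    df.index.name = f"n_subjects={rdm.n_subjects}"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_rdm_tsv(path: str | Path) -> RDM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_subjects = 1
    if df.index.name and "=" in str(df.index.name):
        n_subjects = int(str(df.index.name).split("=", 1)[1])
    return RDM(
        dissim=df.to_numpy(float),
        conditions=tuple(df.columns),
        n_subjects=n_subjects,
    )


def write_pattern_tsv(p: PatternMatrix, path: str | Path) -> None:
    df = pd.DataFrame(p.values, columns=p.conditions)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_pattern_tsv(
    path: str | Path, subject_id: str = "", roi_id: str = ""
) -> PatternMatrix:
    df = pd.read_csv(path, sep="\t")
    return PatternMatrix(
        values=df.to_numpy(float),
        conditions=tuple(df.columns),
        subject_id=subject_id,
        roi_id=roi_id,
    )


def write_pattern_set(
    patterns: Mapping[tuple[str, str], PatternMatrix], outdir: str | Path
) -> Path:
    """Write a directory of per-(subject, ROI) pattern TSVs plus a manifest.

    Returns the manifest path. The manifest columns are subject_id, roi_id,
    path (relative to the manifest's directory).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (subject_id, roi_id), p in sorted(patterns.items()):
        rel = f"sub-{subject_id}_roi-{roi_id}.tsv"
        write_pattern_tsv(p, outdir / rel)
        rows.append(
            {"subject_id": subject_id, "roi_id": roi_id, "path": rel}
        )
    manifest = outdir / "patterns_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_pattern_manifest(
    manifest_path: str | Path,
) -> dict[tuple[str, str], PatternMatrix]:
    """Load all pattern matrices listed in a manifest TSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"subject_id", "roi_id", "path"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"pattern manifest must have columns {sorted(required)}"
        )
    out: dict[tuple[str, str], PatternMatrix] = {}
    for row in df.itertuples(index=False):
        out[(row.subject_id, row.roi_id)] = read_pattern_tsv(
            base / row.path, subject_id=row.subject_id, roi_id=row.roi_id
        )
    return out
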