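"""Synthetic multi-subject voxel patterns with planted representational
geometry.

The generator starts at the GLM-beta level (the pipeline's actual input):
for a region planted with a hypothesis model, each voxel's 12-condition
response is drawn from a zero-mean Gaussian whose covariance encodes the
model's similarity structure, scaled so that signal variance / noise
variance equals the requested SNR, plus i.i.d. unit-variance voxel noise.
"noise" regions are pure noise (SNR forced to 0). Noise is spatially
independent across voxels — sufficient for correlation-distance RDM
behaviour; spatial smoothness is a documented extension point.

The default study mirrors the emulated experiment: 18 subjects, 22 regions
({BA44, BA45, BA47, FOP, aSTG, pSTG, aMTG, pMTG, aITG, pITG, TP} × {L, R}),
with the inflection detector planted in L BA44 / L pSTG / L aITG and the
phrase detector in bilateral aSTG, bilateral aMTG and L pMTG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .design import (
    CORE_MODELS,
    ConditionSet,
    ModelRDM,
    build_condition_set,
    build_model,
)
from .patterns import PatternMatrix
from .volumes import ROIMask, VoxelGrid, extract_patterns, write_mask

__all__ = [
    "REGION_NAMES",
    "DEFAULT_SCENARIO",
    "ROISpec",
    "StudyConfig",
    "SyntheticStudy",
    "similarity_covariance",
    "simulate_roi_patterns",
    "default_roster",
    "simulate_study",
    "export_nifti_study",
    "load_nifti_study",
]

REGION_NAMES: tuple[str, ...] = (
    "BA44", "BA45", "BA47", "FOP",
    "aSTG", "pSTG", "aMTG", "pMTG", "aITG", "pITG", "TP",
)

#: Planted truth of the default scenario (regions not listed are "noise").
DEFAULT_SCENARIO: dict[str, str] = {
    "L_BA44": "detector_inflected",
    "L_pSTG": "detector_inflected",
    "L_aITG": "detector_inflected",
    "L_aSTG": "detector_phrase",
    "R_aSTG": "detector_phrase",
    "L_aMTG": "detector_phrase",
    "R_aMTG": "detector_phrase",
    "L_pMTG": "detector_phrase",
}

#: Similarity assigned to model-unconstrained condition pairs when building
#: the generative covariance (neutral: halfway between alike and unlike).
UNCONSTRAINED_SIMILARITY = 0.5

MIN_ROI_VOXELS, MAX_ROI_VOXELS = 50, 500


@dataclass(frozen=True)
class ROISpec:
    roi_id: str
    n_voxels: int
    planted: str  # model name or "noise"


@dataclass(frozen=True)
class StudyConfig:
    """Study-level generator settings.

    snr is planted signal variance over noise variance; alpha mixes the
    model-derived condition covariance with the identity (alpha = 0 gives
    unstructured signal).
    """

    seed: int
    n_subjects: int = 18
    snr: float = 5.0
    alpha: float = 0.7
    rois: tuple[ROISpec, ...] | None = None
    weights: Mapping[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "snr": self.snr,
            "alpha": self.alpha,
            "rois": None
            if self.rois is None
            else [[r.roi_id, r.n_voxels, r.planted] for r in self.rois],
            "weights": None if self.weights is None else dict(self.weights),
        }


@dataclass
class SyntheticStudy:
    config: StudyConfig
    condition_set: ConditionSet
    rois: tuple[ROISpec, ...]
    patterns: dict[tuple[str, str], PatternMatrix]
    truth: dict[str, str]

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s for s, _ in self.patterns})

    def roi_patterns(self, roi_id: str) -> list[PatternMatrix]:
        return [
            self.patterns[(s, roi_id)] for s in self.subject_ids
        ]


def similarity_covariance(model: ModelRDM, alpha: float) -> np.ndarray:
    """Condition covariance implied by a model RDM.

    S = 1 − dissim on constrained cells, 0.5 on unconstrained cells, 1 on
    the diagonal; the mixture alpha·S + (1 − alpha)·I is projected to the
    nearest PSD matrix by clipping negative eigenvalues.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    n = model.n_conditions
    S = np.where(
        model.mask, 1.0 - np.nan_to_num(model.dissim), UNCONSTRAINED_SIMILARITY
    )
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    sigma = alpha * S + (1.0 - alpha) * np.eye(n)
    w, V = np.linalg.eigh(sigma)
    sigma_psd = (V * np.clip(w, 0.0, None)) @ V.T
    return (sigma_psd + sigma_psd.T) / 2.0


def _covariance_sqrt(sigma: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(sigma)
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_roi_patterns(
    model: ModelRDM | str,
    n_voxels: int,
    n_subjects: int,
    snr: float,
    alpha: float = 0.7,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    condition_set: ConditionSet | None = None,
    roi_id: str = "",
) -> list[PatternMatrix]:
    """Per-subject voxel × condition patterns for one region.

    ``model`` may be a ModelRDM or the string "noise" (pure noise, snr 0).
    """
    if n_voxels < 10:
        raise ValueError("n_voxels must be >= 10")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if snr < 0:
        raise ValueError("snr must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if condition_set is None:
        condition_set = build_condition_set()
    n_cond = condition_set.n
    if isinstance(model, str):
        if model != "noise":
            raise ValueError(f"model must be a ModelRDM or 'noise', got {model!r}")
        A = None
        snr = 0.0
    else:
        sigma = similarity_covariance(model, alpha)
        A = _covariance_sqrt(sigma)
    out = []
    for s in range(n_subjects):
        noise = rng.standard_normal((n_voxels, n_cond))
        if A is not None and snr > 0:
            signal = rng.standard_normal((n_voxels, n_cond)) @ A.T
            values = np.sqrt(snr) * signal + noise
        else:
            values = noise
        out.append(
            PatternMatrix(
                values=values,
                conditions=condition_set.labels,
                subject_id=f"{s + 1:02d}",
                roi_id=roi_id,
            )
        )
    return out


def default_roster(
    rng: np.random.Generator,
    scenario: Mapping[str, str] | None = None,
) -> tuple[ROISpec, ...]:
    """The 22-region bilateral roster with log-uniform voxel counts."""
    if scenario is None:
        scenario = DEFAULT_SCENARIO
    specs = []
    lo, hi = np.log(MIN_ROI_VOXELS), np.log(MAX_ROI_VOXELS)
    for hemi in ("L", "R"):
        for name in REGION_NAMES:
            roi_id = f"{hemi}_{name}"
            n_vox = int(round(np.exp(rng.uniform(lo, hi))))
            specs.append(
                ROISpec(
                    roi_id=roi_id,
                    n_voxels=n_vox,
                    planted=scenario.get(roi_id, "noise"),
                )
            )
    return tuple(specs)


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate the full multi-subject, multi-region study.

    Identical seeds give bit-identical studies: one master generator is
    consumed in a fixed ROI-major order.
    """
    cs = build_condition_set(config.weights)
    rng = np.random.default_rng(config.seed)
    rois = config.rois if config.rois is not None else default_roster(rng)
    for spec in rois:
        if spec.planted != "noise" and spec.planted not in CORE_MODELS:
            # allow any registered model name
            build_model(spec.planted, cs)
    patterns: dict[tuple[str, str], PatternMatrix] = {}
    truth: dict[str, str] = {}
    for spec in rois:
        model: ModelRDM | str
        model = "noise" if spec.planted == "noise" else build_model(
            spec.planted, cs
        )
        roi_pats = simulate_roi_patterns(
            model,
            n_voxels=spec.n_voxels,
            n_subjects=config.n_subjects,
            snr=config.snr,
            alpha=config.alpha,
            rng=rng,
            condition_set=cs,
            roi_id=spec.roi_id,
        )
        for p in roi_pats:
            patterns[(p.subject_id, spec.roi_id)] = p
        truth[spec.roi_id] = spec.planted
    return SyntheticStudy(
        config=config, condition_set=cs, rois=tuple(rois),
        patterns=patterns, truth=truth,
    )


# ---------------------------------------------------------------------------
# NIfTI export / reload


def _block_dims(n: int) -> tuple[int, int, int]:
    a = int(np.ceil(n ** (1 / 3)))
    b = int(np.ceil(np.sqrt(n / a)))
    c = int(np.ceil(n / (a * b)))
    return a, b, c


def _layout(rois: Sequence[ROISpec]) -> tuple[VoxelGrid, dict[str, ROIMask]]:
    """Pack each region as a cuboid block along the x axis of one grid."""
    blocks = {}
    x_off = 1
    max_b = max_c = 1
    dims = {}
    for spec in rois:
        a, b, c = _block_dims(spec.n_voxels)
        dims[spec.roi_id] = (a, b, c)
        max_b, max_c = max(max_b, b), max(max_c, c)
        blocks[spec.roi_id] = x_off
        x_off += a + 2
    shape = (x_off + 1, max_b + 2, max_c + 2)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = (-30.0, -40.0, -20.0)
    grid = VoxelGrid(shape=shape, affine=affine)
    masks = {}
    for spec in rois:
        a, b, c = dims[spec.roi_id]
        x0 = blocks[spec.roi_id]
        idx = np.argwhere(np.ones((a, b, c), bool))[: spec.n_voxels]
        idx = idx + np.array([x0, 1, 1])
        masks[spec.roi_id] = ROIMask(
            grid=grid, voxels=idx, roi_id=spec.roi_id,
            hemisphere=spec.roi_id.split("_", 1)[0],
        )
    return grid, masks


def export_nifti_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write the study as NIfTI volumes: one mask per region and one image
    per subject × condition (sub-<id>/cond-<label>.nii.gz), plus a truth
    manifest JSON. Returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    grid, masks = _layout(study.rois)
    for roi_id, mask in masks.items():
        write_mask(mask, outdir / "masks" / f"{roi_id}.nii.gz")
    labels = study.condition_set.labels
    for subject in study.subject_ids:
        sub_dir = outdir / f"sub-{subject}"
        sub_dir.mkdir(exist_ok=True)
        vols = {
            lab: np.zeros(grid.shape, dtype=np.float32) for lab in labels
        }
        for spec in study.rois:
            p = study.patterns[(subject, spec.roi_id)]
            vox = tuple(masks[spec.roi_id].voxels.T)
            for k, lab in enumerate(labels):
                vols[lab][vox] = p.values[:, k].astype(np.float32)
        import nibabel as nib

        for lab, arr in vols.items():
            nib.save(
                nib.Nifti1Image(arr, affine=grid.affine),
                str(sub_dir / f"cond-{lab}.nii.gz"),
            )
    manifest = {
        "config": study.config.to_dict(),
        "conditions": list(labels),
        "subjects": study.subject_ids,
        "rois": [[r.roi_id, r.n_voxels, r.planted] for r in study.rois],
        "truth": study.truth,
    }
    manifest_path = outdir / "study_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def load_nifti_study(
    outdir: str | Path,
) -> tuple[dict[tuple[str, str], PatternMatrix], dict[str, str]]:
    """Re-extract all patterns from an exported study; returns (patterns,
    truth). Used to verify the export round-trip and to run the pipeline
    from volumes."""
    from .volumes import read_mask

    outdir = Path(outdir)
    manifest = json.loads((outdir / "study_manifest.json").read_text())
    labels = manifest["conditions"]
    patterns: dict[tuple[str, str], PatternMatrix] = {}
    masks = {
        roi_id: read_mask(outdir / "masks" / f"{roi_id}.nii.gz", roi_id=roi_id)
        for roi_id, _, _ in manifest["rois"]
    }
    for subject in manifest["subjects"]:
        sub_dir = outdir / f"sub-{subject}"
        images = {lab: sub_dir / f"cond-{lab}.nii.gz" for lab in labels}
        for roi_id, mask in masks.items():
            patterns[(subject, roi_id)] = extract_patterns(
                images, mask, subject_id=subject, condition_order=labels
            )
    return patterns, dict(manifest["truth"])
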