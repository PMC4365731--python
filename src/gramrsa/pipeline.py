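"""Config-driven orchestration of the full RSA analysis.

Stages: load or simulate patterns → per-subject activation RDMs (degenerate
patterns dropped with a logged reason) → subject-averaged RDM per region →
model fits with permutation inference and per-family FDR → subject-level
model comparisons → MDS embedding of region–model distances. Everything is
deterministic given the config seed; a JSON manifest records the config
hash, seeds, package versions and any dropped data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .design import CORE_MODELS, ModelRDM, build_condition_set, build_model
from .inference import compare_models, fit_models
from .mds import classical_mds, embedding_residuals, model_region_distances
from .patterns import (
    RDM,
    DegeneratePatternError,
    PatternMatrix,
    activation_rdm,
    average_rdms,
    read_pattern_manifest,
    write_rdm_tsv,
)
from .synth import StudyConfig, load_nifti_study, simulate_study

logger = logging.getLogger("gramrsa")

__all__ = ["PipelineError", "RunConfig", "RSAResult", "run_rsa",
           "subject_and_average_rdms"]

DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("complexity_type", "general_complexity"),
    ("detector_phrase", "detector_inflected"),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    seed: int
    synthetic: StudyConfig | None = None
    pattern_manifest: str | Path | None = None
    nifti_dir: str | Path | None = None
    models: tuple[str, ...] = CORE_MODELS
    method: str = "pearson"
    n_perm: int = 10_000
    fdr: str = "storey"
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.synthetic, self.pattern_manifest, self.nifti_dir)
            if s is not None
        ]
        if len(sources) != 1:
            raise PipelineError(
                "config: exactly one input source required "
                "(synthetic | pattern_manifest | nifti_dir)"
            )
        if not self.models:
            raise PipelineError("config: model list must be non-empty")
        self.models = tuple(self.models)
        self.comparisons = tuple(tuple(pair) for pair in self.comparisons)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "synthetic": None
            if self.synthetic is None
            else self.synthetic.to_dict(),
            "pattern_manifest": None
            if self.pattern_manifest is None
            else str(self.pattern_manifest),
            "nifti_dir": None if self.nifti_dir is None else str(self.nifti_dir),
            "models": list(self.models),
            "method": self.method,
            "n_perm": self.n_perm,
            "fdr": self.fdr,
            "comparisons": [list(p) for p in self.comparisons],
        }


@dataclass
class RSAResult:
    fits: pd.DataFrame
    comparisons: pd.DataFrame
    mds_coords: pd.DataFrame
    mds_residuals: pd.DataFrame
    region_rdms: dict[str, RDM]
    subject_rdms: dict[str, list[RDM]]
    manifest: dict


def subject_and_average_rdms(
    patterns: Mapping[tuple[str, str], PatternMatrix],
) -> tuple[dict[str, list[RDM]], dict[str, RDM], list[dict]]:
    """Per-subject RDMs and the subject-averaged RDM for every region.

    Degenerate (zero-variance) patterns are dropped with a logged reason;
    the returned drop log lists them.
    """
    by_region: dict[str, list[RDM]] = {}
    dropped: list[dict] = []
    for (subject_id, roi_id), p in sorted(patterns.items()):
        try:
            rdm = activation_rdm(p)
        except DegeneratePatternError as exc:
            logger.warning(
                "dropping subject %s ROI %s: %s", subject_id, roi_id, exc
            )
            dropped.append(
                {"subject_id": subject_id, "roi_id": roi_id,
                 "reason": str(exc)}
            )
            continue
        by_region.setdefault(roi_id, []).append(rdm)
    if not by_region:
        raise PipelineError("rdm stage: no usable patterns")
    averaged = {roi: average_rdms(rdms) for roi, rdms in by_region.items()}
    return by_region, averaged, dropped


def _load_patterns(
    cfg: RunConfig,
) -> tuple[dict[tuple[str, str], PatternMatrix], dict[str, str] | None]:
    if cfg.synthetic is not None:
        study = simulate_study(cfg.synthetic)
        return study.patterns, study.truth
    if cfg.pattern_manifest is not None:
        return read_pattern_manifest(cfg.pattern_manifest), None
    patterns, truth = load_nifti_study(cfg.nifti_dir)
    return patterns, truth


def run_rsa(cfg: RunConfig) -> RSAResult:
    """Run the full analysis described by ``cfg``; write TSV/JSON outputs
    if ``cfg.outdir`` is set."""
    try:
        patterns, truth = _load_patterns(cfg)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named rewrap
        raise PipelineError(f"input stage: {exc}") from exc

    cs = build_condition_set(
        cfg.synthetic.weights if cfg.synthetic is not None else None
    )
    try:
        subject_rdms, region_rdms, dropped = subject_and_average_rdms(patterns)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"rdm stage: {exc}") from exc

    models = [build_model(name, cs) for name in cfg.models]
    try:
        fits = fit_models(
            region_rdms, models, method=cfg.method, n_perm=cfg.n_perm,
            seed=cfg.seed, fdr=cfg.fdr,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"fit stage: {exc}") from exc

    comp_rows = []
    available = set(cfg.models)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    try:
        for name_a, name_b in cfg.comparisons:
            if name_a not in available or name_b not in available:
                continue
            ma, mb = build_model(name_a, cs), build_model(name_b, cs)
            for region in sorted(subject_rdms):
                res = compare_models(
                    subject_rdms[region], ma, mb, method=cfg.method,
                    n_perm=cfg.n_perm, rng=rng,
                )
                comp_rows.append(
                    {
                        "region": region,
                        "model_a": name_a,
                        "model_b": name_b,
                        "mean_difference": res.mean_difference,
                        "p": res.p_value,
                        "exhaustive": res.exhaustive,
                    }
                )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"comparison stage: {exc}") from exc
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["region", "model_a", "model_b", "mean_difference", "p",
                 "exhaustive"],
    )

    try:
        table = model_region_distances(region_rdms, models, method=cfg.method)
        coords, eigvals = classical_mds(table, dims=2)
        residuals = embedding_residuals(table, coords)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"mds stage: {exc}") from exc

    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "gramrsa_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "dropped": dropped,
        "truth": truth,
        "mds_eigenvalues": [float(v) for v in eigvals],
        "decisions": {
            "general_complexity_stem_cells": "zero",
            "detector_nontarget_cells": "unconstrained",
            "dominance_metric": "absolute_difference",
            "condition_order": "types_major",
            "statistic": cfg.method,
            "sidedness": "one_sided_positive",
            "fdr_family": "per_model_across_regions",
        },
    }

    result = RSAResult(
        fits=fits,
        comparisons=comparisons,
        mds_coords=coords,
        mds_residuals=residuals,
        region_rdms=region_rdms,
        subject_rdms=subject_rdms,
        manifest=manifest,
    )
    if cfg.outdir is not None:
        _write_outputs(result, Path(cfg.outdir))
    return result


def _write_outputs(result: RSAResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.fits.to_csv(
        outdir / "model_fits.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result.comparisons.to_csv(
        outdir / "model_comparisons.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    result.mds_coords.to_csv(
        outdir / "mds_coords.tsv", sep="\t", float_format="%.10g"
    )
    result.mds_residuals.to_csv(
        outdir / "mds_residuals.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    rdm_dir = outdir / "rdms"
    rdm_dir.mkdir(exist_ok=True)
    for roi_id, rdm in sorted(result.region_rdms.items()):
        write_rdm_tsv(rdm, rdm_dir / f"{roi_id}.tsv")
    (outdir / "run_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True)
    )
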