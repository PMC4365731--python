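"""Experimental design and hypothesis model RDMs for grammatical-sequence RSA.

The design crosses three types of spoken sequence — bare stems (e.g. *sing*),
inflected forms (*sings*) and minimal phrases (*I sing*, *a rug*) — with four
stem categories graded by verb/noun dominance (verb-unique, verb-dominant,
noun-dominant, noun-unique), yielding 12 conditions. Dominance is the
corpus-derived verb/(verb+noun) frequency ratio of a stem set, on a 0–1 scale.

Representational hypotheses are expressed as 12 × 12 model RDMs over those
conditions. A model may be agnostic about some condition pairs; such cells are
*unconstrained* (masked out) and excluded from every downstream correlation.
Condition ordering is fixed — sequence types major (stem, inflected, phrase),
categories in the order verb_unique, verb_dominant, noun_dominant, noun_unique
— so RDM cell indices are reproducible across runs and files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEQUENCE_TYPES",
    "CATEGORIES",
    "DEFAULT_DOMINANCE_WEIGHTS",
    "STEMS_PER_CATEGORY",
    "ConditionSet",
    "ModelRDM",
    "build_condition_set",
    "general_complexity_model",
    "complexity_type_model",
    "detector_model",
    "dominance_modulated_detector",
    "MODEL_BUILDERS",
    "build_model",
    "write_model_tsv",
    "read_model_tsv",
    "stimulus_manifest",
    "design_summary",
]

SEQUENCE_TYPES: tuple[str, ...] = ("stem", "inflected", "phrase")
CATEGORIES: tuple[str, ...] = (
    "verb_unique",
    "verb_dominant",
    "noun_dominant",
    "noun_unique",
)

#: Mean verb/noun dominance ratio of each stem category (dimensionless, 0–1).
DEFAULT_DOMINANCE_WEIGHTS: dict[str, float] = {
    "verb_unique": 1.0,
    "verb_dominant": 0.84,
    "noun_dominant": 0.06,
    "noun_unique": 0.0,
}

#: Stimulus-design constants: 40 matched stems per dominance category, each
#: presented as stem, inflected form and phrase; MuR = musical-rain acoustic
#: baseline matched to speech envelopes.
STEMS_PER_CATEGORY = 40
FORMS_PER_STEM = len(SEQUENCE_TYPES)
N_BASELINE_TRIALS = 240
N_SILENCE_TRIALS = 240

COMPLEX_TYPES: tuple[str, ...] = ("inflected", "phrase")

_MASK_TOL = 1e-12


class DesignError(ValueError):
    """Invalid condition set or model specification."""


def condition_label(sequence_type: str, category: str) -> str:
    return f"{sequence_type}.{category}"


@dataclass(frozen=True)
class ConditionSet:
    """The ordered 12-condition design with per-category dominance weights."""

    conditions: tuple[tuple[str, str], ...]
    weights: Mapping[str, float]

    @property
    def n(self) -> int:
        return len(self.conditions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(condition_label(t, c) for t, c in self.conditions)

    def index(self, sequence_type: str, category: str) -> int:
        try:
            return self.conditions.index((sequence_type, category))
        except ValueError:
            raise DesignError(
                f"unknown condition ({sequence_type!r}, {category!r})"
            ) from None

    def weight_vector(self) -> np.ndarray:
        """Dominance weight of each condition, in condition order."""
        return np.array([self.weights[c] for _, c in self.conditions], float)

    def sequence_vector(self) -> np.ndarray:
        """Sequence-type index (0=stem, 1=inflected, 2=phrase) per condition."""
        return np.array(
            [SEQUENCE_TYPES.index(t) for t, _ in self.conditions], int
        )


def build_condition_set(
    weights: Mapping[str, float] | None = None,
) -> ConditionSet:
    """Construct the canonical 12-condition ordered set.

    Parameters
    ----------
    weights
        Optional category → dominance weight map; must cover all four
        categories with values in [0, 1]. Defaults to the study's CELEX-derived
        means (1.0, 0.84, 0.06, 0.0).
    """
    if weights is None:
        weights = dict(DEFAULT_DOMINANCE_WEIGHTS)
    else:
        weights = dict(weights)
    missing = [c for c in CATEGORIES if c not in weights]
    if missing:
        raise DesignError(f"weights missing categories: {missing}")
    for cat, w in weights.items():
        if cat not in CATEGORIES:
            raise DesignError(f"unknown category {cat!r}")
        if not np.isfinite(w) or not (0.0 <= float(w) <= 1.0):
            raise DesignError(f"weight for {cat!r} must lie in [0, 1], got {w}")
    conditions = tuple(
        (t, c) for t in SEQUENCE_TYPES for c in CATEGORIES
    )
    return ConditionSet(conditions=conditions, weights=weights)


@dataclass
class ModelRDM:
    """A hypothesis RDM: dissimilarities on constrained cells, NaN elsewhere.

    ``mask`` marks constrained cells; the diagonal is always unconstrained.
    Constrained values lie in [0, 1] and at least two distinct values must be
    present (rank correlation is undefined against a constant).
    """

    name: str
    dissim: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.dissim = np.asarray(self.dissim, float)
        self.mask = np.asarray(self.mask, bool)
        n = self.dissim.shape[0]
        if self.dissim.shape != (n, n) or self.mask.shape != (n, n):
            raise DesignError("model matrices must be square and congruent")
        if np.any(np.diag(self.mask)):
            raise DesignError("model diagonal must be unconstrained")
        if not np.array_equal(self.mask, self.mask.T):
            raise DesignError("model mask must be symmetric")
        vals = self.dissim[self.mask]
        if vals.size == 0:
            raise DesignError(f"model {self.name!r} constrains no cells")
        if not np.all(np.isfinite(vals)):
            raise DesignError(f"model {self.name!r} has non-finite cells")
        if vals.min() < -_MASK_TOL or vals.max() > 1 + _MASK_TOL:
            raise DesignError(f"model {self.name!r} values must lie in [0, 1]")
        sym = np.where(self.mask, self.dissim, 0.0)
        if not np.allclose(sym, sym.T, atol=1e-12):
            raise DesignError(f"model {self.name!r} is not symmetric")
        if np.unique(np.round(vals, 12)).size < 2:
            raise DesignError(
                f"model {self.name!r} needs >= 2 distinct constrained values"
            )
        # unconstrained cells carry no value
        self.dissim = np.where(self.mask, self.dissim, np.nan)

    @property
    def n_conditions(self) -> int:
        return self.dissim.shape[0]

    def constrained_upper_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of constrained cells in the strict upper triangle."""
        iu, ju = np.triu_indices(self.n_conditions, k=1)
        keep = self.mask[iu, ju]
        return iu[keep], ju[keep]

    def constrained_vector(self) -> np.ndarray:
        i, j = self.constrained_upper_indices()
        return self.dissim[i, j]


def _blank(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.full((n, n), np.nan), np.zeros((n, n), bool)


def general_complexity_model(
    cs: ConditionSet, stem_cells: str = "zero"
) -> ModelRDM:
    """Two-class model: any grammatically complex item (inflected or phrase)
    patterns like every other complex item and unlike simple stems.

    ``stem_cells='zero'`` (default) constrains stem–stem pairs to 0;
    ``'unconstrained'`` leaves them out of the correlation.
    """
    if stem_cells not in ("zero", "unconstrained"):
        raise DesignError(f"stem_cells must be 'zero' or 'unconstrained'")
    n = cs.n
    dissim, mask = _blank(n)
    complex_flag = np.array([t in COMPLEX_TYPES for t, _ in cs.conditions])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if complex_flag[i] and complex_flag[j]:
                dissim[i, j], mask[i, j] = 0.0, True
            elif not complex_flag[i] and not complex_flag[j]:
                if stem_cells == "zero":
                    dissim[i, j], mask[i, j] = 0.0, True
            else:
                dissim[i, j], mask[i, j] = 1.0, True
    return ModelRDM("general_complexity", dissim, mask)


def complexity_type_model(cs: ConditionSet) -> ModelRDM:
    """Three-class model: each sequence type yields its own pattern family —
    similar within type, dissimilar between types."""
    n = cs.n
    seq = cs.sequence_vector()
    dissim = (seq[:, None] != seq[None, :]).astype(float)
    mask = ~np.eye(n, dtype=bool)
    dissim[~mask] = np.nan
    return ModelRDM("complexity_type", dissim, mask)


def detector_model(
    cs: ConditionSet,
    target: str,
    nontarget_value: float | None = None,
) -> ModelRDM:
    """Detector for one sequence type: target conditions pattern alike
    (dissim 0) and unlike everything else (dissim 1), all four dominance
    categories weighted equally.

    Non-target–non-target cells are unconstrained by default (the detector is
    agnostic to structure among non-target conditions); pass
    ``nontarget_value`` (e.g. 0.5) to constrain them instead.
    """
    if target not in SEQUENCE_TYPES:
        raise DesignError(f"target must be one of {SEQUENCE_TYPES}")
    n = cs.n
    is_target = np.array([t == target for t, _ in cs.conditions])
    dissim, mask = _blank(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if is_target[i] and is_target[j]:
                dissim[i, j], mask[i, j] = 0.0, True
            elif is_target[i] != is_target[j]:
                dissim[i, j], mask[i, j] = 1.0, True
            elif nontarget_value is not None:
                dissim[i, j], mask[i, j] = float(nontarget_value), True
    return ModelRDM(f"detector_{target}", dissim, mask)


def dominance_modulated_detector(
    cs: ConditionSet,
    target: str,
    nontarget_value: float | None = None,
) -> ModelRDM:
    """Detector weighted by verb/noun dominance within the target type.

    Within-target dissimilarity is |w_i − w_j| of the category dominance
    weights, grouping the verb sets (1.0, 0.84) apart from the noun sets
    (0.06, 0.0); target–non-target stays 1; non-target–non-target is
    unconstrained unless ``nontarget_value`` is given.
    """
    if target not in SEQUENCE_TYPES:
        raise DesignError(f"target must be one of {SEQUENCE_TYPES}")
    n = cs.n
    w = cs.weight_vector()
    is_target = np.array([t == target for t, _ in cs.conditions])
    dissim, mask = _blank(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if is_target[i] and is_target[j]:
                dissim[i, j], mask[i, j] = abs(w[i] - w[j]), True
            elif is_target[i] != is_target[j]:
                dissim[i, j], mask[i, j] = 1.0, True
            elif nontarget_value is not None:
                dissim[i, j], mask[i, j] = float(nontarget_value), True
    return ModelRDM(f"dominance_{target}", dissim, mask)


#: Registry of the standard model families by canonical name.
MODEL_BUILDERS: dict[str, Callable[[ConditionSet], ModelRDM]] = {
    "general_complexity": general_complexity_model,
    "complexity_type": complexity_type_model,
    "detector_stem": lambda cs: detector_model(cs, "stem"),
    "detector_inflected": lambda cs: detector_model(cs, "inflected"),
    "detector_phrase": lambda cs: detector_model(cs, "phrase"),
    "dominance_stem": lambda cs: dominance_modulated_detector(cs, "stem"),
    "dominance_inflected": lambda cs: dominance_modulated_detector(
        cs, "inflected"
    ),
    "dominance_phrase": lambda cs: dominance_modulated_detector(cs, "phrase"),
}

#: The five core hypothesis families used for recovery and comparison.
CORE_MODELS: tuple[str, ...] = (
    "general_complexity",
    "complexity_type",
    "detector_stem",
    "detector_inflected",
    "detector_phrase",
)


def build_model(name: str, cs: ConditionSet) -> ModelRDM:
    try:
        return MODEL_BUILDERS[name](cs)
    except KeyError:
        raise DesignError(
            f"unknown model {name!r}; known: {sorted(MODEL_BUILDERS)}"
        ) from None


def write_model_tsv(model: ModelRDM, cs: ConditionSet, path: str | Path) -> None:
    """Write a model RDM as TSV: one header line naming the model and the
    condition order, then the matrix with 'NA' in unconstrained cells."""
    path = Path(path)
    lines = [f"# model: {model.name}\tconditions: {','.join(cs.labels)}"]
    for row_d, row_m in zip(model.dissim, model.mask):
        cells = [
            format(v, ".10g") if m else "NA" for v, m in zip(row_d, row_m)
        ]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_model_tsv(path: str | Path) -> tuple[ModelRDM, tuple[str, ...]]:
    """Read a model RDM TSV written by :func:`write_model_tsv`.

    Returns the model and the condition labels from the header.
    """
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    header = lines[0]
    if not header.startswith("# model:"):
        raise DesignError(f"{path}: missing model header line")
    name_part, cond_part = header[1:].split("\t")
    name = name_part.split(":", 1)[1].strip()
    labels = tuple(cond_part.split(":", 1)[1].strip().split(","))
    rows = []
    for line in lines[1:]:
        rows.append(
            [np.nan if c == "NA" else float(c) for c in line.split("\t")]
        )
    dissim = np.array(rows, float)
    mask = np.isfinite(dissim)
    return ModelRDM(name, dissim, mask), labels


def stimulus_manifest(cs: ConditionSet | None = None) -> pd.DataFrame:
    """Tabulate the test-item roster: 40 stems per dominance category, each
    realised as a bare stem, an inflected form and a short phrase (480 rows).

    Stem identifiers are placeholders (the matched word lists are not part of
    this package); counts and structure mirror the design.
    """
    if cs is None:
        cs = build_condition_set()
    rows = []
    for cat in CATEGORIES:
        for k in range(1, STEMS_PER_CATEGORY + 1):
            stem_id = f"{cat}_{k:02d}"
            for t in SEQUENCE_TYPES:
                rows.append(
                    {
                        "stem_id": stem_id,
                        "category": cat,
                        "sequence_type": t,
                        "condition": condition_label(t, cat),
                        "dominance_weight": cs.weights[cat],
                    }
                )
    return pd.DataFrame(rows)


def design_summary(cs: ConditionSet | None = None) -> dict[str, float]:
    """Design bookkeeping counts, computed from the condition set and the
    stimulus manifest (not hard-wired into the summary itself)."""
    if cs is None:
        cs = build_condition_set()
    man = stimulus_manifest(cs)
    per_cat = man.groupby("category")["stem_id"].nunique()
    summary: dict[str, float] = {
        "n_conditions": float(cs.n),
        "n_sequence_types": float(len(SEQUENCE_TYPES)),
        "n_categories": float(len(CATEGORIES)),
        "n_stems": float(man["stem_id"].nunique()),
        "stems_per_category": float(per_cat.iloc[0]),
        "n_test_items": float(len(man)),
        "n_baseline_trials": float(N_BASELINE_TRIALS),
        "n_silence_trials": float(N_SILENCE_TRIALS),
        "n_total_trials": float(
            len(man) + N_BASELINE_TRIALS + N_SILENCE_TRIALS
        ),
    }
    for cat in CATEGORIES:
        summary[f"weight_{cat}"] = float(cs.weights[cat])
    return summary
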