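"""Second-order inference: RDM–model correlation, permutation tests, model
comparison and FDR across regions.

The correspondence between a data RDM and a hypothesis model is a
correlation over the vectorised upper triangle restricted to the model's
constrained cells. Pearson is the default — the second-order analogue of the
first-order correlation distance, and the only offered statistic whose
best-model comparison is not distorted by the heavy ties in categorical
model RDMs (a binary model's Spearman against continuous data is capped by
the group sizes, not by fit quality). Spearman and Kendall tau-a are offered
for rank-based analyses. Significance comes from a condition-label
permutation test: the same random permutation is applied to rows and columns
of the data RDM and the statistic recomputed, with the one-sided add-one
Monte-Carlo p-value (1 + #{null >= observed}) / (n_perm + 1), which is always
positive and valid.

Competing models are compared at the subject level: per-subject statistic
differences are tested with a two-sided sign-flip permutation, exhaustive
over all 2^S flips when the subject count allows. Across the regions tested
for one model family, false discovery is controlled with Storey q-values
(lambda-grid pi0 estimator), with Benjamini–Hochberg available as a simpler
alternative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .design import ModelRDM
from .patterns import RDM

__all__ = [
    "InferenceError",
    "PermutationResult",
    "ModelComparison",
    "rdm_correlation",
    "permutation_test",
    "compare_models",
    "storey_qvalues",
    "bh_fdr",
    "fit_models",
]

METHODS = ("spearman", "kendall_tau_a", "pearson")

_TIE_EPS = 1e-12


class InferenceError(ValueError):
    """Invalid input to a second-order inference routine."""


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of each row of X with y.

    Rows with zero variance get statistic 0 (no association is the only
    defensible value for a flat permuted-data vector).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    ssy = float(yc @ yc)
    ssx = np.einsum("ij,ij->i", Xc, Xc)
    num = Xc @ yc
    den = np.sqrt(ssx * ssy)
    out = np.zeros(X.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def _tau_a_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Kendall tau-a of each row of X with y.

    tau_a = (concordant − discordant) / (m(m−1)/2); tied pairs count 0,
    which is the appropriate normalisation when the model vector has ties.
    """
    m = y.size
    sy = np.sign(y[None, :] - y[:, None])
    sx = np.sign(X[:, None, :] - X[:, :, None])
    n_pairs = m * (m - 1) / 2.0
    return np.einsum("ijk,jk->i", sx, sy) / (2.0 * n_pairs)


def _corr_rows(X: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        return _pearson_rows(rankdata(X, axis=1), rankdata(y))
    if method == "pearson":
        return _pearson_rows(X, y)
    if method == "kendall_tau_a":
        return _tau_a_rows(X, y)
    raise InferenceError(f"unknown method {method!r}; choose from {METHODS}")


def _model_cells(
    data: RDM, model: ModelRDM
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if data.n_conditions != model.n_conditions:
        raise InferenceError(
            f"data RDM has {data.n_conditions} conditions, "
            f"model {model.name!r} has {model.n_conditions}"
        )
    i, j = model.constrained_upper_indices()
    if i.size < 3:
        raise InferenceError(
            f"model {model.name!r} constrains only {i.size} upper-triangle "
            "cells; >= 3 required"
        )
    y = model.dissim[i, j]
    if np.ptp(y) < _TIE_EPS:
        raise InferenceError(
            f"model {model.name!r} is constant on its constrained cells"
        )
    return i, j, y


def rdm_correlation(
    data: RDM, model: ModelRDM, method: str = "pearson"
) -> float:
    """Second-order correlation between a data RDM and a model RDM over the
    model's constrained upper-triangle cells."""
    i, j, y = _model_cells(data, model)
    x = data.dissim[i, j]
    return float(_corr_rows(x[None, :], y, method)[0])


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    null: np.ndarray
    n_perm: int
    seed: int | None


def permutation_test(
    data: RDM,
    model: ModelRDM,
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Condition-label permutation test of model–data correspondence.

    Each permutation relabels the data RDM (same permutation applied to rows
    and columns) and recomputes the statistic on the model's constrained
    cells; p is one-sided for positive correspondence.
    """
    if n_perm < 100:
        raise InferenceError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    i, j, y = _model_cells(data, model)
    observed = float(_corr_rows(data.dissim[i, j][None, :], y, method)[0])
    n = data.n_conditions
    perms = np.empty((n_perm, n), dtype=np.intp)
    for k in range(n_perm):
        perms[k] = rng.permutation(n)
    cells = data.dissim[perms[:, i], perms[:, j]]
    null = _corr_rows(cells, y, method)
    p = (1.0 + np.count_nonzero(null >= observed - _TIE_EPS)) / (n_perm + 1.0)
    return PermutationResult(
        statistic=observed, p_value=float(p), null=null,
        n_perm=n_perm, seed=seed,
    )


@dataclass(frozen=True)
class ModelComparison:
    model_a: str
    model_b: str
    mean_difference: float
    p_value: float
    per_subject: np.ndarray
    exhaustive: bool


def compare_models(
    subject_rdms: Sequence[RDM],
    model_a: ModelRDM,
    model_b: ModelRDM,
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ModelComparison:
    """Subject-level sign-flip test of which model fits better.

    Each subject's RDM is correlated with each model on that model's own
    constrained cells; the per-subject differences d_s = stat_A − stat_B are
    tested two-sidedly by flipping signs — all 2^S flips when S <= 12, else
    ``n_perm`` Monte-Carlo flips.
    """
    S = len(subject_rdms)
    if S < 2:
        raise InferenceError("model comparison needs >= 2 subjects")
    stats_a = np.array(
        [rdm_correlation(r, model_a, method) for r in subject_rdms]
    )
    stats_b = np.array(
        [rdm_correlation(r, model_b, method) for r in subject_rdms]
    )
    d = stats_a - stats_b
    obs = float(d.mean())
    if S <= 12:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=S)))
        means = signs @ d / S
        p = float(np.mean(np.abs(means) >= abs(obs) - _TIE_EPS))
        exhaustive = True
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        flips = rng.choice((1.0, -1.0), size=(n_perm, S))
        means = flips @ d / S
        hits = np.count_nonzero(np.abs(means) >= abs(obs) - _TIE_EPS)
        p = (1.0 + hits) / (n_perm + 1.0)
        exhaustive = False
    return ModelComparison(
        model_a=model_a.name,
        model_b=model_b.name,
        mean_difference=obs,
        p_value=p,
        per_subject=d,
        exhaustive=exhaustive,
    )


def storey_qvalues(
    pvalues: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values with lambda-grid pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 − lambda)) is evaluated on the grid
    and summarised by its median (robust for the small families this
    pipeline corrects — tens of regions — where spline/polynomial smoothers
    are unstable), clamped into (0, 1].  q_i = min over thresholds t >= p_i
    of pi0 · m · t / #{p <= t}, which is monotone in p.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise InferenceError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InferenceError("p-values must lie in (0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.95, 0.05)
    lam = np.asarray(lambda_grid, float)
    if np.any(lam < 0) or np.any(lam >= 1):
        raise InferenceError("lambda grid must lie in [0, 1)")
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    pi0_hat = float(np.median(pi0_lam))
    pi0 = float(np.clip(pi0_hat, 1.0 / m, 1.0))

    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * ps / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def bh_fdr(pvalues: Sequence[float], alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up: indices of rejected hypotheses."""
    p = np.asarray(pvalues, float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InferenceError("p-values must lie in (0, 1]")
    if not (0 < alpha < 1):
        raise InferenceError("alpha must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return np.flatnonzero(reject)


def _hemisphere(region_id: str) -> str:
    head = region_id.split("_", 1)[0]
    return head if head in ("L", "R") else ""


def fit_models(
    region_rdms: Mapping[str, RDM],
    models: Sequence[ModelRDM],
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: int | None = None,
    fdr: str = "storey",
) -> pd.DataFrame:
    """Fit each model to each region's averaged RDM with permutation inference
    and per-model-family FDR across regions.

    Returns a tidy frame (region, hemisphere, model, statistic, p, q, pi0,
    n_perm, seed). q-values are computed within each model family across the
    regions tested, mirroring correction "for the number of regions tested in
    each model".
    """
    if fdr not in ("storey", "bh"):
        raise InferenceError("fdr must be 'storey' or 'bh'")
    regions = sorted(region_rdms)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(len(models))
    rows = []
    for model, child in zip(models, children):
        rng = np.random.default_rng(child)
        pvals = []
        stats = []
        for region in regions:
            res = permutation_test(
                region_rdms[region], model, method=method,
                n_perm=n_perm, rng=rng,
            )
            stats.append(res.statistic)
            pvals.append(res.p_value)
        if fdr == "storey":
            q, pi0 = storey_qvalues(pvals)
        else:
            _, q, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
            pi0 = 1.0
        for region, s, pv, qv in zip(regions, stats, pvals, q):
            rows.append(
                {
                    "region": region,
                    "hemisphere": _hemisphere(region),
                    "model": model.name,
                    "statistic": s,
                    "p": pv,
                    "q": float(qv),
                    "pi0": pi0,
                    "n_perm": n_perm,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
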