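"""Calibration and recovery studies run on the synthetic generator.

These are the package's own validation experiments: type-I error of the
permutation test under pure noise, planted-model recovery on the default
study, model discrimination at the subject level, and false-discovery
calibration of the Storey q-value procedure. They are used both by the test
suite and by the reproduction script, with problem sizes chosen per study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import CORE_MODELS, build_condition_set, build_model
from .inference import compare_models, rdm_correlation, permutation_test, storey_qvalues
from .patterns import activation_rdm
from .pipeline import RunConfig, run_rsa
from .synth import StudyConfig, simulate_roi_patterns

__all__ = [
    "type_one_error_rate",
    "recovery_study",
    "discrimination_study",
    "fdr_calibration",
]


def type_one_error_rate(
    n_sims: int = 1_000,
    n_voxels: int = 100,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "pearson",
    model_name: str = "complexity_type",
) -> dict:
    """Rejection rate of the permutation test on pure-noise patterns.

    Each simulation draws an unstructured voxel × 12-condition pattern
    (SNR 0), builds its activation RDM and tests it against the named model.
    Under the null the p-values are valid, so the rate should sit at alpha
    up to binomial noise.
    """
    cs = build_condition_set()
    model = build_model(model_name, cs)
    rng = np.random.default_rng(seed)
    rejections = 0
    pvals = np.empty(n_sims)
    for k in range(n_sims):
        (p,) = simulate_roi_patterns(
            "noise", n_voxels=n_voxels, n_subjects=1, snr=0.0,
            rng=rng, condition_set=cs,
        )
        res = permutation_test(
            activation_rdm(p), model, method=method, n_perm=n_perm, rng=rng
        )
        pvals[k] = res.p_value
        rejections += res.p_value <= alpha
    return {
        "rate": rejections / n_sims,
        "n_sims": n_sims,
        "alpha": alpha,
        "p_values": pvals,
    }


def binomial_band(n: int, p: float, level: float = 0.99) -> tuple[float, float]:
    """Exact central binomial interval for a rate estimated from n trials."""
    lo_k = stats.binom.ppf((1 - level) / 2, n, p)
    hi_k = stats.binom.ppf(1 - (1 - level) / 2, n, p)
    return lo_k / n, hi_k / n


def recovery_study(
    seed: int = 0,
    n_perm: int = 1_000,
    snr: float = 5.0,
    n_subjects: int = 18,
    q_threshold: float = 0.05,
    method: str = "pearson",
) -> dict:
    """Full-pipeline recovery on the default synthetic study.

    A planted region counts as recovered when its true model has the highest
    statistic of the five core families and reaches q < ``q_threshold``.
    Specificity is the fraction of (noise region × model family) tests that
    stay non-significant at the same q threshold — the unit the per-family
    FDR procedure controls.
    """
    cfg = RunConfig(
        seed=seed,
        synthetic=StudyConfig(seed=seed, snr=snr, n_subjects=n_subjects),
        models=CORE_MODELS,
        method=method,
        n_perm=n_perm,
    )
    result = run_rsa(cfg)
    fits = result.fits
    truth = result.manifest["truth"]
    planted = {r: m for r, m in truth.items() if m != "noise"}
    noise_rois = [r for r, m in truth.items() if m == "noise"]

    recovered = 0
    best_rows = []
    for region, true_model in planted.items():
        sub = fits[fits["region"] == region]
        best = sub.loc[sub["statistic"].idxmax()]
        true_row = sub[sub["model"] == true_model].iloc[0]
        ok = best["model"] == true_model and true_row["q"] < q_threshold
        recovered += ok
        best_rows.append(
            {"region": region, "true": true_model, "best": best["model"],
             "q_true": float(true_row["q"]), "recovered": bool(ok)}
        )
    noise_tests = fits[fits["region"].isin(noise_rois)]
    n_noise_tests = len(noise_tests)
    n_flagged = int((noise_tests["q"] < q_threshold).sum())
    return {
        "recovery_rate": recovered / max(len(planted), 1),
        "n_planted": len(planted),
        "noise_nonsignificant_rate": 1.0 - n_flagged / max(n_noise_tests, 1),
        "n_noise_tests": n_noise_tests,
        "detail": best_rows,
        "fits": fits,
        "result": result,
    }


def discrimination_study(
    n_runs: int = 100,
    n_subjects: int = 8,
    n_voxels: int = 100,
    snr: float = 5.0,
    alpha: float = 0.7,
    seed: int = 0,
    method: str = "pearson",
) -> dict:
    """How often the complexity-type model beats the general-complexity model
    in regions planted with the complexity-type geometry.

    A success is a run where the subject-level sign-flip comparison gives a
    positive mean difference and p < 0.05.
    """
    cs = build_condition_set()
    planted = build_model("complexity_type", cs)
    general = build_model("general_complexity", cs)
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_runs):
        pats = simulate_roi_patterns(
            planted, n_voxels=n_voxels, n_subjects=n_subjects,
            snr=snr, alpha=alpha, rng=rng, condition_set=cs,
        )
        subject_rdms = [activation_rdm(p) for p in pats]
        res = compare_models(subject_rdms, planted, general, method=method)
        wins += (res.mean_difference > 0) and (res.p_value < 0.05)
    return {"win_rate": wins / n_runs, "n_runs": n_runs}


def fdr_calibration(
    n_reps: int = 200,
    m: int = 1_000,
    pi0: float = 0.8,
    effect: float = 3.0,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> dict:
    """Realised FDR of Storey q-values on simulated p-value mixtures.

    Nulls are uniform; alternatives are one-sided normal p-values with mean
    shift ``effect``. Returns the mean realised FDR at q <= ``q_threshold``
    and the mean pi0 estimate across repetitions.
    """
    rng = np.random.default_rng(seed)
    n_null = int(round(m * pi0))
    n_alt = m - n_null
    fdrs = np.empty(n_reps)
    pi0_hats = np.empty(n_reps)
    for k in range(n_reps):
        p_null = rng.uniform(size=n_null)
        p_alt = stats.norm.sf(rng.normal(loc=effect, scale=1.0, size=n_alt))
        p = np.clip(np.concatenate([p_null, p_alt]), 1e-300, 1.0)
        is_null = np.zeros(m, bool)
        is_null[:n_null] = True
        q, pi0_hat = storey_qvalues(p)
        discovered = q <= q_threshold
        R = int(discovered.sum())
        V = int((discovered & is_null).sum())
        fdrs[k] = V / max(R, 1)
        pi0_hats[k] = pi0_hat
    return {
        "realized_fdr": float(fdrs.mean()),
        "pi0_estimate": float(pi0_hats.mean()),
        "pi0_true": pi0,
        "n_reps": n_reps,
    }
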