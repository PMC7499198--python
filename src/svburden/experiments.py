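"""Cohort-level validation experiments on synthetic data.

These drive the whole analysis chain — simulate, classify, build the
carrier matrix, fit the burden model — repeatedly over seeded cohorts to
measure the operating characteristics a user cares about: the type-I error
of the per-key chi-square screen and the recovery of a planted carrier
odds ratio.  Problem sizes follow the preset scenarios in
:mod:`svburden.simulate`.
"""

from __future__ import annotations

import numpy as np

from .classify import classify_all
from .genome import GenomeIndex, load_annotation
from .model import SVBurdenModel, SVBurdenResults
from .simulate import (SimulationConfig, null_scenario, recovery_scenario,
                       simulate_cohort)

__all__ = ["fit_cohort", "type_i_error", "effect_recovery"]


def fit_cohort(config: SimulationConfig, **model_kwargs) -> SVBurdenResults:
    """Simulate one cohort and run it through the full association chain."""
    study = simulate_cohort(config)
    index = GenomeIndex(load_annotation(study.annotation.splitlines()))
    assignments = classify_all(study.records, index)
    model = SVBurdenModel.from_assignments(assignments, study.manifest,
                                           **model_kwargs)
    return model.fit()


def _subseed(seed: int, i: int) -> int:
    return (seed * 1009 + i) % (2 ** 31 - 1)


def type_i_error(seed: int = 0, n_cohorts: int = 10, n_genes: int = 200,
                 carrier_freq: float = 0.05, alpha: float = 0.05) -> dict:
    """Empirical false-positive rate of the chi-square screen under the null.

    Pools the per-key raw chi-square p-values of ``n_cohorts`` seeded
    no-effect cohorts (every gene at the same carrier frequency in cases
    and controls) and reports the fraction below ``alpha``.
    """
    ps: list[float] = []
    for i in range(n_cohorts):
        cfg = null_scenario(seed=_subseed(seed, i), n_genes=n_genes,
                            carrier_freq=carrier_freq)
        res = fit_cohort(cfg)
        ps.extend(res.frame("AA")["chi2_p"].tolist())
    ps_arr = np.asarray(ps)
    return {"rate": float((ps_arr < alpha).mean()), "n_tests": len(ps)}


def effect_recovery(seed: int = 0, n_cohorts: int = 100,
                    control_freq: float = 0.05,
                    odds_ratio: float = 3.0) -> dict:
    """Recovery of one planted intronic-deletion effect per cohort.

    For each seeded recovery-panel cohort, records the estimated carrier
    odds ratio of the planted gene and whether it attains the smallest
    chi-square p among the risk (OR > 1) keys — the paper-style ranking,
    since only risk variants feed downstream analyses.
    """
    planted_key = ("G0001", "intronic", "DEL")
    ors: list[float] = []
    wins = 0
    for i in range(n_cohorts):
        cfg = recovery_scenario(seed=_subseed(seed, i),
                                control_freq=control_freq,
                                odds_ratio=odds_ratio)
        res = fit_cohort(cfg)
        df = res.frame("AA")
        planted = df[df["key"] == planted_key]
        if planted.empty:
            continue
        ors.append(float(planted["odds_ratio"].iloc[0]))
        risk = df[df["is_risk"]]
        if (not risk.empty and bool(planted["is_risk"].iloc[0])
                and float(planted["chi2_p"].iloc[0])
                <= float(risk["chi2_p"].min())):
            wins += 1
    return {"median_or": float(np.median(ors)),
            "rank1_rate": wins / n_cohorts,
            "n_cohorts": n_cohorts}
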