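"""Canonical recovery experiments on the synthetic registry.

Each function runs one self-contained study at its canonical conditions
(cohort size 20,000 in the analyzed sex stratum, planted relative risk
4.0, strong progression) and returns the measured quantities.  They are
used both by the acceptance checks and as programmatic entry points for
power/robustness exploration.
"""

from __future__ import annotations

import numpy as np

from .model import ComorbidityTrajectoryModel
from .network import BuilderConfig, intralayer_links
from .records import apply_washout, to_events
from .simulate import (
    BACKGROUND_CODES,
    SimulationConfig,
    branch_pair_modules,
    planted_pairs,
    rr_recovery_modules,
    simulate_cohort,
    study_config,
)
from .trajectories import jaccard


def type_one_error_rate(seed=0, n_patients=20_000):
    """Intralayer link emission rate under simulated independence.

    No modules are planted, so every emitted link is a false positive.
    Returns ``(rate, n_tested_pairs)`` over pairs with at least one
    usable stratum.
    """
    cfg = study_config(n_patients=n_patients, seed=seed, male_fraction=1.0)
    stays, _ = simulate_cohort(cfg)
    _, kept = apply_washout(stays)
    events = to_events(kept)
    _, audit = intralayer_links(events, BuilderConfig(), "male")
    tested = audit[audit["n_strata_used"] > 0]
    return float(tested["emitted"].mean()), int(len(tested))


def rr_recovery(seed=0, n_patients=20_000, n_sims=2, band=(3.4, 4.6)):
    """Pooled CMH risk ratios of pairs planted at within-layer RR 4.0.

    Returns ``(fraction_in_band, rr_values)`` over the planted pairs of
    ``n_sims`` independent registries.
    """
    mods, extra = rr_recovery_modules()
    values = []
    for k in range(n_sims):
        cfg = study_config(n_patients=n_patients, modules=mods,
                           seed=seed + k, extra_background=extra,
                           male_fraction=1.0)
        stays, gt = simulate_cohort(cfg)
        _, kept = apply_washout(stays)
        events = to_events(kept)
        _, audit = intralayer_links(events, BuilderConfig(), "male")
        indexed = audit.set_index(["layer", "code_i", "code_j"])
        for i, j, layer in planted_pairs(gt):
            row = indexed.loc[(layer, min(i, j), max(i, j))]
            values.append(float(row["rr_ij"]))
    values = np.asarray(values)
    in_band = float(np.mean((values >= band[0]) & (values <= band[1])))
    return in_band, values


def bifurcation_recovery(seed=0, n_patients=20_000, n_runs=20,
                         threshold=1.5, match_jaccard=0.5):
    """Fraction of seeded runs whose planted diverging pair is flagged.

    Each run simulates a registry with one planted branch family (10x
    differential per-diagnosis mortality above the split), fits the full
    pipeline and checks whether some flagged critical event's trajectory
    pair matches the two planted branches at Jaccard >=
    ``match_jaccard`` on both sides.

    The background noise field uses 16 independent common diagnoses at
    hospitalized-population prevalences of 12-25%: frequent enough that
    association estimates rest on large exposure denominators, so the
    planted trunk stays the branch nodes' dominant interlayer parent
    after weight normalization.
    """
    mods, extra = branch_pair_modules()
    truth_a, truth_b = (m.trajectory() for m in mods)
    cycle = (0.12, 0.15, 0.18, 0.22, 0.25)
    background = {
        (code, layer): cycle[k % len(cycle)]
        for k, code in enumerate(BACKGROUND_CODES[:16])
        for layer in range(1, 9)
    }
    background.update(extra)
    hits = []
    for k in range(n_runs):
        cfg = SimulationConfig(n_patients=n_patients, modules=mods,
                               background_prevalence=background,
                               seed=seed + k, male_fraction=1.0)
        model = ComorbidityTrajectoryModel.from_simulation(
            cfg, sex="male", critical_threshold=threshold)
        res = model.fit(compute_summary=False)
        by_id = {t.id: t for t in res.trajectories}
        hit = False
        for event in res.flagged_critical_events:
            x, y = by_id[event.x_id], by_id[event.y_id]
            straight = min(jaccard(x, truth_a), jaccard(y, truth_b))
            crossed = min(jaccard(x, truth_b), jaccard(y, truth_a))
            if max(straight, crossed) >= match_jaccard:
                hit = True
                break
        hits.append(hit)
    return float(np.mean(hits)), hits
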