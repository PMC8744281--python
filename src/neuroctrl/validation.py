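"""Simulation-based validation studies: solver agreement, power, size.

These routines run the package's own machinery under controlled conditions:
cross-checking the Gramian solvers against the truncated series, measuring
recovery of an injected diagnosis-by-age effect, and calibrating the type-I
error of the interaction battery under the null. They back both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .connectome import Connectome
from .controllability import average_controllability, gramian, gramian_series, stabilize
from .simulate import dmn_decline_spec, null_effect_spec, simulate_study, toy_config
from .stats import run_primary_analysis


def _child_seed(seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, index]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def gramian_solver_agreement(
    n_systems: int = 200,
    node_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> dict:
    """Lyapunov-solved vs truncated-series Gramian on random stable systems.

    Returns the maximum absolute elementwise discrepancy over the sampled
    systems, plus the error of the 2-node chain average controllability
    against its closed form 1/(1 - a^2), a = w/(1+w).
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_systems):
        n = int(rng.integers(node_range[0], node_range[1] + 1))
        w = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        w = np.triu(w, 1)
        dyn = stabilize(Connectome("r", w + w.T))
        node = int(rng.integers(n))
        err = float(np.abs(gramian(dyn, node) - gramian_series(dyn, node)).max())
        max_err = max(max_err, err)

    chain_err = 0.0
    for weight in np.linspace(0.1, 1.0, 10):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = weight
        ac = average_controllability(stabilize(Connectome("c", m)))
        a = weight / (1 + weight)
        chain_err = max(chain_err, float(np.abs(ac - 1 / (1 - a**2)).max()))
    return {
        "n_systems": n_systems,
        "gramian_max_abs_error": max_err,
        "chain_ac_abs_error": chain_err,
    }


def recovery_simulation(
    n_replicates: int = 100,
    n_scz: int = 175,
    n_hc: int = 155,
    seed: int = 0,
) -> dict:
    """Recovery of an injected HC-only DMN edge-strength decline.

    Each replicate simulates a toy-atlas cohort with the calibrated decline
    (slope -0.005/yr in controls, patients flat), runs the full primary
    analysis, and records whether the DMN diagnosis-by-age interaction
    survives FDR and whether the group trajectories show the injected
    pattern (HC partial r negative, SCZ trajectory not significant).
    """
    detected = 0
    signs_ok = 0
    spec = dmn_decline_spec()
    for rep in range(n_replicates):
        rep_seed = _child_seed(seed, rep)
        cohort, ctrl = simulate_study(
            toy_config(n_scz, n_hc, seed=rep_seed), spec, seed=rep_seed
        )
        res = run_primary_analysis(cohort, ctrl)
        if "ac_system_DMN" not in res.fdr_systems.significant_targets:
            continue
        detected += 1
        traj = {(t.target, t.group): t for t in res.trajectories}
        hc = traj[("ac_system_DMN", "HC")]
        scz = traj[("ac_system_DMN", "SCZ")]
        if hc.partial_r < 0 and scz.p > 0.05:
            signs_ok += 1
    return {
        "n_replicates": n_replicates,
        "n_detected": detected,
        "detection_rate": detected / n_replicates,
        "sign_agreement_rate": signs_ok / detected if detected else float("nan"),
    }


def null_calibration(
    n_replicates: int = 1000,
    n_scz: int = 50,
    n_hc: int = 50,
    seed: int = 0,
) -> dict:
    """Type-I behaviour of the battery under the null effect specification.

    Pools raw interaction p-values over all systems and nodes of every
    replicate (rejection rate at alpha = 0.05 should sit near 0.05) and
    tracks how often the 8-system FDR family makes any false discovery.
    """
    spec = null_effect_spec()
    n_tests = 0
    n_reject = 0
    n_family_fp = 0
    for rep in range(n_replicates):
        rep_seed = _child_seed(seed, 10_000 + rep)
        cohort, ctrl = simulate_study(
            toy_config(n_scz, n_hc, seed=rep_seed), spec, seed=rep_seed
        )
        res = run_primary_analysis(cohort, ctrl)
        pvals = [r.p_interaction for r in res.systems] + [
            r.p_interaction for r in res.nodes
        ]
        n_tests += len(pvals)
        n_reject += int(np.sum(np.asarray(pvals) < 0.05))
        n_family_fp += bool(res.fdr_systems.significant.any())
    return {
        "n_replicates": n_replicates,
        "n_tests": n_tests,
        "rejection_rate": n_reject / n_tests,
        "fdr_familywise_rate": n_family_fp / n_replicates,
    }
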