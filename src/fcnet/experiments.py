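"""Replicate-study experiment harness: recovery and calibration runs.

These runners stitch the whole pipeline together on simulated studies and
summarise it the way a methods-validation section would: directional
recovery of the planted drug effect, type-I calibration of the AUC t-tests
under null studies, family-wise error calibration of NBS, and recovery of a
planted differential subnetwork. They are used by the validation test suite
and the reproduction script; problem sizes default to desk-scale values
(see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .connectivity import ConnectivityMatrix, correlation_matrix
from .nbs import NBSConfig, nbs_test
from .nulls import NullEnsembleSpec
from .sweep import SweepConfig, group_test, study_aucs
from .synth import (
    DRUG_DEFAULT,
    PLACEBO,
    ConditionEffect,
    LatentNetworkSpec,
    StudyDesignSpec,
    simulate_study,
)

__all__ = [
    "recovery_direction_fractions",
    "null_metric_rejection_rates",
    "nbs_null_positive_rate",
    "nbs_planted_recovery",
]

#: Direction of the planted drug effect on AUC contrasts (drug - placebo):
#: global efficiency and small-worldness expected down, cyclic motifs up.
RECOVERY_DIRECTIONS = {"E_glob": -1, "sigma": -1, "cyclic_total": 1}


def _study_group_stats(net, design, placebo, drug, sweep_cfg):
    sessions, _ = simulate_study(design, net, placebo, drug)
    mats = [correlation_matrix(ts) for ts in sessions]
    aucs = study_aucs(mats, sweep_cfg)
    return group_test(aucs, design.design).set_index("measure")


def recovery_direction_fractions(
    n_replicates: int = 20,
    seed: int = 0,
    n_nulls: int = 4,
    drug: ConditionEffect = DRUG_DEFAULT,
) -> dict:
    """Fraction of replicate studies reproducing each expected direction.

    Each replicate is a full paired cross-over study at the generator
    defaults (90 regions, 15 modules, n = 20 subjects, T = 300) with the
    default planted drug effect, run end to end through connectivity,
    density sweep, AUC and paired t-tests.
    """
    signs = {m: 0 for m in RECOVERY_DIRECTIONS}
    tvals = {m: [] for m in RECOVERY_DIRECTIONS}
    for r in range(n_replicates):
        net = LatentNetworkSpec(seed=seed + r)
        design = StudyDesignSpec(seed=seed + r)
        cfg = SweepConfig(null_spec=NullEnsembleSpec(n_nulls=n_nulls, seed=seed + r))
        res = _study_group_stats(net, design, PLACEBO, drug, cfg)
        for m, direction in RECOVERY_DIRECTIONS.items():
            t = float(res.loc[m, "t"])
            tvals[m].append(t)
            if np.sign(t) == direction:
                signs[m] += 1
    return {
        "fractions": {m: signs[m] / n_replicates for m in signs},
        "mean_t": {m: float(np.mean(tvals[m])) for m in tvals},
        "n_replicates": n_replicates,
    }


def null_metric_rejection_rates(
    n_replicates: int = 600,
    seed: int = 0,
    n_nodes: int = 60,
    n_modules: int = 10,
    n_subjects: int = 6,
    n_timepoints: int = 80,
    n_nulls: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Uncorrected rejection rate per metric under null studies.

    Both conditions use the unperturbed effect, so by exchangeability every
    AUC t-test is a true null and should reject at ``alpha``. Replicates
    where sigma is undefined at the density floor (triangle-free null
    ensemble on these deliberately small networks) are skipped and counted.
    """
    null_drug = ConditionEffect(0.0, 0.0, "drug")
    rejections: dict[str, int] = {}
    completed = 0
    skipped = 0
    for r in range(n_replicates):
        net = LatentNetworkSpec(
            n_nodes=n_nodes, n_modules=n_modules, seed=seed + r
        )
        design = StudyDesignSpec(
            n_subjects_or_per_group=n_subjects,
            n_timepoints=n_timepoints,
            seed=seed + r,
        )
        cfg = SweepConfig(
            motifs=False,
            null_spec=NullEnsembleSpec(n_nulls=n_nulls, seed=seed + r),
        )
        try:
            res = _study_group_stats(net, design, PLACEBO, null_drug, cfg)
        except ValueError:
            skipped += 1
            continue
        completed += 1
        for m in res.index:
            rejections[m] = rejections.get(m, 0) + int(res.loc[m, "p_raw"] < alpha)
    return {
        "rates": {m: rejections[m] / completed for m in rejections},
        "n_completed": completed,
        "n_skipped": skipped,
    }


def nbs_null_positive_rate(
    n_replicates: int = 200,
    seed: int = 0,
    n_nodes: int = 60,
    n_subjects: int = 12,
    n_timepoints: int = 100,
    n_permutations: int = 500,
    threshold_t: float = 3.0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of null studies where NBS declares any significant component."""
    null_drug = ConditionEffect(0.0, 0.0, "drug")
    positives = 0
    for r in range(n_replicates):
        net = LatentNetworkSpec(n_nodes=n_nodes, n_modules=10, seed=seed + r)
        design = StudyDesignSpec(
            n_subjects_or_per_group=n_subjects,
            n_timepoints=n_timepoints,
            seed=seed + r,
        )
        sessions, _ = simulate_study(design, net, PLACEBO, null_drug)
        mats = [correlation_matrix(ts) for ts in sessions]
        cfg = NBSConfig(
            primary_threshold_t=threshold_t,
            design="paired",
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed + r,
        )
        if nbs_test(mats, cfg).significant:
            positives += 1
    return {"rate": positives / n_replicates, "n_replicates": n_replicates}


#: 10-edge connected differential component planted on nodes 0..5.
PLANTED_COMPONENT = (
    (0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
    (0, 2), (1, 3), (2, 4), (3, 5),
)


def nbs_planted_recovery(
    seed: int = 0,
    n_subjects: int = 20,
    n_nodes: int = 60,
    n_permutations: int = 1000,
    delta: float = 0.25,
    threshold_t: float = 4.0,
) -> dict:
    """Recovery of a planted 10-edge differential component (paired design).

    Subject connectivity is a shared subject baseline plus session noise in
    Fisher-z units; the drug session additionally gains ``delta`` on the
    planted edges. Returns the FWER p-value of the largest component and
    its edge-set Jaccard overlap with the planted truth.
    """
    rng = np.random.default_rng(seed)
    labels = [f"r{i:02d}" for i in range(n_nodes)]
    mats = []
    for s in range(n_subjects):
        base = rng.standard_normal((n_nodes, n_nodes)) * 0.2
        base = (base + base.T) / 2
        for cond in ("placebo", "drug"):
            noise = rng.standard_normal((n_nodes, n_nodes)) * 0.1
            z = base + (noise + noise.T) / 2
            if cond == "drug":
                for i, j in PLANTED_COMPONENT:
                    z[i, j] += delta
                    z[j, i] += delta
            np.fill_diagonal(z, 0)
            mats.append(
                ConnectivityMatrix(
                    z=z, region_labels=labels,
                    subject_id=f"s{s:02d}", condition=cond,
                )
            )
    cfg = NBSConfig(
        primary_threshold_t=threshold_t,
        design="paired",
        n_permutations=n_permutations,
        seed=seed,
    )
    result = nbs_test(mats, cfg)
    if not result.components:
        return {"p_fwer": 1.0, "jaccard": 0.0, "size": 0}
    top = result.components[0]
    found = {tuple(sorted(e)) for e in top.edges}
    truth = {tuple(sorted(e)) for e in PLANTED_COMPONENT}
    return {
        "p_fwer": float(top.p_fwer),
        "jaccard": len(found & truth) / len(found | truth),
        "size": top.size,
    }
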