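"""Synthetic ROI time series with a modular latent covariance, and fixture graphs.

No raw recordings from the pharmacological studies this pipeline emulates
are publicly deposited, so every downstream stage is exercised on simulated
data with known ground truth. Sessions are stationary AR(1) multivariate
Gaussian series whose innovation covariance carries a stochastic-block
community structure; a "drug" condition perturbs within-module couplings
upward and between-module couplings downward, which is the planted analogue
of a shift toward more-segregated, less-integrated network topology.

Randomness is organised around one master seed: session streams are
``numpy`` ``SeedSequence`` objects with spawn key (subject index, session
index), so any single session is reproducible in isolation from the
manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import BinaryNetwork, RoiTimeSeries

__all__ = [
    "LatentNetworkSpec",
    "ConditionEffect",
    "StudyDesignSpec",
    "PLACEBO",
    "DRUG_DEFAULT",
    "module_assignment",
    "make_covariance",
    "simulate_session",
    "simulate_study",
    "fixture_graphs",
]


@dataclass(frozen=True)
class LatentNetworkSpec:
    """Stochastic-block latent structure behind the simulated covariance.

    ``n_nodes`` regions are split into ``n_modules`` near-equal blocks.
    Latent edges appear independently with probability ``p_within`` inside a
    block and ``p_between`` across blocks; ``coupling`` scales how strongly
    latent edges contribute to the covariance (must stay below 1 so the
    spectral construction in :func:`make_covariance` is positive definite).
    """

    n_nodes: int = 90
    n_modules: int = 15
    p_within: float = 0.95
    p_between: float = 0.02
    coupling: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or not 1 <= self.n_modules <= self.n_nodes:
            raise ValueError("need 2 <= n_nodes and 1 <= n_modules <= n_nodes")
        if not 0.0 <= self.p_between <= self.p_within <= 1.0:
            raise ValueError("require 0 <= p_between <= p_within <= 1")
        if self.coupling < 0:
            raise ValueError("coupling must be nonnegative")


@dataclass(frozen=True)
class ConditionEffect:
    """Signed perturbation of latent couplings for one study condition.

    ``delta_within`` is added to the (unit) weight of within-module latent
    edges, ``delta_between`` to between-module ones. A positive
    ``delta_within`` with negative ``delta_between`` strengthens module
    interiors relative to bridges, so thresholded networks become more
    clustered/cyclic and less globally efficient in expectation.
    """

    delta_within: float = 0.0
    delta_between: float = 0.0
    label: str = "placebo"

    def __post_init__(self) -> None:
        if self.label not in ("placebo", "drug"):
            raise ValueError("label must be 'placebo' or 'drug'")


#: Unperturbed baseline condition.
PLACEBO = ConditionEffect(0.0, 0.0, "placebo")
#: Default planted drug effect: within-module up, between-module down.
DRUG_DEFAULT = ConditionEffect(0.15, -0.10, "drug")


@dataclass(frozen=True)
class StudyDesignSpec:
    """Shape of a simulated study.

    ``paired`` emits two sessions (placebo, drug) per subject sharing a
    subject-level coupling jitter, emulating a within-subject cross-over;
    ``two_group`` emits one session per subject with independent subjects in
    a placebo and a drug group. ``ar_coefficient`` is the common AR(1)
    temporal autocorrelation of all regional signals and
    ``subject_effect_sd`` the s.d. of the lognormal per-subject coupling
    jitter.
    """

    design: str = "paired"
    n_subjects_or_per_group: int = 20
    n_timepoints: int = 300
    sampling_interval: float = 1.79
    ar_coefficient: float = 0.3
    subject_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("paired", "two_group"):
            raise ValueError("design must be 'paired' or 'two_group'")
        if self.n_subjects_or_per_group < 1:
            raise ValueError("need at least one subject")
        if self.n_timepoints < 1:
            raise ValueError("need at least one time point")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.subject_effect_sd < 0:
            raise ValueError("subject_effect_sd must be nonnegative")


def module_assignment(spec: LatentNetworkSpec) -> np.ndarray:
    """Module id per node, blocks as equal as possible, contiguous."""
    return np.sort(np.arange(spec.n_nodes) % spec.n_modules)


def _latent_edges(spec: LatentNetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the latent edge indicator (upper triangle) and module mask.

    The latent structure depends only on ``spec`` (not on the condition),
    so placebo and drug sessions share one community skeleton.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    mods = module_assignment(spec)
    within = mods[:, None] == mods[None, :]
    p = np.where(within, spec.p_within, spec.p_between)
    u = rng.random((spec.n_nodes, spec.n_nodes))
    u = np.triu(u, 1)
    edges = np.triu(u < p, 1) & np.triu(np.ones_like(within), 1).astype(bool)
    edges = edges | edges.T
    return edges, within


# spectral quantities depend only on (spec, effect), not the subject jitter;
# cached so per-subject covariance assembly is O(N^2) instead of O(N^3)
_SPECTRUM_CACHE: dict[tuple, tuple[float, float]] = {}


def _latent_spectrum(spec: LatentNetworkSpec, effect: ConditionEffect):
    key = (spec, effect.delta_within, effect.delta_between)
    if key not in _SPECTRUM_CACHE:
        edges, within = _latent_edges(spec)
        w = edges * np.where(
            within, 1.0 + effect.delta_within, 1.0 + effect.delta_between
        )
        rho0 = float(np.max(np.abs(np.linalg.eigvalsh(edges.astype(float)))))
        min_eig_w = float(np.linalg.eigvalsh(w)[0])
        _SPECTRUM_CACHE[key] = (rho0, min_eig_w)
    return _SPECTRUM_CACHE[key]


def make_covariance(
    spec: LatentNetworkSpec,
    effect: ConditionEffect = PLACEBO,
    coupling_scale: float = 1.0,
) -> np.ndarray:
    """Condition covariance Sigma = I + c * W_effect / rho(W_baseline).

    ``W_baseline`` is the 0/1 latent edge matrix; ``W_effect`` reweights its
    within-module edges by ``1 + delta_within`` and between-module edges by
    ``1 + delta_between``. Normalising by the spectral radius of the
    *baseline* matrix keeps the condition deltas visible as absolute changes
    in covariance entries (normalising by the perturbed matrix's own radius
    would cancel a uniform delta); positive definiteness is verified
    explicitly by eigendecomposition and violating configurations are
    rejected.
    """
    edges, within = _latent_edges(spec)
    c = spec.coupling * coupling_scale
    if c == 0 or not edges.any():
        return np.eye(spec.n_nodes)
    w = edges * np.where(within, 1.0 + effect.delta_within, 1.0 + effect.delta_between)
    rho0, min_eig_w = _latent_spectrum(spec, effect)
    min_eig = 1.0 + c * min_eig_w / rho0
    if min_eig <= 1e-10:
        raise ValueError(
            f"covariance not positive definite (min eigenvalue {min_eig:.3g}); "
            "reduce coupling or effect deltas"
        )
    return np.eye(spec.n_nodes) + c * w / rho0


def simulate_session(
    cov: np.ndarray,
    n_timepoints: int,
    ar_coefficient: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
    sampling_interval: float = 1.79,
    region_labels: list[str] | None = None,
    subject_id: str = "",
    condition: str = "",
    group: str = "",
) -> RoiTimeSeries:
    """Stationary AR(1) Gaussian series x_t = phi x_{t-1} + eps_t.

    Innovations are N(0, cov); the initial state is drawn from the
    stationary distribution N(0, cov / (1 - phi^2)), so the sample
    covariance converges to cov / (1 - phi^2) as T grows. Bit-identical
    output for identical seeds. Short series (small T) are permitted but
    their sample covariance is a noisy estimate of the target.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    rng = np.random.default_rng(seed)
    phi = ar_coefficient
    eps = rng.standard_normal((n_timepoints, n)) @ chol.T
    x = np.empty((n_timepoints, n))
    x0 = (rng.standard_normal(n) @ chol.T) / np.sqrt(1.0 - phi**2)
    prev = x0
    for t in range(n_timepoints):
        prev = phi * prev + eps[t]
        x[t] = prev
    if region_labels is None:
        width = len(str(n))
        region_labels = [f"R{i:0{width}d}" for i in range(n)]
    return RoiTimeSeries(
        values=x,
        region_labels=region_labels,
        sampling_interval=sampling_interval,
        subject_id=subject_id,
        condition=condition,
        group=group,
    )


def _session_seed(master_seed: int, subject_idx: int, session_idx: int):
    return np.random.SeedSequence(master_seed, spawn_key=(subject_idx, session_idx))


def simulate_study(
    design: StudyDesignSpec,
    net: LatentNetworkSpec,
    placebo: ConditionEffect = PLACEBO,
    drug: ConditionEffect = DRUG_DEFAULT,
) -> tuple[list[RoiTimeSeries], pd.DataFrame]:
    """Simulate a full labelled study; returns (sessions, manifest).

    Paired design: each subject contributes a placebo and a drug session
    built from the same subject-specific coupling jitter (lognormal,
    ``subject_effect_sd``), which is what gives the paired contrast its
    power advantage. Two-group design: one session per subject, first group
    placebo, second group drug, independent jitters.

    The manifest records subject id, condition, group and the spawn-key
    seeds of every session.
    """
    sessions: list[RoiTimeSeries] = []
    rows: list[dict] = []
    n = design.n_subjects_or_per_group
    jitter_rng = np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(0xA5,))
    )

    def _one(subject_idx, session_idx, subject_id, effect, group, scale):
        cov = make_covariance(net, effect, coupling_scale=scale)
        ss = _session_seed(design.seed, subject_idx, session_idx)
        ts = simulate_session(
            cov,
            design.n_timepoints,
            design.ar_coefficient,
            seed=ss,
            sampling_interval=design.sampling_interval,
            subject_id=subject_id,
            condition=effect.label,
            group=group,
        )
        sessions.append(ts)
        rows.append(
            {
                "subject_id": subject_id,
                "condition": effect.label,
                "group": group,
                "master_seed": design.seed,
                "spawn_key": f"{subject_idx},{session_idx}",
            }
        )

    if design.design == "paired":
        for i in range(n):
            scale = float(
                np.exp(design.subject_effect_sd * jitter_rng.standard_normal())
            )
            sid = f"sub{i + 1:02d}"
            for j, effect in enumerate((placebo, drug)):
                _one(i, j, sid, effect, group="", scale=scale)
    else:
        for g, effect in enumerate((placebo, drug)):
            for i in range(n):
                scale = float(
                    np.exp(design.subject_effect_sd * jitter_rng.standard_normal())
                )
                sid = f"{effect.label}{i + 1:02d}"
                _one(g * n + i, 0, sid, effect, group=effect.label, scale=scale)
    return sessions, pd.DataFrame(rows)


def _bn(g: nx.Graph, n: int | None = None) -> BinaryNetwork:
    n = g.number_of_nodes() if n is None else n
    adj = np.zeros((n, n), dtype=np.uint8)
    for u, v in g.edges():
        adj[u, v] = adj[v, u] = 1
    n_pairs = n * (n - 1) // 2
    density = g.number_of_edges() / n_pairs if n_pairs else 0.5
    labels = [f"n{i}" for i in range(n)]
    return BinaryNetwork(adjacency=adj, density=min(max(density, 1e-9), 1 - 1e-9),
                         region_labels=labels)


def fixture_graphs(er_seed: int = 42) -> dict[str, BinaryNetwork]:
    """Named small graphs with known topology, for tests and examples."""
    two_tri = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
    two_tri.add_nodes_from(range(10))
    graphs = {
        "triangle": nx.cycle_graph(3),
        "3-path": nx.path_graph(3),
        "4-path": nx.path_graph(4),
        "4-star": nx.star_graph(3),
        "4-cycle": nx.cycle_graph(4),
        "paw": nx.Graph([(0, 1), (1, 2), (2, 0), (0, 3)]),
        "diamond": nx.Graph([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]),
        "K4": nx.complete_graph(4),
        "K5": nx.complete_graph(5),
        "two-triangles-10": two_tri,
        "ring-lattice-30-4": nx.circulant_graph(30, [1, 2]),
        "er-30-0.2": nx.gnp_random_graph(30, 0.2, seed=er_seed),
    }
    return {name: _bn(g) for name, g in graphs.items()}
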