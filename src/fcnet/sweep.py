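"""Density sweep, AUC summarisation and group-level inference with FDR.

Rather than testing every metric at every threshold (and facing an open
multiple-comparison problem across densities), each subject's metric curve
over the density grid is reduced to its area under the curve (trapezoidal
rule over the grid), giving one threshold-free summary per subject and
measure. AUCs are then compared between conditions with a paired t-test
(cross-over design) or a pooled-variance independent-samples t-test
(two-group design), and p-values are Benjamini–Hochberg FDR-adjusted
within two separate families: the five graph metrics and the eight motif
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix, threshold_proportional
from .metrics import METRIC_NAMES, metric_vector
from .motifs import MOTIF_ORDER, census, cyclic_acyclic_totals
from .nulls import NullEnsembleSpec

__all__ = [
    "SweepConfig",
    "MetricCurve",
    "default_density_grid",
    "sweep_metrics",
    "auc",
    "study_aucs",
    "group_test",
    "fdr_adjust",
    "group_tests_with_fdr",
]

MOTIF_TOTALS = ("cyclic_total", "acyclic_total")


def default_density_grid() -> np.ndarray:
    """Densities 0.05 to 0.20 in steps of 0.01 (16 levels)."""
    return np.round(np.linspace(0.05, 0.20, 16), 2)


@dataclass(frozen=True)
class SweepConfig:
    densities: tuple[float, ...] = tuple(default_density_grid())
    null_spec: NullEnsembleSpec = field(default_factory=NullEnsembleSpec)
    metrics: tuple[str, ...] = METRIC_NAMES
    motifs: bool = True
    ranking: str = "signed"

    def __post_init__(self) -> None:
        d = np.asarray(self.densities)
        if d.size < 1 or np.any(d <= 0) or np.any(d >= 1):
            raise ValueError("densities must lie strictly in (0, 1)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("densities must be strictly increasing")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")


@dataclass
class MetricCurve:
    subject_id: str
    condition: str
    metric: str
    densities: np.ndarray
    values: np.ndarray
    notes: dict[float, str] = field(default_factory=dict)


def sweep_metrics(cm: ConnectivityMatrix, cfg: SweepConfig) -> pd.DataFrame:
    """Threshold at every density and compute metrics (and motif counts).

    Returns a tidy frame (subject_id, condition, group, density, measure,
    value, note). A metric that is undefined at some density (e.g. L on a
    graph with no reachable pair) is recorded as NaN with the failure
    reason in ``note`` — never silently dropped.
    """
    rows = []
    for i, density in enumerate(cfg.densities):
        g = threshold_proportional(cm, float(density), ranking=cfg.ranking)
        null_spec = NullEnsembleSpec(
            n_nulls=cfg.null_spec.n_nulls,
            swaps_per_edge=cfg.null_spec.swaps_per_edge,
            method=cfg.null_spec.method,
            seed=cfg.null_spec.seed + i,
        )
        meta = {
            "subject_id": cm.subject_id,
            "condition": cm.condition,
            "group": cm.group,
            "density": float(density),
        }
        if cfg.metrics:
            try:
                if "sigma" in cfg.metrics:
                    vals = metric_vector(g, null_spec).as_dict()
                else:  # skip the null ensemble when sigma is not requested
                    from .metrics import (
                        _char_path_from_distances,
                        _global_eff_from_distances,
                        clustering_coefficient,
                        local_efficiency,
                        shortest_path_lengths,
                    )

                    dist = shortest_path_lengths(g)
                    vals = {
                        "C": clustering_coefficient(g),
                        "L": _char_path_from_distances(dist)[0],
                        "E_glob": _global_eff_from_distances(dist),
                        "E_loc": local_efficiency(g),
                        "sigma": np.nan,
                    }
                note = ""
            except ValueError as exc:
                vals = {m: np.nan for m in METRIC_NAMES}
                note = str(exc)
            for m in cfg.metrics:
                rows.append({**meta, "measure": m, "value": vals[m], "note": note})
        if cfg.motifs:
            cen = census(g)
            cyc, acyc = cyclic_acyclic_totals(cen)
            for name in MOTIF_ORDER:
                rows.append(
                    {**meta, "measure": name, "value": float(cen.counts[name]),
                     "note": ""}
                )
            rows.append({**meta, "measure": "cyclic_total", "value": float(cyc),
                         "note": ""})
            rows.append({**meta, "measure": "acyclic_total", "value": float(acyc),
                         "note": ""})
    return pd.DataFrame(rows)


def auc(densities: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under one metric curve over the density grid."""
    densities = np.asarray(densities, dtype=float)
    values = np.asarray(values, dtype=float)
    if densities.size < 2:
        raise ValueError("need at least 2 grid points for an AUC")
    bad = ~np.isfinite(values)
    if bad.any():
        raise ValueError(
            "curve has missing values at densities "
            f"{densities[bad].tolist()}; raise the density floor"
        )
    return float(np.trapezoid(values, densities))


def study_aucs(
    matrices: list[ConnectivityMatrix], cfg: SweepConfig
) -> pd.DataFrame:
    """Per-(subject, condition, measure) AUC table for a whole study."""
    frames = [sweep_metrics(cm, cfg) for cm in matrices]
    curves = pd.concat(frames, ignore_index=True)
    out = []
    keys = ["subject_id", "condition", "group", "measure"]
    for key, sub in curves.groupby(keys, sort=False):
        sub = sub.sort_values("density")
        out.append(
            dict(
                zip(keys, key),
                auc=auc(sub["density"].to_numpy(), sub["value"].to_numpy()),
            )
        )
    return pd.DataFrame(out)


def _paired_arrays(auc_df: pd.DataFrame, measure: str):
    sub = auc_df[auc_df["measure"] == measure]
    wide = sub.pivot(index="subject_id", columns="condition", values="auc")
    missing = wide.index[wide.isna().any(axis=1)].tolist()
    if missing or wide.shape[1] != 2:
        raise ValueError(
            f"unpairable subjects for measure {measure!r}: {missing or 'conditions'}"
        )
    return wide["drug"].to_numpy(), wide["placebo"].to_numpy()


def group_test(auc_df: pd.DataFrame, design: str) -> pd.DataFrame:
    """Per-measure condition contrast on AUCs.

    Paired design: one-sample t on per-subject drug-minus-placebo
    differences (df = n - 1). Two-group design: classical pooled-variance
    independent-samples t (df = n1 + n2 - 2). Two-sided p-values.
    ``direction`` is the sign of the mean drug-minus-placebo contrast.
    A contrast with zero differences everywhere yields t = 0, p = 1; a
    nonzero constant contrast with zero variance is degenerate and raises.
    """
    if design not in ("paired", "two_group"):
        raise ValueError("design must be 'paired' or 'two_group'")
    rows = []
    for measure in auc_df["measure"].unique():
        if design == "paired":
            drug, placebo = _paired_arrays(auc_df, measure)
            diffs = drug - placebo
            n = diffs.size
            df = n - 1
            if np.allclose(diffs, 0):
                t, p = 0.0, 1.0
            elif diffs.std(ddof=1) == 0:
                raise ValueError(
                    f"zero-variance nonzero differences for measure {measure!r}"
                )
            else:
                t, p = stats.ttest_rel(drug, placebo)
            effect = float(diffs.mean())
            n_report = n
        else:
            sub = auc_df[auc_df["measure"] == measure]
            drug = sub.loc[sub["condition"] == "drug", "auc"].to_numpy()
            placebo = sub.loc[sub["condition"] == "placebo", "auc"].to_numpy()
            if drug.size < 2 or placebo.size < 2:
                raise ValueError(f"need >= 2 subjects per group for {measure!r}")
            df = drug.size + placebo.size - 2
            if np.allclose(drug.std(ddof=1), 0) and np.allclose(
                placebo.std(ddof=1), 0
            ):
                if np.isclose(drug.mean(), placebo.mean()):
                    t, p = 0.0, 1.0
                else:
                    raise ValueError(
                        f"zero-variance nonzero contrast for measure {measure!r}"
                    )
            else:
                t, p = stats.ttest_ind(drug, placebo, equal_var=True)
            effect = float(drug.mean() - placebo.mean())
            n_report = drug.size + placebo.size
        rows.append(
            {
                "measure": measure,
                "design": design,
                "t": float(t),
                "df": int(df),
                "p_raw": float(p),
                "direction": int(np.sign(effect)),
                "n": n_report,
            }
        )
    return pd.DataFrame(rows)


def fdr_adjust(p_values, family: str = "") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError(f"p-values outside [0, 1] in family {family!r}")
    return multipletests(p, method="fdr_bh")[1]


#: Default FDR families: the five graph metrics and the eight motif classes.
DEFAULT_FAMILIES = {
    "metrics": list(METRIC_NAMES),
    "motifs": list(MOTIF_ORDER),
    "motif_totals": list(MOTIF_TOTALS),
}


def group_tests_with_fdr(
    auc_df: pd.DataFrame,
    design: str,
    families: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Group tests plus per-family BH adjustment (``p_fdr`` column)."""
    res = group_test(auc_df, design)
    families = DEFAULT_FAMILIES if families is None else families
    res["family"] = ""
    res["p_fdr"] = np.nan
    for fam, members in families.items():
        mask = res["measure"].isin(members)
        if mask.any():
            res.loc[mask, "family"] = fam
            res.loc[mask, "p_fdr"] = fdr_adjust(
                res.loc[mask, "p_raw"].to_numpy(), family=fam
            )
    return res
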