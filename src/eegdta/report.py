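"""Run manifests, cross-family statistics and report export.

A :class:`RunManifest` ties one train/validation run to its seed and
configuration hash; collections of manifests are summarized into the
standard report tables: per-family metric means and standard deviations,
decision-time-advantage rows at k = 80/75/70 (with ">1,000" for profiles
censored at the grid edge and an en-dash for undefined ones), per-family
timing, all pairwise Mann-Whitney accuracy comparisons (no multiplicity
correction by default, optionally Holm), and TPR-vs-lag trade-off curves as
plain plot data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .anticipation import DtaEstimate, LagProfile, TimingBudget
from .classifiers import MetricSet
from .stats import ComparisonResult, mann_whitney_u

__all__ = [
    "RunManifest",
    "config_hash",
    "compare_architectures",
    "format_dta_entry",
    "export_report",
    "DEFAULT_K_GRID",
]

DEFAULT_K_GRID = (80.0, 75.0, 70.0)
UNDEFINED_MARK = "–"  # en dash, the table convention for undefined


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunManifest:
    """One training run: provenance plus its evaluation artifacts."""

    dataset_id: str
    family: str
    seed: int
    config: dict = field(default_factory=dict)
    metrics: MetricSet | None = None
    dta: dict[float, DtaEstimate] = field(default_factory=dict)
    timing: TimingBudget | None = None
    lag_profile: LagProfile | None = None

    @property
    def hash(self) -> str:
        return config_hash({"dataset": self.dataset_id, "seed": self.seed,
                            "family": self.family, **self.config})


def compare_architectures(manifests: list[RunManifest],
                          alpha: float = 0.05,
                          holm: bool = False) -> list[ComparisonResult]:
    """All pairwise accuracy comparisons between families.

    Families with fewer than two runs are excluded with a warning. By
    default no multiple-testing correction is applied; ``holm=True`` applies
    the Holm step-down adjustment before flagging significance.
    """
    import warnings

    by_family: dict[str, list[float]] = {}
    for m in manifests:
        if m.metrics is not None:
            by_family.setdefault(m.family, []).append(m.metrics.accuracy)
    usable = {}
    for fam, accs in by_family.items():
        if len(accs) < 2:
            warnings.warn(f"family {fam!r} has {len(accs)} run(s); "
                          "excluded from comparisons", RuntimeWarning)
        else:
            usable[fam] = accs

    results = [
        mann_whitney_u(usable[fa], usable[fb], fa, fb, alpha=alpha)
        for fa, fb in combinations(sorted(usable), 2)
    ]
    if holm and results:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        adjusted = {}
        running_max = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * results[idx].p_value)
            running_max = max(running_max, adj)
            adjusted[idx] = running_max
        results = [
            ComparisonResult(r.group_a, r.group_b, r.u_statistic,
                             r.p_value, r.n_a, r.n_b,
                             adjusted[i] < alpha)
            for i, r in enumerate(results)
        ]
    return results


def format_dta_entry(est: DtaEstimate | None, grid_max_ms: float = 1000.0
                     ) -> str:
    """Render a DTA cell the way the result tables print it."""
    if est is None or est.status == "undefined":
        return UNDEFINED_MARK
    if est.status == "censored_at_grid_max":
        head = f">{grid_max_ms:,.0f}"
    else:
        head = f"{est.dta_ms:,.0f}"
    if est.ci_ms is not None:
        head += f" [{est.ci_ms[0]:,.0f}–{est.ci_ms[1]:,.0f}]"
    return head


def _metrics_summary(manifests: list[RunManifest]) -> pd.DataFrame:
    rows = []
    for m in manifests:
        if m.metrics is None:
            continue
        rows.append({"family": m.family,
                     "accuracy": m.metrics.accuracy,
                     "f1": m.metrics.f1,
                     "precision": m.metrics.precision,
                     "recall": m.metrics.recall})
    df = pd.DataFrame(rows)
    out = df.groupby("family").agg(["mean", "std"])
    out.columns = [f"{metric}_{stat}" for metric, stat in out.columns]
    return out.reset_index()


def export_report(manifests: list[RunManifest],
                  comparisons: list[ComparisonResult] | None,
                  out_dir) -> dict[str, Path]:
    """Write the report tables; returns the paths written.

    Emits ``metrics_summary.csv``, ``dta_table.csv``, ``timing.csv``,
    ``comparisons.csv`` and ``tradeoff_curves.json`` (TPR-vs-lag arrays per
    family). Pure function of the manifests: identical input reproduces
    identical files.
    """
    if not manifests:
        raise ValueError("no manifests to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    p = out_dir / "metrics_summary.csv"
    _metrics_summary(manifests).to_csv(p, index=False)
    written["metrics"] = p

    dta_rows = []
    for m in manifests:
        if not m.dta:
            continue
        row = {"family": m.family, "seed": m.seed}
        for k in sorted(m.dta, reverse=True):
            row[f"dta_{k:g}"] = format_dta_entry(m.dta[k])
        dta_rows.append(row)
    if dta_rows:
        p = out_dir / "dta_table.csv"
        pd.DataFrame(dta_rows).to_csv(p, index=False)
        written["dta"] = p

    timing_rows = [
        {"family": m.family, "seed": m.seed,
         "preprocess_mean_ms": m.timing.preprocess_mean_ms,
         "inference_mean_ms": m.timing.inference_mean_ms,
         "ctd_ms": m.timing.ctd_ms}
        for m in manifests if m.timing is not None
    ]
    if timing_rows:
        p = out_dir / "timing.csv"
        pd.DataFrame(timing_rows).to_csv(p, index=False)
        written["timing"] = p

    if comparisons:
        p = out_dir / "comparisons.csv"
        pd.DataFrame([vars(c) for c in comparisons]).to_csv(p, index=False)
        written["comparisons"] = p

    curves = {}
    for m in manifests:
        if m.lag_profile is not None:
            curves.setdefault(m.family, []).append({
                "seed": m.seed,
                "lag_s": m.lag_profile.lags.tolist(),
                "tpr": m.lag_profile.tpr.tolist(),
            })
    if curves:
        p = out_dir / "tradeoff_curves.json"
        p.write_text(json.dumps(curves, indent=2))
        written["tradeoff"] = p

    return written
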