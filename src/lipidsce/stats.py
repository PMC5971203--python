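"""Group statistics and end-to-end reporting for lipidome time courses.

Replicate group comparisons follow the conventions of the source
experiments: one-way ANOVA with Bonferroni-corrected pairwise comparisons
(pooled-variance two-sample t per pair), two-tailed Student's t tests, and
mean ± SD summaries.  Significance tiers use the usual star convention with
significance at p < 0.05.

``run_report`` drives the full pipeline on a set of lipidome samples:
composition summaries (class mol%, within-class FA mol%, PC/PE ratio), the
lipid SCE-stress estimate tau per sample, the P_SCE proxy per sample, and
per-time-point mean ± SD tables with ANOVA annotations, all with the exact
parameter sets embedded for provenance.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import LipidClass, LipidomeSample, check_unique_samples
from .curvature import CurvatureParams, SceVariant, DEFAULT_VARIANT, mix_c0
from .psce import PsceParams, psce
from .quantify import class_mol_percent, fa_mol_percent, pc_pe_ratio


@dataclass
class GroupSeries:
    """Labelled groups of replicate measurements of one metric."""

    groups: dict[str, np.ndarray]
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}

    def require(self, min_groups: int = 2, min_per_group: int = 2) -> None:
        if len(self.groups) < min_groups:
            raise ValueError(
                f"{self.metric or 'series'}: need >= {min_groups} groups, "
                f"got {len(self.groups)}"
            )
        for label, vals in self.groups.items():
            if len(vals) < min_per_group:
                raise ValueError(
                    f"group {label!r} has {len(vals)} values; need >= {min_per_group}"
                )


def significance_tier(p: float) -> str:
    """Star convention: significance at p < 0.05."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaResult:
    omnibus_p: float
    omnibus_F: float
    pairwise: dict[tuple[str, str], float]  # Bonferroni-adjusted p
    pairwise_raw: dict[tuple[str, str], float]
    tiers: dict[tuple[str, str], str]


def one_way_anova_bonferroni(series: GroupSeries) -> AnovaResult:
    """Omnibus one-way ANOVA plus all pairwise pooled-t comparisons with
    Bonferroni adjustment (adjusted p = min(1, raw p * number of pairs);
    a single pair receives no correction)."""
    series.require()
    labels = list(series.groups)
    F, p = sps.f_oneway(*(series.groups[l] for l in labels))
    if np.isnan(F):  # zero within- and between-group variance
        F, p = 0.0, 1.0
    pairs = list(itertools.combinations(labels, 2))
    k = len(pairs)
    raw: dict[tuple[str, str], float] = {}
    adj: dict[tuple[str, str], float] = {}
    tiers: dict[tuple[str, str], str] = {}
    for a, b in pairs:
        res = sps.ttest_ind(series.groups[a], series.groups[b], equal_var=True)
        pr = float(res.pvalue)
        if np.isnan(pr):
            pr = 1.0
        raw[(a, b)] = pr
        adj[(a, b)] = min(1.0, pr * k) if k > 1 else pr
        tiers[(a, b)] = significance_tier(adj[(a, b)])
    return AnovaResult(float(p) if not np.isnan(p) else 1.0, float(F), adj, raw, tiers)


def two_tailed_t(series: GroupSeries) -> tuple[float, float]:
    """Two-tailed pooled-variance Student's t test on exactly two groups;
    returns ``(p, mean difference first - second)``."""
    series.require(min_groups=2)
    if len(series.groups) != 2:
        raise ValueError(f"t test needs exactly 2 groups, got {len(series.groups)}")
    (la, va), (lb, vb) = series.groups.items()
    res = sps.ttest_ind(va, vb, equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return p, float(np.mean(va) - np.mean(vb))


# ---------------------------------------------------------------------------
# end-to-end report


@dataclass
class Report:
    class_composition: pd.DataFrame  # mean/sd of class mol% per (condition, time)
    fa_composition: pd.DataFrame     # mean/sd of within-class FA mol%
    metrics: pd.DataFrame            # per-sample pc_pe_ratio, tau, p_sce
    metric_summary: pd.DataFrame     # mean/sd per (condition, time) + CV across times
    anova: dict[str, AnovaResult]    # metric -> ANOVA across time points
    provenance: dict

    def write(self, outdir: Union[str, Path]) -> None:
        """Write delimited tables plus a provenance record."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.class_composition.to_csv(outdir / "class_composition.csv", index=False)
        self.fa_composition.to_csv(outdir / "fa_composition.csv", index=False)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        self.metric_summary.to_csv(outdir / "metric_summary.csv", index=False)
        anova_rows = []
        for metric, res in self.anova.items():
            for (a, b), padj in res.pairwise.items():
                anova_rows.append(
                    dict(metric=metric, group_a=a, group_b=b,
                         omnibus_p=res.omnibus_p, p_raw=res.pairwise_raw[(a, b)],
                         p_bonferroni=padj, tier=res.tiers[(a, b)])
                )
        pd.DataFrame(anova_rows).to_csv(outdir / "anova.csv", index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True, default=str)
        )


def run_report(
    samples: Sequence[LipidomeSample],
    curvature_params: CurvatureParams,
    psce_params: PsceParams,
    variant: SceVariant = DEFAULT_VARIANT,
    fa_classes: Sequence[LipidClass] = (LipidClass.PC, LipidClass.PE, LipidClass.PS),
) -> Report:
    """Compute composition summaries, tau and P_SCE for every sample and
    aggregate them per (condition, time point) as mean ± SD.

    ANOVA across time points (one per condition and metric, Bonferroni over
    all pairwise time comparisons) is reported when every group carries at
    least two replicates; with single samples the statistics section is
    left empty.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")
    check_unique_samples(samples)

    comp_rows, fa_rows, metric_rows = [], [], []
    for s in samples:
        for cls, pct in class_mol_percent(s).items():
            comp_rows.append(dict(condition=s.condition, time_h=s.time_h,
                                  replicate=s.replicate, lipid_class=cls.value,
                                  mol_pct=pct))
        for cls in fa_classes:
            try:
                for comp, pct in fa_mol_percent(s, cls).items():
                    fa_rows.append(dict(condition=s.condition, time_h=s.time_h,
                                        replicate=s.replicate, lipid_class=cls.value,
                                        sum_composition=comp, mol_pct=pct))
            except ValueError:
                pass  # class absent in this sample
        tau = mix_c0(s, curvature_params, variant)
        ps = psce(s, psce_params)
        metric_rows.append(dict(condition=s.condition, time_h=s.time_h,
                                replicate=s.replicate,
                                pc_pe_ratio=pc_pe_ratio(s),
                                tau_N=tau.tau, c0_mix_per_m=tau.c0_mix,
                                p_sce=ps.p_sce))

    comp = pd.DataFrame(comp_rows)
    class_composition = (
        comp.groupby(["condition", "time_h", "lipid_class"])["mol_pct"]
        .agg(["mean", "std"]).reset_index()
    )
    fa = pd.DataFrame(fa_rows)
    fa_composition = (
        fa.groupby(["condition", "time_h", "lipid_class", "sum_composition"])["mol_pct"]
        .agg(["mean", "std"]).reset_index()
        if len(fa) else pd.DataFrame(
            columns=["condition", "time_h", "lipid_class", "sum_composition", "mean", "std"])
    )
    metrics = pd.DataFrame(metric_rows)
    summary = (
        metrics.groupby(["condition", "time_h"])[["pc_pe_ratio", "tau_N", "p_sce"]]
        .agg(["mean", "std"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    metric_summary = summary.reset_index()

    anova: dict[str, AnovaResult] = {}
    for cond, grp in metrics.groupby("condition"):
        counts = grp.groupby("time_h").size()
        if len(counts) >= 2 and (counts >= 2).all():
            for metric in ("pc_pe_ratio", "tau_N", "p_sce"):
                series = GroupSeries(
                    {f"t={t:g}h": g[metric].to_numpy()
                     for t, g in grp.groupby("time_h")},
                    metric=metric,
                )
                anova[f"{cond}:{metric}"] = one_way_anova_bonferroni(series)

    provenance = dict(
        n_samples=len(samples),
        conditions=sorted({s.condition for s in samples}),
        time_points=sorted({s.time_h for s in samples}),
        tau_variant=dict(name=variant.name,
                         included_classes=sorted(c.value for c in variant.included_classes),
                         allow_speculative_c0=variant.allow_speculative_c0),
        k_m_J=curvature_params.k_m,
        psce=dict(
            pivot=str(psce_params.pivot_species),
            pivot_w=psce_params.pivot_w,
            included_classes=sorted(c.value for c in psce_params.included_classes),
            denominator_mode=psce_params.denominator_mode,
            head_terms={c.value: h for c, h in psce_params.w_model.head_terms.items()},
            unsat_increment=psce_params.w_model.unsat_increment,
        ),
    )
    return Report(class_composition, fa_composition, metrics, metric_summary,
                  anova, provenance)


def plot_report(report: Report, outdir: Union[str, Path]) -> list[Path]:
    """Static summary plots (class composition, tau and P_SCE time courses)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(7, 4))
    for cls, grp in report.class_composition.groupby("lipid_class"):
        g = grp.sort_values("time_h")
        ax.errorbar(g["time_h"], g["mean"], yerr=g["std"], marker="o", label=cls)
    ax.set_xlabel("time after choline (h)")
    ax.set_ylabel("mol% total lipid")
    ax.legend(fontsize=8, ncol=2)
    path = outdir / "class_composition.png"
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)
    written.append(path)

    for metric, label in (("tau_N", "lipid SCE stress tau (N)"),
                          ("p_sce", "P_SCE"), ("pc_pe_ratio", "PC/PE ratio")):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for cond, grp in report.metric_summary.groupby("condition"):
            g = grp.sort_values("time_h")
            ax.errorbar(g["time_h"], g[f"{metric}_mean"], yerr=g[f"{metric}_std"],
                        marker="o", label=cond)
        ax.set_xlabel("time after choline (h)")
        ax.set_ylabel(label)
        ax.legend(fontsize=8)
        path = outdir / f"{metric}.png"
        fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)
        written.append(path)
    return written
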