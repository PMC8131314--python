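"""Assemble and export the personalized report.

A report always starts with the basic (descriptive) sections; dynamic
networks are added for every enumerated variable subset, filtered by the
relevance rule.  Networks whose filter leaves no between-variable edge are
kept only in a technical appendix, mirroring how a clinician-facing report
omits empty graphs but the analyst retains them.

Export is deterministic: the report JSON is byte-identical across reruns
with the same inputs and seeds (no wall-clock timestamps unless supplied).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .basic_report import (
    CategoryDependency,
    GriddedSeries,
    TimeProfiles,
    TrendDecomposition,
    categorical_dependency,
    lowpass_trend,
    time_profiles,
    to_equidistant_grid,
)
from .compliance import ComplianceSummary, compute_compliance
from .dynamic_network import (
    NetworkModel,
    RelevanceCriteria,
    enumerate_models,
    estimate_network,
    relevance_filter,
)
from .ema_design import design_to_dict, format_clock
from .errors import (
    CollinearityError,
    EmadynError,
    ExportError,
    InadequateDataError,
    InsufficientDataError,
)
from .synthetic_cohort import EmaDataset

__all__ = ["PersonalizedReport", "assemble_report", "export_report", "edge_sentence"]

CAUSALITY_CAVEAT = "this pattern suggests, but does not prove, causality"


def edge_sentence(edge_dict: dict) -> str:
    """Human-readable hypothesis sentence for one network edge."""
    est = edge_dict["estimate"]
    direction = "more" if est >= 0 else "less"
    if edge_dict["type"] == "lagged":
        return (
            f"hypothesis: {direction} {edge_dict['target']} follows "
            f"{edge_dict['source']} (standardized beta = {est:+.2f}, "
            f"p = {edge_dict['p']:.3f}); {CAUSALITY_CAVEAT}"
        )
    return (
        f"hypothesis: {edge_dict['a']} and {edge_dict['b']} move together "
        f"{'in the same direction' if est >= 0 else 'in opposite directions'} "
        f"(partial correlation = {est:+.2f}, p = {edge_dict['p']:.3f}); "
        f"{CAUSALITY_CAVEAT}"
    )


@dataclass
class BasicSection:
    variable: str
    series: GriddedSeries
    trend: TrendDecomposition
    profiles: TimeProfiles
    categories: list[CategoryDependency] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _round(a):
            return [None if np.isnan(v) else round(float(v), 6) for v in np.asarray(a, float)]

        return {
            "variable": self.variable,
            "values": _round(self.series.values),
            "trend": _round(self.trend.trend),
            "day_index": [int(d) for d in self.series.day_index],
            "clock_time": [format_clock(int(m)) for m in self.series.clock_minutes],
            "missing_fraction": round(self.series.missing_fraction, 6),
            "hour_profile": [
                {"clock_time": format_clock(int(r.clock_minutes)), "mean": round(float(r.mean), 6), "n": int(r.n)}
                for r in self.profiles.hour.itertuples()
            ],
            "weekday_profile": [
                {
                    "weekday": int(r.weekday),
                    "mean": None if np.isnan(r.mean) else round(float(r.mean), 6),
                    "n": int(r.n),
                }
                for r in self.profiles.weekday.itertuples()
            ],
            "category_profiles": [
                {
                    "context": c.context,
                    "levels": [
                        {
                            "level": int(r.level),
                            "mean": round(float(r.mean), 6),
                            "n": int(r.n),
                            "low_support": bool(r.low_support),
                        }
                        for r in c.table.itertuples()
                    ],
                }
                for c in self.categories
            ],
        }


@dataclass
class PersonalizedReport:
    subject_id: str
    compliance: ComplianceSummary
    basic_sections: list[BasicSection]
    networks: list[NetworkModel]  # filtered, with >=1 surviving between-variable edge
    appendix: list[dict]  # every attempted model: unfiltered edges or skip reason
    sentences: list[str]
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "compliance": self.compliance.to_dict(),
            "basic_sections": [s.to_dict() for s in self.basic_sections],
            "networks": [m.to_dict() for m in self.networks],
            "technical_appendix": self.appendix,
            "sentences": self.sentences,
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=False)


def _config_hash(dataset: EmaDataset, criteria: RelevanceCriteria, window_days: float) -> str:
    payload = json.dumps(
        {
            "design": design_to_dict(dataset.design),
            "alpha": criteria.alpha,
            "beta_min": criteria.beta_min,
            "window_days": window_days,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def assemble_report(
    dataset: EmaDataset,
    criteria: RelevanceCriteria | None = None,
    override_adequacy: bool = False,
    window_days: float = 3.0,
    focal: str | None = None,
    manual_drop: set[str] | None = None,
    min_pairs_per_predictor: int = 10,
    min_occasions: int = 30,
    timestamp: str | None = None,
) -> PersonalizedReport:
    """Run compliance -> basic report -> dynamic networks -> relevance filter.

    An inadequate dataset raises unless ``override_adequacy`` is set; the
    basic sections are still produced under the override even when no
    network model can be fit.
    """
    if len(dataset.records) == 0:
        raise EmadynError("dataset has no answered records")
    criteria = criteria or RelevanceCriteria()
    summary = compute_compliance(dataset)
    if not summary.adequate and not override_adequacy:
        raise InadequateDataError(
            f"dataset fails the measurement-adequacy rule (at least 50 answered "
            f"measurements and 3 per day required; got {summary.n_answered} answered, "
            f"{summary.mean_answered_per_day:.2f}/day). Pass override_adequacy=True "
            f"to produce a basic-only report."
        )

    answered_items = set(dataset.records["item_id"].unique())
    continuous = [
        it.item_id
        for it in dataset.design.items
        if it.scale == "vas" and it.item_id in answered_items
    ]
    categorical = [
        it.item_id
        for it in dataset.design.items
        if it.scale == "categorical" and it.item_id in answered_items
    ]

    sections: list[BasicSection] = []
    grids: dict[str, GriddedSeries] = {}
    for var in continuous:
        series = to_equidistant_grid(dataset, var)
        grids[var] = series
        trend = lowpass_trend(series, window_days=window_days)
        profiles = time_profiles(series)
        cats = []
        for ctx in categorical:
            ctx_series = grids.get(ctx) or to_equidistant_grid(dataset, ctx)
            grids[ctx] = ctx_series
            try:
                cats.append(categorical_dependency(series, ctx_series))
            except InsufficientDataError:
                pass
        sections.append(BasicSection(var, series, trend, profiles, cats))

    networks: list[NetworkModel] = []
    appendix: list[dict] = []
    sentences: list[str] = []
    if len(continuous) >= 2:
        focal = focal or ("fatigue" if "fatigue" in continuous else continuous[0])
        for subset in enumerate_models(continuous, focal=focal):
            entry: dict = {"variables": list(subset)}
            try:
                model = estimate_network(
                    dataset,
                    subset,
                    window_days=window_days,
                    min_pairs_per_predictor=min_pairs_per_predictor,
                    min_occasions=min_occasions,
                )
            except (InsufficientDataError, CollinearityError) as exc:
                entry["status"] = type(exc).__name__
                entry["detail"] = str(exc)
                appendix.append(entry)
                continue
            entry["status"] = "fitted"
            entry["model"] = model.to_dict()
            appendix.append(entry)
            kept = relevance_filter(model, criteria, manual_drop=manual_drop)
            shown = replace_display(kept)
            if shown.lagged_edges or shown.contemporaneous_edges:
                networks.append(shown)
                for edge in shown.to_dict()["edges"]:
                    sentences.append(edge_sentence(edge))

    metadata = {
        "package_version": __version__,
        "config_hash": _config_hash(dataset, criteria, window_days),
        "alpha": criteria.alpha,
        "beta_min": criteria.beta_min,
        "window_days": window_days,
        "seeds": {k: v for k, v in dataset.meta.items() if "seed" in k},
        "timestamp": timestamp,
        "override_adequacy": override_adequacy,
    }
    return PersonalizedReport(
        subject_id=dataset.subject_id,
        compliance=summary,
        basic_sections=sections,
        networks=networks,
        appendix=appendix,
        sentences=sentences,
        metadata=metadata,
    )


def replace_display(model: NetworkModel) -> NetworkModel:
    """Patient-facing view of a filtered model: between-variable edges only
    (autoregressive self-loops live in the technical appendix)."""
    from dataclasses import replace

    return replace(model, lagged_edges=model.cross_lagged_edges())


VALID_FORMATS = ("json", "dot", "png", "svg")


def export_report(report: PersonalizedReport, out_dir, formats=("json", "dot", "png")) -> list[Path]:
    """Write the report to ``out_dir``; returns the written paths.

    ``formats`` tokens: json (full report), dot (one graph per network),
    png/svg (basic-report graphs and rendered networks).  A manifest JSON
    lists every file.
    """
    for fmt in formats:
        if fmt not in VALID_FORMATS:
            raise ExportError(f"unknown format token {fmt!r}; valid: {VALID_FORMATS}")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ExportError(f"cannot create output directory {out}: {exc}") from exc

    written: list[Path] = []
    if "json" in formats:
        path = out / "report.json"
        path.write_text(report.to_json())
        written.append(path)
    if "dot" in formats:
        for i, model in enumerate(report.networks, start=1):
            path = out / f"network_{i}.dot"
            path.write_text(model.to_dot(name=f"network_{i}"))
            written.append(path)
    image_formats = [f for f in formats if f in ("png", "svg")]
    for fmt in image_formats:
        written.extend(_render_plots(report, out, fmt))

    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps(
            {"subject_id": report.subject_id, "files": sorted(p.name for p in written)},
            indent=2,
            sort_keys=True,
        )
    )
    written.append(manifest)
    return written


def _render_plots(report: PersonalizedReport, out: Path, fmt: str) -> list[Path]:
    # Figure objects straight from the object-oriented API: no pyplot
    # global state, safe in headless use.
    from matplotlib.figure import Figure

    import networkx as nx

    written = []
    for section in report.basic_sections:
        var = section.variable
        x = np.arange(len(section.series.values)) / section.series.per_day_count

        fig = Figure(figsize=(8, 3))
        ax = fig.add_subplot(111)
        ax.plot(x, section.series.values, ".", ms=3, alpha=0.6, label="observed")
        ax.plot(x, section.trend.trend, "-", lw=2, label="low-pass trend")
        ax.set_xlabel("study day")
        ax.set_ylabel(var)
        ax.legend(loc="best", fontsize=8)
        path = out / f"{var}_series_trend.{fmt}"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        written.append(path)

        fig = Figure(figsize=(4, 3))
        ax = fig.add_subplot(111)
        hour = section.profiles.hour
        ax.bar([format_clock(int(m)) for m in hour["clock_minutes"]], hour["mean"])
        ax.set_xlabel("prompt time")
        ax.set_ylabel(f"mean {var}")
        path = out / f"{var}_hour_profile.{fmt}"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        written.append(path)

        fig = Figure(figsize=(4, 3))
        ax = fig.add_subplot(111)
        wk = section.profiles.weekday
        labels = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
        ax.bar(labels, wk["mean"].fillna(0.0))
        ax.set_xlabel("weekday")
        ax.set_ylabel(f"mean {var}")
        path = out / f"{var}_weekday_profile.{fmt}"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        written.append(path)

        for cat in section.categories:
            fig = Figure(figsize=(4, 3))
            ax = fig.add_subplot(111)
            ax.bar([str(level) for level in cat.table["level"]], cat.table["mean"])
            ax.set_xlabel(f"{cat.context} level")
            ax.set_ylabel(f"mean {var}")
            path = out / f"{var}_by_{cat.context}.{fmt}"
            fig.savefig(path, dpi=100, bbox_inches="tight")
            written.append(path)

    for i, model in enumerate(report.networks, start=1):
        g = nx.DiGraph()
        g.add_nodes_from(model.variables)
        pos = nx.circular_layout(g)
        fig = Figure(figsize=(4, 4))
        ax = fig.add_subplot(111)
        nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#dddddd", node_size=2200)
        nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
        for e in model.lagged_edges:
            nx.draw_networkx_edges(
                g,
                pos,
                edgelist=[(e.source, e.target)],
                ax=ax,
                edge_color="black" if e.beta >= 0 else "red",
                connectionstyle="arc3,rad=0.15",
                arrows=True,
                node_size=2200,
            )
        for e in model.contemporaneous_edges:
            nx.draw_networkx_edges(
                g,
                pos,
                edgelist=[(e.a, e.b)],
                ax=ax,
                edge_color="black" if e.r >= 0 else "red",
                style="dashed",
                arrows=False,
                node_size=2200,
            )
        ax.set_axis_off()
        path = out / f"network_{i}.{fmt}"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        written.append(path)
    return written
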