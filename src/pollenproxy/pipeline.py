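"""Config-driven end-to-end runs: read/simulate → match → screen → analyse.

A run takes either CSV inputs (pollen series, search series, metadata) or a
synthetic panel spec, then applies the full chain — station–region matching,
quality screening, correlation with quartile stratification, onset
discrepancy analysis — and writes one CSV per stage plus a human-readable
report.  Every output carries the config hash so a run can be audited and
reproduced; identical config + seed reproduces outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .association import (
    AssociationResult,
    associate_pair,
    quartile_stratify,
)
from .preprocess import TransformConfig, restrict_window
from .quality import QualityReport, QualityThresholds, apply_inclusion, first_data_day
from .season import (
    SiteYearOnset,
    StartDefinition,
    discrepancy_analysis,
)
from .series import RegionYear, StationYear
from .synthetic import (
    MissingnessParams,
    PanelSpec,
    PollenModelParams,
    SearchModelParams,
    generate_panel,
)

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "make_report", "load_config"]

log = logging.getLogger("pollenproxy")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``synthetic`` or (``pollen_csv``, ``search_csv``) must be
    set.  Thresholds and transforms default to the study's operating values.
    """

    synthetic: PanelSpec | None = None
    pollen_csv: str | None = None
    search_csv: str | None = None
    station_meta_csv: str | None = None
    region_meta_csv: str | None = None
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    transform: TransformConfig = field(default_factory=TransformConfig)
    start_definition: StartDefinition = field(
        default_factory=lambda: StartDefinition.cumulative(0.05)
    )
    max_delta_deg: float = 0.3
    censored_zeros_as_missing: bool = True
    outdir: str = "pollenproxy_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.pollen_csv is not None and self.search_csv is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError(
                "exactly one of {synthetic spec, pollen+search CSV paths} "
                "must be provided"
            )

    def config_hash(self) -> str:
        plain = _as_plain(self)
        plain.pop("outdir", None)  # artifact location, not part of the science
        payload = json.dumps(plain, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    return obj


def load_config(path) -> RunConfig:
    """Build a RunConfig from a nested YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "synthetic" in raw:
        synth = dict(raw["synthetic"])
        for key, cls in (
            ("pollen", PollenModelParams),
            ("search", SearchModelParams),
            ("missingness", MissingnessParams),
        ):
            if key in synth:
                params = dict(synth[key])
                if "edge_gap_days" in params:
                    params["edge_gap_days"] = tuple(params["edge_gap_days"])
                synth[key] = cls(**params)
        kwargs["synthetic"] = PanelSpec(**synth)
    for key in (
        "pollen_csv", "search_csv", "station_meta_csv", "region_meta_csv",
        "max_delta_deg", "censored_zeros_as_missing", "outdir", "seed",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "thresholds" in raw:
        kwargs["thresholds"] = QualityThresholds(**raw["thresholds"])
    if "transform" in raw:
        t = dict(raw["transform"])
        if t.get("window") is not None:
            t["window"] = tuple(t["window"])
        kwargs["transform"] = TransformConfig(**t)
    if "start_definition" in raw:
        kwargs["start_definition"] = StartDefinition(**raw["start_definition"])
    return RunConfig(**kwargs)


@dataclass
class RunSummary:
    config_hash: str
    n_read: int
    n_matched: int
    n_unmatched: int
    n_included: int
    n_excluded: int
    exclusions_by_reason: dict[str, int]
    quartile_summaries: dict
    tier_summaries: dict
    manifest: list[str]
    outdir: str


def _load_panel(config: RunConfig) -> tuple[list[StationYear], list[RegionYear]]:
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        pairs = generate_panel(spec)
        return [s for s, _ in pairs], [r for _, r in pairs]
    station_meta = (
        pio.read_metadata_csv(config.station_meta_csv)
        if config.station_meta_csv
        else None
    )
    region_meta = (
        pio.read_metadata_csv(config.region_meta_csv)
        if config.region_meta_csv
        else None
    )
    stations = pio.read_series_csv(config.pollen_csv, "pollen_grains_per_m3",
                                   station_meta)
    regions = pio.read_series_csv(config.search_csv, "search_volume_0_100",
                                  region_meta)
    return stations, regions


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute every stage and write stage outputs under ``config.outdir``.

    Stage counts are conserved: every station-year read is either matched or
    unmatched; every matched one is either included or excluded.  An empty
    post-filter panel exits gracefully with a reason in the summary report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: list[str] = []

    stations, regions = _load_panel(config)
    by_station = {s.station_id: s for s in stations}
    by_region = {r.dma_id: r for r in regions}
    match = pio.match_station_to_region(stations, regions, config.max_delta_deg)
    log.info("matched %d of %d station-years", len(match.pairs), len(stations))

    # --- quality screening (station side) -------------------------------
    reports: list[tuple[str, str, QualityReport]] = []
    for station_id, dma_id in match.pairs:
        station = by_station[station_id]
        report = apply_inclusion(
            station.series,
            config.thresholds,
            config.transform.window_for(station.series.year),
            site_year_id=station.site_year_id,
        )
        if not report.included:
            log.info("excluded %s: %s", station.site_year_id,
                     ",".join(report.exclusion_reasons))
        reports.append((station_id, dma_id, report))

    reason_counts: dict[str, int] = {}
    for _, _, report in reports:
        for reason in report.exclusion_reasons:
            reason_counts[reason] = reason_counts.get(reason, 0) + 1
    included = [(s, d, r) for s, d, r in reports if r.included]

    quality_frame = pd.DataFrame(
        [
            {
                "site_year_id": r.site_year_id,
                "dma_id": d,
                "pct_missing_days": r.pct_missing_days,
                "longest_gap_days": r.longest_gap_days,
                "first_data_day": r.first_data_day,
                "first_high_day": r.first_high_day,
                "gap_near_first_high_days": r.gap_near_first_high_days,
                "included": r.included,
                "exclusion_reasons": ";".join(r.exclusion_reasons),
                "config_hash": chash,
            }
            for _, d, r in reports
        ]
    )
    path = outdir / "quality_reports.csv"
    quality_frame.to_csv(path, index=False)
    manifest.append(str(path))

    quartile_summaries: dict = {}
    tier_summaries: dict = {}
    if included:
        # --- association -------------------------------------------------
        results: list[AssociationResult] = []
        for station_id, dma_id, _ in included:
            results.append(
                associate_pair(
                    by_station[station_id],
                    by_region[dma_id],
                    config.transform,
                    config.censored_zeros_as_missing,
                )
            )
        for by in ("pct_gt_zero_days", "peak_snr"):
            try:
                results, summary = quartile_stratify(results, by)
            except ValueError as err:
                log.warning("quartile stratification by %s skipped: %s", by, err)
                continue
            quartile_summaries[by] = summary
            frame = pd.DataFrame(
                [
                    {
                        "quartile": q,
                        "rho_median": m,
                        "rho_q1": lo,
                        "rho_q3": hi,
                        "cutoff_25": summary.cutoffs[0],
                        "cutoff_50": summary.cutoffs[1],
                        "cutoff_75": summary.cutoffs[2],
                        "config_hash": chash,
                    }
                    for q, (m, lo, hi) in sorted(summary.rho_median_iqr.items())
                ]
            )
            path = outdir / f"quartiles_{by}.csv"
            frame.to_csv(path, index=False)
            manifest.append(str(path))

        association_frame = pd.DataFrame(
            [
                {
                    "site_year_id": r.site_year_id,
                    "rho": r.rho,
                    "n_days": r.n_days,
                    "pct_gt_zero_days": r.pct_gt_zero_days,
                    "pct_gt_missing_days": r.pct_gt_missing_days,
                    "peak_snr": r.peak_snr,
                    "quartile_by_missing": r.quartile_by_missing,
                    "quartile_by_snr": r.quartile_by_snr,
                    "flags": ";".join(r.flags),
                    "config_hash": chash,
                }
                for r in results
            ]
        )
        path = outdir / "association.csv"
        association_frame.to_csv(path, index=False)
        manifest.append(str(path))

        # --- onset discrepancies -----------------------------------------
        site_years = []
        for station_id, dma_id, report in included:
            station = by_station[station_id]
            region = by_region[dma_id]
            window = config.transform.window_for(station.series.year)
            searched = restrict_window(region.averaged, window)
            sv = searched.window_values
            pct_zero = 100.0 * float(np.sum(sv == 0)) / sv.size
            site_years.append(
                SiteYearOnset(
                    site_year_id=f"{station_id}|{dma_id}:{station.series.year}",
                    pollen=station.series,
                    search=region.averaged,
                    gt_pct_missing=pct_zero,
                    nab_first_data_day=report.first_data_day,
                )
            )
        records, tiers = discrepancy_analysis(
            site_years, config.start_definition, config.transform
        )
        tier_summaries = tiers
        onset_frame = pd.DataFrame(
            [
                {
                    "site_year_id": r.site_year_id,
                    "variant": r.variant,
                    "gt_start": r.gt_start,
                    "nab_start": r.nab_start,
                    "delta_days": r.delta_days,
                    "prev_year_delta_days": r.prev_year_delta_days,
                    "config_hash": chash,
                }
                for r in records
            ]
        )
        path = outdir / "onset_discrepancies.csv"
        onset_frame.to_csv(path, index=False)
        manifest.append(str(path))
    else:
        log.warning("no matched site-years passed the quality screen")

    summary = RunSummary(
        config_hash=chash,
        n_read=len(stations),
        n_matched=len(match.pairs),
        n_unmatched=len(match.unmatched_stations),
        n_included=len(included),
        n_excluded=len(reports) - len(included),
        exclusions_by_reason=reason_counts,
        quartile_summaries=quartile_summaries,
        tier_summaries=tier_summaries,
        manifest=manifest,
        outdir=str(outdir),
    )
    report_path = outdir / "report.md"
    report_path.write_text(make_report(summary))
    summary.manifest.append(str(report_path))
    return summary


def _fmt(value: float) -> str:
    return "—" if value is None or (isinstance(value, float) and np.isnan(value)) \
        else f"{value:.2f}"


def make_report(summary: RunSummary) -> str:
    """Render a run summary as markdown tables."""
    lines = [
        "# Search-vs-pollen proxy validation run",
        "",
        f"Config hash: `{summary.config_hash}`",
        "",
        "## Stage counts",
        "",
        f"- station-years read: {summary.n_read}",
        f"- matched to a search region: {summary.n_matched} "
        f"(unmatched: {summary.n_unmatched})",
        f"- passed quality screen: {summary.n_included} "
        f"(excluded: {summary.n_excluded})",
    ]
    for reason, count in sorted(summary.exclusions_by_reason.items()):
        lines.append(f"  - excluded for {reason}: {count}")
    for by, qs in summary.quartile_summaries.items():
        lines += [
            "",
            f"## Correlation by quartile of {by}",
            "",
            f"Cutoffs: {', '.join(f'{c:.2f}' for c in qs.cutoffs)}",
            "",
            "| quartile | median rho | IQR |",
            "|---|---|---|",
        ]
        for q, (med, lo, hi) in sorted(qs.rho_median_iqr.items()):
            lines.append(f"| Q{q} | {_fmt(med)} | ({_fmt(lo)}, {_fmt(hi)}) |")
    if summary.tier_summaries:
        lines += [
            "",
            "## Onset discrepancy (search start − station start, days)",
            "",
            "| tier | n | variant | median delta | IQR |",
            "|---|---|---|---|---|",
        ]
        for tier, ts in summary.tier_summaries.items():
            for variant, (med, lo, hi) in ts.delta_median_iqr.items():
                lines.append(
                    f"| {tier} | {ts.n} | {variant} | {_fmt(med)} "
                    f"| ({_fmt(lo)}, {_fmt(hi)}) |"
                )
    lines.append("")
    return "\n".join(lines)
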