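"""Pipeline orchestration: classify -> spatial -> conserve -> report.

A run is driven by a JSON config that either points at spot/response-log
CSVs or embeds a synthetic-generation block; outputs are a machine-readable
``results.json`` plus three TSV report tables (categories, spatial,
conservation) and a human-readable text summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classification import (
    CategorySummary,
    classify_table,
    read_response_logs,
    summarize_categories,
)
from .conservation import ConservationResult, match_spots
from .spatial_stats import (
    ADResult,
    ClarkEvansResult,
    InsufficientSampleError,
    PointPattern,
    ad_uniform,
    clark_evans,
    segment_counts,
    segment_totals,
)
from .spot_model import SpotTable, StudyRegion, read_spot_table, write_spot_table
from .synthetic import SynthConfig, gen_sessions

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "render_report"]


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of (``spot_csv``), (``simulate``) must be set. The
    exclusion rule ``exclusion_min_n`` applies only to the uniformity test:
    participants with fewer confirmed spots are excluded from it (their
    aggregation index is still computed when n >= 2).
    """

    region: StudyRegion = field(default_factory=StudyRegion)
    spot_csv: str | None = None
    response_log_csv: str | None = None
    simulate: SynthConfig | None = None
    threshold_px: float = 6.0
    ad_lower: float = 0.0
    ad_upper: float | None = None  # defaults to region length
    exclusion_min_n: int = 10
    conservation_convention: str = "component"
    seed: int = 0
    n_mc: int = 10_000

    def __post_init__(self) -> None:
        if (self.spot_csv is None) == (self.simulate is None):
            raise ValueError(
                "config must set exactly one of spot_csv / simulate"
            )
        if self.ad_upper is None:
            self.ad_upper = self.region.length_px

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        region = StudyRegion.from_dict(d.pop("region", {}))
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = SynthConfig.from_dict({"region": region, **sim})
        return cls(region=region, simulate=sim, **d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        payload = {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """Everything a run computes, traceable to the rendered report."""

    summary: CategorySummary
    ad_results: dict[str, ADResult]
    ad_excluded: dict[str, int]  # participant -> n below the exclusion cutoff
    ce_results: dict[str, ClarkEvansResult]
    segment_counts: dict[tuple[str, int], int]
    segment_totals: dict[int, int]
    conservation: ConservationResult
    config_digest: str
    seed: int
    version: str = __version__


def _load_table(config: RunConfig) -> SpotTable:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        table, _, _ = gen_sessions(sim)
        return table
    table = read_spot_table(config.spot_csv, config.region)
    if config.response_log_csv:
        logs = read_response_logs(config.response_log_csv)
        table = classify_table(table, logs)
    return table


def run_pipeline(config: RunConfig, outdir=None) -> ResultsBundle:
    """Execute the full analysis; optionally write results under ``outdir``.

    Deterministic for a given (config, seed): the Monte-Carlo p-values and
    any simulated inputs all derive from ``config.seed``.
    """
    table = _load_table(config)
    summary = summarize_categories(table)

    confirmed = table.confirmed()
    ad_results: dict[str, ADResult] = {}
    ad_excluded: dict[str, int] = {}
    ce_results: dict[str, ClarkEvansResult] = {}
    for k, pid in enumerate(confirmed.participants()):
        pat = PointPattern.from_table(table, pid)
        if pat.n < config.exclusion_min_n:
            ad_excluded[pid] = pat.n
        else:
            ad_results[pid] = ad_uniform(
                pat.points[:, 0],
                config.ad_lower,
                config.ad_upper,
                n_mc=config.n_mc,
                rng=[config.seed & 0x7FFFFFFF, 23, k],
            )
        if pat.n >= 2:
            ce_results[pid] = clark_evans(pat, correction="donnelly")

    seg = segment_counts(confirmed)
    conservation = match_spots(
        table, config.threshold_px, convention=config.conservation_convention
    )

    bundle = ResultsBundle(
        summary=summary,
        ad_results=ad_results,
        ad_excluded=ad_excluded,
        ce_results=ce_results,
        segment_counts=seg,
        segment_totals=segment_totals(seg),
        conservation=conservation,
        config_digest=config.digest(),
        seed=config.seed,
    )
    if outdir is not None:
        _write_outputs(bundle, table, Path(outdir))
    return bundle


def bundle_to_dict(bundle: ResultsBundle) -> dict:
    s = bundle.summary
    cons = bundle.conservation
    return {
        "provenance": {
            "config_digest": bundle.config_digest,
            "seed": bundle.seed,
            "version": bundle.version,
        },
        "categories": {
            "counts": s.counts,
            "percents_of_confirmed": s.percents,
            "per_participant_mean_sd": {
                c: list(v) for c, v in s.per_participant_mean_sd.items()
            },
            "n_confirmed": s.n_confirmed,
            "n_total": s.n_total,
            "unconfirmed_rate_percent": s.unconfirmed_rate_percent,
        },
        "spatial": {
            "anderson_darling": {
                p: dataclasses.asdict(r) for p, r in bundle.ad_results.items()
            },
            "anderson_darling_excluded": bundle.ad_excluded,
            "clark_evans": {
                p: dataclasses.asdict(r) for p, r in bundle.ce_results.items()
            },
            "segment_totals": bundle.segment_totals,
            "segment_counts": [
                {"participant_id": p, "segment": k, "count": c}
                for (p, k), c in bundle.segment_counts.items()
            ],
        },
        "conservation": {
            "n_confirmed": cons.n_confirmed,
            "n_conserved": cons.n_conserved,
            "n_conserved_component": cons.n_conserved_component,
            "n_conserved_reidentified": cons.n_conserved_reidentified,
            "conservation_rate_percent": cons.conservation_rate,
            "max_chain_length": cons.max_chain_length,
            "max_sessions_spanned": cons.max_sessions_spanned,
            "n_category_agree": cons.n_category_agree,
            "threshold_px": cons.threshold_px,
            "convention": cons.convention,
            "n_pairs": len(cons.pairs),
        },
    }


def _write_outputs(bundle: ResultsBundle, table: SpotTable, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "results.json", "w", encoding="utf-8") as fh:
        json.dump(bundle_to_dict(bundle), fh, indent=2, sort_keys=True)
        fh.write("\n")

    s = bundle.summary
    with open(outdir / "categories.tsv", "w", encoding="utf-8") as fh:
        fh.write("category\tcount\tpercent_of_confirmed\tparticipant_mean\tparticipant_sd\n")
        for cat, count in s.counts.items():
            mean, sd = s.per_participant_mean_sd.get(cat, (0.0, 0.0))
            pct = s.percents.get(cat, "")
            fh.write(f"{cat}\t{count}\t{pct}\t{mean:.2f}\t{sd:.2f}\n")

    with open(outdir / "spatial.tsv", "w", encoding="utf-8") as fh:
        fh.write("participant_id\tn\tad_a2\tad_p\tce_R\tce_z\tce_p\n")
        pids = sorted(set(bundle.ce_results) | set(bundle.ad_results))
        for pid in pids:
            ad = bundle.ad_results.get(pid)
            ce = bundle.ce_results.get(pid)
            n = ce.n if ce else (ad.n if ad else 0)
            ad_cols = f"{ad.a2:.4f}\t{ad.p_value:.4g}" if ad else "NA\tNA"
            ce_cols = (
                f"{ce.R:.3f}\t{ce.z:.3f}\t{ce.p_value:.4g}" if ce else "NA\tNA\tNA"
            )
            fh.write(f"{pid}\t{n}\t{ad_cols}\t{ce_cols}\n")

    cons = bundle.conservation
    with open(outdir / "conservation.tsv", "w", encoding="utf-8") as fh:
        fh.write(
            "participant\tsession_a\tsession_b\tx_a\ty_a\tx_b\ty_b\t"
            "distance_px\tsame_category\n"
        )
        for p in cons.pairs:
            fh.write(
                f"{p.spot_a.participant_id}\t{p.spot_a.session_id}\t"
                f"{p.spot_b.session_id}\t{p.spot_a.x_px}\t{p.spot_a.y_px}\t"
                f"{p.spot_b.x_px}\t{p.spot_b.y_px}\t{p.distance_px:.3f}\t"
                f"{p.same_category}\n"
            )

    write_spot_table(table, outdir / "spots_classified.csv")
    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(render_report(bundle))


def render_report(bundle: ResultsBundle) -> str:
    """Human-readable run summary."""
    s = bundle.summary
    cons = bundle.conservation
    lines = [
        "Thermosensitive-spot analysis",
        f"(config {bundle.config_digest}, seed {bundle.seed}, v{bundle.version})",
        "",
        "Spot categories",
        "---------------",
    ]
    if s.n_total == 0:
        lines.append("no data")
    else:
        lines.append(
            f"{s.n_confirmed} confirmed of {s.n_total} candidate spots "
            f"({s.unconfirmed_rate_percent:.1f}% unconfirmed)"
        )
        for cat in ("cold", "warm", "inconsistent", "incongruous"):
            mean, sd = s.per_participant_mean_sd[cat]
            lines.append(
                f"  {cat:13s} {s.counts[cat]:4d}  {s.percents[cat]:3d}%  "
                f"per-participant mean {mean:.2f} (SD {sd:.2f})"
            )
    lines += ["", "Spatial statistics", "------------------"]
    if not bundle.ce_results and not bundle.ad_results:
        lines.append("no data")
    else:
        for pid in sorted(set(bundle.ce_results) | set(bundle.ad_results)):
            parts = [f"  participant {pid}:"]
            ad = bundle.ad_results.get(pid)
            if ad:
                parts.append(f"AD A2={ad.a2:.3f} p={ad.p_value:.4g}")
            ce = bundle.ce_results.get(pid)
            if ce:
                parts.append(f"Clark-Evans R={ce.R:.2f} z={ce.z:.2f} p={ce.p_value:.4g}")
            lines.append(" ".join(parts))
        for pid, n in bundle.ad_excluded.items():
            lines.append(
                f"  participant {pid}: excluded from uniformity test (n={n})"
            )
        lines.append(
            "  spots per segment (wrist->elbow): "
            + ", ".join(f"{k}: {v}" for k, v in bundle.segment_totals.items())
        )
    lines += ["", "Conservation across sessions", "----------------------------"]
    if cons.n_confirmed == 0:
        lines.append("no data")
    else:
        lines.append(
            f"  {cons.n_conserved} of {cons.n_confirmed} confirmed spots conserved "
            f"({cons.conservation_rate:.1f}%, {cons.convention} convention, "
            f"threshold {cons.threshold_px} px)"
        )
        lines.append(
            f"  component count {cons.n_conserved_component}, "
            f"reidentification count {cons.n_conserved_reidentified}, "
            f"{len(cons.pairs)} pairs, longest chain {cons.max_chain_length} "
            f"spots spanning {cons.max_sessions_spanned} sessions"
        )
        lines.append(f"  category agreement on {cons.n_category_agree} conserved spots")
    return "\n".join(lines) + "\n"
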