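"""End-to-end orchestration: synth -> connectivity -> statistics -> report.

Every stage is deterministic for a fixed configuration and seed; manifests
record the configuration hash and seed of each run.  File formats are plain
CSV/JSON so results diff cleanly across reruns.
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

from .atlas import connection_families, enumerate_connections, load_atlas
from .cohort import (
    DESIGNATED_PAIR,
    DESIGNATED_STRUCTURAL,
    Cohort,
    CohortConfig,
    generate_cohort,
    generate_structural_table,
    simulate_subject_timeseries,
)
from .connectivity import (
    DEFAULT_BAND_HZ,
    DEFAULT_N_FREQS,
    DEFAULT_ORDER,
    DEFAULT_ORDER_CANDIDATES,
    pairwise_connectivity,
)
from .errors import StructuralError, ValidationError
from .groupstats import brain_behavior, compare_groups
from .structural import load_structural_table, structural_group_comparison

logger = logging.getLogger(__name__)

DESIGNATED_CONNECTION = f"{DESIGNATED_PAIR[0]}-{DESIGNATED_PAIR[1]}"
DESIGNATED_DIRECTION = f"{DESIGNATED_PAIR[0]}->{DESIGNATED_PAIR[1]}"


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    band: tuple[float, float] = DEFAULT_BAND_HZ
    order: int = DEFAULT_ORDER
    order_candidates: tuple[int, ...] = DEFAULT_ORDER_CANDIDATES
    n_freqs: int = DEFAULT_N_FREQS
    seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if self.seed is not None:
            self.cohort = dataclasses.replace(self.cohort, seed=int(self.seed))
        f1, f2 = self.band
        nyquist = self.cohort.fs / 2.0
        if not (0 < f1 < f2 <= nyquist + 1e-9):
            raise ValidationError(
                f"band ({f1}, {f2}) must satisfy 0 < f1 < f2 <= Nyquist ({nyquist:.4g} Hz)"
            )
        if any(p < 1 or p > 30 for p in self.order_candidates):
            raise ValidationError("order candidates must lie in [1, 30]")
        if self.order < 1:
            raise ValidationError("order must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "band" in data:
            data["band"] = tuple(data["band"])
        if "order_candidates" in data:
            data["order_candidates"] = tuple(data["order_candidates"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["order_candidates"] = list(self.order_candidates)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _prepare_outdir(outdir: Path, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ValidationError(
            f"output directory {outdir} is not empty; pass force=True/--force to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def run_synth(config: PipelineConfig, outdir, force: bool = False) -> Cohort:
    """Generate the cohort and write metadata, time series and structural tables."""
    outdir = _prepare_outdir(outdir, force)
    cohort = generate_cohort(config.cohort)
    cohort.roster.to_csv(outdir / "metadata.csv", index=False)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    run_lengths = None
    for rec in cohort.records:
        ts = simulate_subject_timeseries(cohort, rec.subject_id)
        ts.data.to_csv(ts_dir / f"{rec.subject_id}.csv", index=False, float_format="%.6f")
        run_lengths = ts.run_lengths
    with open(outdir / "runs.json", "w") as fh:
        json.dump({"run_lengths": run_lengths, "fs_hz": cohort.config.fs}, fh, indent=2)
    generate_structural_table(cohort).to_csv(outdir / "structural.csv", index=False)
    manifest = {
        "seed": cohort.config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": cohort.config.n_subjects,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("synth: wrote %d subjects to %s", len(cohort.records), outdir)
    return cohort


def run_analyze(config: PipelineConfig, datadir, outdir, force: bool = False) -> dict:
    """Cohort filtering, connectivity, group statistics and brain-behavior."""
    datadir = Path(datadir)
    outdir = _prepare_outdir(outdir, force)
    roster_path = datadir / "metadata.csv"
    if not roster_path.exists():
        raise StructuralError(f"missing {roster_path}; run synth first")
    roster = pd.read_csv(roster_path)
    roster.to_csv(outdir / "roster.csv", index=False)
    with open(datadir / "runs.json") as fh:
        runs_meta = json.load(fh)
    run_lengths = runs_meta["run_lengths"]
    fs = runs_meta["fs_hz"]

    atlas = load_atlas()
    connections = enumerate_connections(atlas)
    families = connection_families(connections)

    functional = roster[roster["fmri_complete"]]
    logger.info("analyze: functional effective n = %d", len(functional))
    tables = []
    for sid in functional["subject_id"]:
        ts = pd.read_csv(datadir / "timeseries" / f"{sid}.csv")
        tables.append(
            pairwise_connectivity(
                ts, connections, run_lengths=run_lengths, order=config.order,
                fs=fs, band=config.band, n_freqs=config.n_freqs, subject_id=sid,
            )
        )
    conn_table = pd.concat(tables, ignore_index=True)
    conn_table.to_csv(outdir / "connectivity.csv", index=False)

    stats = pd.concat(
        [
            compare_groups(conn_table, "fc", families, functional),
            compare_groups(conn_table, "tgc", families, functional),
        ],
        ignore_index=True,
    )
    stats.to_csv(outdir / "group_stats.csv", index=False)

    rts = {
        r.subject_id: r.response_time_ms
        for r in roster[roster["rt_complete"]].itertuples()
    }
    bb_rows = []
    for con in connections:
        specs = [("fc", "undirected"), ("tgc", f"{con.roi_a}->{con.roi_b}"),
                 ("tgc", f"{con.roi_b}->{con.roi_a}")]
        for metric, direction in specs:
            res = brain_behavior(conn_table, rts, con.label, metric, direction)
            bb_rows.append(res.__dict__)
    bb_table = pd.DataFrame(bb_rows)
    bb_table.to_csv(outdir / "brain_behavior.csv", index=False)
    n_bb_functional = int(
        bb_table.loc[
            (bb_table["connection"] == DESIGNATED_CONNECTION)
            & (bb_table["metric"] == "tgc")
            & (bb_table["direction"] == DESIGNATED_DIRECTION),
            "n",
        ].iloc[0]
    )
    logger.info("analyze: functional brain-behavior effective n = %d", n_bb_functional)

    summary: dict = {
        "effective_n": {
            "functional": int(len(functional)),
            "functional_brain_behavior": n_bb_functional,
        },
        "designated_connection": DESIGNATED_CONNECTION,
    }

    structural_path = datadir / "structural.csv"
    if structural_path.exists():
        struct = load_structural_table(structural_path, roster=roster)
        structural_roster = roster[roster["tract_complete"]]
        summary["effective_n"]["structural"] = int(struct["subject_id"].nunique())
        struct_stats = structural_group_comparison(struct, families, structural_roster)
        struct_stats.to_csv(outdir / "structural_stats.csv", index=False)
        struct_long = struct.melt(
            id_vars=["subject_id", "connection"], value_vars=["fa", "qa"],
            var_name="metric", value_name="value",
        )
        struct_long["direction"] = "undirected"
        sb_rows = []
        for con in connections:
            for metric in ("fa", "qa"):
                res = brain_behavior(struct_long, rts, con.label, metric, "undirected")
                sb_rows.append(res.__dict__)
        sb_table = pd.DataFrame(sb_rows)
        sb_table.to_csv(outdir / "structural_brain_behavior.csv", index=False)
        summary["effective_n"]["structural_brain_behavior"] = int(sb_table["n"].iloc[0])

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_report(results_dir, outdir, force: bool = False) -> Path:
    """Plots and a markdown summary of significant connections."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    outdir = _prepare_outdir(outdir, force)
    stats_path = results_dir / "group_stats.csv"
    if not stats_path.exists():
        raise StructuralError(f"missing {stats_path}; run analyze first")
    stats = pd.read_csv(stats_path)
    bb = pd.read_csv(results_dir / "brain_behavior.csv")
    conn = pd.read_csv(results_dir / "connectivity.csv")

    sig = stats[stats["p_holm"] < 0.05]
    struct_path = results_dir / "structural_stats.csv"
    struct_sig = pd.DataFrame()
    if struct_path.exists():
        struct_stats = pd.read_csv(struct_path)
        struct_sig = struct_stats[struct_stats["p_holm"] < 0.05]

    lines = ["# Connectivity report", ""]
    if sig.empty and struct_sig.empty:
        lines.append("No significant connections after Holm correction.")
    else:
        lines.append("## Significant connections (Holm-corrected p < 0.05)")
        lines.append("")
        lines.append("| connection | direction | metric | family | p_raw | p_holm |")
        lines.append("|---|---|---|---|---|---|")
        for frame in (sig, struct_sig):
            for row in frame.itertuples():
                lines.append(
                    f"| {row.connection} | {row.direction} | {row.metric} "
                    f"| {row.family} | {row.p_raw:.4f} | {row.p_holm:.4f} |"
                )
    bb_sig = bb[bb["p"] < 0.05]
    if not bb_sig.empty:
        lines += ["", "## Brain-behavior correlations (uncorrected p < 0.05)", ""]
        for row in bb_sig.itertuples():
            lines.append(
                f"- {row.connection} ({row.direction}, {row.metric}): "
                f"rho = {row.rho:.2f}, p = {row.p:.4f}, n = {row.n}"
            )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")

    # violin + scatter analogues for the designated connection
    roster_path = results_dir / "roster.csv"
    meta = pd.read_csv(roster_path) if roster_path.exists() else None
    for metric, direction in (("fc", "undirected"), ("tgc", DESIGNATED_DIRECTION)):
        sel = conn[
            (conn["connection"] == DESIGNATED_CONNECTION)
            & (conn["metric"] == metric)
            & (conn["direction"] == direction)
        ]
        if sel.empty or meta is None:
            continue
        merged = sel.merge(meta[["subject_id", "group", "response_time_ms"]], on="subject_id")
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        groups = [merged.loc[merged["group"] == g, "value"] for g in ("gamer", "nongamer")]
        axes[0].violinplot([g.to_numpy() for g in groups], showmedians=True)
        axes[0].set_xticks([1, 2], ["gamer", "nongamer"])
        axes[0].set_ylabel(metric.upper())
        axes[0].set_title(f"{DESIGNATED_CONNECTION} ({direction})")
        ok = merged.dropna(subset=["response_time_ms"])
        axes[1].scatter(ok["value"], ok["response_time_ms"], s=12)
        if len(ok) >= 2:
            k, b = np.polyfit(ok["value"], ok["response_time_ms"], 1)
            xs = np.linspace(ok["value"].min(), ok["value"].max(), 10)
            axes[1].plot(xs, k * xs + b, color="tab:red")
        axes[1].set_xlabel(metric.upper())
        axes[1].set_ylabel("response time (ms)")
        fig.tight_layout()
        fig.savefig(outdir / f"{metric}_{DESIGNATED_CONNECTION.replace(' ', '_')}.png", dpi=100)
        plt.close(fig)
    return outdir / "report.md"
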