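"""End-to-end orchestration: files in, stage tables and a run summary out.

``run_pipeline`` chains the stages — depth equalization, shift estimation,
the five-filter labeling cascade, treatment-contrast guild classification,
fractional uptake, abundance ranking, and the nitrogen balance — writing one
TSV per stage plus ``summary.json`` under the output directory.  A MANIFEST
records which stages completed, so a failed run leaves interpretable partial
output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .chemistry import ProducedFrom, summarize_column
from .classify import classify_guilds, comammox_contrast, rank_abundance_shift
from .density import compute_shifts, shifts_to_frame
from .filters import fractional_uptake, genus_uptake, run_filter_cascade
from .model import Assay, Treatment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (YAML-loadable)."""

    counts: str
    metadata: str
    taxonomy: str
    out: str
    community: str | None = None
    chemistry: str | None = None
    columns: str | None = None  # column_id -> treatment map (TSV)
    equalize: bool = True
    depth: int | None = None  # default: minimum library size across fractions
    min_shift: float = 0.0
    n_boot: int = 1000
    ci_level: float = 0.90
    retain_mode: str = "genus"
    both_assays: bool = True
    reference_genera: dict | None = None  # treatment name -> list of genera
    contrast_genus: str = "Nitrospira"
    ranking_treatment: str = "NH4"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ci_level < 1):
            raise ValueError(f"ci_level must be in (0,1), got {self.ci_level}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("counts", "metadata", "taxonomy", "community", "chemistry", "columns"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p!r} does not exist")


def _reference_map(config: RunConfig) -> dict | None:
    if config.reference_genera is None:
        return None
    return {
        Treatment(k): tuple(v) for k, v in config.reference_genera.items()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict written to summary.json."""
    config.validate_paths()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "MANIFEST"
    completed: list[str] = []
    summary: dict = {"config": {k: v for k, v in dataclasses.asdict(config).items()}}

    def mark(stage: str) -> None:
        completed.append(stage)
        manifest_path.write_text("\n".join(completed) + "\n")

    def run_stage(stage: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            manifest_path.write_text(
                "\n".join(completed + [f"FAILED at {stage}: {exc}"]) + "\n"
            )
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        mark(stage)
        return result

    # --- read ---------------------------------------------------------------
    tables = run_stage(
        "read", lambda: sio.read_fraction_tables(config.counts, config.metadata)
    )
    taxonomy = sio.read_taxonomy(config.taxonomy)

    # --- equalize -----------------------------------------------------------
    if config.equalize:
        def _equalize():
            depth = config.depth
            if depth is None:
                depth = int(min(min(t.column_sums) for t in tables))
            return [
                sio.equalize_depth(t, depth, seed=config.seed + i)
                for i, t in enumerate(tables)
            ]

        tables = run_stage("equalize", _equalize)

    # --- shifts -------------------------------------------------------------
    shifts = run_stage("shifts", lambda: compute_shifts(tables))
    shifts_frame = shifts_to_frame(shifts)
    shifts_frame.to_csv(outdir / "shifts.tsv", sep="\t", index=False)

    # --- filters 1-5 --------------------------------------------------------
    cascade = run_stage(
        "filters",
        lambda: run_filter_cascade(
            shifts,
            taxonomy,
            min_shift=config.min_shift,
            n_boot=config.n_boot,
            seed=config.seed,
            ci_level=config.ci_level,
            reference_genera=_reference_map(config),
            retain_mode=config.retain_mode,
            both_assays=config.both_assays,
        ),
    )
    cascade.membership_frame().to_csv(outdir / "stages.tsv", sep="\t", index=False)
    cascade.genus_ci_frame().to_csv(outdir / "genus_ci.tsv", sep="\t", index=False)
    counts_frame = cascade.stage_counts()
    summary["stage_counts"] = counts_frame.to_dict(orient="records")

    treatments = sorted(
        {t for (t, _a, _s) in cascade.stages}, key=lambda t: t.value
    )
    labeled = {
        (t, a): cascade.labeled(t, a)
        for t in treatments
        for a in (Assay.DNA, Assay.RNA)
    }

    # --- guilds (filter 6) --------------------------------------------------
    universe = sorted({r.otu_id for r in shifts})

    def _classify():
        return classify_guilds(
            {k: v for k, v in labeled.items()}, taxonomy, universe=set(universe)
        )

    guilds = run_stage("classify", _classify)
    guild_frame = pd.DataFrame(
        [
            {
                "otu_id": g.otu_id,
                "genus": g.genus,
                "guild": g.guild.value,
                "evidence": ";".join(
                    sorted(f"{t.value}/{a.value}" for (t, a) in g.evidence)
                ),
            }
            for g in guilds
        ]
    )
    guild_frame.to_csv(outdir / "guilds.tsv", sep="\t", index=False)
    summary["guild_counts"] = (
        guild_frame.groupby("guild")["otu_id"].nunique().to_dict()
    )

    # --- comammox-style binary contrast -------------------------------------
    if Treatment.NH4 in treatments and Treatment.NO2 in treatments:
        contrast_rows = []
        for a in (Assay.DNA, Assay.RNA):
            part = comammox_contrast(
                labeled[(Treatment.NH4, a)],
                labeled[(Treatment.NO2, a)],
                taxonomy,
                genus=config.contrast_genus,
            )
            contrast_rows.append(
                {"genus": part.genus, "assay": a.value, **part.counts()}
            )
        pd.DataFrame(contrast_rows).to_csv(
            outdir / "contrast.tsv", sep="\t", index=False
        )
        summary["contrast"] = contrast_rows
        mark("contrast")

    # --- fractional uptake ---------------------------------------------------
    def _uptake():
        rows = []
        for (t, a), s in labeled.items():
            if not s.otu_ids:
                continue
            for f in fractional_uptake(s, shifts):
                rows.append(
                    {
                        "otu_id": f.otu_id,
                        "treatment": t.value,
                        "assay": a.value,
                        "fraction": f.fraction,
                        "genus": taxonomy.genus(f.otu_id),
                    }
                )
        return pd.DataFrame(rows)

    uptake_frame = run_stage("uptake", _uptake)
    uptake_frame.to_csv(outdir / "uptake.tsv", sep="\t", index=False)

    # --- abundance ranking ---------------------------------------------------
    if config.community is not None:
        def _ranking():
            profiles = sio.read_community_profiles(config.community)
            target = Treatment(config.ranking_treatment)
            selected = [
                p
                for p in profiles
                if p.treatment is None or p.treatment is target
            ]
            labeled_genera = set()
            for (t, _a), s in labeled.items():
                for o in s.otu_ids:
                    labeled_genera.add(taxonomy.genus(o))
            return rank_abundance_shift(
                selected, taxonomy, candidates=labeled_genera or None
            )

        ranking = run_stage("ranking", _ranking)
        ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
        summary["top_ranked"] = (
            ranking.head(5)[["genus", "delta_min"]].to_dict(orient="records")
            if not ranking.empty
            else []
        )

    # --- nitrogen balance ----------------------------------------------------
    if config.chemistry is not None:
        def _balance():
            series = sio.read_chemistry(config.chemistry)
            col_treatment: dict[str, Treatment] = {}
            if config.columns is not None:
                cols = pd.read_csv(config.columns, sep="\t", dtype=str)
                col_treatment = {
                    r.column_id: Treatment(r.treatment) for r in cols.itertuples()
                }
            rows = []
            for column_id, recs in series.items():
                tr = col_treatment.get(column_id, Treatment.NH4)
                no2_mode = (
                    ProducedFrom.FROM_INFLUENT
                    if tr is Treatment.NO2
                    else ProducedFrom.FROM_NH4
                )
                no3_mode = (
                    ProducedFrom.FROM_NO2
                    if tr is Treatment.NO2
                    else ProducedFrom.FROM_NH4
                )
                s = summarize_column(
                    recs,
                    column_id=column_id,
                    no2_mode=no2_mode,
                    no3_mode=no3_mode,
                    alpha=config.alpha,
                )
                rows.append(
                    {
                        "column_id": column_id,
                        "treatment": tr.value,
                        "nh4_removal_mean": s.nh4_removal_pct[0],
                        "nh4_removal_sd": s.nh4_removal_pct[1],
                        "no2_removal_mean": s.no2_removal_pct[0],
                        "no2_removal_sd": s.no2_removal_pct[1],
                        "no3_accretion_mean": s.no3_accretion_pct[0],
                        "no3_accretion_sd": s.no3_accretion_pct[1],
                        "balance_closed": s.balance_closed,
                        "p_value": s.p_value,
                    }
                )
            return pd.DataFrame(rows)

        balance = run_stage("balance", _balance)
        balance.to_csv(outdir / "balance.tsv", sep="\t", index=False)
        summary["balance"] = balance.to_dict(orient="records")

    # monotonicity sanity check on the summary itself
    order = ["F1", "F2", "F3", "F4", "F5"]
    for (t, a), _s in labeled.items():
        sizes = [
            len(cascade.get(t, a, stage)) for stage in order
        ]
        if any(sizes[i] < sizes[i + 1] for i in range(len(sizes) - 1)):
            raise PipelineError(
                f"stage sizes not monotone for {t.value}/{a.value}: {sizes}"
            )
    summary["n_otus"] = len(universe)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    mark("summary")
    return summary
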