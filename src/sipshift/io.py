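"""Readers and writers for the tabular formats the pipeline consumes.

Formats (all plain text):

* counts TSV — dense OTU x sample integer matrix, header ``#OTU_ID`` then
  sample ids, one row per OTU;
* metadata TSV — one row per sample with the fraction fields
  (sample_id, treatment, isotope, assay, column_id, fraction_index,
  buoyant_density, na_concentration);
* taxonomy TSV — ``otu_id <TAB> lineage`` with semicolon-delimited ranks,
  Greengenes ``g__Genus`` tokens accepted;
* community TSV — long format: assay, timepoint, otu_id, relabund
  (optional treatment column);
* chemistry CSV — ``day,nh4_in,nh4_out,no2_in,no2_out,no3_in,no3_out``,
  optionally preceded by a ``column_id`` column when one file carries several
  replicate columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Assay,
    ChemistryRecord,
    CommunityProfile,
    FractionSample,
    Isotope,
    OtuFractionTable,
    TaxonomyMap,
    Timepoint,
    Treatment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_fraction_tables",
    "write_fraction_tables",
    "read_taxonomy",
    "write_taxonomy",
    "read_community_profiles",
    "write_community_profiles",
    "read_chemistry",
    "write_chemistry",
    "equalize_depth",
]

_METADATA_COLUMNS = [
    "sample_id",
    "treatment",
    "isotope",
    "assay",
    "column_id",
    "fraction_index",
    "buoyant_density",
    "na_concentration",
]


def _parse_sample_row(row: pd.Series) -> FractionSample:
    return FractionSample(
        sample_id=str(row["sample_id"]),
        treatment=Treatment(row["treatment"]),
        isotope=Isotope(row["isotope"]),
        assay=Assay(row["assay"]),
        column_id=str(row["column_id"]),
        fraction_index=int(row["fraction_index"]),
        buoyant_density=float(row["buoyant_density"]),
        na_concentration=float(row["na_concentration"]),
    )


def read_fraction_tables(path, metadata_path) -> list[OtuFractionTable]:
    """Read a dense counts TSV plus sample metadata into per-gradient tables.

    Returns one :class:`OtuFractionTable` per (treatment, isotope, assay,
    column_id) group, samples sorted by fraction_index.  Counts columns with
    no metadata row are a hard error naming the column; metadata rows without
    a counts column are reported via a warning log and skipped.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = pd.read_csv(
        metadata_path,
        sep="\t",
        dtype={"sample_id": str, "column_id": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata {metadata_path} lacks columns: {missing_cols}")
    meta = meta.set_index("sample_id", drop=False)

    absent = [c for c in counts.columns if c not in meta.index]
    if absent:
        raise ValueError(
            f"counts columns missing from metadata {metadata_path}: {absent}"
        )
    unmatched = [s for s in meta.index if s not in counts.columns]
    if unmatched:
        logger.warning("metadata samples with no counts column: %s", unmatched)

    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.round(values)):
        bad = np.argwhere(
            ~np.isclose(values.astype(float), np.round(values.astype(float)))
        )
        o, s = bad[0]
        raise ValueError(
            f"non-integer count at OTU {counts.index[o]!r}, "
            f"sample {counts.columns[s]!r}"
        )
    if np.any(values < 0):
        o, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at OTU {counts.index[o]!r}, sample {counts.columns[s]!r}"
        )

    samples = {sid: _parse_sample_row(meta.loc[sid]) for sid in counts.columns}
    groups: dict[tuple, list[str]] = {}
    for sid, sample in samples.items():
        groups.setdefault(sample.gradient_key, []).append(sid)

    tables = []
    otu_ids = list(counts.index)
    for key in sorted(groups, key=lambda k: tuple(map(str, k))):
        sids = groups[key]
        tables.append(
            OtuFractionTable(
                otu_ids=list(otu_ids),
                samples=[samples[s] for s in sids],
                counts=counts[sids].to_numpy().astype(np.int64),
            )
        )
    return tables


def write_fraction_tables(tables, counts_path, metadata_path) -> None:
    """Write tables back to the dense counts TSV + metadata TSV pair."""
    all_otus: list[str] = []
    for t in tables:
        for o in t.otu_ids:
            if o not in all_otus:
                all_otus.append(o)
    columns: dict[str, pd.Series] = {}
    meta_rows = []
    for t in tables:
        for j, s in enumerate(t.samples):
            columns[s.sample_id] = (
                pd.Series(t.counts[:, j], index=t.otu_ids)
                .reindex(all_otus, fill_value=0)
                .astype(np.int64)
            )
            meta_rows.append(
                {
                    "sample_id": s.sample_id,
                    "treatment": s.treatment.value,
                    "isotope": s.isotope.value,
                    "assay": s.assay.value,
                    "column_id": s.column_id,
                    "fraction_index": s.fraction_index,
                    "buoyant_density": s.buoyant_density,
                    "na_concentration": s.na_concentration,
                }
            )
    frame = pd.DataFrame(columns, index=pd.Index(all_otus, name="#OTU_ID"))
    frame.to_csv(counts_path, sep="\t")
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False, float_format="%.17g")


def read_taxonomy(path) -> TaxonomyMap:
    lineages: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        otu, _, lineage = line.partition("\t")
        lineages[otu.strip()] = lineage.strip()
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        for otu, lineage in taxonomy.lineages.items():
            fh.write(f"{otu}\t{lineage}\n")


def read_community_profiles(path) -> list[CommunityProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str}, float_precision="round_trip")
    if "treatment" in df.columns:
        df["treatment"] = df["treatment"].fillna("")
    keys = ["assay", "timepoint"] + (["treatment"] if "treatment" in df.columns else [])
    profiles = []
    for key, sub in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rel = dict(zip(sub["otu_id"], sub["relabund"].astype(float)))
        treatment = None
        if "treatment" in df.columns:
            treatment = Treatment(key[2]) if pd.notna(key[2]) and key[2] != "" else None
        profiles.append(
            CommunityProfile(
                assay=Assay(key[0]),
                timepoint=Timepoint(key[1]),
                relabund=rel,
                treatment=treatment,
            )
        )
    return profiles


def write_community_profiles(profiles, path) -> None:
    rows = []
    for p in profiles:
        for otu, ra in p.relabund.items():
            rows.append(
                {
                    "assay": p.assay.value,
                    "timepoint": p.timepoint.value,
                    "treatment": "" if p.treatment is None else p.treatment.value,
                    "otu_id": otu,
                    "relabund": ra,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_chemistry(path) -> dict[str, list[ChemistryRecord]]:
    """Read daily chemistry into per-column record lists keyed by column_id."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "column_id" not in df.columns:
        df["column_id"] = "column_1"
    out: dict[str, list[ChemistryRecord]] = {}
    for col, sub in df.groupby("column_id", sort=True):
        days = sub["day"].astype(int)
        if days.duplicated().any():
            raise ValueError(f"column {col!r}: duplicate days in chemistry series")
        out[str(col)] = [
            ChemistryRecord(
                day=int(r.day),
                nh4_in=float(r.nh4_in),
                nh4_out=float(r.nh4_out),
                no2_in=float(r.no2_in),
                no2_out=float(r.no2_out),
                no3_in=float(r.no3_in),
                no3_out=float(r.no3_out),
            )
            for r in sub.sort_values("day").itertuples()
        ]
    return out


def write_chemistry(series: dict[str, list[ChemistryRecord]], path) -> None:
    rows = []
    for col, recs in series.items():
        for r in recs:
            rows.append(
                {
                    "column_id": col,
                    "day": r.day,
                    "nh4_in": r.nh4_in,
                    "nh4_out": r.nh4_out,
                    "no2_in": r.no2_in,
                    "no2_out": r.no2_out,
                    "no3_in": r.no3_in,
                    "no3_out": r.no3_out,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def equalize_depth(
    table: OtuFractionTable, depth: int, seed: int
) -> OtuFractionTable:
    """Rarefy every fraction library to a common depth.

    Subsampling is without replacement (multivariate hypergeometric), so no
    OTU can gain counts.  Columns whose library size is below ``depth`` are
    dropped with a logged warning rather than upsampled.
    """
    if depth <= 0:
        raise ValueError(f"equalization depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.column_sums
    keep = sums >= depth
    dropped = [s.sample_id for s, k in zip(table.samples, keep) if not k]
    if dropped:
        logger.warning(
            "equalize_depth: dropping %d columns below depth %d: %s",
            len(dropped), depth, dropped,
        )
    new_counts = np.zeros((len(table.otu_ids), int(keep.sum())), dtype=np.int64)
    j_out = 0
    for j in range(len(table.samples)):
        if not keep[j]:
            continue
        col = table.counts[:, j]
        if col.sum() == depth:
            new_counts[:, j_out] = col
        else:
            new_counts[:, j_out] = rng.multivariate_hypergeometric(col, depth)
        j_out += 1
    return OtuFractionTable(
        otu_ids=list(table.otu_ids),
        samples=[s for s, k in zip(table.samples, keep) if k],
        counts=new_counts,
    )
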