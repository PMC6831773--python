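"""The sequential filter cascade that calls significantly 13C-labeled OTUs.

Five filters progressively restrict the OTUs of one treatment (the sixth,
treatment-contrast step lives in :mod:`sipshift.classify`):

1. keep OTUs whose buoyant density shifted upward between 12C- and 13C-fed
   replicate columns;
2. keep OTUs whose genus has shifted OTUs in BOTH the DNA- and RNA-SIP assay;
3. bootstrap a genus-level confidence interval for the mean shift and keep
   only significantly labeled genera (CI excluding zero from below);
4. discard candidate OTUs whose shift is below the maximum shift of the
   labeled reference nitrifier genus (Nitrosomonas for ammonia-side
   treatments, Nitrospira for the nitrite-side treatment) — this removes
   cross-feeders and anaplerotic CO2 fixers, which acquire far less label
   than chemolithoautotrophs;
5. re-apply the both-assay genus rule, since filter 4 can break it.

Filter sets are nested within a treatment x assay path:
F5 ⊆ F4 ⊆ F3 ⊆ F2 ⊆ F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import ShiftRecord
from .model import Assay, TaxonomyMap, Treatment

logger = logging.getLogger(__name__)

__all__ = [
    "LabelCallSet",
    "GenusCI",
    "UptakeFraction",
    "DEFAULT_REFERENCE_GENERA",
    "filter1_shifted",
    "filter2_both_assays",
    "bootstrap_genus_ci",
    "filter3_genus_ci",
    "filter4_reference_max",
    "filter5_both_assays_again",
    "fractional_uptake",
    "genus_uptake",
    "run_filter_cascade",
    "CascadeResult",
]

#: Reference genus whose labeled OTUs set the filter-4 shift threshold,
#: per treatment: the canonical ammonia oxidizer for ammonia-fed contrasts
#: and the canonical nitrite oxidizer for the nitrite-fed contrast.
DEFAULT_REFERENCE_GENERA: dict[Treatment, tuple[str, ...]] = {
    Treatment.NH4: ("Nitrosomonas",),
    Treatment.NH4_ATU: ("Nitrosomonas",),
    Treatment.NH4_CLO3: ("Nitrosomonas",),
    Treatment.NO2: ("Nitrospira",),
}


@dataclass(frozen=True)
class GenusCI:
    """Bootstrap percentile CI for the mean buoyant-density shift of a genus."""

    genus: str
    treatment: Treatment
    assay: Assay
    lo: float
    hi: float
    n_otus: int
    significant: bool
    degenerate: bool = False  # single-OTU genus: point CI at its shift

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"genus {self.genus}: CI lo {self.lo} > hi {self.hi}")


@dataclass
class LabelCallSet:
    """OTUs surviving one filter stage of one treatment x assay path."""

    treatment: Treatment
    assay: Assay
    stage: str  # "F1" .. "F5"
    otu_ids: frozenset[str]
    genus_ci: dict[str, GenusCI] = field(default_factory=dict)
    #: otu -> stage at which it was removed (provenance across the cascade)
    removed_at: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.otu_ids)

    def advance(self, stage: str, kept: set[str], **extra) -> "LabelCallSet":
        removed = dict(self.removed_at)
        for otu in self.otu_ids - kept:
            removed[otu] = stage
        if not kept <= set(self.otu_ids):
            raise ValueError(f"stage {stage} tried to add OTUs to the cascade")
        return LabelCallSet(
            treatment=self.treatment,
            assay=self.assay,
            stage=stage,
            otu_ids=frozenset(kept),
            genus_ci=extra.get("genus_ci", self.genus_ci),
            removed_at=removed,
        )


def _shift_lookup(
    shifts: list[ShiftRecord],
) -> dict[tuple[Treatment, Assay], dict[str, float]]:
    out: dict[tuple[Treatment, Assay], dict[str, float]] = {}
    for r in shifts:
        out.setdefault((r.treatment, r.assay), {})[r.otu_id] = r.shift
    return out


def filter1_shifted(
    shifts: list[ShiftRecord], min_shift: float = 0.0
) -> dict[tuple[Treatment, Assay], LabelCallSet]:
    """Filter 1: keep OTUs with a positive 12C -> 13C density shift.

    Only OTUs detected under both isotopes carry a shift record at all, so
    presence under both isotopes is implied.  ``min_shift`` defaults to 0
    (any upward shift passes), matching the permissiveness suggested by the
    very large filter-1 survivor counts typical of this design.
    """
    if min_shift < 0:
        raise ValueError(f"min_shift must be >= 0, got {min_shift}")
    sets: dict[tuple[Treatment, Assay], set[str]] = {}
    removed: dict[tuple[Treatment, Assay], dict[str, str]] = {}
    for r in shifts:
        key = (r.treatment, r.assay)
        sets.setdefault(key, set())
        removed.setdefault(key, {})
        if r.shift > min_shift:
            sets[key].add(r.otu_id)
        else:
            removed[key][r.otu_id] = "F1"
    return {
        key: LabelCallSet(
            treatment=key[0],
            assay=key[1],
            stage="F1",
            otu_ids=frozenset(otus),
            removed_at=removed[key],
        )
        for key, otus in sets.items()
    }


def _both_assay_rule(
    dna: LabelCallSet, rna: LabelCallSet, taxonomy: TaxonomyMap, stage: str
) -> tuple[LabelCallSet, LabelCallSet]:
    genera_dna = set(taxonomy.genus_members(dna.otu_ids))
    genera_rna = set(taxonomy.genus_members(rna.otu_ids))
    shared = genera_dna & genera_rna
    unclassified = {g for g in shared if g.startswith("unclassified")}
    if unclassified:
        logger.info(
            "%s: unclassified genus bins satisfying the both-assay rule: %s",
            stage, sorted(unclassified),
        )
    keep_dna = {o for o in dna.otu_ids if taxonomy.genus(o) in shared}
    keep_rna = {o for o in rna.otu_ids if taxonomy.genus(o) in shared}
    return dna.advance(stage, keep_dna), rna.advance(stage, keep_rna)


def filter2_both_assays(
    f1_dna: LabelCallSet, f1_rna: LabelCallSet, taxonomy: TaxonomyMap
) -> tuple[LabelCallSet, LabelCallSet]:
    """Filter 2: keep an OTU iff its genus has shifted OTUs in DNA AND RNA."""
    if f1_dna.treatment is not f1_rna.treatment:
        raise ValueError("filter2 requires DNA and RNA sets of the same treatment")
    return _both_assay_rule(f1_dna, f1_rna, taxonomy, "F2")


def bootstrap_genus_ci(
    shifts: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    ci_level: float = 0.90,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of a genus's OTU shifts."""
    shifts = np.asarray(shifts, dtype=float)
    if shifts.size == 0:
        raise ValueError("cannot bootstrap an empty shift set")
    if shifts.size == 1:
        return float(shifts[0]), float(shifts[0])
    idx = rng.integers(0, shifts.size, size=(n_boot, shifts.size))
    means = shifts[idx].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def filter3_genus_ci(
    f2_dna: LabelCallSet,
    f2_rna: LabelCallSet,
    shifts: list[ShiftRecord],
    taxonomy: TaxonomyMap,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.90,
    retain_mode: str = "genus",
    both_assays: bool = True,
) -> tuple[LabelCallSet, LabelCallSet, list[GenusCI]]:
    """Filter 3: genus-level bootstrap significance gate on the mean shift.

    For every genus in the filter-2 set, the mean shift of ALL its OTUs with
    a shift record in the treatment (any sign — absence of labeling pulls
    the genus mean down) is bootstrapped ``n_boot`` times; the percentile CI
    at ``ci_level`` (default 90%) declares the genus significantly labeled
    iff its lower bound exceeds zero.  With ``both_assays=True`` (default)
    a genus must be significant in both the DNA and the RNA assay, mirroring
    the cascade's both-assay philosophy and keeping the genus-wise false-call
    rate near the product of the per-assay rates.

    ``retain_mode`` controls which filter-2 member OTUs of a significant
    genus survive:

    * ``"genus"`` (default) — all of them;
    * ``"above_lower"`` — only those with shift >= the CI lower bound;
    * ``"above_upper"`` — only those with shift > the CI upper bound.

    Single-OTU genera get a degenerate point CI at their shift (flagged) and
    are significant iff that shift is positive.  Deterministic given ``seed``.
    """
    if retain_mode not in ("genus", "above_lower", "above_upper"):
        raise ValueError(f"unknown retain_mode {retain_mode!r}")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if f2_dna.treatment is not f2_rna.treatment:
        raise ValueError("filter3 requires DNA and RNA sets of the same treatment")
    treatment = f2_dna.treatment
    lookup = _shift_lookup(shifts)
    rng = np.random.default_rng(seed)

    sets = {Assay.DNA: f2_dna, Assay.RNA: f2_rna}
    genera = sorted(
        set(taxonomy.genus_members(f2_dna.otu_ids))
        | set(taxonomy.genus_members(f2_rna.otu_ids))
    )
    cis: list[GenusCI] = []
    ci_by: dict[tuple[str, Assay], GenusCI] = {}
    for genus in genera:
        for assay in (Assay.DNA, Assay.RNA):
            assay_shifts = lookup.get((treatment, assay), {})
            member_shifts = np.array(
                sorted(
                    s for o, s in assay_shifts.items() if taxonomy.genus(o) == genus
                )
            )
            if member_shifts.size == 0:
                continue
            degenerate = member_shifts.size == 1
            lo, hi = bootstrap_genus_ci(member_shifts, n_boot, rng, ci_level)
            ci = GenusCI(
                genus=genus,
                treatment=treatment,
                assay=assay,
                lo=lo,
                hi=hi,
                n_otus=int(member_shifts.size),
                significant=lo > 0,
                degenerate=degenerate,
            )
            cis.append(ci)
            ci_by[(genus, assay)] = ci

    def genus_significant(genus: str) -> bool:
        dna_ci = ci_by.get((genus, Assay.DNA))
        rna_ci = ci_by.get((genus, Assay.RNA))
        if both_assays:
            return bool(dna_ci and rna_ci and dna_ci.significant and rna_ci.significant)
        return bool((dna_ci and dna_ci.significant) or (rna_ci and rna_ci.significant))

    out: dict[Assay, LabelCallSet] = {}
    for assay, f2 in sets.items():
        assay_shifts = lookup.get((treatment, assay), {})
        kept: set[str] = set()
        for otu in f2.otu_ids:
            genus = taxonomy.genus(otu)
            if not genus_significant(genus):
                continue
            ci = ci_by.get((genus, assay))
            if ci is None:
                continue
            shift = assay_shifts.get(otu)
            if shift is None:
                continue
            if retain_mode == "genus":
                kept.add(otu)
            elif retain_mode == "above_lower" and shift >= ci.lo:
                kept.add(otu)
            elif retain_mode == "above_upper" and shift > ci.hi:
                kept.add(otu)
        genus_ci = {g: c for (g, a), c in ci_by.items() if a is assay}
        out[assay] = f2.advance("F3", kept, genus_ci=genus_ci)
    return out[Assay.DNA], out[Assay.RNA], cis


def filter4_reference_max(
    f3: LabelCallSet,
    shifts: list[ShiftRecord],
    taxonomy: TaxonomyMap,
    reference_genera: tuple[str, ...] | None = None,
) -> LabelCallSet:
    """Filter 4: drop candidates shifted less than the labeled reference
    nitrifier's maximum shift.

    A reference-genus OTU counts as labeled — and is retained — iff its own
    shift clears its genus's filter-3 CI lower bound (a reference genus can
    contain members that merely rode through on the genus-level significance
    call; they must not anchor the threshold nor be immune to it).  The
    threshold is the maximum shift among those labeled reference OTUs;
    non-reference OTUs need shift >= threshold.  If the reference genera have
    no labeled OTU in the set, the filter is skipped with a warning
    (pass-through).
    """
    if reference_genera is None:
        reference_genera = DEFAULT_REFERENCE_GENERA[f3.treatment]
    lookup = _shift_lookup(shifts).get((f3.treatment, f3.assay), {})
    ref_otus = {o for o in f3.otu_ids if taxonomy.genus(o) in reference_genera}
    ref_labeled = set()
    for o in ref_otus:
        if o not in lookup:
            continue
        ci = f3.genus_ci.get(taxonomy.genus(o))
        if ci is None or lookup[o] >= ci.lo:
            ref_labeled.add(o)
    if not ref_labeled:
        logger.warning(
            "filter4 (%s/%s): no labeled OTU of reference genera %s; passing through",
            f3.treatment.value, f3.assay.value, list(reference_genera),
        )
        return f3.advance("F4", set(f3.otu_ids))
    threshold = max(lookup[o] for o in ref_labeled)
    kept = ref_labeled | {
        o for o in f3.otu_ids if o in lookup and lookup[o] >= threshold
    }
    return f3.advance("F4", kept)


def filter5_both_assays_again(
    f4_dna: LabelCallSet, f4_rna: LabelCallSet, taxonomy: TaxonomyMap
) -> tuple[LabelCallSet, LabelCallSet]:
    """Filter 5: re-apply the both-assay genus rule after filter 4."""
    if f4_dna.treatment is not f4_rna.treatment:
        raise ValueError("filter5 requires DNA and RNA sets of the same treatment")
    return _both_assay_rule(f4_dna, f4_rna, taxonomy, "F5")


@dataclass(frozen=True)
class UptakeFraction:
    """Share of a treatment x assay's total density shift carried by one OTU."""

    otu_id: str
    treatment: Treatment
    assay: Assay
    fraction: float


def fractional_uptake(
    labeled: LabelCallSet, shifts: list[ShiftRecord]
) -> list[UptakeFraction]:
    """Fractional 13C uptake: each labeled OTU's shift over the summed shift.

    Fractions sum to one across the labeled set of a treatment x assay.
    """
    if not labeled.otu_ids:
        raise ValueError("fractional_uptake requires a nonempty labeled set")
    lookup = _shift_lookup(shifts).get((labeled.treatment, labeled.assay), {})
    missing = [o for o in labeled.otu_ids if o not in lookup]
    if missing:
        raise ValueError(f"labeled OTUs without shift records: {sorted(missing)}")
    total = sum(lookup[o] for o in labeled.otu_ids)
    if total <= 0:
        raise ValueError(
            f"summed shift {total:.4g} is not positive; cannot normalize uptake"
        )
    return [
        UptakeFraction(
            otu_id=o,
            treatment=labeled.treatment,
            assay=labeled.assay,
            fraction=lookup[o] / total,
        )
        for o in sorted(labeled.otu_ids)
    ]


def genus_uptake(
    fractions: list[UptakeFraction], taxonomy: TaxonomyMap
) -> dict[str, float]:
    """Genus-level uptake: sum of member-OTU fractions."""
    out: dict[str, float] = {}
    for f in fractions:
        g = taxonomy.genus(f.otu_id)
        out[g] = out.get(g, 0.0) + f.fraction
    return out


@dataclass
class CascadeResult:
    """All stage sets of the filter cascade, indexed (treatment, assay, stage)."""

    stages: dict[tuple[Treatment, Assay, str], LabelCallSet]
    genus_cis: list[GenusCI]

    def get(self, treatment: Treatment, assay: Assay, stage: str) -> LabelCallSet:
        return self.stages[(treatment, assay, stage)]

    def labeled(self, treatment: Treatment, assay: Assay) -> LabelCallSet:
        """The final (post-filter-5) labeled set of a treatment x assay."""
        return self.get(treatment, assay, "F5")

    def stage_counts(self) -> pd.DataFrame:
        rows = [
            {
                "treatment": t.value,
                "assay": a.value,
                "stage": stage,
                "n_otus": len(s),
            }
            for (t, a, stage), s in sorted(
                self.stages.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2])
            )
        ]
        return pd.DataFrame(rows)

    def genus_ci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genus": c.genus,
                    "treatment": c.treatment.value,
                    "assay": c.assay.value,
                    "ci_lo": c.lo,
                    "ci_hi": c.hi,
                    "n_otus": c.n_otus,
                    "significant": c.significant,
                    "degenerate": c.degenerate,
                }
                for c in self.genus_cis
            ]
        )

    def membership_frame(self) -> pd.DataFrame:
        """Per-OTU last stage passed (the stages.tsv layout)."""
        rows = []
        for (t, a, stage), s in self.stages.items():
            if stage != "F5":
                continue
            f1 = self.stages[(t, a, "F1")]
            universe = set(f1.otu_ids) | set(f1.removed_at)
            for otu in sorted(universe):
                if otu in s.otu_ids:
                    last = "F5"
                else:
                    removed_stage = s.removed_at.get(otu, "F1")
                    order = ["F1", "F2", "F3", "F4", "F5"]
                    last = order[order.index(removed_stage) - 1] if removed_stage != "F1" else "none"
                rows.append(
                    {
                        "otu_id": otu,
                        "treatment": t.value,
                        "assay": a.value,
                        "last_stage_passed": last,
                    }
                )
        return pd.DataFrame(rows)


def run_filter_cascade(
    shifts: list[ShiftRecord],
    taxonomy: TaxonomyMap,
    min_shift: float = 0.0,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.90,
    reference_genera: dict[Treatment, tuple[str, ...]] | None = None,
    retain_mode: str = "genus",
    both_assays: bool = True,
) -> CascadeResult:
    """Run filters 1-5 for every treatment present in the shift records.

    Treatments lacking either assay's shift records are skipped with a
    warning (the both-assay filters cannot run on them).
    """
    f1 = filter1_shifted(shifts, min_shift)
    treatments = sorted({t for (t, _a) in f1}, key=lambda t: t.value)
    stages: dict[tuple[Treatment, Assay, str], LabelCallSet] = {}
    cis: list[GenusCI] = []
    for i, treatment in enumerate(treatments):
        if (treatment, Assay.DNA) not in f1 or (treatment, Assay.RNA) not in f1:
            logger.warning(
                "treatment %s lacks one assay; skipping its cascade", treatment.value
            )
            continue
        f1_dna, f1_rna = f1[(treatment, Assay.DNA)], f1[(treatment, Assay.RNA)]
        f2_dna, f2_rna = filter2_both_assays(f1_dna, f1_rna, taxonomy)
        f3_dna, f3_rna, treatment_cis = filter3_genus_ci(
            f2_dna,
            f2_rna,
            shifts,
            taxonomy,
            n_boot=n_boot,
            seed=seed + i,  # distinct stream per treatment, reproducible
            ci_level=ci_level,
            retain_mode=retain_mode,
            both_assays=both_assays,
        )
        cis.extend(treatment_cis)
        ref = None if reference_genera is None else reference_genera.get(treatment)
        f4_dna = filter4_reference_max(f3_dna, shifts, taxonomy, ref)
        f4_rna = filter4_reference_max(f3_rna, shifts, taxonomy, ref)
        f5_dna, f5_rna = filter5_both_assays_again(f4_dna, f4_rna, taxonomy)
        for s in (f1_dna, f2_dna, f3_dna, f4_dna, f5_dna):
            stages[(treatment, Assay.DNA, s.stage)] = s
        for s in (f1_rna, f2_rna, f3_rna, f4_rna, f5_rna):
            stages[(treatment, Assay.RNA, s.stage)] = s
    return CascadeResult(stages=stages, genus_cis=cis)
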