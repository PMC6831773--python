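"""Treatment-contrast logic: guild calls (filter 6) and abundance ranking.

The four feed regimes differ in which metabolisms can assimilate H13CO3-:
ammonia oxidizers only gain energy where ammonia oxidation proceeds
(NH4-only), nitrite oxidizers wherever nitrite is available and nitrite
oxidoreductase is not poisoned (NH4 and NO2 but not NH4+ClO3-).  Set
differences between the labeled OTU libraries of the treatments therefore
isolate the guilds:

* ammonia oxidizers = labeled(NH4) minus labeled in any other treatment;
* nitrite oxidizers = labeled(NO2) minus labeled(NH4+ClO3-).

A binary comparison of labeled Nitrospira OTUs between the NH4- and NO2-fed
treatments further separates comammox-like phylotypes (labeled only under
ammonia) from canonical nitrite oxidizers (labeled only under nitrite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import LabelCallSet
from .model import Assay, CommunityProfile, Guild, TaxonomyMap, Timepoint, Treatment

__all__ = [
    "GuildAssignment",
    "AbundanceShift",
    "classify_guilds",
    "comammox_contrast",
    "ContrastPartition",
    "rank_abundance_shift",
    "PSEUDO_FRACTION",
]

#: Pseudo relative abundance used in fold changes when a genus is absent at
#: one timepoint.
PSEUDO_FRACTION = 1e-6


@dataclass(frozen=True)
class GuildAssignment:
    """Functional role called for one OTU, with the supporting contrasts.

    ``evidence`` lists the (treatment, assay) paths in which the OTU was in
    the final labeled set.  An OTU labeled in both defining contrasts can
    legitimately hold both oxidizer guilds (a comammox-like profile); such
    OTUs yield two assignments rather than being suppressed.
    """

    otu_id: str
    genus: str
    guild: Guild
    evidence: frozenset  # of (Treatment, Assay)


def _labeled_sets(
    labeled: dict, assays: tuple[Assay, ...]
) -> dict[tuple[Treatment, Assay], frozenset]:
    """Normalise the input mapping to (treatment, assay) -> OTU set."""
    out: dict[tuple[Treatment, Assay], frozenset] = {}
    for key, value in labeled.items():
        if isinstance(value, LabelCallSet):
            out[(value.treatment, value.assay)] = frozenset(value.otu_ids)
        else:
            out[key] = frozenset(value)
    for t in Treatment:
        for a in assays:
            if (t, a) not in out:
                raise ValueError(
                    f"classify_guilds: missing labeled set for treatment "
                    f"{t.value} / {a.value}"
                )
    return out


def classify_guilds(
    labeled: dict,
    taxonomy: TaxonomyMap,
    universe: set[str] | None = None,
    assays: tuple[Assay, ...] = (Assay.DNA, Assay.RNA),
) -> list[GuildAssignment]:
    """Filter 6: assign guilds by subtracting labeled OTU libraries.

    Per assay: AO = L(NH4) - (L(NH4_ATU) | L(NO2) | L(NH4_CLO3));
    NO = L(NO2) - L(NH4_CLO3).  Per-assay calls are then unioned, with the
    supporting (treatment, assay) evidence recorded.  Remaining labeled OTUs
    are LABELED_OTHER; everything else in ``universe`` (if given) is
    UNLABELED.

    ``labeled`` maps treatments (or (treatment, assay) keys) to
    :class:`~sipshift.filters.LabelCallSet` or plain OTU sets; a missing
    treatment x assay is a hard error naming it.
    """
    sets = _labeled_sets(labeled, assays)
    ao: set[str] = set()
    no: set[str] = set()
    for a in assays:
        ao |= sets[(Treatment.NH4, a)] - (
            sets[(Treatment.NH4_ATU, a)]
            | sets[(Treatment.NO2, a)]
            | sets[(Treatment.NH4_CLO3, a)]
        )
        no |= sets[(Treatment.NO2, a)] - sets[(Treatment.NH4_CLO3, a)]

    evidence: dict[str, set] = {}
    for (t, a), otus in sets.items():
        for o in otus:
            evidence.setdefault(o, set()).add((t, a))
    all_labeled = set(evidence)

    def record(otu: str, guild: Guild) -> GuildAssignment:
        return GuildAssignment(
            otu_id=otu,
            genus=taxonomy.genus(otu),
            guild=guild,
            evidence=frozenset(evidence.get(otu, set())),
        )

    out = [record(o, Guild.AMMONIA_OXIDIZER) for o in sorted(ao)]
    out += [record(o, Guild.NITRITE_OXIDIZER) for o in sorted(no)]
    out += [record(o, Guild.LABELED_OTHER) for o in sorted(all_labeled - ao - no)]
    if universe is not None:
        out += [record(o, Guild.UNLABELED) for o in sorted(set(universe) - all_labeled)]
    return out


@dataclass(frozen=True)
class ContrastPartition:
    """Disjoint split of a genus's labeled OTUs between two treatments."""

    genus: str
    unique_nh4: frozenset
    unique_no2: frozenset
    shared: frozenset

    def counts(self) -> dict[str, int]:
        return {
            "unique_NH4": len(self.unique_nh4),
            "unique_NO2": len(self.unique_no2),
            "shared": len(self.shared),
        }


def comammox_contrast(
    l_nh4: LabelCallSet | set,
    l_no2: LabelCallSet | set,
    taxonomy: TaxonomyMap,
    genus: str = "Nitrospira",
) -> ContrastPartition:
    """Binary NH4-vs-NO2 comparison of one genus's labeled OTUs.

    OTUs labeled only under ammonia feeding are comammox candidates (they
    were active when ammonia, not external nitrite, was the energy source);
    OTUs labeled only under nitrite feeding are canonical nitrite oxidizers;
    shared OTUs are ambiguous.  The three sets are pairwise disjoint and
    their union is the genus's labeled OTUs in either treatment.
    """
    set_nh4 = frozenset(
        o
        for o in (l_nh4.otu_ids if isinstance(l_nh4, LabelCallSet) else l_nh4)
        if taxonomy.genus(o) == genus
    )
    set_no2 = frozenset(
        o
        for o in (l_no2.otu_ids if isinstance(l_no2, LabelCallSet) else l_no2)
        if taxonomy.genus(o) == genus
    )
    return ContrastPartition(
        genus=genus,
        unique_nh4=set_nh4 - set_no2,
        unique_no2=set_no2 - set_nh4,
        shared=set_nh4 & set_no2,
    )


@dataclass(frozen=True)
class AbundanceShift:
    """Change of a genus's total-community relative abundance over the run."""

    genus: str
    assay: Assay
    day0_relabund: float
    day15_relabund: float
    delta: float  # day15 - day0
    fold: float  # day15 / day0 with pseudo-fraction floor


def _assay_shifts(
    day0: CommunityProfile,
    day15: CommunityProfile,
    taxonomy: TaxonomyMap,
    genera: set[str],
) -> dict[str, AbundanceShift]:
    g0 = day0.genus_relabund(taxonomy)
    g15 = day15.genus_relabund(taxonomy)
    out = {}
    for g in genera:
        a0 = g0.get(g, 0.0)
        a15 = g15.get(g, 0.0)
        out[g] = AbundanceShift(
            genus=g,
            assay=day0.assay,
            day0_relabund=a0,
            day15_relabund=a15,
            delta=a15 - a0,
            fold=max(a15, PSEUDO_FRACTION) / max(a0, PSEUDO_FRACTION),
        )
    return out


def rank_abundance_shift(
    profiles: list[CommunityProfile],
    taxonomy: TaxonomyMap,
    candidates: set[str] | None = None,
) -> pd.DataFrame:
    """Rank genera by their relative-abundance increase in BOTH total DNA and
    total RNA from day 0 to day 15.

    The primary sort key is min(delta_DNA, delta_RNA), descending: a genus
    must rise in both assays to rank high.  Ties break alphabetically.
    Genera absent at both timepoints in an assay get delta 0 and are flagged.
    Returns a frame with one row per genus, sorted.
    """
    by_key: dict[tuple[Assay, Timepoint], CommunityProfile] = {}
    for p in profiles:
        by_key[(p.assay, p.timepoint)] = p
    for a in (Assay.DNA, Assay.RNA):
        for tp in (Timepoint.DAY0, Timepoint.DAY15):
            if (a, tp) not in by_key:
                raise ValueError(f"missing community profile: {a.value} {tp.value}")

    if candidates is None:
        candidates = set()
        for p in profiles:
            candidates |= set(p.genus_relabund(taxonomy))

    rows = []
    for genus in sorted(candidates):
        per_assay = {}
        for a in (Assay.DNA, Assay.RNA):
            per_assay[a] = _assay_shifts(
                by_key[(a, Timepoint.DAY0)], by_key[(a, Timepoint.DAY15)],
                taxonomy, {genus},
            )[genus]
        dna, rna = per_assay[Assay.DNA], per_assay[Assay.RNA]
        absent = (
            dna.day0_relabund == 0 and dna.day15_relabund == 0
            and rna.day0_relabund == 0 and rna.day15_relabund == 0
        )
        rows.append(
            {
                "genus": genus,
                "day0_dna": dna.day0_relabund,
                "day15_dna": dna.day15_relabund,
                "delta_dna": dna.delta,
                "fold_dna": dna.fold,
                "day0_rna": rna.day0_relabund,
                "day15_rna": rna.day15_relabund,
                "delta_rna": rna.delta,
                "fold_rna": rna.fold,
                "delta_min": min(dna.delta, rna.delta),
                "absent_both_timepoints": absent,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(
        ["delta_min", "genus"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
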