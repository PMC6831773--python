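"""Domain types shared across the SIP analysis stages.

A stable-isotope-probing (SIP) experiment ultracentrifuges DNA or rRNA on an
isopycnic density gradient (CsCl for DNA, CsTFA for rRNA), fractionates the
gradient, and sequences 16S rRNA amplicons per fraction.  Organisms that
assimilated a heavy substrate (here H13CO3-) band at a higher buoyant density
than their unlabeled counterparts.  These types model one such experiment:
fractions, per-gradient OTU count tables, taxonomy, nonfractionated community
profiles, and the daily water chemistry of the feed columns.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Treatment",
    "Isotope",
    "Assay",
    "Timepoint",
    "Guild",
    "FractionSample",
    "OtuFractionTable",
    "TaxonomyMap",
    "CommunityProfile",
    "ChemistryRecord",
    "GradientKey",
    "DNA_DENSITY_WINDOW",
    "RNA_DENSITY_WINDOW",
]

#: Typical buoyant-density windows (g/ml) for the two gradient media.
DNA_DENSITY_WINDOW = (1.66, 1.78)  # CsCl
RNA_DENSITY_WINDOW = (1.74, 1.84)  # CsTFA


class Treatment(str, enum.Enum):
    """Feed regime of a column: N source plus optional nitrification inhibitor."""

    NH4 = "NH4"  # ammonium only
    NH4_ATU = "NH4_ATU"  # ammonium + allylthiourea (AMO inhibitor)
    NO2 = "NO2"  # nitrite only
    NH4_CLO3 = "NH4_CLO3"  # ammonium + chlorate (NXR inhibitor)


class Isotope(str, enum.Enum):
    C12 = "C12"
    C13 = "C13"


class Assay(str, enum.Enum):
    DNA = "DNA"
    RNA = "RNA"


class Timepoint(str, enum.Enum):
    DAY0 = "day0"
    DAY15 = "day15"


class Guild(str, enum.Enum):
    """Functional role assigned by the treatment-contrast logic."""

    AMMONIA_OXIDIZER = "AMMONIA_OXIDIZER"
    NITRITE_OXIDIZER = "NITRITE_OXIDIZER"
    LABELED_OTHER = "LABELED_OTHER"
    UNLABELED = "UNLABELED"


#: Identity of one gradient: (treatment, isotope, assay, column_id).
GradientKey = tuple  # (Treatment, Isotope, Assay, str)


@dataclass(frozen=True)
class FractionSample:
    """One gradient fraction: its position, density, and nucleic-acid yield.

    ``fraction_index`` is 1-based and ordered heavy-to-light, following the
    convention that fraction 1 is drawn from the bottom (densest part) of the
    tube.  ``buoyant_density`` is in g/ml, ``na_concentration`` in ng/ul.
    """

    sample_id: str
    treatment: Treatment
    isotope: Isotope
    assay: Assay
    column_id: str
    fraction_index: int
    buoyant_density: float
    na_concentration: float

    def __post_init__(self) -> None:
        if self.buoyant_density <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: buoyant_density must be > 0, "
                f"got {self.buoyant_density}"
            )
        if self.na_concentration < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: na_concentration must be >= 0"
            )
        if self.fraction_index < 1:
            raise ValueError(f"sample {self.sample_id!r}: fraction_index must be >= 1")
        lo, hi = DNA_DENSITY_WINDOW if self.assay is Assay.DNA else RNA_DENSITY_WINDOW
        if not (lo - 0.02 <= self.buoyant_density <= hi + 0.02):
            warnings.warn(
                f"sample {self.sample_id!r}: buoyant density "
                f"{self.buoyant_density:.4f} g/ml outside the usual "
                f"{self.assay.value} window [{lo}, {hi}]",
                stacklevel=2,
            )

    @property
    def gradient_key(self) -> GradientKey:
        return (self.treatment, self.isotope, self.assay, self.column_id)


@dataclass
class OtuFractionTable:
    """Counts of OTUs across the sequenced fractions of one gradient.

    All samples must share the same (treatment, isotope, assay, column_id);
    within the gradient, densities must be strictly monotone in
    fraction_index.  ``counts`` is an integer [otu x sample] matrix.
    """

    otu_ids: list[str]
    samples: list[FractionSample]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            o, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.otu_ids[o]!r}, "
                f"sample {self.samples[s].sample_id!r}"
            )
        keys = {s.gradient_key for s in self.samples}
        if len(keys) > 1:
            raise ValueError(f"samples span multiple gradients: {sorted(map(str, keys))}")
        order = np.argsort([s.fraction_index for s in self.samples])
        self.samples = [self.samples[i] for i in order]
        self.counts = self.counts[:, order]
        dens = self.densities
        diffs = np.diff(dens)
        if len(dens) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError(
                "buoyant densities are not strictly monotone in fraction_index"
            )

    @property
    def key(self) -> GradientKey:
        return self.samples[0].gradient_key

    @property
    def treatment(self) -> Treatment:
        return self.samples[0].treatment

    @property
    def isotope(self) -> Isotope:
        return self.samples[0].isotope

    @property
    def assay(self) -> Assay:
        return self.samples[0].assay

    @property
    def column_id(self) -> str:
        return self.samples[0].column_id

    @property
    def densities(self) -> np.ndarray:
        """Buoyant density (g/ml) of each sample column, in sample order."""
        return np.array([s.buoyant_density for s in self.samples])

    @property
    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Within-fraction relative abundances; zero columns map to zeros."""
        sums = self.column_sums.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / sums
        rel[:, sums == 0] = 0.0
        return rel

    def otu_index(self, otu_id: str) -> int:
        try:
            return self.otu_ids.index(otu_id)
        except ValueError:
            raise KeyError(f"OTU {otu_id!r} not in table {self.key}") from None


@dataclass
class TaxonomyMap:
    """otu_id -> lineage; exposes the genus grouping the filter cascade uses.

    Lineages are semicolon-delimited strings; Greengenes-style rank prefixes
    ("g__Nitrospira") are recognised.  OTUs without a genus token fall into an
    "unclassified_<last rank>" bin so the genus-level rules still apply.
    """

    lineages: dict[str, str]

    def genus(self, otu_id: str) -> str:
        try:
            lineage = self.lineages[otu_id]
        except KeyError:
            raise KeyError(f"OTU {otu_id!r} has no taxonomy entry") from None
        ranks = [r.strip() for r in lineage.split(";") if r.strip()]
        for rank in ranks:
            if rank.startswith("g__"):
                name = rank[3:].strip()
                return name if name else self._unclassified(ranks)
        if ranks and not any(r[1:3] == "__" for r in ranks if len(r) > 2):
            # plain lineage without rank prefixes: last token is the genus
            return ranks[-1]
        return self._unclassified(ranks)

    @staticmethod
    def _unclassified(ranks: list[str]) -> str:
        for rank in reversed(ranks):
            if rank.startswith(("f__", "o__", "c__", "p__", "k__")) and rank[3:]:
                return f"unclassified_{rank[3:]}"
        return "unclassified"

    def genus_members(self, otu_ids) -> dict[str, set[str]]:
        """Group the given OTU ids by genus."""
        out: dict[str, set[str]] = {}
        for otu in otu_ids:
            out.setdefault(self.genus(otu), set()).add(otu)
        return out


@dataclass
class CommunityProfile:
    """Relative abundances in a nonfractionated (total) DNA or rRNA extract."""

    assay: Assay
    timepoint: Timepoint
    relabund: dict[str, float]
    treatment: Treatment | None = None

    def __post_init__(self) -> None:
        total = float(sum(self.relabund.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"community profile relative abundances sum to {total}, not 1"
            )

    def genus_relabund(self, taxonomy: TaxonomyMap) -> dict[str, float]:
        out: dict[str, float] = {}
        for otu, ra in self.relabund.items():
            g = taxonomy.genus(otu)
            out[g] = out.get(g, 0.0) + ra
        return out


@dataclass(frozen=True)
class ChemistryRecord:
    """One day's influent/effluent N species concentrations (uM) for a column."""

    day: int
    nh4_in: float
    nh4_out: float
    no2_in: float
    no2_out: float
    no3_in: float
    no3_out: float

    def __post_init__(self) -> None:
        for name in ("nh4_in", "nh4_out", "no2_in", "no2_out", "no3_in", "no3_out"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"day {self.day}: {name}={v} must be finite and >= 0")

    @property
    def total_n_in(self) -> float:
        return self.nh4_in + self.no2_in + self.no3_in

    @property
    def total_n_out(self) -> float:
        return self.nh4_out + self.no2_out + self.no3_out
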