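"""Synthetic SIP experiments with known ground truth.

The generator emulates the full four-treatment x two-isotope column design:
each taxon bands at a Gaussian position in buoyant-density space, 13C feeding
moves the band center upward by ``atom_fraction x max_shift`` for organisms
that assimilate bicarbonate under the given feed regime, and per-fraction
sequencing counts are multinomial draws at a fixed depth.  It also produces
the companion inputs of a real experiment: bulk nucleic-acid concentration
profiles per gradient, total-community profiles at day 0 and day 15 (labeled
autotrophs grow over the run), and daily column chemistry with first-order
substrate removal plus measurement noise.

Roles encode the biology of the design: comammox organisms and canonical
ammonia oxidizers assimilate H13CO3- only when ammonia oxidation can proceed
(NH4-only feed); nitrite oxidizers are labeled under NH4 (nitrite supplied by
ammonia oxidation in situ) and NO2 feeding but not when chlorate poisons
nitrite oxidoreductase; cross-feeders acquire a small secondary label;
heterotrophs none.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

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
from . import io as sio

__all__ = [
    "Role",
    "TaxonSpec",
    "DesignSpec",
    "SyntheticDataset",
    "default_community",
    "simulate_gradient",
    "simulate_experiment",
    "write_dataset",
]


class Role(str, enum.Enum):
    COMAMMOX = "COMAMMOX"
    AOB = "AOB"
    NOB = "NOB"
    CROSS_FEEDER = "CROSS_FEEDER"
    HETEROTROPH = "HETEROTROPH"


@dataclass(frozen=True)
class TaxonSpec:
    """One simulated OTU: its band positions and per-treatment labeling."""

    otu_id: str
    genus: str
    role: Role
    base_abundance: float
    unlabeled_mu_dna: float  # g/ml, CsCl band center without label
    unlabeled_mu_rna: float  # g/ml, CsTFA band center without label
    atom_fraction: dict[Treatment, float] = field(default_factory=dict)
    sigma_band: float = 0.010  # g/ml

    def center(self, treatment: Treatment, isotope: Isotope, assay: Assay,
               max_shift: float) -> float:
        mu = self.unlabeled_mu_dna if assay is Assay.DNA else self.unlabeled_mu_rna
        if isotope is Isotope.C13:
            mu += self.atom_fraction.get(treatment, 0.0) * max_shift
        return mu


@dataclass(frozen=True)
class DesignSpec:
    """Structure of the simulated experiment (the study design)."""

    treatments: tuple[Treatment, ...] = tuple(Treatment)
    isotopes: tuple[Isotope, ...] = (Isotope.C12, Isotope.C13)
    assays: tuple[Assay, ...] = (Assay.DNA, Assay.RNA)
    replicates: int = 1  # replicate columns per treatment x isotope
    n_fractions: int = 16
    dna_density_range: tuple[float, float] = (1.66, 1.78)
    rna_density_range: tuple[float, float] = (1.74, 1.84)
    depth: int = 10_000  # reads per fraction
    max_shift_dna: float = 0.036  # g/ml at atom fraction 1 (full 13C labeling)
    max_shift_rna: float = 0.035
    rna_sequenced: int = 8  # of n_fractions (RNA-SIP sequences a subset)
    n_days: int = 15
    chem_noise_sd: float = 1.0  # uM, effluent measurement noise
    growth_gain: float = 3.0  # day-15 enrichment per unit atom fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 100:
            raise ValueError(f"depth must be >= 100, got {self.depth}")
        if not (1 <= self.rna_sequenced <= self.n_fractions):
            raise ValueError("rna_sequenced must be in [1, n_fractions]")


_LINEAGES = {
    "Nitrospira": "k__Bacteria; p__Nitrospirae; c__Nitrospira; o__Nitrospirales; f__Nitrospiraceae; g__Nitrospira",
    "Nitrosomonas": "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Nitrosomonadales; f__Nitrosomonadaceae; g__Nitrosomonas",
    "Pedomicrobium": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhizobiales; f__Hyphomicrobiaceae; g__Pedomicrobium",
    "Pseudomonas": "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Pseudomonadales; f__Pseudomonadaceae; g__Pseudomonas",
    "Flavobacterium": "k__Bacteria; p__Bacteroidetes; c__Flavobacteriia; o__Flavobacteriales; f__Flavobacteriaceae; g__Flavobacterium",
    "Sphingomonas": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Sphingomonadales; f__Sphingomonadaceae; g__Sphingomonas",
    "Rhodoferax": "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Burkholderiales; f__Comamonadaceae; g__Rhodoferax",
}

# Labeling by role: which feed regimes let the organism assimilate H13CO3-.
_ROLE_ATOM_FRACTIONS: dict[Role, dict[Treatment, float]] = {
    Role.COMAMMOX: {Treatment.NH4: 1.0},
    # Canonical AOB assimilate slightly less than comammox per cell division
    # in this system, so the filter-4 reference threshold (max Nitrosomonas
    # shift) sits below the comammox shifts, as observed in situ.
    Role.AOB: {Treatment.NH4: 0.85},
    Role.NOB: {Treatment.NH4: 1.0, Treatment.NO2: 1.0},
    Role.CROSS_FEEDER: {Treatment.NH4: 0.1},
    Role.HETEROTROPH: {},
}


def default_community(seed: int = 20190715) -> list[TaxonSpec]:
    """The default 60-OTU community: 6 comammox + 6 NOB Nitrospira, 4
    Nitrosomonas AOB, 4 Pedomicrobium cross-feeders, 40 heterotrophs.

    The heterotroph band centers tile the whole collected density window
    (GC content varies widely across a community, so bulk nucleic acid is
    found in every fraction); the nitrifier/cross-feeder bands sit in the
    mid-gradient so their 13C-shifted positions stay within the window.
    Because every fraction carries material from resident taxa under both
    isotopes, within-fraction relative abundances are well conditioned and
    the density-shift estimators are nearly unbiased.  Abundances are flat
    within role and sum to one.
    """
    rng = np.random.default_rng(seed)
    plan = [
        ("Nitrospira", Role.COMAMMOX, 6, 0.012),
        ("Nitrospira", Role.NOB, 6, 0.012),
        ("Nitrosomonas", Role.AOB, 4, 0.008),
        ("Pedomicrobium", Role.CROSS_FEEDER, 4, 0.008),
        ("Pseudomonas", Role.HETEROTROPH, 10, 0.0198),
        ("Flavobacterium", Role.HETEROTROPH, 10, 0.0198),
        ("Sphingomonas", Role.HETEROTROPH, 10, 0.0198),
        ("Rhodoferax", Role.HETEROTROPH, 10, 0.0198),
    ]
    n_het = sum(n for _g, r, n, _a in plan if r is Role.HETEROTROPH)
    het_mu_dna = iter(np.linspace(1.665, 1.775, n_het))
    het_mu_rna = iter(np.linspace(1.745, 1.835, n_het))
    taxa: list[TaxonSpec] = []
    i = 0
    for genus, role, n, abund in plan:
        for _ in range(n):
            i += 1
            if role is Role.HETEROTROPH:
                mu_dna = float(next(het_mu_dna) + rng.uniform(-0.002, 0.002))
                mu_rna = float(next(het_mu_rna) + rng.uniform(-0.002, 0.002))
            else:
                mu_dna = float(rng.uniform(1.695, 1.715))
                mu_rna = float(rng.uniform(1.770, 1.785))
            taxa.append(
                TaxonSpec(
                    otu_id=f"OTU_{i:03d}",
                    genus=genus,
                    role=role,
                    base_abundance=abund,
                    unlabeled_mu_dna=mu_dna,
                    unlabeled_mu_rna=mu_rna,
                    atom_fraction=dict(_ROLE_ATOM_FRACTIONS[role]),
                )
            )
    total = sum(t.base_abundance for t in taxa)
    return [replace(t, base_abundance=t.base_abundance / total) for t in taxa]


def dose_response_community(
    levels: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0),
    n_per_level: int = 3,
    seed: int = 20190715,
) -> tuple[list[TaxonSpec], dict[str, float]]:
    """Calibration community: focal taxa planted at given NH4 atom fractions
    on top of the gradient-spanning heterotroph background.

    Returns the taxa plus a map otu_id -> planted atom fraction for the focal
    taxa, used to validate dose-response of shift recovery.
    """
    rng = np.random.default_rng(seed)
    background = [
        t for t in default_community(seed) if t.role is Role.HETEROTROPH
    ]
    focal: list[TaxonSpec] = []
    planted: dict[str, float] = {}
    i = 0
    for level in levels:
        for _ in range(n_per_level):
            i += 1
            otu = f"FOCAL_{i:03d}"
            focal.append(
                TaxonSpec(
                    otu_id=otu,
                    genus=f"Dosegenus_{int(round(level * 100)):03d}",
                    role=Role.HETEROTROPH,
                    base_abundance=0.01,
                    unlabeled_mu_dna=float(rng.uniform(1.695, 1.715)),
                    unlabeled_mu_rna=float(rng.uniform(1.770, 1.785)),
                    atom_fraction={Treatment.NH4: level},
                )
            )
            planted[otu] = level
    taxa = background + focal
    total = sum(t.base_abundance for t in taxa)
    return (
        [replace(t, base_abundance=t.base_abundance / total) for t in taxa],
        planted,
    )


def _expected_relabund(
    taxa: list[TaxonSpec],
    densities: np.ndarray,
    treatment: Treatment,
    isotope: Isotope,
    assay: Assay,
    max_shift: float,
) -> np.ndarray:
    """Expected within-fraction relative abundances [taxon x fraction]."""
    w = np.zeros((len(taxa), len(densities)))
    for i, t in enumerate(taxa):
        mu = t.center(treatment, isotope, assay, max_shift)
        w[i] = t.base_abundance * norm.pdf(densities, mu, t.sigma_band)
    sums = w.sum(axis=0)
    sums[sums == 0] = 1.0
    return w / sums


def simulate_gradient(
    taxa: list[TaxonSpec],
    design: DesignSpec,
    treatment: Treatment,
    isotope: Isotope,
    assay: Assay,
    seed: int,
    column_id: str = "column_1",
) -> OtuFractionTable:
    """Simulate one gradient's sequenced fraction table.

    Fraction 1 is the densest; expected abundances are the Gaussian band
    model normalised within each fraction, counts are multinomial at the
    design depth.  RNA gradients report only ``rna_sequenced`` evenly spaced
    fractions (the rest were not sequenced), exercising the sparse
    band-center estimator downstream.
    """
    rng = np.random.default_rng(seed)
    lo, hi = (
        design.dna_density_range if assay is Assay.DNA else design.rna_density_range
    )
    densities = np.linspace(hi, lo, design.n_fractions)  # heavy -> light
    max_shift = design.max_shift_dna if assay is Assay.DNA else design.max_shift_rna
    p = _expected_relabund(taxa, densities, treatment, isotope, assay, max_shift)

    counts = np.zeros((len(taxa), design.n_fractions), dtype=np.int64)
    for f in range(design.n_fractions):
        counts[:, f] = rng.multinomial(design.depth, p[:, f])

    # bulk nucleic-acid concentration profile (ng/ul), light multiplicative noise
    bulk = np.zeros(design.n_fractions)
    for t in taxa:
        mu = t.center(treatment, isotope, assay, max_shift)
        bulk += t.base_abundance * norm.pdf(densities, mu, t.sigma_band)
    conc = 50.0 * bulk / bulk.max()
    conc = conc * rng.lognormal(0.0, 0.02, size=conc.shape)

    if assay is Assay.RNA and design.rna_sequenced < design.n_fractions:
        idx = np.unique(
            np.round(np.linspace(0, design.n_fractions - 1, design.rna_sequenced))
        ).astype(int)
    else:
        idx = np.arange(design.n_fractions)

    samples = [
        FractionSample(
            sample_id=f"{treatment.value}_{isotope.value}_{assay.value}_{column_id}_f{f + 1:02d}",
            treatment=treatment,
            isotope=isotope,
            assay=assay,
            column_id=column_id,
            fraction_index=int(f + 1),
            buoyant_density=float(densities[f]),
            na_concentration=float(conc[f]),
        )
        for f in idx
    ]
    return OtuFractionTable(
        otu_ids=[t.otu_id for t in taxa],
        samples=samples,
        counts=counts[:, idx],
    )


# Chemistry parameters per treatment: (nh4_in, no2_in, no3_in, nh4 removal
# fraction, no2 effluent above trace as a fraction of produced NO2).
_CHEM_REGIME: dict[Treatment, tuple[float, float, float, float, float]] = {
    Treatment.NH4: (71.0, 0.3, 5.0, 0.99, 0.0),
    Treatment.NH4_ATU: (71.0, 0.3, 5.0, 0.15, 0.0),
    Treatment.NO2: (0.5, 71.0, 5.0, 0.0, 0.12),
    Treatment.NH4_CLO3: (71.0, 0.3, 5.0, 0.08, 0.30),
}


def _simulate_chemistry(
    treatment: Treatment, design: DesignSpec, rng: np.random.Generator
) -> list[ChemistryRecord]:
    nh4_in, no2_in, no3_in, nh4_frac, no2_resid = _CHEM_REGIME[treatment]
    records = []
    for day in range(1, design.n_days + 1):
        nh4_out = nh4_in * (1.0 - nh4_frac)
        if treatment is Treatment.NO2:
            produced_no2 = no2_in
        else:
            produced_no2 = nh4_in - nh4_out
        no2_out = 0.3 + no2_resid * produced_no2
        total_in = nh4_in + no2_in + no3_in
        # nitrogen is conserved: whatever is neither NH4 nor NO2 leaves as NO3
        no3_out = total_in - nh4_out - no2_out
        def measured(value: float) -> float:
            # measurement error scales down near the detection limit
            sd = design.chem_noise_sd if value >= 3.0 else 0.1
            return max(value + rng.normal(0.0, sd), 0.0)

        records.append(
            ChemistryRecord(
                day=day,
                nh4_in=nh4_in,
                nh4_out=measured(nh4_out),
                no2_in=no2_in,
                no2_out=measured(no2_out),
                no3_in=no3_in,
                no3_out=measured(no3_out),
            )
        )
    return records


def _community_profiles(
    taxa: list[TaxonSpec], design: DesignSpec
) -> list[CommunityProfile]:
    base = {t.otu_id: t.base_abundance for t in taxa}
    profiles = [
        CommunityProfile(assay=a, timepoint=Timepoint.DAY0, relabund=dict(base))
        for a in design.assays
    ]
    for treatment in design.treatments:
        grown = {
            t.otu_id: t.base_abundance
            * (1.0 + design.growth_gain * t.atom_fraction.get(treatment, 0.0))
            for t in taxa
        }
        total = sum(grown.values())
        grown = {o: v / total for o, v in grown.items()}
        for a in design.assays:
            profiles.append(
                CommunityProfile(
                    assay=a,
                    timepoint=Timepoint.DAY15,
                    relabund=dict(grown),
                    treatment=treatment,
                )
            )
    return profiles


@dataclass
class SyntheticDataset:
    """A complete simulated experiment plus its ground truth."""

    taxa: list[TaxonSpec]
    design: DesignSpec
    tables: list[OtuFractionTable]
    profiles: list[CommunityProfile]
    chemistry: dict[str, list[ChemistryRecord]]
    column_treatments: dict[str, Treatment]
    taxonomy: TaxonomyMap

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.taxa:
            row = {
                "otu_id": t.otu_id,
                "genus": t.genus,
                "role": t.role.value,
                "base_abundance": t.base_abundance,
            }
            for tr in Treatment:
                row[f"atom_fraction_{tr.value}"] = t.atom_fraction.get(tr, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    def role_otus(self, *roles: Role) -> set[str]:
        return {t.otu_id for t in self.taxa if t.role in roles}

    def profiles_for(self, treatment: Treatment) -> list[CommunityProfile]:
        """Day-0 profiles plus the day-15 profiles of one treatment."""
        return [
            p
            for p in self.profiles
            if p.timepoint is Timepoint.DAY0
            or (p.timepoint is Timepoint.DAY15 and p.treatment is treatment)
        ]


def simulate_experiment(
    taxa: list[TaxonSpec] | None = None, design: DesignSpec | None = None
) -> SyntheticDataset:
    """Simulate the complete experiment: every gradient table the reader
    would produce, community profiles, chemistry, and the truth table.

    All randomness derives from ``design.seed`` via spawned generator
    streams, so the same design yields byte-identical output files.
    """
    taxa = default_community() if taxa is None else taxa
    design = DesignSpec() if design is None else design
    root = np.random.SeedSequence(design.seed)
    n_gradients = (
        len(design.treatments) * len(design.isotopes) * design.replicates
        * len(design.assays)
    )
    streams = root.spawn(n_gradients + len(design.treatments))

    tables: list[OtuFractionTable] = []
    column_treatments: dict[str, Treatment] = {}
    k = 0
    col = 0
    for treatment in design.treatments:
        for isotope in design.isotopes:
            for rep in range(design.replicates):
                col += 1
                column_id = f"column_{col}"
                column_treatments[column_id] = treatment
                for assay in design.assays:
                    tables.append(
                        simulate_gradient(
                            taxa,
                            design,
                            treatment,
                            isotope,
                            assay,
                            seed=int(streams[k].generate_state(1)[0] % (2**31)),
                            column_id=column_id,
                        )
                    )
                    k += 1

    chemistry: dict[str, list[ChemistryRecord]] = {}
    for i, treatment in enumerate(design.treatments):
        rng = np.random.default_rng(streams[n_gradients + i])
        for column_id, tr in column_treatments.items():
            if tr is treatment:
                chemistry[column_id] = _simulate_chemistry(treatment, design, rng)

    taxonomy = TaxonomyMap(
        {t.otu_id: _LINEAGES.get(t.genus, f"k__Bacteria; g__{t.genus}") for t in taxa}
    )
    return SyntheticDataset(
        taxa=taxa,
        design=design,
        tables=tables,
        profiles=_community_profiles(taxa, design),
        chemistry=chemistry,
        column_treatments=column_treatments,
        taxonomy=taxonomy,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the dataset as the text-file set the pipeline reads, plus
    truth.tsv and the column -> treatment map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "community": outdir / "community.tsv",
        "chemistry": outdir / "chemistry.csv",
        "truth": outdir / "truth.tsv",
        "columns": outdir / "columns.tsv",
    }
    sio.write_fraction_tables(dataset.tables, paths["counts"], paths["metadata"])
    sio.write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    sio.write_community_profiles(dataset.profiles, paths["community"])
    sio.write_chemistry(dataset.chemistry, paths["chemistry"])
    dataset.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"column_id": c, "treatment": t.value}
            for c, t in dataset.column_treatments.items()
        ]
    ).to_csv(paths["columns"], sep="\t", index=False)
    return paths
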