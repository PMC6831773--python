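"""Buoyant-density estimation and the 12C -> 13C shift per OTU.

Two band-center estimators are provided:

* :func:`weighted_mean_bd` — the abundance-weighted mean buoyant density of an
  OTU across all fractions of a gradient (DNA-SIP, where every fraction was
  sequenced).  Relative abundance is computed within-fraction, so deeply
  sequenced fractions do not dominate by library size.
* :func:`mean_bd_sparse` — for gradients where only selected fractions were
  sequenced (RNA-SIP): the OTU's abundance profile across density is assumed
  Gaussian with a standard deviation fixed at the value fitted to the bulk
  nucleic-acid concentration profile of the gradient; the band center is the
  grid maximizer of the abundance-weighted normal log-density.

An OTU's shift is then the difference of its mean buoyant density between
replicate 13C- and 12C-fed gradients of the same treatment and assay; a
positive shift means the OTU banded heavier under 13C, the signature of
isotope assimilation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import Assay, GradientKey, Isotope, OtuFractionTable, Treatment

logger = logging.getLogger(__name__)

__all__ = [
    "AbsentOtuError",
    "ShiftRecord",
    "GradientProfile",
    "weighted_mean_bd",
    "fit_gradient_profile",
    "mean_bd_sparse",
    "gradient_mean_bds",
    "compute_shifts",
    "shifts_to_frame",
]

#: Density-grid step (g/ml) for the fixed-sigma band-center search.
GRID_STEP = 1e-4


class AbsentOtuError(KeyError):
    """The OTU has zero counts in every sequenced fraction of the gradient."""


@dataclass(frozen=True)
class ShiftRecord:
    """Per-OTU mean buoyant densities under each isotope and their difference.

    ``shift = mean_bd_13c - mean_bd_12c`` (g/ml); positive = heavier under 13C.
    """

    otu_id: str
    treatment: Treatment
    assay: Assay
    mean_bd_12c: float
    mean_bd_13c: float
    shift: float
    n_fractions_12c: int
    n_fractions_13c: int
    estimator: str  # WEIGHTED_MEAN or GAUSSIAN_FIXED_SIGMA


@dataclass
class GradientProfile:
    """Gaussian fit of bulk nucleic-acid concentration vs. buoyant density."""

    densities: np.ndarray
    concentrations: np.ndarray
    fitted_mu: float
    fitted_sigma: float
    fitted_amplitude: float
    moment_fallback: bool = False

    def __post_init__(self) -> None:
        if self.fitted_sigma <= 0:
            raise ValueError(f"fitted_sigma must be > 0, got {self.fitted_sigma}")
        lo = float(np.min(self.densities)) - 0.02
        hi = float(np.max(self.densities)) + 0.02
        if not (lo <= self.fitted_mu <= hi):
            raise ValueError(
                f"fitted_mu {self.fitted_mu:.4f} outside density span [{lo:.4f}, {hi:.4f}]"
            )


def weighted_mean_bd(table: OtuFractionTable, otu_id: str) -> float:
    """Abundance-weighted mean buoyant density of one OTU in one gradient.

    Returns ``sum_f(rel_of * rho_f) / sum_f(rel_of)`` where ``rel_of`` is the
    OTU's relative abundance within fraction f and ``rho_f`` the fraction's
    buoyant density.

    Raises :class:`AbsentOtuError` if the OTU has no counts in the gradient —
    absence is not a shift of zero.
    """
    i = table.otu_index(otu_id)
    rel = table.relative_abundance()[i]
    total = rel.sum()
    if total <= 0:
        raise AbsentOtuError(f"OTU {otu_id!r} absent from gradient {table.key}")
    return float(np.dot(rel, table.densities) / total)


def _moment_profile(densities, concentrations) -> tuple[float, float, float]:
    w = concentrations / concentrations.sum()
    mu = float(np.dot(w, densities))
    var = float(np.dot(w, (densities - mu) ** 2))
    if var <= 0:
        # flat/degenerate: spread over the sampled span
        var = float(np.var(densities)) or (GRID_STEP ** 2)
    return mu, float(np.sqrt(var)), float(np.max(concentrations))


def fit_gradient_profile(densities, concentrations) -> GradientProfile:
    """Least-squares Gaussian fit A*exp(-(rho-mu)^2 / 2 sigma^2) to the bulk
    concentration profile of a gradient.

    Falls back to concentration-weighted moment estimates (with
    ``moment_fallback=True``) when the fit does not converge or collapses.
    """
    densities = np.asarray(densities, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    pos = concentrations > 0
    if pos.sum() < 4:
        raise ValueError(
            f"need >= 4 fractions with positive concentration, got {int(pos.sum())}"
        )
    mu0, sigma0, amp0 = _moment_profile(densities[pos], concentrations[pos])

    def gauss(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))

    try:
        popt, _ = curve_fit(
            gauss,
            densities[pos],
            concentrations[pos],
            p0=[amp0, mu0, max(sigma0, 1e-4)],
            maxfev=10000,
        )
        amp, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        span_lo = float(densities.min()) - 0.02
        span_hi = float(densities.max()) + 0.02
        span = float(densities.max() - densities.min())
        if not (span_lo <= mu <= span_hi) or sigma <= 0 or amp <= 0:
            raise RuntimeError("implausible Gaussian fit")
        if sigma > span:
            # a band wider than the sampled window is unidentifiable
            raise RuntimeError("degenerate (flat) profile")
        resid = float(np.sum((gauss(densities[pos], *popt) - concentrations[pos]) ** 2))
        logger.debug("gradient profile fit: mu=%.4f sigma=%.4f rss=%.3g", mu, sigma, resid)
        return GradientProfile(densities, concentrations, mu, sigma, amp)
    except (RuntimeError, ValueError):
        logger.warning(
            "Gaussian profile fit failed; using moment estimates "
            "(mu=%.4f, sigma=%.4f)", mu0, sigma0,
        )
        return GradientProfile(
            densities, concentrations, mu0, sigma0, amp0, moment_fallback=True
        )


def mean_bd_sparse(
    table: OtuFractionTable, otu_id: str, profile: GradientProfile
) -> float:
    """Band center of an OTU when only some fractions were sequenced.

    Assumes the OTU's density distribution is normal with sigma fixed at the
    bulk-profile value and maximizes the abundance-weighted log-density
    ``sum_f w_of * log N(rho_f; mu, sigma)`` over a density grid of step
    1e-4 g/ml spanning the gradient +/- 2 sigma.
    """
    i = table.otu_index(otu_id)
    rel = table.relative_abundance()[i]
    if rel.sum() <= 0:
        raise AbsentOtuError(f"OTU {otu_id!r} absent from gradient {table.key}")
    return float(_sparse_centers(table, profile, rel[None, :])[0])


def _sparse_centers(
    table: OtuFractionTable, profile: GradientProfile, weights: np.ndarray
) -> np.ndarray:
    """Grid argmax of the fixed-sigma weighted normal log-density, vectorized
    over OTU weight rows.  Rows with zero total weight yield NaN."""
    rho = table.densities
    sigma = profile.fitted_sigma
    lo = rho.min() - 2.0 * sigma
    hi = rho.max() + 2.0 * sigma
    grid = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    # log N(rho; mu, sigma) = -(rho - mu)^2 / (2 sigma^2) + const
    ll = -((rho[None, :] - grid[:, None]) ** 2) / (2.0 * sigma ** 2)  # [grid x frac]
    score = weights @ ll.T  # [otu x grid]
    centers = grid[np.argmax(score, axis=1)]
    centers = centers.astype(float)
    centers[weights.sum(axis=1) <= 0] = np.nan
    return centers


def gradient_mean_bds(
    table: OtuFractionTable, profile: GradientProfile | None = None
) -> np.ndarray:
    """Mean buoyant density per OTU for one gradient (NaN where absent).

    DNA gradients (``profile is None``) use the weighted mean over all
    fractions; RNA gradients use the fixed-sigma sparse estimator.
    """
    rel = table.relative_abundance()
    totals = rel.sum(axis=1)
    if profile is None:
        with np.errstate(invalid="ignore"):
            out = (rel @ table.densities) / totals
        out[totals <= 0] = np.nan
        return out
    return _sparse_centers(table, profile, rel)


def _fit_rna_profile(table: OtuFractionTable) -> GradientProfile:
    conc = np.array([s.na_concentration for s in table.samples])
    return fit_gradient_profile(table.densities, conc)


def compute_shifts(
    tables: list[OtuFractionTable],
    rna_profiles: dict[GradientKey, GradientProfile] | None = None,
) -> list[ShiftRecord]:
    """Per-OTU buoyant-density shift for every treatment x assay combination.

    Mean buoyant density is computed per gradient (DNA: weighted mean over all
    fractions; RNA: fixed-sigma estimator with sigma fitted from that
    gradient's bulk concentration profile unless supplied in
    ``rna_profiles``), then averaged with equal weight across replicate
    columns of the same treatment x isotope.  OTUs absent from all gradients
    of either isotope get no record.  A treatment x assay present under only
    one isotope is a hard error.
    """
    groups: dict[tuple[Treatment, Assay], dict[Isotope, list[OtuFractionTable]]] = {}
    for t in tables:
        groups.setdefault((t.treatment, t.assay), {}).setdefault(t.isotope, []).append(t)

    records: list[ShiftRecord] = []
    for (treatment, assay), by_iso in sorted(
        groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        for iso in (Isotope.C12, Isotope.C13):
            if iso not in by_iso:
                raise ValueError(
                    f"treatment {treatment.value} / {assay.value}: no {iso.value} gradient"
                )
        estimator = "WEIGHTED_MEAN" if assay is Assay.DNA else "GAUSSIAN_FIXED_SIGMA"
        stats: dict[Isotope, tuple[pd.Series, pd.Series]] = {}
        for iso, iso_tables in by_iso.items():
            means, nfr = [], []
            for tb in iso_tables:
                profile = None
                if assay is Assay.RNA:
                    if rna_profiles is not None and tb.key in rna_profiles:
                        profile = rna_profiles[tb.key]
                    else:
                        profile = _fit_rna_profile(tb)
                means.append(pd.Series(gradient_mean_bds(tb, profile), index=tb.otu_ids))
                nfr.append(pd.Series((tb.counts > 0).sum(axis=1), index=tb.otu_ids))
            mean_df = pd.concat(means, axis=1)
            # equal-weight average across replicate gradients where present
            stats[iso] = (mean_df.mean(axis=1), pd.concat(nfr, axis=1).sum(axis=1))

        mean12, n12 = stats[Isotope.C12]
        mean13, n13 = stats[Isotope.C13]
        common = mean12.index.union(mean13.index)
        for otu in common:
            m12 = mean12.get(otu, np.nan)
            m13 = mean13.get(otu, np.nan)
            if np.isnan(m12) or np.isnan(m13):
                continue  # absent from one isotope's gradients: not evaluable
            records.append(
                ShiftRecord(
                    otu_id=str(otu),
                    treatment=treatment,
                    assay=assay,
                    mean_bd_12c=float(m12),
                    mean_bd_13c=float(m13),
                    shift=float(m13 - m12),
                    n_fractions_12c=int(n12.get(otu, 0)),
                    n_fractions_13c=int(n13.get(otu, 0)),
                    estimator=estimator,
                )
            )
    return records


def shifts_to_frame(records: list[ShiftRecord]) -> pd.DataFrame:
    """Tabulate shift records (the shifts.tsv layout)."""
    return pd.DataFrame(
        [
            {
                "otu_id": r.otu_id,
                "treatment": r.treatment.value,
                "assay": r.assay.value,
                "mean_bd_12C": r.mean_bd_12c,
                "mean_bd_13C": r.mean_bd_13c,
                "shift": r.shift,
                "n_fractions_12C": r.n_fractions_12c,
                "n_fractions_13C": r.n_fractions_13c,
                "estimator": r.estimator,
            }
            for r in records
        ]
    )
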