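"""Deterministic genome-scale calculators.

Pure-arithmetic estimators chaining plasmid-scale measurements up to
genome-wide DSB counts at therapeutic doses: at-risk lesion arrangements,
per-genome DSB estimates, quadratic dose scaling, conversion rates, and the
repair patch-size bookkeeping.

Every result carries both the exact value and a 2-significant-figure
rounding, since the published chain rounds at each step.  Two genome sizes
are deliberately kept: 6e9 nt (single-strand nucleotides, used for lesion
*density*) and 3e9 bp (used for DSB *scaling*); a consistent mode can be
obtained by setting both fields to the same value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

#: Static radiobiology reference constants (2 Gy of ionizing radiation).
IR_2GY_SSB_PER_CELL = 2000
IR_2GY_DSB_PER_CELL = 40


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (2 matches the reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class GenomeLesionLoad:
    """Per-genome lesion loads and the MMR excision window.

    Defaults are the loads measured at a 50 uM daily clinical serum dose.
    """

    n_oalkyl: float = 5.2e4
    n_nalkyl: float = 7.3e5
    genome_nt_for_density: float = 6e9
    genome_bp_for_scaling: float = 3e9
    window_nt: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "n_oalkyl",
            "n_nalkyl",
            "genome_nt_for_density",
            "genome_bp_for_scaling",
            "window_nt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.genome_nt_for_density <= 0 or self.genome_bp_for_scaling <= 0:
            raise ValueError("genome sizes must be positive")


@dataclass(frozen=True)
class AtRiskResult:
    prob: float  # exact
    prob_rounded: float  # 2 decimals, as printed
    count: float  # exact: n_oalkyl * prob
    count_rounded: float  # n_oalkyl * prob_rounded, the rounded-chain value


def at_risk(load: GenomeLesionLoad) -> AtRiskResult:
    """Probability and count of O-alkyl lesions with an N-alkyl lesion in
    their excision window.

    prob = window_nt * n_nalkyl / genome_nt_for_density;
    count = n_oalkyl * prob.  The ``_rounded`` variant rounds the
    probability to two decimals before multiplying, matching the
    round-at-each-step reporting convention.
    """
    prob = load.window_nt * load.n_nalkyl / load.genome_nt_for_density
    if prob > 1.0:
        raise ValueError(
            f"window too large for density: at-risk probability {prob:.3g} > 1"
        )
    prob_rounded = round(prob, 2)
    return AtRiskResult(
        prob=prob,
        prob_rounded=prob_rounded,
        count=load.n_oalkyl * prob,
        count_rounded=load.n_oalkyl * prob_rounded,
    )


@dataclass(frozen=True)
class DsbEstimate:
    exact: float
    rounded: float  # 2 significant figures


def dsb_per_genome_from_plasmid(
    linear_fraction: float, plasmid_bp: float, genome_bp: float = 3e9
) -> DsbEstimate:
    """Scale a plasmid linear fraction to DSBs per genome.

    genome_bp * linear_fraction / plasmid_bp (e.g. 3e9 * 0.06 / 11300).
    """
    if not 0.0 <= linear_fraction <= 1.0:
        raise ValueError("linear_fraction must be in [0, 1]")
    if plasmid_bp <= 0 or genome_bp <= 0:
        raise ValueError("sizes must be positive")
    exact = genome_bp * linear_fraction / plasmid_bp
    return DsbEstimate(exact, round_sig(exact))


def scale_dose_quadratic(dsb_ref: float, dose_ref_mM: float, dose_new_mM: float) -> float:
    """Quadratic dose scaling: dsb_ref * (dose_new / dose_ref)^2."""
    if dose_ref_mM <= 0 or dose_new_mM <= 0:
        raise ValueError("doses must be positive")
    if dsb_ref < 0:
        raise ValueError("dsb_ref must be non-negative")
    return dsb_ref * (dose_new_mM / dose_ref_mM) ** 2


def conversion_rate(dsb_count: float, at_risk_count: float) -> float:
    """Fraction of at-risk lesion arrangements actually converted to DSBs."""
    if at_risk_count <= 0:
        raise ValueError("at_risk_count must be positive")
    if dsb_count < 0:
        raise ValueError("dsb_count must be non-negative")
    return dsb_count / at_risk_count


@dataclass(frozen=True)
class PatchSizeEstimate:
    """UDS percent -> nt bookkeeping for either or both adduct families."""

    total_o6mg_synthesis_nt: Optional[float] = None
    per_o6mg_patch_nt: Optional[float] = None
    per_engaged_patch_nt: Optional[float] = None
    total_nalkyl_synthesis_nt: Optional[float] = None
    per_nalkyl_patch_nt: Optional[float] = None


def patch_size_estimates(
    plasmid_bp: float,
    uds_pct_o6mg: Optional[float] = None,
    n_o6mg: Optional[float] = None,
    engaged_fraction: float = 1.0,
    uds_pct_nalkyl: Optional[float] = None,
    n_nalkyl: Optional[float] = None,
) -> PatchSizeEstimate:
    """Convert UDS percentages to total and per-adduct repair patch sizes.

    A UDS of p% of one replication round corresponds to p/100 * 2 *
    plasmid_bp nt of synthesis; dividing by the adduct count gives the
    per-adduct patch, and by the engaged fraction the per-engaged-event
    patch (e.g. 270 nt / 1.7 O6mG / 0.30 engaged ~= 530 nt).
    """
    if plasmid_bp <= 0:
        raise ValueError("plasmid_bp must be positive")
    if not 0.0 < engaged_fraction <= 1.0:
        raise ValueError("engaged_fraction must be in (0, 1]")
    out: dict[str, Optional[float]] = {}
    if uds_pct_o6mg is not None:
        if uds_pct_o6mg < 0:
            raise ValueError("uds_pct_o6mg must be >= 0")
        if n_o6mg is None or n_o6mg <= 0:
            raise ValueError("n_o6mg must be a positive count")
        total = uds_pct_o6mg / 100.0 * 2.0 * plasmid_bp
        out["total_o6mg_synthesis_nt"] = total
        out["per_o6mg_patch_nt"] = total / n_o6mg
        out["per_engaged_patch_nt"] = total / n_o6mg / engaged_fraction
    if uds_pct_nalkyl is not None:
        if uds_pct_nalkyl < 0:
            raise ValueError("uds_pct_nalkyl must be >= 0")
        if n_nalkyl is None or n_nalkyl <= 0:
            raise ValueError("n_nalkyl must be a positive count")
        total = uds_pct_nalkyl / 100.0 * 2.0 * plasmid_bp
        out["total_nalkyl_synthesis_nt"] = total
        out["per_nalkyl_patch_nt"] = total / n_nalkyl
    if not out:
        raise ValueError("provide uds_pct_o6mg and/or uds_pct_nalkyl")
    return PatchSizeEstimate(**out)


def stimulation_factor(delta_with_mms: float, delta_without_mms: float) -> float:
    """Fold-stimulation of O6mG-attributable UDS by N-alkyl co-treatment."""
    if delta_without_mms <= 0:
        raise ValueError("delta_without_mms must be positive")
    if delta_with_mms < 0:
        raise ValueError("delta_with_mms must be non-negative")
    return delta_with_mms / delta_without_mms


@dataclass(frozen=True)
class GenomeEstimate:
    """The full extrapolation chain at reference and clinical doses."""

    at_risk_prob: float
    at_risk_count: float
    dsb_ref_dose: float
    dsb_clinical: float
    conversion_rate: float
    # exact (unrounded-chain) companions
    at_risk_prob_exact: float
    at_risk_count_exact: float
    dsb_ref_dose_exact: float
    dsb_clinical_exact: float
    conversion_rate_exact: float


def genome_estimate(
    load: GenomeLesionLoad = GenomeLesionLoad(),
    linear_fraction: float = 0.06,
    plasmid_bp: float = 11300.0,
    dose_ref_mM: float = 2.0,
    dose_clinical_mM: float = 0.05,
) -> GenomeEstimate:
    """Chain every calculator from lesion loads to the conversion rate.

    The headline fields round intermediates at each step (probability to
    2 decimals, DSB counts to 2 significant figures) as the estimates are
    conventionally reported; the ``*_exact`` companions propagate full
    precision throughout.
    """
    ar = at_risk(load)
    dsb_ref = dsb_per_genome_from_plasmid(
        linear_fraction, plasmid_bp, load.genome_bp_for_scaling
    )
    clin = scale_dose_quadratic(dsb_ref.rounded, dose_ref_mM, dose_clinical_mM)
    clin_exact = scale_dose_quadratic(dsb_ref.exact, dose_ref_mM, dose_clinical_mM)
    return GenomeEstimate(
        at_risk_prob=ar.prob_rounded,
        at_risk_count=ar.count_rounded,
        dsb_ref_dose=dsb_ref.rounded,
        dsb_clinical=round_sig(clin),
        conversion_rate=conversion_rate(round_sig(clin), ar.count_rounded),
        at_risk_prob_exact=ar.prob,
        at_risk_count_exact=ar.count,
        dsb_ref_dose_exact=dsb_ref.exact,
        dsb_clinical_exact=clin_exact,
        conversion_rate_exact=conversion_rate(clin_exact, ar.count),
    )
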