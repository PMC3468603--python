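"""GC-wave correction, paired/cohort normalization, genotype calling and
TumorBoost-style BAF correction.

Order of operations in the standard pipeline: correct the tumor LRR for
GC waves, normalize it against the paired blood LRR (or the per-probe
median of same-platform blood samples), call germline genotypes from the
blood BAF, then rescale the tumor BAF with TumorBoost using the paired
blood BAF at genotyped probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import (
    GENO_AA,
    GENO_AB,
    GENO_BB,
    GENO_MISSING,
    PairedSample,
    ProbeSet,
    SampleIntensities,
)

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    gc_slope_before: float
    gc_slope_after: float
    n_probes_corrected: int
    normalization_mode: str = "paired"  # or "cohort_median"
    n_het_used: int = 0


def _gc_slope(lrr: np.ndarray, gc: np.ndarray) -> float:
    """OLS slope of LRR on centered GC over finite probes."""
    ok = np.isfinite(lrr) & np.isfinite(gc)
    x = gc[ok] - gc[ok].mean()
    if np.allclose(x, 0):
        return 0.0
    return float(np.sum(x * lrr[ok]) / np.sum(x * x))


def correct_gc_waves(
    s: SampleIntensities, probes: ProbeSet
) -> tuple[SampleIntensities, PreprocessReport]:
    """Remove the GC wave from LRR by a quadratic least-squares fit.

    LRR is regressed on (gc, gc^2); the fitted component is subtracted and
    the track re-centered to preserve its pre-correction median.  Degenerate
    (constant) GC makes this a no-op with a warning.
    """
    lrr = s.lrr
    gc = probes.gc_frac
    ok = np.isfinite(lrr)
    if int(ok.sum()) < 100:
        raise ValueError("GC correction requires >= 100 probes with finite LRR")

    slope_before = _gc_slope(lrr, gc)
    gcc = gc - gc[ok].mean()
    if np.allclose(gcc[ok], 0):
        warnings.warn("constant GC fraction; GC correction skipped")
        return s.copy(), PreprocessReport(slope_before, slope_before, 0)

    X = np.column_stack([np.ones(int(ok.sum())), gcc[ok], gcc[ok] ** 2])
    beta, *_ = np.linalg.lstsq(X, lrr[ok], rcond=None)
    fitted = beta[0] + beta[1] * gcc + beta[2] * gcc**2
    corrected = lrr - fitted
    med_before = float(np.nanmedian(lrr))
    corrected = corrected - np.nanmedian(corrected) + med_before

    out = s.copy()
    out.lrr = corrected
    report = PreprocessReport(
        gc_slope_before=slope_before,
        gc_slope_after=_gc_slope(corrected, gc),
        n_probes_corrected=int(ok.sum()),
    )
    return out, report


class PlatformError(ValueError):
    pass


def normalize_to_reference(
    t: SampleIntensities,
    ref: Optional[SampleIntensities] = None,
    cohort: Optional[Sequence[SampleIntensities]] = None,
) -> SampleIntensities:
    """Subtract the paired-blood LRR probe-wise, or the per-probe median of
    >= 3 same-platform blood samples when no pair exists.  BAF is untouched."""
    out = t.copy()
    if ref is not None:
        if len(ref) != len(t):
            raise ValueError("reference not aligned to the same probe set")
        out.lrr = t.lrr - ref.lrr
        return out
    if cohort is None or len(cohort) < 3:
        raise ValueError("cohort mode requires >= 3 normal samples")
    platforms = {c.platform_id for c in cohort}
    if platforms != {t.platform_id}:
        raise PlatformError(
            f"cohort normals span platforms {sorted(platforms)}; tumor is {t.platform_id}"
        )
    stack = np.vstack([c.lrr for c in cohort])
    out.lrr = t.lrr - np.nanmedian(stack, axis=0)
    return out


# genotype-caller guard bands: hom below 0.15 / above 0.85, het in [0.25, 0.75]
HOM_A_MAX, HET_LO, HET_HI, HOM_B_MIN = 0.15, 0.25, 0.75, 0.85


def call_germline_genotypes(normal: SampleIntensities) -> np.ndarray:
    """Threshold genotype caller on blood BAF.

    The guard bands (0.15-0.25 and 0.75-0.85) are left uncalled, trading
    call rate for purity of the heterozygous set used downstream.
    """
    baf = normal.baf
    geno = np.full(len(normal), GENO_MISSING, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        geno[baf < HOM_A_MAX] = GENO_AA
        geno[baf > HOM_B_MIN] = GENO_BB
        geno[(baf >= HET_LO) & (baf <= HET_HI)] = GENO_AB
    return geno


def tumorboost_correct(
    tumor_baf: np.ndarray, normal_baf: np.ndarray, genotypes: np.ndarray
) -> np.ndarray:
    """Rescale tumor BAF against the paired blood BAF (multiplicative variant).

    With mu = 0 (AA), 0.5 (AB), 1 (BB) the germline expectation: where
    tumor <= normal the lower side is rescaled by mu/normal, otherwise the
    upper side by (1-mu)/(1-normal).  Probes with missing genotype pass
    through; an AB probe whose blood BAF is exactly 0 or 1 passes through
    with a warning (the rescale is undefined there).
    """
    tumor_baf = np.asarray(tumor_baf, dtype=np.float64)
    normal_baf = np.asarray(normal_baf, dtype=np.float64)
    genotypes = np.asarray(genotypes)
    out = tumor_baf.copy()

    mu = np.full(tumor_baf.shape, np.nan)
    mu[genotypes == GENO_AA] = 0.0
    mu[genotypes == GENO_AB] = 0.5
    mu[genotypes == GENO_BB] = 1.0

    valid = np.isfinite(mu) & np.isfinite(tumor_baf) & np.isfinite(normal_baf)
    degenerate = valid & (genotypes == GENO_AB) & ((normal_baf == 0) | (normal_baf == 1))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} AB probe(s) with blood BAF exactly 0/1 "
            "passed through uncorrected"
        )
        valid &= ~degenerate

    lower = valid & (tumor_baf <= normal_baf)
    upper = valid & (tumor_baf > normal_baf)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[lower] = mu[lower] * tumor_baf[lower] / normal_baf[lower]
        out[upper] = 1.0 - (1.0 - mu[upper]) * (1.0 - tumor_baf[upper]) / (
            1.0 - normal_baf[upper]
        )
    # 0/0 at a hom probe sitting exactly on its expectation: corrected = mu
    nan_fix = valid & ~np.isfinite(out)
    out[nan_fix] = mu[nan_fix]
    return np.clip(out, 0.0, 1.0)


def preprocess_pair(
    pair: PairedSample,
    probes: ProbeSet,
    cohort_normals: Optional[Sequence[SampleIntensities]] = None,
) -> tuple[PairedSample, PreprocessReport]:
    """Full preprocessing of one tumor (GC wave -> normalization -> genotypes
    -> TumorBoost).  Falls back to cohort-median normalization and uncorrected
    BAF when no paired blood sample exists."""
    tumor, report = correct_gc_waves(pair.tumor, probes)
    if pair.normal is not None:
        tumor = normalize_to_reference(tumor, ref=pair.normal)
        genotypes = call_germline_genotypes(pair.normal)
        tumor.baf = tumorboost_correct(tumor.baf, pair.normal.baf, genotypes)
        report.normalization_mode = "paired"
        report.n_het_used = int((genotypes == GENO_AB).sum())
        return (
            PairedSample(tumor=tumor, normal=pair.normal, normal_genotypes=genotypes),
            report,
        )
    if cohort_normals:
        tumor = normalize_to_reference(tumor, cohort=cohort_normals)
        report.normalization_mode = "cohort_median"
    return PairedSample(tumor=tumor), report
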