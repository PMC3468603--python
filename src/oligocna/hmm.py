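"""Six-state allele-specific copy-number HMM with purity-adaptive bounds.

States (fixed order): HOMDEL, LOSS, NORMAL, CNLOH, GAIN, AMP.  Emissions
combine a Gaussian LRR term per state with a BAF mixture over germline
genotype and affected-allele branch (truncated Gaussians at the purity-
dependent band centers of :func:`oligocna.synthetic.band_center`, plus a
uniform outlier component); the homozygous-deletion BAF is uniform.

Fitting is EM with a twist: the free emission parameters (per-state LRR
means and heterozygous BAF band deviations) are box-constrained, and the
boxes are recomputed at every iteration around the values the *current*
purity estimate implies.  Purity itself is re-estimated each iteration by
inverting the band-center geometry on the posterior-weighted heterozygous
BAF deviations.  This keeps low-purity samples from collapsing onto the
all-normal solution while letting the parameters track the data.

Transitions use a distance-decay mixture A(d) = rho*I + (1-rho)*1*pi^T
with rho = exp(-d / L), applied per chromosome independently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit
from scipy.special import ndtr

from .synthetic import band_center, lrr_mean
from .types import (
    CNState,
    GENO_AA,
    GENO_AB,
    GENO_BB,
    N_STATES,
    PairedSample,
    ProbeSet,
    SampleIntensities,
    Segment,
    STATE_INDEX,
    STATE_ORDER,
)

log = logging.getLogger(__name__)

I_HOMDEL = STATE_INDEX[CNState.HOMDEL]
I_LOSS = STATE_INDEX[CNState.LOSS]
I_NORMAL = STATE_INDEX[CNState.NORMAL]
I_CNLOH = STATE_INDEX[CNState.CNLOH]
I_GAIN = STATE_INDEX[CNState.GAIN]
I_AMP = STATE_INDEX[CNState.AMP]

#: states whose heterozygous BAF band is displaced from 0.5
ABERRANT_BAF_STATES = (I_LOSS, I_CNLOH, I_GAIN, I_AMP)


def het_band_deviation(state: CNState, p: float) -> float:
    """|0.5 - lower-branch het band center| implied by purity p (0 for
    NORMAL; undefined for HOMDEL)."""
    if state is CNState.NORMAL:
        return 0.0
    return 0.5 - band_center(state, GENO_AB, p, "B" if state in (
        CNState.LOSS, CNState.CNLOH) else "A")


@dataclass
class HMMParams:
    """Model parameters plus the purity-implied boxes they live in."""

    p: float = 0.7
    s0: float = 0.0
    mu_lrr: np.ndarray = None  # (6,) free state LRR means
    sigma_lrr: np.ndarray = None  # (6,)
    dev_baf: np.ndarray = None  # (6,) free het-band deviations in [0, 0.5]
    sigma_baf: float = 0.05
    pi_o: float = 0.02  # uniform-outlier weight, in [0, 0.3]
    pi_z: np.ndarray = None  # (6,) stationary state probabilities
    L: float = 5e6  # transition length scale, bp
    delta_lrr: float = 0.15  # LRR-mean slack around formula(p)
    delta_baf: float = 0.05  # band-deviation slack around formula(p)

    def __post_init__(self):
        if self.mu_lrr is None:
            self.mu_lrr = np.array([lrr_mean(s, self.p, self.s0) for s in STATE_ORDER])
        if self.sigma_lrr is None:
            self.sigma_lrr = np.full(N_STATES, 0.2)
        if self.dev_baf is None:
            self.dev_baf = np.array(
                [0.0 if i in (I_HOMDEL, I_NORMAL) else
                 het_band_deviation(STATE_ORDER[i], self.p) for i in range(N_STATES)]
            )
        if self.pi_z is None:
            self.pi_z = np.array([0.01, 0.08, 0.8, 0.05, 0.05, 0.01])
        self.pi_z = np.asarray(self.pi_z, dtype=np.float64)
        self.pi_z = self.pi_z / self.pi_z.sum()

    def bound_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Formula-implied centers of the (mu_lrr, dev_baf) boxes."""
        mu_c = np.array([lrr_mean(s, self.p, self.s0) for s in STATE_ORDER])
        dev_c = np.array(
            [0.0 if i in (I_HOMDEL, I_NORMAL) else
             het_band_deviation(STATE_ORDER[i], self.p) for i in range(N_STATES)]
        )
        return mu_c, dev_c

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) per parameter, rows = [mu_lrr(6), dev_baf(6)]."""
        mu_c, dev_c = self.bound_centers()
        low = np.concatenate([mu_c - self.delta_lrr,
                              np.clip(dev_c - self.delta_baf, 0.0, 0.5)])
        high = np.concatenate([mu_c + self.delta_lrr,
                               np.clip(dev_c + self.delta_baf, 0.0, 0.5)])
        return low, high

    def copy(self) -> "HMMParams":
        return replace(
            self,
            mu_lrr=self.mu_lrr.copy(),
            sigma_lrr=self.sigma_lrr.copy(),
            dev_baf=self.dev_baf.copy(),
            pi_z=self.pi_z.copy(),
        )


@dataclass
class DecodingResult:
    states: np.ndarray  # per-probe Viterbi state index
    posteriors: np.ndarray  # (n, 6)
    loglik: float
    iterations: int
    converged: bool
    purity_identifiable: bool = True
    ll_trace: list = field(default_factory=list)  # accepted loglik per iteration


# ---------------------------------------------------------------- emissions

_SQRT2PI = np.sqrt(2 * np.pi)


def _trunc_norm_pdf(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Gaussian truncated (renormalized) to [0, 1]; center is scalar."""
    z_mass = ndtr((1.0 - center) / sigma) - ndtr((0.0 - center) / sigma)
    dens = np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * _SQRT2PI)
    return dens / max(z_mass, 1e-300)


def genotype_weights(
    genotypes: Optional[np.ndarray], pop_b_freq: np.ndarray
) -> np.ndarray:
    """(n, 3) prior over germline genotype: called genotypes are certain,
    missing ones fall back to Hardy-Weinberg from the population frequency."""
    f = np.asarray(pop_b_freq, dtype=np.float64)
    w = np.column_stack([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    if genotypes is not None:
        g = np.asarray(genotypes)
        for code, col in ((GENO_AA, 0), (GENO_AB, 1), (GENO_BB, 2)):
            mask = g == code
            w[mask] = 0.0
            w[mask, col] = 1.0
    return w


def emission_log_matrix(
    lrr: np.ndarray,
    baf: np.ndarray,
    geno_w: np.ndarray,
    params: HMMParams,
) -> np.ndarray:
    """(n, 6) log emission densities.

    Missing BAF contributes only the LRR term; probes with missing LRR
    contribute only the BAF term; fully missing probes emit log(1) = 0.
    """
    n = lrr.size
    out = np.zeros((n, N_STATES))

    lrr_ok = np.isfinite(lrr)
    x = np.where(lrr_ok, lrr, 0.0)
    for z in range(N_STATES):
        s = params.sigma_lrr[z]
        ll = -0.5 * ((x - params.mu_lrr[z]) / s) ** 2 - np.log(s * _SQRT2PI)
        out[:, z] += np.where(lrr_ok, ll, 0.0)

    baf_ok = np.isfinite(baf)
    b = np.where(baf_ok, baf, 0.5)
    sb = params.sigma_baf
    d_homA = _trunc_norm_pdf(b, 0.0, sb)  # germline AA: tumor BAF ~ 0, any state
    d_homB = _trunc_norm_pdf(b, 1.0, sb)
    w_aa, w_ab, w_bb = geno_w[:, 0], geno_w[:, 1], geno_w[:, 2]
    pio = params.pi_o
    for z in range(N_STATES):
        if z == I_HOMDEL:
            dens = np.ones(n)  # uniform on [0, 1]
        else:
            dev = params.dev_baf[z]
            d_het = 0.5 * (
                _trunc_norm_pdf(b, 0.5 - dev, sb) + _trunc_norm_pdf(b, 0.5 + dev, sb)
            )
            dens = (1 - pio) * (w_aa * d_homA + w_ab * d_het + w_bb * d_homB) + pio
        out[:, z] += np.where(baf_ok, np.log(np.maximum(dens, 1e-300)), 0.0)
    return out


def emission_loglik(
    lrr: float, baf: float, geno_w_row: np.ndarray, state: CNState, params: HMMParams
) -> float:
    """Log emission density of a single probe under one state."""
    m = emission_log_matrix(
        np.array([lrr]), np.array([baf]), geno_w_row.reshape(1, 3), params
    )
    return float(m[0, STATE_INDEX[state]])


# ------------------------------------------------------------- transitions

def transition_matrix(d: float, params: HMMParams) -> np.ndarray:
    """6x6 stochastic matrix A = rho*I + (1-rho)*1*pi^T with rho=exp(-d/L)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    rho = np.exp(-d / params.L)
    return rho * np.eye(N_STATES) + (1 - rho) * np.tile(params.pi_z, (N_STATES, 1))


# --------------------------------------------------- numba inference kernels

@njit(cache=True)
def _fb_kernel(logB, rho, pi):  # pragma: no cover - exercised via wrapper
    """Scaled forward-backward for the rho*I + (1-rho)*pi transition family.

    Returns (loglik, gamma).  rho[t] couples probes t-1 and t (rho[0] unused).
    """
    n, k = logB.shape
    gamma = np.empty((n, k))
    alpha = np.empty((n, k))
    c = np.empty(n)
    loglik = 0.0

    m = np.empty(n)
    E = np.empty((n, k))
    for t in range(n):
        mt = logB[t, 0]
        for j in range(1, k):
            if logB[t, j] > mt:
                mt = logB[t, j]
        m[t] = mt
        for j in range(k):
            E[t, j] = np.exp(logB[t, j] - mt)

    s = 0.0
    for j in range(k):
        alpha[0, j] = pi[j] * E[0, j]
        s += alpha[0, j]
    c[0] = s
    loglik += np.log(s) + m[0]
    for j in range(k):
        alpha[0, j] /= s

    for t in range(1, n):
        r = rho[t]
        s = 0.0
        for j in range(k):
            v = (r * alpha[t - 1, j] + (1.0 - r) * pi[j]) * E[t, j]
            alpha[t, j] = v
            s += v
        c[t] = s
        loglik += np.log(s) + m[t]
        for j in range(k):
            alpha[t, j] /= s

    beta = np.ones(k)
    for j in range(k):
        gamma[n - 1, j] = alpha[n - 1, j]
    for t in range(n - 2, -1, -1):
        r = rho[t + 1]
        dot = 0.0
        for j in range(k):
            dot += pi[j] * E[t + 1, j] * beta[j]
        newbeta = np.empty(k)
        for j in range(k):
            newbeta[j] = (r * E[t + 1, j] * beta[j] + (1.0 - r) * dot) / c[t + 1]
        beta = newbeta
        s = 0.0
        for j in range(k):
            gamma[t, j] = alpha[t, j] * beta[j]
            s += gamma[t, j]
        for j in range(k):
            gamma[t, j] /= s
    return loglik, gamma


@njit(cache=True)
def _viterbi_kernel(logB, rho, pi):  # pragma: no cover - exercised via wrapper
    n, k = logB.shape
    logpi = np.log(pi)
    delta = np.empty((n, k))
    back = np.zeros((n, k), dtype=np.int64)
    for j in range(k):
        delta[0, j] = logpi[j] + logB[0, j]
    for t in range(1, n):
        r = rho[t]
        for j in range(k):
            best = -1e300
            arg = 0
            for i in range(k):
                a = r * (1.0 if i == j else 0.0) + (1.0 - r) * pi[j]
                v = delta[t - 1, i] + np.log(a)
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logB[t, j]
            back[t, j] = arg
    path = np.empty(n, dtype=np.int64)
    best = -1e300
    for j in range(k):
        if delta[n - 1, j] > best:
            best = delta[n - 1, j]
            path[n - 1] = j
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ------------------------------------------------------------ E-step driver

def _chrom_rhos(probes: ProbeSet, L: float) -> dict[str, np.ndarray]:
    out = {}
    for chrom, sl in probes.chrom_slices().items():
        pos = probes.pos[sl]
        rho = np.empty(pos.size)
        rho[0] = 0.0
        if pos.size > 1:
            rho[1:] = np.exp(-np.diff(pos) / L)
        out[chrom] = rho
    return out


def forward_backward(
    probes: ProbeSet,
    tumor: SampleIntensities,
    genotypes: Optional[np.ndarray],
    params: HMMParams,
) -> tuple[float, np.ndarray]:
    """Exact forward log-likelihood and per-probe posteriors, chromosome by
    chromosome (chromosomes are independent)."""
    geno_w = genotype_weights(genotypes, probes.pop_b_freq)
    logB = emission_log_matrix(tumor.lrr, tumor.baf, geno_w, params)
    bad = ~np.isfinite(logB).all(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} probe(s) with non-finite emission skipped")
        logB[bad] = 0.0
    total = 0.0
    gamma = np.empty_like(logB)
    for chrom, sl in probes.chrom_slices().items():
        rho = np.exp(
            -np.diff(probes.pos[sl], prepend=probes.pos[sl][0]) / params.L
        )
        rho[0] = 0.0
        ll, g = _fb_kernel(logB[sl], rho, params.pi_z)
        total += ll
        gamma[sl] = g
    return total, gamma


def viterbi_decode(
    probes: ProbeSet,
    tumor: SampleIntensities,
    genotypes: Optional[np.ndarray],
    params: HMMParams,
) -> np.ndarray:
    geno_w = genotype_weights(genotypes, probes.pop_b_freq)
    logB = emission_log_matrix(tumor.lrr, tumor.baf, geno_w, params)
    logB[~np.isfinite(logB).all(axis=1)] = 0.0
    path = np.empty(len(probes), dtype=np.int8)
    for chrom, sl in probes.chrom_slices().items():
        rho = np.exp(
            -np.diff(probes.pos[sl], prepend=probes.pos[sl][0]) / params.L
        )
        rho[0] = 0.0
        path[sl] = _viterbi_kernel(logB[sl], rho, params.pi_z)
    return path


# ------------------------------------------------------- purity estimation

def _invert_band(state_idx: int, b: float) -> tuple[float, float]:
    """(p, |dp/db|) from the lower-branch het band value b."""
    if state_idx == I_LOSS:
        return (1 - 2 * b) / (1 - b), 1.0 / (1 - b) ** 2
    if state_idx == I_CNLOH:
        return 1 - 2 * b, 2.0
    if state_idx == I_GAIN:
        return 1.0 / b - 2.0, 1.0 / b**2
    raise ValueError("no closed-form inversion for this state")


def estimate_purity(
    posteriors: np.ndarray,
    tumor: SampleIntensities,
    genotypes: Optional[np.ndarray],
    params: HMMParams,
    min_mass: float = 5.0,
) -> tuple[float, bool]:
    """Invert the BAF band geometry to a purity estimate.

    For each aberrant state with enough posterior mass on heterozygous
    probes, the posterior-weighted mean folded BAF b = E[min(baf, 1-baf)]
    estimates the lower band; closed-form inversion gives a per-state
    purity, combined by inverse delta-method variance.  Returns
    (p_hat clipped to [0.05, 1], identifiable_flag); an unidentifiable
    sample (no aberrant mass) returns the input purity with flag False.
    """
    if genotypes is None:
        het = (tumor.baf > 0.25) & (tumor.baf < 0.75)
    else:
        het = np.asarray(genotypes) == GENO_AB
    het = het & np.isfinite(tumor.baf)
    folded = np.minimum(tumor.baf, 1 - tumor.baf)

    estimates, weights = [], []
    for z in (I_LOSS, I_CNLOH, I_GAIN):
        w = posteriors[:, z] * het
        mass = w.sum()
        if mass < min_mass:
            continue
        b = float((w * folded).sum() / mass)
        b = min(max(b, 1e-4), 0.4999)
        p_z, dpdb = _invert_band(z, b)
        var_b = float((w * (folded - b) ** 2).sum() / mass) / mass + 1e-8
        var_p = dpdb**2 * var_b
        estimates.append(min(max(p_z, 0.05), 1.0))
        weights.append(1.0 / var_p)
    if not estimates:
        return params.p, False
    p_hat = float(np.average(estimates, weights=weights))
    return min(max(p_hat, 0.05), 1.0), True


def update_bounds(params: HMMParams, p_hat: float) -> HMMParams:
    """Recenter the parameter boxes on the new purity estimate and project
    any parameter that fell outside onto the nearest bound."""
    if not 0 < p_hat <= 1:
        raise ValueError("purity must be in (0, 1]")
    out = params.copy()
    out.p = p_hat
    low, high = out.bounds()
    out.mu_lrr = np.clip(out.mu_lrr, low[:N_STATES], high[:N_STATES])
    out.dev_baf = np.clip(out.dev_baf, low[N_STATES:], high[N_STATES:])
    out.dev_baf[[I_HOMDEL, I_NORMAL]] = 0.0
    return out


# ------------------------------------------------------------------ M-step

def _m_step(
    params: HMMParams,
    gamma: np.ndarray,
    probes: ProbeSet,
    tumor: SampleIntensities,
    genotypes: Optional[np.ndarray],
) -> HMMParams:
    out = params.copy()
    lrr, baf = tumor.lrr, tumor.baf
    lrr_ok = np.isfinite(lrr)
    baf_ok = np.isfinite(baf)

    # stationary state probabilities: expected occupancy
    occ = gamma.sum(axis=0)
    out.pi_z = np.maximum(occ / occ.sum(), 1e-6)
    out.pi_z /= out.pi_z.sum()

    # state LRR means and variances (projected onto the purity boxes below)
    for z in range(N_STATES):
        w = gamma[lrr_ok, z]
        mass = w.sum()
        if mass > 1e-6:
            mu = float((w * lrr[lrr_ok]).sum() / mass)
            out.mu_lrr[z] = mu
            var = float((w * (lrr[lrr_ok] - mu) ** 2).sum() / mass)
            out.sigma_lrr[z] = float(np.clip(np.sqrt(var), 0.02, 1.0))

    # baseline shift: occupancy-weighted mean offset from the formula means
    base = np.array([lrr_mean(s, out.p, 0.0) for s in STATE_ORDER])
    wsum = gamma[lrr_ok].sum()
    if wsum > 0:
        out.s0 = float((gamma[lrr_ok] * (lrr[lrr_ok, None] - base)).sum() / wsum)

    # BAF: component responsibilities on het probes -> band deviations,
    # outlier weight and shared BAF noise scale
    if genotypes is None:
        het = baf_ok & (baf > 0.25) & (baf < 0.75)
    else:
        het = baf_ok & (np.asarray(genotypes) == GENO_AB)
    b = baf[het]
    folded = np.minimum(b, 1 - b)
    sb = params.sigma_baf
    dev_num = np.zeros(N_STATES)
    dev_den = np.zeros(N_STATES)
    out_num = 0.0
    out_den = 0.0
    var_num = 0.0
    var_den = 0.0
    for z in range(N_STATES):
        if z == I_HOMDEL:
            continue
        g = gamma[het, z]
        if g.sum() < 1e-9:
            continue
        dev = params.dev_baf[z]
        d_lo = _trunc_norm_pdf(b, 0.5 - dev, sb)
        d_hi = _trunc_norm_pdf(b, 0.5 + dev, sb)
        d_band = 0.5 * (d_lo + d_hi)
        denom = (1 - params.pi_o) * d_band + params.pi_o
        r_out = params.pi_o / denom
        r_band = 1.0 - r_out
        out_num += float((g * r_out).sum())
        out_den += float(g.sum())
        if z != I_NORMAL:
            dev_num[z] += float((g * r_band * (0.5 - folded)).sum())
            dev_den[z] += float((g * r_band).sum())
        # residual around the nearer band branch
        resid2 = (folded - (0.5 - dev)) ** 2
        var_num += float((g * r_band * resid2).sum())
        var_den += float((g * r_band).sum())
    if out_den > 0:
        out.pi_o = float(np.clip(out_num / out_den, 0.0, 0.3))
    for z in ABERRANT_BAF_STATES:
        if dev_den[z] > 1e-6:
            out.dev_baf[z] = dev_num[z] / dev_den[z]
    if var_den > 5:
        out.sigma_baf = float(np.clip(np.sqrt(var_num / var_den), 0.01, 0.2))

    low, high = out.bounds()
    out.mu_lrr = np.clip(out.mu_lrr, low[:N_STATES], high[:N_STATES])
    out.dev_baf = np.clip(out.dev_baf, low[N_STATES:], high[N_STATES:])
    out.dev_baf[[I_HOMDEL, I_NORMAL]] = 0.0
    return out


# ----------------------------------------------------------------- fitting

DEFAULT_PURITY_STARTS = (0.3, 0.5, 0.7, 0.9)


def fit_hmm(
    pair: PairedSample,
    probes: ProbeSet,
    purity_starts: tuple = DEFAULT_PURITY_STARTS,
    max_iter: int = 100,
    tol: float = 1e-6,
    delta_lrr: float = 0.15,
    delta_baf: float = 0.05,
    L: float = 5e6,
) -> tuple[HMMParams, DecodingResult]:
    """EM fit with multi-start over purity initializations.

    Each iteration: forward-backward E-step; closed-form M-step projected
    onto the purity boxes; purity re-estimate from the posterior band
    geometry; box recentering (the genoCN-style moving limits).  An update
    that would lower the log-likelihood is rejected and the start stops
    there, so the accepted log-likelihood sequence is non-decreasing.
    Ties across starts go to the larger initial purity (the high-purity
    reading of the band-ambiguous likelihood).
    """
    tumor, genotypes = pair.tumor, pair.normal_genotypes
    best = None
    for p0 in purity_starts:
        params = HMMParams(
            p=p0, s0=float(np.nanmedian(tumor.lrr)),
            delta_lrr=delta_lrr, delta_baf=delta_baf, L=L,
        )
        prev_ll = -np.inf
        ll_trace = []
        identifiable = True
        converged = False
        iterations = 0
        gamma = None
        for it in range(max_iter):
            ll, g = forward_backward(probes, tumor, genotypes, params)
            iterations = it + 1
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
                params = prev_params  # reject the decreasing update
                gamma = prev_gamma
                converged = True
                break
            ll_trace.append(ll)
            gamma = g
            if prev_ll > -np.inf and abs(ll - prev_ll) < tol * abs(prev_ll):
                converged = True
                prev_ll = ll
                break
            prev_params, prev_gamma, prev_ll = params.copy(), g, ll
            params = _m_step(params, g, probes, tumor, genotypes)
            p_hat, identifiable = estimate_purity(g, tumor, genotypes, params)
            params = update_bounds(params, p_hat)
        if not converged:
            # loop exhausted: report the last parameter set whose likelihood
            # was actually evaluated
            params, gamma = prev_params, prev_gamma
        cand = (prev_ll, params.p, params, gamma, iterations, converged,
                identifiable, ll_trace)
        if best is None or cand[0] > best[0] + 1e-9 or (
            abs(cand[0] - best[0]) <= 1e-9 and p0 > best_p0
        ):
            best = cand
            best_p0 = p0
    ll, p_final, params, gamma, iterations, converged, identifiable, trace = best
    path = viterbi_decode(probes, tumor, genotypes, params)
    decoding = DecodingResult(
        states=path,
        posteriors=gamma,
        loglik=float(ll),
        iterations=iterations,
        converged=converged,
        purity_identifiable=identifiable,
        ll_trace=trace,
    )
    return params, decoding


# ---------------------------------------------------------------- segments

def segments_from_decoding(
    decoding: DecodingResult,
    probes: ProbeSet,
    tumor: SampleIntensities,
    genotypes: Optional[np.ndarray] = None,
    min_snps: int = 10,
) -> list[Segment]:
    """Maximal constant-state runs, with short runs (< min_snps probes)
    absorbed into the flanking neighbor whose state carries the higher mean
    posterior over the short run; merging repeats until every segment has
    at least min_snps probes.  A chromosome with fewer than min_snps probes
    becomes a single flagged segment."""
    segments: list[Segment] = []
    states = decoding.states
    post = decoding.posteriors
    if genotypes is None:
        het = (tumor.baf > 0.25) & (tumor.baf < 0.75) & np.isfinite(tumor.baf)
    else:
        het = np.asarray(genotypes) == GENO_AB

    for chrom, sl in probes.chrom_slices().items():
        st = states[sl].astype(np.int64).copy()
        n = st.size
        if n < min_snps:
            segments.append(
                _make_segment(chrom, probes, tumor, het, sl.start, 0, n - 1,
                              int(np.bincount(st).argmax()), "short_chrom")
            )
            continue
        runs = _runs(st)
        while True:
            short = [
                (length, i) for i, (s_i, e_i, z) in enumerate(runs)
                if (length := e_i - s_i + 1) < min_snps
            ]
            if not short or len(runs) == 1:
                break
            _, i = min(short)  # smallest run first, leftmost on ties
            s_i, e_i, z = runs[i]
            neighbors = []
            if i > 0:
                neighbors.append(runs[i - 1][2])
            if i < len(runs) - 1:
                neighbors.append(runs[i + 1][2])
            mean_post = {
                zz: post[sl.start + s_i : sl.start + e_i + 1, zz].mean()
                for zz in set(neighbors)
            }
            target = max(sorted(mean_post), key=lambda zz: mean_post[zz])
            st[s_i : e_i + 1] = target
            runs = _runs(st)
        for s_i, e_i, z in runs:
            segments.append(
                _make_segment(chrom, probes, tumor, het, sl.start, s_i, e_i, z, "")
            )
    return segments


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end, state) runs of a 1-D state vector (end inclusive)."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [states.size - 1]])
    return [(int(s), int(e), int(states[s])) for s, e in zip(starts, ends)]


def _make_segment(chrom, probes, tumor, het, offset, s_i, e_i, z, sub_label):
    idx = slice(offset + s_i, offset + e_i + 1)
    lrr = tumor.lrr[idx]
    baf = tumor.baf[idx]
    het_seg = het[idx] & np.isfinite(baf)
    het_dev = (
        float(np.mean(np.abs(baf[het_seg] - 0.5))) if het_seg.any() else float("nan")
    )
    return Segment(
        chrom=chrom,
        start_pos=int(probes.pos[offset + s_i]),
        end_pos=int(probes.pos[offset + e_i]),
        n_snps=e_i - s_i + 1,
        state=STATE_ORDER[z],
        mean_lrr=float(np.nanmean(lrr)) if np.isfinite(lrr).any() else float("nan"),
        het_band=het_dev,
        sub_label=sub_label,
    )
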