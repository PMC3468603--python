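"""Synthetic paired tumor/blood SNP-array data with known segment truth.

The generator emulates Illumina-style LRR/BAF tracks for a tumor admixed
with normal cells at purity ``p``.  For a locus with tumor total copy
number ``c`` and tumor B-allele count ``nB`` on a germline background with
``gB`` B alleles, the expected signals of the mixture are

    BAF band center  = (p * nB + (1 - p) * gB) / (p * c + 2 * (1 - p))
    LRR mean         = s0 + log2(max(p * c + 2 * (1 - p), 0.1) / 2)

These two formulas are the common geometry the simulator emits and the HMM
inverts; they are defined here and imported by :mod:`oligocna.hmm`.

Scenario templates mirror the tumor classes seen in anaplastic
oligodendroglioma cohorts: canonical 1p/19q co-deletion (with optional 9p
CNLOH or focal CDKN2A-like homozygous deletion) and an astrocytoma-like
pattern (focal 7p amplification, chromosome-10 loss, 17p CNLOH).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .types import (
    ArmTable,
    CNState,
    GENO_AB,
    PairedSample,
    ProbeSet,
    SampleIntensities,
    STATE_INDEX,
    STATE_ORDER,
)

AUTOSOMES = [str(i) for i in range(1, 23)]

#: tumor B-allele count for a germline-heterozygous probe, by state and
#: affected allele (the allele lost for LOSS/CNLOH, duplicated for GAIN/AMP)
_HET_B_COPIES = {
    CNState.NORMAL: {"A": 1, "B": 1},
    CNState.LOSS: {"A": 1, "B": 0},
    CNState.CNLOH: {"A": 2, "B": 0},
    CNState.GAIN: {"A": 1, "B": 2},
    CNState.AMP: {"A": 1, "B": 3},
}


def tumor_b_copies(state: CNState, germline_b: int, which_branch: str) -> int:
    """Number of B alleles in the tumor clone.

    Homozygous germlines have a single branch (the event can only involve the
    allele that is present); heterozygous germlines have two, selected by
    ``which_branch`` in {"A", "B"}.
    """
    if state is CNState.HOMDEL:
        raise ValueError("HOMDEL carries no alleles; its BAF is uninformative")
    if germline_b == 0:
        return 0
    if germline_b == 2:
        return state.total_copies
    return _HET_B_COPIES[state][which_branch]


def band_center(
    state: CNState, germline_b: int, p: float, which_branch: str = "B"
) -> float:
    """Expected BAF of the tumor/normal mixture (see module docstring).

    ``germline_b`` is the germline B-allele count (0=AA, 1=AB, 2=BB).
    """
    if not 0 < p <= 1:
        raise ValueError("purity must be in (0, 1]")
    n_b = tumor_b_copies(state, germline_b, which_branch)
    c = state.total_copies
    return (p * n_b + (1 - p) * germline_b) / (p * c + 2 * (1 - p))


def lrr_mean(state: CNState, p: float, s0: float = 0.0) -> float:
    """Expected LRR of the mixture; the 0.1 effective-copy floor keeps the
    homozygous-deletion mean finite as p -> 1."""
    if not 0 < p <= 1:
        raise ValueError("purity must be in (0, 1]")
    eff = max(p * state.total_copies + 2 * (1 - p), 0.1)
    return s0 + np.log2(eff / 2.0)


@dataclass
class TruthProfile:
    """Ground-truth aberration intervals plus the noise model of one tumor."""

    intervals: list  # (chrom, start_pos, end_pos, CNState), non-overlapping per chrom
    purity: float = 0.8
    gc_wave_amp: float = 0.3  # LRR units per unit of centered GC fraction
    lrr_sd: float = 0.18
    baf_sd: float = 0.04
    outlier_rate: float = 0.02
    s0: float = 0.0

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if not 0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier_rate must be in [0, 0.5)")
        by_chrom: dict[str, list] = {}
        for chrom, start, end, state in self.intervals:
            if start > end:
                raise ValueError("interval start > end")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping truth intervals on chr{chrom}")


TEMPLATE_NAMES = (
    "codel", "codel_9p_cnloh", "codel_cdkn2a_homdel", "astro_like", "flat_normal",
)


@dataclass
class ScenarioTemplate:
    """A named tumor class with optional noise/purity overrides."""

    name: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in TEMPLATE_NAMES:
            raise ValueError(f"unknown template {self.name!r}; "
                             f"choose from {TEMPLATE_NAMES}")


class TemplateError(ValueError):
    pass


def _arm_probe_index(probes: ProbeSet, arms: ArmTable, arm: str) -> np.ndarray:
    chrom, start, end = arms.arm_bounds(arm)
    return np.flatnonzero(
        (probes.chrom == chrom) & (probes.pos >= start) & (probes.pos <= end)
    )


#: genomic anchors of the recurrent focal events the templates emulate
#: (CDKN2A-like tumor-suppressor locus on 9p, EGFR-like oncogene on 7p)
FOCAL_ANCHORS = {"9p": 22_000_000, "7p": 55_150_000}


def _focal_interval(
    probes: ProbeSet, arms: ArmTable, arm: str, n_probes: int, rng: np.random.Generator
) -> tuple[str, int, int]:
    """A focal interval covering ``n_probes`` consecutive probes inside an
    arm, centered on the arm's anchor locus so the event recurs at the same
    place across tumors (as recurrent drivers do)."""
    idx = _arm_probe_index(probes, arms, arm)
    if idx.size < n_probes:
        raise TemplateError(f"arm {arm} has {idx.size} probes; need >= {n_probes}")
    anchor = FOCAL_ANCHORS.get(arm)
    if anchor is None:
        start_i = int(rng.integers(0, idx.size - n_probes + 1))
    else:
        center = int(np.argmin(np.abs(probes.pos[idx] - anchor)))
        start_i = int(np.clip(center - n_probes // 2, 0, idx.size - n_probes))
    chosen = idx[start_i : start_i + n_probes]
    chrom = arm[:-1]
    return chrom, int(probes.pos[chosen[0]]), int(probes.pos[chosen[-1]])


def expand_template(
    t: ScenarioTemplate, probes: ProbeSet, arms: ArmTable, seed: int
) -> TruthProfile:
    """Expand a scenario template into a concrete TruthProfile.

    Whole-arm events abut the centromere edges exactly, so downstream
    co-deletion calling sees genuine centromeric breakpoints.
    """
    rng = np.random.default_rng(seed)
    for arm in ("1p", "19q", "9p", "7p", "17p", "10p", "10q"):
        if _arm_probe_index(probes, arms, arm).size < 10:
            raise TemplateError(f"arm {arm} has fewer than 10 probes")

    def whole_arm(arm: str, state: CNState):
        chrom, start, end = arms.arm_bounds(arm)
        return (chrom, start, end, state)

    name = t.name
    intervals: list = []
    if name == "flat_normal":
        pass
    elif name in ("codel", "codel_9p_cnloh", "codel_cdkn2a_homdel"):
        intervals.append(whole_arm("1p", CNState.LOSS))
        intervals.append(whole_arm("19q", CNState.LOSS))
        if name == "codel_9p_cnloh":
            intervals.append(whole_arm("9p", CNState.CNLOH))
        elif name == "codel_cdkn2a_homdel":
            n_focal = max(10, _arm_probe_index(probes, arms, "9p").size // 20)
            intervals.append(
                _focal_interval(probes, arms, "9p", n_focal, rng) + (CNState.HOMDEL,)
            )
    elif name == "astro_like":
        n_focal = max(10, _arm_probe_index(probes, arms, "7p").size // 20)
        intervals.append(
            _focal_interval(probes, arms, "7p", n_focal, rng) + (CNState.AMP,)
        )
        chrom10_len = int(arms.table.loc["10", "length"])
        intervals.append(("10", 1, chrom10_len, CNState.LOSS))
        intervals.append(whole_arm("17p", CNState.CNLOH))
    profile = TruthProfile(intervals=intervals)
    return replace(profile, **t.overrides)


def make_probe_set(
    n_per_chrom: int,
    seed: int,
    arms: Optional[ArmTable] = None,
    chroms: Optional[list[str]] = None,
) -> ProbeSet:
    """A random probe scaffold: uniform positions, autocorrelated GC fraction
    (moving-average of white noise clipped to [0.3, 0.7]) and symmetric-Beta
    population B-allele frequencies."""
    if n_per_chrom < 20:
        raise ValueError("n_per_chrom must be >= 20")
    from .io import read_arm_table

    arms = arms or read_arm_table()
    chroms = chroms or [c for c in AUTOSOMES if c in arms.table.index]
    rng = np.random.default_rng(seed)

    snp_ids, chrom_col, pos_col, gc_col, pbf_col = [], [], [], [], []
    counter = 0
    for chrom in chroms:
        length = int(arms.table.loc[chrom, "length"])
        pos = np.sort(rng.choice(length, size=n_per_chrom, replace=False)) + 1
        white = rng.normal(0.0, 1.0, n_per_chrom + 24)
        kernel = np.ones(25) / 25.0
        smooth = np.convolve(white, kernel, mode="valid")
        gc = np.clip(0.5 + 0.6 * smooth, 0.3, 0.7)
        pbf = rng.beta(0.9, 0.9, n_per_chrom)
        snp_ids.extend(f"rs{counter + i:07d}" for i in range(n_per_chrom))
        counter += n_per_chrom
        chrom_col.extend([chrom] * n_per_chrom)
        pos_col.append(pos)
        gc_col.append(gc)
        pbf_col.append(pbf)
    return ProbeSet(
        snp_id=np.array(snp_ids, dtype=object),
        chrom=np.array(chrom_col, dtype=object),
        pos=np.concatenate(pos_col),
        gc_frac=np.concatenate(gc_col),
        pop_b_freq=np.concatenate(pbf_col),
    )


def state_track(probes: ProbeSet, truth: TruthProfile) -> np.ndarray:
    """Per-probe state index (into STATE_ORDER) implied by the truth intervals."""
    states = np.full(len(probes), STATE_INDEX[CNState.NORMAL], dtype=np.int8)
    for chrom, start, end, state in truth.intervals:
        mask = (probes.chrom == str(chrom)) & (probes.pos >= start) & (probes.pos <= end)
        states[mask] = STATE_INDEX[state]
    return states


def _truncated_noise(
    centers: np.ndarray, noise: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """centers + noise, with out-of-[0,1] draws redrawn (rejection sampling of
    the Gaussian truncated to keep the sum in [0,1])."""
    out = centers + noise
    if sd == 0:
        return np.clip(out, 0.0, 1.0)
    bad = (out < 0) | (out > 1)
    for _ in range(200):
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        out[bad] = centers[bad] + rng.normal(0.0, sd, n_bad)
        bad = (out < 0) | (out > 1)
    return np.clip(out, 0.0, 1.0)


def simulate_pair(
    probes: ProbeSet, truth: TruthProfile, seed: int
) -> tuple[PairedSample, dict]:
    """Simulate one tumor/blood pair.

    Germline genotypes are Hardy-Weinberg draws from ``pop_b_freq``.  Tumor
    and blood BAF noise share a common component (correlation 0.75), the
    situation TumorBoost exploits; tumor LRR carries a linear GC wave plus
    Gaussian noise; a small fraction of tumor BAFs are uniform outliers.

    Returns the pair (blood attached, genotypes left to the genotype caller)
    and truth tracks: per-probe state index, germline genotype and branch.
    """
    rng = np.random.default_rng(seed)
    n = len(probes)
    p, s0 = truth.purity, truth.s0

    genotype = rng.binomial(2, probes.pop_b_freq).astype(np.int8)
    states = state_track(probes, truth)
    branch = np.where(rng.integers(0, 2, n) == 0, "A", "B")

    # blood: diploid germline signal
    geno_mean = genotype / 2.0
    shared_sd = truth.baf_sd * np.sqrt(0.75)
    indep_sd = truth.baf_sd * 0.5
    shared = rng.normal(0.0, shared_sd, n) if truth.baf_sd > 0 else np.zeros(n)
    normal_baf = _truncated_noise(
        geno_mean, shared + (rng.normal(0.0, indep_sd, n) if truth.baf_sd > 0 else 0.0),
        truth.baf_sd, rng,
    )
    normal_lrr = rng.normal(0.0, truth.lrr_sd, n) if truth.lrr_sd > 0 else np.zeros(n)

    # tumor LRR: state mean + GC wave + noise
    state_means = np.array([lrr_mean(s, p, s0) for s in STATE_ORDER])
    gc_centered = probes.gc_frac - probes.gc_frac.mean()
    tumor_lrr = (
        state_means[states]
        + truth.gc_wave_amp * gc_centered
        + (rng.normal(0.0, truth.lrr_sd, n) if truth.lrr_sd > 0 else 0.0)
    )

    # tumor BAF: mixture band centers + shared/independent noise
    centers = np.empty(n)
    homdel_idx = STATE_INDEX[CNState.HOMDEL]
    for i in range(n):
        if states[i] == homdel_idx:
            centers[i] = np.nan
        else:
            centers[i] = band_center(
                STATE_ORDER[states[i]], int(genotype[i]), p, str(branch[i])
            )
    tumor_baf = _truncated_noise(
        np.nan_to_num(centers, nan=0.5),
        shared + (rng.normal(0.0, indep_sd, n) if truth.baf_sd > 0 else 0.0),
        truth.baf_sd, rng,
    )
    homdel_mask = states == homdel_idx
    tumor_baf[homdel_mask] = rng.uniform(0.0, 1.0, int(homdel_mask.sum()))
    if truth.outlier_rate > 0:
        out_mask = rng.random(n) < truth.outlier_rate
        tumor_baf[out_mask] = rng.uniform(0.0, 1.0, int(out_mask.sum()))
    else:
        out_mask = np.zeros(n, dtype=bool)

    pair = PairedSample(
        tumor=SampleIntensities("tumor", tumor_lrr, tumor_baf),
        normal=SampleIntensities("normal", normal_lrr, normal_baf),
    )
    tracks = {
        "state": states,
        "genotype": genotype,
        "branch": branch,
        "outlier": out_mask,
    }
    return pair, tracks


def het_mask(tracks: dict) -> np.ndarray:
    return tracks["genotype"] == GENO_AB
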