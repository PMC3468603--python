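"""Domain containers shared by every stage of the pipeline.

The genomic scaffold is a :class:`ProbeSet` (ordered SNP probes), per-sample
signal lives in :class:`SampleIntensities` (LRR/BAF tracks aligned to the
scaffold), and segmentation output is a list of :class:`Segment` in 1-based
inclusive coordinates.  Copy-number/allelic states are the six-level
:class:`CNState`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

#: canonical chromosome ordering: autosomes 1..22 then X
CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X"]
CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chrom(label: str) -> Optional[str]:
    """Map a chromosome label to the canonical {1..22, X} set.

    Returns ``None`` for labels outside that set (Y, MT, ...), which callers
    drop with a logged count.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s in CHROM_RANK:
        return s
    if s in {"23", "x"}:
        return "X"
    return None


class CNState(Enum):
    """Copy-number/allelic state of a segment.

    NORMAL and CNLOH share total copy number 2 and differ only in allelic
    composition (CNLOH = uniparental disomy: one parental allele lost, the
    other duplicated).
    """

    HOMDEL = ("HOMDEL", 0)
    LOSS = ("LOSS", 1)
    NORMAL = ("NORMAL", 2)
    CNLOH = ("CNLOH", 2)
    GAIN = ("GAIN", 3)
    AMP = ("AMP", 4)

    def __init__(self, label: str, total_copies: int):
        self.label = label
        self.total_copies = total_copies

    @classmethod
    def from_label(cls, label: str) -> "CNState":
        return cls[label.upper()]


#: fixed state order used by the HMM (index = state id)
STATE_ORDER = [
    CNState.HOMDEL,
    CNState.LOSS,
    CNState.NORMAL,
    CNState.CNLOH,
    CNState.GAIN,
    CNState.AMP,
]
STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}
N_STATES = len(STATE_ORDER)


@dataclass
class ProbeSet:
    """Ordered SNP probes: identifiers, positions, GC fraction and population
    B-allele frequency.  Probes are strictly sorted by (chrom, pos) with no
    duplicate positions per chromosome."""

    snp_id: np.ndarray  # object
    chrom: np.ndarray  # object, values in CHROMOSOMES
    pos: np.ndarray  # int64, 1-based
    gc_frac: np.ndarray  # float64 in [0, 1]
    pop_b_freq: np.ndarray  # float64 in [0, 1]

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gc_frac = np.asarray(self.gc_frac, dtype=np.float64)
        self.pop_b_freq = np.asarray(self.pop_b_freq, dtype=np.float64)
        self.validate()

    def __len__(self) -> int:
        return self.pos.size

    def validate(self) -> None:
        n = len(self)
        for name in ("snp_id", "chrom", "gc_frac", "pop_b_freq"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name} length mismatch")
        rank = np.array([CHROM_RANK[c] for c in self.chrom])
        key = rank.astype(np.int64) * (2**40) + self.pos
        if n and not np.all(np.diff(key) > 0):
            raise ValueError("probes must be strictly sorted by (chrom, pos) "
                             "with no duplicate positions")
        for name in ("gc_frac", "pop_b_freq"):
            v = getattr(self, name)
            if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
                raise ValueError(f"{name} outside [0, 1]")

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in canonical order."""
        out: dict[str, slice] = {}
        for c in CHROMOSOMES:
            idx = np.flatnonzero(self.chrom == c)
            if idx.size:
                out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP_Name": self.snp_id,
                "Chr": self.chrom,
                "Position": self.pos,
                "GC": self.gc_frac,
                "PopBFreq": self.pop_b_freq,
            }
        )


@dataclass
class SampleIntensities:
    """Per-probe LRR and BAF for one sample, aligned to a ProbeSet.

    Missing values are NaN; BAF may be missing where the probe failed.
    """

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray
    platform_id: str = "platformA"

    def __post_init__(self):
        self.lrr = np.asarray(self.lrr, dtype=np.float64)
        self.baf = np.asarray(self.baf, dtype=np.float64)
        if self.lrr.shape != self.baf.shape:
            raise ValueError("lrr and baf must have equal length")

    def __len__(self) -> int:
        return self.lrr.size

    def copy(self) -> "SampleIntensities":
        return SampleIntensities(
            self.sample_id, self.lrr.copy(), self.baf.copy(), self.platform_id
        )


# germline genotype codes (per-probe int8): number of B alleles, -1 = missing
GENO_AA, GENO_AB, GENO_BB, GENO_MISSING = 0, 1, 2, -1
GENO_LABELS = {GENO_AA: "AA", GENO_AB: "AB", GENO_BB: "BB", GENO_MISSING: "NC"}


@dataclass
class PairedSample:
    """A tumor with (optionally) its matched blood sample and the blood-derived
    germline genotype calls."""

    tumor: SampleIntensities
    normal: Optional[SampleIntensities] = None
    normal_genotypes: Optional[np.ndarray] = None  # int8 codes

    def __post_init__(self):
        if self.normal is None and self.normal_genotypes is not None:
            raise ValueError("normal_genotypes require a normal sample")
        if self.normal_genotypes is not None:
            self.normal_genotypes = np.asarray(self.normal_genotypes, dtype=np.int8)


@dataclass
class Segment:
    """A maximal run of probes sharing one copy-number/allelic state.

    Coordinates are 1-based inclusive positions of the first and last probe.
    ``het_band`` summarizes the BAF deviation from 0.5 of heterozygous probes
    in the segment (in [0, 0.5]; NaN when no het probes).
    """

    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int
    state: CNState
    mean_lrr: float
    het_band: float = float("nan")
    sub_label: str = ""  # e.g. "high_level" for extreme AMP segments

    def __post_init__(self):
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @property
    def region_string(self) -> str:
        return f"chr{self.chrom}_{self.start_pos}_{self.end_pos}"


@dataclass
class ArmTable:
    """Chromosome arm and centromere extents (1-based inclusive).

    Arms tile the chromosome outside the centromere gap:
    p = [1, cen_start-1], q = [cen_end+1, length].
    """

    table: pd.DataFrame  # columns: chrom, length, cen_start, cen_end

    def __post_init__(self):
        req = {"chrom", "length", "cen_start", "cen_end"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"arm table needs columns {sorted(req)}")
        t = self.table
        if ((t["cen_start"] <= 1) | (t["cen_end"] >= t["length"])).any():
            raise ValueError("centromere gap must lie strictly inside the chromosome")
        self.table = t.assign(chrom=t["chrom"].astype(str)).set_index("chrom", drop=False)

    def chroms(self) -> list[str]:
        return [c for c in CHROMOSOMES if c in self.table.index]

    def arm_bounds(self, arm: str) -> tuple[str, int, int]:
        """(chrom, start, end) for an arm id like '1p' or '19q'."""
        chrom, side = arm[:-1], arm[-1]
        row = self.table.loc[chrom]
        if side == "p":
            return chrom, 1, int(row["cen_start"]) - 1
        if side == "q":
            return chrom, int(row["cen_end"]) + 1, int(row["length"])
        raise ValueError(f"bad arm id {arm!r}")

    def centromere(self, chrom: str) -> tuple[int, int]:
        row = self.table.loc[str(chrom)]
        return int(row["cen_start"]), int(row["cen_end"])

    def arms(self) -> list[str]:
        return [c + s for c in self.chroms() for s in ("p", "q")]


@dataclass
class CohortTable:
    """Per-tumor binary event calls joined with phenotypes."""

    data: pd.DataFrame  # index: sample_id; event columns + phenotype columns
    event_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        for col in ("pfs_days", "os_days"):
            if col in self.data.columns and (self.data[col].dropna() < 0).any():
                raise ValueError(f"{col} must be nonnegative")
        for col in ("pfs_event", "os_event"):
            if col in self.data.columns:
                vals = self.data[col].dropna().unique()
                if not set(vals).issubset({0, 1, True, False}):
                    raise ValueError(f"{col} must be binary")
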