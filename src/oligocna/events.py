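"""Per-tumor segments -> cohort-level genomic events.

Arm-level calls, 1p/19q co-deletion classification via centromeric
breakpoints (the surrogate marker of the t(1;19)(q10;p10) translocation),
breakpoint extraction and cross-tumor co-occurrence, recurrent focal
homozygous-deletion/amplification regions, and copy-number clustering of
tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .synthetic import lrr_mean
from .types import ArmTable, CNState, ProbeSet, Segment

log = logging.getLogger(__name__)

# default thresholds: an arm is called when >= 90% of its probes carry the
# state (whole-arm convention); CNLOH uses 50% ("large CNLOH")
THETA_ARM = 0.9
THETA_CNLOH = 0.5
CENTROMERE_TOL = 3_000_000  # bp: breakpoint-to-centromere match tolerance
MATCH_TOL = 1_000_000  # bp: cross-tumor breakpoint locus matching


@dataclass
class ArmCall:
    arm: str
    fraction_loss: float
    fraction_gain: float
    fraction_cnloh: float
    call: str  # {loss, gain, cnloh, neutral}


@dataclass
class Breakpoint:
    """State-change point between adjacent retained segments: the floor of
    the midpoint between the flanking probes."""

    chrom: str
    pos: int
    left_state: CNState
    right_state: CNState

    def __post_init__(self):
        if self.left_state is self.right_state:
            raise ValueError("flanking states must differ")


@dataclass
class CodelClass:
    cls: str  # {codel, partial_1p, isolated_1p, isolated_19q, other}
    breakpoint_1_pos: Optional[int] = None
    breakpoint_19_pos: Optional[int] = None


@dataclass
class RecurrentRegion:
    chrom: str
    start: int
    end: int
    n_tumors: int
    event_type: str  # {homdel, amp}
    genes: list = field(default_factory=list)


def _probe_state_fractions(
    segments: Sequence[Segment], probes: ProbeSet, chrom: str, start: int, end: int
) -> tuple[dict[CNState, float], int]:
    """Per-state probe fractions over a genomic window."""
    in_win = (probes.chrom == chrom) & (probes.pos >= start) & (probes.pos <= end)
    n = int(in_win.sum())
    if n == 0:
        return {}, 0
    counts: dict[CNState, int] = {}
    for seg in segments:
        if seg.chrom != chrom or seg.end_pos < start or seg.start_pos > end:
            continue
        n_seg = int(
            (in_win & (probes.pos >= seg.start_pos) & (probes.pos <= seg.end_pos)).sum()
        )
        counts[seg.state] = counts.get(seg.state, 0) + n_seg
    return {s: c / n for s, c in counts.items()}, n


def call_arms(
    segments: Sequence[Segment],
    probes: ProbeSet,
    arms: ArmTable,
    theta_arm: float = THETA_ARM,
    theta_cnloh: float = THETA_CNLOH,
) -> list[ArmCall]:
    """Probe-weighted per-arm state fractions and the resulting call.

    loss/gain require a fraction >= theta_arm of the arm's probes;
    CNLOH requires >= theta_cnloh.  Arms without probes are skipped.
    """
    if not 0.5 < theta_arm <= 1:
        raise ValueError("theta_arm must be in (0.5, 1]")
    out = []
    for arm in arms.arms():
        chrom, start, end = arms.arm_bounds(arm)
        fracs, n = _probe_state_fractions(segments, probes, chrom, start, end)
        if n == 0:
            log.warning("arm %s has no probes; skipped", arm)
            continue
        f_loss = fracs.get(CNState.LOSS, 0.0) + fracs.get(CNState.HOMDEL, 0.0)
        f_gain = fracs.get(CNState.GAIN, 0.0) + fracs.get(CNState.AMP, 0.0)
        f_cnloh = fracs.get(CNState.CNLOH, 0.0)
        if f_loss >= theta_arm:
            call = "loss"
        elif f_gain >= theta_arm:
            call = "gain"
        elif f_cnloh >= theta_cnloh:
            call = "cnloh"
        else:
            call = "neutral"
        out.append(ArmCall(arm, f_loss, f_gain, f_cnloh, call))
    return out


def extract_breakpoints(segments: Sequence[Segment]) -> list[Breakpoint]:
    """One breakpoint per adjacent same-chromosome segment pair with
    differing states; position = floor of the midpoint between the two
    flanking probe coordinates."""
    out = []
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start_pos)
        for a, b in zip(segs, segs[1:]):
            if a.state is b.state:
                continue
            out.append(
                Breakpoint(
                    chrom=chrom,
                    pos=(a.end_pos + b.start_pos) // 2,
                    left_state=a.state,
                    right_state=b.state,
                )
            )
    return out


def _has_centromeric_breakpoint(
    segments: Sequence[Segment],
    breakpoints: Sequence[Breakpoint],
    arms: ArmTable,
    chrom: str,
    tol: int,
) -> Optional[int]:
    """A breakpoint within tol of the centromere, or a whole-arm segment
    starting/ending at the arm's centromeric edge (which is a centromeric
    breakpoint even when the whole chromosome arm is one segment)."""
    cen_start, cen_end = arms.centromere(chrom)
    for bp in breakpoints:
        if bp.chrom == chrom and cen_start - tol <= bp.pos <= cen_end + tol:
            return bp.pos
    # whole-arm aberrant segment abutting the centromere counts
    for seg in segments:
        if seg.chrom != chrom or seg.state is CNState.NORMAL:
            continue
        if abs(seg.end_pos - (cen_start - 1)) <= tol:  # p arm ends at centromere
            return seg.end_pos
        if abs(seg.start_pos - (cen_end + 1)) <= tol:  # q arm starts at centromere
            return seg.start_pos
    return None


def call_codel(
    segments: Sequence[Segment],
    arm_calls: Sequence[ArmCall],
    arms: ArmTable,
    tol: int = CENTROMERE_TOL,
) -> CodelClass:
    """Classify the 1p/19q status of one tumor.

    codel requires whole-arm 1p and 19q loss, neutral 1q and 19p, and a
    centromeric breakpoint on both chromosomes (within tol).  Isolated
    whole-arm 1p (or 19q) loss without the partner is the "false
    co-deletion" pattern; sub-threshold 1p loss segments give partial_1p.
    """
    calls = {a.arm: a for a in arm_calls}
    loss_1p = calls.get("1p") and calls["1p"].call == "loss"
    loss_19q = calls.get("19q") and calls["19q"].call == "loss"
    neutral_1q = calls.get("1q") and calls["1q"].call == "neutral"
    neutral_19p = calls.get("19p") and calls["19p"].call == "neutral"
    breakpoints = extract_breakpoints(segments)

    if loss_1p and loss_19q and neutral_1q and neutral_19p:
        bp1 = _has_centromeric_breakpoint(segments, breakpoints, arms, "1", tol)
        bp19 = _has_centromeric_breakpoint(segments, breakpoints, arms, "19", tol)
        if bp1 is not None and bp19 is not None:
            return CodelClass("codel", bp1, bp19)
    if loss_1p and not loss_19q:
        return CodelClass("isolated_1p")
    if loss_19q and not loss_1p:
        return CodelClass("isolated_19q")
    if not loss_1p:
        frac_1p = calls["1p"].fraction_loss if "1p" in calls else 0.0
        if 0 < frac_1p < THETA_ARM:
            return CodelClass("partial_1p")
    return CodelClass("other")


def cooccurrence_matrix(
    per_tumor_breakpoints: dict[str, Sequence[Breakpoint]],
    match_tol: int = MATCH_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster breakpoints across tumors into loci and build the binary
    tumor x locus presence matrix.

    Loci are founded greedily over position-sorted breakpoints: a breakpoint
    joins the nearest existing same-chromosome locus whose running-mean
    position is within match_tol, else founds a new locus.  Returns
    (matrix, locus catalog with columns chrom/pos/n_tumors); pairwise locus
    co-occurrence counts are matrix.T @ matrix.
    """
    records = []
    for sample_id, bps in per_tumor_breakpoints.items():
        for bp in bps:
            records.append((sample_id, bp.chrom, bp.pos))
    if not records:
        return pd.DataFrame(), pd.DataFrame(columns=["locus", "chrom", "pos", "n_tumors"])
    df = pd.DataFrame(records, columns=["sample_id", "chrom", "pos"])
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    loci: list[dict] = []  # {"chrom", "positions": [...]}
    assignment = np.empty(len(df), dtype=np.int64)
    for i, row in df.iterrows():
        best_j, best_d = -1, match_tol + 1
        for j, locus in enumerate(loci):
            if locus["chrom"] != row["chrom"]:
                continue
            d = abs(row["pos"] - np.mean(locus["positions"]))
            if d <= match_tol and d < best_d:
                best_j, best_d = j, d
        if best_j < 0:
            loci.append({"chrom": row["chrom"], "positions": [row["pos"]]})
            best_j = len(loci) - 1
        else:
            loci[best_j]["positions"].append(row["pos"])
        assignment[i] = best_j

    catalog = pd.DataFrame(
        {
            "locus": [
                f"chr{l['chrom']}:{int(round(np.mean(l['positions'])))}" for l in loci
            ],
            "chrom": [l["chrom"] for l in loci],
            "pos": [int(round(np.mean(l["positions"]))) for l in loci],
        }
    )
    samples = sorted(per_tumor_breakpoints)
    mat = pd.DataFrame(0, index=samples, columns=catalog["locus"], dtype=int)
    for i, row in df.iterrows():
        mat.loc[row["sample_id"], catalog["locus"].iloc[assignment[i]]] = 1
    catalog["n_tumors"] = mat.sum(axis=0).to_numpy()
    return mat, catalog


def recurrent_regions(
    per_tumor_segments: dict[str, Sequence[Segment]],
    event_type: str,
    k: int = 2,
    gene_bed: Optional[pd.DataFrame] = None,
) -> list[RecurrentRegion]:
    """Maximal genomic intervals covered by the event in >= k tumors
    (sweep-line over interval endpoints), annotated with overlapping genes.

    event_type selects HOMDEL segments ("homdel") or AMP segments ("amp").
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    state = {"homdel": CNState.HOMDEL, "amp": CNState.AMP}[event_type]
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for sample_id, segs in per_tumor_segments.items():
        for s in segs:
            if s.state is state:
                intervals.setdefault(s.chrom, []).append(
                    (s.start_pos, s.end_pos, sample_id)
                )
    out: list[RecurrentRegion] = []
    for chrom in sorted(intervals):
        ivals = intervals[chrom]
        # sweep-line: +1 at start, -1 at end+1 (closed intervals)
        events = sorted(
            [(s, +1) for s, _, _ in ivals] + [(e + 1, -1) for _, e, _ in ivals]
        )
        depth, region_start = 0, None
        for pos, delta in events:
            prev_depth = depth
            depth += delta
            if prev_depth < k <= depth:
                region_start = pos
            elif prev_depth >= k > depth and region_start is not None:
                out.append(
                    _annotate_region(
                        chrom, region_start, pos - 1, ivals, event_type, gene_bed
                    )
                )
                region_start = None
    return out


def _annotate_region(chrom, start, end, ivals, event_type, gene_bed):
    tumors = {sid for s, e, sid in ivals if s <= end and e >= start}
    genes: list[str] = []
    if gene_bed is not None:
        hit = gene_bed[
            (gene_bed["chrom"] == chrom)
            & (gene_bed["start"] <= end)
            & (gene_bed["end"] >= start)
        ]
        genes = sorted(hit["gene"].tolist())
    return RecurrentRegion(chrom, start, end, len(tumors), event_type, genes)


def flag_high_level_amp(
    segments: Sequence[Segment], purity: float, s0: float = 0.0
) -> list[Segment]:
    """Label AMP segments whose mean LRR exceeds the 5-copy expectation at
    the fitted purity as high_level (ordinary AMP is modeled at 4 copies)."""
    threshold = s0 + np.log2((purity * 5 + 2 * (1 - purity)) / 2.0)
    out = []
    for s in segments:
        if s.state is CNState.AMP and s.mean_lrr > threshold:
            out.append(
                Segment(
                    s.chrom, s.start_pos, s.end_pos, s.n_snps, s.state,
                    s.mean_lrr, s.het_band, "high_level",
                )
            )
        else:
            out.append(s)
    return out


def copy_number_vectors(
    per_tumor_segments: dict[str, Sequence[Segment]],
    arms: ArmTable,
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Per-tumor total-copy-number vectors over fixed genomic bins.

    CNLOH maps to 2 (copy-neutral), so the vectors reflect copy number only.
    Bins not covered by any segment default to 2.
    """
    bins = []
    for chrom in arms.chroms():
        length = int(arms.table.loc[chrom, "length"])
        for start in range(1, length + 1, bin_size):
            bins.append((chrom, start, min(start + bin_size - 1, length)))
    samples = sorted(per_tumor_segments)
    mat = np.full((len(samples), len(bins)), 2.0)
    bin_index: dict[str, list[tuple[int, int, int]]] = {}
    for j, (chrom, s, e) in enumerate(bins):
        bin_index.setdefault(chrom, []).append((s, e, j))
    for i, sid in enumerate(samples):
        for seg in per_tumor_segments[sid]:
            for s, e, j in bin_index.get(seg.chrom, ()):
                if s <= seg.end_pos and e >= seg.start_pos:
                    mat[i, j] = seg.state.total_copies
    cols = [f"chr{c}:{s}-{e}" for c, s, e in bins]
    return pd.DataFrame(mat, index=samples, columns=cols)


def cluster_tumors(
    cn_vectors: pd.DataFrame,
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative clustering of tumors on Euclidean distance with average
    linkage.  Returns (scipy linkage matrix, leaf order, Newick string).

    Input rows are sorted by sample_id first so that ties merge
    deterministically.
    """
    if len(cn_vectors) < 2:
        raise ValueError("clustering requires >= 2 tumors")
    cn_vectors = cn_vectors.sort_index()
    Z = linkage(cn_vectors.to_numpy(), method="average", metric="euclidean")
    labels = list(cn_vectors.index)
    newick = _linkage_to_newick(Z, labels)

    from scipy.cluster.hierarchy import leaves_list

    order = [labels[i] for i in leaves_list(Z)]
    return Z, order, newick


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Ultrametric Newick: node height = merge distance / 2, leaves at 0."""
    n = len(labels)

    def node(i: int, parent_height: float) -> str:
        if i < n:
            return f"{labels[i]}:{parent_height:.6g}"
        row = Z[i - n]
        h = row[2] / 2.0
        left = node(int(row[0]), h)
        right = node(int(row[1]), h)
        return f"({left},{right}):{max(parent_height - h, 0.0):.6g}"

    root_h = Z[-1, 2] / 2.0
    left = node(int(Z[-1, 0]), root_h)
    right = node(int(Z[-1, 1]), root_h)
    return f"({left},{right});"


def top_split(Z: np.ndarray, labels: Sequence[str]) -> tuple[set, set]:
    """The two clusters produced by cutting the dendrogram at its root."""
    from scipy.cluster.hierarchy import fcluster

    assign = fcluster(Z, t=2, criterion="maxclust")
    a = {l for l, c in zip(labels, assign) if c == 1}
    b = {l for l, c in zip(labels, assign) if c == 2}
    return a, b
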