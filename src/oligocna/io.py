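"""Readers and writers for the tab-separated dialects the pipeline touches.

Coordinates are 1-based inclusive everywhere in memory and in TSV output;
BED export converts to 0-based half-open.  Segment TSVs carry the
``chrN_start_end`` region-string convention alongside explicit columns.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ArmTable,
    CHROM_RANK,
    CNState,
    CohortTable,
    ProbeSet,
    SampleIntensities,
    Segment,
    normalize_chrom,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input table (missing column, unparsable value)."""


class AlignmentError(ValueError):
    """Sample table does not match the probe scaffold."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_probe_table(path: PathLike) -> ProbeSet:
    """Read a probe scaffold TSV (SNP_Name, Chr, Position, GC, PopBFreq).

    Rows on non-canonical chromosomes (Y, MT) are dropped with a logged
    count; rows failing range checks are rejected with their row numbers.
    Out-of-order input is re-sorted with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    _require_columns(df, ["SNP_Name", "Chr", "Position", "GC", "PopBFreq"], path)

    chrom = df["Chr"].map(normalize_chrom)
    n_dropped = int(chrom.isna().sum())
    if n_dropped:
        log.info("%s: dropped %d probes on non-canonical chromosomes", path, n_dropped)
    df = df.loc[chrom.notna()].assign(Chr=chrom.dropna())

    bad = df.index[
        (df["GC"] < 0) | (df["GC"] > 1) | (df["PopBFreq"] < 0) | (df["PopBFreq"] > 1)
    ]
    if len(bad):
        raise FormatError(
            f"{path}: GC/PopBFreq outside [0,1] at row(s) {[int(i) + 2 for i in bad]}"
        )

    rank = df["Chr"].map(CHROM_RANK)
    order = np.lexsort((df["Position"].to_numpy(), rank.to_numpy()))
    if not np.array_equal(order, np.arange(len(df))):
        log.warning("%s: probe rows out of (chrom, pos) order; re-sorting", path)
        df = df.iloc[order]

    return ProbeSet(
        snp_id=df["SNP_Name"].to_numpy(dtype=object),
        chrom=df["Chr"].to_numpy(dtype=object),
        pos=df["Position"].to_numpy(dtype=np.int64),
        gc_frac=df["GC"].to_numpy(dtype=np.float64),
        pop_b_freq=df["PopBFreq"].to_numpy(dtype=np.float64),
    )


def write_probe_table(probes: ProbeSet, path: PathLike) -> None:
    probes.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_sample_intensities(
    path: PathLike, probes: ProbeSet, max_unmatched: float = 0.10
) -> SampleIntensities:
    """Read an Illumina FinalReport-style intensity table and align it to the
    probe scaffold by SNP identifier.

    Probes absent from the file are marked missing (NaN).  More than
    ``max_unmatched`` of the scaffold unmatched raises :class:`AlignmentError`.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["SNP Name", "Log R Ratio", "B Allele Freq"], path)
    sample_id = (
        str(df["Sample ID"].iloc[0]) if "Sample ID" in df.columns and len(df) else Path(path).stem
    )
    platform = str(df["Platform"].iloc[0]) if "Platform" in df.columns and len(df) else "platformA"

    by_snp = df.drop_duplicates("SNP Name").set_index("SNP Name")
    aligned = by_snp.reindex(np.asarray(probes.snp_id, dtype=object))
    n_missing = int(aligned["Log R Ratio"].isna().sum())
    frac = 1.0 - (len(by_snp.index.intersection(probes.snp_id)) / max(len(probes), 1))
    if frac > max_unmatched:
        raise AlignmentError(
            f"{path}: {frac:.0%} of scaffold probes unmatched (limit {max_unmatched:.0%})"
        )
    if n_missing:
        log.info("%s: %d probes missing from file", path, n_missing)
    return SampleIntensities(
        sample_id=sample_id,
        lrr=aligned["Log R Ratio"].to_numpy(dtype=np.float64),
        baf=aligned["B Allele Freq"].to_numpy(dtype=np.float64),
        platform_id=platform,
    )


def write_sample_intensities(
    s: SampleIntensities, probes: ProbeSet, path: PathLike
) -> None:
    pd.DataFrame(
        {
            "SNP Name": probes.snp_id,
            "Sample ID": s.sample_id,
            "Log R Ratio": s.lrr,
            "B Allele Freq": s.baf,
            "Platform": s.platform_id,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


SEGMENT_COLUMNS = [
    "region", "chrom", "start_pos", "end_pos", "n_snps",
    "state", "mean_lrr", "het_band", "sub_label",
]


def segments_to_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    rows = [
        {
            "region": s.region_string,
            "chrom": s.chrom,
            "start_pos": s.start_pos,
            "end_pos": s.end_pos,
            "n_snps": s.n_snps,
            "state": s.state.label,
            "mean_lrr": s.mean_lrr,
            "het_band": s.het_band,
            "sub_label": s.sub_label,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments(segments: Sequence[Segment], path: PathLike) -> None:
    """Write segments as a TSV (1-based inclusive, region strings) and a BED
    (0-based half-open, state in the name field) side by side.

    ``path`` names the TSV; the BED gets the same stem with suffix ``.bed``.
    """
    path = Path(path)
    segments_to_frame(segments).to_csv(path, sep="\t", index=False, float_format="%.6f")
    bed = path.with_suffix(".bed")
    with open(bed, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for s in segments:
            name = s.state.label + (f":{s.sub_label}" if s.sub_label else "")
            fh.write(f"chr{s.chrom}\t{s.start_pos - 1}\t{s.end_pos}\t{name}\n")


def read_segments(path: PathLike) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, SEGMENT_COLUMNS[1:8], path)
    out = []
    for _, r in df.iterrows():
        out.append(
            Segment(
                chrom=str(r["chrom"]),
                start_pos=int(r["start_pos"]),
                end_pos=int(r["end_pos"]),
                n_snps=int(r["n_snps"]),
                state=CNState.from_label(r["state"]),
                mean_lrr=float(r["mean_lrr"]),
                het_band=float(r["het_band"]),
                sub_label="" if pd.isna(r.get("sub_label", "")) else str(r.get("sub_label", "")),
            )
        )
    return out


def read_arm_table(path: Optional[PathLike] = None) -> ArmTable:
    """Read a chromosome-arm/centromere table; default is the packaged one.

    The packaged table uses GRCh37-scale chromosome lengths and centromere
    gaps; the genome build is a configuration item, so analyses that depend
    on exact base-pair coordinates should supply their own table.
    """
    if path is None:
        ref = resources.files("oligocna.data").joinpath("arms_grch37like.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "length", "cen_start", "cen_end"], path or "<packaged>")
    return ArmTable(df)


def read_gene_bed(path: Optional[PathLike] = None) -> pd.DataFrame:
    """Read a gene annotation BED (0-based half-open) into a 1-based frame
    with columns chrom, start, end, gene."""
    if path is None:
        ref = resources.files("oligocna.data").joinpath("genes_synthetic.bed")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", header=None,
                             names=["chrom", "start", "end", "gene"])
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "gene"])
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df = df.dropna(subset=["chrom"])
    df["start"] = df["start"].astype(np.int64) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(np.int64)
    return df.reset_index(drop=True)


PHENOTYPE_COLUMNS = [
    "sample_id", "idh_status", "age", "sex", "kps",
    "pfs_days", "pfs_event", "os_days", "os_event",
]


def read_phenotypes(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    return df.set_index("sample_id", drop=False)


def build_cohort_table(
    phenotypes: pd.DataFrame, event_calls: pd.DataFrame
) -> CohortTable:
    """Join per-tumor binary event calls (index sample_id) with phenotypes."""
    joined = phenotypes.join(event_calls, how="inner")
    return CohortTable(joined, event_columns=list(event_calls.columns))
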