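"""Relative-quantification qPCR copy-number calculator (2^-ddCt).

Used to validate SNP-array homozygous-deletion and amplification calls
(e.g. CDKN2A, EGFR) against a diploid reference locus (RNase P) and a
diploid calibrator sample:

    dCt  = mean Ct(target) - mean Ct(reference)
    ddCt = dCt - dCt(calibrator)
    copies = 2 * 2^(-ddCt)

A diploid calibrator and diploid reference locus are assumed, hence the
factor 2.  Classification thresholds are conventional and reported in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Ct at/above which the target is considered failed amplification
CT_FAIL = 45.0
#: duplicates differing by more than this many cycles get a QC flag
DUPLICATE_TOL = 1.5

#: copy-number class boundaries (copies): homdel < 0.5 <= loss < 1.5 <=
#: normal <= 2.5 < gain <= 5 < amp
CLASS_BOUNDS = {"homdel": 0.5, "loss": 1.5, "normal": 2.5, "gain": 5.0}


@dataclass
class QpcrAssay:
    sample_id: str
    target: str
    ct_target: Sequence[float]  # duplicate measurements
    ct_reference: Sequence[float]
    calibrator_dct: float  # dCt of a diploid control sample
    qc_flags: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("ct_target", "ct_reference"):
            vals = np.asarray(getattr(self, name), dtype=np.float64)
            if ((vals <= 0) | (vals >= 50)).any():
                raise ValueError(f"{name} outside (0, 50)")
            if vals.size >= 2 and np.ptp(vals) >= DUPLICATE_TOL:
                self.qc_flags.append(f"{name}_duplicates_discordant")
            setattr(self, name, vals)


def copy_number_ddct(assay: QpcrAssay) -> tuple[float, list]:
    """Estimated copy number via 2^-ddCt, with flags.

    Failed target amplification (mean Ct >= 45) with a normal reference is
    reported as copies < 0.5 with a homozygous-deletion-consistent flag.
    """
    flags = list(assay.qc_flags)
    mean_t = float(np.mean(assay.ct_target))
    mean_r = float(np.mean(assay.ct_reference))
    if mean_t >= CT_FAIL and mean_r < CT_FAIL:
        flags.append("homozygous_deletion_consistent")
        return 0.0, flags
    dct = mean_t - mean_r
    ddct = dct - assay.calibrator_dct
    return float(2.0 * 2.0 ** (-ddct)), flags


def classify_qpcr(copies: float) -> str:
    """Copy-number class from the estimated copies (conventional cut-offs)."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if copies < CLASS_BOUNDS["homdel"]:
        return "homdel"
    if copies < CLASS_BOUNDS["loss"]:
        return "loss"
    if copies <= CLASS_BOUNDS["normal"]:
        return "normal"
    if copies <= CLASS_BOUNDS["gain"]:
        return "gain"
    return "amp"


def run_qpcr_table(df: pd.DataFrame) -> pd.DataFrame:
    """Process a TSV-style assay table.

    Expected columns: sample_id, target, ct_target_1, ct_target_2,
    ct_ref_1, ct_ref_2, calibrator_dct.
    """
    rows = []
    for _, r in df.iterrows():
        assay = QpcrAssay(
            sample_id=str(r["sample_id"]),
            target=str(r["target"]),
            ct_target=[float(r["ct_target_1"]), float(r["ct_target_2"])],
            ct_reference=[float(r["ct_ref_1"]), float(r["ct_ref_2"])],
            calibrator_dct=float(r["calibrator_dct"]),
        )
        copies, flags = copy_number_ddct(assay)
        rows.append(
            {
                "sample_id": assay.sample_id,
                "target": assay.target,
                "copies": copies,
                "class": classify_qpcr(copies),
                "qc_flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
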