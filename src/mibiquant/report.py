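"""Per-subject tissue concentration statistics and cohort aggregation.

Each subject yields up to seven region columns: the whole breast, and
adipose/glandular means for each of the three segmentation methods
(minimum, crosspoint, purity95).  The cohort summary averages the
per-subject region means (unweighted across subjects); subjects excluded
from segmentation contribute only to the columns they have.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BreastMask, VoxelGrid
from .segmentation import TissueMasks

METHODS = ("minimum", "crosspoint", "purity95")
COLUMNS = ("total",) + tuple(f"adipose_{m}" for m in METHODS) + \
    tuple(f"glandular_{m}" for m in METHODS)


@dataclass
class RegionStats:
    """Mean and spread of in-mask voxel concentrations (uCi/mL)."""

    mean: float
    std: float
    n: int


@dataclass
class QuantReport:
    """One subject's per-region concentration statistics.

    Regions with zero voxels are absent from ``regions``, never reported
    as zero.
    """

    subject_id: str
    regions: dict[str, RegionStats] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def mean_of(self, region: str) -> float | None:
        st = self.regions.get(region)
        return None if st is None else st.mean


def tissue_stats(spect: VoxelGrid,
                 masks: TissueMasks | dict[str, TissueMasks] | None,
                 breast: BreastMask, subject_id: str = "subject",
                 ddof: int = 0) -> QuantReport:
    """Per-region mean +/- std of voxel concentrations on the SPECT grid.

    ``masks`` may be a single :class:`TissueMasks`, a dict keyed by method
    name, or None (whole-breast only, as for subjects excluded from the
    segmentation analysis).  Zero-valued voxels are measurements and are
    included; the std is the population std by default (``ddof=0``).
    """
    if breast.mask.shape != spect.shape:
        raise ValueError("breast mask must be on the SPECT grid")
    report = QuantReport(subject_id)

    def add(name: str, region: np.ndarray) -> None:
        region = region & breast.mask
        n = int(region.sum())
        if n == 0:
            return
        v = spect.values[region]
        report.regions[name] = RegionStats(float(v.mean()),
                                           float(v.std(ddof=ddof)), n)

    add("total", np.ones(spect.shape, dtype=bool))
    if masks is None:
        report.flags.append("segmentation excluded")
        return report
    if isinstance(masks, TissueMasks):
        masks = {masks.method: masks}
    for method, tm in masks.items():
        if tm.fat_mask.shape != spect.shape:
            raise ValueError("tissue masks must be on the SPECT grid")
        add(f"adipose_{method}", tm.fat_mask)
        add(f"glandular_{method}", tm.gland_mask)
    return report


@dataclass
class CohortSummary:
    """Across-subject mean and std of the per-subject region means."""

    mean: dict[str, float]
    std: dict[str, float]
    n: dict[str, int]

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        """Display values at the table's two-decimal precision; the
        machine-precision means stay in ``mean``."""
        return {k: round(v, decimals) for k, v in self.mean.items()}


def aggregate_cohort(reports: list[QuantReport]) -> CohortSummary:
    """Unweighted across-subject aggregation of region means.

    Each column's entry is the arithmetic mean (and sample spread) of the
    per-subject means of the subjects that have that column.
    """
    if not reports:
        raise ValueError("no subject reports to aggregate")
    mean, std, n = {}, {}, {}
    for col in COLUMNS:
        vals = [r.mean_of(col) for r in reports]
        vals = [v for v in vals if v is not None]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        mean[col] = float(arr.mean())
        std[col] = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
        n[col] = len(arr)
    return CohortSummary(mean, std, n)


def reports_from_means(means_by_subject: dict[str, dict[str, float]]
                       ) -> list[QuantReport]:
    """Build minimal QuantReports from bare per-subject region means
    (e.g., a published per-subject table used as input)."""
    out = []
    for sid, cols in means_by_subject.items():
        r = QuantReport(str(sid))
        for col, v in cols.items():
            r.regions[col] = RegionStats(float(v), float("nan"), 0)
        out.append(r)
    return out


_HEADERS = {"total": "Total breast",
            "adipose_minimum": "Adipose (minimum)",
            "adipose_crosspoint": "Adipose (cross-point)",
            "adipose_purity95": "Adipose (95% interval)",
            "glandular_minimum": "Glandular (minimum)",
            "glandular_crosspoint": "Glandular (cross-point)",
            "glandular_purity95": "Glandular (95% interval)"}


def render_table(summary: CohortSummary, reports: list[QuantReport],
                 csv_path: str | None = None, md_path: str | None = None
                 ) -> pd.DataFrame:
    """Subjects x regions table of mean concentrations (uCi/mL) with a
    Total row of across-subject means; missing cells rendered as em-dash in
    the Markdown output and NaN in the CSV."""
    rows = []
    for r in reports:
        rows.append({"subject": r.subject_id,
                     **{c: r.mean_of(c) for c in COLUMNS}})
    rows.append({"subject": "Total",
                 **{c: summary.mean.get(c) for c in COLUMNS}})
    df = pd.DataFrame(rows, columns=["subject", *COLUMNS])
    if csv_path:
        df.to_csv(csv_path, index=False)
    if md_path:
        lines = ["| Subject | " + " | ".join(_HEADERS[c] for c in COLUMNS)
                 + " |",
                 "|" + "---|" * (len(COLUMNS) + 1)]
        for _, row in df.iterrows():
            cells = [str(row["subject"])]
            for c in COLUMNS:
                v = row[c]
                cells.append("—" if v is None or (isinstance(v, float)
                                                  and np.isnan(v))
                             else f"{v:.2f}")
            lines.append("| " + " | ".join(cells) + " |")
        with open(md_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return df
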