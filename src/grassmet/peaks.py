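"""Peak nomenclature and the peak annotation table.

Peaks are named ``CP434.2167_4.58``: ``CP``/``CN`` for the C18 column in
positive/negative ESI, then the measured m/z to 4 decimal places and the
apex retention time in minutes to 2 decimal places.

The annotation table is a plain :class:`pandas.DataFrame` with one row per
peak (columns ``peak_id, mz, rt, rtmin, rtmax, mzmin, mzmax, adduct,
isotope_links``) and travels alongside the peaks x samples intensity matrix
through every pipeline stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "format_peak_id",
    "parse_peak_id",
    "PeakIdError",
    "PeakRecord",
    "ANNOTATION_COLUMNS",
    "empty_annotation_table",
    "read_peak_table",
    "write_peak_table",
    "read_sample_meta",
    "write_sample_meta",
]

_PEAK_ID = re.compile(r"^(CP|CN)(\d+\.\d{4})_(\d+\.\d{2})$")

ANNOTATION_COLUMNS = [
    "peak_id", "mz", "rt", "rtmin", "rtmax", "mzmin", "mzmax",
    "adduct", "isotope_links",
]

META_COLUMNS = [
    "sample_id", "population", "genotype", "replicate", "batch",
    "ion_mode", "is_control",
]


class PeakIdError(ValueError):
    pass


def format_peak_id(ion_mode: str, mz: float, rt: float) -> str:
    """Render the peak nomenclature string, e.g. ``CP434.2167_4.58``."""
    if mz <= 0:
        raise ValueError(f"mz must be positive, got {mz}")
    if rt < 0:
        raise ValueError(f"rt must be nonnegative, got {rt}")
    prefix = {"positive": "CP", "negative": "CN"}.get(ion_mode)
    if prefix is None:
        raise ValueError(f"ion_mode must be 'positive' or 'negative', got {ion_mode!r}")
    return f"{prefix}{mz:.4f}_{rt:.2f}"


def parse_peak_id(peak_id: str) -> tuple[str, float, float]:
    """Invert :func:`format_peak_id`. Returns (ion_mode, mz, rt)."""
    m = _PEAK_ID.match(peak_id)
    if m is None:
        raise PeakIdError(f"malformed peak id {peak_id!r}")
    ion_mode = "positive" if m.group(1) == "CP" else "negative"
    return ion_mode, float(m.group(2)), float(m.group(3))


@dataclass
class PeakRecord:
    """One row of the peak annotation table."""

    peak_id: str
    mz: float
    rt: float
    rt_range: tuple[float, float]
    mz_range: tuple[float, float]
    ion_mode: str
    adduct: str = "unknown"
    isotope_partners: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        rtmin, rtmax = self.rt_range
        mzmin, mzmax = self.mz_range
        if not (rtmin <= self.rt <= rtmax):
            raise ValueError(f"{self.peak_id}: rt {self.rt} outside [{rtmin}, {rtmax}]")
        if not (mzmin <= self.mz <= mzmax):
            raise ValueError(f"{self.peak_id}: mz {self.mz} outside [{mzmin}, {mzmax}]")
        # The id must round-trip through the nomenclature parser.
        mode, _, _ = parse_peak_id(self.peak_id)
        if mode != self.ion_mode:
            raise ValueError(f"{self.peak_id}: id prefix disagrees with ion_mode {self.ion_mode}")

    def to_row(self) -> dict:
        return {
            "peak_id": self.peak_id,
            "mz": self.mz,
            "rt": self.rt,
            "rtmin": self.rt_range[0],
            "rtmax": self.rt_range[1],
            "mzmin": self.mz_range[0],
            "mzmax": self.mz_range[1],
            "adduct": self.adduct,
            "isotope_links": ";".join(self.isotope_partners),
        }


def empty_annotation_table() -> pd.DataFrame:
    return pd.DataFrame(columns=ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def write_peak_table(path, matrix: pd.DataFrame, annot: pd.DataFrame) -> None:
    """Write the peak table: annotation columns then one column per sample."""
    annot = annot.set_index("peak_id").loc[matrix.index].reset_index()
    merged = pd.concat(
        [annot.set_index("peak_id"), matrix], axis=1
    ).reset_index().rename(columns={"index": "peak_id"})
    merged.to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a peak table written by :func:`write_peak_table`.

    Returns ``(matrix, annot)`` with the matrix indexed by peak_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"isotope_links": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    annot = df[ANNOTATION_COLUMNS].copy()
    annot["isotope_links"] = annot["isotope_links"].fillna("")
    sample_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    matrix = df.set_index("peak_id")[sample_cols].astype(float)
    return matrix, annot


def write_sample_meta(path, meta: pd.DataFrame) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    meta["is_control"] = meta["is_control"].astype(bool)
    return meta
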