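"""Readers, writers and validated containers for the pipeline's file formats.

Formats handled
---------------
* Bismark cytosine coverage reports (6 columns: chrom, start, end,
  methylation %, methylated count, unmethylated count; start == end, 1-based).
  The percentage column is ignored on input and recomputed from the counts.
* Tab-delimited sample sheets (sample_id, patient_id, tissue, subtype, split).
* BED for DMR export (internally 1-based inclusive, exported 0-based
  half-open) and for SNP masks.
* UCSC-style two-column chrom.sizes tables.

Coordinates are 1-based inclusive everywhere inside the package; only BED
import/export converts. CpGs are keyed by (chrom, pos) — strand is not
modeled, matching the site keying of the methylation-extractor output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import build_interval_index, overlaps_any

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .regions import DMR


class FormatError(ValueError):
    """A malformed input file (reported with the offending line number)."""


class Tissue(str, Enum):
    tumor = "tumor"
    NAT = "NAT"


class Subtype(str, Enum):
    SSL = "SSL"
    TA = "TA"
    VA_TVA = "VA_TVA"
    CRC = "CRC"


class Split(str, Enum):
    discovery = "discovery"
    validation = "validation"


APL_SUBTYPES: tuple[Subtype, ...] = (Subtype.SSL, Subtype.TA, Subtype.VA_TVA)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    tissue: Tissue
    subtype: Subtype
    split: Split


class SampleSheet:
    """Validated cohort description with tumor/NAT pairing.

    A "paired" patient contributes exactly one tumor and one NAT record.
    Validation-split samples may be unpaired tumors; discovery-split patients
    must be fully paired.
    """

    def __init__(self, records: Sequence[SampleRecord]):
        seen: set[str] = set()
        for r in records:
            if r.sample_id in seen:
                raise ValueError(f"duplicate sample_id {r.sample_id!r}")
            seen.add(r.sample_id)
        self.records: list[SampleRecord] = list(records)
        self._pairs: dict[str, tuple[str, str]] = {}
        by_patient: dict[str, list[SampleRecord]] = {}
        for r in self.records:
            by_patient.setdefault(r.patient_id, []).append(r)
        for pid, recs in by_patient.items():
            tumors = [r for r in recs if r.tissue == Tissue.tumor]
            nats = [r for r in recs if r.tissue == Tissue.NAT]
            if len(tumors) > 1:
                raise ValueError(f"patient {pid!r} has {len(tumors)} tumor records")
            if len(nats) > 1:
                raise ValueError(f"patient {pid!r} has {len(nats)} NAT records")
            if len({r.subtype for r in recs}) > 1:
                raise ValueError(f"patient {pid!r} has inconsistent subtype labels")
            if tumors and nats:
                self._pairs[pid] = (tumors[0].sample_id, nats[0].sample_id)
            elif nats and not tumors:
                raise ValueError(f"patient {pid!r} has a NAT record but no tumor")
            elif tumors and tumors[0].split == Split.discovery:
                raise ValueError(
                    f"discovery patient {pid!r} lacks a NAT partner"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def pairs(self, subtype: Subtype | None = None) -> list[tuple[str, str]]:
        """(tumor_id, nat_id) per paired patient, optionally one subtype."""
        out = []
        subtype_of = {r.patient_id: r.subtype for r in self.records}
        for pid, pair in sorted(self._pairs.items()):
            if subtype is None or subtype_of[pid] == subtype:
                out.append(pair)
        return out

    def samples(
        self,
        tissue: Tissue | None = None,
        subtype: Subtype | None = None,
        split: Split | None = None,
    ) -> list[str]:
        return [
            r.sample_id
            for r in self.records
            if (tissue is None or r.tissue == tissue)
            and (subtype is None or r.subtype == subtype)
            and (split is None or r.split == split)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sample_id, r.patient_id, r.tissue.value, r.subtype.value, r.split.value)
                for r in self.records
            ],
            columns=["sample_id", "patient_id", "tissue", "subtype", "split"],
        )


class CpGSiteTable:
    """Per-CpG methylated/unmethylated read counts across samples.

    Rows are keyed by (chrom, pos) with pos 1-based; ``meth`` and ``unmeth``
    are aligned integer DataFrames with one column per sample. Beta values are
    derived, never stored: beta = meth/(meth+unmeth), missing iff depth 0.
    """

    def __init__(self, meth: pd.DataFrame, unmeth: pd.DataFrame):
        if not meth.index.equals(unmeth.index) or list(meth.columns) != list(unmeth.columns):
            raise ValueError("meth/unmeth frames must be aligned")
        if (meth.to_numpy() < 0).any() or (unmeth.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.meth = meth
        self.unmeth = unmeth

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def index(self) -> pd.MultiIndex:
        return self.meth.index

    @property
    def n_sites(self) -> int:
        return len(self.meth)

    def depth(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    def beta(self) -> pd.DataFrame:
        depth = self.depth().to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            b = self.meth.to_numpy(dtype=float) / depth
        b[depth == 0] = np.nan
        return pd.DataFrame(b, index=self.index, columns=self.meth.columns)

    def select_rows(self, mask: np.ndarray | pd.Series) -> "CpGSiteTable":
        return CpGSiteTable(self.meth.loc[mask], self.unmeth.loc[mask])

    def select_samples(self, sample_ids: Sequence[str]) -> "CpGSiteTable":
        return CpGSiteTable(self.meth[list(sample_ids)], self.unmeth[list(sample_ids)])

    @classmethod
    def from_sample_frames(cls, frames: Mapping[str, pd.DataFrame]) -> "CpGSiteTable":
        """Build from per-sample (chrom, pos, meth, unmeth) frames.

        Sites absent from a sample get zero counts (depth 0 -> beta missing);
        the coverage filter removes them later.
        """
        meth_cols = {}
        unmeth_cols = {}
        for sid, df in frames.items():
            idx = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]], names=["chrom", "pos"])
            meth_cols[sid] = pd.Series(df["meth"].to_numpy(), index=idx)
            unmeth_cols[sid] = pd.Series(df["unmeth"].to_numpy(), index=idx)
        meth = pd.DataFrame(meth_cols).fillna(0).astype(np.int64).sort_index()
        unmeth = pd.DataFrame(unmeth_cols).fillna(0).astype(np.int64).sort_index()
        return cls(meth, unmeth)


@dataclass
class GenomeInfo:
    """Chromosome lengths plus the autosome flag used by enrichment."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for c, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {c!r}")

    @staticmethod
    def is_autosome(chrom: str) -> bool:
        m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
        return m is not None and 1 <= int(m.group(1)) <= 22

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if self.is_autosome(c)]


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------

def read_bismark_cov(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Parse one Bismark coverage report into (chrom, pos, meth, unmeth).

    The methylation-% column is ignored; betas are recomputed from the counts
    downstream to avoid rounding drift.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(parts)}"
                )
            chrom, start, end, _pct, m, u = parts
            try:
                start_i, end_i, m_i, u_i = int(start), int(end), int(m), int(u)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if start_i != end_i:
                raise FormatError(
                    f"{path}:{lineno}: start != end ({start_i} != {end_i}); "
                    "expected single-cytosine records"
                )
            if start_i < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            if m_i < 0 or u_i < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            rows.append((chrom, start_i, m_i, u_i))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    df.attrs["sample_id"] = sample_id
    return df


def write_bismark_cov(df: pd.DataFrame, path: str | Path) -> None:
    """Write (chrom, pos, meth, unmeth) rows as a Bismark coverage report."""
    with open(path, "w") as fh:
        for chrom, pos, m, u in df[["chrom", "pos", "meth", "unmeth"]].itertuples(index=False):
            depth = m + u
            pct = 100.0 * m / depth if depth else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:g}\t{m}\t{u}\n")


def read_cov_files(paths: Mapping[str, str | Path]) -> CpGSiteTable:
    """Read one coverage file per sample into a joint count table."""
    return CpGSiteTable.from_sample_frames(
        {sid: read_bismark_cov(p, sid) for sid, p in paths.items()}
    )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ["sample_id", "patient_id", "tissue", "subtype", "split"]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    patient_id=row.patient_id,
                    tissue=Tissue(row.tissue),
                    subtype=Subtype(row.subtype),
                    split=Split(row.split),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DMR BED
# ---------------------------------------------------------------------------

_DMR_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tn_cpgs\tn_sig\tmean_delta\tdirection"
)


def write_dmr_bed(dmrs: Sequence["DMR"], path: str | Path) -> None:
    """Export DMRs as BED6+4, 0-based half-open, sorted by (chrom, start)."""
    with open(path, "w") as fh:
        fh.write(_DMR_BED_HEADER + "\n")
        for d in sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end)):
            score = round(d.frac_significant * 1000)
            fh.write(
                f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.comparison}\t{score}\t.\t"
                f"{d.n_cpgs}\t{d.n_sig}\t{d.mean_delta!r}\t{d.direction}\n"
            )


def read_dmr_bed(path: str | Path) -> list["DMR"]:
    from .regions import DMR

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise FormatError(f"{path}:{lineno}: expected 10 columns")
            chrom, start, end, name, _score, _strand, n_cpgs, n_sig, mean_delta, direction = parts
            out.append(
                DMR(
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    n_cpgs=int(n_cpgs),
                    n_sig=int(n_sig),
                    mean_delta=float(mean_delta),
                    direction=direction,
                    comparison=name,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED masks and chrom sizes
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read plain BED3(+) intervals as 1-based inclusive triples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval")
            out.append((chrom, start + 1, end))
    return out


def write_bed_intervals(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write 1-based inclusive triples as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def position_mask(
    index: pd.MultiIndex, intervals: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Boolean array marking (chrom, pos) index entries inside any interval."""
    ref = build_interval_index(intervals)
    chroms = index.get_level_values("chrom")
    poss = index.get_level_values("pos")
    return np.array(
        [overlaps_any(c, p, p, ref) for c, p in zip(chroms, poss)], dtype=bool
    )


def read_chrom_sizes(path: str | Path) -> GenomeInfo:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom and length")
            lengths[parts[0]] = int(parts[1])
    return GenomeInfo(lengths)


def write_chrom_sizes(genome: GenomeInfo, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.lengths.items():
            fh.write(f"{chrom}\t{length}\n")
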