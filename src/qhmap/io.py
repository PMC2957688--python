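"""Readers and writers for genotype-call tables and region (BED) files.

Two call-table formats are supported:

* **native-tsv** — tab-separated with a header row and columns
  ``snp_id, chrom, pos_bp, pos_cm, call`` (calls in AA/AB/BB/NC), one sample
  per file.
* **plink-like** — a PLINK ``.map`` file (chrom, snp_id, pos_cm, pos_bp)
  alongside a single-column call file in the same row order.

Regions are written as BED (0-based half-open bp) with extra columns for the
genetic bounds; metadata needed for a lossless round trip travels in ``#``
header lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AUTOSOMES,
    CALL_TO_TEXT,
    TEXT_TO_CALL,
    GenomeRegions,
    GenotypeTrack,
    Segment,
    SegmentKind,
)

logger = logging.getLogger(__name__)

NATIVE_COLUMNS = ["snp_id", "chrom", "pos_bp", "pos_cm", "call"]


class ParseError(ValueError):
    """Raised for malformed input rows; carries the offending line number."""


def _normalize_chrom(raw: object) -> int | None:
    s = str(raw).removeprefix("chr")
    if not s.isdigit():
        return None
    c = int(s)
    return c if c in AUTOSOMES else None


def _tracks_from_frame(df: pd.DataFrame, sample_id: str, source: str) -> list[GenotypeTrack]:
    bad_call = ~df["call"].isin(TEXT_TO_CALL)
    if bad_call.any():
        line = int(df.index[bad_call][0]) + 2  # +1 header, +1 1-based
        raise ParseError(
            f"{source}: invalid call {df.loc[df.index[bad_call][0], 'call']!r} at line {line}"
        )
    chroms = df["chrom"].map(_normalize_chrom)
    n_dropped = int(chroms.isna().sum())
    if n_dropped:
        logger.info("%s: dropped %d non-autosomal row(s)", source, n_dropped)
    df = df.loc[chroms.notna()].assign(chrom=chroms.dropna().astype(int))

    tracks = []
    for chrom, grp in df.groupby("chrom", sort=True):
        if not grp["pos_bp"].is_monotonic_increasing:
            logger.warning("%s: chr%d not sorted by pos_bp; sorting", source, chrom)
            grp = grp.sort_values("pos_bp", kind="mergesort")
        if grp["pos_bp"].duplicated().any():
            dup = int(grp.loc[grp["pos_bp"].duplicated(), "pos_bp"].iloc[0])
            raise ParseError(f"{source}: duplicate pos_bp {dup} on chr{chrom}")
        tracks.append(
            GenotypeTrack(
                sample_id=sample_id,
                chrom=int(chrom),
                snp_ids=grp["snp_id"].astype(str).to_numpy(object),
                pos_bp=grp["pos_bp"].to_numpy(np.int64),
                pos_cm=grp["pos_cm"].to_numpy(np.float64),
                calls=grp["call"].map(TEXT_TO_CALL).to_numpy(np.int8),
            )
        )
    return tracks


def read_calls(
    path,
    format: str = "native-tsv",
    sample_id: str | None = None,
    map_path=None,
) -> list[GenotypeTrack]:
    """Read one sample's genotype calls into per-autosome tracks.

    Parameters
    ----------
    path
        Calls file (native TSV, or the call-column file for plink-like input).
    format
        ``"native-tsv"`` or ``"plink-like"``.
    sample_id
        Defaults to the file stem.
    map_path
        For plink-like input: the ``.map`` file; defaults to ``path`` with a
        ``.map`` suffix.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    if format == "native-tsv":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                dtype={"snp_id": str, "chrom": str, "pos_bp": np.int64,
                       "pos_cm": np.float64, "call": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ParseError(f"{path}: malformed native TSV ({exc})") from exc
        missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        return _tracks_from_frame(df[NATIVE_COLUMNS], sid, str(path))
    if format == "plink-like":
        mp = Path(map_path) if map_path is not None else path.with_suffix(".map")
        try:
            mdf = pd.read_csv(mp, sep=r"\s+", header=None,
                              names=["chrom", "snp_id", "pos_cm", "pos_bp"])
            calls = pd.read_csv(path, sep=r"\s+", header=None, names=["call"])
        except (ValueError, pd.errors.ParserError) as exc:
            raise ParseError(f"{path}: malformed plink-like input ({exc})") from exc
        if len(mdf) != len(calls):
            raise ParseError(
                f"{path}: {len(calls)} calls but {len(mdf)} map rows in {mp}"
            )
        df = mdf.assign(call=calls["call"].to_numpy())[NATIVE_COLUMNS]
        return _tracks_from_frame(df, sid, str(path))
    raise ValueError(f"unknown format {format!r}")


def write_calls(tracks: list[GenotypeTrack], path) -> None:
    """Write tracks (one sample) to the native TSV format."""
    frames = []
    for t in sorted(tracks, key=lambda t: t.chrom):
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": t.snp_ids,
                    "chrom": t.chrom,
                    "pos_bp": t.pos_bp,
                    "pos_cm": t.pos_cm,
                    "call": [CALL_TO_TEXT[c] for c in t.calls],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=NATIVE_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False)


BED_COLUMNS = [
    "chrom", "start_bp", "end_bp", "start_cm", "end_cm",
    "genetic_length_cm", "n_snps", "kind",
]


def write_regions(regions: GenomeRegions, path) -> None:
    """Write segments as BED6+ (0-based half-open bp) with genetic bounds."""
    with open(path, "w") as fh:
        fh.write(f"#sample_id={regions.sample_id}\n")
        fh.write(f"#total_autosome_cm={regions.total_autosome_cm:.6f}\n")
        fh.write("#" + "\t".join(BED_COLUMNS) + "\n")
        for seg in sorted(regions.segments, key=lambda s: (s.chrom, s.start_bp)):
            fh.write(
                f"{seg.chrom}\t{seg.start_bp}\t{seg.end_bp}\t"
                f"{seg.start_cm:.6f}\t{seg.end_cm:.6f}\t"
                f"{seg.genetic_length_cm:.6f}\t{seg.n_snps}\t{seg.kind.value}\n"
            )


def read_regions(path) -> GenomeRegions:
    """Read back a BED file written by :func:`write_regions`."""
    sample_id, total_cm = Path(path).stem, None
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#sample_id="):
                    sample_id = line.split("=", 1)[1]
                elif line.startswith("#total_autosome_cm="):
                    total_cm = float(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != len(BED_COLUMNS):
                raise ParseError(f"{path}: expected {len(BED_COLUMNS)} fields at line {lineno}")
            try:
                segments.append(
                    Segment(
                        chrom=int(parts[0].removeprefix("chr")),
                        start_bp=int(parts[1]),
                        end_bp=int(parts[2]),
                        start_cm=float(parts[3]),
                        end_cm=float(parts[4]),
                        n_snps=int(parts[6]),
                        kind=SegmentKind(parts[7]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: malformed segment at line {lineno} ({exc})") from exc
    if total_cm is None:
        raise ParseError(f"{path}: missing #total_autosome_cm header")
    return GenomeRegions(sample_id=sample_id, segments=segments, total_autosome_cm=total_cm)
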