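"""Genetic-map handling: cM interpolation and autosome genetic lengths.

A :class:`ReferenceMap` holds per-chromosome anchor points ``(pos_bp, pos_cm)``
from any sex-averaged genetic map.  Marker cM positions are obtained by
piecewise-linear interpolation between the bracketing anchors; beyond the map
ends the line through the two outermost anchors is extended and floored at
0 cM so the result stays monotone and non-negative.

A table of sex-averaged autosome genetic lengths (~3,455 cM in total) is
bundled and serves as the default ``L_autosome`` and as default chromosome
lengths for the segment simulator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

from .core import AUTOSOMES


@lru_cache(maxsize=1)
def default_autosome_lengths_cm() -> dict[int, float]:
    """Bundled sex-averaged genetic length (cM) of each autosome."""
    ref = importlib.resources.files("qhmap").joinpath("data/autosome_lengths.yaml")
    data = yaml.safe_load(ref.read_text())
    return {int(k): float(v) for k, v in data["autosome_lengths_cm"].items()}


@dataclass
class ReferenceMap:
    """Per-chromosome anchors for bp -> cM interpolation.

    Parameters
    ----------
    anchors
        Mapping chromosome -> array of shape (n, 2) with columns
        ``(pos_bp, pos_cm)``, strictly increasing in both columns.
    chrom_length_cm
        Genetic length of each chromosome; defaults to the last anchor's cM.
    """

    anchors: dict[int, np.ndarray]
    chrom_length_cm: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.anchors.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"chr{chrom}: need >= 2 (bp, cM) anchors")
            if not (np.all(np.diff(arr[:, 0]) > 0) and np.all(np.diff(arr[:, 1]) > 0)):
                raise ValueError(f"chr{chrom}: anchors must strictly increase in bp and cM")
            self.anchors[chrom] = arr
            length = self.chrom_length_cm.get(chrom, float(arr[-1, 1]))
            if length < arr[-1, 1]:
                raise ValueError(f"chr{chrom}: chrom_length_cm below last anchor")
            self.chrom_length_cm[chrom] = float(length)

    @classmethod
    def from_lengths(cls, lengths_cm: dict[int, float], bp_per_cm: float = 1e6) -> "ReferenceMap":
        """A toy uniform-rate map: 1 cM per ``bp_per_cm`` bases on each chromosome."""
        anchors = {
            c: np.array([[1.0, 0.0], [length * bp_per_cm, length]])
            for c, length in lengths_cm.items()
        }
        return cls(anchors, dict(lengths_cm))

    @classmethod
    def default(cls) -> "ReferenceMap":
        return cls.from_lengths(default_autosome_lengths_cm())

    @classmethod
    def from_tsv(cls, path) -> "ReferenceMap":
        """Read a reference map TSV with columns chrom, pos_bp, pos_cm."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "pos_bp", "pos_cm"}
        if not required.issubset(df.columns):
            raise ValueError(f"reference map must have columns {sorted(required)}")
        anchors = {}
        for chrom_str, grp in df.groupby("chrom", sort=False):
            chrom_norm = str(chrom_str).removeprefix("chr")
            if not chrom_norm.isdigit() or int(chrom_norm) not in AUTOSOMES:
                continue
            grp = grp.sort_values("pos_bp")
            anchors[int(chrom_norm)] = grp[["pos_bp", "pos_cm"]].to_numpy(float)
        return cls(anchors)


def interpolate_cm(ref: ReferenceMap, chrom: int, pos_bp) -> np.ndarray | float:
    """Interpolate genetic position(s) in cM for physical position(s) on ``chrom``.

    Linear between anchors, linear extrapolation from the two outermost
    anchors beyond the map ends, floored at 0 cM.
    """
    if chrom not in ref.anchors:
        raise KeyError(f"chromosome {chrom} not present in reference map")
    arr = ref.anchors[chrom]
    bp, cm = arr[:, 0], arr[:, 1]
    pos = np.asarray(pos_bp, dtype=np.float64)
    out = np.interp(pos, bp, cm)
    lo_slope = (cm[1] - cm[0]) / (bp[1] - bp[0])
    hi_slope = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
    out = np.where(pos < bp[0], cm[0] + (pos - bp[0]) * lo_slope, out)
    out = np.where(pos > bp[-1], cm[-1] + (pos - bp[-1]) * hi_slope, out)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(pos_bp) else out


def total_autosome_cm(ref: ReferenceMap) -> float:
    """Total genetic length L_autosome (cM) summed over autosomes 1-22."""
    missing = [c for c in AUTOSOMES if c not in ref.chrom_length_cm]
    if missing:
        raise ValueError(f"reference map is missing autosomes: {missing}")
    return float(sum(ref.chrom_length_cm[c] for c in AUTOSOMES))
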