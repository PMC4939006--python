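"""Mapping epigenomic peak tracks onto network fragments.

Peak calls (BED intervals) are binarized over fixed genome windows (200 bp by
default, tiling each chromosome from position 0).  The value of a feature on
a fragment is the fraction of windows overlapping the fragment that are
called, so every value lies in [0, 1].  Collecting one column per feature
over the network's fragments yields the fragment-by-feature matrix; the
abundance of a feature is the mean of its column over the fragments of the
network under consideration.

The feature matrix is a plain :class:`pandas.DataFrame` (rows indexed by
fragment_id, one column per feature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ContactNetwork, GenomicFragment

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 200

#: The fragment-by-feature matrix type: rows fragments, columns features.
FeatureMatrix = pd.DataFrame


@dataclass
class FeatureTrack:
    """One epigenomic feature, as raw peak intervals or binarized windows.

    ``peaks`` is a DataFrame with columns chrom/start/end (0-based
    half-open).  After binarization ``windows`` maps each chromosome to the
    sorted array of called window indices at ``window_size`` bp.
    """

    name: str
    peaks: pd.DataFrame | None = None
    windows: dict[str, np.ndarray] | None = None
    window_size: int | None = None

    @property
    def is_binarized(self) -> bool:
        return self.windows is not None

    def __post_init__(self) -> None:
        if self.peaks is not None:
            bad = self.peaks[self.peaks["start"] >= self.peaks["end"]]
            if len(bad):
                row = bad.iloc[0]
                raise ValueError(
                    f"track {self.name}: malformed peak "
                    f"{row['chrom']}:{row['start']}-{row['end']}"
                )


def read_peaks_bed(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a BED3+ peak file; the feature name defaults to the file stem."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        fields = stripped.split("\t")
        if len(fields) == 1:
            fields = stripped.split()
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2])))
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from None
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return FeatureTrack(name=name or path.stem, peaks=peaks)


def read_manifest(path: str | Path) -> list[FeatureTrack]:
    """Read a two-column manifest (feature name, BED path) of peak tracks.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    tracks = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 'name<TAB>path'")
        bed = Path(parts[1])
        if not bed.is_absolute():
            bed = path.parent / bed
        tracks.append(read_peaks_bed(bed, name=parts[0]))
    return tracks


def binarize_peaks(
    track: FeatureTrack,
    window_size: int = DEFAULT_WINDOW,
    sizes: Mapping[str, int] | None = None,
) -> FeatureTrack:
    """Binarize raw peaks over fixed windows tiling each chromosome from 0.

    A window is called (1) iff it overlaps any peak by at least one bp.
    Already-binarized tracks are returned unchanged if the window size
    matches.
    """
    if track.is_binarized:
        if track.window_size != window_size:
            raise ValueError(
                f"track {track.name} already binarized at {track.window_size} bp"
            )
        return track
    if track.peaks is None:
        raise ValueError(f"track {track.name} has neither peaks nor windows")
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows: dict[str, set[int]] = {}
    for row in track.peaks.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        if sizes is not None and chrom not in sizes:
            raise ValueError(
                f"track {track.name}: peak on chromosome {chrom} absent from "
                f"sizes table"
            )
        first = start // window_size
        last = (end - 1) // window_size  # end is exclusive
        windows.setdefault(chrom, set()).update(range(first, last + 1))
    arrays = {c: np.array(sorted(w), dtype=np.int64) for c, w in windows.items()}
    return FeatureTrack(name=track.name, windows=arrays, window_size=window_size)


def fragment_value(fragment: GenomicFragment, track: FeatureTrack) -> float:
    """Fraction of the fragment's overlapping windows that are called.

    The denominator counts windows overlapping the fragment (any-overlap
    rule), not fragment length in bp; fragments shorter than one window use
    the single window they fall in.
    """
    if not track.is_binarized:
        raise ValueError(f"track {track.name} must be binarized first")
    ws = track.window_size
    assert ws is not None
    first = fragment.start // ws
    last = (fragment.end - 1) // ws
    n_windows = last - first + 1
    called = track.windows.get(fragment.chrom)
    if called is None or len(called) == 0:
        return 0.0
    lo = np.searchsorted(called, first, side="left")
    hi = np.searchsorted(called, last, side="right")
    return float(hi - lo) / n_windows


def build_matrix(
    net: ContactNetwork,
    tracks: Sequence[FeatureTrack],
    window_size: int = DEFAULT_WINDOW,
    sizes: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Fragment-by-feature matrix over exactly the network's fragments.

    Column order follows the input track order; duplicate feature names are
    an error.  Raw tracks are binarized at ``window_size``.
    """
    names = [t.name for t in tracks]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate feature names: {sorted(dupes)}")
    fragments = net.fragments
    if sizes is not None:
        for f in fragments.values():
            if f.chrom not in sizes:
                raise ValueError(
                    f"fragment {f.fragment_id} on chromosome {f.chrom} absent "
                    f"from sizes table"
                )
    data = {}
    for track in tracks:
        bin_track = binarize_peaks(track, window_size=window_size, sizes=sizes)
        data[track.name] = [
            fragment_value(f, bin_track) for f in fragments.values()
        ]
    return pd.DataFrame(data, index=list(fragments), columns=names)


def abundance(
    matrix: FeatureMatrix, node_subset: Iterable[str] | None = None
) -> pd.Series:
    """Per-feature mean value over the (sub)set of fragments."""
    if node_subset is not None:
        subset = list(node_subset)
        if not subset:
            raise ValueError("empty node subset")
        missing = set(subset) - set(matrix.index)
        if missing:
            raise KeyError(f"fragments not in matrix: {sorted(missing)[:5]}")
        matrix = matrix.loc[subset]
    return matrix.mean(axis=0)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.rename_axis("fragment_id").to_csv(path, sep="\t")
    return path


def read_matrix(path: str | Path) -> FeatureMatrix:
    return pd.read_csv(path, sep="\t", index_col="fragment_id")
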