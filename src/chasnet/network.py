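"""Typed chromatin contact networks.

A contact network has restriction/capture fragments as nodes and significant
3D interactions as edges.  Nodes carry a class (``promoter`` bait vs
``other_end``), edges carry a class (P-P, P-O, O-O), an optional interaction
score, and the linear genomic distance between fragment midpoints for
intra-chromosomal (cis) contacts.

Interaction lists are read from BEDPE-style pair files or from a
CHiCAGO-like bait/other-end table; the network itself is an undirected
simple :class:`networkx.Graph` wrapped with fragment-aware accessors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PROMOTER = "promoter"
OTHER_END = "other_end"
NODE_CLASSES = (PROMOTER, OTHER_END)
EDGE_CLASSES = ("PP", "PO", "OO")


@dataclass(frozen=True)
class GenomicFragment:
    """A restriction/capture fragment: one node of the contact network.

    Coordinates are 0-based half-open (BED convention).  ``node_class`` is
    ``promoter`` for captured bait fragments and ``other_end`` otherwise.
    """

    chrom: str
    start: int
    end: int
    fragment_id: str
    node_class: str = OTHER_END

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"fragment {self.fragment_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.node_class not in NODE_CLASSES:
            raise ValueError(
                f"fragment {self.fragment_id}: unknown node_class "
                f"{self.node_class!r}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def edge_class_of(class_u: str, class_v: str) -> str:
    """Edge class implied by the endpoint node classes."""
    n_prom = (class_u == PROMOTER) + (class_v == PROMOTER)
    return {2: "PP", 1: "PO", 0: "OO"}[n_prom]


def coords_id(chrom: str, start: int, end: int) -> str:
    """Canonical fragment identifier derived from coordinates."""
    return f"{chrom}:{start}-{end}"


class ContactNetwork:
    """Undirected simple graph over genomic fragments.

    Thin wrapper around :class:`networkx.Graph`; node attributes hold the
    :class:`GenomicFragment`, edge attributes hold ``score``, ``edge_class``,
    ``distance`` (bp between fragment midpoints, NaN for trans contacts) and
    ``trans``.
    """

    def __init__(self, provenance: str = "") -> None:
        self._g = nx.Graph()
        self.provenance = provenance

    # -- construction -----------------------------------------------------

    def add_fragment(self, frag: GenomicFragment) -> None:
        """Add a node.  Re-adding the same id with identical coordinates is
        allowed; the promoter class wins over other_end (a bait seen as an
        other end on some row is still a promoter)."""
        if frag.fragment_id in self._g:
            old: GenomicFragment = self._g.nodes[frag.fragment_id]["fragment"]
            if (old.chrom, old.start, old.end) != (frag.chrom, frag.start, frag.end):
                raise ValueError(
                    f"fragment id {frag.fragment_id} re-used with different "
                    f"coordinates"
                )
            if old.node_class != frag.node_class:
                merged = GenomicFragment(
                    frag.chrom, frag.start, frag.end, frag.fragment_id, PROMOTER
                )
                self._g.nodes[frag.fragment_id]["fragment"] = merged
            return
        self._g.add_node(frag.fragment_id, fragment=frag)

    def add_edge(self, u: str, v: str, score: float = math.nan) -> bool:
        """Add an undirected edge between existing fragments.

        Self-loops are rejected with a warning.  A duplicate unordered pair
        keeps the maximum score.  Returns True if a new edge was created.
        """
        if u == v:
            log.warning("self-interaction on fragment %s dropped", u)
            return False
        for fid in (u, v):
            if fid not in self._g:
                raise KeyError(f"unknown fragment {fid}")
        if self._g.has_edge(u, v):
            old = self._g.edges[u, v]["score"]
            if not math.isnan(score) and (math.isnan(old) or score > old):
                self._g.edges[u, v]["score"] = score
            return False
        fu = self.fragment(u)
        fv = self.fragment(v)
        cis = fu.chrom == fv.chrom
        dist = abs(fu.midpoint - fv.midpoint) if cis else math.nan
        self._g.add_edge(
            u,
            v,
            score=score,
            edge_class=edge_class_of(fu.node_class, fv.node_class),
            distance=dist,
            trans=not cis,
        )
        return True

    def refresh_edge_classes(self) -> None:
        """Recompute edge classes from current endpoint node classes."""
        for u, v, data in self._g.edges(data=True):
            data["edge_class"] = edge_class_of(
                self.fragment(u).node_class, self.fragment(v).node_class
            )

    def copy(self) -> "ContactNetwork":
        out = ContactNetwork(self.provenance)
        out._g = self._g.copy()
        return out

    # -- accessors --------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    def fragment(self, fragment_id: str) -> GenomicFragment:
        try:
            return self._g.nodes[fragment_id]["fragment"]
        except KeyError:
            raise KeyError(f"unknown fragment {fragment_id}") from None

    @property
    def fragment_ids(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def fragments(self) -> dict[str, GenomicFragment]:
        return {fid: self.fragment(fid) for fid in self.fragment_ids}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def mean_degree(self) -> float:
        if self.n_nodes == 0:
            return math.nan
        return 2.0 * self.n_edges / self.n_nodes

    def neighbors(self, fragment_id: str) -> list[str]:
        return sorted(self._g.neighbors(fragment_id))

    def edges(self) -> list[tuple[str, str]]:
        """Edge list with each unordered pair reported as (min, max) id."""
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "fragment_id": fid,
                "chrom": f.chrom,
                "start": f.start,
                "end": f.end,
                "node_class": f.node_class,
                "degree": self._g.degree[fid],
            }
            for fid, f in self.fragments.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["fragment_id", "chrom", "start", "end", "node_class", "degree"],
        )

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v in self.edges():
            d = self._g.edges[u, v]
            rows.append(
                {
                    "u": u,
                    "v": v,
                    "edge_class": d["edge_class"],
                    "score": d["score"],
                    "distance": d["distance"],
                    "trans": d["trans"],
                }
            )
        return pd.DataFrame(
            rows, columns=["u", "v", "edge_class", "score", "distance", "trans"]
        )

    # -- persistence ------------------------------------------------------

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        nodes_path = prefix.with_name(prefix.name + ".nodes.tsv")
        edges_path = prefix.with_name(prefix.name + ".edges.tsv")
        self.node_table().to_csv(nodes_path, sep="\t", index=False)
        self.edge_table().to_csv(edges_path, sep="\t", index=False)
        return nodes_path, edges_path

    @classmethod
    def read(cls, prefix: str | Path, provenance: str = "") -> "ContactNetwork":
        prefix = Path(prefix)
        nodes = pd.read_csv(prefix.with_name(prefix.name + ".nodes.tsv"), sep="\t")
        edges = pd.read_csv(prefix.with_name(prefix.name + ".edges.tsv"), sep="\t")
        net = cls(provenance or f"read from {prefix}")
        for row in nodes.itertuples(index=False):
            net.add_fragment(
                GenomicFragment(
                    str(row.chrom), int(row.start), int(row.end),
                    str(row.fragment_id), str(row.node_class),
                )
            )
        for row in edges.itertuples(index=False):
            net.add_edge(str(row.u), str(row.v), float(row.score))
        return net


# -- pair-file parsing ----------------------------------------------------


def read_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-sizes table."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 'chrom size'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def _parse_coord(fields: Sequence[str], i: int, lineno: int, one_based: bool) -> tuple[str, int, int]:
    chrom = fields[i]
    try:
        start = int(fields[i + 1])
        end = int(fields[i + 2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinate: {exc}") from None
    if one_based:
        start -= 1
    if start < 0 or start >= end:
        raise ValueError(
            f"line {lineno}: invalid interval {chrom}:{start}-{end} "
            f"(need 0 <= start < end)"
        )
    return chrom, start, end


def _check_chrom(chrom: str, end: int, sizes: Mapping[str, int] | None, lineno: int) -> None:
    if sizes is None:
        return
    if chrom not in sizes:
        raise ValueError(f"line {lineno}: chromosome {chrom} absent from sizes table")
    if end > sizes[chrom]:
        raise ValueError(
            f"line {lineno}: interval end {end} exceeds {chrom} size {sizes[chrom]}"
        )


def read_interactions(
    path: str | Path,
    fmt: str = "bedpe",
    score_threshold: float = 5.0,
    bait_ids: Iterable[str] | None = None,
    sizes: Mapping[str, int] | None = None,
) -> ContactNetwork:
    """Parse a pair file into a typed :class:`ContactNetwork`.

    Parameters
    ----------
    path
        Tab-delimited pair table.  ``fmt="bedpe"`` expects
        ``chrom1 start1 end1 chrom2 start2 end2 [name] [score] [strand1
        strand2] [bait1 bait2]`` with 0-based half-open coordinates;
        ``fmt="chicago"`` expects ``baitChr baitStart baitEnd baitID oeChr
        oeStart oeEnd oeID score`` with 1-based inclusive coordinates
        (converted on read).
    score_threshold
        Keep rows with score >= threshold (default 5, the CHiCAGO
        significance cutoff).  A file without a score column passes any
        threshold <= 0; a positive threshold then raises.
    bait_ids
        Fragment ids to class as promoter baits.  When given, overrides any
        per-row bait flags.
    sizes
        Optional chromosome-sizes mapping used to validate coordinates.

    Rows below threshold are dropped, duplicate unordered pairs are collapsed
    keeping the maximum score, and self-pairs are dropped with a warning.
    """
    if fmt not in ("bedpe", "chicago"):
        raise ValueError(f"unknown format {fmt!r}")
    bait_set = set(bait_ids) if bait_ids is not None else None

    rows: list[tuple[GenomicFragment, GenomicFragment, float, bool, bool]] = []
    has_score = True
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        fields = stripped.split("\t")
        if len(fields) == 1:
            fields = stripped.split()
        if fmt == "bedpe":
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BEDPE needs >= 6 columns, got "
                    f"{len(fields)}"
                )
            c1, s1, e1 = _parse_coord(fields, 0, lineno, one_based=False)
            c2, s2, e2 = _parse_coord(fields, 3, lineno, one_based=False)
            score = math.nan
            if len(fields) >= 8 and fields[7] not in (".", ""):
                try:
                    score = float(fields[7])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric score {fields[7]!r}"
                    ) from None
            bait1 = len(fields) >= 12 and fields[10] == "1"
            bait2 = len(fields) >= 12 and fields[11] == "1"
            id1, id2 = coords_id(c1, s1, e1), coords_id(c2, s2, e2)
        else:  # chicago
            if len(fields) < 9:
                if lineno == 1:
                    continue  # header row
                raise ValueError(
                    f"{path}: line {lineno}: CHiCAGO table needs >= 9 columns"
                )
            try:
                c1, s1, e1 = _parse_coord(fields, 0, lineno, one_based=True)
                c2, s2, e2 = _parse_coord(fields, 4, lineno, one_based=True)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise
            try:
                score = float(fields[8])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score {fields[8]!r}"
                ) from None
            id1, id2 = fields[3], fields[7]
            bait1, bait2 = True, False
        _check_chrom(c1, e1, sizes, lineno)
        _check_chrom(c2, e2, sizes, lineno)
        if math.isnan(score):
            has_score = False
        f1 = GenomicFragment(c1, s1, e1, id1, OTHER_END)
        f2 = GenomicFragment(c2, s2, e2, id2, OTHER_END)
        rows.append((f1, f2, score, bait1, bait2))

    if not has_score and score_threshold > 0:
        raise ValueError(
            f"{path}: score_threshold={score_threshold} but the file has rows "
            f"without a score column"
        )

    # promoter iff bait on any row, or listed in bait_ids (which overrides)
    promoters: set[str] = set()
    if bait_set is None:
        for f1, f2, _, b1, b2 in rows:
            if b1:
                promoters.add(f1.fragment_id)
            if b2:
                promoters.add(f2.fragment_id)
    else:
        promoters = bait_set

    net = ContactNetwork(
        provenance=f"read_interactions({Path(path).name}, fmt={fmt}, "
        f"score>={score_threshold})"
    )
    n_dropped = 0
    for f1, f2, score, _, _ in rows:
        if not math.isnan(score) and score < score_threshold:
            n_dropped += 1
            continue
        for f in (f1, f2):
            cls = PROMOTER if f.fragment_id in promoters else OTHER_END
            net.add_fragment(
                GenomicFragment(f.chrom, f.start, f.end, f.fragment_id, cls)
            )
        net.add_edge(f1.fragment_id, f2.fragment_id, score)
    log.info(
        "read %d rows from %s: %d below threshold, %d nodes, %d edges",
        len(rows), path, n_dropped, net.n_nodes, net.n_edges,
    )
    return net


# -- subnetwork extraction ------------------------------------------------


def subnetwork(
    net: ContactNetwork,
    edge_classes: Iterable[str] | None = None,
    min_distance: float | None = None,
    cis_only: bool = False,
) -> ContactNetwork:
    """Edge-filtered subnetwork; nodes left without edges are dropped.

    ``edge_classes`` restricts to the given classes (subset of PP/PO/OO),
    ``min_distance`` keeps cis edges spanning at least that many bp, and
    ``cis_only`` drops inter-chromosomal (trans) edges.
    """
    wanted = set(edge_classes) if edge_classes is not None else None
    if wanted is not None and not wanted <= set(EDGE_CLASSES):
        raise ValueError(f"edge_classes must be a subset of {EDGE_CLASSES}")
    out = ContactNetwork(
        provenance=f"{net.provenance} | subnetwork(classes={sorted(wanted) if wanted else 'all'}, "
        f"min_distance={min_distance}, cis_only={cis_only})"
    )
    kept = []
    for u, v in net.edges():
        d = net.graph.edges[u, v]
        if wanted is not None and d["edge_class"] not in wanted:
            continue
        if cis_only and d["trans"]:
            continue
        if min_distance is not None:
            if d["trans"] or d["distance"] < min_distance:
                continue
        kept.append((u, v, d["score"]))
    for u, v, score in kept:
        out.add_fragment(net.fragment(u))
        out.add_fragment(net.fragment(v))
        out.add_edge(u, v, score)
    if out.n_edges == 0:
        log.warning("subnetwork filter left no edges (%s)", out.provenance)
    return out


def connected_components(net: ContactNetwork) -> list[set[str]]:
    """Connected components, largest first (ties: smallest fragment_id)."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def largest_component(net: ContactNetwork) -> ContactNetwork:
    """Subnetwork induced by the largest connected component."""
    comps = connected_components(net)
    out = ContactNetwork(provenance=f"{net.provenance} | LCC")
    if not comps:
        return out
    lcc = comps[0]
    for fid in lcc:
        out.add_fragment(net.fragment(fid))
    for u, v in net.edges():
        if u in lcc and v in lcc:
            out.add_edge(u, v, net.graph.edges[u, v]["score"])
    return out


def virtual_4c(net: ContactNetwork, anchor: str) -> ContactNetwork:
    """Star subnetwork of one anchor fragment and its direct neighbors.

    The virtual-4C view of genome-wide data: all contacts centered on a
    single locus (e.g. one promoter bait).
    """
    net.fragment(anchor)  # raises KeyError on unknown anchor
    out = ContactNetwork(provenance=f"{net.provenance} | virtual_4c({anchor})")
    out.add_fragment(net.fragment(anchor))
    for nb in net.neighbors(anchor):
        out.add_fragment(net.fragment(nb))
        out.add_edge(anchor, nb, net.graph.edges[anchor, nb]["score"])
    return out
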