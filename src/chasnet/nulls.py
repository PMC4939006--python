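"""Significance and robustness machinery for ChAs.

Four complementary procedures:

* label shuffling — permute feature values over nodes, keeping topology,
  which preserves abundance exactly and yields empirical p values;
* distance-preserving redraw — relocate each other-end fragment to a random
  same-length region of its chromosome at the original bait distance and
  re-score it from the peak tracks, preserving topology and the features'
  distance-to-bait profile;
* partial degree-preserving rewiring (double-edge swaps);
* random / targeted edge removal, probing robustness to missing contacts.

Empirical p values use the add-one rule p = (k + 1) / (n + 1), which never
returns zero.  Every procedure is reproducible bit-for-bit from a single
root seed; per-replicate generators are spawned deterministically by
replicate index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .assortativity import chas, symmetrized_pearson
from .features import FeatureMatrix, FeatureTrack, fragment_value
from .network import OTHER_END, PROMOTER, ContactNetwork, GenomicFragment

log = logging.getLogger(__name__)


@dataclass
class NullEnsemble:
    """Replicate ChAs values under one named null model."""

    feature_name: str
    null_model: str
    replicate_values: np.ndarray
    observed: float
    seed: int
    n_reps: int

    def __post_init__(self) -> None:
        self.replicate_values = np.asarray(self.replicate_values, dtype=float)
        if len(self.replicate_values) != self.n_reps:
            raise ValueError("replicate_values length must equal n_reps")

    def p_value(self, alternative: str = "greater") -> float:
        return empirical_p(self.observed, self, alternative=alternative)


def empirical_p(
    observed: float,
    ensemble: NullEnsemble | Sequence[float] | np.ndarray,
    alternative: str = "greater",
) -> float:
    """Add-one empirical p value: (#{at least as extreme} + 1) / (n + 1).

    Undefined replicates (NaN) are excluded from n; an undefined observed
    value gives a missing (NaN) p.  ``two_sided`` doubles the smaller
    one-sided p, capped at 1.
    """
    reps = (
        ensemble.replicate_values
        if isinstance(ensemble, NullEnsemble)
        else np.asarray(ensemble, dtype=float)
    )
    reps = reps[~np.isnan(reps)]
    if math.isnan(observed) or len(reps) == 0:
        return float("nan")
    n = len(reps)
    p_greater = (np.sum(reps >= observed) + 1) / (n + 1)
    p_less = (np.sum(reps <= observed) + 1) / (n + 1)
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown alternative {alternative!r}")


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


def _edge_index_arrays(
    net: ContactNetwork, order: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    pos = {fid: i for i, fid in enumerate(order)}
    iu = np.empty(net.n_edges, dtype=np.int64)
    iv = np.empty(net.n_edges, dtype=np.int64)
    for k, (u, v) in enumerate(net.edges()):
        iu[k] = pos[u]
        iv[k] = pos[v]
    return iu, iv


def label_shuffle_null(
    net: ContactNetwork,
    matrix: FeatureMatrix,
    feature: str,
    n_reps: int = 100,
    seed: int = 0,
) -> NullEnsemble:
    """Shuffle the assignment of feature values between network nodes.

    Each replicate permutes the feature column over all nodes uniformly at
    random and recomputes ChAs; topology and the value multiset (hence
    abundance) are untouched.  Default 100 replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    nodes = net.fragment_ids
    vals = matrix.loc[nodes, feature].to_numpy(dtype=float)
    iu, iv = _edge_index_arrays(net, nodes)
    observed = chas(net, matrix.loc[nodes, feature], warn=False)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        rng = _replicate_rng(seed, r)
        perm = rng.permutation(vals)
        reps[r] = symmetrized_pearson(perm[iu], perm[iv])
    return NullEnsemble(
        feature_name=feature,
        null_model="label_shuffle",
        replicate_values=reps,
        observed=observed,
        seed=seed,
        n_reps=n_reps,
    )


def rewire(
    net: ContactNetwork, fraction: float, seed: int = 0
) -> ContactNetwork:
    """Partial degree-preserving rewiring by double-edge swaps.

    Performs swaps until ``fraction * |E|`` edges have been exchanged (each
    accepted swap exchanges two edges).  The degree sequence is preserved
    exactly and no self-loops or multi-edges are introduced.  Edge classes
    are recomputed from endpoint classes; swapped-in edges carry no score.
    If the graph is too small or rigid to achieve the requested fraction
    within the attempt budget, the best effort is returned and the achieved
    fraction logged.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    out = net.copy()
    out.provenance = f"{net.provenance} | rewire(fraction={fraction}, seed={seed})"
    m = net.n_edges
    nswap = int(round(fraction * m / 2.0))
    if nswap == 0:
        return out
    g = out.graph
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap + 100, seed=seed)
    except nx.NetworkXAlgorithmError as exc:
        log.warning("rewire: attempt budget exhausted (%s); best effort kept", exc)
    except nx.NetworkXError as exc:
        log.warning("rewire: graph too small to swap (%s); returned unchanged", exc)
    # swapped-in edges lack attributes; restore the full attribute schema
    original = {tuple(sorted(e)): d for *e, d in net.graph.edges(data=True)}
    achieved = sum(1 for e in g.edges if tuple(sorted(e)) not in original)
    for u, v, d in g.edges(data=True):
        key = tuple(sorted((u, v)))
        if key in original:
            d.update(original[key])
        else:
            fu, fv = out.fragment(u), out.fragment(v)
            cis = fu.chrom == fv.chrom
            d["score"] = math.nan
            d["distance"] = abs(fu.midpoint - fv.midpoint) if cis else math.nan
            d["trans"] = not cis
    out.refresh_edge_classes()
    log.info("rewire: %d/%d edges exchanged (requested %d)", achieved, m, 2 * nswap)
    return out


def edge_removal_robustness(
    net: ContactNetwork,
    matrix: FeatureMatrix,
    fractions: Sequence[float],
    n_reps: int = 20,
    seed: int = 0,
    targeted: bool = False,
) -> pd.DataFrame:
    """ChAs stability under edge removal.

    For each fraction, drop that share of edges — uniformly at random
    (``n_reps`` replicates), or in ``targeted`` mode deterministically in
    decreasing order of the mean endpoint feature value — and recompute ChAs
    per feature.  Returns a tidy table with mean and standard deviation of
    ChAs over replicates plus the full-network observed value.
    """
    for f in fractions:
        if not (0 <= f < 1):
            raise ValueError("fractions must lie in [0, 1)")
    nodes = net.fragment_ids
    iu, iv = _edge_index_arrays(net, nodes)
    m = net.n_edges
    cols = {feat: matrix.loc[nodes, feat].to_numpy(dtype=float) for feat in matrix.columns}
    rows = []
    for feat, vals in cols.items():
        observed = symmetrized_pearson(vals[iu], vals[iv])
        for frac in fractions:
            n_drop = int(round(frac * m))
            if targeted:
                endpoint_mean = 0.5 * (vals[iu] + vals[iv])
                keep = np.argsort(-endpoint_mean, kind="stable")[n_drop:]
                reps = [symmetrized_pearson(vals[iu[keep]], vals[iv[keep]])]
            else:
                reps = []
                for r in range(n_reps):
                    rng = _replicate_rng(seed, r)
                    keep = rng.permutation(m)[n_drop:]
                    reps.append(
                        symmetrized_pearson(vals[iu[keep]], vals[iv[keep]])
                    )
            reps = np.asarray(reps, dtype=float)
            rows.append(
                {
                    "feature": feat,
                    "fraction": frac,
                    "mode": "targeted" if targeted else "random",
                    "observed": observed,
                    "mean_chas": float(np.nanmean(reps)),
                    "sd_chas": float(np.nanstd(reps)),
                    "n_reps": len(reps),
                }
            )
    return pd.DataFrame(rows)


def _relocate_fragment(
    frag: GenomicFragment,
    bait: GenomicFragment,
    chrom_size: int,
    rng: np.random.Generator,
) -> GenomicFragment:
    """Random same-length fragment at the original distance from the bait.

    The side (upstream/downstream) is chosen uniformly; if the fragment
    would fall off the chromosome the opposite side is tried, and if both
    fail an error is raised.
    """
    length = frag.length
    dist = abs(frag.midpoint - bait.midpoint)
    sides = [1, -1] if rng.random() < 0.5 else [-1, 1]
    for side in sides:
        mid = bait.midpoint + side * dist
        start = int(round(mid - length / 2.0))
        end = start + length
        if start >= 0 and end <= chrom_size:
            return GenomicFragment(
                frag.chrom, start, end, frag.fragment_id, frag.node_class
            )
    raise ValueError(
        f"cannot place a {length} bp fragment at distance {dist:.0f} from "
        f"bait {bait.fragment_id} on {frag.chrom} (size {chrom_size})"
    )


def distance_preserving_null(
    net: ContactNetwork,
    tracks: Sequence[FeatureTrack],
    sizes: Mapping[str, int],
    n_reps: int = 100,
    seed: int = 0,
    chroms: Iterable[str] | None = None,
) -> dict[str, NullEnsemble]:
    """Relocate other-end fragments at fixed bait distance and re-score.

    Each replicate replaces every other-end fragment (optionally restricted
    to ``chroms``) with a random same-length fragment on the same chromosome
    at the same distance from its anchor bait, recomputes the relocated
    fragments' feature values from the binarized tracks, and recomputes ChAs
    per feature.  Topology is untouched.  The anchor is the smallest-id
    same-chromosome promoter neighbor; other-end fragments without one keep
    their observed value.
    """
    from .features import binarize_peaks

    chrom_set = set(chroms) if chroms is not None else None
    bin_tracks = [binarize_peaks(t) if not t.is_binarized else t for t in tracks]
    nodes = net.fragment_ids
    iu, iv = _edge_index_arrays(net, nodes)

    base = {
        t.name: np.array(
            [fragment_value(net.fragment(fid), t) for fid in nodes], dtype=float
        )
        for t in bin_tracks
    }

    movable: list[tuple[int, GenomicFragment, GenomicFragment]] = []
    for i, fid in enumerate(nodes):
        frag = net.fragment(fid)
        if frag.node_class != OTHER_END:
            continue
        if chrom_set is not None and frag.chrom not in chrom_set:
            continue
        anchors = [
            nb
            for nb in net.neighbors(fid)
            if net.fragment(nb).node_class == PROMOTER
            and net.fragment(nb).chrom == frag.chrom
        ]
        if not anchors:
            continue
        bait = net.fragment(min(anchors))
        if frag.chrom not in sizes:
            raise ValueError(f"chromosome {frag.chrom} absent from sizes table")
        movable.append((i, frag, bait))

    reps: dict[str, np.ndarray] = {t.name: np.empty(n_reps) for t in bin_tracks}
    for r in range(n_reps):
        rng = _replicate_rng(seed, r)
        new_vals = {name: col.copy() for name, col in base.items()}
        for i, frag, bait in movable:
            moved = _relocate_fragment(frag, bait, sizes[frag.chrom], rng)
            for t in bin_tracks:
                new_vals[t.name][i] = fragment_value(moved, t)
        for name, col in new_vals.items():
            reps[name][r] = symmetrized_pearson(col[iu], col[iv])

    return {
        name: NullEnsemble(
            feature_name=name,
            null_model="distance_preserving",
            replicate_values=reps[name],
            observed=symmetrized_pearson(base[name][iu], base[name][iv]),
            seed=seed,
            n_reps=n_reps,
        )
        for name in reps
    }


def null_summary(
    ensembles: Mapping[str, NullEnsemble] | Iterable[NullEnsemble],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Summary table (feature, observed, mean_null, sd_null, p) per ensemble."""
    if isinstance(ensembles, Mapping):
        ensembles = list(ensembles.values())
    rows = []
    for ens in ensembles:
        reps = ens.replicate_values[~np.isnan(ens.replicate_values)]
        rows.append(
            {
                "feature": ens.feature_name,
                "null_model": ens.null_model,
                "observed": ens.observed,
                "mean_null": float(reps.mean()) if len(reps) else float("nan"),
                "sd_null": float(reps.std()) if len(reps) else float("nan"),
                "p": ens.p_value(alternative),
                "n_reps": ens.n_reps,
            }
        )
    return pd.DataFrame(rows)
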