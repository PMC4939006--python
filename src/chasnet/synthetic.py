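"""Synthetic promoter-capture-style fixtures with planted structure.

The generator emulates the shape of a promoter-capture interaction dataset:
two node classes (promoter baits and other ends), a sparse network with mean
degree ~2.5, one large connected component holding ~63 % of nodes plus many
small components, and epigenomic features whose values cluster spatially on
the network.  Scaled down from genome scale to a few thousand fragments so
the whole analysis stack can be exercised without downloads.

Feature planting: each node value mixes a module-level latent signal with
node-level noise, v = clip01(mu0 + sigma * (w*L + sqrt(1-w^2)*eps)),
quantized to multiples of 1/(windows per fragment) so peak BED files can
represent the values exactly.  The mixing weight w is calibrated by
bisection until the realized edge-level correlation matches the requested
assortativity rho (module latents for rho > 0; an alternating two-coloring
of each module's spanning tree for rho < 0).  mu0 is solved per candidate w
so the realized abundance matches the request.  No closed form ties rho to w
under arbitrary topology, hence the search.

Two wiring modes share the feature machinery:

* capture-shaped (default, edge probabilities unset): modules are built from
  random spanning trees plus extra within-module edges; a designated group
  of modules is interconnected into the large component, the rest stay as
  small disconnected components.
* planted-partition (``within_module_edge_prob`` set): classic Bernoulli
  within/between wiring over ``n_modules`` equal blocks, used for community
  -recovery fixtures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix, FeatureTrack
from .network import (
    OTHER_END,
    PROMOTER,
    ContactNetwork,
    GenomicFragment,
    coords_id,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSpec:
    """One feature to plant: name, target edge assortativity, abundance."""

    name: str
    rho: float
    abundance: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"{self.name}: |rho| must be <= 1")
        if not 0.0 < self.abundance < 1.0:
            raise ValueError(f"{self.name}: abundance must be in (0, 1)")


#: Default feature panel (names, assortativities and abundances
#: chosen to resemble a mESC promoter-capture analysis: a rare but highly
#: assortative Polycomb factor, enhancer/promoter histone marks, and an
#: elongating vs non-specific RNA polymerase II pair).
DEFAULT_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("H3K4me1", 0.15, 0.30),
    FeatureSpec("H3K27ac", 0.12, 0.20),
    FeatureSpec("H3K27me3", 0.30, 0.15),
    FeatureSpec("EZH2", 0.34, 0.05),
    FeatureSpec("RNAPII_S2P", 0.23, 0.25),
    FeatureSpec("RNAPII_8WG16", 0.01, 0.25),
)


@dataclass
class GeneratorConfig:
    n_chromosomes: int = 4
    chromosome_length: int = 3_200_000
    n_fragments: int = 4000
    fragment_length: int = 2000
    fragment_gap: int = 1000
    promoter_fraction: float = 0.3
    mean_degree: float = 2.5
    connected_fraction: float = 0.63
    between_edge_fraction: float = 0.06
    module_size: int = 25
    small_component_mean: int = 6
    n_modules: int | None = None
    within_module_edge_prob: float | None = None
    between_module_edge_prob: float | None = None
    overlap_nodes: int = 0
    features: tuple[FeatureSpec, ...] = DEFAULT_FEATURES
    window_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.features = tuple(
            f if isinstance(f, FeatureSpec) else FeatureSpec(*f)
            for f in self.features
        )
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names")
        for p in (self.promoter_fraction, self.connected_fraction,
                  self.between_edge_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for p in (self.within_module_edge_prob, self.between_module_edge_prob):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must lie in [0, 1]")
        if self.fragment_length % self.window_size != 0:
            raise ValueError("fragment_length must be a multiple of window_size")
        if (self.fragment_length + self.fragment_gap) % self.window_size != 0:
            raise ValueError(
                "fragment pitch (length + gap) must be a multiple of "
                "window_size to keep fragments window-aligned"
            )
        capacity = self.n_chromosomes * (
            self.chromosome_length // (self.fragment_length + self.fragment_gap)
        )
        if capacity < self.n_fragments:
            raise ValueError(
                f"genome too small: capacity {capacity} < {self.n_fragments} "
                f"fragments"
            )

    @property
    def windows_per_fragment(self) -> int:
        return self.fragment_length // self.window_size

    @property
    def prob_mode(self) -> bool:
        return self.within_module_edge_prob is not None


@dataclass
class SyntheticDataset:
    """Generated fixture: files on disk plus the in-memory ground truth."""

    config: GeneratorConfig
    outdir: Path
    paths: dict[str, Path]
    network: ContactNetwork
    values: FeatureMatrix
    truth_nodes: pd.DataFrame
    truth_features: pd.DataFrame


# -- wiring ---------------------------------------------------------------


def _place_fragments(cfg: GeneratorConfig) -> list[GenomicFragment]:
    pitch = cfg.fragment_length + cfg.fragment_gap
    per_chrom = cfg.chromosome_length // pitch
    frags = []
    for i in range(cfg.n_fragments):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * pitch
        end = start + cfg.fragment_length
        frags.append(GenomicFragment(chrom, start, end, coords_id(chrom, start, end)))
    return frags


def _random_tree_edges(
    members: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random recursive spanning tree over the member indices."""
    order = rng.permutation(members)
    return [
        (int(order[i]), int(order[rng.integers(0, i)]))
        for i in range(1, len(order))
    ]


def _capture_mode_wiring(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[set[int]], set[tuple[int, int]], list[int], dict[int, int]]:
    """Modules, edges and overlap nodes for the capture-shaped mode.

    Returns (module id per node, module node-sets, edge set, giant module
    ids, overlap node -> secondary module).
    """
    n = cfg.n_fragments
    perm = rng.permutation(n)
    giant_n = int(round(cfg.connected_fraction * n))
    modules: list[np.ndarray] = []
    giant_ids: list[int] = []

    pos = 0
    while pos < giant_n:
        size = min(cfg.module_size, giant_n - pos)
        if giant_n - pos - size == 1:  # avoid a trailing 1-node module
            size += 1
        giant_ids.append(len(modules))
        modules.append(perm[pos : pos + size])
        pos += size
    while pos < n:
        mean = max(2, cfg.small_component_mean)
        size = int(rng.geometric(1.0 / (mean - 1))) + 1
        size = min(size, n - pos)
        if n - pos - size == 1:
            size += 1
        modules.append(perm[pos : pos + size])
        pos += size

    mod_of = np.empty(n, dtype=np.int64)
    for mid, members in enumerate(modules):
        mod_of[members] = mid

    edges: set[tuple[int, int]] = set()

    def add(u: int, v: int) -> bool:
        if u == v:
            return False
        key = (u, v) if u < v else (v, u)
        if key in edges:
            return False
        edges.add(key)
        return True

    for members in modules:
        for u, v in _random_tree_edges(members, rng):
            add(u, v)

    target_m = int(round(cfg.mean_degree * n / 2.0))
    extra = max(0, target_m - len(edges))
    between_target = (
        int(round(cfg.between_edge_fraction * target_m)) if len(giant_ids) > 1 else 0
    )
    between_target = min(between_target, extra)
    within_target = extra - between_target

    sizes = np.array([len(m) for m in modules], dtype=float)
    weights = sizes * (sizes - 1) / 2.0
    weights = np.where(sizes >= 2, weights, 0.0)
    weights /= weights.sum()
    added, attempts = 0, 0
    while added < within_target and attempts < 50 * within_target + 100:
        attempts += 1
        mid = int(rng.choice(len(modules), p=weights))
        u, v = rng.choice(modules[mid], size=2, replace=False)
        if add(int(u), int(v)):
            added += 1

    added, attempts = 0, 0
    while added < between_target and attempts < 50 * between_target + 100:
        attempts += 1
        ma, mb = rng.choice(giant_ids, size=2, replace=False)
        u = int(rng.choice(modules[ma]))
        v = int(rng.choice(modules[mb]))
        if add(u, v):
            added += 1

    overlap: dict[int, int] = {}
    if cfg.overlap_nodes:
        hosts = [m for m in giant_ids if len(modules[m]) >= 4] or giant_ids
        for _ in range(cfg.overlap_nodes):
            ma = int(rng.choice(hosts))
            mb = int(rng.choice([m for m in giant_ids if m != ma]))
            node = int(rng.choice(modules[ma]))
            targets = rng.choice(
                modules[mb], size=min(4, len(modules[mb])), replace=False
            )
            for t in targets:
                add(node, int(t))
            overlap[node] = mb

    return mod_of, [set(map(int, m)) for m in modules], edges, giant_ids, overlap


def _prob_mode_wiring(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[set[int]], set[tuple[int, int]], list[int], dict[int, int]]:
    """Planted-partition wiring over ``n_modules`` equal blocks."""
    n = cfg.n_fragments
    k = cfg.n_modules or 4
    p_in = cfg.within_module_edge_prob or 0.0
    p_out = cfg.between_module_edge_prob or 0.0
    perm = rng.permutation(n)
    modules = [perm[i::k] for i in range(k)]
    mod_of = np.empty(n, dtype=np.int64)
    for mid, members in enumerate(modules):
        mod_of[members] = mid
    edges: set[tuple[int, int]] = set()
    nodes = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if mod_of[i] == mod_of[j] else p_out
            if p > 0 and rng.random() < p:
                edges.add((int(nodes[i]), int(nodes[j])))
    overlap: dict[int, int] = {}
    for _ in range(cfg.overlap_nodes):
        ma, mb = rng.choice(k, size=2, replace=False)
        node = int(rng.choice(modules[ma]))
        # few cross edges: enough for a triangle in the second module, too
        # sparse to percolate the two communities into one
        targets = rng.choice(modules[mb], size=min(4, len(modules[mb])), replace=False)
        for t in targets:
            t = int(t)
            if node != t:
                edges.add((node, t) if node < t else (t, node))
        overlap[node] = int(mb)
    return mod_of, [set(map(int, m)) for m in modules], edges, list(range(k)), overlap


# -- feature planting -----------------------------------------------------


def _edge_pearson(vals: np.ndarray, iu: np.ndarray, iv: np.ndarray) -> float:
    """Symmetrized edge-list Pearson used for calibration only."""
    a = np.concatenate([vals[iu], vals[iv]])
    b = np.concatenate([vals[iv], vals[iu]])
    if len(a) == 0 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (a.std() * b.std()))


def _tree_two_coloring(
    modules: list[set[int]], edges: set[tuple[int, int]], n: int
) -> np.ndarray:
    """Alternating +/-1 coloring over a BFS tree of each module subgraph."""
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for u, v in sorted(edges):
        adj[u].append(v)
        adj[v].append(u)
    sign = np.zeros(n)
    for members in modules:
        member_set = members
        seen: set[int] = set()
        for root in sorted(member_set):
            if root in seen:
                continue
            sign[root] = 1.0
            seen.add(root)
            frontier = [root]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v in member_set and v not in seen:
                            sign[v] = -sign[u]
                            seen.add(v)
                            nxt.append(v)
                frontier = nxt
    return sign


def _quantized_values(
    mu0: float, sigma: float, w: float, latent: np.ndarray,
    noise: np.ndarray, n_windows: int,
) -> np.ndarray:
    raw = mu0 + sigma * (w * latent + math.sqrt(max(0.0, 1 - w * w)) * noise)
    return np.round(np.clip(raw, 0.0, 1.0) * n_windows) / n_windows


def _solve_mu0(
    target_mean: float, sigma: float, w: float, latent: np.ndarray,
    noise: np.ndarray, n_windows: int,
) -> float:
    lo, hi = -3.0, 4.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        m = _quantized_values(mid, sigma, w, latent, noise, n_windows).mean()
        if m < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _plant_feature(
    spec: FeatureSpec,
    mod_latent: np.ndarray,
    sign_latent: np.ndarray,
    noise: np.ndarray,
    iu: np.ndarray,
    iv: np.ndarray,
    n_windows: int,
) -> tuple[np.ndarray, float, float]:
    """Calibrate w to the target edge correlation; returns (values, w, rho)."""
    sigma = 0.05 + 0.8 * min(spec.abundance, 1 - spec.abundance)
    latent = mod_latent if spec.rho >= 0 else sign_latent

    def realize(w: float) -> tuple[np.ndarray, float]:
        mu0 = _solve_mu0(spec.abundance, sigma, w, latent, noise, n_windows)
        vals = _quantized_values(mu0, sigma, w, latent, noise, n_windows)
        return vals, _edge_pearson(vals, iu, iv)

    if abs(spec.rho) < 0.005:
        vals, r = realize(0.0)
        return vals, 0.0, r

    _, r_max = realize(1.0)
    if np.isnan(r_max) or (spec.rho > 0 and r_max < spec.rho - 0.02) or (
        spec.rho < 0 and r_max > spec.rho + 0.02
    ):
        raise ValueError(
            f"feature {spec.name}: target rho={spec.rho} unreachable on this "
            f"topology (extreme achievable rho at full mixing: {r_max:.3f}); "
            f"use denser modules or a weaker target"
        )
    lo, hi = 0.0, 1.0
    vals, r = realize(1.0)
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        vals, r = realize(mid)
        if np.isnan(r):
            lo = mid
            continue
        toward_extreme = r < spec.rho if spec.rho > 0 else r > spec.rho
        if toward_extreme:
            lo = mid
        else:
            hi = mid
    return vals, 0.5 * (lo + hi), r


# -- generation -----------------------------------------------------------


def generate(
    config: GeneratorConfig, outdir: str | Path
) -> SyntheticDataset:
    """Generate a complete fixture and write its files under ``outdir``.

    Writes fragments BED, chromosome sizes, bait id list, interactions
    BEDPE, one peak BED per feature (plus a manifest), and node/feature
    truth tables.  Re-running with the same config and seed reproduces the
    files byte for byte.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)

    frags = _place_fragments(cfg)
    n = cfg.n_fragments
    n_prom = int(round(cfg.promoter_fraction * n))
    prom_idx = set(map(int, rng.choice(n, size=n_prom, replace=False)))
    frags = [
        replace(f, node_class=PROMOTER if i in prom_idx else OTHER_END)
        for i, f in enumerate(frags)
    ]

    if cfg.prob_mode:
        mod_of, modules, edges, giant_ids, overlap = _prob_mode_wiring(cfg, rng)
    else:
        mod_of, modules, edges, giant_ids, overlap = _capture_mode_wiring(cfg, rng)

    edge_list = sorted(edges)
    scores = np.round(5.0 + 15.0 * rng.random(len(edge_list)), 2)

    net = ContactNetwork(provenance=f"synthetic(seed={cfg.seed})")
    for f in frags:
        net.add_fragment(f)
    for (u, v), s in zip(edge_list, scores):
        net.add_edge(frags[u].fragment_id, frags[v].fragment_id, float(s))

    # index arrays over node order 0..n-1 for calibration
    iu = np.array([e[0] for e in edge_list], dtype=np.int64)
    iv = np.array([e[1] for e in edge_list], dtype=np.int64)
    n_windows = cfg.windows_per_fragment

    mod_latents = rng.standard_normal(len(modules))
    mod_latent = mod_latents[mod_of]
    sign_latent = _tree_two_coloring(modules, edges, n)

    values: dict[str, np.ndarray] = {}
    feat_rows = []
    for spec in cfg.features:
        noise = rng.standard_normal(n)
        vals, w, realized = _plant_feature(
            spec, mod_latent, sign_latent, noise, iu, iv, n_windows
        )
        values[spec.name] = vals
        feat_rows.append(
            {
                "feature": spec.name,
                "target_rho": spec.rho,
                "realized_rho": realized,
                "target_abundance": spec.abundance,
                "realized_abundance": float(vals.mean()),
                "mixing_weight": w,
            }
        )

    ids = [f.fragment_id for f in frags]
    matrix = pd.DataFrame(values, index=ids, columns=[s.name for s in cfg.features])

    # -- write files ------------------------------------------------------
    paths: dict[str, Path] = {}

    sizes_path = outdir / "sizes.tsv"
    with sizes_path.open("w") as fh:
        for c in range(1, cfg.n_chromosomes + 1):
            fh.write(f"chr{c}\t{cfg.chromosome_length}\n")
    paths["sizes"] = sizes_path

    frag_path = outdir / "fragments.bed"
    with frag_path.open("w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.fragment_id}\n")
    paths["fragments"] = frag_path

    baits_path = outdir / "baits.txt"
    with baits_path.open("w") as fh:
        for f in frags:
            if f.node_class == PROMOTER:
                fh.write(f.fragment_id + "\n")
    paths["baits"] = baits_path

    pairs_path = outdir / "interactions.bedpe"
    with pairs_path.open("w") as fh:
        for k, ((u, v), s) in enumerate(zip(edge_list, scores)):
            a, b = frags[u], frags[v]
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\te{k}\t{s:.2f}\n"
            )
    paths["interactions"] = pairs_path

    manifest_path = outdir / "peaks_manifest.tsv"
    with manifest_path.open("w") as mf:
        for spec in cfg.features:
            bed_path = outdir / "peaks" / f"{spec.name}.bed"
            with bed_path.open("w") as fh:
                for f, v in zip(frags, values[spec.name]):
                    k = int(round(v * n_windows))
                    if k > 0:
                        fh.write(
                            f"{f.chrom}\t{f.start}\t{f.start + k * cfg.window_size}\n"
                        )
            mf.write(f"{spec.name}\tpeaks/{spec.name}.bed\n")
            paths[f"peaks:{spec.name}"] = bed_path
    paths["manifest"] = manifest_path

    truth_nodes = pd.DataFrame(
        {
            "fragment_id": ids,
            "module": mod_of,
            "node_class": [f.node_class for f in frags],
            "in_giant_group": [bool(mod_of[i] in set(giant_ids)) for i in range(n)],
            "overlap_module": [overlap.get(i, -1) for i in range(n)],
        }
    )
    for spec in cfg.features:
        truth_nodes[spec.name] = values[spec.name]
    truth_nodes_path = outdir / "truth_nodes.tsv"
    truth_nodes.to_csv(truth_nodes_path, sep="\t", index=False, float_format="%.6g")
    paths["truth_nodes"] = truth_nodes_path

    truth_features = pd.DataFrame(feat_rows)
    truth_features_path = outdir / "truth_features.tsv"
    truth_features.to_csv(
        truth_features_path, sep="\t", index=False, float_format="%.6g"
    )
    paths["truth_features"] = truth_features_path

    log.info(
        "generated %d fragments, %d edges (mean degree %.2f), %d features -> %s",
        n, net.n_edges, net.mean_degree, len(cfg.features), outdir,
    )
    return SyntheticDataset(
        config=cfg,
        outdir=outdir,
        paths=paths,
        network=net,
        values=matrix,
        truth_nodes=truth_nodes,
        truth_features=truth_features,
    )


def perturb(
    values: FeatureMatrix, relabel_fraction: float, seed: int = 0
) -> FeatureMatrix:
    """Randomly reassign a fraction of node values (rows permuted in place).

    Expected ChAs decreases monotonically with the fraction: at 0 the matrix
    is unchanged, at 1 all values are shuffled across nodes and the planted
    edge correlation collapses to ~0.
    """
    if not 0.0 <= relabel_fraction <= 1.0:
        raise ValueError("relabel_fraction must lie in [0, 1]")
    out = values.copy()
    n = len(out)
    k = int(round(relabel_fraction * n))
    if k < 2:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    out.iloc[idx] = out.iloc[rng.permutation(idx)].to_numpy()
    return out
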