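"""Chromatin assortativity (ChAs).

ChAs of a feature on a contact network is the Pearson correlation of the
feature's per-fragment values across all connected fragment pairs.  Each
undirected edge is enumerated in both orientations (symmetrization), which
makes the statistic orientation-independent and equal to the continuous
assortativity coefficient of the underlying graph.  As a correlation, ChAs
lies in [-1, 1]; a feature with zero variance over edge endpoints has no
defined correlation and is reported as NaN (with a warning) rather than 0,
distinguishing "not measurable" from "no relationship".
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .features import FeatureMatrix, abundance
from .network import OTHER_END, PROMOTER, ContactNetwork, subnetwork

log = logging.getLogger(__name__)

ENHANCER_FLAGS = ("active_enhancer", "poised_enhancer", "non_enhancer")


def symmetrized_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of the doubled edge list [(x,y)] + [(y,x)].

    NaN when either concatenated vector has zero variance.  For the doubled
    list both vectors equal (x‖y) up to ordering, so this reduces to
    cov(x,y) (symmetrized) over var(x‖y).
    """
    a = np.concatenate([x, y]).astype(float)
    b = np.concatenate([y, x]).astype(float)
    # exact constancy check: a float std of a constant vector can be a tiny
    # nonzero residue of the mean, which would fabricate a correlation of 1
    if len(a) == 0 or np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    sa = a.std()
    sb = b.std()
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _edge_value_arrays(
    net: ContactNetwork, values: Mapping[str, float] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for u, v in net.edges():
        for fid in (u, v):
            if fid not in values:
                raise KeyError(f"no feature value for fragment {fid}")
        xs.append(values[u])
        ys.append(values[v])
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def chas(
    net: ContactNetwork,
    values: Mapping[str, float] | pd.Series,
    warn: bool = True,
) -> float:
    """ChAs of one feature: symmetrized edge-list Pearson correlation.

    ``values`` must provide a value for every fragment incident to an edge
    (a missing value raises, naming the fragment).  Returns NaN with a
    warning for an edgeless network or a zero-variance feature.
    """
    if net.n_edges == 0:
        if warn:
            warnings.warn("ChAs undefined: network has no edges", stacklevel=2)
        return float("nan")
    x, y = _edge_value_arrays(net, values)
    r = symmetrized_pearson(x, y)
    if np.isnan(r) and warn:
        warnings.warn(
            "ChAs undefined: feature has zero variance over edge endpoints",
            stacklevel=2,
        )
    return r


def chas_all(
    net: ContactNetwork, matrix: FeatureMatrix, label: str = "all"
) -> pd.DataFrame:
    """ChAs table: one row per feature with ChAs, abundance, edge count.

    Abundance is computed over this network's own fragments.  Undefined ChAs
    values propagate as NaN rows, not failures.
    """
    nodes = net.fragment_ids
    missing = set(nodes) - set(matrix.index)
    if missing:
        raise KeyError(
            f"matrix lacks rows for fragments: {sorted(missing)[:5]}"
        )
    sub = matrix.loc[nodes]
    ab = abundance(sub) if nodes else pd.Series(dtype=float)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for feat in matrix.columns:
            rows.append(
                {
                    "feature": feat,
                    "chas": chas(net, sub[feat], warn=False) if nodes else float("nan"),
                    "abundance": float(ab.get(feat, float("nan"))),
                    "n_edges": net.n_edges,
                    "subnetwork": label,
                }
            )
    return pd.DataFrame(
        rows, columns=["feature", "chas", "abundance", "n_edges", "subnetwork"]
    )


def chas_delta(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.Series:
    """Per-feature ChAs difference (a - b) between two ChAs tables.

    The two tables must cover the same feature set; NaN propagates.
    """
    a = table_a.set_index("feature")["chas"]
    b = table_b.set_index("feature")["chas"]
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise ValueError(
            f"feature sets differ: only in a={only_a[:5]}, only in b={only_b[:5]}"
        )
    return (a - b.loc[a.index]).rename("chas_delta")


def compare_subnetworks(
    net: ContactNetwork, matrix: FeatureMatrix
) -> pd.DataFrame:
    """P-P vs P-O comparison table: chas_PP, chas_PO and their difference."""
    pp = chas_all(subnetwork(net, edge_classes={"PP"}), matrix, label="PP")
    po = chas_all(subnetwork(net, edge_classes={"PO"}), matrix, label="PO")
    out = pd.DataFrame(
        {
            "feature": pp["feature"],
            "chas_PP": pp["chas"].values,
            "chas_PO": po.set_index("feature").loc[pp["feature"], "chas"].values,
        }
    )
    out["delta_PO_minus_PP"] = out["chas_PO"] - out["chas_PP"]
    return out


def classify_other_ends(
    matrix: FeatureMatrix,
    other_end_ids: Iterable[str],
    h3k4me1: str = "H3K4me1",
    h3k27ac: str = "H3K27ac",
    h3k27me3: str = "H3K27me3",
) -> pd.DataFrame:
    """Enhancer-class flags for other-end fragments.

    active_enhancer:  H3K4me1 > 0 and H3K27ac > 0
    poised_enhancer:  H3K4me1 > 0 and H3K27me3 > 0
    non_enhancer:     H3K4me1 = 0

    The active and poised flags may co-occur (the definitions are not
    exclusive); non_enhancer excludes both.  Only the listed other-end
    fragments are classified — promoters are never labeled.
    """
    for col in (h3k4me1, h3k27ac, h3k27me3):
        if col not in matrix.columns:
            raise KeyError(f"feature column {col!r} not in matrix")
    ids = sorted(set(other_end_ids))
    missing = set(ids) - set(matrix.index)
    if missing:
        raise KeyError(f"fragments not in matrix: {sorted(missing)[:5]}")
    sub = matrix.loc[ids]
    k4 = sub[h3k4me1] > 0
    flags = pd.DataFrame(
        {
            "active_enhancer": k4 & (sub[h3k27ac] > 0),
            "poised_enhancer": k4 & (sub[h3k27me3] > 0),
            "non_enhancer": ~k4,
        },
        index=ids,
    )
    return flags


def chas_by_class(
    net: ContactNetwork,
    matrix: FeatureMatrix,
    flags: pd.DataFrame,
    class_flag: str,
    label: str | None = None,
) -> pd.DataFrame:
    """ChAs over P-O edges whose other end carries the given class flag.

    ``flags`` is the output of :func:`classify_other_ends`; ``class_flag``
    is one of its boolean columns.  Returns an empty table with a warning
    when no edge qualifies.
    """
    if class_flag not in flags.columns:
        raise KeyError(f"unknown class flag {class_flag!r}")
    tagged = set(flags.index[flags[class_flag]])
    po = subnetwork(net, edge_classes={"PO"})
    restricted = ContactNetwork(
        provenance=f"{net.provenance} | PO edges with O in {class_flag}"
    )
    for u, v in po.edges():
        fu, fv = po.fragment(u), po.fragment(v)
        o_end = u if fu.node_class == OTHER_END else v
        if o_end in tagged:
            restricted.add_fragment(fu)
            restricted.add_fragment(fv)
            restricted.add_edge(u, v, po.graph.edges[u, v]["score"])
    if restricted.n_edges == 0:
        warnings.warn(
            f"no P-O edges with other end classed {class_flag}", stacklevel=2
        )
        return pd.DataFrame(
            columns=["feature", "chas", "abundance", "n_edges", "subnetwork"]
        )
    return chas_all(restricted, matrix, label=label or class_flag)
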