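"""Expression atlas: replicate averaging, calls, PO attribution, co-expression.

Expression calls use platform-specific thresholds: on log2 array intensities a
cell is ``expressed`` above 8 (strict), ``detected`` in [5, 8], ``background``
below 5; on read counts ``expressed`` at >= 10 reads (inclusive), ``detected``
for 1..9, ``background`` at 0.  A gene is a ``gene`` if any cell is expressed,
``putative`` if only detected cells exist, else ``hypothetical``.

Co-expression is two-tier hierarchical clustering on Pearson distance
(d = 1 - r) with average linkage: conditions more similar than 0.05 are first
collapsed within platform into pseudo-conditions (averaging), then genes
closer than 0.15 are grouped.  Both thresholds are strict; array values below
the log2 = 5 noise floor are smoothed up to 5 beforehand, and count platforms
enter on the log2(reads + 1) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster

log = logging.getLogger(__name__)

CALLS = ("background", "detected", "expressed")
ARRAY_EXPRESSED = 8.0  # strict
ARRAY_BACKGROUND = 5.0  # also the smoothing floor
COUNT_EXPRESSED = 10.0  # inclusive
COLLAPSE_THRESHOLD = 0.05
GROUP_THRESHOLD = 0.15
_STRICT = 1.0 - 1e-9  # scipy merges at <= t; thresholds here are strict


class PlatformError(ValueError):
    pass


@dataclass
class ExpressionAtlas:
    """Gene x condition table with per-condition platform/PO provenance."""

    values: pd.DataFrame  # genes x conditions
    platform: dict[str, str]  # condition -> platform name
    kind: dict[str, str]  # condition -> 'array' | 'count'
    po: dict[str, str] = field(default_factory=dict)  # condition -> PO id
    smoothed: bool = False

    def __post_init__(self):
        missing = [c for c in self.values.columns if c not in self.kind]
        if missing:
            raise PlatformError(f"conditions without platform kind: {missing}")
        bad = {k for k in self.kind.values()} - {"array", "count"}
        if bad:
            raise PlatformError(f"unknown platform kinds: {sorted(bad)}")


@dataclass
class CoexprResult:
    gene_ids: list[str]
    linkage: np.ndarray
    groups: list[frozenset]
    threshold: float
    metric: str = "pearson-average"

    def group_of(self) -> dict[str, int]:
        return {g: i for i, grp in enumerate(self.groups) for g in grp}


def average_replicates(matrix: pd.DataFrame, sample_map: pd.DataFrame) -> pd.DataFrame:
    """Average replicate samples of each condition (arithmetic mean).

    ``sample_map`` needs columns ``sample`` and ``condition``; samples missing
    from the matrix are dropped with a warning, as are empty conditions.
    """
    cond_of = dict(zip(sample_map["sample"], sample_map["condition"]))
    unknown = [s for s in matrix.columns if s not in cond_of]
    if unknown:
        raise ValueError(f"samples without condition mapping: {unknown}")
    cols: dict[str, np.ndarray] = {}
    for cond in dict.fromkeys(cond_of.values()):  # preserve first-seen order
        samples = [s for s in matrix.columns if cond_of[s] == cond]
        if not samples:
            log.warning("condition %s has no samples in the matrix; dropped", cond)
            continue
        cols[cond] = matrix[samples].mean(axis=1).to_numpy()
    return pd.DataFrame(cols, index=matrix.index)


def _call_cell(value: float, kind: str) -> str:
    if kind == "array":
        if value > ARRAY_EXPRESSED:
            return "expressed"
        if value >= ARRAY_BACKGROUND:
            return "detected"
        return "background"
    if kind == "count":
        if value >= COUNT_EXPRESSED:
            return "expressed"
        if value >= 1:
            return "detected"
        return "background"
    raise PlatformError(f"unknown platform kind {kind!r}")


def call_expression(atlas: ExpressionAtlas):
    """Per-cell calls and per-gene status.

    Returns ``(calls, status)``: ``calls`` mirrors the atlas shape with values
    in {background, detected, expressed}; ``status`` maps each gene to
    gene / putative / hypothetical.
    """
    calls = pd.DataFrame(index=atlas.values.index, columns=atlas.values.columns, dtype=object)
    for cond in atlas.values.columns:
        kind = atlas.kind[cond]
        calls[cond] = [_call_cell(v, kind) for v in atlas.values[cond]]
    status = {}
    for gene in calls.index:
        row = set(calls.loc[gene])
        if "expressed" in row:
            status[gene] = "gene"
        elif "detected" in row:
            status[gene] = "putative"
        else:
            status[gene] = "hypothetical"
    return calls, pd.Series(status)


def attribute_po(atlas: ExpressionAtlas, condition_po: dict[str, str] | None = None) -> dict[str, set]:
    """PO terms of every condition where a gene's cell is ``expressed``."""
    po_map = condition_po if condition_po is not None else atlas.po
    calls, _ = call_expression(atlas)
    out: dict[str, set] = {g: set() for g in atlas.values.index}
    warned = set()
    for cond in calls.columns:
        po = po_map.get(cond)
        if po is None:
            if cond not in warned:
                log.warning("condition %s has no PO mapping; skipped", cond)
                warned.add(cond)
            continue
        for gene in calls.index[calls[cond] == "expressed"]:
            out[gene].add(po)
    return out


def smooth_background(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Clustering-scale copy: array values floored at log2 = 5, counts as
    log2(reads + 1) with the same floor.  The input atlas is untouched."""
    values = atlas.values.copy()
    for cond in values.columns:
        if atlas.kind[cond] == "count":
            values[cond] = np.log2(values[cond].astype(float) + 1.0)
        values[cond] = np.maximum(values[cond], ARRAY_BACKGROUND)
    return replace(atlas, values=values, smoothed=True)


def pearson_distance(profiles: np.ndarray) -> np.ndarray:
    """Full d = 1 - r matrix over rows; zero-variance rows get d = 2."""
    n = profiles.shape[0]
    sd = profiles.std(axis=1)
    d = np.full((n, n), 2.0)
    ok = sd > 0
    if ok.sum() >= 2:
        r = np.corrcoef(profiles[ok])
        d_ok = np.clip(1.0 - r, 0.0, 2.0)
        d[np.ix_(ok, ok)] = d_ok
    np.fill_diagonal(d, 0.0)
    return d


def _condensed(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def collapse_redundant_conditions(atlas: ExpressionAtlas, threshold: float = COLLAPSE_THRESHOLD) -> ExpressionAtlas:
    """Average near-identical conditions (d < threshold) within each platform.

    Conditions are clustered (average linkage on 1 - Pearson r of the family
    genes' smoothed profiles) and flat clusters cut strictly below the
    threshold are averaged into one pseudo-condition each.  Zero-variance
    profiles are forced into singletons.
    """
    if atlas.values.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    values = atlas.values
    new_cols: dict[str, np.ndarray] = {}
    platform: dict[str, str] = {}
    kind: dict[str, str] = {}
    po: dict[str, str] = {}
    for plat in dict.fromkeys(atlas.platform.values()):
        conds = [c for c in values.columns if atlas.platform[c] == plat]
        if len(conds) == 1:
            labels = np.array([1])
        else:
            d = pearson_distance(values[conds].T.to_numpy())
            Z = average(_condensed(d))
            labels = fcluster(Z, t=threshold * _STRICT, criterion="distance")
        for lab in sorted(set(labels)):
            members = [c for c, l in zip(conds, labels) if l == lab]
            name = members[0] if len(members) == 1 else "|".join(members)
            new_cols[name] = values[members].mean(axis=1).to_numpy()
            platform[name] = plat
            kind[name] = atlas.kind[members[0]]
            pos = {atlas.po[m] for m in members if m in atlas.po}
            if len(pos) == 1:
                po[name] = pos.pop()
    collapsed = pd.DataFrame(new_cols, index=values.index)
    return ExpressionAtlas(values=collapsed, platform=platform, kind=kind, po=po, smoothed=atlas.smoothed)


def group_coexpressed(atlas: ExpressionAtlas, threshold: float = GROUP_THRESHOLD) -> CoexprResult:
    """Group genes with the same expression profile (d < threshold, strict).

    Same metric and linkage as the condition collapse; zero-variance genes end
    up as singletons.  Returns the dendrogram (scipy linkage matrix) plus the
    flat partition.
    """
    if atlas.values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    genes = list(atlas.values.index)
    d = pearson_distance(atlas.values.to_numpy(dtype=float))
    Z = average(_condensed(d))
    labels = fcluster(Z, t=threshold * _STRICT, criterion="distance")
    groups = [
        frozenset(g for g, l in zip(genes, labels) if l == lab) for lab in sorted(set(labels))
    ]
    return CoexprResult(gene_ids=genes, linkage=Z, groups=groups, threshold=threshold)


def dendrogram_newick(result: CoexprResult) -> str:
    """Export the gene dendrogram as a Newick string with branch heights."""
    n = len(result.gene_ids)
    nodes = {i: (result.gene_ids[i], 0.0) for i in range(n)}
    for k, (a, b, height, _cnt) in enumerate(result.linkage):
        na, ha = nodes.pop(int(a))
        nb, hb = nodes.pop(int(b))
        h = float(height) / 2.0
        nodes[n + k] = (f"({na}:{h - ha:.6g},{nb}:{h - hb:.6g})", h)
    return nodes.popitem()[1][0] + ";"
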