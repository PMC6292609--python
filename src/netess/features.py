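"""Cross-organism design matrices.

Feature matrices are pandas DataFrames indexed by a two-level
(``organism_id``, ``gene_id``) MultiIndex. Because organisms' networks differ
enormously in size, every column is min-max scaled *within* each organism
before organisms are stacked — a raw degree of 50 means something different in
a 300-node network than in an 8000-node one, but its within-organism rank
position transfers. Scaling state and per-column categories ride along in
``DataFrame.attrs``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import centrality as ctr
from . import refex as rfx
from .catalogue import FeatureCatalogue, merge

logger = logging.getLogger(__name__)

FEATURE_SET_ALIASES = {
    "refex_union": "refex_union",
    "refex267-style-union": "refex_union",
    "centrality12": "centrality12",
    "network14": "network14",
    "naive_baseline": "naive_baseline",
    "full": "full",
    "full283-style": "full",
}


def _as_multiindex(df: pd.DataFrame, organism_id: str) -> pd.DataFrame:
    out = df.copy()
    out.index = pd.MultiIndex.from_product(
        [[organism_id], df.index], names=["organism_id", "gene_id"]
    )
    return out


def minmax_scale_per_network(m: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each column to [0, 1]; constant columns map to 0.

    The rows must belong to a single organism (scaling is per network). Raises
    on non-finite input, naming the gene and feature.
    """
    if m.attrs.get("scaled"):
        raise ValueError("matrix is already scaled")
    if isinstance(m.index, pd.MultiIndex):
        orgs = m.index.get_level_values("organism_id").unique()
        if len(orgs) > 1:
            raise ValueError(f"scaling is per network; matrix spans organisms {list(orgs)}")
    bad = ~np.isfinite(m.to_numpy(dtype=float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-finite value for gene {m.index[i]!r}, feature {m.columns[j]!r}")
    lo = m.min(axis=0)
    span = m.max(axis=0) - lo
    scaled = (m - lo).div(span.where(span > 0, 1.0), axis=1)
    scaled.loc[:, span == 0] = 0.0
    scaled.attrs = dict(m.attrs)
    scaled.attrs["scaled"] = True
    return scaled


def _network_blocks(net, which: str, prune_params, union_cat):
    """Unscaled feature blocks for one network, as (DataFrame, FeatureCatalogue)."""
    if which == "refex_union":
        mat = rfx.compute_named(net, union_cat)
        return mat, union_cat
    if which in ("centrality12", "network14", "naive_baseline"):
        names = ctr.MEASURE_SETS[which]
        cat = FeatureCatalogue(
            list(names), {n: ("other_network" if n in ctr.EXTRA_PROPERTIES else "centrality") for n in names}
        )
        return ctr.compute_all(net, names), cat
    if which == "full":
        refex_mat = rfx.compute_named(net, union_cat)
        cent_cat = FeatureCatalogue(
            list(ctr.CENTRALITY12), {n: "centrality" for n in ctr.CENTRALITY12}
        )
        extra_cat = FeatureCatalogue(
            list(ctr.EXTRA_PROPERTIES), {n: "other_network" for n in ctr.EXTRA_PROPERTIES}
        )
        cat = merge([union_cat, cent_cat, extra_cat])  # dedup by canonical name
        cent_names = [n for n in cat if n not in union_cat]
        cent_mat = ctr.compute_all(net, cent_names)
        mat = pd.concat([refex_mat, cent_mat], axis=1)
        return mat[cat.names], cat
    raise ValueError(f"unknown feature set {which!r}")


def build_network_feature_set(
    nets, which: str = "full", prune_params=None, catalogue: FeatureCatalogue | None = None
) -> pd.DataFrame:
    """Compute, scale and stack a named network feature set across organisms.

    ``which`` is one of ``refex_union`` (the union of each organism's retained
    recursive features, evaluated on all organisms), ``centrality12``,
    ``network14``, ``naive_baseline``, or ``full`` (recursive union block plus
    the twelve centralities plus clique number, clustering coefficient,
    biconnected-component count and weighted degree, de-duplicated by
    canonical name). Scaling is min-max within each organism; the stacked
    matrix is indexed by (organism_id, gene_id).

    For the recursive blocks a ``catalogue`` may be supplied to skip the
    per-network extraction (e.g. a catalogue loaded from file).
    """
    which = FEATURE_SET_ALIASES.get(which)
    if which is None:
        raise ValueError(f"unknown feature set name; valid: {sorted(set(FEATURE_SET_ALIASES))}")
    nets = list(nets)
    if not nets:
        raise ValueError("need at least one network")
    union_cat = catalogue
    if which in ("refex_union", "full") and union_cat is None:
        per_net = [rfx.extract_refex(net, prune_params)[1] for net in nets]
        union_cat = rfx.union_catalogue(per_net)
        logger.info(
            "recursive union catalogue: %d features from %d networks", len(union_cat), len(nets)
        )
    pieces = []
    cat = None
    for net in nets:
        mat, cat = _network_blocks(net, which, prune_params, union_cat)
        scaled = minmax_scale_per_network(mat)
        pieces.append(_as_multiindex(scaled, net.organism_id))
    stacked = pd.concat(pieces, axis=0)
    if stacked.index.duplicated().any():
        dup = stacked.index[stacked.index.duplicated()][0]
        raise ValueError(f"duplicate (organism, gene) row {dup!r}")
    stacked.attrs["scaled"] = True
    stacked.attrs["categories"] = dict(cat.categories)
    return stacked


def attach_external_features(m: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Append an external per-gene numeric feature table (e.g. sequence-derived).

    The table is indexed (or keyed by a ``gene_id`` column) by gene. Genes
    missing from the table receive the per-organism column median (logged);
    external columns are then min-max scaled per organism, like network
    columns, and carry category ``external``.
    """
    if table is not None and "gene_id" in getattr(table, "columns", []):
        table = table.set_index("gene_id")
    if table is None or table.shape[1] == 0:
        return m
    if not all(np.issubdtype(dt, np.number) for dt in table.dtypes):
        bad = [c for c in table.columns if not np.issubdtype(table[c].dtype, np.number)]
        raise ValueError(f"non-numeric external feature columns: {bad}")
    clash = set(table.columns) & set(m.columns)
    if clash:
        raise ValueError(f"external features collide with existing columns: {sorted(clash)}")
    genes = m.index.get_level_values("gene_id")
    ext = table.reindex(genes)
    ext.index = m.index
    pieces = []
    for org in m.index.get_level_values("organism_id").unique():
        block = ext[ext.index.get_level_values("organism_id") == org]
        n_missing = int(block.isna().any(axis=1).sum())
        if n_missing:
            logger.info("%s: imputing %d gene(s) with per-organism medians", org, n_missing)
            block = block.fillna(block.median())
        block = block.fillna(0.0)  # column entirely missing for this organism
        block.attrs = {}
        pieces.append(minmax_scale_per_network(block))
    ext_scaled = pd.concat(pieces, axis=0).reindex(m.index)
    out = pd.concat([m, ext_scaled], axis=1)
    out.attrs = dict(m.attrs)
    cats = dict(out.attrs.get("categories", {}))
    cats.update({c: "external" for c in table.columns})
    out.attrs["categories"] = cats
    return out


def assemble_catalogue(
    refex_cat: FeatureCatalogue,
    include_centralities: bool = True,
    include_extras: bool = True,
    external_blocks=(),
) -> FeatureCatalogue:
    """Catalogue-level assembly of the combined feature set.

    Mirrors :func:`build_network_feature_set` bookkeeping without touching any
    network: recursive block, optionally the twelve centralities and the four
    extra node properties, then any external blocks given as
    (prefix, n_features) pairs; duplicates collapse by canonical name.
    """
    parts = [refex_cat]
    if include_centralities:
        parts.append(
            FeatureCatalogue(list(ctr.CENTRALITY12), {n: "centrality" for n in ctr.CENTRALITY12})
        )
    if include_extras:
        parts.append(
            FeatureCatalogue(
                list(ctr.EXTRA_PROPERTIES), {n: "other_network" for n in ctr.EXTRA_PROPERTIES}
            )
        )
    for prefix, count in external_blocks:
        names = [f"{prefix}_{i + 1:03d}" for i in range(count)]
        parts.append(FeatureCatalogue(names, {n: "external" for n in names}))
    return merge(parts)


def write_feature_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=["organism_id", "gene_id"])
    df.attrs["scaled"] = True
    return df
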