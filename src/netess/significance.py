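"""Centrality–lethality significance testing.

For each organism and each centrality measure, two one-sided tests of the
hypothesis that essential genes sit higher on the measure than non-essential
genes:

* a subsample bootstrap: repeatedly draw, without replacement, as many
  non-essential genes as there are essential genes; the p-value is the
  fraction of draws whose subsample mean is greater than or equal to the
  essential-gene mean (the >= boundary counts toward p);
* a one-sided Wilcoxon rank-sum test (essential > non-essential), exact where
  feasible, otherwise the tie-corrected normal approximation.

Cohort-level summaries count, per measure and per test, the organisms with
p below a significance level — the usual way the centrality–lethality
hypothesis is tabulated across many species. Counts are of raw p-values;
no multiple-testing correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import centrality as ctr
from .network_io import restrict_to_network

_BOOT_CHUNK = 2000  # iterations per vectorised block; bounds memory at ~chunk*n floats


def bootstrap_pvalue(essential_values, nonessential_values, iters: int = 10_000, seed: int = 0) -> float:
    """Subsample-bootstrap p-value for 'essential genes have higher values'."""
    ess = np.asarray(essential_values, dtype=float)
    non = np.asarray(nonessential_values, dtype=float)
    if len(ess) == 0 or len(non) == 0:
        raise ValueError("both groups must be nonempty")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    k = len(ess)
    if k > len(non):
        raise ValueError(
            f"subsample size {k} exceeds the {len(non)} non-essential values"
        )
    target = ess.mean()
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < iters:
        block = min(_BOOT_CHUNK, iters - done)
        keys = rng.random((block, len(non)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        means = non[idx].mean(axis=1)
        hits += int((means >= target).sum())
        done += block
    return hits / iters


def ranksum_pvalue(essential_values, nonessential_values) -> float:
    """One-sided Wilcoxon rank-sum p-value (essential > non-essential)."""
    ess = np.asarray(essential_values, dtype=float)
    non = np.asarray(nonessential_values, dtype=float)
    if len(ess) == 0 or len(non) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([ess, non])
    if np.all(pooled == pooled[0]):
        return 0.5  # degenerate: no ordering information
    return float(stats.mannwhitneyu(ess, non, alternative="greater", method="auto").pvalue)


def split_by_essentiality(values: pd.Series, labels) -> tuple[np.ndarray, np.ndarray]:
    """Split a node-indexed measure Series into (essential, non-essential) arrays,
    restricted to labelled genes present in the Series."""
    lab = labels.labels if hasattr(labels, "labels") else dict(labels)
    ess = [values[g] for g, e in lab.items() if e and g in values.index]
    non = [values[g] for g, e in lab.items() if not e and g in values.index]
    return np.asarray(ess, dtype=float), np.asarray(non, dtype=float)


def cohort_significance(
    networks,
    labels,
    measures=None,
    alpha: float = 0.05,
    iters: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both significance tests for every (organism, measure) pair in a cohort.

    ``networks`` and ``labels`` are parallel sequences per organism;
    ``measures`` defaults to the twelve centrality measures. Returns
    ``(pvalues, counts)``: a long-format table with one row per (organism,
    measure) carrying both p-values, and a per-measure table counting the
    organisms significant at ``alpha`` under each test.
    """
    networks, labels = list(networks), list(labels)
    if not networks:
        raise ValueError("need at least one network")
    if measures is None:
        measures = ctr.CENTRALITY12
    elif isinstance(measures, str):
        measures = ctr.MEASURE_SETS[measures]
    ss = np.random.SeedSequence(seed)
    net_seeds = ss.spawn(len(networks))
    rows = []
    for net, lab, sub_ss in zip(networks, labels, net_seeds):
        lab = restrict_to_network(lab, net)
        measure_seeds = sub_ss.spawn(len(measures))
        for measure, m_ss in zip(measures, measure_seeds):
            values = ctr.compute_measure(net, measure)
            ess, non = split_by_essentiality(values, lab)
            rows.append(
                {
                    "organism_id": net.organism_id,
                    "measure": measure,
                    "bootstrap_p": bootstrap_pvalue(
                        ess, non, iters=iters, seed=int(m_ss.generate_state(1)[0] % (2**31))
                    ),
                    "ranksum_p": ranksum_pvalue(ess, non),
                }
            )
    pvalues = pd.DataFrame(rows)
    counts = (
        pvalues.groupby("measure", sort=False)[["bootstrap_p", "ranksum_p"]]
        .agg(lambda p: int((p < alpha).sum()))
        .rename(columns={"bootstrap_p": "bootstrap_count", "ranksum_p": "ranksum_count"})
        .reindex(measures)
    )
    return pvalues, counts
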