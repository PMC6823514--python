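"""Autosomal-rate correction, group statistics, and the turnover-dating scan.

The observed quantity is, per species, the cumulative synonymous branch
length from a focal common ancestor down to the tip.  Lineage-specific rate
variation is removed by subtracting each species' deviation from the group
mean on matched autosomal data (``corrected = x - (a - mean(a))``), applied
replicate-wise so bootstrap uncertainty propagates.  Simulated datasets are
rescaled to the observed scale through a reference group that carries no
X-linkage signal (base-composition drift makes the absolute scales differ).

The dating itself is an interval-intersection scan: for every scenario
retention time T, the Welch 95% CI of the simulated lineage mean (over
simulation replicates) is compared with the observed 95% bootstrap CI; the
retention times whose intervals overlap form the inferred interval
[T_min, T_max], and loss dates follow as system_age - T.  Whether the null
scenario (T = 0, never X-linked) overlaps is the hypothesis test for a
shared ancestral system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bootstrap import ConsensusTree
from .trees import _clade_key

logger = logging.getLogger(__name__)


@dataclass
class GroupedLengths:
    """Per-species cumulative branch lengths with replicate distributions.

    ``values[species]`` is the array of bootstrap (or simulation) replicate
    values; ``groups[species]`` names the group the species belongs to.
    """

    values: dict            # species -> np.ndarray (replicates)
    groups: dict            # species -> group tag

    def __post_init__(self):
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        missing = set(self.values) - set(self.groups)
        if missing:
            raise ValueError(f"species without group tag: {sorted(missing)}")

    def species(self):
        return sorted(self.values)

    def group_members(self, group: str):
        return sorted(s for s in self.values if self.groups[s] == group)


def cumulative_from_consensus(cons: ConsensusTree, ancestor_label_or_leaves,
                              species: list, groups: dict) -> GroupedLengths:
    """Replicate-wise cumulative lengths from an ancestor to each species tip.

    ``ancestor_label_or_leaves`` is either an internal node label or a list
    of leaf labels whose MRCA anchors the summation.
    """
    tree = cons.tree
    if isinstance(ancestor_label_or_leaves, (list, tuple)):
        anc = tree.mrca(list(ancestor_label_or_leaves))
    else:
        anc = tree.find(ancestor_label_or_leaves)
    values = {}
    for sp in species:
        node = tree.find(sp)
        total = np.zeros(cons.n_replicates)
        while node is not anc:
            if node.parent is None:
                raise ValueError(f"{sp!r} does not descend from the ancestor")
            total = total + cons.branch_distributions[_clade_key(node)]
            node = node.parent
        values[sp] = total
    return GroupedLengths(values=values, groups={s: groups[s] for s in species})


def autosomal_correction(x_lengths: GroupedLengths, a_lengths: GroupedLengths,
                         focal_species: list | None = None) -> GroupedLengths:
    """Subtract each species' autosomal deviation from the focal-group mean.

    ``corrected_i = x_i - (a_i - mean_j a_j)`` with the mean over the focal
    species, replicate-wise.  Species outside the focal set pass through
    unchanged.  The corrections sum to zero across the focal set by
    construction.
    """
    if focal_species is None:
        focal_species = x_lengths.species()
    missing = [s for s in focal_species if s not in a_lengths.values]
    if missing:
        raise ValueError(f"species lacking autosomal estimates: {missing}")
    a_stack = np.stack([a_lengths.values[s] for s in focal_species])
    a_mean = a_stack.mean(axis=0)
    corrected = {}
    for sp, vals in x_lengths.values.items():
        if sp in focal_species:
            corrected[sp] = vals - (a_lengths.values[sp] - a_mean)
        else:
            corrected[sp] = vals.copy()
    return GroupedLengths(values=corrected, groups=dict(x_lengths.groups))


def group_average(lengths: GroupedLengths) -> dict:
    """Replicate-wise mean over the species of each group."""
    out = {}
    for group in sorted(set(lengths.groups.values())):
        members = lengths.group_members(group)
        if not members:
            raise ValueError(f"group {group!r} is empty")
        out[group] = np.stack([lengths.values[s] for s in members]).mean(axis=0)
    return out


# -- statistics --------------------------------------------------------------


def welch_ci(values, level: float = 0.95):
    """t confidence interval of the mean of one sample: (mean, low, high)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    se = v.std(ddof=1) / np.sqrt(v.size)
    if se == 0:
        logger.warning("degenerate (constant) sample in welch_ci")
        return float(mean), float(mean), float(mean)
    tq = stats.t.ppf(0.5 + level / 2.0, df=v.size - 1)
    return float(mean), float(mean - tq * se), float(mean + tq * se)


def welch_test(a, b) -> float:
    """Two-sided Welch two-sample t-test p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        logger.warning("both samples constant in welch_test")
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U p-value (exact where SciPy permits)."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# -- simulated-vs-observed scale and overlap ---------------------------------


def rescale_simulated(sim_values: dict, observed_reference_median: float,
                      simulated_reference_median: float) -> dict:
    """Multiply all simulated values by obs_ref/sim_ref.

    The reference group must carry no X-linkage signal in either dataset
    (e.g. the never-X-linked outgroup); rescaling preserves every
    within-simulation ratio.
    """
    if simulated_reference_median == 0:
        raise ValueError("simulated reference median is zero; cannot rescale")
    factor = observed_reference_median / simulated_reference_median
    return {k: np.asarray(v, float) * factor for k, v in sim_values.items()}


def _intervals_overlap(lo1, hi1, lo2, hi2) -> bool:
    return max(lo1, lo2) <= min(hi1, hi2)


@dataclass
class ScanResult:
    """Per-scenario overlap table and the inferred loss-time interval."""

    table: pd.DataFrame
    intervals: dict = field(default_factory=dict)      # lineage -> (T_min, T_max) | None
    loss_dates: dict = field(default_factory=dict)     # lineage -> (age_min, age_max) | None
    null_compatible: dict = field(default_factory=dict)
    contiguous: dict = field(default_factory=dict)
    overlap_sets: dict = field(default_factory=dict)   # lineage -> sorted list of T
    system_age: float = 0.0

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False, float_format="%.6g")


def overlap_scan(observed: dict, per_scenario_sim: dict, system_age: float,
                 ci_level: float = 0.95) -> ScanResult:
    """Intersect observed CIs with per-scenario simulated Welch CIs.

    ``observed``: lineage -> replicate array (bootstrap distribution of the
    lineage's corrected group-average length); its 95% interval is the
    percentile CI.  ``per_scenario_sim``: retention T -> {lineage ->
    simulation replicate array}; each gets a Welch 95% CI of the mean.
    """
    if not per_scenario_sim:
        raise ValueError("no scenarios to scan")
    rows = []
    lineages = sorted(observed)
    obs_summ = {}
    for lin in lineages:
        vals = np.asarray(observed[lin], float)
        lo, hi = np.percentile(vals, [50 * (1 - ci_level), 100 - 50 * (1 - ci_level)])
        obs_summ[lin] = (float(np.median(vals)), float(lo), float(hi))
    overlap_sets = {lin: [] for lin in lineages}
    for t in sorted(per_scenario_sim):
        sims = per_scenario_sim[t]
        for lin in lineages:
            if lin not in sims:
                raise ValueError(f"scenario T={t} lacks lineage {lin!r}")
            sim_mean, sim_lo, sim_hi = welch_ci(sims[lin], level=ci_level)
            obs_med, obs_lo, obs_hi = obs_summ[lin]
            hit = _intervals_overlap(sim_lo, sim_hi, obs_lo, obs_hi)
            if hit:
                overlap_sets[lin].append(float(t))
            rows.append({"lineage": lin, "retention_t": float(t),
                         "sim_mean": sim_mean, "sim_lo": sim_lo,
                         "sim_hi": sim_hi, "obs_med": obs_med,
                         "obs_lo": obs_lo, "obs_hi": obs_hi,
                         "overlap": hit})
    result = ScanResult(table=pd.DataFrame(rows), system_age=system_age,
                        overlap_sets=overlap_sets)
    all_t = sorted(per_scenario_sim)
    for lin in lineages:
        hits = overlap_sets[lin]
        result.null_compatible[lin] = 0.0 in hits
        if not hits:
            result.intervals[lin] = None
            result.loss_dates[lin] = None
            result.contiguous[lin] = True
            logger.warning("lineage %s: no compatible scenario", lin)
            continue
        t_min, t_max = min(hits), max(hits)
        idx = [all_t.index(t) for t in hits]
        contiguous = idx == list(range(idx[0], idx[-1] + 1))
        if not contiguous:
            logger.warning("lineage %s: non-contiguous overlap set %s", lin, hits)
        result.contiguous[lin] = contiguous
        result.intervals[lin] = (t_min, t_max)
        result.loss_dates[lin] = (system_age - t_max, system_age - t_min)
    return result
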