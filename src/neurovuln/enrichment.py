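"""Median-rank permutation tests on PLS-ranked gene lists.

The central statistic is the median *centered* rank of a gene set within a
ranked list (centered rank = rank - (N+1)/2, so 0 is the middle of the
list).  Null distributions come from random gene-rank permutations:

- P_RAND-Trans: size-matched sets drawn uniformly from the whole list;
- P_RAND-Cis:   size-matched sets drawn only from the CNV's chromosome;
- most-extreme-chromosome: probability that, under rank permutation, the
  target chromosome attains the most extreme median of all chromosomes.

Test direction is declared a priori from the CNV sign: chromosomal or
segmental *gains* are tested for a high median rank and *losses* for a low
median rank, mirroring the observed polarity split between duplications
and deletions.  All p-values use the add-one estimator.

Dosage-sensitivity analyses compare DS vs nDS median ranks, localize the
difference by rank decile, and extract the extreme-ranked DS subset
(DS^SS) from the significant deciles.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd

from ._stats import PermutationResult, add_one_p, permutation_result
from .pls import RankedGeneList

#: default direction per CNV sign
DIRECTION_BY_SIGN = {"gain": "high", "loss": "low", 1: "high", -1: "low"}

_EXHAUSTIVE_LIMIT = 300_000


@dataclass
class DecileTable:
    """Per-decile DS/nDS proportions, differences and one-sided p-values.

    Decile 1 holds the most extreme *low* centered ranks (strongly positive
    PLS weights); decile 10 the most extreme high ranks.  Within each gene
    set the proportions sum to 1 across deciles.  The per-decile p tests
    for DS over-representation (difference > 0): DS genes sitting in a
    decile where DS is *depleted* cannot, by construction, drive a DS-nDS
    median rank difference, so depletion is not flagged.
    """

    table: pd.DataFrame  # columns: decile, proportion_ds, proportion_nds, difference, p

    def significant_deciles(self, alpha: float = 0.05) -> list[int]:
        t = self.table
        return t.loc[t["p"] < alpha, "decile"].astype(int).tolist()


def median_rank(ranked: RankedGeneList, gene_set) -> float:
    """Median centered rank of the set members (midpoint for even sets)."""
    members = [g for g in gene_set]
    present = set(ranked.genes)
    missing = [g for g in members if g not in present]
    hits = [g for g in members if g in present]
    if not hits:
        raise ValueError(f"gene set has empty intersection with list; missing={missing[:10]}")
    return float(np.median(ranked.centered_ranks(hits)))


def _sample_set_medians(
    pool: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Medians of ``n_perm`` uniform without-replacement draws from ``pool``.

    Uses the random-keys trick (the ``set_size`` smallest of iid uniform
    keys index a uniform random subset), chunked to bound memory.
    """
    n = pool.size
    out = np.empty(n_perm)
    chunk = max(1, int(2e7) // n)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        out[done : done + m] = np.median(pool[idx], axis=1)
        done += m
    return out


def _exhaustive_set_medians(pool: np.ndarray, set_size: int) -> np.ndarray:
    return np.array(
        [np.median(np.asarray(c)) for c in combinations(pool, set_size)]
    )


def p_rand_trans(
    ranked: RankedGeneList,
    set_size: int,
    observed: float,
    direction: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Whole-genome size-matched median-rank permutation test.

    ``direction`` must be declared a priori from the CNV sign ("high" for
    gains, "low" for losses).  With ``exhaustive=True`` (only feasible for
    tiny lists) the p-value is the exact fraction of all size-matched
    subsets at least as extreme as the observed median, the observed subset
    counting itself.
    """
    if direction is None:
        raise ValueError("direction must be declared a priori from the CNV sign")
    pool = ranked.centered_ranks()
    if set_size >= pool.size:
        raise ValueError("set_size must be smaller than the ranked list")
    if exhaustive:
        if comb(pool.size, set_size) > _EXHAUSTIVE_LIMIT:
            raise ValueError("exhaustive enumeration too large for this list")
        null = _exhaustive_set_medians(pool, set_size)
        if direction == "high":
            count = int(np.sum(null >= observed))
        elif direction == "low":
            count = int(np.sum(null <= observed))
        else:
            count = int(np.sum(np.abs(null) >= abs(observed)))
        return PermutationResult(
            statistic="median_centered_rank",
            observed=float(observed),
            null_sample=null,
            p=count / null.size,
            direction=direction,
            n_perm=int(null.size),
            seed=seed,
            meta={"mode": "exhaustive", "set_size": set_size},
        )
    rng = np.random.default_rng(seed)
    null = _sample_set_medians(pool, set_size, n_perm, rng)
    return permutation_result(
        "median_centered_rank", observed, null, direction, seed,
        mode="trans", set_size=set_size,
    )


def p_rand_cis(
    ranked: RankedGeneList,
    chromosome_genes,
    set_size: int,
    observed: float,
    direction: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """As :func:`p_rand_trans` but resampling within one chromosome."""
    chrom = [g for g in chromosome_genes if g in set(ranked.genes)]
    if set_size >= len(chrom):
        raise ValueError(
            f"set_size={set_size} must be smaller than the chromosome ({len(chrom)} genes)"
        )
    pool = ranked.centered_ranks(chrom)
    rng = np.random.default_rng(seed)
    null = _sample_set_medians(pool, set_size, n_perm, rng)
    return permutation_result(
        "median_centered_rank", observed, null, direction, seed,
        mode="cis", set_size=set_size, chromosome_size=len(chrom),
    )


def test_gene_set(
    ranked: RankedGeneList,
    gene_set,
    direction: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    chromosome_genes=None,
) -> PermutationResult:
    """Observed median + P_RAND (trans, or cis when a chromosome is given)."""
    members = [g for g in gene_set if g in set(ranked.genes)]
    observed = median_rank(ranked, members)
    if chromosome_genes is None:
        return p_rand_trans(ranked, len(members), observed, direction, n_perm, seed)
    return p_rand_cis(
        ranked, chromosome_genes, len(members), observed, direction, n_perm, seed
    )


def chromosome_rank_profile(
    ranked: RankedGeneList,
    annotations: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Median centered rank (+ bootstrap SE over member genes) per chromosome.

    ``annotations`` must have columns ``gene`` and ``chromosome`` (PAR is a
    distinct label).  Chromosomes with no ranked genes are omitted.
    """
    rng = np.random.default_rng(seed)
    ann = annotations.set_index("gene")["chromosome"]
    rows = []
    for chrom, genes in ann.groupby(ann).groups.items():
        members = [g for g in genes if g in set(ranked.genes)]
        if not members:
            continue
        ranks = ranked.centered_ranks(members)
        boots = rng.choice(ranks, size=(n_boot, ranks.size), replace=True)
        rows.append(
            {
                "chromosome": str(chrom),
                "n_genes": len(members),
                "median_centered_rank": float(np.median(ranks)),
                "se": float(np.median(boots, axis=1).std(ddof=1)) if ranks.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values("chromosome").reset_index(drop=True)


def p_most_extreme_chromosome(
    ranked: RankedGeneList,
    annotations: pd.DataFrame,
    target_chromosome: str,
    direction: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Chance of the target chromosome's observed most-extreme median rank.

    Gene ranks are permuted across the whole list; in each permutation all
    chromosome medians are recomputed and the joint event "the target is
    the most extreme chromosome in the declared direction AND its median
    is at least as extreme as observed" is recorded.  The add-one
    frequency of that event is the p-value (ties for the extreme count as
    a success).  Anchoring at the observed median makes the test sensitive
    to planted enrichment; with a typical observed median and a symmetric
    two-chromosome null it reduces to ~1/2.
    """
    ann = annotations.set_index("gene")["chromosome"]
    genes = ranked.genes
    labels = np.array([str(ann.get(g, "NA")) for g in genes])
    chroms = [c for c in np.unique(labels) if c != "NA"]
    if target_chromosome not in chroms:
        raise ValueError(f"target chromosome {target_chromosome!r} absent")
    if len(chroms) < 2:
        raise ValueError("need at least 2 chromosomes")
    masks = {c: labels == c for c in chroms}
    ranks = ranked.centered_ranks()

    observed_medians = {c: float(np.median(ranks[m])) for c, m in masks.items()}
    obs_t = observed_medians[target_chromosome]
    if direction == "high":
        observed_extreme = obs_t >= max(observed_medians.values())
    elif direction == "low":
        observed_extreme = obs_t <= min(observed_medians.values())
    else:
        observed_extreme = abs(obs_t) >= max(abs(v) for v in observed_medians.values())

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, int(2e7) // ranks.size)
    done = 0
    null_events = np.empty(n_perm, dtype=bool)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, ranks.size)), axis=1)
        pr = ranks[perm]
        meds = np.column_stack([np.median(pr[:, masks[c]], axis=1) for c in chroms])
        tcol = chroms.index(target_chromosome)
        if direction == "high":
            ev = (meds[:, tcol] >= meds.max(axis=1)) & (meds[:, tcol] >= obs_t)
        elif direction == "low":
            ev = (meds[:, tcol] <= meds.min(axis=1)) & (meds[:, tcol] <= obs_t)
        else:
            ev = (np.abs(meds[:, tcol]) >= np.abs(meds).max(axis=1)) & (
                np.abs(meds[:, tcol]) >= abs(obs_t)
            )
        null_events[done : done + m] = ev
        done += m
    hits = int(null_events.sum())
    return PermutationResult(
        statistic="target_most_extreme_chromosome",
        observed=obs_t,
        null_sample=null_events.astype(float),
        p=(1 + hits) / (n_perm + 1),
        direction=direction,
        n_perm=n_perm,
        seed=seed,
        meta={
            "target": target_chromosome,
            "observed_extreme": bool(observed_extreme),
            "n_chromosomes": len(chroms),
        },
    )


def omnibus_p(results: list[PermutationResult]) -> float:
    """Joint p for all CNVs simultaneously showing their observed extremeness.

    The joint null treats each result's stored null sample as one of
    ``n_perm`` simultaneous independent permutations: permutation b is a
    joint success when every CNV's null draw is at least as extreme as its
    observed statistic (for event-style results, when the event occurred).
    The add-one estimate of the joint success probability is returned.
    This is one defensible construction of an omnibus permutation p; the
    choice is recorded in output metadata by the pipeline.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 independent results")
    n_perm = results[0].n_perm
    if any(r.n_perm != n_perm for r in results):
        raise ValueError("results must share n_perm for the joint permutation null")
    joint = np.ones(n_perm, dtype=bool)
    for r in results:
        null = r.null_sample
        if r.statistic == "target_most_extreme_chromosome":
            joint &= null.astype(bool)
        elif r.direction == "high":
            joint &= null >= r.observed
        elif r.direction == "low":
            joint &= null <= r.observed
        else:
            joint &= np.abs(null) >= abs(r.observed)
    return (1 + int(joint.sum())) / (n_perm + 1)


def ds_nds_median_test(
    ranked: RankedGeneList,
    ds_set,
    nds_set,
    n_perm: int = 10_000,
    seed: int | None = None,
    direction: str = "most_extreme",
) -> PermutationResult:
    """median(DS ranks) - median(nDS ranks) vs label permutations.

    The null permutes the DS/nDS labels over the union's rank positions,
    which under exchangeability is equivalent to permuting gene ranks.
    Two-sided by default.
    """
    ds = [g for g in ds_set]
    nds = [g for g in nds_set]
    if set(ds) & set(nds):
        raise ValueError("DS and nDS sets overlap")
    if not ds or not nds:
        raise ValueError("DS and nDS sets must be nonempty")
    r_ds = ranked.centered_ranks(ds)
    r_nds = ranked.centered_ranks(nds)
    observed = float(np.median(r_ds) - np.median(r_nds))
    pool = np.concatenate([r_ds, r_nds])
    k = r_ds.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    chunk = max(1, int(2e7) // pool.size)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, pool.size)), axis=1)
        pp = pool[perm]
        null[done : done + m] = np.median(pp[:, :k], axis=1) - np.median(
            pp[:, k:], axis=1
        )
        done += m
    return permutation_result(
        "ds_minus_nds_median_rank", observed, null, direction, seed,
        n_ds=len(ds), n_nds=len(nds),
    )


def _decile_of(centered_ranks: np.ndarray, n: int) -> np.ndarray:
    """Decile index (1..10) from centered ranks on a list of length n."""
    ranks = centered_ranks + (n + 1) / 2.0
    return np.ceil(10.0 * ranks / n).astype(int).clip(1, 10)


def decile_enrichment(
    ranked: RankedGeneList,
    ds_set,
    nds_set,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> DecileTable:
    """Per-decile DS-vs-nDS proportion differences with permutation p-values.

    Deciles are defined on the full ranked list.  Proportions are within-set
    (each set's proportions sum to 1).  The per-decile null permutes DS/nDS
    labels within the union; p is one-sided for DS over-representation.
    """
    ds = [g for g in ds_set]
    nds = [g for g in nds_set]
    if set(ds) & set(nds):
        raise ValueError("DS and nDS sets overlap")
    if not ds or not nds:
        raise ValueError("DS and nDS sets must be nonempty")
    n = ranked.n
    d_ds = _decile_of(ranked.centered_ranks(ds), n)
    d_nds = _decile_of(ranked.centered_ranks(nds), n)
    pool = np.concatenate([d_ds, d_nds])
    k = d_ds.size
    obs_prop_ds = np.array([(d_ds == d).mean() for d in range(1, 11)])
    obs_prop_nds = np.array([(d_nds == d).mean() for d in range(1, 11)])
    obs_diff = obs_prop_ds - obs_prop_nds

    rng = np.random.default_rng(seed)
    exceed = np.zeros(10, dtype=int)
    chunk = max(1, int(2e7) // pool.size)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, pool.size)), axis=1)
        pp = pool[perm]
        ds_part, nds_part = pp[:, :k], pp[:, k:]
        for d in range(1, 11):
            diff = (ds_part == d).mean(axis=1) - (nds_part == d).mean(axis=1)
            exceed[d - 1] += int(np.sum(diff >= obs_diff[d - 1]))
        done += m
    p = (1 + exceed) / (n_perm + 1)
    table = pd.DataFrame(
        {
            "decile": np.arange(1, 11),
            "proportion_ds": obs_prop_ds,
            "proportion_nds": obs_prop_nds,
            "difference": obs_diff,
            "p": p,
        }
    )
    return DecileTable(table)


def extract_dsss(
    decile_table: DecileTable,
    ds_set,
    ranked: RankedGeneList,
    alpha: float = 0.05,
) -> list[str]:
    """DS genes in deciles significantly enriched for DS membership (DS^SS)."""
    sig = set(decile_table.significant_deciles(alpha))
    ds = [g for g in ds_set]
    if not sig:
        import warnings

        warnings.warn("no significant decile; DS^SS is empty", stacklevel=2)
        return []
    dec = _decile_of(ranked.centered_ranks(ds), ranked.n)
    return [g for g, d in zip(ds, dec) if int(d) in sig]


def set_size_sensitivity(
    ranked: RankedGeneList,
    donor_genes,
    sizes,
    direction: str,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """p-value of donor-set subsample medians vs genome draws, per set size.

    For each size s: the observed statistic is the median of ``n_draws``
    size-s subsample medians from the donor set; the null is ``n_draws``
    medians of size-s draws from the whole list.
    """
    donor = [g for g in donor_genes if g in set(ranked.genes)]
    pool_all = ranked.centered_ranks()
    pool_donor = ranked.centered_ranks(donor)
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        s = int(s)
        if s <= 0 or s > len(donor):
            raise ValueError(f"size {s} outside (0, {len(donor)}]")
        if s == len(donor):
            sub_meds = np.full(n_draws, np.median(pool_donor))
        else:
            sub_meds = _sample_set_medians(pool_donor, s, n_draws, rng)
        null_meds = _sample_set_medians(pool_all, s, n_draws, rng)
        observed = float(np.median(sub_meds))
        rows.append(
            {
                "size": s,
                "observed_median_of_medians": observed,
                "p": add_one_p(null_meds, observed, direction),
            }
        )
    return pd.DataFrame(rows)
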