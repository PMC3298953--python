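"""Nuclear diversity, relatedness and the pre/post supplementation comparison.

Per locus and population: observed heterozygosity, Nei's unbiased expected
heterozygosity, rarefacted allelic richness, F_IS and an exact
Hardy-Weinberg test (complete enumeration of genotype arrays conditional on
allele counts when feasible, Monte-Carlo permutation of gene copies
otherwise, Holm-corrected across tests). Pairwise relatedness uses the
Lynch & Ritland (1999) regression estimator by default (Queller & Goodnight
1989 available), with a percentile bootstrap CI over pairs.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .formats_io import PopulationSample, logger


def observed_heterozygosity(sample: PopulationSample, locus: str) -> float | None:
    pairs = [
        ind.genotype[locus]
        for ind in sample.individuals
        if ind.genotype.get(locus) is not None
    ]
    if not pairs:
        return None
    return sum(1 for a, b in pairs if a != b) / len(pairs)


def expected_heterozygosity_unbiased(
    allele_counts: Mapping[int, int] | Sequence[int],
) -> float | None:
    """Nei's unbiased expected heterozygosity 2n/(2n-1) (1 - sum p_i^2)."""
    values = (
        list(allele_counts.values())
        if isinstance(allele_counts, Mapping)
        else list(allele_counts)
    )
    two_n = sum(values)
    if two_n < 2:
        return None
    p = np.asarray(values, dtype=float) / two_n
    return float(two_n / (two_n - 1) * (1.0 - np.sum(p**2)))


def allelic_richness(
    allele_counts: Mapping[int, int] | Sequence[int], g: int
) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies.

    Rarefaction controls for unequal sample sizes: A_R = sum over alleles of
    1 - C(2N - N_a, g)/C(2N, g), the probability each allele appears at least
    once among g copies drawn without replacement.
    """
    values = (
        list(allele_counts.values())
        if isinstance(allele_counts, Mapping)
        else list(allele_counts)
    )
    two_n = sum(values)
    if g < 1 or g > two_n:
        raise ValueError(f"g={g} outside [1, {two_n}]")

    def log_comb(m: int, k: int) -> float:
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    total = 0.0
    for n_a in values:
        if two_n - n_a < g:
            total += 1.0
        else:
            total += 1.0 - np.exp(log_comb(two_n - n_a, g) - log_comb(two_n, g))
    return float(total)


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test


def _genotype_array_log_prob(table: Mapping[tuple[int, int], int]) -> float:
    """Log conditional probability of a genotype array given allele counts
    (Levene's distribution): n! prod m_a! 2^h / ((2n)! prod n_ab!)."""
    n = sum(table.values())
    allele: dict[int, int] = {}
    n_het = 0
    for (a, b), c in table.items():
        allele[a] = allele.get(a, 0) + c
        allele[b] = allele.get(b, 0) + c
        if a != b:
            n_het += c
    two_n = 2 * n
    lp = gammaln(n + 1) - gammaln(two_n + 1) + n_het * np.log(2.0)
    for m in allele.values():
        lp += gammaln(m + 1)
    for c in table.values():
        lp -= gammaln(c + 1)
    return float(lp)


def _enumerate_tables(allele_counts: dict[int, int]):
    """Yield all genotype-count tables consistent with the allele counts."""
    alleles = sorted(allele_counts)
    pairs = [
        (a, b) for i, a in enumerate(alleles) for b in alleles[i:]
    ]

    def rec(idx: int, remaining: dict[int, int], table: dict):
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                yield dict(table)
            return
        a, b = pairs[idx]
        if a == b:
            max_c = remaining[a] // 2
        else:
            max_c = min(remaining[a], remaining[b])
        # remaining copies of later alleles must still be placeable; simple
        # pruning: try all counts, recursion depth is small for small tables
        for c in range(max_c, -1, -1):
            remaining[a] -= c if a == b else c
            if a == b:
                remaining[a] -= c
            else:
                remaining[b] -= c
            table[(a, b)] = c
            yield from rec(idx + 1, remaining, table)
            if a == b:
                remaining[a] += 2 * c
            else:
                remaining[a] += c
                remaining[b] += c
        del table[(a, b)]

    yield from rec(0, dict(allele_counts), {})


def _table_space_size(allele_counts: dict[int, int]) -> float:
    """Crude upper bound on the number of genotype tables."""
    alleles = sorted(allele_counts)
    size = 1.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            size *= 1 + (
                allele_counts[a] // 2 if a == b else min(allele_counts[a], allele_counts[b])
            )
            if size > 1e7:
                return size
    return size


def hwe_exact_test(
    genotype_counts: Mapping[tuple[int, int], int],
    mc_steps: int = 100_000,
    seed: int = 0,
    method: str = "auto",
) -> float | None:
    """Exact conditional test for Hardy-Weinberg proportions at one locus.

    The p-value is the total Levene probability of genotype arrays (with the
    observed allele counts) no more probable than the observed one. Complete
    enumeration is used when the array space is small (<= 1e6 tables by a
    crude bound); otherwise a Monte-Carlo permutation of the 2n gene copies
    with ``mc_steps`` shuffles. Returns None for monomorphic data.
    """
    table = {(min(a, b), max(a, b)): c for (a, b), c in genotype_counts.items() if c > 0}
    allele_counts: dict[int, int] = {}
    for (a, b), c in table.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    if len(allele_counts) < 2 or sum(table.values()) < 2:
        return None
    lp_obs = _genotype_array_log_prob(table)
    tol = 1e-9
    if method not in ("auto", "enum", "mc"):
        raise ValueError(f"unknown method {method!r}")
    use_enum = (
        method == "enum"
        or (method == "auto" and _table_space_size(allele_counts) <= 1e6)
    )

    if use_enum:
        total = 0.0
        extreme = 0.0
        for t in _enumerate_tables(allele_counts):
            lp = _genotype_array_log_prob(t)
            p = np.exp(lp)
            total += p
            if lp <= lp_obs + tol:
                extreme += p
        return float(extreme / total)

    # Monte-Carlo: permute the 2n gene copies, pair consecutive copies, and
    # compare each array's Levene log-probability to the observed one.
    # Vectorised in batches; only the sum of gammaln(c+1) over genotype cells
    # and the heterozygote count vary between arrays.
    rng = np.random.default_rng(seed)
    alleles = sorted(allele_counts)
    k = len(alleles)
    copies = np.repeat(
        np.arange(k), [allele_counts[a] for a in alleles]
    )
    n_ind = copies.size // 2
    const = (
        gammaln(n_ind + 1)
        - gammaln(2 * n_ind + 1)
        + sum(gammaln(m + 1) for m in allele_counts.values())
    )
    n_extreme = 0
    batch = 20_000
    done = 0
    while done < mc_steps:
        b = min(batch, mc_steps - done)
        perms = rng.permuted(np.tile(copies, (b, 1)), axis=1)
        ga = perms[:, ::2]
        gb = perms[:, 1::2]
        lo = np.minimum(ga, gb)
        hi = np.maximum(ga, gb)
        keys = lo * k + hi
        offsets = (np.arange(b) * (k * k))[:, None]
        cell_counts = np.bincount(
            (keys + offsets).ravel(), minlength=b * k * k
        ).reshape(b, k * k)
        n_het = (lo != hi).sum(axis=1)
        lp = const + n_het * np.log(2.0) - gammaln(cell_counts + 1).sum(axis=1)
        n_extreme += int((lp <= lp_obs + tol).sum())
        done += b
    return (n_extreme + 1) / (mc_steps + 1)


def holm_correct(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm (sequential Bonferroni) rejection flags across tests."""
    reject, _, _, _ = multipletests(pvalues, alpha=alpha, method="holm")
    return reject


# ---------------------------------------------------------------------------
# Pairwise relatedness


def _genotype_matrix(sample: PopulationSample) -> tuple[np.ndarray, np.ndarray, list[str]]:
    loci = sample.loci
    n = len(sample.individuals)
    a = np.full((n, len(loci)), -1, dtype=np.int64)
    b = np.full((n, len(loci)), -1, dtype=np.int64)
    for i, ind in enumerate(sample.individuals):
        for l, locus in enumerate(loci):
            pair = ind.genotype.get(locus)
            if pair is not None:
                a[i, l], b[i, l] = pair
    return a, b, loci


def _lynch_ritland_pair(ga, gb, ha, hb, freqs) -> tuple[float, float]:
    """One direction of the Lynch-Ritland estimator for a pair at one locus.

    Reference individual has alleles (ga, gb); proband (ha, hb). Returns the
    locus estimate and its information weight; the caller averages both
    directions with weights.
    """
    pa = freqs[ga]
    pb = freqs[gb]
    dab = 1.0 if ga == gb else 0.0
    sac = 1.0 if ga == ha else 0.0
    sad = 1.0 if ga == hb else 0.0
    sbc = 1.0 if gb == ha else 0.0
    sbd = 1.0 if gb == hb else 0.0
    denom = (1.0 + dab) * (pa + pb) - 4.0 * pa * pb
    if denom <= 0:
        return 0.0, 0.0
    r = (pa * (sbc + sbd) + pb * (sac + sad) - 4.0 * pa * pb) / denom
    weight = denom / (2.0 * pa * pb)
    return r, weight


def _queller_goodnight_pair(ga, gb, ha, hb, freqs) -> tuple[float, float]:
    """One direction of the Queller-Goodnight estimator (numerator, denom)."""
    pa = freqs[ga]
    pb = freqs[gb]
    sac = 1.0 if ga == ha else 0.0
    sad = 1.0 if ga == hb else 0.0
    sbc = 1.0 if gb == ha else 0.0
    sbd = 1.0 if gb == hb else 0.0
    dab = 1.0 if ga == gb else 0.0
    num = 0.5 * (sac + sad + sbc + sbd) - pa - pb
    den = 1.0 + dab - pa - pb
    return num, den


def pairwise_relatedness(
    sample: PopulationSample,
    reference_frequencies: Mapping[str, Mapping[int, float]] | None = None,
    estimator: str = "lynch_ritland",
    n_bootstrap: int = 9999,
    seed: int = 0,
) -> dict:
    """Mean pairwise relatedness with a percentile bootstrap CI over pairs.

    Locus estimates are combined with the estimator's information weights,
    and the two directions of each pair are averaged. Reference allele
    frequencies default to the sample's own. Pairs sharing no typed locus
    are excluded and logged.
    """
    if estimator not in ("lynch_ritland", "queller_goodnight"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if reference_frequencies is None:
        reference_frequencies = {
            locus: _normalised(sample.allele_counts(locus)) for locus in sample.loci
        }
    a, b, loci = _genotype_matrix(sample)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    pair_fn = (
        _lynch_ritland_pair if estimator == "lynch_ritland" else _queller_goodnight_pair
    )

    values = []
    pairs = []
    n_dropped = 0
    for i, j in combinations(range(n), 2):
        num_ij = den_ij = num_ji = den_ji = 0.0
        shared = 0
        for l, locus in enumerate(loci):
            if a[i, l] < 0 or a[j, l] < 0:
                continue
            freqs = reference_frequencies[locus]
            shared += 1
            r1, w1 = pair_fn(a[i, l], b[i, l], a[j, l], b[j, l], freqs)
            r2, w2 = pair_fn(a[j, l], b[j, l], a[i, l], b[i, l], freqs)
            if estimator == "lynch_ritland":
                num_ij += r1 * w1
                den_ij += w1
                num_ji += r2 * w2
                den_ji += w2
            else:
                num_ij += r1
                den_ij += w1
                num_ji += r2
                den_ji += w2
        if shared == 0:
            n_dropped += 1
            continue
        r_ij = num_ij / den_ij if den_ij else 0.0
        r_ji = num_ji / den_ji if den_ji else 0.0
        values.append(0.5 * (r_ij + r_ji))
        pairs.append((i, j))
    if n_dropped:
        logger.warning("pairwise_relatedness: dropped %d pairs with no shared loci", n_dropped)
    values_arr = np.array(values)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values_arr), size=(n_bootstrap, len(values_arr)))
    boot_means = values_arr[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return {
        "estimator": estimator,
        "mean": float(values_arr.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_pairs": len(values_arr),
        "n_dropped_pairs": n_dropped,
        "values": values_arr,
        "pairs": pairs,
    }


def _normalised(counts: Mapping[int, int]) -> dict[int, float]:
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}


# ---------------------------------------------------------------------------
# Paired comparison across loci


def paired_t_across_loci(
    pre_values: Sequence[float], post_values: Sequence[float]
) -> tuple[float, int, float]:
    """Paired t-test of per-locus metric values, df = n_loci - 1."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need equal-length vectors of at least 2 loci")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, pre.size - 1, 1.0
        return float(np.sign(diff.mean()) * np.inf), pre.size - 1, 0.0
    res = stats.ttest_rel(post, pre)
    return float(res.statistic), pre.size - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# Summary table


def diversity_table(
    samples: Mapping[str, PopulationSample],
    rarefaction_g: int | None = None,
    hwe_seed: int = 0,
) -> pd.DataFrame:
    """Per-population x locus H_O, H_E, A_R, F_IS, n_typed and HWE p-values.

    Rarefaction size defaults to twice the smallest number of complete
    genotypes at each locus across the populations compared.
    """
    rows = []
    loci = next(iter(samples.values())).loci
    for locus in loci:
        n_typed = {
            label: sum(
                1 for ind in s.individuals if ind.genotype.get(locus) is not None
            )
            for label, s in samples.items()
        }
        g = rarefaction_g if rarefaction_g is not None else 2 * min(n_typed.values())
        for label, s in samples.items():
            counts = s.allele_counts(locus)
            h_o = observed_heterozygosity(s, locus)
            h_e = expected_heterozygosity_unbiased(counts)
            geno_counts: dict[tuple[int, int], int] = {}
            for ind in s.individuals:
                pair = ind.genotype.get(locus)
                if pair is not None:
                    geno_counts[pair] = geno_counts.get(pair, 0) + 1
            a_r = (
                allelic_richness(counts, g)
                if counts and g >= 1 and g <= sum(counts.values())
                else None
            )
            rows.append(
                {
                    "population": label,
                    "locus": locus,
                    "n_typed": n_typed[label],
                    "H_O": h_o,
                    "H_E": h_e,
                    "A_R": a_r,
                    "F_IS": (
                        1.0 - h_o / h_e if h_o is not None and h_e else None
                    ),
                    "hwe_p": hwe_exact_test(geno_counts, seed=hwe_seed),
                }
            )
    df = pd.DataFrame(rows)
    tested = df["hwe_p"].notna()
    if tested.any():
        flags = holm_correct(df.loc[tested, "hwe_p"].to_numpy())
        df["hwe_reject_holm"] = False
        df.loc[tested, "hwe_reject_holm"] = flags
    return df
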