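"""Control-region haplotype collapsing and mitochondrial diversity statistics.

Aligned sequences are collapsed into haplotypes by exact identity, ignoring
positions where either sequence carries an N or a gap (pairwise deletion, so
a sporadically ambiguous read can still be resolved). Haplotype diversity and
the mean number of pairwise nucleotide differences use the standard unbiased
n/(n-1) sample-size correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

AMBIGUOUS = set("N-.")


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with per-population counts.

    ``assignments`` maps sequence id -> haplotype label (None when the
    sequence is ambiguous enough to match several haplotypes and is left
    unresolved rather than forced). ``private_to`` marks haplotypes observed
    in exactly one baseline population.
    """

    sequences: dict[str, str]  # haplotype label -> representative sequence
    assignments: dict[str, str | None]
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    variable_sites: list[int] = field(default_factory=list)
    private_to: dict[str, str] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def population_counts(self, population: str) -> dict[str, int]:
        return self.counts.get(population, {})


def _compatible(a: str, b: str) -> bool:
    return all(
        x == y or x in AMBIGUOUS or y in AMBIGUOUS for x, y in zip(a, b)
    )


def collapse_haplotypes(
    alignment: Mapping[str, str],
    populations: Mapping[str, str] | None = None,
    baseline_populations: set[str] | None = None,
) -> HaplotypeTable:
    """Collapse an alignment into haplotypes and enumerate variable sites.

    Unambiguous sequences define the haplotypes (exact identity); ambiguous
    sequences are assigned when compatible with exactly one haplotype and
    left unresolved otherwise. Labels are A, B, ... by descending overall
    count, ties broken by first occurrence. ``private_to`` is computed
    against ``baseline_populations`` when given (else all populations).
    """
    if not alignment:
        raise ValueError("empty alignment")
    length = len(next(iter(alignment.values())))
    ids = list(alignment)

    clean_reps: list[str] = []  # representative sequences, first-seen order
    raw_assign: dict[str, int | None] = {}
    ambiguous_ids = []
    for sid in ids:
        seq = alignment[sid]
        if set(seq) & AMBIGUOUS:
            ambiguous_ids.append(sid)
            continue
        for h, rep in enumerate(clean_reps):
            if seq == rep:
                raw_assign[sid] = h
                break
        else:
            raw_assign[sid] = len(clean_reps)
            clean_reps.append(seq)
    for sid in ambiguous_ids:
        seq = alignment[sid]
        matches = [h for h, rep in enumerate(clean_reps) if _compatible(seq, rep)]
        raw_assign[sid] = matches[0] if len(matches) == 1 else None

    order = sorted(
        range(len(clean_reps)),
        key=lambda h: (-sum(1 for v in raw_assign.values() if v == h), h),
    )
    label_of = {h: _label(i) for i, h in enumerate(order)}
    sequences = {label_of[h]: clean_reps[h] for h in order}
    assignments = {
        sid: (label_of[h] if h is not None else None)
        for sid, h in raw_assign.items()
    }

    variable_sites = []
    for col in range(length):
        bases = {
            alignment[sid][col]
            for sid in ids
            if alignment[sid][col] not in AMBIGUOUS
        }
        if len(bases) >= 2:
            variable_sites.append(col)

    counts: dict[str, dict[str, int]] = {}
    if populations is not None:
        for sid, label in assignments.items():
            if label is None:
                continue
            pop = populations.get(sid)
            if pop is None:
                continue
            counts.setdefault(pop, {})
            counts[pop][label] = counts[pop].get(label, 0) + 1

    private_to: dict[str, str] = {}
    if counts:
        base = baseline_populations or set(counts)
        for label in sequences:
            pops_with = [
                p for p in base if counts.get(p, {}).get(label, 0) > 0
            ]
            if len(pops_with) == 1:
                private_to[label] = pops_with[0]

    return HaplotypeTable(
        sequences=sequences,
        assignments=assignments,
        counts=counts,
        variable_sites=variable_sites,
        private_to=private_to,
    )


def _label(i: int) -> str:
    out = ""
    while True:
        out = chr(ord("A") + i % 26) + out
        i = i // 26 - 1
        if i < 0:
            return out


def haplotype_diversity(counts: Mapping[str, int] | list[int]) -> float | None:
    """Unbiased haplotype (gene) diversity H_D = n/(n-1) (1 - sum p_i^2).

    Analogous to single-locus heterozygosity; maximal when haplotypes are
    equifrequent. Returns None for samples of fewer than two sequences.
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    n = sum(values)
    if n < 2:
        return None
    p = np.asarray(values, dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def pairwise_site_differences(sequences: Mapping[str, str]) -> dict:
    """d[h1][h2] = substitution steps between haplotypes (pairwise deletion)."""
    labels = list(sequences)
    d: dict[str, dict[str, int]] = {h: {} for h in labels}
    for i, h1 in enumerate(labels):
        for h2 in labels[i:]:
            diff = sum(
                1
                for x, y in zip(sequences[h1], sequences[h2])
                if x != y and x not in AMBIGUOUS and y not in AMBIGUOUS
            )
            d[h1][h2] = diff
            d[h2][h1] = diff
    return d


def mean_pairwise_differences(
    counts: Mapping[str, int], site_differences: Mapping[str, Mapping[str, int]]
) -> float | None:
    """Unbiased mean pairwise nucleotide differences within a population.

    k = n/(n-1) * sum_ij p_i p_j d_ij with p the haplotype frequencies.
    """
    n = sum(counts.values())
    if n < 2:
        return None
    labels = list(counts)
    p = np.array([counts[h] for h in labels], dtype=float) / n
    d = np.array(
        [[site_differences[h1][h2] for h2 in labels] for h1 in labels], dtype=float
    )
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("site_differences must be symmetric with zero diagonal")
    return float(n / (n - 1) * (p @ d @ p))


def diversity_summary(table: HaplotypeTable) -> "pd.DataFrame":
    """Per-population haplotype counts, H_D and k as a tidy frame."""
    import pandas as pd

    d = pairwise_site_differences(table.sequences)
    rows = []
    for pop, counts in table.counts.items():
        rows.append(
            {
                "population": pop,
                "n": sum(counts.values()),
                "n_haplotypes": len(counts),
                "H_D": haplotype_diversity(counts),
                "k": mean_pairwise_differences(counts, d),
            }
        )
    return pd.DataFrame(rows)
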