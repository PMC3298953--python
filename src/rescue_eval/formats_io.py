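"""Readers, writers and run configuration for the pipeline's file formats.

Microsatellite genotypes travel as Genepop files (2- or 3-digit allele codes),
mtDNA control-region sequences as aligned FASTA, and per-individual metadata
(sex, age, haplotype) as a sidecar CSV keyed by individual id, since Genepop
has no fields for any of those. Run configuration is YAML.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import yaml

logger = logging.getLogger("rescue_eval")

MISSING = None  # sentinel for a missing genotype at a locus

SEXES = ("ewe", "ram", "unknown")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class Individual:
    """One sampled animal: multilocus genotype plus field metadata.

    ``genotype`` maps locus name -> unordered allele pair (tuple of two int
    codes, stored sorted) or ``None`` when the locus failed to type.
    ``age`` is integer years when known (horn-annuli count in the field),
    ``mt_haplotype`` a haplotype label or ``None`` when sequencing failed.
    """

    id: str
    population: str
    sex: str = "unknown"
    age: int | None = None
    genotype: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    mt_haplotype: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"individual {self.id}: sex {self.sex!r} not in {SEXES}")
        if self.age is not None and self.age < 0:
            raise ValueError(f"individual {self.id}: negative age {self.age}")
        for locus, pair in self.genotype.items():
            if pair is not None:
                a, b = pair
                self.genotype[locus] = (min(a, b), max(a, b))

    @property
    def missing_rate(self) -> float:
        if not self.genotype:
            return 0.0
        n_missing = sum(1 for g in self.genotype.values() if g is None)
        return n_missing / len(self.genotype)


@dataclass
class PopulationSample:
    """All individuals sampled from one population in one epoch."""

    label: str
    individuals: list[Individual]
    epoch: str = "post"  # {pre, post, source}

    def __post_init__(self) -> None:
        for ind in self.individuals:
            if ind.population != self.label:
                raise ValueError(
                    f"individual {ind.id} has population {ind.population!r}, "
                    f"sample is {self.label!r}"
                )

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def loci(self) -> list[str]:
        return list(self.individuals[0].genotype) if self.individuals else []

    def allele_counts(self, locus: str) -> dict[int, int]:
        """Observed allele counts at ``locus`` (missing genotypes skipped)."""
        counts: dict[int, int] = {}
        for ind in self.individuals:
            pair = ind.genotype.get(locus)
            if pair is None:
                continue
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
        return counts


@dataclass
class StudyConfig:
    """Run configuration mirroring the supplementation experiment's knobs.

    ``census_size_post`` and ``supplemented_ewe_ages`` are keyed by treatment
    population label. ``years_elapsed`` is the gap between supplementation and
    resampling; ``age_cutoff`` is the oldest age that can postdate it.
    """

    census_size_post: dict[str, int] = field(default_factory=dict)
    supplemented_ewe_ages: dict[str, list[int]] = field(default_factory=dict)
    years_elapsed: int = 6
    age_cutoff: int = 6
    rng_seed: int = 0
    genotypes_path: str | None = None
    sequences_path: str | None = None
    metadata_path: str | None = None
    baseline_lambs_per_100_ewes: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = []
        for pop, n in self.census_size_post.items():
            if n <= 0:
                bad.append(f"census_size_post[{pop}]={n}")
        for pop, ages in self.supplemented_ewe_ages.items():
            if any(a < 0 for a in ages):
                bad.append(f"supplemented_ewe_ages[{pop}] has negative age")
        if self.years_elapsed < 1:
            bad.append(f"years_elapsed={self.years_elapsed}")
        if self.age_cutoff < 0:
            bad.append(f"age_cutoff={self.age_cutoff}")
        if bad:
            raise ConfigError("invalid config values: " + ", ".join(bad))


# ---------------------------------------------------------------------------
# Genepop


def _parse_allele_pair(token: str, line_no: int) -> tuple[int, int] | None:
    if len(token) == 4:
        width = 2
    elif len(token) == 6:
        width = 3
    else:
        raise ParseError(
            f"line {line_no}: genotype token {token!r} is not 2- or 3-digit encoded"
        )
    try:
        a, b = int(token[:width]), int(token[width:])
    except ValueError:
        raise ParseError(f"line {line_no}: non-numeric genotype token {token!r}") from None
    if a == 0 or b == 0:
        return None
    return (min(a, b), max(a, b))


def read_genepop(path: str | Path) -> dict[str, PopulationSample]:
    """Parse a Genepop file into population samples.

    Accepts both 2- and 3-digit allele encodings; an all-zero token is a
    missing genotype. Population labels are recovered from the shared
    ``label_`` prefix of individual ids when present, else ``pop1``..``popK``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("line 1: empty Genepop file")
    # locus names: either one per line until first 'Pop', or comma-separated
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if not chunk:
            raise ParseError(f"line {i + 1}: blank line in locus header")
        loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"line {len(lines)}: no 'Pop' line found")
    if not loci:
        raise ParseError("line 2: no locus names before first 'Pop'")

    pops: list[list[Individual]] = []
    current: list[Individual] | None = None
    for j in range(i, len(lines)):
        raw = lines[j].strip()
        if not raw:
            continue
        if raw.lower() == "pop":
            current = []
            pops.append(current)
            continue
        if current is None:
            raise ParseError(f"line {j + 1}: individual before first 'Pop'")
        if "," not in raw:
            raise ParseError(f"line {j + 1}: missing comma after individual id")
        ind_id, geno_part = raw.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"line {j + 1}: expected {len(loci)} genotypes, got {len(tokens)}"
            )
        genotype = {
            locus: _parse_allele_pair(tok, j + 1) for locus, tok in zip(loci, tokens)
        }
        current.append(
            Individual(id=ind_id.strip(), population="", genotype=genotype)
        )

    samples: dict[str, PopulationSample] = {}
    for k, inds in enumerate(pops, start=1):
        prefixes = {ind.id.rsplit("_", 1)[0] for ind in inds if "_" in ind.id}
        label = prefixes.pop() if len(prefixes) == 1 else f"pop{k}"
        if label in samples:
            label = f"pop{k}"
        for ind in inds:
            ind.population = label
        samples[label] = PopulationSample(label=label, individuals=inds)
    n_in = sum(len(p) for p in pops)
    logger.info(
        "read_genepop: %s -> %d populations, %d individuals, %d loci (digest %s)",
        path, len(samples), n_in, len(loci), file_digest(path),
    )
    return samples


def write_genepop(
    path: str | Path,
    samples: Mapping[str, PopulationSample],
    title: str = "rescue-eval genotypes",
) -> None:
    """Write samples as a 3-digit Genepop file (missing = ``000000``)."""
    samples = dict(samples)
    loci = next(iter(samples.values())).loci
    out = [title]
    out.extend(loci)
    for label, sample in samples.items():
        out.append("Pop")
        for ind in sample.individuals:
            toks = []
            for locus in loci:
                pair = ind.genotype.get(locus)
                toks.append("000000" if pair is None else f"{pair[0]:03d}{pair[1]:03d}")
            out.append(f"{ind.id}, " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into id -> uppercase sequence; enforce alignment."""
    records: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ParseError(
                f"sequence {rec.id!r} length {len(seq)} != alignment length {length}"
            )
        records[rec.id] = seq
    return records


def write_fasta_alignment(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Metadata sidecar CSV

METADATA_COLUMNS = ["id", "population", "sex", "age", "mt_haplotype"]


def read_metadata(path: str | Path) -> dict[str, dict]:
    """Read the sidecar CSV into id -> {population, sex, age, mt_haplotype}."""
    meta: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(METADATA_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise ParseError(f"metadata missing columns: {sorted(missing_cols)}")
        for row in reader:
            age = row["age"].strip()
            hap = row["mt_haplotype"].strip()
            meta[row["id"]] = {
                "population": row["population"],
                "sex": row["sex"] or "unknown",
                "age": int(age) if age else None,
                "mt_haplotype": hap or None,
            }
    return meta


def write_metadata(path: str | Path, individuals: Iterable[Individual]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for ind in individuals:
            writer.writerow(
                [
                    ind.id,
                    ind.population,
                    ind.sex,
                    "" if ind.age is None else ind.age,
                    ind.mt_haplotype or "",
                ]
            )


def attach_metadata(
    samples: Mapping[str, PopulationSample], meta: Mapping[str, dict]
) -> None:
    """Fill sex/age/haplotype on individuals in place from the sidecar table."""
    for sample in samples.values():
        for ind in sample.individuals:
            row = meta.get(ind.id)
            if row is None:
                continue
            ind.sex = row["sex"]
            ind.age = row["age"]
            ind.mt_haplotype = row["mt_haplotype"]


# ---------------------------------------------------------------------------
# Config


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML run configuration, applying defaults and validating."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {
        "census_size_post",
        "supplemented_ewe_ages",
        "years_elapsed",
        "age_cutoff",
        "rng_seed",
        "genotypes_path",
        "sequences_path",
        "metadata_path",
        "baseline_lambs_per_100_ewes",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        cfg = StudyConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    logger.info("load_config: %s -> %s", path, cfg)
    return cfg


def file_digest(path: str | Path) -> str:
    """Short SHA-256 digest of a file, for provenance logging."""
    h = hashlib.sha256(Path(path).read_bytes())
    return h.hexdigest()[:12]
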