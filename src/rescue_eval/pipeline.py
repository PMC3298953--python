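"""End-to-end evaluation: simulate -> classify -> diversity -> demography -> report.

The report mirrors how a supplementation experiment is read: a hybrid census
per treatment population, a diversity block (microsatellite and mtDNA),
a classifier power block, and a demography block ending in the
lamb-survival interval and its baseline verdict.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import demography as dem
from . import diversity as div
from . import hybrid_model as hm
from . import mtdna
from . import synthetic_data as sd
from .formats_io import StudyConfig, logger


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


# rounding conventions for the human-readable report: diversity metrics to 3
# decimals, demography quantities to 1 decimal
def _r3(x):
    return None if x is None else round(float(x), 3)


def _r1(x):
    return None if x is None else round(float(x), 1)


def run_pipeline(
    config: StudyConfig,
    spec: sd.GeneratorSpec | None = None,
    settings: hm.McmcSettings | None = None,
    n_demography_runs: int = 10_000,
    hybrid_proportion_override: float | None = None,
) -> dict:
    """Run the full evaluation on a generated study and return the report.

    ``hybrid_proportion_override`` lets a known census proportion feed the
    demography block directly (e.g. when replaying published arithmetic)
    instead of the classifier's estimate.
    """
    spec = spec or sd.GeneratorSpec(seed=config.rng_seed)
    settings = settings or hm.McmcSettings(
        burn_in=1000, sweeps=5000, n_chains=2, seeds=[11, 223]
    )
    report: dict = {
        "provenance": {
            "rng_seed": config.rng_seed,
            "generator_seed": spec.seed,
            "mcmc": {
                "burn_in": settings.burn_in,
                "sweeps": settings.sweeps,
                "n_chains": settings.n_chains,
            },
        }
    }

    try:
        study = sd.build_study(spec)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc

    # --- mtDNA stage
    try:
        populations = {
            ind.id: s.label
            for s in study.samples.values()
            for ind in s.individuals
        }
        table = mtdna.collapse_haplotypes(
            study.sequences,
            populations,
            baseline_populations={study.resident_pre.label, study.source.label},
        )
        mt_summary = mtdna.diversity_summary(table)
        source_private = {
            h for h, p in table.private_to.items() if p == study.source.label
        }
        # haplotype labels must come from the collapse, not the sidecar: the
        # collapse relabels by frequency rank
        for s in study.samples.values():
            for ind in s.individuals:
                ind.mt_haplotype = table.assignments.get(ind.id)
        report["mtdna"] = {
            "n_haplotypes": table.n_haplotypes,
            "n_variable_sites": len(table.variable_sites),
            "source_private_haplotypes": sorted(source_private),
            "per_population": [
                {
                    "population": row["population"],
                    "n": int(row["n"]),
                    "n_haplotypes": int(row["n_haplotypes"]),
                    "H_D": _r3(row["H_D"]),
                    "k": _r3(row["k"]),
                }
                for row in mt_summary.to_dict("records")
            ],
        }
    except Exception as exc:
        raise StageError(f"mtdna: {exc}") from exc

    # --- classification stage
    try:
        hybrid_zero = sum(
            v for k, v in spec.hybrid_composition.items() if k != "pure_sup"
        ) == 0
        posteriors, diags = hm.run_gibbs(
            study.post, study.resident_pre, study.source, settings
        )
        updated, census = hm.apply_mtdna_override(
            posteriors,
            study.post.individuals,
            source_private,
            age_cutoff=config.age_cutoff,
        )
        report["hybrid_census"] = {
            study.post.label: {
                "n_sampled": census["n_sampled"],
                "n_excluded": census["n_excluded"],
                "n_hybrids": census["n_hybrids"],
                "denominator": census["denominator"],
                "proportion": _r3(census["proportion"]),
                "diagnostics": diags,
            }
        }
    except Exception as exc:
        raise StageError(f"classify: {exc}") from exc

    # --- diversity stage
    try:
        pair = {
            study.resident_pre.label: study.resident_pre,
            study.post.label: study.post,
        }
        table2 = div.diversity_table(study.samples)
        pre_label, post_label = study.resident_pre.label, study.post.label
        comp_table = div.diversity_table(pair)
        comparisons = {}
        for metric in ("H_E", "A_R"):
            pre_vals = comp_table[comp_table.population == pre_label].sort_values("locus")[metric]
            post_vals = comp_table[comp_table.population == post_label].sort_values("locus")[metric]
            t, df_, p = div.paired_t_across_loci(
                pre_vals.to_numpy(dtype=float), post_vals.to_numpy(dtype=float)
            )
            comparisons[metric] = {"t": _r3(t), "df": df_, "p": _r3(p)}
        # pooled pre+post reference frequencies: per-sample references would
        # differ by a sample-size artifact rather than by actual kinship
        pooled: dict[str, dict[int, float]] = {}
        for locus in study.resident_pre.loci:
            counts: dict[int, int] = {}
            for s in pair.values():
                for a, c in s.allele_counts(locus).items():
                    counts[a] = counts.get(a, 0) + c
            tot = sum(counts.values())
            pooled[locus] = {a: c / tot for a, c in counts.items()}
        rel = {
            label: div.pairwise_relatedness(
                s, reference_frequencies=pooled, n_bootstrap=999,
                seed=config.rng_seed,
            )
            for label, s in pair.items()
        }
        report["diversity"] = {
            "per_population": [
                {
                    "population": label,
                    "mean_H_O": _r3(grp["H_O"].mean()),
                    "mean_H_E": _r3(grp["H_E"].mean()),
                    "mean_A_R": _r3(grp["A_R"].mean()),
                }
                for label, grp in table2.groupby("population")
            ],
            "paired_tests_pre_vs_post": comparisons,
            "relatedness": {
                label: {
                    "mean": _r3(r["mean"]),
                    "ci_low": _r3(r["ci_low"]),
                    "ci_high": _r3(r["ci_high"]),
                }
                for label, r in rel.items()
            },
        }
    except Exception as exc:
        raise StageError(f"diversity: {exc}") from exc

    # --- demography stage
    try:
        proportion = (
            hybrid_proportion_override
            if hybrid_proportion_override is not None
            else census["proportion"]
        )
        if hybrid_zero and not hybrid_proportion_override:
            report["demography"] = {
                "skipped": "no hybrids in composition; nothing to bound"
            }
        else:
            params = dem.DemographicParams()
            lam, _vec, stable_prop = dem.stable_age_distribution(
                dem.build_leslie(params), age_cutoff=config.age_cutoff
            )
            blocks = {}
            for pop, census_size in config.census_size_post.items():
                adj = dem.adjusted_population_size(census_size, stable_prop)
                e, lo, hi = dem.expected_hybrids(proportion, round(adj))
                ages = config.supplemented_ewe_ages.get(pop)
                block = {
                    "stable_age_proportion": _r3(stable_prop),
                    "lambda": _r3(lam),
                    "adjusted_size": round(adj),
                    "expected_hybrids": _r1(e),
                    "window": [_r1(lo), _r1(hi)],
                }
                if ages:
                    ensemble = dem.run_ensemble(
                        ages,
                        params,
                        n_runs=n_demography_runs,
                        years=config.years_elapsed,
                        age_cutoff=config.age_cutoff,
                        seed=config.rng_seed,
                    )
                    interval = dem.infer_lamb_survival(ensemble, (lo, hi))
                    block["lamb_survival"] = {
                        "mean": _r3(interval.mean),
                        "sd": _r3(interval.sd),
                        "interval": [_r3(interval.lower), _r3(interval.upper)],
                        "n_accepted": interval.n_accepted,
                    }
                    baselines = config.baseline_lambs_per_100_ewes.get(pop)
                    if baselines:
                        verdict = dem.compare_to_baseline(interval, baselines)
                        block["baseline_verdict"] = verdict["verdict"]
                blocks[pop] = block
            report["demography"] = blocks
    except Exception as exc:
        raise StageError(f"demography: {exc}") from exc

    return report


def run_power(
    spec: sd.GeneratorSpec | None = None,
    n_per_class: int = 1000,
    settings: hm.McmcSettings | None = None,
    seed: int = 0,
):
    """Power block: classifier error rates on simulated known hybrids."""
    spec = spec or sd.GeneratorSpec(seed=seed)
    study = sd.build_study(spec)
    return hm.power_simulation(
        study.resident_pre, study.source, n_per_class=n_per_class,
        settings=settings, seed=seed,
    )


def write_report(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", path)


# ---------------------------------------------------------------------------
# Report schema (hand-rolled check; docs/report.schema.json mirrors this)

REQUIRED_SECTIONS = {
    "provenance": dict,
    "mtdna": dict,
    "hybrid_census": dict,
    "diversity": dict,
    "demography": dict,
}


def validate_report(report: dict) -> list[str]:
    """Return a list of schema violations (empty when the report is valid)."""
    problems = []
    for key, typ in REQUIRED_SECTIONS.items():
        if key not in report:
            problems.append(f"missing section {key!r}")
        elif not isinstance(report[key], typ):
            problems.append(f"section {key!r} is not a {typ.__name__}")
    for pop, block in report.get("hybrid_census", {}).items():
        for field in ("n_sampled", "n_hybrids", "denominator", "proportion"):
            if field not in block:
                problems.append(f"hybrid_census[{pop}] missing {field!r}")
    return problems


def make_figures(report: dict, ensemble, outdir: str | Path) -> list[str]:
    """Diagnostic figures: survival-vs-count scatter and the interval chart."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if ensemble:
        draws = [r.lamb_survival_draw for r in ensemble]
        counts = [r.final_count for r in ensemble]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(draws, counts, s=4, alpha=0.3)
        ax.set_xlabel("lamb survival draw")
        ax.set_ylabel("descendants ≤ cutoff age")
        path = outdir / "survival_vs_count.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    else:
        logger.warning("make_figures: empty ensemble, no scatter produced")
    rel = report.get("diversity", {}).get("relatedness")
    if rel:
        fig, ax = plt.subplots(figsize=(5, 4))
        labels = list(rel)
        means = [rel[l]["mean"] for l in labels]
        err = [
            [rel[l]["mean"] - rel[l]["ci_low"] for l in labels],
            [rel[l]["ci_high"] - rel[l]["mean"] for l in labels],
        ]
        ax.errorbar(labels, means, yerr=err, fmt="o", capsize=4)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("mean pairwise relatedness")
        path = outdir / "relatedness_pre_post.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
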