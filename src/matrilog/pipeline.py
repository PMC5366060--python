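"""End-to-end orchestration: inputs -> haplotypes -> classes -> spatial -> divergence.

``run_pipeline`` composes the analysis stages on a FASTA alignment plus
metadata table and writes every tabular output with a header recording the
seed and a hash of the configuration, so two runs with identical configs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from matrilog import classify, divergence, haplotypes, seq_io, spatial
from matrilog._version import __version__ as _version

logger = logging.getLogger("matrilog")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    fasta: str
    metadata: str
    out_dir: str
    delimiter: str | None = None
    unknown_sex_token: str | None = None
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_reps: int = 9999
    seed: int = 1
    schemes: tuple[str, ...] = ("omh", "sh", "combined")
    metric: str = "haversine"
    global_correction: bool = False
    make_plot: bool = False

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (file paths excluded)."""
        payload = asdict(self)
        for key in ("fasta", "metadata", "out_dir"):
            payload.pop(key, None)
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all outputs under ``config.out_dir``.

    Returns a dict with the in-memory results (haplotype table, class table,
    sex-ratio tests, clustering and elevation tables, divergence records and
    histogram, summary dict) and the paths written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"matrilog {_version}",
        f"seed={config.seed}",
        f"config_hash={config.config_hash()}",
    ]

    aln = _stage("read_alignment")(seq_io.read_alignment)(config.fasta)
    records = _stage("read_metadata")(seq_io.read_metadata)(
        config.metadata, aln, delimiter=config.delimiter,
        unknown_sex_token=config.unknown_sex_token,
    )
    logger.info("loaded %d sequences, %d individuals", aln.n, len(records))

    hap_table = _stage("collapse_haplotypes")(haplotypes.collapse_haplotypes)(aln)
    logger.info("%d unique haplotypes, %d segregating sites", hap_table.n_hap, hap_table.s_sites)
    haplotypes.write_haplotype_table(hap_table, out / "haplotypes.tsv", header)

    assemblages = _stage("build_assemblages")(classify.build_assemblages)(records, hap_table)
    class_table = _stage("classify_all")(classify.classify_all)(assemblages)
    seq_io.write_table(class_table, out / "log_classes.tsv", header)
    class_summary = classify.summarize_classes(class_table)
    logger.info("classes: %s", class_summary)

    sex_rows = []
    for label, classes in (("MF", ["MF"]), ("OMH", ["OMH"]), ("multi_haplotype", ["MF", "OMH"])):
        try:
            r = classify.sex_ratio_for_classes(assemblages, class_table, classes)
        except ValueError:
            continue
        sex_rows.append(
            {
                "group": label,
                "n_female": r.n_female,
                "n_male": r.n_male,
                "pct_female": r.pct_female,
                "chi2": round(r.chi2, 3),
                "df": r.df,
                "p": round(r.p, 4),
            }
        )
    sex_table = pd.DataFrame(sex_rows)
    seq_io.write_table(sex_table, out / "sex_ratio.tsv", header)

    cluster_table = _stage("run_clustering_suite")(spatial.run_clustering_suite)(
        class_table,
        k_values=config.k_values,
        schemes=config.schemes,
        n_reps=config.n_reps,
        seed=config.seed,
        metric=config.metric,
        global_correction=config.global_correction,
    )
    seq_io.write_table(cluster_table, out / "clustering.tsv", header)

    elev_table = _stage("elevation_tests")(spatial.elevation_tests)(class_table, config.schemes)
    seq_io.write_table(elev_table.round(4), out / "elevation.tsv", header)

    diff_records = _stage("within_log_pairs")(divergence.within_log_pairs)(assemblages, hap_table)
    divergence.write_records(diff_records, out / "diff_records.tsv", header)
    hist = _stage("build_histogram")(divergence.build_histogram)(diff_records) if diff_records else None
    compare = None
    if hist is not None:
        divergence.write_histogram(hist, out / "diff_histogram.tsv", header)
        if config.make_plot:
            divergence.plot_histogram(hist, out / "diff_histogram.png")
        try:
            compare = divergence.compare_distributions(diff_records)
        except ValueError:
            compare = None

    max_diff = max((r.n_diff for r in diff_records), default=0)
    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_individuals": len(records),
        "alignment_length": hap_table.length,
        "gc_percent": hap_table.gc_percent,
        "s_sites": hap_table.s_sites,
        "n_haplotypes": hap_table.n_hap,
        **class_summary,
        "n_within_log_pairs": len(diff_records),
        "max_within_log_diff": max_diff,
        "max_within_log_divergence_pct": haplotypes.percent_divergence(max_diff, hap_table.length),
        "fraction_pairs_le2": round(hist.fraction_le2, 3) if hist else None,
        "ambiguous_fraction_mf": (
            round(hist.ambiguous_fraction_mf, 3)
            if hist and hist.ambiguous_fraction_mf is not None
            else None
        ),
        "mf_vs_omh_paired_t": (
            {"t": round(compare.t, 3), "df": compare.df, "p": round(compare.p, 4)}
            if compare
            else None
        ),
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "haplotype_table": hap_table,
        "assemblages": assemblages,
        "class_table": class_table,
        "class_summary": class_summary,
        "sex_ratio": sex_table,
        "clustering": cluster_table,
        "elevation": elev_table,
        "diff_records": diff_records,
        "histogram": hist,
        "compare": compare,
        "summary": summary,
        "out_dir": out,
    }
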