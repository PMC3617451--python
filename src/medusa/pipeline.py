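"""Pipeline orchestration: validated run configuration and staged execution.

A run is fully described by a :class:`RunConfig`; every output file starts
with commented ``#key=value`` header lines carrying all parameters and the
config hash, so a rerun with the same config and inputs is bit-identical
and self-documenting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import bisulfite_validate as bv
from . import coverage_qc as qc
from . import dmr_core, fragments_io, lengthnorm
from .genome import read_chrom_sizes

__all__ = ["RunConfig", "run_pipeline", "write_tsv_with_header"]


@dataclass
class RunConfig:
    """Every tunable of every stage, with the pipeline defaults."""

    min_score: int = 10  # alignment-score threshold (pair kept if either read reaches it)
    length_bin_width: int = 5  # bp, fragment-length histogram bins
    length_normalize: bool = True
    window: int = 500  # bp, DMR test windows
    depth_threshold: int = 10  # combined depth across all samples
    max_fdr: float = 0.05
    max_gap_windows: int = 1
    dispersion_sharing: str = "maximum"  # maximum | fit-only
    pseudo_count: float = 0.5  # fold-change display only
    qc_window: int = 500
    qc_step: int = 250
    qc_min_reads: int = 5
    min_depth: int = 10  # bisulfite CpG depth filter
    min_cpgs: int = 10  # CpGs required per DMR for validation
    n_perm: int = 1000
    asym_p_threshold: float = 0.01
    asym_min_fraction: float = 0.8
    priority: tuple[str, ...] = ("cpg_island", "promoter", "exon", "intron")
    max_upstream: int = 10_000
    max_downstream: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.qc_window < 1:
            raise ValueError("window sizes must be >= 1")
        if self.qc_step > self.qc_window:
            raise ValueError("qc_step > qc_window would leave gaps")
        if not 0 < self.max_fdr <= 1:
            raise ValueError("max_fdr must lie in (0, 1]")
        if self.min_score < 0 or self.depth_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.dispersion_sharing not in ("maximum", "fit-only"):
            raise ValueError("dispersion_sharing must be 'maximum' or 'fit-only'")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "priority" in data:
            data["priority"] = tuple(data["priority"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["priority"] = list(d["priority"])
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_tsv_with_header(df: pd.DataFrame, path: str, config: RunConfig, stage: str) -> None:
    """TSV with '#key=value' comment headers (config hash included)."""
    with open(path, "w") as fh:
        fh.write(f"#stage={stage}\n")
        fh.write(f"#config_hash={config.config_hash}\n")
        for key, value in sorted(config.to_dict().items()):
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: RunConfig,
    cohort_a_beds: list[str],
    cohort_b_beds: list[str],
    genome_path: str,
    outdir: str,
    feature_beds: dict[str, str] | None = None,
    genes_path: str | None = None,
    bisulfite_a: str | None = None,
    bisulfite_b: str | None = None,
    repeats_path: str | None = None,
    lmr_path: str | None = None,
) -> dict:
    """Execute the staged analysis and write artifacts under ``outdir``.

    Stages: read fragments -> length normalisation -> replicate QC ->
    window testing and DMR merging -> annotation (when features given) ->
    bisulfite Δms validation and LMR overlap (when references given).
    Returns a dict of in-memory results keyed by stage.
    """
    os.makedirs(outdir, exist_ok=True)
    genome = read_chrom_sizes(genome_path)
    out: dict = {"config_hash": config.config_hash}

    try:
        fragsets_a = [
            fragments_io.read_bed(p, genome, cohort_label="A") for p in cohort_a_beds
        ]
        fragsets_b = [
            fragments_io.read_bed(p, genome, cohort_label="B") for p in cohort_b_beds
        ]
    except ValueError as exc:
        raise RuntimeError(f"stage 'read': {exc}") from exc

    if config.length_normalize and len(fragsets_a) + len(fragsets_b) >= 2:
        try:
            normed = lengthnorm.equalize_lengths(
                fragsets_a + fragsets_b,
                bin_width=config.length_bin_width,
                seed=config.seed,
            )
        except ValueError as exc:
            raise RuntimeError(f"stage 'lengthnorm': {exc}") from exc
        fragsets_a = normed[: len(fragsets_a)]
        fragsets_b = normed[len(fragsets_a):]

    qc_rows = []
    for group in (fragsets_a, fragsets_b):
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                r = qc.replicate_correlation(
                    group[i], group[j], genome,
                    window=config.qc_window, step=config.qc_step,
                    min_reads=config.qc_min_reads,
                )
                qc_rows.append(
                    {"sample_1": group[i].sample_id, "sample_2": group[j].sample_id,
                     "cohort": group[i].cohort_label,
                     "pearson_r": r if r is not None else float("nan")}
                )
    qc_df = pd.DataFrame(qc_rows, columns=["sample_1", "sample_2", "cohort", "pearson_r"])
    write_tsv_with_header(qc_df, os.path.join(outdir, "qc_correlations.tsv"), config, "qc")
    out["qc"] = qc_df

    try:
        dmrs, window_results = dmr_core.call_dmrs(
            fragsets_a, fragsets_b, genome,
            window=config.window,
            depth_threshold=config.depth_threshold,
            max_fdr=config.max_fdr,
            max_gap_windows=config.max_gap_windows,
            sharing=config.dispersion_sharing,
        )
    except ValueError as exc:
        raise RuntimeError(f"stage 'dmr': {exc}") from exc
    dmr_df = dmr_core.dmrs_to_dataframe(dmrs)
    asym_rows = []
    hyper_sets = {"hyper": fragsets_b, "hypo": fragsets_a}
    for d in dmrs:
        frac, p, flag = dmr_core.strand_asymmetry(
            d, hyper_sets[d.direction],
            p_threshold=config.asym_p_threshold,
            min_fraction=config.asym_min_fraction,
        )
        asym_rows.append(
            {"forward_fraction": frac if frac is not None else float("nan"),
             "strand_p": p if p is not None else float("nan"),
             "asym_flag": flag}
        )
    if asym_rows:
        dmr_df = pd.concat([dmr_df, pd.DataFrame(asym_rows)], axis=1)
    write_tsv_with_header(dmr_df, os.path.join(outdir, "dmrs.tsv"), config, "dmr")
    write_tsv_with_header(
        window_results, os.path.join(outdir, "windows.tsv"), config, "dmr"
    )
    out["dmrs"] = dmrs
    out["dmr_table"] = dmr_df
    out["windows"] = window_results

    if feature_beds:
        try:
            feature_sets = {
                name: annotate_mod.load_features(path, name)
                for name, path in feature_beds.items()
            }
            genes = annotate_mod.load_features(genes_path, "gene") if genes_path else None
            annot = annotate_mod.annotate_dmrs(
                dmrs, feature_sets, genes=genes,
                priority=config.priority,
                max_upstream=config.max_upstream,
                max_downstream=config.max_downstream,
            )
        except ValueError as exc:
            raise RuntimeError(f"stage 'annotate': {exc}") from exc
        write_tsv_with_header(
            annot, os.path.join(outdir, "dmrs_annotated.tsv"), config, "annotate"
        )
        out["annotation"] = annot

    if bisulfite_a and bisulfite_b:
        try:
            calls_a = bv.filter_depth(bv.read_cpg_calls(bisulfite_a), config.min_depth)
            calls_b = bv.filter_depth(bv.read_cpg_calls(bisulfite_b), config.min_depth)
            repeats = (
                annotate_mod.load_features(repeats_path, "simple_repeat")
                if repeats_path
                else None
            )
            merged = calls_a.table.merge(calls_b.table, on=["chrom", "pos"], suffixes=("_a", "_b"))
            norm_a, norm_b = bv.quantile_normalize(
                (merged["meth_a"] / merged["total_a"]).values,
                (merged["meth_b"] / merged["total_b"]).values,
            )
            shared_a = bv.CpGCallSet(
                merged[["chrom", "pos"]].assign(meth=merged["meth_a"], total=merged["total_a"], score=norm_a)
            )
            shared_b = bv.CpGCallSet(
                merged[["chrom", "pos"]].assign(meth=merged["meth_b"], total=merged["total_b"], score=norm_b)
            )
            eligible = bv.dmr_validation_filter(dmrs, shared_a, repeats, config.min_cpgs)
            deltas = [bv.delta_ms(d, shared_a, shared_b) for d in eligible]
            summary = bv.concordance(deltas)
        except ValueError as exc:
            raise RuntimeError(f"stage 'validate': {exc}") from exc
        delta_df = pd.DataFrame(
            [
                {"chrom": r.dmr.chrom, "start": r.dmr.start, "end": r.dmr.end,
                 "direction": r.dmr.direction, "n_cpgs": r.n_cpgs,
                 "delta_ms": r.delta_ms, "supported": r.supported}
                for r in deltas
            ],
            columns=["chrom", "start", "end", "direction", "n_cpgs", "delta_ms", "supported"],
        )
        write_tsv_with_header(
            delta_df, os.path.join(outdir, "validation_delta_ms.tsv"), config, "validate"
        )
        out["validation"] = summary
        out["delta_table"] = delta_df

    if lmr_path:
        try:
            lmrs = annotate_mod.load_features(lmr_path, "LMR")
            observed, expected, ratio = bv.oe_overlap(dmrs, lmrs, genome)

            def null_ratio(rng):
                regions = bv.random_regions(
                    genome, n=max(len(dmrs), 1), size=config.window, rng=rng
                )
                _, _, r = bv.oe_overlap(regions, lmrs, genome)
                return r if r is not None else 0.0

            p = bv.permutation_pvalue(
                ratio if ratio is not None else 0.0,
                null_ratio, n_perm=config.n_perm, tail="ge", seed=config.seed,
            )
        except ValueError as exc:
            raise RuntimeError(f"stage 'overlap': {exc}") from exc
        oe_df = pd.DataFrame(
            [{"observed_bp": observed, "expected_bp": expected,
              "oe_ratio": ratio, "empirical_p": p}]
        )
        write_tsv_with_header(oe_df, os.path.join(outdir, "lmr_overlap.tsv"), config, "overlap")
        out["overlap"] = oe_df

    with open(os.path.join(outdir, "run_log.yaml"), "w") as fh:
        yaml.safe_dump(
            {"config": self_config_dict(config), "inputs": {
                "cohort_a": list(cohort_a_beds), "cohort_b": list(cohort_b_beds),
                "genome": genome_path,
            }},
            fh, sort_keys=True,
        )
    return out


def self_config_dict(config: RunConfig) -> dict:
    d = config.to_dict()
    d["config_hash"] = config.config_hash
    return d
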