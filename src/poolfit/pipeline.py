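"""End-to-end orchestration: scans -> normalize -> tag statistics -> calls
-> clustering -> enrichment, driven by a single declarative config.

Every stage is a pure function of its inputs and the config, so rerunning
a pipeline with the same inputs and seed reproduces every output file
bit for bit; a JSON manifest (config hash, seed, package/library versions)
accompanies each run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calls as calls_mod
from . import cluster as cluster_mod
from . import enrich as enrich_mod
from . import formats, normalize, tagstats
from .errors import PoolfitError


@dataclass
class PipelineConfig:
    key: str = ""
    scans: list[str] = field(default_factory=list)
    gmt: str = ""
    output_dir: str = "poolfit_out"
    mode: str = "homozygous"  # thresholding regime
    loess_span: float = 0.3
    loess_iterations: int = 3
    target_fpr: float = 0.05
    min_fraction: float = 0.40
    fold_threshold_log2: float = 1.0
    min_timepoints: int = 3
    call_mode: str = "any"  # any | sequential
    value_scale: str = "z"  # z | m
    filter_mode: str = "any_change"  # any_change | half_significant
    filter_level: float = 1.0
    filter_frac: float = 0.5
    report_cutoff: float = 0.01
    bonferroni_m: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.loess_span <= 1.0, "loess_span must be in (0, 1]"),
            (self.loess_iterations >= 0, "loess_iterations must be >= 0"),
            (0.0 <= self.target_fpr <= 1.0, "target_fpr must be in [0, 1]"),
            (0.0 <= self.min_fraction <= 1.0, "min_fraction must be in [0, 1]"),
            (self.fold_threshold_log2 > 0, "fold_threshold_log2 must be positive"),
            (self.min_timepoints >= 1, "min_timepoints must be >= 1"),
            (self.call_mode in ("any", "sequential"), "call_mode must be any|sequential"),
            (self.value_scale in ("z", "m"), "value_scale must be z|m"),
            (self.mode in ("homozygous", "heterozygous"), "mode must be homozygous|heterozygous"),
            (
                self.filter_mode in ("any_change", "half_significant"),
                "filter_mode must be any_change|half_significant",
            ),
            (0.0 < self.report_cutoff <= 1.0, "report_cutoff must be in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise PoolfitError(f"invalid config: {msg}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PoolfitError(f"unknown config key: {sorted(unknown)[0]!r}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PoolfitError("config file must contain a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_scans(paths) -> dict[int, pd.DataFrame]:
    scans: dict[int, pd.DataFrame] = {}
    for path in paths:
        df = formats.read_scan_table(path)
        for day, sub in df.groupby("day"):
            if day in scans:
                raise PoolfitError(f"day {day} appears in more than one scan file")
            scans[int(day)] = sub.reset_index(drop=True)
    if not scans:
        raise PoolfitError("no scan tables given")
    return dict(sorted(scans.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the artifact bundle.

    Returns a dict with the in-memory results (fitness matrix, calls per
    mode, enrichment tables, QC report, manifest).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                log(f"stage {name}: start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(f"stage {name}: FAILED: {exc}")
                    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
                    raise PoolfitError(f"stage {name!r} failed: {exc}") from exc
                log(f"stage {name}: done")

        return _Ctx()

    key = formats.read_key(config.key)
    scans = _load_scans(config.scans)
    log(f"inputs: {len(key)} strains in key, days {sorted(scans)}")

    with _stage("normalize"):
        normalized = normalize.normalize_all(
            scans, key=key, span=config.loess_span, iterations=config.loess_iterations
        )

    with _stage("tagstats"):
        matrix, tag_matrix = tagstats.build_fitness_matrix(
            normalized,
            key,
            mode=config.mode,
            target_fpr=config.target_fpr,
            min_fraction=config.min_fraction,
            value_scale=config.value_scale,
        )
        qc = tag_matrix.qc_report()
        formats.write_results_table(qc, out_dir / "qc_report.tsv")
        matrix.to_csv(out_dir / "fitness_matrix.tsv", sep="\t", lineterminator="\n")

    gene_of = key.set_index("strain_id")["gene"]

    with _stage("calls"):
        call_tables: dict[str, pd.DataFrame] = {}
        for mode in ("any", "sequential"):
            calls = calls_mod.classify_matrix(
                matrix,
                fold_threshold_log2=config.fold_threshold_log2,
                min_timepoints=config.min_timepoints,
                mode=mode,
            )
            calls.insert(1, "gene", gene_of.reindex(calls["strain_id"]).to_numpy())
            call_tables[mode] = calls
            for direction in ("depleted", "enriched"):
                sub = calls[calls["direction"] == direction]
                formats.write_results_table(
                    sub, out_dir / f"calls_{direction}_{mode}.tsv"
                )
        summary = calls_mod.summarize_calls(call_tables[config.call_mode], key)
        formats.write_results_table(summary, out_dir / "call_summary.tsv")

    with _stage("cluster"):
        filtered = cluster_mod.filter_rows(
            matrix,
            mode=config.filter_mode,
            level=config.filter_level,
            frac=config.filter_frac,
        )
        if len(filtered) >= 2:
            tree = cluster_mod.average_linkage(filtered)
            formats.write_cdt_gtr(
                filtered,
                tree,
                out_dir / "clustered.cdt",
                out_dir / "clustered.gtr",
                gene_names=gene_of.reindex(filtered.index),
            )
            log(f"clustered {len(filtered)} filtered profiles")
        else:
            tree = None
            log("fewer than 2 profiles pass the filter; clustering skipped")

    enrichments: dict[str, pd.DataFrame] = {}
    if config.gmt:
        with _stage("enrich"):
            genesets = formats.read_gmt(config.gmt)
            present = matrix.notna().any(axis=1)
            universe = set(gene_of.reindex(matrix.index[present]))
            calls = call_tables[config.call_mode]
            for direction in ("depleted", "enriched"):
                hits = set(
                    calls.loc[calls["direction"] == direction, "gene"]
                ) & universe
                res = enrich_mod.enrich_categories(
                    hits,
                    universe,
                    genesets,
                    report_cutoff=config.report_cutoff,
                    m_override=config.bonferroni_m,
                )
                enrichments[direction] = res
                formats.write_results_table(
                    res, out_dir / f"enrichment_{direction}.tsv"
                )

    manifest = {
        "package": "poolfit",
        "config_digest": config.digest(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "versions": _versions(),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "matrix": matrix,
        "tag_matrix": tag_matrix,
        "calls": call_tables,
        "tree": tree,
        "enrichments": enrichments,
        "qc": qc,
        "manifest": manifest,
    }


def _versions() -> dict[str, str]:
    import numpy
    import scipy
    import sklearn

    from . import __version__

    return {
        "poolfit": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
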