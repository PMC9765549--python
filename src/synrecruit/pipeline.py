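"""Pipeline configuration and stage orchestration.

Stages run in the order assign -> profile -> filter -> cluster -> envtest,
with growth fitting independent of the recruitment branch.  Every run writes
its outputs together with a ``manifest.json`` recording inputs, thresholds,
seed and package version, so a run can be reproduced from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, community, io
from .errors import ConfigurationError, SynrecruitError
from .recruitment import Thresholds, assign_all, pass1_retained_reads

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and statistical settings for a full run."""

    taxonomy: Optional[str] = None
    pass1_hits: dict[str, str] = field(default_factory=dict)   # station -> path
    pass2_hits: dict[str, str] = field(default_factory=dict)
    station_meta: Optional[str] = None
    growth_curves: Optional[str] = None
    outdir: str = "synrecruit_out"

    thresholds: Thresholds = field(default_factory=Thresholds)
    min_density: float = 600.0      # reads/Mbp station floor
    k: Optional[int] = 9            # dendrogram cut (cluster count)
    cut_height: Optional[float] = None
    env_variables: tuple[str, ...] = ("temperature_C", "salinity_psu")
    adjust: str = "holm"
    alpha: float = 0.05
    n_bootstrap: int = 1000
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.thresholds.validate()
        if self.min_density < 0:
            raise ConfigurationError("min_density must be non-negative")
        if self.k is not None and self.cut_height is not None:
            raise ConfigurationError("set only one of k and cut_height")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        thresholds = Thresholds(**data.pop("thresholds", {}))
        cfg = cls(thresholds=thresholds, **data)
        return cfg.validate()

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["version"] = __version__
        return d


class StageError(SynrecruitError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SynrecruitError as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


@_stage("assign")
def run_assign(config: PipelineConfig, tree, station: str):
    stats1, stats2 = io.HitReadStats(), io.HitReadStats()
    pass1 = io.read_hit_table(config.pass1_hits[station], stats=stats1)
    retained = pass1_retained_reads(pass1, tree, config.thresholds)
    pass2 = io.read_hit_table(config.pass2_hits[station], stats=stats2)
    assignments, log = assign_all(retained, pass2, tree, config.thresholds)
    log.malformed_rows += stats1.malformed + stats2.malformed
    logger.info("station %s: %s", station, log.as_dict())
    return assignments, log


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write all outputs under ``outdir``.

    Returns a result bundle with the in-memory tables keyed by stage name.
    Any stage failure aborts with a stage-labelled error; outputs written so
    far are renamed with a ``.partial`` suffix.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {"logs": {}}

    def emit(name: str, writer, *args) -> Path:
        path = outdir / name
        writer(*args, path)
        written.append(path)
        return path

    try:
        if config.taxonomy is None:
            raise ConfigurationError("a taxonomy file is required")
        tree = io.read_taxonomy(config.taxonomy)

        # assign + profile
        rows = []
        for station in sorted(config.pass1_hits):
            if station not in config.pass2_hits:
                raise StageError(
                    "assign", ConfigurationError(f"no pass-2 hits for {station}")
                )
            assignments, log = run_assign(config, tree, station)
            results["logs"][station] = log.as_dict()
            rows.append(community.aggregate_by_clade(assignments, tree, station))
        counts = community.build_count_table(rows)
        results["counts"] = counts
        emit("clade_counts.tsv", io.write_count_table, counts)

        normalized = community.length_normalize(counts, tree)
        filtered, removed = community.filter_stations(normalized, config.min_density)
        results["normalized"] = normalized
        results["removed_stations"] = removed
        emit("clade_counts_per_mbp.tsv", io.write_count_table, normalized)

        profiles = community.relative_abundance(filtered)
        results["profiles"] = profiles
        emit("profiles.tsv", io.write_count_table, profiles)

        # cluster
        if len(profiles) >= 2:
            dist = community.bray_curtis(profiles)
            dend = community.upgma(dist)
            k = config.k
            if k is not None:
                k = min(k, len(profiles))
            labels = community.cut_clusters(dend, k=k, height=config.cut_height)
            results["dendrogram"] = dend
            results["clusters"] = labels
            (outdir / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
            written.append(outdir / "dendrogram.nwk")
            emit("clusters.tsv", io.write_cluster_labels, labels)

            # envtest
            if config.station_meta is not None:
                meta = io.read_station_meta(config.station_meta)
                env_reports = {}
                for variable in config.env_variables:
                    report = community.compare_clusters_env(
                        labels, meta, variable,
                        adjust=config.adjust, alpha=config.alpha,
                    )
                    env_reports[variable] = report
                results["env_tests"] = env_reports
                summary = []
                for variable, rep in env_reports.items():
                    if not rep.testable:
                        summary.append(
                            {"variable": variable, "testable": 0, "H": "NA",
                             "p": "NA", "letters": rep.reason}
                        )
                    else:
                        letters = ";".join(
                            f"{k}={v}" for k, v in sorted(rep.letters.items())
                        )
                        summary.append(
                            {"variable": variable, "testable": 1,
                             "H": round(rep.h_statistic, 4),
                             "p": format(rep.p_value, ".3e"), "letters": letters}
                        )
                pd.DataFrame(summary).to_csv(
                    outdir / "env_tests.tsv", sep="\t", index=False
                )
                written.append(outdir / "env_tests.tsv")

        # growth (independent branch)
        if config.growth_curves is not None:
            from .growth import fit_exponential_rate, fit_strain

            curves = io.curves_from_frame(io.read_growth_curves(config.growth_curves))
            rates = [fit_exponential_rate(c) for c in curves]
            emit("rates.tsv", io.write_rates, rates)
            reports = []
            by_strain: dict[str, list] = {}
            for r in rates:
                by_strain.setdefault(r.strain, []).append(r)
            for strain in sorted(by_strain):
                reports.append(
                    fit_strain(
                        by_strain[strain],
                        n_bootstrap=config.n_bootstrap,
                        seed=config.seed,
                    )
                )
            results["growth_fits"] = reports
            emit("growth_fits.tsv", io.write_fit_reports, reports)

        manifest = config.manifest()
        manifest["outputs"] = [p.name for p in written]
        manifest["removed_stations"] = results.get("removed_stations", [])
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        results["manifest"] = manifest
        return results
    except StageError:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise
    except SynrecruitError as exc:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise StageError("pipeline", exc) from exc
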