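"""Readers and writers for the package's external tabular formats.

One TSV dialect throughout: tab-separated, UTF-8, ``NA`` for missing values,
``.`` decimal separator, header rows everywhere except tabular alignment hit
files, which follow the headerless BLAST outfmt-6 convention (12 standard
columns, optional 13th ``qlen``).  Hit files may be gzip-compressed; reading
is transparent.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .recruitment import AlignmentHit, ReadAssignment
from .taxonomy import TaxonomyTree, build_taxonomy

logger = logging.getLogger(__name__)

TAXONOMY_COLUMNS = [
    "strain_id", "subclade", "clade", "subcluster", "genus",
    "genome_length_bp", "outgroup",
]
META_COLUMNS = [
    "station_id", "temperature_C", "salinity_psu", "lat", "lon", "dist_coast_nm",
]
CURVE_COLUMNS = ["strain", "temperature_C", "replicate", "time_days", "cells_per_ml"]
RATE_COLUMNS = ["strain", "temperature_C", "mu_per_day", "stderr", "n_points"]


def _open_text(path: Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def read_taxonomy(path) -> TaxonomyTree:
    """Read a strain taxonomy TSV and build the tree."""
    table = pd.read_csv(path, sep="\t", dtype={"strain_id": str}, na_values=["NA"])
    missing = set(TAXONOMY_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigurationError(f"taxonomy file lacks columns: {sorted(missing)}")
    records = [
        (
            row.strain_id,
            None if pd.isna(row.subclade) else str(row.subclade),
            None if pd.isna(row.clade) else str(row.clade),
            None if pd.isna(row.subcluster) else str(row.subcluster),
            None if pd.isna(row.genus) else str(row.genus),
            int(row.genome_length_bp),
            bool(row.outgroup),
        )
        for row in table.itertuples()
    ]
    return build_taxonomy(records)


def write_taxonomy(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Alignment hit tables (headerless outfmt-6 + optional qlen)
# ---------------------------------------------------------------------------


class HitReadStats:
    """Row counters populated while streaming a hit table."""

    def __init__(self) -> None:
        self.rows = 0
        self.malformed = 0


def read_hit_table(
    path,
    read_lengths: Optional[dict[str, int]] = None,
    stats: Optional[HitReadStats] = None,
) -> Iterator[AlignmentHit]:
    """Lazily yield validated hits from a 12/13-column tabular alignment file.

    A 13th column is taken as the query length; without it, per-read lengths
    must be supplied via ``read_lengths``.  Malformed lines are skipped with
    a warning and counted in ``stats``.
    """
    stats = stats if stats is not None else HitReadStats()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                stats.malformed += 1
                logger.warning("%s:%d: expected 12/13 columns, got %d",
                               path, lineno, len(fields))
                continue
            try:
                read_id = fields[0]
                if len(fields) == 13:
                    qlen = int(fields[12])
                elif read_lengths is not None:
                    qlen = int(read_lengths[read_id])
                else:
                    raise ConfigurationError(
                        f"{path}: hit table has no qlen column and no "
                        "read-length table was provided"
                    )
                hit = AlignmentHit(
                    read_id=read_id,
                    genome_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    read_length=qlen,
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                ).validate()
            except ConfigurationError:
                raise
            except (ValidationError, KeyError, ValueError) as exc:
                stats.malformed += 1
                logger.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
                continue
            stats.rows += 1
            yield hit


def hits_from_frame(frame: pd.DataFrame) -> list[AlignmentHit]:
    """Convert an in-memory outfmt-6(+qlen) frame to validated hits."""
    return [
        AlignmentHit(
            read_id=str(r.qseqid),
            genome_id=str(r.sseqid),
            percent_identity=float(r.pident),
            alignment_length=int(r.length),
            read_length=int(r.qlen),
            e_value=float(r.evalue),
            bit_score=float(r.bitscore),
        ).validate()
        for r in frame.itertuples()
    ]


def write_hit_table(frame: pd.DataFrame, path) -> None:
    """Write an outfmt-6(+qlen) hit table (headerless, tab-separated)."""
    frame.to_csv(path, sep="\t", index=False, header=False)


def read_read_lengths(path) -> dict[str, int]:
    table = pd.read_csv(path, sep="\t", header=None, names=["read_id", "length"])
    return dict(zip(table["read_id"].astype(str), table["length"].astype(int)))


# ---------------------------------------------------------------------------
# Assignments
# ---------------------------------------------------------------------------


def write_assignments(assignments: Iterable[ReadAssignment], path) -> None:
    rows = [
        {
            "read_id": a.read_id,
            "taxon_id": a.taxon.id,
            "rank": a.taxon.rank,
            "n_candidates": a.n_candidate_hits,
        }
        for a in assignments
    ]
    pd.DataFrame(
        rows, columns=["read_id", "taxon_id", "rank", "n_candidates"]
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path, tree: TaxonomyTree) -> list[ReadAssignment]:
    table = pd.read_csv(path, sep="\t", dtype={"read_id": str, "taxon_id": str})
    return [
        ReadAssignment(row.read_id, tree.node(row.taxon_id), int(row.n_candidates))
        for row in table.itertuples()
    ]


# ---------------------------------------------------------------------------
# Count tables, profiles, metadata, cluster labels
# ---------------------------------------------------------------------------


def read_count_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.index.name = "station_id"
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "station_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_station_meta(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"station_id": str})
    missing = set(META_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigurationError(f"station metadata lacks columns: {sorted(missing)}")
    bad_lat = table["lat"].dropna().abs() > 90
    if bad_lat.any():
        raise ValidationError("latitudes outside [-90, 90]")
    if (table["salinity_psu"].dropna() < 0).any():
        raise ValidationError("negative salinities")
    return table.set_index("station_id")


def write_station_meta(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index() if meta.index.name == "station_id" else meta
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_cluster_labels(labels: pd.Series, path) -> None:
    labels.rename_axis("station_id").rename("cluster").to_csv(path, sep="\t")


def read_cluster_labels(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype={"station_id": str})
    return table.set_index("station_id")["cluster"]


# ---------------------------------------------------------------------------
# Growth curves and rates
# ---------------------------------------------------------------------------


def read_growth_curves(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"strain": str})
    missing = set(CURVE_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigurationError(f"growth-curve file lacks columns: {sorted(missing)}")
    return table


def write_growth_curves(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def curves_from_frame(table: pd.DataFrame):
    """Group a long-format curve table into GrowthCurve objects."""
    from .growth import GrowthCurve

    curves = []
    for (strain, temp, rep), group in table.groupby(
        ["strain", "temperature_C", "replicate"], sort=True
    ):
        group = group.sort_values("time_days")
        curves.append(
            GrowthCurve(
                str(strain), float(temp), int(rep),
                group["time_days"].to_numpy(),
                group["cells_per_ml"].to_numpy(),
            )
        )
    return curves


def write_rates(rates, path) -> None:
    rows = [
        {
            "strain": r.strain,
            "temperature_C": r.temperature,
            "mu_per_day": r.mu,
            "stderr": r.stderr,
            "n_points": r.n_points,
        }
        for r in rates
    ]
    pd.DataFrame(rows, columns=RATE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_fit_reports(reports, path) -> None:
    """Write per-strain cardinal-temperature fit summaries."""
    rows = []
    for r in reports:
        ci = r.ci
        rows.append(
            {
                "strain": r.strain,
                "Topt_measured": r.t_opt_measured,
                "Topt_model": round(r.params.t_opt, 2),
                "Topt_lo": round(ci["t_opt"][0], 2) if "t_opt" in ci else "NA",
                "Topt_hi": round(ci["t_opt"][1], 2) if "t_opt" in ci else "NA",
                "Tmax_measured": r.t_max_measured,
                "Tmax_model": round(r.params.t_max, 2),
                "Tmax_lo": round(ci["t_max"][0], 2) if "t_max" in ci else "NA",
                "Tmax_hi": round(ci["t_max"][1], 2) if "t_max" in ci else "NA",
                "mu_opt": round(r.params.mu_opt, 3),
                "rss": round(r.params.rss, 6),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
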