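"""Ground-truth-labelled synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the analysis assumes rather
than sequences themselves: alignment hits are drawn directly as (identity,
aligned length, bit score) tuples, because the assignment logic consumes
only those statistics.  Identity bands are clade-structured — a read's
source strain scores highest, other strains of the same clade fall in a
slightly lower band, strains of other clades stay below the 80% identity
discontinuity that separates clades, and outgroup genomes lower still.  Bit
scores follow the monotone stand-in ``2 * aligned_length * (identity/100 -
0.5)`` floored at 30.

Station communities are drawn from regime compositions (e.g. a cold,
clade I/IV-dominated regime versus a warm, clade II/III-dominated one)
perturbed by Dirichlet noise, with temperature and salinity drawn per
regime.  Growth curves follow N(t) = N0 * exp(mu(T) * t) capped at a
carrying capacity, with mu(T) from the CTMI response and multiplicative
lognormal measurement noise.

All generators are deterministic: the same (config, seed) yields identical
tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .growth import CardinalParams, ctmi_mu
from .taxonomy import TaxonomyTree, build_taxonomy

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
         "XI", "XII", "XIII", "XIV", "XV"]
SUBCLADE_SUFFIX = "abcdefghijklmnopqrstuvwxyz"

BITSCORE_FLOOR = 30.0


def bitscore(aligned_length: float, identity: float) -> float:
    """Monotone stand-in for an alignment bit score."""
    return max(2.0 * aligned_length * (identity / 100.0 - 0.5), BITSCORE_FLOOR)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class TaxonomySpec:
    n_clades: int = 4
    strains_per_clade: int = 2
    genome_length_range: tuple[int, int] = (2_100_000, 2_800_000)
    n_outgroup: int = 3
    subcluster: str = "5.1"
    genus: str = "Synechococcus"


@dataclass
class ReadModel:
    """Read length and clade-structured identity bands (percent identity)."""

    mean_length: float = 242.0      # bp, matches the coastal metagenome reads
    sd_length: float = 15.0
    min_length: int = 100
    within_strain: tuple[float, float] = (97.5, 100.0)
    within_clade: tuple[float, float] = (95.0, 96.5)
    cross_clade: tuple[float, float] = (70.0, 78.0)
    outgroup_band: tuple[float, float] = (65.0, 75.0)
    aligned_fraction: tuple[float, float] = (0.92, 1.0)
    clade_ambiguity: float = 0.2    # fraction of reads equally close to 2 strains
    outgroup_fraction: float = 0.0  # pass-1 best hits landing on outgroup genomes
    frac_low_qcov: float = 0.0      # pass-1 hits covering <90% of the read
    frac_high_evalue: float = 0.0   # pass-1 hits with e-value above the bound
    n_cross_clade_hits: int = 2

    def validate(self) -> "ReadModel":
        if not (
            self.within_strain[0] >= self.within_clade[0]
            and self.within_clade[0] > self.cross_clade[1]
        ):
            raise ValidationError(
                "identity bands must satisfy within-strain >= within-clade "
                "> cross-clade"
            )
        fractions = (
            self.outgroup_fraction + self.frac_low_qcov + self.frac_high_evalue
        )
        if fractions > 1.0:
            raise ValidationError("pass-1 failure fractions exceed 1")
        return self


@dataclass
class Regime:
    name: str
    composition: dict[str, float]           # clade -> fraction, sums to 1
    temperature: tuple[float, float]        # mean, sd (deg C)
    salinity: tuple[float, float] = (35.0, 1.0)  # mean, sd (psu)
    latitude: tuple[float, float] = (45.0, 5.0)


@dataclass
class StationModel:
    regimes: list[Regime] = field(
        default_factory=lambda: [
            Regime(
                "cold",
                {"I": 0.55, "IV": 0.30, "II": 0.08, "III": 0.07},
                temperature=(12.0, 1.5),
                salinity=(34.0, 1.0),
                latitude=(55.0, 4.0),
            ),
            Regime(
                "warm",
                {"I": 0.07, "IV": 0.08, "II": 0.30, "III": 0.55},
                temperature=(25.0, 1.5),
                salinity=(37.5, 0.8),
                latitude=(35.0, 4.0),
            ),
        ]
    )
    n_stations_per_regime: int = 10
    reads_per_station: int = 3000
    dirichlet_concentration: float = 200.0
    n_shallow: int = 0              # stations planted below the density floor
    shallow_reads: int = 400


@dataclass
class GrowthModel:
    strains: dict[str, CardinalParams] = field(
        default_factory=lambda: {
            "cold-I": CardinalParams(2.0, 24.0, 28.0, 0.75),
            "warm-II": CardinalParams(8.0, 29.0, 32.5, 0.90),
        }
    )
    temperatures: tuple[float, ...] = tuple(float(t) for t in range(10, 34, 3))
    replicates: int = 3
    noise_cv: float = 0.05          # coefficient of variation of cell counts
    n0: float = 1e6                 # inoculum, cells/mL
    carrying_capacity: float = 5e8  # cells/mL
    sampling_times: tuple[float, ...] = tuple(float(t) for t in range(15))


@dataclass
class SimulationConfig:
    seed: int = 0
    taxonomy: TaxonomySpec = field(default_factory=TaxonomySpec)
    reads: ReadModel = field(default_factory=ReadModel)
    stations: StationModel = field(default_factory=StationModel)
    growth: GrowthModel = field(default_factory=GrowthModel)


# ---------------------------------------------------------------------------
# Reference taxonomy
# ---------------------------------------------------------------------------


def simulate_reference_set(
    cfg: SimulationConfig, seed: Optional[int] = None
) -> tuple[TaxonomyTree, pd.DataFrame]:
    """Generate a strain-resolved reference taxonomy with an outgroup subtree.

    Returns the built tree and the corresponding taxonomy table (one row per
    strain, ``NA`` for the outgroup strains' in-group ranks).
    """
    spec = cfg.taxonomy
    if spec.n_clades < 1:
        raise ValidationError("need at least one clade")
    if spec.n_clades > len(ROMAN):
        raise ValidationError(f"at most {len(ROMAN)} clades supported")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = spec.genome_length_range
    rows = []
    for c in range(spec.n_clades):
        clade = ROMAN[c]
        for s in range(spec.strains_per_clade):
            subclade = f"{clade}{SUBCLADE_SUFFIX[s]}"
            rows.append(
                {
                    "strain_id": f"SYN-{clade}-{s + 1}",
                    "subclade": subclade,
                    "clade": clade,
                    "subcluster": spec.subcluster,
                    "genus": spec.genus,
                    "genome_length_bp": int(rng.integers(lo, hi + 1)),
                    "outgroup": 0,
                }
            )
    for o in range(spec.n_outgroup):
        rows.append(
            {
                "strain_id": f"OUT-{o + 1}",
                "subclade": "NA",
                "clade": "NA",
                "subcluster": "NA",
                "genus": "NA",
                "genome_length_bp": int(rng.integers(lo, hi + 1)),
                "outgroup": 1,
            }
        )
    table = pd.DataFrame(rows)
    tree = build_taxonomy(
        [
            (
                r.strain_id,
                None if r.subclade == "NA" else r.subclade,
                None if r.clade == "NA" else r.clade,
                None if r.subcluster == "NA" else r.subcluster,
                None if r.genus == "NA" else r.genus,
                r.genome_length_bp,
                bool(r.outgroup),
            )
            for r in table.itertuples()
        ]
    )
    return tree, table


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen",
]


def _hit_row(
    read_id: str,
    genome_id: str,
    identity: float,
    aligned: int,
    qlen: int,
    evalue: float,
    rng: np.random.Generator,
) -> dict:
    mismatch = int(round(aligned * (1.0 - identity / 100.0)))
    sstart = int(rng.integers(1, 2_000_000))
    return {
        "qseqid": read_id,
        "sseqid": genome_id,
        "pident": round(identity, 2),
        "length": aligned,
        "mismatch": mismatch,
        "gapopen": 0,
        "qstart": 1,
        "qend": aligned,
        "sstart": sstart,
        "send": sstart + aligned - 1,
        "evalue": evalue,
        "bitscore": round(bitscore(aligned, identity), 1),
        "qlen": qlen,
    }


def simulate_hit_tables(
    cfg: SimulationConfig,
    tree: TaxonomyTree,
    composition: Mapping[str, float],
    n_reads: int,
    seed: int,
    read_prefix: str = "read",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the two-pass hit tables for one sample.

    ``composition`` maps clade labels to fractions summing to 1.  Returns
    (pass1, pass2, truth, plan): the truth table carries each read's true
    strain and clade plus the expected pass-1 fate, and ``plan`` counts how
    many reads were planted to fail each pass-1 filter.
    """
    rm = cfg.reads.validate()
    clades = sorted(composition)
    fractions = np.array([composition[c] for c in clades], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError("composition fractions must sum to 1")
    strains_by_clade = {}
    for c in clades:
        if c not in tree.nodes or not tree.strains_under(c):
            raise ValidationError(f"composition references unknown clade {c!r}")
        strains_by_clade[c] = sorted(tree.strains_under(c))
    outgroup_strains = sorted(
        s for s, info in tree.strains.items() if info.outgroup
    )
    if rm.outgroup_fraction > 0 and not outgroup_strains:
        raise ValidationError("outgroup_fraction > 0 but taxonomy has no outgroup")
    all_ingroup = sorted(tree.ingroup_strains())

    rng = np.random.default_rng(seed)
    fates = rng.choice(
        4,
        size=n_reads,
        p=[
            1.0 - rm.outgroup_fraction - rm.frac_low_qcov - rm.frac_high_evalue,
            rm.outgroup_fraction,
            rm.frac_low_qcov,
            rm.frac_high_evalue,
        ],
    )
    fate_names = np.array(["ok", "outgroup", "low_qcov", "high_evalue"])
    clade_idx = rng.choice(len(clades), size=n_reads, p=fractions)

    pass1_rows, pass2_rows, truth_rows = [], [], []
    for i in range(n_reads):
        read_id = f"{read_prefix}{i:06d}"
        qlen = int(max(rm.min_length, round(rng.normal(rm.mean_length, rm.sd_length))))
        clade = clades[clade_idx[i]]
        members = strains_by_clade[clade]
        source = members[rng.integers(len(members))]
        fate = fate_names[fates[i]]
        aligned = int(round(qlen * rng.uniform(*rm.aligned_fraction)))
        evalue = 10.0 ** (-rng.uniform(5.0, 30.0))

        if fate == "outgroup":
            genome = outgroup_strains[rng.integers(len(outgroup_strains))]
            pass1_rows.append(
                _hit_row(read_id, genome, rng.uniform(*rm.outgroup_band),
                         aligned, qlen, evalue, rng)
            )
        elif fate == "low_qcov":
            short = int(round(qlen * rng.uniform(0.50, 0.88)))
            pass1_rows.append(
                _hit_row(read_id, source, rng.uniform(*rm.within_strain),
                         max(short, 30), qlen, evalue, rng)
            )
        elif fate == "high_evalue":
            pass1_rows.append(
                _hit_row(read_id, source, rng.uniform(*rm.within_strain),
                         aligned, qlen, rng.uniform(2e-3, 1e-1), rng)
            )
        else:  # retained; gets second-pass hits
            ambiguous = len(members) >= 2 and rng.random() < rm.clade_ambiguity
            if ambiguous:
                top_identity = rng.uniform(*rm.within_clade)
            else:
                top_identity = rng.uniform(*rm.within_strain)
            pass1_rows.append(
                _hit_row(read_id, source, top_identity, aligned, qlen, evalue, rng)
            )
            pass2_rows.append(
                _hit_row(read_id, source, top_identity, aligned, qlen, evalue, rng)
            )
            for other in members:
                if other == source:
                    continue
                if ambiguous:
                    ident = max(
                        top_identity - rng.uniform(0.0, 0.4), rm.within_clade[0]
                    )
                else:
                    ident = rng.uniform(*rm.within_clade)
                pass2_rows.append(
                    _hit_row(read_id, other, ident, aligned, qlen,
                             evalue * 10.0, rng)
                )
            others = [s for s in all_ingroup if s not in members]
            if others and rm.n_cross_clade_hits > 0:
                picks = rng.choice(
                    len(others),
                    size=min(rm.n_cross_clade_hits, len(others)),
                    replace=False,
                )
                for p in sorted(picks):
                    pass2_rows.append(
                        _hit_row(read_id, others[p],
                                 rng.uniform(*rm.cross_clade),
                                 aligned, qlen, evalue * 1e3, rng)
                    )
        truth_rows.append(
            {
                "read_id": read_id,
                "true_strain": source if fate != "outgroup" else "NA",
                "true_clade": clade if fate != "outgroup" else "NA",
                "fate": fate,
                "pass1_expected": int(fate == "ok"),
            }
        )

    pass1 = pd.DataFrame(pass1_rows, columns=OUTFMT6_COLUMNS)
    pass2 = pd.DataFrame(pass2_rows, columns=OUTFMT6_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    plan = {
        "n_reads": n_reads,
        "n_retained": int((truth["fate"] == "ok").sum()),
        "n_outgroup": int((truth["fate"] == "outgroup").sum()),
        "n_low_qcov": int((truth["fate"] == "low_qcov").sum()),
        "n_high_evalue": int((truth["fate"] == "high_evalue").sum()),
    }
    return pass1, pass2, truth, plan


# ---------------------------------------------------------------------------
# Stations
# ---------------------------------------------------------------------------


@dataclass
class StationSimulation:
    tree: TaxonomyTree
    taxonomy_table: pd.DataFrame
    hit_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]]  # sid -> (p1, p2)
    read_truth: dict[str, pd.DataFrame]
    meta: pd.DataFrame              # station metadata incl. temperature
    station_truth: pd.DataFrame    # station -> regime, depth plan


def simulate_stations(
    cfg: SimulationConfig, seed: Optional[int] = None
) -> StationSimulation:
    """Simulate a multi-station survey under regime-structured compositions.

    Stations are split evenly across regimes; each station's composition is
    a Dirichlet perturbation of its regime's composition, and its metadata
    (temperature, salinity, position) is drawn from the regime's
    distributions.  ``n_shallow`` stations (spread across regimes) receive
    ``shallow_reads`` reads instead of ``reads_per_station`` so that they
    fall below the recruitment-density floor downstream.
    """
    sm = cfg.stations
    if len(sm.regimes) < 1:
        raise ValidationError("need at least one regime")
    category_sets = {frozenset(r.composition) for r in sm.regimes}
    if len(category_sets) != 1:
        raise ValidationError("all regimes must share one clade category set")
    for r in sm.regimes:
        if abs(sum(r.composition.values()) - 1.0) > 1e-9:
            raise ValidationError(f"regime {r.name!r} composition must sum to 1")

    root_seed = cfg.seed if seed is None else seed
    seq = np.random.SeedSequence(root_seed)
    tax_seed, meta_seed, *station_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(
            2 + len(sm.regimes) * sm.n_stations_per_regime
        )
    ]
    tree, tax_table = simulate_reference_set(cfg, seed=tax_seed)
    meta_rng = np.random.default_rng(meta_seed)

    clades = sorted(sm.regimes[0].composition)
    n_total = len(sm.regimes) * sm.n_stations_per_regime
    shallow_ids = set(range(0, n_total, max(n_total // max(sm.n_shallow, 1), 1))[: sm.n_shallow]) if sm.n_shallow else set()

    hit_tables, read_truth = {}, {}
    meta_rows, truth_rows = [], []
    idx = 0
    for regime in sm.regimes:
        base = np.array([regime.composition[c] for c in clades])
        for _ in range(sm.n_stations_per_regime):
            sid = f"S{idx + 1:02d}"
            shallow = idx in shallow_ids
            comp = meta_rng.dirichlet(sm.dirichlet_concentration * base)
            comp = comp / comp.sum()
            composition = dict(zip(clades, comp))
            n_reads = sm.shallow_reads if shallow else sm.reads_per_station
            p1, p2, truth, _ = simulate_hit_tables(
                cfg, tree, composition, n_reads, station_seeds[idx],
                read_prefix=f"{sid}_r",
            )
            hit_tables[sid] = (p1, p2)
            read_truth[sid] = truth
            meta_rows.append(
                {
                    "station_id": sid,
                    "temperature_C": round(meta_rng.normal(*regime.temperature), 2),
                    "salinity_psu": round(meta_rng.normal(*regime.salinity), 2),
                    "lat": round(meta_rng.normal(*regime.latitude), 3),
                    "lon": round(meta_rng.uniform(-15.0, 35.0), 3),
                    "dist_coast_nm": round(float(meta_rng.lognormal(-1.0, 1.2)), 2),
                }
            )
            truth_rows.append(
                {"station_id": sid, "regime": regime.name, "planted_shallow": int(shallow)}
            )
            idx += 1
    meta = pd.DataFrame(meta_rows).set_index("station_id")
    station_truth = pd.DataFrame(truth_rows).set_index("station_id")
    return StationSimulation(tree, tax_table, hit_tables, read_truth, meta, station_truth)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


def simulate_growth_curves(
    cfg: SimulationConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, dict[str, CardinalParams]]:
    """Simulate strain x temperature x replicate growth time series.

    Cultures grow exponentially at the CTMI rate for their temperature until
    the carrying capacity, with multiplicative lognormal noise on every cell
    count.  Returns the long-format curve table and the true parameters.
    """
    gm = cfg.growth
    for name, params in gm.strains.items():
        params.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sigma = float(np.sqrt(np.log1p(gm.noise_cv**2)))
    times = np.asarray(gm.sampling_times, dtype=float)
    rows = []
    for strain in sorted(gm.strains):
        params = gm.strains[strain]
        for temp in gm.temperatures:
            mu = ctmi_mu(temp, params)
            for rep in range(1, gm.replicates + 1):
                ideal = np.minimum(gm.n0 * np.exp(mu * times), gm.carrying_capacity)
                if sigma > 0:
                    noise = rng.lognormal(mean=0.0, sigma=sigma, size=times.size)
                else:
                    noise = 1.0
                observed = ideal * noise
                for t, n_obs in zip(times, observed):
                    rows.append(
                        {
                            "strain": strain,
                            "temperature_C": float(temp),
                            "replicate": rep,
                            "time_days": float(t),
                            "cells_per_ml": float(n_obs),
                        }
                    )
    return pd.DataFrame(rows), dict(gm.strains)


def minimal_config(seed: int = 0) -> SimulationConfig:
    """Small, fast preset for smoke tests and the worked example."""
    cfg = SimulationConfig(seed=seed)
    cfg.stations = replace(
        cfg.stations, n_stations_per_regime=3, reads_per_station=2000
    )
    cfg.growth = replace(
        cfg.growth,
        strains={"cold-I": CardinalParams(2.0, 24.0, 28.0, 0.75)},
        replicates=2,
    )
    return cfg
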