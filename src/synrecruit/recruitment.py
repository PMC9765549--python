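"""Two-pass filtering of read-vs-genome alignment hits and per-read LCA assignment.

The assignment mirrors a whole-genome-recruitment workflow run in two
alignment passes:

* **Pass 1** (screen against the full reference database, best hit only):
  a read is carried forward when its best hit targets a picocyanobacterial
  (in-group) genome with e-value below 1e-3 and covers at least 90% of the
  read length.  Reads whose best hit lands on an outgroup genome are
  discarded regardless of score.
* **Pass 2** (multi-target alignment against in-group genomes only): for each
  retained read, hits with identity >= 80%, query coverage >= 90% and bit
  score within 5% of the read's best bit score form the candidate set; the
  read is attributed to the lowest common ancestor of the candidate strains.

Boundary policy: comparative filters are inclusive (>= 80 identity,
>= 0.90 coverage, >= 0.95 x best score); the e-value bound is strict
(< 1e-3).  Aligned fraction uses the full read length as denominator.
"Score" in the 5% window means the bit score.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ValidationError
from .taxonomy import ROOT_ID, TaxonNode, TaxonomyTree, lowest_common_ancestor

logger = logging.getLogger(__name__)

#: alignment_length may exceed read_length by at most this factor (gap columns)
GAP_SLACK = 1.10


@dataclass(frozen=True)
class AlignmentHit:
    """One aligned read-vs-genome match (one row of a tabular hit file)."""

    read_id: str
    genome_id: str
    percent_identity: float
    alignment_length: int
    read_length: int
    e_value: float
    bit_score: float

    def validate(self) -> "AlignmentHit":
        if self.read_length <= 0:
            raise ValidationError(
                f"read {self.read_id!r}: non-positive read length {self.read_length}"
            )
        if self.alignment_length <= 0:
            raise ValidationError(
                f"read {self.read_id!r}: non-positive alignment length"
            )
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"read {self.read_id!r}: percent identity {self.percent_identity} "
                "outside [0, 100]"
            )
        if self.alignment_length > GAP_SLACK * self.read_length:
            raise ValidationError(
                f"read {self.read_id!r}: alignment length {self.alignment_length} "
                f"exceeds read length {self.read_length} beyond gap slack"
            )
        if self.e_value < 0 or self.bit_score <= 0:
            raise ValidationError(
                f"read {self.read_id!r}: invalid e-value or bit score"
            )
        return self

    @property
    def aligned_fraction(self) -> float:
        return self.alignment_length / self.read_length


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    taxon: TaxonNode
    n_candidate_hits: int


@dataclass
class Thresholds:
    """Filter thresholds; defaults reproduce the published workflow."""

    max_evalue: float = 1e-3
    min_identity: float = 80.0
    min_qcov: float = 0.90
    score_window: float = 0.05

    def validate(self) -> "Thresholds":
        if not 0 <= self.min_identity <= 100:
            raise ValidationError("min_identity must be in [0, 100]")
        if not 0 <= self.min_qcov <= 1:
            raise ValidationError("min_qcov must be in [0, 1]")
        if not 0 <= self.score_window < 1:
            raise ValidationError("score_window must be in [0, 1)")
        if self.max_evalue < 0:
            raise ValidationError("max_evalue must be non-negative")
        return self


@dataclass
class AssignmentLog:
    """Bookkeeping counters for one assignment run (read conservation)."""

    input_reads: int = 0
    assigned: int = 0
    unassigned_empty: int = 0
    unassigned_outgroup: int = 0
    missing_pass2: int = 0
    malformed_rows: int = 0
    assigned_per_rank: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        d = {
            "input_reads": self.input_reads,
            "assigned": self.assigned,
            "unassigned_empty": self.unassigned_empty,
            "unassigned_outgroup": self.unassigned_outgroup,
            "missing_pass2": self.missing_pass2,
            "malformed_rows": self.malformed_rows,
        }
        d.update({f"assigned_{r}": n for r, n in sorted(self.assigned_per_rank.items())})
        return d


def best_hit(hits: Iterable[AlignmentHit]) -> AlignmentHit:
    """Deterministic best-hit reduction: max bit score, ties broken by min
    e-value, then lexicographic genome id."""
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, h.genome_id))


def pass1_retained_reads(
    hits: Iterable[AlignmentHit],
    tree: TaxonomyTree,
    thresholds: Optional[Thresholds] = None,
) -> set[str]:
    """Read ids surviving the first-pass screen.

    Each read is reduced to its best hit; the read is retained when that hit
    has e-value below the bound, targets a non-outgroup genome, and covers at
    least ``min_qcov`` of the read.
    """
    th = (thresholds or Thresholds()).validate()
    per_read: dict[str, AlignmentHit] = {}
    for hit in hits:
        hit.validate()
        prev = per_read.get(hit.read_id)
        if prev is None:
            per_read[hit.read_id] = hit
        else:
            per_read[hit.read_id] = best_hit((prev, hit))
    retained = set()
    for read_id, hit in per_read.items():
        tree.strain_for_genome(hit.genome_id)  # raises for unknown genomes
        if hit.e_value >= th.max_evalue:
            continue
        if tree.is_outgroup(tree.strain_for_genome(hit.genome_id)):
            continue
        if hit.aligned_fraction < th.min_qcov:
            continue
        retained.add(read_id)
    return retained


def candidate_hits(
    read_hits: list[AlignmentHit],
    thresholds: Optional[Thresholds] = None,
) -> list[AlignmentHit]:
    """Second-pass candidate set for one read.

    Keeps hits with identity >= ``min_identity``, aligned fraction >=
    ``min_qcov`` and bit score within ``score_window`` of the read's best bit
    score.  May be empty, in which case the read stays unassigned.
    """
    th = (thresholds or Thresholds()).validate()
    if not read_hits:
        raise ValidationError("candidate_hits requires at least one hit")
    read_ids = {h.read_id for h in read_hits}
    if len(read_ids) > 1:
        raise ValidationError(f"hits mix several read ids: {sorted(read_ids)}")
    top = max(h.bit_score for h in read_hits)
    floor = (1.0 - th.score_window) * top
    return [
        h
        for h in read_hits
        if h.percent_identity >= th.min_identity
        and h.aligned_fraction >= th.min_qcov
        and h.bit_score >= floor
    ]


def assign_read(
    read_hits: list[AlignmentHit],
    tree: TaxonomyTree,
    thresholds: Optional[Thresholds] = None,
) -> Optional[ReadAssignment]:
    """LCA assignment of one read from its second-pass hits.

    Returns ``None`` (unassigned) when the candidate set is empty, includes
    an outgroup strain, or its LCA falls above the genus.
    """
    candidates = candidate_hits(read_hits, thresholds)
    if not candidates:
        return None
    strains = {tree.strain_for_genome(h.genome_id) for h in candidates}
    if any(tree.is_outgroup(s) for s in strains):
        return None
    taxon = lowest_common_ancestor(tree, strains)
    if taxon.id == ROOT_ID or taxon.rank in ("root", "outgroup"):
        return None
    return ReadAssignment(read_hits[0].read_id, taxon, len(candidates))


def assign_all(
    pass1_reads: set[str],
    pass2_hits: Iterable[AlignmentHit],
    tree: TaxonomyTree,
    thresholds: Optional[Thresholds] = None,
) -> tuple[list[ReadAssignment], AssignmentLog]:
    """Assign every first-pass-retained read from the second-pass hit stream.

    Hits for reads absent from ``pass1_reads`` are ignored.  Returns the
    assignments and a log of counters satisfying
    ``input_reads == assigned + unassigned_empty + unassigned_outgroup +
    missing_pass2``.
    """
    th = (thresholds or Thresholds()).validate()
    log = AssignmentLog(input_reads=len(pass1_reads))
    grouped: dict[str, list[AlignmentHit]] = defaultdict(list)
    for hit in pass2_hits:
        if hit.read_id not in pass1_reads:
            continue
        try:
            grouped[hit.read_id].append(hit.validate())
        except ValidationError as exc:
            log.malformed_rows += 1
            logger.warning("skipping malformed hit row: %s", exc)

    assignments: list[ReadAssignment] = []
    for read_id in sorted(pass1_reads):
        hits = grouped.get(read_id)
        if not hits:
            log.missing_pass2 += 1
            continue
        candidates = candidate_hits(hits, th)
        if not candidates:
            log.unassigned_empty += 1
            continue
        strains = {tree.strain_for_genome(h.genome_id) for h in candidates}
        if any(tree.is_outgroup(s) for s in strains):
            log.unassigned_outgroup += 1
            continue
        taxon = lowest_common_ancestor(tree, strains)
        if taxon.rank in ("root", "outgroup"):
            log.unassigned_outgroup += 1
            continue
        assignments.append(ReadAssignment(read_id, taxon, len(candidates)))
        log.assigned += 1
        log.assigned_per_rank[taxon.rank] += 1
    return assignments, log
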