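"""Assignment of SNPs to their closest gene.

Every genotyped SNP is assigned to the nearest gene locus on the same
chromosome (distance 0 when the SNP lies inside the locus, otherwise the
bp distance to the nearer boundary).  The mapping drives association-graph
construction: each SNP pair becomes a triple of (endpoint gene, endpoint
gene, trait gene).

Deterministic tie-breaks, since coordinates can tie:

* equal distance to two loci -> the locus with the smaller start wins;
* SNP inside two overlapping loci -> the smaller-span locus wins
  (more specific annotation), span tie -> smaller start.

SNPs on a chromosome with no annotated gene, or without coordinates at
all, stay UNASSIGNED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .domain import GeneLocus, SnpMeta

logger = logging.getLogger(__name__)

UNASSIGNED = None


@dataclass
class SnpGeneMap:
    """Result of closest-gene assignment.

    ``assignments`` maps snp_id -> gene name (or ``None`` = UNASSIGNED);
    ``distances`` maps snp_id -> bp distance (0 inside the locus), absent
    for unassigned SNPs.
    """

    assignments: dict[str, Optional[str]]
    distances: dict[str, int]
    ties: list[str] = field(default_factory=list)

    def gene_of(self, snp_id: str) -> Optional[str]:
        return self.assignments.get(snp_id)

    @property
    def n_unassigned(self) -> int:
        return sum(1 for g in self.assignments.values() if g is None)

    def snps_of_gene(self, gene: str) -> list[str]:
        return sorted(s for s, g in self.assignments.items() if g == gene)


def _best_locus(pos: int, candidates: list[GeneLocus]) -> tuple[GeneLocus, int, bool]:
    """Pick the closest locus with the declared tie-breaks.

    Returns (locus, distance, tied) where ``tied`` records that another
    locus was equally good before tie-breaking.
    """
    containing = [loc for loc in candidates if loc.contains(pos)]
    if containing:
        best = min(containing, key=lambda loc: (loc.span, loc.start))
        return best, 0, len(containing) > 1
    dists = [(loc.distance(pos), loc.start, loc) for loc in candidates]
    dmin = min(d for d, _, _ in dists)
    at_min = sorted(((s, loc) for d, s, loc in dists if d == dmin),
                    key=lambda t: t[0])
    return at_min[0][1], dmin, len(at_min) > 1


def assign_snps_to_genes(
    snps: list[SnpMeta],
    loci: list[GeneLocus],
    max_dist: Optional[int] = None,
) -> SnpGeneMap:
    """Assign every SNP to its closest same-chromosome gene.

    ``max_dist``, if given, unassigns SNPs farther than that many bp from
    every locus (no cutoff by default).  The result is independent of the
    order of ``loci`` and ``snps``.
    """
    if not loci:
        raise ValueError("locus table is empty")
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)

    assignments: dict[str, Optional[str]] = {}
    distances: dict[str, int] = {}
    ties: list[str] = []
    for snp in snps:
        if snp.chrom is None or snp.pos is None:
            assignments[snp.snp_id] = UNASSIGNED
            continue
        candidates = by_chrom.get(snp.chrom)
        if not candidates:
            assignments[snp.snp_id] = UNASSIGNED
            continue
        locus, dist, tied = _best_locus(snp.pos, candidates)
        if max_dist is not None and dist > max_dist:
            assignments[snp.snp_id] = UNASSIGNED
            continue
        assignments[snp.snp_id] = locus.gene
        distances[snp.snp_id] = dist
        if tied:
            ties.append(snp.snp_id)
            logger.debug("tie-broken assignment for SNP %s -> %s", snp.snp_id,
                         locus.gene)
    if ties:
        logger.info("%d SNP(s) required a tie-break during gene assignment",
                    len(ties))
    n_un = sum(1 for g in assignments.values() if g is None)
    if n_un:
        logger.info("%d SNP(s) left UNASSIGNED (no same-chromosome locus)", n_un)
    return SnpGeneMap(assignments, distances, ties)
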